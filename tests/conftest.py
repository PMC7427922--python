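import numpy as np
import pandas as pd
import pytest

from phenomap import synthetic
from phenomap.cohort import VariableSchema
from phenomap.preprocess import EncodedMatrix


@pytest.fixture(scope="session")
def small_spec() -> synthetic.CohortSpec:
    """Compact 3-phenogroup cohort for fast end-to-end tests."""
    nv = synthetic.NumericVar
    cv = synthetic.CategoricalVar
    return synthetic.CohortSpec(
        n_patients=60,
        cluster_sizes=(10, 20, 30),
        numeric_vars=[
            nv("biomarker", (10.0, 5.0, 1.0), (1.0, 1.0, 1.0)),
            nv("wall_thickness", (2.0, 1.5, 1.0), (0.2, 0.2, 0.2), "cm"),
            nv("gradient", (50.0, 20.0, 10.0), (8.0, 5.0, 3.0), "mmHg"),
        ],
        categorical_vars=[
            cv("dm", ("yes", "no"), ((0.6, 0.4), (0.5, 0.5), (0.3, 0.7))),
            cv("diuretic", ("yes", "no"), ((0.7, 0.3), (0.5, 0.5), (0.4, 0.6))),
        ],
        missing_rates={"biomarker": 0.2, "dm": 0.1},
        outcome_intercept=-0.5,
        outcome_coefficients={"dm=yes": 1.0},
        hazard_params={"hfpef": (0.5, 0.2, 0.1), "death": (0.3, 0.2, 0.1)},
        censor_horizon=12.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return synthetic.generate(small_spec, seed=7)


def make_matrix(values: np.ndarray, prefix: str = "v") -> EncodedMatrix:
    """Wrap a complete numeric array as an EncodedMatrix of numeric columns."""
    values = np.array(values, dtype=float)
    return EncodedMatrix(
        values=values,
        mask=np.ones_like(values, dtype=bool),
        column_meta=[(f"{prefix}{j}", None) for j in range(values.shape[1])],
        row_ids=[f"P{i:03d}" for i in range(values.shape[0])],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
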