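"""Synthetic diastolic-dysfunction cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes: a small cohort (default 162 patients) with three latent
phenogroups of very unequal size, 46 numeric + 19 categorical clinical and
echocardiographic variables, per-variable missing-completely-at-random
masking, a logistic outcome (progression to HFpEF, prevalence near 0.5),
and right-censored times to HFpEF and death.  Nothing here attempts the
real cohort's joint distribution — only its shape and scale.

Numeric variables are Gaussian per cluster; skewed biomarkers (the
NT-proBNP-like column) may be flagged log-normal, in which case the
per-cluster location/scale are on the natural-log scale.  Event times are
Weibull (exponential at the default shape 1) with administrative censoring
at a fixed horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, VariableSchema


@dataclass
class NumericVar:
    """One numeric variable: per-cluster means and SDs (log scale if log_normal)."""

    name: str
    means: tuple[float, ...]
    sds: tuple[float, ...]
    units: str = ""
    log_normal: bool = False


@dataclass
class CategoricalVar:
    """One categorical variable: levels and one probability vector per cluster."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[tuple[float, ...], ...]  # cluster -> level probabilities


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_patients: int
    cluster_sizes: tuple[int, ...]
    numeric_vars: list[NumericVar]
    categorical_vars: list[CategoricalVar]
    missing_rates: dict[str, float] = field(default_factory=dict)
    outcome_intercept: float = 0.0
    outcome_coefficients: dict[str, float] = field(default_factory=dict)
    hazard_params: dict[str, tuple[float, ...]] = field(default_factory=dict)
    weibull_shape: float = 1.0
    censor_horizon: float = 15.0
    age_mean: float = 70.0
    age_sd: float = 10.0
    outlier_shifts: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        k = len(self.cluster_sizes)
        if sum(self.cluster_sizes) != self.n_patients:
            raise ValueError(
                f"cluster_sizes sum {sum(self.cluster_sizes)} != n_patients "
                f"{self.n_patients}"
            )
        for v in self.numeric_vars:
            if len(v.means) != k or len(v.sds) != k:
                raise ValueError(f"numeric_vars[{v.name}]: need {k} per-cluster params")
            if any(s < 0 for s in v.sds):
                raise ValueError(f"numeric_vars[{v.name}]: negative SD")
        for v in self.categorical_vars:
            if len(v.probs) != k:
                raise ValueError(
                    f"categorical_vars[{v.name}]: need {k} probability vectors"
                )
            for p in v.probs:
                if len(p) != len(v.levels):
                    raise ValueError(
                        f"categorical_vars[{v.name}]: probability vector length "
                        f"!= number of levels"
                    )
                if abs(sum(p) - 1.0) > 1e-9:
                    raise ValueError(
                        f"categorical_vars[{v.name}]: probabilities sum to "
                        f"{sum(p)}, not 1"
                    )
        names = self.variable_names()
        if len(set(names)) != len(names):
            raise ValueError("numeric_vars/categorical_vars: duplicate variable name")
        for name, rate in self.missing_rates.items():
            if name not in names:
                raise ValueError(f"missing_rates: unknown variable {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing_rates[{name}]: rate {rate} outside [0,1]")
        for key in self.outcome_coefficients:
            base = key.split("=", 1)[0]
            if base not in names:
                raise ValueError(f"outcome_coefficients: unknown variable {key!r}")
        for which, rates in self.hazard_params.items():
            if which not in ("hfpef", "death"):
                raise ValueError(f"hazard_params: unknown endpoint {which!r}")
            if len(rates) != k:
                raise ValueError(f"hazard_params[{which}]: need {k} per-cluster rates")
            if any(r <= 0 for r in rates):
                raise ValueError(f"hazard_params[{which}]: rates must be positive")

    def variable_names(self) -> list[str]:
        return [v.name for v in self.numeric_vars] + [
            v.name for v in self.categorical_vars
        ]

    def schema(self) -> list[VariableSchema]:
        out = [
            VariableSchema(v.name, "numeric", units=v.units) for v in self.numeric_vars
        ]
        out += [
            VariableSchema(v.name, "categorical", list(v.levels))
            for v in self.categorical_vars
        ]
        return out

    # -- YAML round trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "n_patients": self.n_patients,
            "cluster_sizes": list(self.cluster_sizes),
            "numeric_vars": [
                {
                    "name": v.name,
                    "means": list(v.means),
                    "sds": list(v.sds),
                    "units": v.units,
                    "log_normal": v.log_normal,
                }
                for v in self.numeric_vars
            ],
            "categorical_vars": [
                {
                    "name": v.name,
                    "levels": list(v.levels),
                    "probs": [list(p) for p in v.probs],
                }
                for v in self.categorical_vars
            ],
            "missing_rates": dict(self.missing_rates),
            "outcome_intercept": self.outcome_intercept,
            "outcome_coefficients": dict(self.outcome_coefficients),
            "hazard_params": {k: list(v) for k, v in self.hazard_params.items()},
            "weibull_shape": self.weibull_shape,
            "censor_horizon": self.censor_horizon,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "outlier_shifts": dict(self.outlier_shifts),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        p = yaml.safe_load(Path(path).read_text())
        return cls(
            n_patients=p["n_patients"],
            cluster_sizes=tuple(p["cluster_sizes"]),
            numeric_vars=[
                NumericVar(
                    v["name"],
                    tuple(v["means"]),
                    tuple(v["sds"]),
                    v.get("units", ""),
                    v.get("log_normal", False),
                )
                for v in p["numeric_vars"]
            ],
            categorical_vars=[
                CategoricalVar(
                    v["name"],
                    tuple(v["levels"]),
                    tuple(tuple(q) for q in v["probs"]),
                )
                for v in p["categorical_vars"]
            ],
            missing_rates=p.get("missing_rates", {}),
            outcome_intercept=p.get("outcome_intercept", 0.0),
            outcome_coefficients=p.get("outcome_coefficients", {}),
            hazard_params={k: tuple(v) for k, v in p.get("hazard_params", {}).items()},
            weibull_shape=p.get("weibull_shape", 1.0),
            censor_horizon=p.get("censor_horizon", 15.0),
            age_mean=p.get("age_mean", 70.0),
            age_sd=p.get("age_sd", 10.0),
            outlier_shifts=p.get("outlier_shifts", {}),
            seed=p.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# generation


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortTable:
    """Draw the patient-by-variable grid and latent cluster labels.

    Numeric values are per-cluster Gaussian (log-normal when flagged),
    categorical values per-cluster multinomial.  If ``spec.outlier_shifts``
    is set, the last generated patient's named variables are shifted by the
    given number of that cluster's SDs — a planted extreme outlier for the
    screening stage.  Fully deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = np.repeat(np.arange(len(spec.cluster_sizes)), spec.cluster_sizes)
    n = spec.n_patients
    ids = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")

    cols: dict[str, np.ndarray | pd.Series] = {}
    for v in spec.numeric_vars:
        mu = np.asarray(v.means)[labels]
        sd = np.asarray(v.sds)[labels]
        x = rng.normal(mu, sd)
        if v.log_normal:
            x = np.exp(x)
        cols[v.name] = x
    for v in spec.categorical_vars:
        out = np.empty(n, dtype=object)
        for c, p in enumerate(v.probs):
            idx = np.where(labels == c)[0]
            out[idx] = rng.choice(np.asarray(v.levels, dtype=object), size=len(idx), p=p)
        cols[v.name] = out

    data = pd.DataFrame(cols, index=ids)

    for name, shift in spec.outlier_shifts.items():
        v = next(x for x in spec.numeric_vars if x.name == name)
        c = labels[-1]
        data.iloc[-1, data.columns.get_loc(name)] = v.means[c] + shift * v.sds[c]

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 18.0, None)
    return CohortTable(
        data=data,
        age_at_dd=pd.Series(age, index=ids),
        true_cluster=pd.Series(labels, index=ids),
    )


def _covariate_value(table: CohortTable, key: str) -> np.ndarray:
    """Resolve an outcome-coefficient key to a numeric design column.

    Numeric variables are used as-is; ``"var=level"`` means the 0/1
    indicator of that level; a bare categorical name means the indicator of
    its ``"yes"`` level.
    """
    if "=" in key:
        name, level = key.split("=", 1)
    else:
        name, level = key, None
    if name not in table.data.columns:
        raise ValueError(f"outcome coefficient references unknown variable {name!r}")
    col = table.data[name]
    if col.dtype == object or level is not None:
        level = "yes" if level is None else level
        return (col == level).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def attach_outcomes(
    table: CohortTable, spec: CohortSpec, seed: int | None = None
) -> CohortTable:
    """Draw outcome and censored event times onto a (pre-masking) cohort.

    Outcome is Bernoulli with logistic probability
    ``sigmoid(intercept + sum coef * x)`` over the current (unmasked)
    values.  For progressors, time to HFpEF is Weibull truncated to the
    censoring horizon (so every progressor's event is observed within the
    study window); non-progressors are censored at the horizon.  Death for
    progressors follows the HFpEF event by an independent Weibull draw;
    everything is administratively censored at the horizon.
    """
    spec.validate()
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    n = table.n_patients
    eta = np.full(n, spec.outcome_intercept, dtype=float)
    for key, coef in spec.outcome_coefficients.items():
        eta += coef * _covariate_value(table, key)
    from scipy.special import expit

    p = expit(eta)
    outcome = (rng.uniform(size=n) < p).astype(int)

    labels = (
        table.true_cluster.to_numpy()
        if table.true_cluster is not None
        else np.zeros(n, dtype=int)
    )
    k = spec.weibull_shape
    horizon = spec.censor_horizon
    hf_rates = np.asarray(
        spec.hazard_params.get("hfpef", (0.1,) * (labels.max() + 1))
    )[labels]
    de_rates = np.asarray(
        spec.hazard_params.get("death", (0.05,) * (labels.max() + 1))
    )[labels]

    def _weibull_inv(u: np.ndarray, rate: np.ndarray) -> np.ndarray:
        return (1.0 / rate) * (-np.log1p(-u)) ** (1.0 / k)

    def _weibull_cdf(t: float, rate: np.ndarray) -> np.ndarray:
        return -np.expm1(-((rate * t) ** k))

    u = rng.uniform(size=n)
    # truncated draw for progressors: event guaranteed inside the window
    t_hf = np.where(
        outcome == 1,
        _weibull_inv(u * _weibull_cdf(horizon, hf_rates), hf_rates),
        horizon,
    )
    hf_obs = outcome == 1

    t_gap = _weibull_inv(rng.uniform(size=n), de_rates)
    t_death_raw = np.where(outcome == 1, t_hf + t_gap, t_gap)
    death_obs = t_death_raw <= horizon
    t_death = np.minimum(t_death_raw, horizon)

    ids = table.patient_ids
    out = table.copy()
    out.outcome = pd.Series(outcome, index=ids)
    out.time_to_hfpef = pd.Series(t_hf, index=ids)
    out.hfpef_observed = pd.Series(hf_obs, index=ids)
    out.time_to_death = pd.Series(t_death, index=ids)
    out.death_observed = pd.Series(death_obs, index=ids)
    out.__post_init__()
    return out


def inject_missingness(
    table: CohortTable, rates: dict[str, float], seed: int = 0
) -> CohortTable:
    """MCAR masking: each cell of a variable goes missing with its rate.

    Outcome and event-time columns are carried on the table outside the
    variable grid and are never masked.
    """
    for name, rate in rates.items():
        if name not in table.data.columns:
            raise ValueError(f"missing_rates: unknown variable {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {name!r} outside [0,1]: {rate}")
    rng = np.random.default_rng(seed + 2)
    out = table.copy()
    data = out.data.copy()
    for name, rate in rates.items():
        if rate == 0.0:
            continue
        mask = rng.uniform(size=len(data)) < rate
        data[name] = data[name].where(~mask, np.nan)
    out.data = data
    return out


def generate(spec: CohortSpec, seed: int | None = None) -> CohortTable:
    """generate_cohort -> attach_outcomes -> inject_missingness, one seed."""
    s = spec.seed if seed is None else seed
    table = generate_cohort(spec, seed=s)
    table = attach_outcomes(table, spec, seed=s)
    return inject_missingness(table, spec.missing_rates, seed=s)


# ---------------------------------------------------------------------------
# default study-scale spec


def default_spec(seed: int = 0) -> CohortSpec:
    """Cohort recipe at the study's scale.

    162 patients in three latent phenogroups of 7/59/96 (the last patient
    carries planted extreme LVOT outliers, so the outlier screen removes
    exactly one, leaving 7/59/95 for clustering).  46 numeric and 19
    categorical variables whose per-cluster locations echo the published
    phenogroup profiles (severe hypertrophy + aortic stenosis in the small
    high-risk group, female-predominant low-NT-proBNP large group, ...).
    The outcome model uses the four-binary-predictor logistic form with
    intercept -1.94 and coefficients 1.14 (diabetes), 1.37 (CKD), 1.08
    (atrial fibrillation), 1.39 (diuretics) on the log-odds scale, giving
    outcome prevalence near one half.  HFpEF hazards are set so median
    progression times are roughly 1.7 / 5.3 / 9.4 years across clusters.
    """

    def nv(name, a, b, c, sa, sb, sc, units="", log_normal=False):
        return NumericVar(name, (a, b, c), (sa, sb, sc), units, log_normal)

    numeric = [
        nv("age_at_dd_years", 70.0, 68.0, 71.0, 10.0, 10.0, 10.0, "years"),
        nv("weight", 195.0, 210.0, 185.0, 55.0, 55.0, 50.0, "lb"),
        nv("height", 65.5, 67.0, 64.8, 4.0, 4.0, 4.0, "in"),
        nv("bsa", 1.95, 2.05, 1.90, 0.28, 0.28, 0.25, "m^2"),
        nv("sbp", 140.0, 138.0, 136.0, 20.0, 20.0, 18.0, "mmHg"),
        nv("dbp", 74.0, 74.0, 72.0, 12.0, 12.0, 11.0, "mmHg"),
        nv("pulse_pressure", 68.0, 72.0, 64.0, 18.0, 18.0, 16.0, "mmHg"),
        nv("gfr", 50.0, 52.0, 60.0, 22.0, 24.0, 24.0, "mL/min/1.73m^2"),
        # NT-proBNP-like biomarker: log-normal, cluster medians ~ 20000/12000/3800
        nv("nt_probnp", 9.9, 9.4, 8.2, 1.2, 1.2, 1.2, "pg/mL", log_normal=True),
        nv("e_over_a", 1.35, 1.30, 1.25, 0.45, 0.40, 0.40),
        nv("avg_e_prime", 6.5, 6.8, 7.2, 1.6, 1.6, 1.6, "cm/s"),
        nv("mitral_e_velocity", 118.0, 112.0, 98.0, 23.0, 31.0, 24.0, "cm/s"),
        nv("mitral_a_velocity", 103.0, 90.0, 79.0, 40.0, 36.0, 23.0, "cm/s"),
        nv("lvpw_diastole", 1.37, 1.27, 1.06, 0.38, 0.23, 0.20, "cm"),
        nv("lvpw_systole", 2.00, 1.91, 1.61, 0.48, 0.35, 0.24, "cm"),
        nv("septal_wall_diastole", 1.44, 1.28, 1.10, 0.35, 0.23, 0.20, "cm"),
        nv("lv_mass", 276.0, 236.0, 163.0, 100.0, 69.0, 39.0, "g"),
        nv("lv_mass_index", 143.0, 115.0, 87.0, 45.0, 34.0, 20.0, "g/m^2"),
        nv("relative_wall_thickness", 0.60, 0.55, 0.49, 0.18, 0.15, 0.10),
        nv("fractional_shortening", 41.4, 34.3, 33.3, 11.0, 10.5, 8.9, "%"),
        nv("lvef", 65.6, 60.2, 60.7, 8.0, 6.7, 5.2, "%"),
        nv("lvedv", 133.0, 98.0, 75.0, 45.0, 36.0, 23.0, "mL"),
        nv("edvi", 70.0, 47.0, 40.0, 18.0, 16.0, 11.0, "mL/m^2"),
        nv("lvesv", 46.0, 40.0, 30.0, 23.0, 16.0, 11.0, "mL"),
        nv("esvi", 23.8, 19.3, 15.9, 10.0, 6.8, 5.1, "mL/m^2"),
        nv("la_dimension", 4.24, 4.24, 3.80, 0.85, 0.61, 0.54, "cm"),
        nv("lv_internal_dim_systole", 3.30, 3.07, 2.95, 0.60, 0.62, 0.55, "cm"),
        nv("sv_lvot", 97.0, 84.0, 72.0, 34.0, 14.0, 17.0, "mL"),
        nv("svi_lvot", 52.6, 41.6, 37.9, 20.0, 8.3, 9.7, "mL/m^2"),
        nv("lvot_velocity_max", 138.0, 115.0, 104.0, 37.0, 22.0, 17.0, "cm/s"),
        nv("lvot_velocity_mean", 96.0, 79.0, 70.0, 25.0, 15.0, 11.0, "cm/s"),
        nv("lvot_max_gradient", 8.2, 5.5, 4.4, 3.7, 2.0, 1.4, "mmHg"),
        nv("lvot_mean_gradient", 4.4, 2.9, 2.3, 1.9, 1.1, 0.7, "mmHg"),
        nv("av_velocity_max", 364.0, 215.0, 174.0, 56.0, 65.0, 41.0, "cm/s"),
        nv("av_velocity_mean", 244.0, 149.0, 118.0, 46.0, 46.0, 26.0, "cm/s"),
        nv("av_max_gradient", 56.0, 20.2, 13.0, 18.0, 11.8, 6.1, "mmHg"),
        nv("av_mean_gradient", 28.2, 10.9, 6.6, 10.4, 6.6, 2.9, "mmHg"),
        nv("aortic_distensibility", 0.0016, 0.0023, 0.0026, 0.0008, 0.0010, 0.0011,
           "1/mmHg"),
        nv("arterial_stiffness", 2.2, 2.0, 1.8, 0.8, 0.8, 0.7, "mmHg/mL/m^2"),
        nv("arterial_elastance", 1.9, 1.7, 1.6, 0.6, 0.6, 0.5, "mmHg/mL"),
        nv("diastolic_wall_strain", 0.30, 0.33, 0.34, 0.08, 0.08, 0.08),
        nv("deceleration_time", 210.0, 215.0, 220.0, 50.0, 50.0, 50.0, "ms"),
        nv("ivrt", 95.0, 97.0, 100.0, 25.0, 25.0, 25.0, "ms"),
        nv("tr_velocity", 2.9, 2.7, 2.6, 0.5, 0.5, 0.4, "m/s"),
        nv("la_volume_index", 40.0, 36.0, 32.0, 12.0, 11.0, 10.0, "mL/m^2"),
        nv("heart_rate", 74.0, 72.0, 71.0, 13.0, 13.0, 12.0, "bpm"),
    ]
    assert len(numeric) == 46

    def cv(name, p_yes):  # binary yes/no history variable
        return CategoricalVar(
            name, ("yes", "no"), tuple((p, 1.0 - p) for p in p_yes)
        )

    categorical = [
        CategoricalVar(
            "gender",
            ("male", "female"),
            ((0.571, 0.429), (0.475, 0.525), (0.211, 0.789)),
        ),
        CategoricalVar(
            "race", ("white", "black"), ((0.78, 0.22), (0.78, 0.22), (0.78, 0.22))
        ),
        cv("htn", (0.86, 0.84, 0.79)),
        cv("dm", (0.57, 0.50, 0.36)),
        cv("ckd", (0.57, 0.52, 0.38)),
        cv("alcohol_use", (0.54, 0.54, 0.54)),
        cv("tobacco_use", (0.56, 0.58, 0.55)),
        cv("cad", (0.57, 0.55, 0.48)),
        cv("cva_tia", (0.18, 0.19, 0.17)),
        cv("afib", (0.43, 0.33, 0.25)),
        cv("beta_blocker", (0.71, 0.70, 0.66)),
        cv("ccb", (0.29, 0.28, 0.27)),
        cv("ace_inhibitor", (0.24, 0.24, 0.23)),
        cv("arb", (0.18, 0.18, 0.18)),
        cv("digoxin", (0.09, 0.07, 0.05)),
        cv("diuretic", (0.60, 0.57, 0.48)),
        cv("aldosterone_antagonist", (0.10, 0.12, 0.12)),
        CategoricalVar(
            "dd_severity",
            ("mild", "moderate", "severe"),
            ((0.14, 0.72, 0.14), (0.15, 0.78, 0.07), (0.19, 0.77, 0.04)),
        ),
        CategoricalVar(
            "cardiac_hypertrophy",
            ("none", "mild", "moderate", "severe"),
            (
                (0.0, 0.43, 0.14, 0.43),
                (0.41, 0.16, 0.14, 0.29),
                (0.75, 0.16, 0.06, 0.03),
            ),
        ),
    ]
    assert len(categorical) == 19

    missing = {
        "nt_probnp": 0.556,
        "gfr": 0.09,
        "aortic_distensibility": 0.35,
        "arterial_stiffness": 0.40,
        "arterial_elastance": 0.40,
        "pulse_pressure": 0.30,
        "sv_lvot": 0.45,
        "svi_lvot": 0.47,
        "lvedv": 0.15,
        "edvi": 0.15,
        "lvesv": 0.16,
        "esvi": 0.16,
        "lvef": 0.18,
        "lvpw_systole": 0.06,
        "cardiac_hypertrophy": 0.06,
        "dbp": 0.25,
    }
    missing.update(
        {
            v.name: 0.03
            for v in numeric + categorical
            if v.name not in missing and v.name != "age_at_dd_years"
        }
    )

    ln2 = math.log(2.0)
    return CohortSpec(
        n_patients=162,
        cluster_sizes=(7, 59, 96),
        numeric_vars=numeric,
        categorical_vars=categorical,
        missing_rates=missing,
        outcome_intercept=-1.94,
        outcome_coefficients={
            "dm=yes": 1.14,
            "ckd=yes": 1.37,
            "afib=yes": 1.08,
            "diuretic=yes": 1.39,
        },
        hazard_params={
            "hfpef": (ln2 / 1.7, ln2 / 5.3, ln2 / 9.4),
            "death": (ln2 / 3.0, ln2 / 3.6, ln2 / 5.4),
        },
        censor_horizon=15.0,
        # shifts are in cluster-C SDs; sized so the patient sits >= 8 SDs
        # above the pooled cohort mean even though pooled SDs exceed the
        # within-cluster SDs (and are inflated by the outlier itself)
        outlier_shifts={
            "lvot_velocity_max": 20.0,
            "lvot_velocity_mean": 20.0,
            "lvot_max_gradient": 20.0,
            "lvot_mean_gradient": 20.0,
        },
        seed=seed,
    )
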