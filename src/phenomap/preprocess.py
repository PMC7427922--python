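"""From raw mixed-type cohort to a complete numeric matrix.

Stages: whole-patient extreme-outlier screening on the numeric variables,
full one-hot encoding of categoricals (L indicator columns per L-level
variable), iterative SVD matrix completion of the missing entries, and an
optional standardization before distance computation.  Also the two
clinical grading rules used by the study population: diastolic-dysfunction
severity from E/A and average e', and CKD staging from GFR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSchema


@dataclass
class EncodedMatrix:
    """Fully numeric patient matrix with missingness mask and provenance.

    ``values`` is patients x columns (float, NaN where unobserved),
    ``mask`` is True where observed, ``column_meta`` maps each column to
    its (source variable, level-or-None).  After imputation the mask is
    all-True and the pre-imputation mask is retained in ``original_mask``.
    """

    values: np.ndarray
    mask: np.ndarray
    column_meta: list[tuple[str, str | None]]
    row_ids: list[str]
    original_mask: np.ndarray | None = None
    scale_params: dict | None = None  # column -> (mean, sd) for inversion
    converged: bool | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.values.shape[1] != len(self.column_meta):
            raise ValueError("column_meta length mismatch")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length mismatch")

    @property
    def columns(self) -> list[str]:
        return [
            name if level is None else f"{name}={level}"
            for name, level in self.column_meta
        ]

    def source_variables(self) -> set[str]:
        return {name for name, _ in self.column_meta}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.columns)

    def is_complete(self) -> bool:
        return bool(self.mask.all()) and not np.isnan(self.values).any()


# ---------------------------------------------------------------------------
# outlier screening


def screen_outliers(
    table: CohortTable,
    schema: list[VariableSchema] | None = None,
    z_threshold: float = 8.0,
) -> tuple[CohortTable, list[tuple[str, list[str]]]]:
    """Remove patients with any numeric value >= z_threshold SDs from the mean.

    Means and SDs are computed on the observed values of each numeric
    column, including the candidate patient.  Zero-dispersion columns are
    skipped with a warning.  Returns the retained table and a log of
    (patient_id, offending variables).
    """
    if schema is not None:
        numeric_names = [s.name for s in schema if s.kind == "numeric"]
    else:
        numeric_names = [
            c for c in table.data.columns if table.data[c].dtype != object
        ]
    flags: dict[str, list[str]] = {}
    for name in numeric_names:
        col = pd.to_numeric(table.data[name], errors="coerce")
        obs = col.dropna()
        if len(obs) < 2:
            continue
        sd = float(obs.std(ddof=0))
        if sd == 0.0:
            warnings.warn(f"screen_outliers: column {name!r} has zero SD; skipped")
            continue
        z = (col - obs.mean()).abs() / sd
        for pid in col.index[z >= z_threshold]:
            flags.setdefault(pid, []).append(name)
    keep = [pid for pid in table.patient_ids if pid not in flags]
    excluded = [(pid, vars_) for pid, vars_ in flags.items()]
    return table.subset(keep), excluded


# ---------------------------------------------------------------------------
# encoding


def one_hot_encode(
    table: CohortTable, schema: list[VariableSchema]
) -> EncodedMatrix:
    """Full one-hot encoding: L indicator columns per L-level categorical.

    Numeric variables pass through unchanged; a missing source value
    propagates NaN to every one of its indicator columns.
    """
    by_name = {s.name: s for s in schema}
    for name in table.data.columns:
        if name not in by_name:
            raise ValueError(f"variable {name!r} missing from schema")
    cols: list[np.ndarray] = []
    meta: list[tuple[str, str | None]] = []
    for name in table.data.columns:
        s = by_name[name]
        col = table.data[name]
        if s.kind == "numeric":
            cols.append(pd.to_numeric(col).to_numpy(dtype=float))
            meta.append((name, None))
        else:
            observed = col.dropna()
            bad = set(observed.unique()) - set(s.levels)
            if bad:
                raise ValueError(
                    f"variable {name!r}: observed value(s) {sorted(bad)!r} not "
                    f"in declared levels {s.levels!r}"
                )
            isna = col.isna().to_numpy()
            for level in s.levels:
                ind = (col == level).to_numpy(dtype=float)
                ind[isna] = np.nan
                cols.append(ind)
                meta.append((name, level))
    values = np.column_stack(cols) if cols else np.empty((table.n_patients, 0))
    mask = ~np.isnan(values)
    return EncodedMatrix(
        values=values,
        mask=mask,
        column_meta=meta,
        row_ids=list(table.patient_ids),
    )


# ---------------------------------------------------------------------------
# SVD imputation


def impute_svd(
    matrix: EncodedMatrix,
    rank: int = 5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> EncodedMatrix:
    """Iterative truncated-SVD matrix completion.

    Columns are scaled internally by their observed SD (scaling, unlike
    centering, preserves the rank of the raw matrix, so an exactly rank-r
    matrix is completed exactly at rank r).  Missing entries start at the
    column mean, then repeatedly: take the rank-`rank` SVD reconstruction
    and overwrite the missing entries with it, until the relative
    Frobenius change of the imputed entries falls below ``tol`` or
    ``max_iter`` is reached (non-convergence flagged, not fatal).  Observed
    entries are returned bit-identical to the input.
    """
    X = matrix.values.copy()
    obs = matrix.mask.copy()
    n, p = X.shape
    if not (1 <= rank <= min(n, p)):
        raise ValueError(f"rank {rank} outside [1, {min(n, p)}]")
    if (~obs).sum() == 0:
        return replace(
            matrix, original_mask=obs, converged=True, mask=np.ones_like(obs)
        )
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = [matrix.columns[j] for j in np.where(n_obs == 0)[0]]
        raise ValueError(f"entirely-missing column(s): {bad}")

    # internal scale (not center) on observed entries; see docstring
    mu = np.array([X[obs[:, j], j].mean() for j in range(p)])
    sd = np.array([X[obs[:, j], j].std() for j in range(p)])
    sd[sd == 0.0] = 1.0
    Z = X / sd
    miss_cols = np.where(~obs)[1]
    Z[~obs] = (mu / sd)[miss_cols]  # start at the observed column mean

    miss = ~obs
    prev = Z[miss].copy()
    converged = False
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        Z[miss] = recon[miss]
        cur = Z[miss]
        denom = np.linalg.norm(prev)
        change = np.linalg.norm(cur - prev) / (denom if denom > 0 else 1.0)
        prev = cur.copy()
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"impute_svd: not converged after {max_iter} iterations", stacklevel=2
        )

    out = X.copy()
    filled = Z * sd
    out[miss] = filled[miss]
    return replace(
        matrix,
        values=out,
        mask=np.ones_like(obs),
        original_mask=obs,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# standardization


def standardize(matrix: EncodedMatrix, policy: str = "numeric_only") -> EncodedMatrix:
    """Scale columns to mean 0, SD 1 (population SD, divisor n).

    ``numeric_only`` (default) scales columns of numeric provenance and
    leaves indicator columns untouched; ``all`` scales everything;
    ``none`` is the identity.  Transformation parameters are recorded so
    :func:`destandardize` can invert exactly.
    """
    if policy not in ("numeric_only", "all", "none"):
        raise ValueError(f"unknown policy {policy!r}")
    if not matrix.is_complete():
        raise ValueError("standardize requires a complete (imputed) matrix")
    if policy == "none":
        return replace(matrix, scale_params={})
    values = matrix.values.copy()
    params: dict[int, tuple[float, float]] = {}
    for j, (name, level) in enumerate(matrix.column_meta):
        if policy == "numeric_only" and level is not None:
            continue
        m = float(values[:, j].mean())
        s = float(values[:, j].std())  # population convention
        if s == 0.0:
            warnings.warn(f"standardize: column {matrix.columns[j]!r} has zero SD")
            continue
        values[:, j] = (values[:, j] - m) / s
        params[j] = (m, s)
    return replace(matrix, values=values, scale_params=params)


def destandardize(matrix: EncodedMatrix) -> EncodedMatrix:
    """Invert :func:`standardize` using the recorded parameters."""
    if not matrix.scale_params:
        return replace(matrix, scale_params=None)
    values = matrix.values.copy()
    for j, (m, s) in matrix.scale_params.items():
        values[:, j] = values[:, j] * s + m
    return replace(matrix, values=values, scale_params=None)


# ---------------------------------------------------------------------------
# clinical grading rules


def grade_dd_severity(e_over_a: float, e_prime: float) -> str:
    """Grade diastolic dysfunction from the E/A ratio and average e' (cm/s).

    The grading table covers only e' <= 9 cm/s: below that, severity is
    mild for E/A < 1, moderate for 1 <= E/A < 2, severe for E/A >= 2.
    Above e' = 9 the rule does not apply and ``indeterminate`` is returned.
    """
    if not (np.isfinite(e_over_a) and np.isfinite(e_prime)):
        raise ValueError("grade_dd_severity: inputs must be finite")
    if e_over_a <= 0 or e_prime <= 0:
        raise ValueError("grade_dd_severity: inputs must be positive")
    if e_prime > 9.0:
        return "indeterminate"
    if e_over_a >= 2.0:
        return "severe"
    if e_over_a >= 1.0:
        return "moderate"
    return "mild"


def stage_ckd(gfr: float) -> str:
    """CKD stage from GFR (mL/min/1.73 m^2), half-open interval convention.

    >= 60 -> stage1_2; [45, 60) -> stage3a; [30, 45) -> stage3b;
    [15, 30) -> stage4; < 15 -> stage5.
    """
    if not np.isfinite(gfr) or gfr <= 0:
        raise ValueError("stage_ckd: GFR must be positive and finite")
    if gfr >= 60:
        return "stage1_2"
    if gfr >= 45:
        return "stage3a"
    if gfr >= 30:
        return "stage3b"
    if gfr >= 15:
        return "stage4"
    return "stage5"


# ---------------------------------------------------------------------------
# persistence


def write_matrix(matrix: EncodedMatrix, path: str | Path) -> None:
    """Matrix as CSV plus a ``<path>.meta.yaml`` provenance sidecar."""
    import yaml

    matrix.to_frame().rename_axis("patient_id").to_csv(path)
    sidecar = {
        "column_meta": [[n, l] for n, l in matrix.column_meta],
        "original_mask": (
            matrix.original_mask.astype(int).tolist()
            if matrix.original_mask is not None
            else None
        ),
        "scale_params": (
            {int(k): [float(v[0]), float(v[1])] for k, v in matrix.scale_params.items()}
            if matrix.scale_params
            else None
        ),
        "converged": matrix.converged,
    }
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(sidecar))


def read_matrix(path: str | Path) -> EncodedMatrix:
    import yaml

    frame = pd.read_csv(path, index_col="patient_id")
    sidecar_path = Path(str(path) + ".meta.yaml")
    if sidecar_path.exists():
        sc = yaml.safe_load(sidecar_path.read_text())
        meta = [(n, l) for n, l in sc["column_meta"]]
        original_mask = (
            np.array(sc["original_mask"], dtype=bool)
            if sc.get("original_mask") is not None
            else None
        )
        scale_params = (
            {int(k): (v[0], v[1]) for k, v in sc["scale_params"].items()}
            if sc.get("scale_params")
            else None
        )
        converged = sc.get("converged")
    else:
        meta = [(c, None) for c in frame.columns]
        original_mask, scale_params, converged = None, None, None
    values = frame.to_numpy(dtype=float)
    return EncodedMatrix(
        values=values,
        mask=~np.isnan(values),
        column_meta=meta,
        row_ids=[str(i) for i in frame.index],
        original_mask=original_mask,
        scale_params=scale_params,
        converged=converged,
    )
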