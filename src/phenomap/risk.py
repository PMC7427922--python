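"""Logistic risk modelling of progression to HFpEF.

The published prediction equations use the display convention
``P = 1 / (1 + e^(a - sum(binary terms) + sum(signed continuous terms)))``
where each binary history variable contributes 0 or its coefficient and
continuous terms appear with their printed sign inside the exponent.  On
the standard log-odds scale this is ``logit P = -a + sum(c_j x_j) -
sum(m_j x_j)``.  Models are fitted by iteratively reweighted least squares
(cross-checked against statsmodels in the test suite), classified at the
complete-case outcome-prevalence cutoff (predict HFpEF iff P strictly
exceeds it), and validated by alternating two-fold cross-validation with
outcome-stratified fold assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable, VariableSchema


# ---------------------------------------------------------------------------
# display-convention model container


@dataclass
class LogisticModel:
    """Prediction equation in the display (subtracted-exponent) convention.

    ``intercept_a`` is the leading constant of the exponent;
    ``binary_coefficients`` are subtracted when the factor is present;
    ``continuous_terms`` are signed multipliers added to the exponent as
    printed (so the standard-scale slope of a continuous term is the
    negative of its stored value).
    """

    intercept_a: float
    binary_coefficients: dict[str, float] = field(default_factory=dict)
    continuous_terms: dict[str, float] = field(default_factory=dict)
    cutoff: float = 0.5
    complete_case_n: int | None = None
    prevalence: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.binary_coefficients) + list(self.continuous_terms)

    def standard_params(self) -> pd.Series:
        """Equivalent standard log-odds parameterization (const + slopes)."""
        params = {"const": -self.intercept_a}
        params.update(self.binary_coefficients)
        params.update({k: -v for k, v in self.continuous_terms.items()})
        return pd.Series(params)


def predict_probability(model: LogisticModel, covariates: dict) -> float:
    """Evaluate the display-convention equation exactly."""
    exponent = model.intercept_a
    for name, c in model.binary_coefficients.items():
        if name not in covariates:
            raise ValueError(f"missing covariate {name!r}")
        exponent -= c * float(covariates[name])
    for name, m in model.continuous_terms.items():
        if name not in covariates:
            raise ValueError(f"missing covariate {name!r}")
        exponent += m * float(covariates[name])
    from scipy.special import expit

    return float(expit(-exponent))


def odds_ratios(model: LogisticModel) -> dict[str, float]:
    """exp(coefficient magnitude) per binary factor, exp(standard slope)
    per unit of each continuous term."""
    out = {k: float(np.exp(abs(c))) for k, c in model.binary_coefficients.items()}
    out.update(
        {k: float(np.exp(-m)) for k, m in model.continuous_terms.items()}
    )
    return out


@dataclass
class ClassificationResult:
    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else np.nan


def classify(
    model: LogisticModel,
    covariates: pd.DataFrame,
    labels: pd.Series,
    cutoff: float | None = None,
) -> ClassificationResult:
    """Predict HFpEF iff P strictly exceeds the cutoff; score vs labels."""
    if len(covariates) == 0:
        raise ValueError("no labelled cases supplied")
    cut = model.cutoff if cutoff is None else cutoff
    if not 0.0 <= cut < 1.0:
        raise ValueError(f"cutoff {cut} outside [0, 1)")
    y = labels.loc[covariates.index].astype(int).to_numpy()
    probs = np.array(
        [
            predict_probability(model, covariates.loc[i].to_dict())
            for i in covariates.index
        ]
    )
    pred = (probs > cut).astype(int)
    return ClassificationResult(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        cutoff=cut,
    )


# ---------------------------------------------------------------------------
# published equations as evaluable fixtures

WHOLE_COHORT_MODEL = LogisticModel(
    intercept_a=1.94,
    binary_coefficients={"dm": 1.14, "ckd": 1.37, "afib": 1.08, "diuretic": 1.39},
    cutoff=0.530,
    complete_case_n=151,
    prevalence=0.530,
)

CLUSTER_B_MODEL = LogisticModel(
    intercept_a=4.44,
    binary_coefficients={"dm": 2.30, "ckd": 2.30, "diuretic": 2.28},
    continuous_terms={"av_max_gradient": 0.11, "diastolic_wall_strain": -13.29},
    cutoff=0.618,
    complete_case_n=55,
    prevalence=0.618,
)

CLUSTER_C_MODEL = LogisticModel(
    intercept_a=3.12,
    binary_coefficients={"ckd": 1.23, "diuretic": 1.79},
    continuous_terms={"age_at_dd": -0.06, "esvi": 0.17},
    cutoff=0.413,
    complete_case_n=75,
    prevalence=0.413,
)


def diastolic_wall_strain(lvpw_systole: float, lvpw_diastole: float) -> float:
    """(LVPWs - LVPWd) / LVPWs, the standard stiffness surrogate."""
    if lvpw_systole <= 0:
        raise ValueError("LVPWs must be positive")
    return (lvpw_systole - lvpw_diastole) / lvpw_systole


# ---------------------------------------------------------------------------
# IRLS fit


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50):
    from scipy.special import expit

    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    ll_trace: list[float] = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            raise ValueError("rank-deficient design matrix")
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta
        ll_trace.append(float(np.sum(y * eta - np.logaddexp(0.0, eta))))
        if step < tol:
            converged = True
            break
    mu = expit(X @ beta)
    cov = np.linalg.inv(X.T @ (X * (np.clip(mu * (1 - mu), 1e-10, None))[:, None]))
    return beta, cov, ll_trace, converged, it


def fit_logistic(
    X: pd.DataFrame, y: pd.Series, tol: float = 1e-8, max_iter: int = 50
) -> "LogisticRiskResults":
    """Shortcut for ``LogisticRisk(X, y).fit()``."""
    return LogisticRisk(X, y).fit(tol=tol, max_iter=max_iter)


class LogisticRisk:
    """Logistic risk model builder on complete-case data.

    Parameters
    ----------
    X : pandas.DataFrame
        Numeric covariates (no constant column; one is added).
    y : pandas.Series
        Binary outcome, index-aligned with ``X``.
    """

    def __init__(self, X: pd.DataFrame, y: pd.Series):
        if X.shape[1] < 1:
            raise ValueError("need at least one covariate")
        X = X.astype(float)
        y = y.loc[X.index].astype(int)
        if X.isna().any().any() or y.isna().any():
            raise ValueError("complete cases only: design contains missing values")
        if y.nunique() < 2:
            raise ValueError("outcome has a single class")
        self.X = X
        self.y = y

    @classmethod
    def from_cohort(
        cls,
        table: CohortTable,
        variables: list[str],
        schema: list[VariableSchema] | None = None,
    ) -> "LogisticRisk":
        """Complete-case design from cohort variables (see build_design)."""
        design = build_design(table, variables, schema)
        design = design.dropna()
        y = table.outcome.loc[design.index]
        return cls(design, y)

    def fit(self, tol: float = 1e-8, max_iter: int = 50) -> "LogisticRiskResults":
        names = ["const"] + list(self.X.columns)
        M = np.column_stack([np.ones(len(self.X)), self.X.to_numpy()])
        if np.linalg.matrix_rank(M) < M.shape[1]:
            # name the aliased columns for the error message
            aliased = []
            base_rank = np.linalg.matrix_rank(M[:, :1])
            keep = [0]
            for j in range(1, M.shape[1]):
                r = np.linalg.matrix_rank(M[:, keep + [j]])
                if r == len(keep):
                    aliased.append(names[j])
                else:
                    keep.append(j)
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
        beta, cov, ll_trace, converged, iters = _irls(
            M, self.y.to_numpy(dtype=float), tol, max_iter
        )
        ll = ll_trace[-1]
        if np.max(np.abs(beta)) > 15:
            warnings.warn("possible separation: |coefficient| > 15")
        params = pd.Series(beta, index=names)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        zvals = params / bse
        pvals = pd.Series(2 * sps.norm.sf(np.abs(zvals)), index=names)
        prev = float(self.y.mean())
        return LogisticRiskResults(
            model=self,
            params=params,
            bse=bse,
            pvalues=pvals,
            llf=ll,
            converged=converged,
            iterations=iters,
            nobs=len(self.y),
            prevalence=prev,
            ll_trace=ll_trace,
        )


@dataclass
class LogisticRiskResults:
    """Fitted logistic risk model (standard log-odds parameterization)."""

    model: LogisticRisk
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    converged: bool
    iterations: int
    nobs: int
    prevalence: float
    ll_trace: list[float] = field(default_factory=list)

    @property
    def cutoff(self) -> float:
        return self.prevalence

    def predict(self, X: pd.DataFrame | None = None) -> pd.Series:
        from scipy.special import expit

        X = self.model.X if X is None else X
        eta = self.params["const"] + X.astype(float) @ self.params.drop("const")
        return expit(eta)

    def to_display_model(self, cutoff: float | None = None) -> LogisticModel:
        """Re-express in the display convention used by the printed equations.

        Columns whose observed values are all 0/1 are treated as binary
        history factors (subtracted-coefficient form); the rest become
        signed continuous terms (sign flipped relative to the standard
        slope).
        """
        binary, cont = {}, {}
        for name in self.params.index.drop("const"):
            col = self.model.X[name]
            if set(np.unique(col)) <= {0.0, 1.0}:
                binary[name] = float(self.params[name])
            else:
                cont[name] = float(-self.params[name])
        return LogisticModel(
            intercept_a=float(-self.params["const"]),
            binary_coefficients=binary,
            continuous_terms=cont,
            cutoff=self.prevalence if cutoff is None else cutoff,
            complete_case_n=self.nobs,
            prevalence=self.prevalence,
            diagnostics={
                "converged": self.converged,
                "iterations": self.iterations,
                "log_likelihood": self.llf,
            },
        )

    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params.drop("const"))

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.params / self.bse,
                "P>|z|": self.pvalues,
                "OR": np.exp(self.params),
            }
        )
        head = (
            f"Logistic risk model  n={self.nobs}  "
            f"prevalence={self.prevalence:.3f}  cutoff>{self.cutoff:.3f}\n"
            f"log-likelihood={self.llf:.3f}  converged={self.converged} "
            f"({self.iterations} IRLS iterations)\n"
        )
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")


# ---------------------------------------------------------------------------
# design construction


def build_design(
    table: CohortTable,
    variables: list[str],
    schema: list[VariableSchema] | None = None,
) -> pd.DataFrame:
    """Numeric design columns from cohort variables.

    Numeric variables pass through.  A categorical variable named bare is
    encoded as the 0/1 indicator of its ``"yes"`` level; ``"var=level"``
    selects another level's indicator.  ``diastolic_wall_strain`` is
    derived from the posterior-wall measurements when not itself a column.
    Missing values stay NaN (complete-case handling is the caller's).
    """
    cols = {}
    for key in variables:
        if "=" in key:
            name, level = key.split("=", 1)
        else:
            name, level = key, None
        if name not in table.data.columns:
            if name == "diastolic_wall_strain" and {
                "lvpw_systole",
                "lvpw_diastole",
            } <= set(table.data.columns):
                s = pd.to_numeric(table.data["lvpw_systole"])
                d = pd.to_numeric(table.data["lvpw_diastole"])
                cols[key] = (s - d) / s
                continue
            raise ValueError(f"unknown variable {name!r}")
        col = table.data[name]
        if col.dtype == object or level is not None:
            level = "yes" if level is None else level
            ind = (col == level).astype(float)
            ind[col.isna()] = np.nan
            cols[key] = ind
        else:
            cols[key] = pd.to_numeric(col)
    return pd.DataFrame(cols, index=table.patient_ids)


# ---------------------------------------------------------------------------
# predictor selection


@dataclass
class SelectionResult:
    selected: list[str]
    results: LogisticRiskResults | None  # None when nothing passed screening
    univariate_p: dict[str, float]
    log: list[str]

    def to_display_model(self) -> LogisticModel:
        if self.results is None:
            return LogisticModel(intercept_a=0.0)
        return self.results.to_display_model()


def select_predictors(
    table: CohortTable,
    candidates: list[str],
    alpha: float = 0.05,
    collinearity_r: float = 0.5,
    schema: list[VariableSchema] | None = None,
) -> SelectionResult:
    """Univariate screen, progressive addition with collinearity pruning.

    (1) univariate logistic screen keeps candidates with Wald p < alpha;
    (2) survivors enter in order of univariate significance; (3) after
    each addition, an already-included variable whose adjusted p rises
    above alpha while correlating with the newcomer beyond
    ``collinearity_r`` loses to the more significant of the pair; (4) a
    final backward prune leaves only variables significant while adjusting
    for the others.  Complete-case on the final variable set.
    """
    design_all = build_design(table, candidates, schema)
    log: list[str] = []
    uni_p: dict[str, float] = {}
    for v in design_all.columns:
        sub = design_all[[v]].dropna()
        y = table.outcome.loc[sub.index]
        try:
            res = LogisticRisk(sub, y).fit()
            uni_p[v] = float(res.pvalues[v])
        except (ValueError, np.linalg.LinAlgError) as e:
            log.append(f"screen {v}: failed ({e})")
            uni_p[v] = 1.0
    survivors = sorted(
        [v for v in design_all.columns if uni_p[v] < alpha], key=lambda v: uni_p[v]
    )
    log.append(f"univariate survivors (p<{alpha}): {survivors}")
    if not survivors:
        warnings.warn("select_predictors: no candidate passed univariate screening")
        return SelectionResult([], None, uni_p, log)

    def refit(varlist):
        sub = design_all[varlist].dropna()
        return LogisticRisk(sub, table.outcome.loc[sub.index]).fit()

    included: list[str] = []
    for v in survivors:
        # perfect collinearity with an already-included variable: skip
        dup = False
        for w in included:
            pair = design_all[[v, w]].dropna()
            if len(pair) >= 2 and abs(np.corrcoef(pair[v], pair[w])[0, 1]) > 0.9999:
                log.append(f"skip {v}: aliased with {w}")
                dup = True
                break
        if dup:
            continue
        trial = included + [v]
        try:
            res = refit(trial)
        except ValueError as e:
            log.append(f"skip {v}: {e}")
            continue
        # collinearity pruning against the newcomer
        changed = True
        while changed and len(trial) > 1:
            changed = False
            for w in [x for x in trial if x != v]:
                if res.pvalues[w] <= alpha:
                    continue
                pair = design_all[[v, w]].dropna()
                r = abs(np.corrcoef(pair[v], pair[w])[0, 1]) if len(pair) > 1 else 0.0
                if r > collinearity_r:
                    drop = w if res.pvalues[w] >= res.pvalues[v] else v
                    log.append(
                        f"collinearity |r|={r:.2f} between {v} and {w}: drop {drop}"
                    )
                    trial.remove(drop)
                    res = refit(trial)
                    changed = drop != v
                    if drop == v:
                        break
        included = trial
    # backward prune: only variables significant while adjusting for others
    res = refit(included)
    while len(included) > 1:
        worst = res.pvalues.drop("const").idxmax()
        if res.pvalues[worst] < alpha:
            break
        log.append(f"backward prune {worst} (p={res.pvalues[worst]:.3f})")
        included.remove(worst)
        res = refit(included)
    if len(included) == 1 and res.pvalues.drop("const").iloc[0] >= alpha:
        warnings.warn("select_predictors: nothing significant after adjustment")
        return SelectionResult([], None, uni_p, log)
    log.append(f"final model: {included}")
    return SelectionResult(included, res, uni_p, log)


# ---------------------------------------------------------------------------
# alternating two-fold cross-validation


@dataclass
class CVResult:
    folds: pd.Series  # patient -> 1 or 2
    coefficients: dict[int, pd.Series]  # discovery fold -> refitted params
    accuracy: dict[str, float]  # "discovery_1", "validation_1", ...
    details: dict[str, ClassificationResult]


def twofold_cv(
    table: CohortTable,
    fixed_variables: list[str],
    schema: list[VariableSchema] | None = None,
) -> CVResult:
    """Alternating two-fold CV with outcome-stratified fold assignment.

    Within each outcome stratum patients are ordered by identifier and
    assigned alternately to folds 1 and 2.  The model (variables fixed to
    the whole-cohort selection) is refitted on each discovery fold and its
    prevalence-cutoff classification accuracy reported on both folds, in
    both directions.
    """
    design = build_design(table, fixed_variables, schema).dropna()
    y = table.outcome.loc[design.index]
    fold = pd.Series(0, index=design.index)
    offset = 0  # alternation continues across strata so fold sizes balance
    for cls_ in sorted(y.unique()):
        ids = sorted(design.index[y == cls_])
        if len(ids) < 2:
            raise ValueError(f"outcome stratum {cls_} has fewer than 2 members")
        for i, pid in enumerate(ids):
            fold.loc[pid] = 1 + ((i + offset) % 2)
        offset += len(ids)
    coefs: dict[int, pd.Series] = {}
    acc: dict[str, float] = {}
    details: dict[str, ClassificationResult] = {}
    for disc in (1, 2):
        val = 2 if disc == 1 else 1
        Xd, yd = design[fold == disc], y[fold == disc]
        Xv, yv = design[fold == val], y[fold == val]
        res = LogisticRisk(Xd, yd).fit()
        coefs[disc] = res.params
        pm = res.to_display_model()
        for tag, Xs, ys in (
            (f"discovery_{disc}", Xd, yd),
            (f"validation_{disc}", Xv, yv),
        ):
            cr = classify(pm, Xs, ys)
            acc[tag] = cr.accuracy
            details[tag] = cr
    return CVResult(folds=fold, coefficients=coefs, accuracy=acc, details=details)
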