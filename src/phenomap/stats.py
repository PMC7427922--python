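"""Comparative statistics for phenogroup tables.

Conventions matter here and are pinned by the published worked examples:
the chi-square test applies Yates' continuity correction to 2x2 tables
only (the ``auto`` default), never to larger tables; no minimum expected
count is enforced (small expectations only raise a warning); ANOVA is the
classic one-way F; post-hoc multiple comparisons are the Newman-Keuls and
Duncan stepwise studentized-range procedures with the harmonic-mean group
size for unbalanced designs.  No multiple-testing adjustment is applied
across variables — reports state this prominently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable, VariableSchema


@dataclass
class TestResult:
    statistic: float
    df: object  # int, or tuple for F tests
    p_value: float
    correction_applied: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass
class PosthocResult:
    method: str
    alpha: float
    decisions: dict[tuple[object, object], str]  # pair -> "differ"/"not_differ"
    means: dict[object, float]
    warnings: list[str] = field(default_factory=list)

    def rejected_pairs(self) -> set[tuple[object, object]]:
        return {p for p, d in self.decisions.items() if d == "differ"}


# ---------------------------------------------------------------------------
# chi-square


def chi_square_test(table, correction: str = "auto") -> TestResult:
    """Pearson chi-square on an r x c count table.

    ``correction='auto'`` applies Yates' continuity correction
    (|O-E| shrunk by 0.5, clamped at 0) to 2x2 tables only; ``on``/``off``
    force it.  Expected counts below 5 produce a warning, never an error.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column sum")
    if correction not in ("auto", "on", "off"):
        raise ValueError(f"unknown correction mode {correction!r}")
    apply = correction == "on" or (correction == "auto" and counts.shape == (2, 2))
    res = sps.chi2_contingency(counts, correction=apply)
    warn = []
    if (res.expected_freq < 5).any():
        warn.append(
            f"{int((res.expected_freq < 5).sum())} expected count(s) below 5"
        )
    return TestResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        correction_applied=apply,
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# ANOVA


def one_way_anova(groups: list) -> TestResult:
    """Classic one-way F test; groups with < 2 observations are dropped."""
    warn = []
    usable = []
    for g in groups:
        arr = np.asarray(pd.Series(g).dropna(), dtype=float)
        if len(arr) < 2:
            warn.append(f"group with n={len(arr)} dropped")
            continue
        usable.append(arr)
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    all_vals = np.concatenate(usable)
    k = len(usable)
    N = len(all_vals)
    if np.ptp(all_vals) == 0:
        return TestResult(statistic=0.0, df=(k - 1, N - k), p_value=1.0, warnings=warn)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in usable)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in usable)
    df_b, df_w = k - 1, N - k
    if ss_within == 0:
        return TestResult(
            statistic=np.inf, df=(df_b, df_w), p_value=0.0, warnings=warn
        )
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return TestResult(statistic=float(F), df=(df_b, df_w), p_value=p, warnings=warn)


# ---------------------------------------------------------------------------
# stepwise studentized-range procedures


from functools import lru_cache


@lru_cache(maxsize=4096)
def _q_crit(prob: float, span: int, df: int) -> float:
    """Cached studentized-range quantile (ppf is numerically integrated)."""
    return float(sps.studentized_range.ppf(prob, span, df))


def _stepwise_range(groups, alpha, method, names=None):
    warn = []
    cleaned = []
    for g in groups:
        arr = np.asarray(pd.Series(g).dropna(), dtype=float)
        cleaned.append(arr)
    if names is None:
        names = list(range(len(cleaned)))
    keep = [i for i, g in enumerate(cleaned) if len(g) >= 2]
    if len(keep) < len(cleaned):
        warn.append("groups with n<2 dropped")
    cleaned = [cleaned[i] for i in keep]
    names = [names[i] for i in keep]
    k = len(cleaned)
    means = {nm: float(g.mean()) for nm, g in zip(names, cleaned)}
    if k < 2:
        raise ValueError("need at least 2 usable groups")
    if k == 2:
        # two groups: plain pooled t test on the single pair
        warn.append("fewer than 3 groups: pairwise t test fallback")
        t, p = sps.ttest_ind(cleaned[0], cleaned[1])
        pair = tuple(sorted(names))
        decisions = {pair: "differ" if p < alpha else "not_differ"}
        return PosthocResult(method, alpha, decisions, means, warn)

    N = sum(len(g) for g in cleaned)
    df_w = N - k
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in cleaned) / df_w
    n_h = k / sum(1.0 / len(g) for g in cleaned)  # harmonic mean size
    order = sorted(range(k), key=lambda i: means[names[i]])
    sorted_names = [names[i] for i in order]
    sorted_means = [means[nm] for nm in sorted_names]
    se = np.sqrt(ms_within / n_h)

    # rejected[i][j]: range from sorted position i..j declared significant
    rejected = np.zeros((k, k), dtype=bool)
    blocked = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if blocked[i, j]:
                continue
            if ms_within == 0:
                differs = sorted_means[j] != sorted_means[i]
            else:
                q_obs = (sorted_means[j] - sorted_means[i]) / se
                if method == "newman_keuls":
                    a_r = alpha
                else:  # duncan's protection level
                    a_r = 1.0 - (1.0 - alpha) ** (span - 1)
                q_crit = _q_crit(1.0 - a_r, span, int(df_w))
                differs = q_obs > q_crit
            if differs:
                rejected[i, j] = True
            else:
                # non-rejected range blocks every inner comparison
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        blocked[a, b] = True
    decisions = {}
    for a, b in combinations(range(k), 2):
        pair = tuple(sorted((sorted_names[a], sorted_names[b])))
        decisions[pair] = "differ" if rejected[a, b] else "not_differ"
    return PosthocResult(method, alpha, decisions, means, warn)


def newman_keuls(groups, alpha: float = 0.05, names=None) -> PosthocResult:
    """Newman-Keuls stepwise studentized-range multiple comparisons."""
    return _stepwise_range(groups, alpha, "newman_keuls", names)


def duncan(groups, alpha: float = 0.05, names=None) -> PosthocResult:
    """Duncan's multiple range test (protection level 1-(1-a)^(span-1))."""
    return _stepwise_range(groups, alpha, "duncan", names)


# ---------------------------------------------------------------------------
# report generator


def _ci_halfwidth(x: np.ndarray) -> float:
    """95% CI half-width: t-quantile x SD/sqrt(n) (sample SD)."""
    n = len(x)
    if n < 2:
        return np.nan
    return float(sps.t.ppf(0.975, n - 1) * x.std(ddof=1) / np.sqrt(n))


@dataclass
class GroupComparisonReport:
    """Per-variable comparisons across groups, phenotype-table style."""

    table: pd.DataFrame
    posthoc: dict[str, dict[str, PosthocResult]]
    group_names: list
    note: str = (
        "No multiple-testing adjustment is applied across variables; "
        "p-values are per-variable."
    )

    def to_text(self) -> str:
        lines = [self.note, ""]
        lines.append(self.table.to_string())
        return "\n".join(lines)


def compare_groups(
    table: CohortTable,
    grouping: pd.Series,
    schema: list[VariableSchema],
    alpha: float = 0.05,
) -> GroupComparisonReport:
    """Compare every schema variable across the grouping.

    Categorical variables get the chi-square test (auto correction),
    numeric variables one-way ANOVA with Newman-Keuls and Duncan appended
    when ANOVA p < alpha and >= 3 groups.  Complete-case per variable with
    per-cell n reported; continuous cells are "mean ± 95% CI half-width (n)".
    """
    grouping = grouping.loc[grouping.index.intersection(table.patient_ids)]
    missing = table.patient_ids.difference(grouping.index)
    if len(missing):
        raise ValueError(f"grouping missing for patients {list(missing)[:5]}")
    groups = sorted(grouping.unique())
    by_name = {s.name: s for s in schema}
    rows = []
    posthoc: dict[str, dict[str, PosthocResult]] = {}
    for name in table.data.columns:
        s = by_name.get(name)
        if s is None:
            warnings.warn(f"compare_groups: variable {name!r} absent from schema")
            continue
        col = table.data[name]
        row: dict = {"variable": name, "kind": s.kind}
        if s.kind == "categorical":
            counts = []
            for g in groups:
                sub = col[grouping.loc[col.index] == g].dropna()
                counts.append([int((sub == lv).sum()) for lv in s.levels])
                row[f"group_{g}"] = (
                    "/".join(str(c) for c in counts[-1]) + f" ({len(sub)})"
                )
            tab = np.array(counts)
            # drop all-zero levels so marginals stay positive
            tab = tab[:, tab.sum(axis=0) > 0]
            keep_rows = tab.sum(axis=1) > 0
            try:
                if tab.shape[1] < 2 or keep_rows.sum() < 2:
                    raise ValueError("degenerate table")
                res = chi_square_test(tab[keep_rows], correction="auto")
                row["p_value"] = res.p_value
                row["test"] = "chi-square" + (
                    " (Yates)" if res.correction_applied else ""
                )
            except ValueError:
                row["p_value"] = np.nan
                row["test"] = "chi-square (degenerate)"
        else:
            samples, ns = [], []
            for g in groups:
                sub = pd.to_numeric(col[grouping.loc[col.index] == g]).dropna()
                samples.append(sub.to_numpy(dtype=float))
                ns.append(len(sub))
                if len(sub) >= 1:
                    hw = _ci_halfwidth(sub.to_numpy(dtype=float))
                    row[f"group_{g}"] = f"{sub.mean():.2f} ± {hw:.2f} ({len(sub)})"
                else:
                    row[f"group_{g}"] = "— (0)"
            try:
                res = one_way_anova(samples)
                row["p_value"] = res.p_value
                row["test"] = "ANOVA"
            except ValueError:
                row["p_value"] = np.nan
                row["test"] = "ANOVA (degenerate)"
                res = None
            if (
                res is not None
                and res.p_value < alpha
                and sum(n >= 2 for n in ns) >= 3
            ):
                usable = [(g, x) for g, x, n in zip(groups, samples, ns) if n >= 2]
                nk = newman_keuls(
                    [x for _, x in usable], alpha, names=[g for g, _ in usable]
                )
                dn = duncan(
                    [x for _, x in usable], alpha, names=[g for g, _ in usable]
                )
                posthoc[name] = {"newman_keuls": nk, "duncan": dn}
                row["posthoc"] = "; ".join(
                    f"{m}: "
                    + (
                        ", ".join(
                            f"{a}≠{b}" for (a, b) in sorted(r.rejected_pairs())
                        )
                        or "none"
                    )
                    for m, r in posthoc[name].items()
                )
        rows.append(row)
    report = pd.DataFrame(rows).set_index("variable")
    return GroupComparisonReport(
        table=report, posthoc=posthoc, group_names=list(groups)
    )
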