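"""Kaplan-Meier disease-trajectory summaries.

Product-limit estimation and log-rank comparison are delegated to
lifelines; this module wraps them in the containers and report structure
the pipeline needs: per-cluster curves for the four endpoints (time from
diastolic-dysfunction diagnosis to HFpEF, age at HFpEF diagnosis, time
from HFpEF to death, age at death), optionally stratified by gender, LV
hypertrophy, or outcome, with pairwise log-rank p-values.  The median is
the first time the survival estimate drops to 0.5 or below; patients who
never develop HFpEF are right-censored for the HFpEF endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cohort import CohortTable
from .cluster import ClusterAssignment
from .stats import TestResult


@dataclass
class SurvivalCurve:
    """Step-function survival estimate with risk/event bookkeeping."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None
    n: int

    def step(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimate; ties process events before censorings."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("need at least one sample")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be finite and nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    median = kmf.median_survival_time_
    return SurvivalCurve(
        event_times=ev.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        median=None if np.isinf(median) else float(median),
        n=len(t),
    )


def logrank_test(groups: list[tuple]) -> TestResult:
    """Log-rank chi-square across >= 2 samples of (times, events)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ts, es, gs = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        ts.append(t)
        es.append(e)
        gs.append(np.full(len(t), gi))
    events_total = sum(e.sum() for e in es)
    if events_total == 0:
        raise ValueError("no observed events in any group")
    res = multivariate_logrank_test(
        np.concatenate(ts), np.concatenate(gs), np.concatenate(es)
    )
    return TestResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# trajectory report

ENDPOINTS = ("dd_to_hfpef", "age_at_hfpef", "hfpef_to_death", "age_at_death")


def _endpoint_samples(table: CohortTable, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
    """(times, event flags) for one endpoint.

    HFpEF endpoints censor non-progressors at their last-known-alive time
    (their death/censoring time).  The HFpEF-to-death interval is defined
    only for progressors.
    """
    hf = table.hfpef_observed.astype(bool)
    if endpoint == "dd_to_hfpef":
        t = np.where(hf, table.time_to_hfpef, table.time_to_death)
        return t.astype(float), hf.to_numpy()
    if endpoint == "age_at_hfpef":
        t = table.age_at_dd + np.where(hf, table.time_to_hfpef, table.time_to_death)
        return t.to_numpy(dtype=float), hf.to_numpy()
    if endpoint == "hfpef_to_death":
        sub = table.subset(table.patient_ids[hf])
        t = np.maximum(sub.time_to_death - sub.time_to_hfpef, 0.0)
        return t.to_numpy(dtype=float), sub.death_observed.to_numpy(dtype=bool)
    if endpoint == "age_at_death":
        t = table.age_at_dd + table.time_to_death
        return t.to_numpy(dtype=float), table.death_observed.to_numpy(dtype=bool)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def _strata_masks(table: CohortTable, stratum: str) -> dict[str, pd.Series]:
    ids = table.patient_ids
    if stratum == "all":
        return {"all": pd.Series(True, index=ids)}
    if stratum == "gender":
        col = table.data.get("gender")
        if col is None:
            return {}
        return {str(v): col == v for v in col.dropna().unique()}
    if stratum == "lvh":
        col = table.data.get("cardiac_hypertrophy")
        if col is None:
            return {}
        present = col.notna()
        return {
            "no_lvh": (col == "none") & present,
            "lvh": (col != "none") & present,
        }
    if stratum == "outcome":
        y = table.outcome.astype(bool)
        return {"hfpef": y, "asymptomatic": ~y}
    raise ValueError(f"unknown stratum {stratum!r}")


@dataclass
class TrajectoryReport:
    """curves[(stratum, level, endpoint, cluster)] -> SurvivalCurve;
    tests[(stratum, level, endpoint)] -> overall + pairwise log-rank."""

    curves: dict = field(default_factory=dict)
    medians: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    pairwise: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (stratum, level, endpoint, cluster), curve in self.curves.items():
            rows.append(
                {
                    "stratum": stratum,
                    "level": level,
                    "endpoint": endpoint,
                    "cluster": cluster,
                    "n": curve.n,
                    "events": int(curve.n_events.sum()),
                    "median": curve.median,
                }
            )
        return pd.DataFrame(rows)


def trajectory_report(
    table: CohortTable,
    assignment: ClusterAssignment,
    strata: tuple[str, ...] = ("all",),
) -> TrajectoryReport:
    """Per cluster x stratum: KM curve + median per endpoint, log-rank tests."""
    for col in ("time_to_hfpef", "time_to_death", "hfpef_observed",
                "death_observed", "age_at_dd", "outcome"):
        if getattr(table, col) is None:
            raise ValueError(f"required column {col!r} absent from cohort")
    labels = assignment.labels.loc[table.patient_ids]
    clusters = sorted(labels[labels >= 0].unique())
    report = TrajectoryReport()
    for stratum in strata:
        for level, mask in _strata_masks(table, stratum).items():
            ids = table.patient_ids[mask.loc[table.patient_ids].fillna(False)]
            if len(ids) == 0:
                continue  # empty stratum reported as absent
            for endpoint in ENDPOINTS:
                samples = {}
                for c in clusters:
                    cids = ids[labels.loc[ids] == c]
                    if len(cids) == 0:
                        continue
                    sub = table.subset(cids)
                    t, e = _endpoint_samples(sub, endpoint)
                    if len(t) == 0:
                        continue
                    curve = km_estimate(t, e)
                    samples[c] = (t, e)
                    report.curves[(stratum, level, endpoint, int(c))] = curve
                    report.medians[(stratum, level, endpoint, int(c))] = curve.median
                usable = {
                    c: s for c, s in samples.items() if np.asarray(s[1]).sum() > 0
                }
                if len(usable) >= 2:
                    try:
                        report.tests[(stratum, level, endpoint)] = logrank_test(
                            list(usable.values())
                        )
                    except ValueError:
                        pass
                    keys = sorted(usable)
                    for i in range(len(keys)):
                        for j in range(i + 1, len(keys)):
                            try:
                                report.pairwise[
                                    (stratum, level, endpoint, keys[i], keys[j])
                                ] = logrank_test([usable[keys[i]], usable[keys[j]]])
                            except ValueError:
                                pass
    return report


def write_curves(report: TrajectoryReport, path) -> None:
    """Export every curve as delimited text (one long table)."""
    rows = []
    for (stratum, level, endpoint, cluster), c in report.curves.items():
        for t, s, r, d in zip(c.event_times, c.survival, c.at_risk, c.n_events):
            rows.append(
                {
                    "stratum": stratum,
                    "level": level,
                    "endpoint": endpoint,
                    "cluster": cluster,
                    "time": t,
                    "survival": s,
                    "at_risk": r,
                    "events": d,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
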