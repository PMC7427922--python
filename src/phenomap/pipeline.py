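"""End-to-end orchestration: simulate/ingest -> preprocess -> cluster ->
per-cluster statistics -> risk models -> survival report.

The clustering inputs provably exclude outcome and survival data: those
columns live outside the variable grid by construction, and the encoded
matrix's column provenance is asserted against them before any distance
is computed.  A run is fully determined by its config + seed; the
manifest records everything needed to reproduce it bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    OUTCOME_COLUMNS,
    CohortTable,
    read_schema,
    write_schema,
)
from . import synthetic, preprocess, cluster, stats, risk, survival


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the package defaults."""

    cohort_path: str | None = None  # None -> simulate from spec
    schema_path: str | None = None
    spec_path: str | None = None  # None -> packaged default spec
    seed: int = 0
    z_threshold: float = 8.0
    svd_rank: int = 5
    svd_tol: float = 1e-6
    svd_max_iter: int = 100
    scale_policy: str = "numeric_only"
    linkage: str = "ward"
    k_min: int = 2
    k_max: int = 5
    stats_alpha: float = 0.05
    risk_alpha: float = 0.05
    collinearity_r: float = 0.5
    candidates: list[str] = field(default_factory=list)
    cluster_variables: list[str] = field(default_factory=list)  # empty = all
    strata: list[str] = field(default_factory=lambda: ["all", "gender", "lvh", "outcome"])
    out_dir: str = "phenomap_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


DEFAULT_CANDIDATES = [
    "dm",
    "ckd",
    "afib",
    "diuretic",
    "htn",
    "cad",
    "digoxin",
    "beta_blocker",
    "aldosterone_antagonist",
    "tobacco_use",
    "alcohol_use",
    "cva_tia",
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # stage: cohort
        if config.cohort_path is not None:
            schema = read_schema(config.schema_path) if config.schema_path else None
            table = CohortTable.from_csv(config.cohort_path, schema)
            if schema is None:
                from .cohort import infer_schema

                schema = infer_schema(table)
        else:
            spec = (
                synthetic.CohortSpec.from_yaml(config.spec_path)
                if config.spec_path
                else synthetic.default_spec(seed=config.seed)
            )
            table = synthetic.generate(spec, seed=config.seed)
            schema = spec.schema()
        table.to_csv(out / "cohort.csv")
        write_schema(schema, out / "schema.yaml")
        manifest["stages"]["cohort"] = {
            "n_patients": table.n_patients,
            "n_variables": len(table.data.columns),
        }

        # leakage guard on user-specified clustering variables
        bad = sorted(set(config.cluster_variables) & set(OUTCOME_COLUMNS))
        if bad:
            raise ValueError(
                f"outcome/survival column(s) listed among clustering "
                f"variables: {bad}"
            )
        if config.cluster_variables:
            keep = [c for c in table.data.columns if c in config.cluster_variables]
            cl_table = table.copy()
            cl_table.data = cl_table.data[keep]
            cl_schema = [s for s in schema if s.name in keep]
        else:
            cl_table, cl_schema = table, schema

        # stage: outlier screen
        screened, excluded = preprocess.screen_outliers(
            cl_table, cl_schema, z_threshold=config.z_threshold
        )
        manifest["stages"]["outlier_screen"] = {
            "retained": screened.n_patients,
            "excluded": [
                {"patient_id": pid, "variables": v} for pid, v in excluded
            ],
        }

        # stage: encode + impute + scale
        encoded = preprocess.one_hot_encode(screened, cl_schema)
        leaked = set(encoded.source_variables()) & set(OUTCOME_COLUMNS)
        assert not leaked, f"outcome columns leaked into clustering matrix: {leaked}"
        imputed = preprocess.impute_svd(
            encoded,
            rank=config.svd_rank,
            tol=config.svd_tol,
            max_iter=config.svd_max_iter,
        )
        scaled = preprocess.standardize(imputed, policy=config.scale_policy)
        preprocess.write_matrix(scaled, out / "matrix.csv")
        manifest["stages"]["preprocess"] = {
            "n_columns": scaled.values.shape[1],
            "svd_converged": bool(imputed.converged),
            "missing_fraction": float(1 - encoded.mask.mean()),
        }

        # stage: clustering + k selection
        y = screened.outcome
        model = cluster.PhenomapModel(scaled, y)
        fitres = model.fit(
            linkage=config.linkage, k_range=range(config.k_min, config.k_max + 1)
        )
        fitres.assignment.labels.rename("cluster").to_csv(out / "assignment.csv")
        (out / "phenomap_summary.txt").write_text(fitres.summary() + "\n")
        evals = [
            {
                "k": e.k,
                "purity": e.purity,
                "chi2": e.chi2,
                "p_value": e.p_value,
                "sizes": e.sizes,
                "outcome_freq": e.per_cluster_outcome_freq,
            }
            for e in fitres.evaluations
        ]
        (out / "evaluations.yaml").write_text(yaml.safe_dump(evals, sort_keys=False))
        manifest["stages"]["cluster"] = {
            "selected_k": fitres.k,
            "purity": fitres.evaluations[
                [e.k for e in fitres.evaluations].index(fitres.k)
            ].purity,
        }

        # stage: per-cluster comparative statistics (phenotype comparison table)
        assign = fitres.assignment
        letters = assign.labels.map(lambda c: chr(ord("A") + int(c)))
        report2 = stats.compare_groups(
            screened, letters, cl_schema, alpha=config.stats_alpha
        )
        report2.table.to_csv(out / "cluster_comparison.csv")
        (out / "cluster_comparison.txt").write_text(report2.to_text() + "\n")

        # outcome comparison within each cluster
        for c in sorted(assign.labels.unique()):
            ids = assign.labels.index[assign.labels == c]
            sub = screened.subset(ids)
            grouping = sub.outcome.map({1: "hfpef", 0: "asymptomatic"})
            if grouping.nunique() < 2:
                continue
            rep = stats.compare_groups(sub, grouping, cl_schema, config.stats_alpha)
            rep.table.to_csv(out / f"within_cluster_{chr(ord('A') + int(c))}.csv")
        manifest["stages"]["stats"] = {"variables_compared": len(report2.table)}

        # stage: risk models (whole cohort + per cluster), alternating CV
        candidates = config.candidates or [
            c for c in DEFAULT_CANDIDATES if c in table.data.columns
        ]
        risk_out: dict = {}
        if candidates:
            sel = risk.select_predictors(
                screened,
                candidates,
                alpha=config.risk_alpha,
                collinearity_r=config.collinearity_r,
                schema=cl_schema,
            )
            risk_out["whole_cohort"] = {
                "selected": sel.selected,
                "univariate_p": {k: float(v) for k, v in sel.univariate_p.items()},
            }
            if sel.results is not None:
                pm = sel.results.to_display_model()
                risk_out["whole_cohort"].update(
                    {
                        "intercept_a": pm.intercept_a,
                        "binary_coefficients": pm.binary_coefficients,
                        "continuous_terms": pm.continuous_terms,
                        "cutoff": pm.cutoff,
                        "complete_case_n": pm.complete_case_n,
                        "odds_ratios": risk.odds_ratios(pm),
                    }
                )
                (out / "risk_model_summary.txt").write_text(
                    sel.results.summary() + "\n"
                )
                cv = risk.twofold_cv(screened, sel.selected, cl_schema)
                risk_out["cross_validation"] = {
                    k: float(v) for k, v in cv.accuracy.items()
                }
            for c in sorted(assign.labels.unique()):
                ids = assign.labels.index[assign.labels == c]
                sub = screened.subset(ids)
                if sub.outcome.nunique() < 2 or len(ids) < 20:
                    continue
                try:
                    sel_c = risk.select_predictors(
                        sub,
                        candidates,
                        alpha=config.risk_alpha,
                        collinearity_r=config.collinearity_r,
                        schema=cl_schema,
                    )
                except ValueError:
                    continue
                risk_out[f"cluster_{chr(ord('A') + int(c))}"] = {
                    "selected": sel_c.selected
                }
        (out / "risk_models.yaml").write_text(yaml.safe_dump(risk_out, sort_keys=False))
        manifest["stages"]["risk"] = {
            "whole_cohort_selected": risk_out.get("whole_cohort", {}).get(
                "selected", []
            )
        }

        # stage: survival trajectories
        traj = survival.trajectory_report(
            screened, assign, strata=tuple(config.strata)
        )
        survival.write_curves(traj, out / "survival_curves.csv")
        traj.to_frame().to_csv(out / "survival_medians.csv", index=False)
        manifest["stages"]["survival"] = {"n_curves": len(traj.curves)}

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# published worked examples as runnable fixtures


def reproduce_fixtures() -> list[dict]:
    """Recompute every printed worked example and compare at printed precision.

    Covers: the 3-cluster purity, the five printed contingency-table
    p-values, the three prediction equations over canonical covariate
    patterns (including the 2-of-4-factors decision rule), and the
    per-factor odds ratios.
    """
    checks: list[dict] = []

    def add(name, computed, printed, tol):
        checks.append(
            {
                "fixture": name,
                "computed": float(computed),
                "printed": float(printed),
                "pass": bool(abs(computed - printed) <= tol),
            }
        )

    # purity of the published 3-cluster grouping
    counts = [(5, 2), (35, 24), (40, 55)]
    labels, outcomes = [], []
    pid = 0
    for c, (hf, nohf) in enumerate(counts):
        for _ in range(hf):
            labels.append((f"P{pid}", c))
            outcomes.append((f"P{pid}", 1))
            pid += 1
        for _ in range(nohf):
            labels.append((f"P{pid}", c))
            outcomes.append((f"P{pid}", 0))
            pid += 1
    assign = cluster.ClusterAssignment(
        labels=pd.Series(dict(labels)), k=3
    )
    y = pd.Series(dict(outcomes))
    add("purity_3_clusters_percent", 100 * cluster.purity(assign, y), 59.0, 0.5)

    chi2, p = cluster.outcome_homogeneity_test(assign, y)
    add("hfpef_homogeneity_p", p, 0.058, 0.0005)

    add(
        "mortality_2x2_yates_p",
        stats.chi_square_test([[26, 55], [40, 41]], "auto").p_value,
        0.038,
        0.0005,
    )
    add(
        "dd_severity_2x3_p",
        stats.chi_square_test([[7, 68, 6], [21, 57, 3]], "auto").p_value,
        0.011,
        0.0005,
    )
    add(
        "gender_3x2_p",
        stats.chi_square_test([[4, 3], [28, 31], [20, 75]], "auto").p_value,
        0.001,
        0.0005,
    )
    add(
        "ckd_3x5_p",
        stats.chi_square_test(
            [[0, 1, 3, 1, 0], [18, 8, 10, 5, 9], [44, 23, 13, 5, 6]], "auto"
        ).p_value,
        0.031,
        0.0005,
    )

    # whole-cohort equation at canonical covariate patterns
    m = risk.WHOLE_COHORT_MODEL
    all4 = {"dm": 1, "ckd": 1, "afib": 1, "diuretic": 1}
    none_ = {"dm": 0, "ckd": 0, "afib": 0, "diuretic": 0}
    add("P_all_four_factors", risk.predict_probability(m, all4), 0.9543, 0.0005)
    add("P_no_factors", risk.predict_probability(m, none_), 0.1256, 0.0005)

    # decision rule: >= 2 of 4 factors <=> P > 53%
    rule_holds = True
    import itertools

    for pattern in itertools.product([0, 1], repeat=4):
        cov = dict(zip(["dm", "ckd", "afib", "diuretic"], pattern))
        P = risk.predict_probability(m, cov)
        if (P > 0.53) != (sum(pattern) >= 2):
            rule_holds = False
    checks.append(
        {
            "fixture": "two_or_more_factors_rule",
            "computed": float(rule_holds),
            "printed": 1.0,
            "pass": rule_holds,
        }
    )

    # cluster C equation at the all-zero covariate pattern
    add(
        "cluster_c_P_at_zero",
        risk.predict_probability(
            risk.CLUSTER_C_MODEL,
            {"ckd": 0, "diuretic": 0, "age_at_dd": 0, "esvi": 0},
        ),
        0.0424,
        0.0005,
    )

    # per-factor odds ratios sit in the printed 3-4-fold band
    ors = risk.odds_ratios(m)
    for name, printed in [
        ("dm", 3.13),
        ("ckd", 3.94),
        ("afib", 2.94),
        ("diuretic", 4.01),
    ]:
        add(f"odds_ratio_{name}", ors[name], printed, 0.005)

    return checks
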