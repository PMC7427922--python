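"""Cohort containers and delimited-text / schema I/O.

A cohort is a patient-by-variable grid of mixed categorical and numeric
values with missing entries, carried separately from the outcome
(progression to HFpEF) and the right-censored event-time columns.  Keeping
outcome and survival information out of the variable grid makes it
structurally impossible for downstream clustering to see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MISSING = np.nan

#: reserved column names in the cohort CSV that are outcome/survival data,
#: never clustering variables
OUTCOME_COLUMNS = (
    "outcome",
    "time_to_hfpef",
    "hfpef_observed",
    "time_to_death",
    "death_observed",
    "age_at_dd",
    "true_cluster",
)


@dataclass
class VariableSchema:
    """Declared type of one cohort variable.

    kind is ``"numeric"`` or ``"categorical"``; categorical variables carry
    an ordered list of >= 2 levels, numeric variables carry none.
    """

    name: str
    kind: str
    levels: list[str] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(
                    f"categorical variable {self.name!r} needs >= 2 levels"
                )
        elif self.levels:
            raise ValueError(f"numeric variable {self.name!r} must not have levels")


def write_schema(schema: list[VariableSchema], path: str | Path) -> None:
    payload = [
        {"name": s.name, "kind": s.kind, "levels": s.levels, "units": s.units}
        for s in schema
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_schema(path: str | Path) -> list[VariableSchema]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        VariableSchema(
            name=item["name"],
            kind=item["kind"],
            levels=item.get("levels"),
            units=item.get("units") or "",
        )
        for item in payload
    ]


@dataclass
class CohortTable:
    """Patient-by-variable table plus outcome and censored event times.

    ``data`` holds only the clinical/echocardiographic variables (NaN =
    missing).  Outcome, event times, the observation flags and the latent
    cluster label (synthetic cohorts only) are separate, index-aligned
    series.
    """

    data: pd.DataFrame
    outcome: pd.Series | None = None
    time_to_hfpef: pd.Series | None = None
    hfpef_observed: pd.Series | None = None
    time_to_death: pd.Series | None = None
    death_observed: pd.Series | None = None
    age_at_dd: pd.Series | None = None
    true_cluster: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("patient ids must be unique")
        for name in OUTCOME_COLUMNS:
            if name in self.data.columns:
                raise ValueError(
                    f"outcome/survival column {name!r} must not appear among "
                    "the clustering variables"
                )
        for name in (
            "outcome",
            "time_to_hfpef",
            "hfpef_observed",
            "time_to_death",
            "death_observed",
            "age_at_dd",
            "true_cluster",
        ):
            s = getattr(self, name)
            if s is not None and not s.index.equals(self.data.index):
                raise ValueError(f"{name} index does not match the patient grid")
        if self.outcome is not None and self.hfpef_observed is not None:
            if not (self.outcome.astype(bool) == self.hfpef_observed.astype(bool)).all():
                raise ValueError("outcome must be 1 exactly when hfpef_observed")

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def subset(self, ids) -> "CohortTable":
        """Row-subset every aligned column to the given patient ids."""
        kw = {}
        for name in (
            "outcome",
            "time_to_hfpef",
            "hfpef_observed",
            "time_to_death",
            "death_observed",
            "age_at_dd",
            "true_cluster",
        ):
            s = getattr(self, name)
            kw[name] = s.loc[ids] if s is not None else None
        return CohortTable(data=self.data.loc[ids], **kw)

    def copy(self) -> "CohortTable":
        return self.subset(self.patient_ids)

    # -- delimited-text round trip --------------------------------------

    def to_csv(self, path: str | Path) -> None:
        frame = self.data.copy()
        for name in OUTCOME_COLUMNS:
            s = getattr(self, name)
            if s is not None:
                frame[name] = s
        frame.index.name = "patient_id"
        frame.to_csv(path, na_rep="")

    @classmethod
    def from_csv(
        cls, path: str | Path, schema: list[VariableSchema] | None = None
    ) -> "CohortTable":
        frame = pd.read_csv(path, index_col="patient_id")
        kw = {}
        for name in OUTCOME_COLUMNS:
            if name in frame.columns:
                col = frame.pop(name)
                if name in ("outcome",):
                    col = col.astype(int)
                elif name in ("hfpef_observed", "death_observed"):
                    col = col.astype(bool)
                elif name == "true_cluster":
                    col = col.astype(int)
                kw[name] = col
        if schema is not None:
            for s in schema:
                if s.name not in frame.columns:
                    raise ValueError(f"schema variable {s.name!r} missing from file")
                if s.kind == "numeric":
                    frame[s.name] = pd.to_numeric(frame[s.name])
        return cls(data=frame, **kw)


def infer_schema(table: CohortTable) -> list[VariableSchema]:
    """Fallback schema from dtypes: object columns categorical, rest numeric."""
    out = []
    for name in table.data.columns:
        col = table.data[name]
        if col.dtype == object:
            levels = sorted(x for x in col.dropna().unique())
            out.append(VariableSchema(name, "categorical", [str(x) for x in levels]))
        else:
            out.append(VariableSchema(name, "numeric"))
    return out
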