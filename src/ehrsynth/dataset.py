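"""Consolidated per-patient representation of mixed static / event-sequence records.

A :class:`ConsolidatedDataset` holds one static row per patient plus a long-format
event table in which every row is one (patient, day-offset) visit carrying one slot
per dynamic variable (NaN / empty when that variable did not occur on that day).
The accompanying :class:`Schema` fixes variable order, kinds and category levels so
that encoders, metrics and the generator all agree on the feature layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PATIENT_ID = "patient_id"
TIMESTAMP = "TIMESTAMP"


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one modelled variable.

    Parameters
    ----------
    name:
        Column name in the static or event table.
    role:
        ``"static"`` (one value per patient) or ``"dynamic"`` (one slot per event row).
    kind:
        ``"categorical"`` or ``"numeric"``.
    levels:
        Ordered category levels (categorical variables only).
    vmin, vmax:
        Observed numeric range (numeric variables only); used for min-max scaling.
    transform:
        ``"none"`` or ``"log1p"`` — long-tailed positives are scaled on a
        log1p(x - vmin) axis so the encoder does not squash their bulk near 0.
    integer:
        Numeric variable whose observed values are all integral; decoded values
        are rounded back to integers.
    """

    name: str
    role: str
    kind: str
    levels: tuple[str, ...] = ()
    vmin: float = 0.0
    vmax: float = 1.0
    transform: str = "none"
    integer: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("static", "dynamic"):
            raise ValueError(f"bad role {self.role!r} for variable {self.name!r}")
        if self.kind not in ("categorical", "numeric"):
            raise ValueError(f"bad kind {self.kind!r} for variable {self.name!r}")

    def to_dict(self) -> dict:
        d = {"name": self.name, "role": self.role, "kind": self.kind}
        if self.kind == "categorical":
            d["levels"] = list(self.levels)
        else:
            d["vmin"] = self.vmin
            d["vmax"] = self.vmax
            d["transform"] = self.transform
            d["integer"] = self.integer
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSpec":
        return cls(
            name=d["name"],
            role=d["role"],
            kind=d["kind"],
            levels=tuple(d.get("levels", ())),
            vmin=float(d.get("vmin", 0.0)),
            vmax=float(d.get("vmax", 1.0)),
            transform=d.get("transform", "none"),
            integer=bool(d.get("integer", False)),
        )


@dataclass(frozen=True)
class Schema:
    """Ordered collection of :class:`VariableSpec`, static first then dynamic."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")

    @property
    def static(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.role == "static")

    @property
    def dynamic(self) -> tuple[VariableSpec, ...]:
        return tuple(v for v in self.variables if v.role == "dynamic")

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def get(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps({"variables": [v.to_dict() for v in self.variables]}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Schema":
        d = json.loads(text)
        return cls(tuple(VariableSpec.from_dict(v) for v in d["variables"]))


@dataclass
class ConsolidatedDataset:
    """Per-patient static vectors plus variable-length timestamped event sequences.

    ``static`` has one row per patient with a ``patient_id`` column and one column
    per static schema variable. ``events`` is long format: ``patient_id``,
    ``TIMESTAMP`` (integer days since first diagnosis, >= 0) and one column per
    dynamic schema variable other than TIMESTAMP itself.
    """

    static: pd.DataFrame
    events: pd.DataFrame
    schema: Schema
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if PATIENT_ID not in self.static.columns:
            raise ValueError("static table lacks patient_id")
        if len(self.events) and PATIENT_ID not in self.events.columns:
            raise ValueError("event table lacks patient_id")
        self.static = self.static.reset_index(drop=True)
        if len(self.events):
            self.events = self.events.sort_values(
                [PATIENT_ID, TIMESTAMP], kind="mergesort"
            ).reset_index(drop=True)

    @property
    def n_patients(self) -> int:
        return len(self.static)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.static[PATIENT_ID].to_numpy()

    def sequence_lengths(self) -> pd.Series:
        """Events per patient, 0 for patients with no event rows."""
        counts = self.events.groupby(PATIENT_ID).size() if len(self.events) else pd.Series(dtype=int)
        return pd.Series(self.patient_ids).map(counts).fillna(0).astype(int)

    def subset(self, patient_ids: Sequence) -> "ConsolidatedDataset":
        ids = set(patient_ids)
        stat = self.static[self.static[PATIENT_ID].isin(ids)].copy()
        ev = self.events[self.events[PATIENT_ID].isin(ids)].copy() if len(self.events) else self.events.copy()
        return ConsolidatedDataset(stat, ev, self.schema, dict(self.meta))

    def copy(self) -> "ConsolidatedDataset":
        return ConsolidatedDataset(self.static.copy(), self.events.copy(), self.schema, dict(self.meta))

    # ---- persistence: two CSVs + schema JSON -------------------------------
    def save(self, directory: str | Path, prefix: str = "dataset") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.static.to_csv(directory / f"{prefix}_static.csv", index=False)
        self.events.to_csv(directory / f"{prefix}_events.csv", index=False)
        (directory / f"{prefix}_schema.json").write_text(self.schema.to_json())

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "dataset") -> "ConsolidatedDataset":
        directory = Path(directory)
        schema = Schema.from_json((directory / f"{prefix}_schema.json").read_text())
        static = pd.read_csv(directory / f"{prefix}_static.csv")
        events = pd.read_csv(directory / f"{prefix}_events.csv")
        for v in schema:
            frame = static if v.role == "static" else events
            if v.name in frame.columns and v.kind == "categorical":
                frame[v.name] = frame[v.name].astype("object")
        return cls(static, events, schema)


def check_matching_schemas(a: ConsolidatedDataset, b: ConsolidatedDataset) -> None:
    """Raise with the offending variable names if the two schemas differ."""
    na = {v.name: (v.role, v.kind) for v in a.schema}
    nb = {v.name: (v.role, v.kind) for v in b.schema}
    if na != nb:
        diff = sorted(set(na.items()) ^ set(nb.items()))
        raise ValueError(f"schema mismatch: {diff}")
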