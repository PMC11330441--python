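"""Cohort selection and consolidation.

Selection applies the "Diff" rule: Diff = min(first surgery date, first
systemic anti-cancer treatment date) - first diagnosis date, in days. Patients
enter the study cohort when 0 <= Diff < cutoff (default 91 days, i.e. roughly
three months); patients with Diff at or beyond the cutoff, negative Diff, or no
treatment date at all are excluded, and the exclusion reasons are tallied so the
partition can be reported alongside the retained count.

Consolidation joins every event table onto the static table, replaces calendar
dates by integer day offsets from first diagnosis, and merges same-day events
from different tables into a single sequence row per (patient, day).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import PATIENT_ID, TIMESTAMP, ConsolidatedDataset, Schema, VariableSpec
from .sim import CohortSource, first_treatment_dates

DEFAULT_CUTOFF_DAYS = 91  # "three months", implemented as days and configurable


def compute_diff(first_diagnosis_date, first_surgery_date, first_chemo_date):
    """Days from first diagnosis to the earlier of first surgery / first chemo.

    Returns ``None`` when both treatment dates are missing; the result may be
    negative (treatment recorded before diagnosis). A missing diagnosis date is a
    record-level error and also yields ``None``.
    """
    if pd.isna(first_diagnosis_date):
        return None
    candidates = [d for d in (first_surgery_date, first_chemo_date) if not pd.isna(d)]
    if not candidates:
        return None
    return int((min(candidates) - first_diagnosis_date).days)


@dataclass
class SelectionResult:
    cohort: CohortSource
    partition: dict  # total / target / ge_cutoff / negative / null
    diff_values: pd.Series  # per input patient, NaN where null

    def __post_init__(self) -> None:
        p = self.partition
        assert p["total"] == p["target"] + p["ge_cutoff"] + p["negative"] + p["null"]


def select_cohort(cohort: CohortSource, cutoff_days: int = DEFAULT_CUTOFF_DAYS) -> SelectionResult:
    """Retain patients with 0 <= Diff < cutoff; partition the exclusions."""
    treat = first_treatment_dates(cohort)
    static = cohort.static_table
    diag = static.set_index(PATIENT_ID)["first_diagnosis_date"]
    treat = treat.set_index(PATIENT_ID)
    diffs = {}
    for pid_i in diag.index:
        diffs[pid_i] = compute_diff(
            diag[pid_i], treat.loc[pid_i, "first_surgery_date"], treat.loc[pid_i, "first_chemo_date"]
        )
    diff_series = pd.Series(diffs, dtype="float64")

    null_mask = diff_series.isna()
    neg_mask = diff_series < 0
    late_mask = diff_series >= cutoff_days
    keep_mask = ~(null_mask | neg_mask | late_mask)
    partition = {
        "total": int(len(diff_series)),
        "target": int(keep_mask.sum()),
        "ge_cutoff": int(late_mask.sum()),
        "negative": int(neg_mask.sum()),
        "null": int(null_mask.sum()),
        "cutoff_days": int(cutoff_days),
    }
    keep_ids = set(diff_series.index[keep_mask])
    new_static = static[static[PATIENT_ID].isin(keep_ids)].reset_index(drop=True)
    new_tables = {
        name: tab[tab[PATIENT_ID].isin(keep_ids)].reset_index(drop=True)
        for name, tab in cohort.event_tables.items()
    }
    return SelectionResult(CohortSource(new_static, new_tables), partition, diff_series)


def _infer_spec(name: str, role: str, values: pd.Series) -> VariableSpec:
    non_null = values.dropna()
    if non_null.empty:
        raise ValueError(f"variable {name!r} has no observed values")
    if pd.api.types.is_numeric_dtype(non_null):
        x = non_null.to_numpy(dtype=float)
        sd = x.std()
        skew = float(((x - x.mean()) ** 3).mean() / sd**3) if sd > 0 else 0.0
        return VariableSpec(
            name,
            role,
            "numeric",
            vmin=float(x.min()),
            vmax=float(x.max()),
            transform="log1p" if skew > 2.0 else "none",
            integer=bool(np.all(np.mod(x, 1.0) == 0.0)),
        )
    levels = tuple(sorted(map(str, non_null.unique())))
    return VariableSpec(name, role, "categorical", levels=levels)


def consolidate(cohort: CohortSource, censor_date=None) -> ConsolidatedDataset:
    """Join event tables onto the static table as day-offset sequences.

    Static output per patient: sex, age, diagnosis code, stage, death indicator
    and survival time in days (death or administrative censoring at
    ``censor_date``, defaulting to the latest date observed anywhere in the
    cohort). Events before diagnosis are inconsistencies and are dropped with a
    count kept in ``meta`` (as are same-day collisions within one column).
    """
    static_in = cohort.static_table
    all_dates = [static_in["first_diagnosis_date"], static_in["death_date"].dropna()]
    for tab in cohort.event_tables.values():
        if len(tab):
            all_dates.append(tab["event_date"])
    if censor_date is None:
        censor_date = max(s.max() for s in all_dates if len(s))
    censor_date = pd.Timestamp(censor_date)

    diag = static_in.set_index(PATIENT_ID)["first_diagnosis_date"]
    dead = static_in["death_date"].notna()
    end = static_in["death_date"].fillna(censor_date)
    survival_days = (end - static_in["first_diagnosis_date"]).dt.days.clip(lower=0)

    static = pd.DataFrame(
        {
            PATIENT_ID: static_in[PATIENT_ID].to_numpy(),
            "sex": static_in["sex"].astype(str).to_numpy(),
            "age": static_in["age"].astype(float).to_numpy(),
            "diagnosis_code": static_in["diagnosis_code"].astype(str).to_numpy(),
            "stage": static_in["stage"].astype(str).to_numpy(),
            "dead": np.where(dead, "1", "0"),
            "survival_days": survival_days.astype(float).to_numpy(),
        }
    )

    long_parts = []
    dropped_pre_diag = 0
    for name, tab in cohort.event_tables.items():
        if not len(tab):
            continue
        t = tab.copy()
        t[TIMESTAMP] = (t["event_date"] - t[PATIENT_ID].map(diag)).dt.days
        pre = t[TIMESTAMP] < 0
        dropped_pre_diag += int(pre.sum())
        t = t[~pre].drop(columns=["event_date"])
        long_parts.append(t)
    if long_parts:
        merged = pd.concat(long_parts, axis=0, ignore_index=True, sort=False)
        payload_cols = [c for c in merged.columns if c not in (PATIENT_ID, TIMESTAMP)]
        n_payload_in = int(merged[payload_cols].notna().sum().sum())
        grouped = merged.groupby([PATIENT_ID, TIMESTAMP], as_index=False).first()
        n_payload_out = int(grouped[payload_cols].notna().sum().sum())
        dropped_collisions = n_payload_in - n_payload_out
        events = grouped
    else:
        events = pd.DataFrame(columns=[PATIENT_ID, TIMESTAMP])
        dropped_collisions = 0

    specs = [
        _infer_spec("sex", "static", static["sex"]),
        _infer_spec("age", "static", static["age"]),
        _infer_spec("diagnosis_code", "static", static["diagnosis_code"]),
        _infer_spec("stage", "static", static["stage"]),
        VariableSpec("dead", "static", "categorical", levels=("0", "1")),
        _infer_spec("survival_days", "static", static["survival_days"]),
        _infer_spec(TIMESTAMP, "dynamic", events[TIMESTAMP].astype(float))
        if len(events)
        else VariableSpec(TIMESTAMP, "dynamic", "numeric", vmin=0.0, vmax=1.0),
    ]
    for col in events.columns:
        if col in (PATIENT_ID, TIMESTAMP):
            continue
        specs.append(_infer_spec(col, "dynamic", events[col]))

    ds = ConsolidatedDataset(static, events, Schema(tuple(specs)))
    ds.meta["dropped_pre_diagnosis"] = dropped_pre_diag
    ds.meta["dropped_same_day_collisions"] = dropped_collisions
    ds.meta["censor_date"] = str(censor_date.date())
    return ds


def split_T_H(dataset: ConsolidatedDataset, frac_T: float, seed: int):
    """Seed-deterministic disjoint, exhaustive patient-level split into (T, H)."""
    if not 0.0 < frac_T < 1.0:
        raise ValueError("frac_T must be in (0, 1)")
    ids = dataset.patient_ids.copy()
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_t = int(round(frac_T * len(ids)))
    if n_t < 2 or len(ids) - n_t < 2:
        raise ValueError(f"degenerate split: {n_t} vs {len(ids) - n_t} patients")
    return dataset.subset(ids[:n_t]), dataset.subset(ids[n_t:])
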