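"""Simulated multi-table EHR cohort.

Emulates the layout of a cancer-registry extract: one static patient table
(demographics, first diagnosis date, stage, death date) plus several dynamic event
tables (surgery, chemotherapy, laboratory results) keyed by patient id, with
irregular inter-event intervals, overdispersed visit counts and long-tailed
numeric payloads. Survival times come from a proportional-hazards mechanism with
administrative censoring at the study-window end, so downstream survival models
have a recoverable signal.

The generator produces a *clean* cohort; :func:`inject_inconsistencies` then
plants the record errors that cohort selection is meant to remove: first
treatment before diagnosis, first treatment far beyond the diagnosis-to-treatment
cutoff, or missing treatment dates entirely. Injected errors are flagged in a
hidden ``_flag`` column so tests can assert against the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PATIENT_ID

STUDY_EPOCH = pd.Timestamp("2008-01-01")

# Composition defaults mirror a colorectal-cancer registry cohort:
# ~57% male, ~18% five-year-window mortality, tumour site split roughly
# 58/33/10 across rectosigmoid junction / colon / rectum.
DIAG_CODES = ("C19", "C18", "C20")
DIAG_PROBS = (0.579, 0.326, 0.095)
STAGE_LEVELS = ("I", "II", "III", "IV")
STAGE_PROBS = (0.20, 0.35, 0.30, 0.15)
REGIMEN_LEVELS = ("FOLFOX", "FOLFIRI", "CAPOX", "5FU", "OTHER")
REGIMEN_PROBS = (0.35, 0.25, 0.2, 0.12, 0.08)
OP_LEVELS = ("LAR", "AR", "RHC", "OTHER")
OP_PROBS = (0.4, 0.3, 0.2, 0.1)
MARKER_LEVELS = ("CEA", "CA199")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cohort.

    ``frac_male`` / ``frac_dead`` default to the 57.4% / 17.8% composition of the
    cohort the pipeline is modelled on. ``heavy_tail_shape`` is the log-normal
    sigma of the long-tailed numeric payloads. ``hazard_coefficients`` are
    log-hazard effects on named covariates (``age`` in years, ``stage`` as the
    ordinal 1-4 stage, ``sex`` as a male indicator).
    """

    n_patients: int = 2000
    seed: int = 0
    max_events_per_patient: int = 16
    frac_male: float = 0.574
    frac_dead: float = 0.178
    frac_diff_violations: float = 0.0
    frac_null_treatment: float = 0.0
    heavy_tail_shape: float = 1.0
    hazard_coefficients: dict = field(
        default_factory=lambda: {"age": 0.03, "stage": 0.45}
    )
    study_window: tuple[str, str] = ("2008-01-01", "2021-07-31")

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.max_events_per_patient < 1:
            raise ValueError("max_events_per_patient must be >= 1")
        for name in ("frac_male", "frac_dead", "frac_diff_violations", "frac_null_treatment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_diff_violations + self.frac_null_treatment > 1.0:
            raise ValueError("frac_diff_violations + frac_null_treatment must be <= 1")
        if self.heavy_tail_shape <= 0:
            raise ValueError("heavy_tail_shape must be positive")


@dataclass
class CohortSource:
    """Raw simulated cohort: static table + named long-format event tables.

    Columns whose names start with ``_`` are hidden ground truth (true survival
    time, injected-error flags) and are not part of the modelled data.
    """

    static_table: pd.DataFrame
    event_tables: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        ids = set(self.static_table[PATIENT_ID])
        for name, tab in self.event_tables.items():
            if len(tab) and not set(tab[PATIENT_ID]).issubset(ids):
                raise ValueError(f"event table {name!r} references unknown patient ids")

    def copy(self) -> "CohortSource":
        return CohortSource(
            self.static_table.copy(), {k: v.copy() for k, v in self.event_tables.items()}
        )


def _zero_truncated_negbin(rng: np.random.Generator, r: float, p: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial draws (overdispersed event counts >= 1)."""
    out = rng.negative_binomial(r, p, size)
    for _ in range(100):
        zeros = out == 0
        if not zeros.any():
            break
        out[zeros] = rng.negative_binomial(r, p, int(zeros.sum()))
    out[out == 0] = 1
    return out


def _calibrate_baseline_hazard(lp: np.ndarray, followup: np.ndarray, frac_dead: float) -> float:
    """Bisect the baseline exponential rate so mean in-window death prob hits frac_dead."""
    if frac_dead <= 0.0:
        return 0.0

    def death_prob(lam0: float) -> float:
        return float(np.mean(1.0 - np.exp(-lam0 * np.exp(lp) * followup)))

    lo, hi = 1e-10, 1.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if death_prob(mid) < frac_dead:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_cohort(config: SimConfig) -> CohortSource:
    """Draw a clean multi-table cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start = pd.Timestamp(config.study_window[0])
    end = pd.Timestamp(config.study_window[1])
    window_days = (end - start).days

    pid = np.array([f"P{i:06d}" for i in range(n)])
    diag_offset = rng.integers(0, max(window_days - 30, 1), n)
    diag_date = start + pd.to_timedelta(diag_offset, unit="D")
    followup = (window_days - diag_offset).astype(float)

    age = np.clip(np.round(rng.normal(59.0, 11.0, n)), 18, 94)
    sex = np.where(rng.random(n) < config.frac_male, "M", "F")
    diagnosis_code = rng.choice(DIAG_CODES, n, p=DIAG_PROBS)
    stage = rng.choice(STAGE_LEVELS, n, p=STAGE_PROBS)
    stage_num = np.array([STAGE_LEVELS.index(s) + 1 for s in stage], dtype=float)

    covars = {"age": age, "sex": (sex == "M").astype(float), "stage": stage_num}
    lp = np.zeros(n)
    for name, beta in config.hazard_coefficients.items():
        if name not in covars:
            raise ValueError(f"unknown hazard covariate {name!r}")
        x = covars[name]
        lp += beta * (x - x.mean())

    lam0 = _calibrate_baseline_hazard(lp, followup, config.frac_dead)
    if lam0 > 0:
        true_time = rng.exponential(1.0 / (lam0 * np.exp(lp)), n)
    else:
        true_time = np.full(n, np.inf)
    dead = true_time <= followup
    death_date = pd.Series([pd.NaT] * n, dtype="datetime64[ns]")
    death_date[dead] = diag_date[dead] + pd.to_timedelta(
        np.ceil(true_time[dead]).astype(int), unit="D"
    )
    # last date the record can carry events: death or administrative window end
    last_obs_days = np.where(dead, np.ceil(true_time), followup)

    static = pd.DataFrame(
        {
            PATIENT_ID: pid,
            "first_diagnosis_date": diag_date,
            "death_date": death_date,
            "age": age,
            "sex": sex,
            "diagnosis_code": diagnosis_code,
            "stage": stage,
            "_true_time": true_time,
            "_followup": followup,
            "_flag": "none",
        }
    )

    # ---- treatment timing: Diff (diagnosis -> first treatment) ------------
    diff_days = np.clip(np.round(rng.gamma(2.0, 12.0, n)), 0, 89).astype(int)
    has_surgery = rng.random(n) < 0.85
    has_chemo = rng.random(n) < 0.70
    neither = ~has_surgery & ~has_chemo
    has_surgery[neither] = True  # clean cohort: everyone has some treatment

    sigma = config.heavy_tail_shape

    surgery_rows = []
    chemo_rows = []
    lab_rows = []
    lab_counts = np.minimum(
        _zero_truncated_negbin(rng, 2.0, 0.25, n), config.max_events_per_patient
    )
    chemo_counts = np.minimum(
        _zero_truncated_negbin(rng, 2.0, 0.3, n), config.max_events_per_patient
    )
    # patient-level gap heterogeneity -> irregular visit spacing
    gap_mean = rng.gamma(2.0, 12.0, n)

    for i in range(n):
        horizon = max(float(last_obs_days[i]), 1.0)
        first_t = int(min(diff_days[i], horizon))
        surg_first = has_surgery[i]
        other_delay = int(np.ceil(rng.exponential(30.0))) + 1
        if has_surgery[i]:
            t = first_t if surg_first else min(first_t + other_delay, int(horizon))
            surgery_rows.append(
                (
                    pid[i],
                    diag_date[i] + pd.Timedelta(days=int(t)),
                    rng.choice(OP_LEVELS, p=OP_PROBS),
                    float(np.round(rng.lognormal(5.0, 0.4), 1)),
                )
            )
        if has_chemo[i]:
            t0 = first_t if not surg_first else min(first_t + other_delay, int(horizon))
            gaps = np.ceil(rng.exponential(gap_mean[i], chemo_counts[i] - 1)) + 1
            times = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
            times = times[times <= horizon]
            if len(times) == 0:
                times = np.array([min(t0, horizon)])
            regimen = rng.choice(REGIMEN_LEVELS, p=REGIMEN_PROBS)
            for cyc, t in enumerate(times, start=1):
                chemo_rows.append(
                    (
                        pid[i],
                        diag_date[i] + pd.Timedelta(days=int(t)),
                        regimen,
                        int(cyc),
                        float(np.round(rng.lognormal(5.5, sigma * 0.5), 1)),
                    )
                )
        t0 = float(rng.integers(0, 11))
        gaps = np.ceil(rng.exponential(gap_mean[i], lab_counts[i] - 1)) + 1
        times = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
        times = times[times <= horizon]
        if len(times) == 0:
            times = np.array([0.0])
        for t in times:
            lab_rows.append(
                (
                    pid[i],
                    diag_date[i] + pd.Timedelta(days=int(t)),
                    rng.choice(MARKER_LEVELS),
                    float(np.round(rng.lognormal(1.0, sigma), 3)),
                )
            )

    surgery = pd.DataFrame(
        surgery_rows, columns=[PATIENT_ID, "event_date", "op_kind_cd", "op_duration_min"]
    )
    chemo = pd.DataFrame(
        chemo_rows, columns=[PATIENT_ID, "event_date", "regimen_cd", "cycle_no", "dose_mg"]
    )
    labs = pd.DataFrame(
        lab_rows, columns=[PATIENT_ID, "event_date", "marker_cd", "result_value"]
    )
    return CohortSource(static, {"surgery": surgery, "chemo": chemo, "labs": labs})


def inject_inconsistencies(cohort: CohortSource, config: SimConfig) -> CohortSource:
    """Plant Diff-rule violations and null treatments; flags go into ``_flag``.

    A separate substream (seed + 1) keeps the base cohort byte-identical to the
    clean draw for the untouched patients.
    """
    if config.frac_diff_violations == 0.0 and config.frac_null_treatment == 0.0:
        return cohort
    out = cohort.copy()
    rng = np.random.default_rng(config.seed + 1)
    static = out.static_table
    n = len(static)
    n_viol = int(round(config.frac_diff_violations * n))
    n_null = int(round(config.frac_null_treatment * n))
    chosen = rng.choice(n, size=n_viol + n_null, replace=False)
    viol_idx, null_idx = chosen[:n_viol], chosen[n_viol:]

    null_ids = set(static[PATIENT_ID].iloc[null_idx])
    for name in ("surgery", "chemo"):
        tab = out.event_tables[name]
        out.event_tables[name] = tab[~tab[PATIENT_ID].isin(null_ids)].reset_index(drop=True)
    static.loc[static[PATIENT_ID].isin(null_ids), "_flag"] = "null_treatment"

    neg = viol_idx[: n_viol // 2]
    late = viol_idx[n_viol // 2 :]
    for idx, kind in ((neg, "neg_diff"), (late, "late_diff")):
        for i in idx:
            row = static.iloc[i]
            pid_i, diag = row[PATIENT_ID], row["first_diagnosis_date"]
            first = None
            for name in ("surgery", "chemo"):
                tab = out.event_tables[name]
                dates = tab.loc[tab[PATIENT_ID] == pid_i, "event_date"]
                if len(dates):
                    first = min(first, dates.min()) if first is not None else dates.min()
            if first is None:
                continue
            if kind == "neg_diff":
                target = diag - pd.Timedelta(days=int(rng.integers(1, 61)))
            else:
                target = diag + pd.Timedelta(days=int(92 + rng.integers(0, 300)))
            delta = target - first
            for name in ("surgery", "chemo"):
                tab = out.event_tables[name]
                mask = tab[PATIENT_ID] == pid_i
                tab.loc[mask, "event_date"] = tab.loc[mask, "event_date"] + delta
            static.iloc[i, static.columns.get_loc("_flag")] = kind
    return out


def first_treatment_dates(cohort: CohortSource) -> pd.DataFrame:
    """Per patient: earliest surgery date and earliest chemo date (NaT if none)."""
    pieces = {}
    for name in ("surgery", "chemo"):
        tab = cohort.event_tables[name]
        if len(tab):
            pieces[name] = tab.groupby(PATIENT_ID)["event_date"].min()
        else:
            pieces[name] = pd.Series(dtype="datetime64[ns]")
    out = cohort.static_table[[PATIENT_ID]].copy()
    out["first_surgery_date"] = out[PATIENT_ID].map(pieces["surgery"])
    out["first_chemo_date"] = out[PATIENT_ID].map(pieces["chemo"])
    return out


# ---- on-disk layout: CSVs + manifest JSON ----------------------------------

def _column_types(df: pd.DataFrame, role: str) -> dict:
    types = {}
    for col in df.columns:
        if col.startswith("_") or col == PATIENT_ID:
            continue
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            types[col] = [role, "date"]
        elif pd.api.types.is_numeric_dtype(df[col]):
            types[col] = [role, "numeric"]
        else:
            types[col] = [role, "categorical"]
    return types


def write_cohort(cohort: CohortSource, directory: str | Path) -> None:
    """Write static + event CSVs (ISO dates, empty string = null) and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.static_table.to_csv(directory / "static.csv", index=False, date_format="%Y-%m-%d")
    manifest = {
        "patient_id_key": PATIENT_ID,
        "static_table": "static.csv",
        "event_tables": {},
        "column_types": _column_types(cohort.static_table, "static"),
    }
    for name, tab in cohort.event_tables.items():
        tab.to_csv(directory / f"events_{name}.csv", index=False, date_format="%Y-%m-%d")
        manifest["event_tables"][name] = f"events_{name}.csv"
        manifest["column_types"].update(_column_types(tab, "dynamic"))
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(directory: str | Path) -> CohortSource:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    date_cols = [c for c, (_, k) in manifest["column_types"].items() if k == "date"]
    static = pd.read_csv(directory / manifest["static_table"])
    for c in static.columns:
        if c in date_cols or c == "death_date" or c.endswith("_date"):
            static[c] = pd.to_datetime(static[c])
    tables = {}
    for name, fname in manifest["event_tables"].items():
        tab = pd.read_csv(directory / fname)
        for c in tab.columns:
            if c in date_cols or c.endswith("_date"):
                tab[c] = pd.to_datetime(tab[c])
        tables[name] = tab
    return CohortSource(static, tables)
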