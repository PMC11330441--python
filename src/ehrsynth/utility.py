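"""Downstream-utility evaluation: five-year survival modelling.

A survival model (random survival forest by default) is trained once on real and
once on synthetic data and both are scored on the same real holdout using
Harrell's concordance index, the censoring-weighted (IPCW) Brier score over a
time grid, its trapezoidal integral (IBS), and a time-resolved AUC obtained by
dichotomizing vital status at each grid time among subjects still under
observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .dataset import ConsolidatedDataset
from .encoding import summary_features

FIVE_YEARS_DAYS = 1825
_FEATURE_EXCLUDE = ("dead", "survival_days")


def survival_outcomes(dataset: ConsolidatedDataset) -> tuple[np.ndarray, np.ndarray]:
    """(time in days, event indicator) per patient; event 1 = death observed."""
    times = dataset.static["survival_days"].to_numpy(dtype=float)
    events = (dataset.static["dead"].astype(str) == "1").to_numpy()
    if (times < 0).any():
        raise ValueError("negative survival time")
    return times, events.astype(int)


class SurvivalModel:
    """Wrapper exposing per-subject survival curves S(t | x) on a time grid."""

    def __init__(self, estimator, feature_columns, schema):
        self.estimator = estimator
        self.feature_columns = feature_columns
        self.schema = schema  # featurization scales fixed at training time

    def predict_survival(self, dataset: ConsolidatedDataset, times: np.ndarray) -> np.ndarray:
        x = summary_features(dataset, exclude=_FEATURE_EXCLUDE, schema=self.schema)[self.feature_columns].to_numpy()
        fns = self.estimator.predict_survival_function(x)
        out = np.ones((len(x), len(times)))
        for i, fn in enumerate(fns):
            lo, hi = fn.domain
            hi = hi if np.isfinite(hi) else np.inf
            tt = np.clip(times, lo, hi)
            out[i] = fn(tt)
            out[i, times < lo] = 1.0  # no event can have occurred before the grid
        out[:, times <= 0] = 1.0  # survival-curve boundary S(0 | x) = 1
        return np.clip(out, 0.0, 1.0)

    def predict_risk(self, dataset: ConsolidatedDataset) -> np.ndarray:
        x = summary_features(dataset, exclude=_FEATURE_EXCLUDE, schema=self.schema)[self.feature_columns].to_numpy()
        return np.asarray(self.estimator.predict(x), dtype=float)


def fit_survival_model(
    train: ConsolidatedDataset, model_spec=None, seed: int = 0
) -> SurvivalModel:
    """Fit the five-year survival predictor; errors if training data has no events."""
    times, events = survival_outcomes(train)
    if events.sum() == 0:
        raise ValueError("no observed events in training data")
    feats = summary_features(train, exclude=_FEATURE_EXCLUDE)
    if model_spec is None:
        model_spec = RandomSurvivalForest(
            n_estimators=50, min_samples_leaf=15, random_state=seed, n_jobs=1
        )
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    model_spec.fit(feats.to_numpy(), y)
    return SurvivalModel(model_spec, feats.columns, train.schema)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------
def concordance_index(risk: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's C: fraction of comparable pairs ranked concordantly by risk.

    A pair (i, j) is comparable when subject i has the observed event and either
    t_i < t_j, or t_i == t_j with j censored. Risk ties get 0.5 credit.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if i == j:
                continue
            comparable = times[i] < times[j] or (times[i] == times[j] and not events[j])
            if not comparable:
                continue
            den += 1.0
            if risk[i] > risk[j]:
                num += 1.0
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def _censoring_survival(times: np.ndarray, events: np.ndarray):
    """Kaplan-Meier estimate of the censoring distribution G(t) as a step function."""
    order = np.argsort(times, kind="mergesort")
    t_sorted = times[order]
    c_sorted = 1 - np.asarray(events)[order]  # censoring is the "event" here
    uniq = np.unique(t_sorted[c_sorted == 1])
    at_risk_t = np.sort(times)
    surv = []
    g = 1.0
    for t in uniq:
        n_risk = np.sum(at_risk_t >= t)
        d = np.sum((t_sorted == t) & (c_sorted == 1))
        if n_risk > 0:
            g *= 1.0 - d / n_risk
        surv.append((t, g))
    grid = np.array([s[0] for s in surv])
    vals = np.array([s[1] for s in surv])

    def G(t, minus: bool = False):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.ones_like(t)
        for k, tk in enumerate(t):
            if minus:
                idx = np.searchsorted(grid, tk, side="left") - 1
            else:
                idx = np.searchsorted(grid, tk, side="right") - 1
            out[k] = vals[idx] if idx >= 0 else 1.0
        return out

    return G


def brier_score(
    surv_at_t: np.ndarray, times: np.ndarray, events: np.ndarray, t: float
) -> float:
    """IPCW (Graf) Brier score at time t.

    Subjects dead by t contribute (0 - S(t|x))^2 / G(t_i-); subjects still under
    observation contribute (1 - S(t|x))^2 / G(t); subjects censored before t
    contribute 0. With no censoring before t all weights are 1 and this is the
    plain mean squared error against observed status.
    """
    surv_at_t = np.asarray(surv_at_t, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    G = _censoring_survival(times, events)
    g_t = float(G(t)[0])
    n = len(times)
    total = 0.0
    for i in range(n):
        if times[i] <= t and events[i]:
            g = float(G(times[i], minus=True)[0])
            if g <= 0:
                raise ValueError(f"censoring weight is zero before t={t}")
            total += (surv_at_t[i]) ** 2 / g
        elif times[i] > t:
            if g_t <= 0:
                raise ValueError(f"censoring weight is zero at t={t}")
            total += (1.0 - surv_at_t[i]) ** 2 / g_t
        # censored at or before t: weight 0
    return total / n


def integrated_brier_score(
    surv_curves: np.ndarray, times: np.ndarray, events: np.ndarray, t_grid: np.ndarray
) -> float:
    """Trapezoidal integral of the Brier curve over t_grid, normalized by span."""
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) < 2:
        raise ValueError("t_grid needs at least 2 points")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    briers = np.array(
        [brier_score(surv_curves[:, k], times, events, t) for k, t in enumerate(t_grid)]
    )
    return float(np.trapezoid(briers, t_grid) / (t_grid[-1] - t_grid[0]))


def time_dependent_auc(
    surv_at_t: np.ndarray, times: np.ndarray, events: np.ndarray, t: float
) -> float:
    """AUC of risk (1 - S(t|x)) for status at t among subjects with known status."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    known = (times > t) | events
    status = ((times <= t) & events)[known].astype(int)
    if len(np.unique(status)) < 2:
        return float("nan")
    return float(roc_auc_score(status, 1.0 - np.asarray(surv_at_t)[known]))


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------
@dataclass
class UtilityReport:
    metrics: dict  # {"real": {"c_index":..., "ibs":...}, "synthetic": {...}}
    brier_curves: dict  # source -> list[(t, brier)]
    auc_curves: dict  # source -> list[(t, auc)]
    t_grid: np.ndarray = field(repr=False, default=None)


def default_time_grid(times: np.ndarray, events: np.ndarray, n_points: int = 50) -> np.ndarray:
    """Event-time quantile grid up to five years (stable desk-scale cost)."""
    ev_times = times[events.astype(bool)]
    ev_times = ev_times[ev_times <= FIVE_YEARS_DAYS]
    if len(ev_times) < 2:
        raise ValueError("too few events for a time grid")
    qs = np.quantile(ev_times, np.linspace(0.05, 0.95, n_points))
    return np.unique(np.round(qs))


def compare_utility(
    real_train: ConsolidatedDataset,
    synth: ConsolidatedDataset,
    holdout: ConsolidatedDataset,
    model_spec=None,
    t_grid: np.ndarray | None = None,
    seed: int = 0,
) -> UtilityReport:
    """Train on real and on synthetic, evaluate both on the same real holdout."""
    shared = set(real_train.patient_ids) & set(holdout.patient_ids)
    if shared:
        raise ValueError("holdout overlaps real training data")
    times, events = survival_outcomes(holdout)
    if t_grid is None:
        t_grid = default_time_grid(times, events)
    metrics, brier_curves, auc_curves = {}, {}, {}
    for source, train in (("real", real_train), ("synthetic", synth)):
        model = fit_survival_model(train, model_spec=model_spec, seed=seed)
        surv = model.predict_survival(holdout, t_grid)
        risk = model.predict_risk(holdout)
        c = concordance_index(risk, times, events)
        briers = [
            (float(t), brier_score(surv[:, k], times, events, t)) for k, t in enumerate(t_grid)
        ]
        aucs = [
            (float(t), time_dependent_auc(surv[:, k], times, events, t))
            for k, t in enumerate(t_grid)
        ]
        ibs = integrated_brier_score(surv, times, events, t_grid)
        mid = surv[:, len(t_grid) // 2]
        metrics[source] = {
            "c_index": float(c),
            "ibs": float(ibs),
            "brier_at_median_t": float(
                brier_score(mid, times, events, float(t_grid[len(t_grid) // 2]))
            ),
        }
        brier_curves[source] = briers
        auc_curves[source] = aucs
    return UtilityReport(metrics, brier_curves, auc_curves, t_grid)
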