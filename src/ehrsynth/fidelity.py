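"""Real-vs-synthetic similarity metrics.

Per-variable Hellinger distance (finite even on disjoint supports, unlike KL or
Jensen-Shannon divergence), train-on-synthetic/test-on-real style AUC checks,
the scaled propensity MSE, paired histograms, and a t-SNE dispersion summary of
the encoder's latent codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .dataset import ConsolidatedDataset, check_matching_schemas
from .encoding import summary_features

DEFAULT_BINS = 50


# ---------------------------------------------------------------------------
# Hellinger distance
# ---------------------------------------------------------------------------
@dataclass
class HellingerResult:
    variable: str
    distance: float
    role: str  # static | dynamic
    kind: str  # categorical | numeric
    bins: object  # int bin count or tuple of levels
    note: str = ""


def hellinger_from_probs(p: np.ndarray, q: np.ndarray) -> float:
    """H(P, Q) = sqrt(1 - sum_k sqrt(p_k q_k)); zero-mass bins contribute 0.

    Evaluated through the algebraically equal form sqrt(0.5 * sum (sqrt(p) -
    sqrt(q))^2), which is exactly 0 for identical inputs instead of suffering
    cancellation in 1 - BC.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = np.sqrt(p) - np.sqrt(q)
    return float(min(np.sqrt(0.5 * (d * d).sum()), 1.0))


def hellinger_distance(
    real_values,
    synth_values,
    kind: str,
    bins: int = DEFAULT_BINS,
    variable: str = "",
    role: str = "",
) -> HellingerResult:
    """Hellinger distance between empirical distributions of two value arrays.

    Categorical variables use probabilities over the union of observed levels;
    numeric variables use shared equal-width bins spanning the pooled min-max
    range, so both sides are binned on a common support.
    """
    rv = pd.Series(real_values).dropna()
    sv = pd.Series(synth_values).dropna()
    if rv.empty or sv.empty:
        raise ValueError(f"all-null input for variable {variable!r}")
    note = ""
    if kind == "categorical":
        levels = sorted(set(rv.astype(str)) | set(sv.astype(str)))
        p = rv.astype(str).value_counts(normalize=True).reindex(levels).fillna(0.0).to_numpy()
        q = sv.astype(str).value_counts(normalize=True).reindex(levels).fillna(0.0).to_numpy()
        used_bins: object = tuple(levels)
    else:
        lo = float(min(rv.min(), sv.min()))
        hi = float(max(rv.max(), sv.max()))
        if hi <= lo:  # constant on both sides
            d = 0.0 if np.isclose(rv.iloc[0], sv.iloc[0]) else 1.0
            return HellingerResult(variable, d, role, kind, 1, note="degenerate range")
        edges = np.linspace(lo, hi, bins + 1)
        p = np.histogram(rv.to_numpy(dtype=float), bins=edges)[0].astype(float)
        q = np.histogram(sv.to_numpy(dtype=float), bins=edges)[0].astype(float)
        p /= p.sum()
        q /= q.sum()
        used_bins = bins
    return HellingerResult(variable, hellinger_from_probs(p, q), role, kind, used_bins, note)


def hellinger_table(
    real: ConsolidatedDataset, synth: ConsolidatedDataset, bins: int = DEFAULT_BINS
) -> list[HellingerResult]:
    """One Hellinger distance per schema variable.

    Static variables compare per-patient values; dynamic variables pool all
    event rows (non-null slots) on each side.
    """
    check_matching_schemas(real, synth)
    results = []
    for spec in real.schema:
        if spec.role == "static":
            rv, sv = real.static[spec.name], synth.static[spec.name]
        else:
            rv = real.events[spec.name] if len(real.events) else pd.Series(dtype=float)
            sv = synth.events[spec.name] if len(synth.events) else pd.Series(dtype=float)
        results.append(
            hellinger_distance(rv, sv, spec.kind, bins=bins, variable=spec.name, role=spec.role)
        )
    return results


# ---------------------------------------------------------------------------
# TSTR / TRTS
# ---------------------------------------------------------------------------
@dataclass
class TstrResult:
    direction: str  # TSTR | TRTS | TRTR
    auc: float
    label: str
    classifier: str


def _label_vector(dataset: ConsolidatedDataset, label: str) -> np.ndarray:
    spec = dataset.schema.get(label)
    if spec.kind != "categorical" or len(spec.levels) != 2:
        raise ValueError(f"label {label!r} must be a binary categorical variable")
    return (dataset.static[label].astype(str) == spec.levels[1]).to_numpy().astype(int)


def tstr_trts(
    real_train: ConsolidatedDataset,
    real_test: ConsolidatedDataset,
    synth: ConsolidatedDataset,
    label: str = "dead",
    classifier=None,
    exclude: tuple[str, ...] = ("survival_days",),
) -> list[TstrResult]:
    """TSTR (fit synth, test real), TRTS (fit real, test synth) and the TRTR
    baseline, with identical featurization in every direction."""
    if classifier is None:
        classifier = LogisticRegression(max_iter=2000)
    drop = tuple(set(exclude) | {label})
    feats = {
        "real_train": summary_features(real_train, exclude=drop),
        "real_test": summary_features(real_test, exclude=drop, schema=real_train.schema),
        "synth": summary_features(synth, exclude=drop, schema=real_train.schema),
    }
    labels = {
        "real_train": _label_vector(real_train, label),
        "real_test": _label_vector(real_test, label),
        "synth": _label_vector(synth, label),
    }
    cols = feats["real_train"].columns
    directions = {
        "TSTR": ("synth", "real_test"),
        "TRTS": ("real_train", "synth"),
        "TRTR": ("real_train", "real_test"),
    }
    out = []
    for name, (tr, te) in directions.items():
        y_tr, y_te = labels[tr], labels[te]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise ValueError(f"single-class label on a side of {name}")
        clf = clone(classifier)
        clf.fit(feats[tr][cols].to_numpy(), y_tr)
        p = clf.predict_proba(feats[te][cols].to_numpy())[:, 1]
        out.append(TstrResult(name, float(roc_auc_score(y_te, p)), label, type(classifier).__name__))
    return out


# ---------------------------------------------------------------------------
# Propensity MSE
# ---------------------------------------------------------------------------
@dataclass
class PropensityResult:
    scaled_pmse: float
    unscaled_pmse: float
    fold_scaled: list[float]
    classifier: str
    n: int
    probs: np.ndarray = field(repr=False, default=None)


def propensity_from_probs(probs: np.ndarray) -> tuple[float, float]:
    """(unscaled, scaled) propensity MSE: mean (p_i - 0.5)^2, and the same
    divided by 0.25 so a perfect discriminator scores 1."""
    probs = np.asarray(probs, dtype=float)
    unscaled = float(np.mean((probs - 0.5) ** 2))
    return unscaled, unscaled / 0.25


def propensity_mse(
    real: ConsolidatedDataset,
    synth: ConsolidatedDataset,
    classifier=None,
    n_folds: int = 5,
    seed: int = 0,
) -> PropensityResult:
    """Discriminator-based distinguishability on a balanced 1:1 real/synthetic mix.

    Records are labelled real=0 / synthetic=1; p_i are out-of-fold predicted
    probabilities of the synthetic class under stratified k-fold cross-fitting,
    so a memorizing classifier cannot score its own training rows.
    """
    if classifier is None:
        classifier = HistGradientBoostingClassifier(random_state=seed)
    if not hasattr(classifier, "predict_proba"):
        raise ValueError("classifier must expose predict_proba")
    rng = np.random.default_rng(seed)
    m = min(real.n_patients, synth.n_patients)
    if m < n_folds:
        raise ValueError("too few records for the requested number of folds")
    ids_r = rng.choice(real.patient_ids, m, replace=False)
    ids_s = rng.choice(synth.patient_ids, m, replace=False)
    fr = summary_features(real.subset(ids_r))
    fs = summary_features(synth.subset(ids_s), schema=real.schema)
    x = np.concatenate([fr.to_numpy(), fs[fr.columns].to_numpy()])
    y = np.concatenate([np.zeros(m), np.ones(m)])
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    probs = cross_val_predict(clone(classifier), x, y, cv=cv, method="predict_proba")[:, 1]
    unscaled, scaled = propensity_from_probs(probs)
    fold_scaled = []
    for _, test_idx in cv.split(x, y):
        fold_scaled.append(propensity_from_probs(probs[test_idx])[1])
    return PropensityResult(scaled, unscaled, fold_scaled, type(classifier).__name__, 2 * m, probs)


# ---------------------------------------------------------------------------
# t-SNE dispersion
# ---------------------------------------------------------------------------
@dataclass
class TsneDispersion:
    embedding: np.ndarray  # (n_real + n_synth, 2)
    is_synth: np.ndarray  # boolean per row
    dispersion: dict  # {"real": (axis1, axis2), "synth": (axis1, axis2)}


def tsne_dispersion(
    real_codes: np.ndarray, synth_codes: np.ndarray, seed: int = 0, perplexity: float = 30.0
) -> TsneDispersion:
    """Joint 2-D t-SNE of pooled latent codes; per-axis, per-group dispersion
    is the sample variance of the embedding coordinates."""
    pooled = np.concatenate([real_codes, synth_codes])
    n = len(pooled)
    if n <= 3 * perplexity:
        raise ValueError(f"need more than {int(3 * perplexity)} points for perplexity={perplexity}")
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(pooled)
    is_synth = np.zeros(n, dtype=bool)
    is_synth[len(real_codes) :] = True
    disp = {
        "real": tuple(np.var(emb[~is_synth], axis=0, ddof=1).tolist()),
        "synth": tuple(np.var(emb[is_synth], axis=0, ddof=1).tolist()),
    }
    return TsneDispersion(emb, is_synth, disp)


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------
@dataclass
class HistogramEntry:
    variable: str
    kind: str
    edges_or_levels: object
    real_counts: np.ndarray
    synth_counts: np.ndarray
    real_freq: np.ndarray
    synth_freq: np.ndarray


def histogram_report(
    real: ConsolidatedDataset, synth: ConsolidatedDataset, bins: int = DEFAULT_BINS
) -> list[HistogramEntry]:
    """Shared-bin paired histograms per variable, for side-by-side plotting."""
    check_matching_schemas(real, synth)
    out = []
    for spec in real.schema:
        if spec.role == "static":
            rv, sv = real.static[spec.name], synth.static[spec.name]
        else:
            rv = real.events[spec.name] if len(real.events) else pd.Series(dtype=float)
            sv = synth.events[spec.name] if len(synth.events) else pd.Series(dtype=float)
        rv, sv = rv.dropna(), sv.dropna()
        if spec.kind == "categorical":
            levels = sorted(set(rv.astype(str)) | set(sv.astype(str)))
            rc = rv.astype(str).value_counts().reindex(levels).fillna(0).to_numpy(dtype=float)
            sc = sv.astype(str).value_counts().reindex(levels).fillna(0).to_numpy(dtype=float)
            support: object = tuple(levels)
        else:
            lo = float(min(rv.min(), sv.min())) if len(rv) and len(sv) else 0.0
            hi = float(max(rv.max(), sv.max())) if len(rv) and len(sv) else 1.0
            edges = np.linspace(lo, hi if hi > lo else lo + 1.0, bins + 1)
            rc = np.histogram(rv.to_numpy(dtype=float), bins=edges)[0].astype(float)
            sc = np.histogram(sv.to_numpy(dtype=float), bins=edges)[0].astype(float)
            support = edges
        out.append(
            HistogramEntry(
                spec.name,
                spec.kind,
                support,
                rc,
                sc,
                rc / max(rc.sum(), 1.0),
                sc / max(sc.sum(), 1.0),
            )
        )
    return out
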