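"""Disclosure-risk auditing: distance to closest record and membership inference.

DCR measures, for every query record, the exact Euclidean distance to its
nearest neighbour in a reference set, on the shared encoded representation
(one-hot categoricals, min-max numerics, mask-zeroed padded sequences). A
minimum distance near zero means a synthetic record nearly duplicates a real
one. The comparison of interest pairs the generator's training data T against a
real holdout H (baseline: how close do *real* strangers get?) and against the
synthetic sample S; risk is flagged when synthetic records come closer to T
than the holdout does.

The membership-inference test (MIT) attacks a label classifier trained on T:
shadow models trained on disjoint in/out subsamples of S teach an attack model
to recognize "was this record in training?" from prediction vectors; the attack
is then scored on a 1:1 balanced mix of members (T) and non-members (H).
Accuracy near 50% means the synthetic data does not leak membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .dataset import ConsolidatedDataset, check_matching_schemas
from .encoding import FeatureEncoder, summary_features


@dataclass
class SplitTriple:
    """Target training data T, real holdout H, synthetic sample S."""

    T: ConsolidatedDataset
    H: ConsolidatedDataset
    S: ConsolidatedDataset

    def __post_init__(self) -> None:
        if set(self.T.patient_ids) & set(self.H.patient_ids):
            raise ValueError("T and H must be disjoint by patient id")


@dataclass
class DcrResult:
    pair: str  # "T-H" | "T-S" | free-form
    distances: np.ndarray = field(repr=False)
    min: float = 0.0
    mean: float = 0.0
    quantiles: dict = field(default_factory=dict)
    convention: str = "euclidean on one-hot/min-max encoded, mask-zeroed padded sequences"

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        self.min = float(d.min())
        self.mean = float(d.mean())
        self.quantiles = {
            q: float(np.quantile(d, q)) for q in (0.01, 0.05, 0.25, 0.5, 0.75, 0.95)
        }


def _shared_flat(query: ConsolidatedDataset, reference: ConsolidatedDataset):
    check_matching_schemas(query, reference)
    max_len = int(
        max(
            np.max(query.sequence_lengths().to_numpy(), initial=1),
            np.max(reference.sequence_lengths().to_numpy(), initial=1),
        )
    )
    enc = FeatureEncoder(query.schema, max_seq_len=max_len)
    return enc.flatten(enc.encode(query)), enc.flatten(enc.encode(reference))


def dcr(query: ConsolidatedDataset, reference: ConsolidatedDataset, pair: str = "") -> DcrResult:
    """Exact nearest-neighbour distance from each query record to the reference set."""
    if reference.n_patients == 0:
        raise ValueError("reference set is empty")
    xq, xr = _shared_flat(query, reference)
    nn = NearestNeighbors(n_neighbors=1, algorithm="brute", metric="euclidean").fit(xr)
    dist, _ = nn.kneighbors(xq)
    return DcrResult(pair or "query-reference", dist[:, 0])


@dataclass
class DcrComparison:
    t_h: DcrResult
    t_s: DcrResult
    risk_flagged: bool
    verdict: str


def dcr_compare(triple: SplitTriple) -> DcrComparison:
    """DCR of the holdout vs T and of the synthetic sample vs T, plus a verdict.

    Risk is flagged when synthetic records get closer to the training data than
    genuinely unseen real records do (min DCR(T-S) < min DCR(T-H))."""
    t_h = dcr(triple.H, triple.T, pair="T-H")
    t_s = dcr(triple.S, triple.T, pair="T-S")
    flagged = t_s.min < t_h.min
    verdict = (
        "elevated disclosure risk: synthetic records approach training records "
        "more closely than holdout records do"
        if flagged
        else "no elevated disclosure risk: synthetic records are no closer to the "
        "training data than unseen real records"
    )
    return DcrComparison(t_h, t_s, flagged, verdict)


# ---------------------------------------------------------------------------
# Membership inference
# ---------------------------------------------------------------------------
@dataclass
class MitResult:
    accuracy: float
    attack_set_size: int
    n_members: int
    n_non_members: int
    n_shadow_models: int
    attack_model: str


def _label_vector(dataset: ConsolidatedDataset, label: str) -> np.ndarray:
    spec = dataset.schema.get(label)
    if spec.kind != "categorical" or len(spec.levels) != 2:
        raise ValueError(f"label {label!r} must be binary categorical")
    return (dataset.static[label].astype(str) == spec.levels[1]).to_numpy().astype(int)


def _attack_features(model, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per record: class-probability vector, predicted label, true label."""
    p = model.predict_proba(x)
    pred = p.argmax(axis=1)
    return np.column_stack([p, pred, y])


def membership_inference_test(
    triple: SplitTriple,
    label: str = "dead",
    target_spec=None,
    shadow_spec=None,
    attack_spec=None,
    n_shadow: int = 4,
    seed: int = 0,
) -> MitResult:
    """Shadow-model membership attack against a label classifier trained on T.

    The target model (a probability-calibrated support-vector classifier by
    default) is trained on T. ``n_shadow`` shadow models are trained on disjoint
    "in" subsamples of S, with matched disjoint "out" subsamples; their
    prediction vectors, labelled in/out, train the attack model. The attack is
    evaluated on the target model's predictions for an exactly 1:1 balanced set
    of members (T) and non-members (H).
    """
    if target_spec is None:
        target_spec = SVC(probability=True, random_state=seed)
    if shadow_spec is None:
        shadow_spec = SVC(probability=True, random_state=seed)
    if attack_spec is None:
        attack_spec = SVC(probability=True, random_state=seed)
    rng = np.random.default_rng(seed)
    exclude = (label, "survival_days")
    ft = summary_features(triple.T, exclude=exclude)
    fh = summary_features(triple.H, exclude=exclude, schema=triple.T.schema)[ft.columns]
    fs = summary_features(triple.S, exclude=exclude, schema=triple.T.schema)[ft.columns]
    yt, yh, ys = (
        _label_vector(triple.T, label),
        _label_vector(triple.H, label),
        _label_vector(triple.S, label),
    )

    # 1:1 member/non-member evaluation set
    m = min(len(ft), len(fh))
    idx_t = rng.choice(len(ft), m, replace=False)
    idx_h = rng.choice(len(fh), m, replace=False)

    # shadow splits: 2 * n_shadow disjoint chunks of S (in/out per shadow)
    chunk = len(fs) // (2 * n_shadow)
    if chunk < 10:
        raise ValueError(
            f"synthetic set too small for {n_shadow} shadow models: need >= {20 * n_shadow} records"
        )
    perm = rng.permutation(len(fs))
    xs, ys_arr = fs.to_numpy(), ys
    attack_x, attack_y = [], []
    for k in range(n_shadow):
        in_idx = perm[2 * k * chunk : (2 * k + 1) * chunk]
        out_idx = perm[(2 * k + 1) * chunk : (2 * k + 2) * chunk]
        if len(np.unique(ys_arr[in_idx])) < 2:
            raise ValueError("shadow training chunk has a single label class")
        shadow = clone(shadow_spec)
        shadow.fit(xs[in_idx], ys_arr[in_idx])
        attack_x.append(_attack_features(shadow, xs[in_idx], ys_arr[in_idx]))
        attack_y.append(np.ones(len(in_idx)))
        attack_x.append(_attack_features(shadow, xs[out_idx], ys_arr[out_idx]))
        attack_y.append(np.zeros(len(out_idx)))
    attack = clone(attack_spec)
    attack.fit(np.concatenate(attack_x), np.concatenate(attack_y))

    target = clone(target_spec)
    target.fit(ft.to_numpy(), yt)
    eval_x = np.concatenate(
        [
            _attack_features(target, ft.to_numpy()[idx_t], yt[idx_t]),
            _attack_features(target, fh.to_numpy()[idx_h], yh[idx_h]),
        ]
    )
    eval_y = np.concatenate([np.ones(m), np.zeros(m)])
    acc = float((attack.predict(eval_x) == eval_y).mean())
    return MitResult(acc, 2 * m, m, m, n_shadow, type(attack_spec).__name__)
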