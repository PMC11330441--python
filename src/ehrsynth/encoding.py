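"""Feature encoding shared by the generator, the privacy metrics and the classifiers.

Two representations are produced from a :class:`~ehrsynth.dataset.ConsolidatedDataset`:

* the *padded* representation used by the autoencoder and by distance-to-closest-
  record: static one-hot / min-max features plus a (n, max_seq_len, channels)
  sequence tensor with an explicit row-validity mask. Dynamic categoricals carry
  an extra "missing" level; dynamic numerics carry a presence flag; the
  TIMESTAMP axis is stored as non-negative inter-event gaps so any decoded
  sequence is sorted by construction.
* *summary* features (per-variable aggregates) used by the train-on-synthetic /
  propensity / membership classifiers, where padded tensors would be wasteful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import PATIENT_ID, TIMESTAMP, ConsolidatedDataset, Schema


@dataclass
class EncodedData:
    static: np.ndarray  # (n, d_static)
    seq: np.ndarray  # (n, L, d_dyn)
    mask: np.ndarray  # (n, L) 1 = real event row
    lengths: np.ndarray  # (n,)
    patient_ids: np.ndarray


class FeatureEncoder:
    """Schema-driven encoder with an exact inverse for in-range values."""

    def __init__(self, schema: Schema, max_seq_len: int | None = None):
        self.schema = schema
        self.max_seq_len = max_seq_len
        # static layout
        self.static_slices: list[tuple] = []  # (spec, slice)
        pos = 0
        for spec in schema.static:
            width = len(spec.levels) if spec.kind == "categorical" else 1
            self.static_slices.append((spec, slice(pos, pos + width)))
            pos += width
        self.static_dim = pos
        # dynamic layout (TIMESTAMP first, as a single gap channel)
        self.dyn_slices: list[tuple] = []
        pos = 0
        for spec in schema.dynamic:
            if spec.name == TIMESTAMP:
                width = 1
            elif spec.kind == "categorical":
                width = len(spec.levels) + 1  # + missing
            else:
                width = 2  # scaled value + presence flag
            self.dyn_slices.append((spec, slice(pos, pos + width)))
            pos += width
        self.dyn_dim = pos
        # gaps live on a log1p axis: inter-event intervals are long-tailed and a
        # linear scale against the maximum timestamp squashes typical gaps to ~0
        ts = schema.get(TIMESTAMP)
        self.gap_log_scale = np.log1p(max(ts.vmax, 1.0))

    # ---- helpers -----------------------------------------------------------
    @staticmethod
    def _scale(spec, x):
        x = np.asarray(x, dtype=float)
        rng = spec.vmax - spec.vmin
        if rng <= 0:
            return np.zeros_like(x)
        if spec.transform == "log1p":
            return np.log1p(np.maximum(x - spec.vmin, 0.0)) / np.log1p(rng)
        return (x - spec.vmin) / rng

    @staticmethod
    def _unscale(spec, z):
        z = np.asarray(z, dtype=float)
        rng = spec.vmax - spec.vmin
        if rng <= 0:
            out = np.full_like(z, spec.vmin)
        elif spec.transform == "log1p":
            out = np.expm1(z * np.log1p(rng)) + spec.vmin
        else:
            out = z * rng + spec.vmin
        if spec.integer:
            out = np.round(out)
        return out

    def _level_index(self, spec, values) -> np.ndarray:
        lut = {lv: i for i, lv in enumerate(spec.levels)}
        out = np.empty(len(values), dtype=int)
        for i, v in enumerate(values):
            try:
                out[i] = lut[str(v)]
            except KeyError:
                raise KeyError(f"unseen category {v!r} for variable {spec.name!r}") from None
        return out

    # ---- forward -----------------------------------------------------------
    def encode(self, dataset: ConsolidatedDataset) -> EncodedData:
        n = dataset.n_patients
        lengths = dataset.sequence_lengths().to_numpy()
        L = self.max_seq_len if self.max_seq_len is not None else max(int(lengths.max(initial=1)), 1)
        self.max_seq_len = L
        if lengths.max(initial=0) > L:
            raise ValueError(
                f"sequence of length {int(lengths.max())} exceeds max_seq_len={L}"
            )

        static = np.zeros((n, self.static_dim))
        for spec, sl in self.static_slices:
            col = dataset.static[spec.name]
            if spec.kind == "categorical":
                idx = self._level_index(spec, col.to_numpy())
                static[np.arange(n), sl.start + idx] = 1.0
            else:
                static[:, sl.start] = self._scale(spec, col.to_numpy())

        seq = np.zeros((n, L, self.dyn_dim))
        mask = np.zeros((n, L))
        pid_to_row = {p: i for i, p in enumerate(dataset.patient_ids)}
        if len(dataset.events):
            for pid_i, grp in dataset.events.groupby(PATIENT_ID, sort=False):
                i = pid_to_row[pid_i]
                k = len(grp)
                mask[i, :k] = 1.0
                ts = grp[TIMESTAMP].to_numpy(dtype=float)
                gaps = np.diff(ts, prepend=0.0)
                for spec, sl in self.dyn_slices:
                    if spec.name == TIMESTAMP:
                        seq[i, :k, sl.start] = np.clip(
                            np.log1p(np.maximum(gaps, 0.0)) / self.gap_log_scale, 0.0, 1.0
                        )
                        continue
                    vals = grp[spec.name]
                    present = vals.notna().to_numpy()
                    if spec.kind == "categorical":
                        offs = np.full(k, len(spec.levels))  # missing slot
                        if present.any():
                            offs[present] = self._level_index(spec, vals[present].to_numpy())
                        seq[i, np.arange(k), sl.start + offs] = 1.0
                    else:
                        v = np.zeros(k)
                        if present.any():
                            v[present] = self._scale(spec, vals[present].to_numpy())
                        seq[i, :k, sl.start] = v
                        seq[i, :k, sl.start + 1] = present.astype(float)
        return EncodedData(static, seq, mask, lengths, dataset.patient_ids.copy())

    def flatten(self, enc: EncodedData) -> np.ndarray:
        """Single matrix per patient: static + mask-zeroed padded sequence + length."""
        n = len(enc.static)
        seq = (enc.seq * enc.mask[:, :, None]).reshape(n, -1)
        ln = (enc.lengths / max(self.max_seq_len, 1))[:, None]
        return np.concatenate([enc.static, seq, ln], axis=1)

    # ---- inverse -----------------------------------------------------------
    def decode(
        self,
        static: np.ndarray,
        seq: np.ndarray,
        lengths: np.ndarray,
        patient_ids=None,
    ) -> ConsolidatedDataset:
        """Inverse transform. Categorical slots must be one-hot-like (argmax is
        taken); numeric slots are clipped into [0, 1] before unscaling."""
        n = len(static)
        if patient_ids is None:
            patient_ids = np.array([f"S{i:06d}" for i in range(n)])
        stat_cols = {PATIENT_ID: patient_ids}
        for spec, sl in self.static_slices:
            block = static[:, sl]
            if spec.kind == "categorical":
                idx = block.argmax(axis=1)
                if idx.max(initial=0) >= len(spec.levels):
                    raise ValueError(f"level index out of range for {spec.name!r}")
                stat_cols[spec.name] = np.array(spec.levels, dtype=object)[idx]
            else:
                stat_cols[spec.name] = self._unscale(spec, np.clip(block[:, 0], 0.0, 1.0))
        static_df = pd.DataFrame(stat_cols)

        rows = []
        for i in range(n):
            k = int(lengths[i])
            if k <= 0:
                continue
            g = np.clip(seq[i, :k, self.dyn_slices[0][1].start], 0.0, 1.0)
            gaps = np.expm1(g * self.gap_log_scale)
            ts = np.round(np.cumsum(np.maximum(gaps, 0.0))).astype(int)
            for t in range(k):
                row = {PATIENT_ID: patient_ids[i], TIMESTAMP: int(ts[t])}
                for spec, sl in self.dyn_slices:
                    if spec.name == TIMESTAMP:
                        continue
                    block = seq[i, t, sl]
                    if spec.kind == "categorical":
                        idx = int(block.argmax())
                        row[spec.name] = (
                            np.nan if idx == len(spec.levels) else spec.levels[idx]
                        )
                    else:
                        if block[1] > 0.5:
                            row[spec.name] = float(
                                self._unscale(spec, np.clip(block[0], 0.0, 1.0))
                            )
                        else:
                            row[spec.name] = np.nan
                rows.append(row)
        ev_cols = [PATIENT_ID, TIMESTAMP] + [
            s.name for s, _ in self.dyn_slices if s.name != TIMESTAMP
        ]
        events = pd.DataFrame(rows, columns=ev_cols)
        return ConsolidatedDataset(static_df, events, self.schema)


def encode_features(dataset: ConsolidatedDataset, max_seq_len: int | None = None):
    """Fit an encoder on the dataset's schema and return (encoder, encoded data)."""
    enc = FeatureEncoder(dataset.schema, max_seq_len=max_seq_len)
    data = enc.encode(dataset)
    return enc, data


def summary_features(
    dataset: ConsolidatedDataset,
    exclude: tuple[str, ...] = (),
    schema: Schema | None = None,
) -> pd.DataFrame:
    """Flat per-patient feature frame for classifier-based metrics.

    Static categoricals become level indicators, static numerics are min-max
    scaled; each dynamic numeric contributes (count, mean, last), each dynamic
    categorical its per-level event fractions; sequence length and mean
    inter-event gap summarize the time axis. Pass a common ``schema`` when two
    datasets must be featurized on identical scales.
    """
    schema = schema or dataset.schema
    idx = pd.Index(dataset.patient_ids, name=PATIENT_ID)
    out = pd.DataFrame(index=idx)
    for spec in schema.static:
        if spec.name in exclude:
            continue
        col = dataset.static.set_index(PATIENT_ID)[spec.name].reindex(idx)
        if spec.kind == "categorical":
            for lv in spec.levels:
                out[f"{spec.name}={lv}"] = (col.astype(str) == lv).astype(float)
        else:
            out[spec.name] = FeatureEncoder._scale(spec, col.to_numpy())
    ev = dataset.events
    grouped = ev.groupby(PATIENT_ID) if len(ev) else None
    lengths = dataset.sequence_lengths().to_numpy(dtype=float)
    out["n_events"] = lengths
    if grouped is not None:
        ts_max = grouped[TIMESTAMP].max().reindex(idx).fillna(0.0)
    else:
        ts_max = pd.Series(0.0, index=idx)
    out["mean_gap"] = ts_max.to_numpy() / np.maximum(lengths, 1.0)
    for spec in schema.dynamic:
        if spec.name in exclude or spec.name == TIMESTAMP:
            continue
        if grouped is None:
            if spec.kind == "numeric":
                out[f"{spec.name}__count"] = 0.0
                out[f"{spec.name}__mean"] = 0.0
                out[f"{spec.name}__last"] = 0.0
            else:
                for lv in spec.levels:
                    out[f"{spec.name}={lv}__frac"] = 0.0
            continue
        col = ev[spec.name]
        if spec.kind == "numeric":
            scaled = pd.Series(
                FeatureEncoder._scale(spec, col.to_numpy()), index=ev.index
            ).where(col.notna())
            g = scaled.groupby(ev[PATIENT_ID])
            out[f"{spec.name}__count"] = g.count().reindex(idx).fillna(0.0)
            out[f"{spec.name}__mean"] = g.mean().reindex(idx).fillna(0.0)
            out[f"{spec.name}__last"] = g.last().reindex(idx).fillna(0.0)
        else:
            denom = np.maximum(lengths, 1.0)
            for lv in spec.levels:
                hits = (col.astype("object") == lv).groupby(ev[PATIENT_ID]).sum()
                out[f"{spec.name}={lv}__frac"] = hits.reindex(idx).fillna(0.0).to_numpy() / denom
    return out.astype(float)
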