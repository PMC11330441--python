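import numpy as np
import pandas as pd
import pytest

from ehrsynth.dataset import TIMESTAMP
from ehrsynth.encoding import FeatureEncoder, encode_features
from ehrsynth.preprocess import (
    compute_diff,
    consolidate,
    select_cohort,
    split_T_H,
)
from ehrsynth.sim import SimConfig, generate_cohort, inject_inconsistencies

D = pd.Timestamp


class TestComputeDiff:
    def test_surgery_only(self):
        assert compute_diff(D("2020-01-01"), D("2020-02-15"), pd.NaT) == 45

    def test_negative_diff(self):
        assert compute_diff(D("2020-01-01"), D("2019-12-30"), pd.NaT) == -2

    def test_min_of_two_dates(self):
        assert compute_diff(D("2020-01-01"), D("2020-03-01"), D("2020-01-11")) == 10

    def test_both_null(self):
        assert compute_diff(D("2020-01-01"), pd.NaT, pd.NaT) is None

    def test_missing_diagnosis_flags_not_raises(self):
        assert compute_diff(pd.NaT, D("2020-01-01"), pd.NaT) is None


class TestSelectCohort:
    def _toy(self, diffs):
        """Cohort of len(diffs) patients with prescribed Diff values (None = no treatment)."""
        diag = D("2020-01-01")
        static = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(len(diffs))],
                "first_diagnosis_date": diag,
                "death_date": pd.NaT,
                "age": 60.0,
                "sex": "M",
                "diagnosis_code": "C18",
                "stage": "II",
            }
        )
        rows = [
            (f"P{i}", diag + pd.Timedelta(days=d), "LAR", 100.0)
            for i, d in enumerate(diffs)
            if d is not None
        ]
        surgery = pd.DataFrame(rows, columns=["patient_id", "event_date", "op_kind_cd", "op_duration_min"])
        empty = surgery.iloc[:0]
        from ehrsynth.sim import CohortSource

        return CohortSource(static, {"surgery": surgery, "chemo": empty.copy(), "labs": empty.copy()})

    def test_partition_on_toy_cohort(self):
        res = select_cohort(self._toy([10, 45, 100, -3, None]), cutoff_days=90)
        assert res.partition["target"] == 2
        assert res.partition["ge_cutoff"] == 1
        assert res.partition["negative"] == 1
        assert res.partition["null"] == 1

    def test_partition_sums_to_total(self):
        cfg = SimConfig(n_patients=600, seed=8, frac_diff_violations=0.15, frac_null_treatment=0.1)
        res = select_cohort(inject_inconsistencies(generate_cohort(cfg), cfg))
        p = res.partition
        assert p["total"] == p["target"] + p["ge_cutoff"] + p["negative"] + p["null"]

    def test_huge_cutoff_keeps_all_treated(self):
        res = select_cohort(self._toy([0, 5, 400]), cutoff_days=10**6)
        assert res.partition["target"] == 3

    def test_diff_zero_retained(self):
        res = select_cohort(self._toy([0]), cutoff_days=90)
        assert res.partition["target"] == 1

    def test_retained_fraction_matches_injection(self):
        cfg = SimConfig(n_patients=2000, seed=2, frac_diff_violations=0.2)
        res = select_cohort(inject_inconsistencies(generate_cohort(cfg), cfg))
        assert abs(res.partition["target"] / 2000 - 0.8) < 0.02


class TestConsolidate:
    def test_timestamps_sorted_nonnegative(self, small_dataset):
        ev = small_dataset.events
        assert (ev[TIMESTAMP] >= 0).all()
        for _, grp in ev.groupby("patient_id"):
            assert grp[TIMESTAMP].is_monotonic_increasing

    def test_same_day_events_merge(self, small_dataset):
        ev = small_dataset.events
        assert not ev.duplicated(subset=["patient_id", TIMESTAMP]).any()

    def test_survival_time_nonnegative_and_consistent(self, small_cohort, small_dataset):
        st = small_dataset.static
        assert (st["survival_days"] >= 0).all()
        src = small_cohort.static_table.set_index("patient_id")
        dead = st[st["dead"] == "1"]
        for _, row in dead.head(20).iterrows():
            expect = (
                src.loc[row["patient_id"], "death_date"]
                - src.loc[row["patient_id"], "first_diagnosis_date"]
            ).days
            assert row["survival_days"] == expect

    def test_payload_conservation(self, small_cohort):
        """Non-null payload counts are conserved up to logged drops."""
        ds = consolidate(select_cohort(small_cohort).cohort, censor_date="2021-07-31")
        sel = select_cohort(small_cohort).cohort
        payload_cols = {
            "surgery": ["op_kind_cd", "op_duration_min"],
            "chemo": ["regimen_cd", "cycle_no", "dose_mg"],
            "labs": ["marker_cd", "result_value"],
        }
        n_in = sum(
            int(tab[cols].notna().sum().sum())
            for (name, tab), cols in zip(sel.event_tables.items(), payload_cols.values())
        )
        out_cols = [c for c in ds.events.columns if c not in ("patient_id", TIMESTAMP)]
        n_out = int(ds.events[out_cols].notna().sum().sum())
        dropped = ds.meta["dropped_pre_diagnosis"] + ds.meta["dropped_same_day_collisions"]
        assert n_in == n_out + dropped

    def test_schema_covers_all_payloads(self, small_dataset):
        names = {v.name for v in small_dataset.schema}
        assert {"sex", "age", "dead", "survival_days", TIMESTAMP}.issubset(names)
        assert {"op_kind_cd", "regimen_cd", "marker_cd", "result_value"}.issubset(names)


class TestSplit:
    def test_sizes_and_disjointness(self, medium_dataset):
        t, h = split_T_H(medium_dataset, 0.8, seed=7)
        assert t.n_patients == round(0.8 * medium_dataset.n_patients)
        assert set(t.patient_ids).isdisjoint(h.patient_ids)

    def test_exhaustive(self, medium_dataset):
        t, h = split_T_H(medium_dataset, 0.8, seed=7)
        assert set(t.patient_ids) | set(h.patient_ids) == set(medium_dataset.patient_ids)

    def test_seed_determinism(self, medium_dataset):
        t1, _ = split_T_H(medium_dataset, 0.7, seed=3)
        t2, _ = split_T_H(medium_dataset, 0.7, seed=3)
        assert list(t1.patient_ids) == list(t2.patient_ids)

    def test_degenerate_split_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            split_T_H(small_dataset, 0.999, seed=0)


class TestEncodeFeatures:
    def test_one_hot_rows_sum_to_one(self, small_dataset):
        enc, data = encode_features(small_dataset)
        for spec, sl in enc.static_slices:
            if spec.kind == "categorical":
                assert np.allclose(data.static[:, sl].sum(axis=1), 1.0)

    def test_round_trip_exact(self, small_dataset):
        enc, data = encode_features(small_dataset)
        back = enc.decode(data.static, data.seq, data.lengths, patient_ids=small_dataset.patient_ids)
        for spec in small_dataset.schema.static:
            a = small_dataset.static[spec.name]
            b = back.static[spec.name]
            if spec.kind == "categorical":
                assert (a.astype(str) == b.astype(str)).all()
            else:
                assert np.abs(a.to_numpy(dtype=float) - b.to_numpy(dtype=float)).max() < 1e-6
        a = small_dataset.events.sort_values(["patient_id", TIMESTAMP]).reset_index(drop=True)
        b = back.events.sort_values(["patient_id", TIMESTAMP]).reset_index(drop=True)
        assert (a[TIMESTAMP].to_numpy() == b[TIMESTAMP].to_numpy()).all()

    def test_degenerate_constant_numeric(self):
        from ehrsynth.dataset import Schema, VariableSpec
        from ehrsynth.dataset import ConsolidatedDataset

        schema = Schema(
            (
                VariableSpec("x", "static", "numeric", vmin=5.0, vmax=5.0),
                VariableSpec(TIMESTAMP, "dynamic", "numeric", vmin=0.0, vmax=1.0),
            )
        )
        ds = ConsolidatedDataset(
            pd.DataFrame({"patient_id": ["a", "b"], "x": [5.0, 5.0]}),
            pd.DataFrame(columns=["patient_id", TIMESTAMP]),
            schema,
        )
        enc = FeatureEncoder(schema, max_seq_len=1)
        data = enc.encode(ds)
        assert np.allclose(data.static, 0.0)
        back = enc.decode(data.static, data.seq, data.lengths, patient_ids=ds.patient_ids)
        assert (back.static["x"] == 5.0).all()

    def test_unseen_category_errors(self, small_dataset):
        enc = FeatureEncoder(small_dataset.schema)
        bad = small_dataset.copy()
        bad.static.loc[0, "sex"] = "X"
        with pytest.raises(KeyError, match="unseen category"):
            enc.encode(bad)

    def test_too_long_sequence_errors(self, small_dataset):
        enc = FeatureEncoder(small_dataset.schema, max_seq_len=1)
        with pytest.raises(ValueError, match="max_seq_len"):
            enc.encode(small_dataset)

    def test_flatten_width_and_mask_zeroing(self, small_dataset):
        enc, data = encode_features(small_dataset)
        flat = enc.flatten(data)
        L = enc.max_seq_len
        assert flat.shape == (small_dataset.n_patients, enc.static_dim + L * enc.dyn_dim + 1)
        # padded rows contribute exactly zero
        i = int(np.argmin(data.lengths))
        k = int(data.lengths[i])
        if k < L:
            assert np.allclose(data.seq[i, k:] * data.mask[i, k:, None], 0.0)
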