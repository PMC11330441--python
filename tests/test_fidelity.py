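import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrsynth.fidelity import (
    hellinger_distance,
    hellinger_from_probs,
    hellinger_table,
    histogram_report,
    propensity_from_probs,
    propensity_mse,
    tsne_dispersion,
    tstr_trts,
)
from ehrsynth.preprocess import split_T_H


class TestHellinger:
    def test_identical_distributions_zero(self):
        r = ["a", "b", "c", "d"] * 25
        res = hellinger_distance(r, list(r), "categorical")
        assert res.distance == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        res = hellinger_distance(["a"] * 10, ["b"] * 10, "categorical")
        assert res.distance == pytest.approx(1.0)

    def test_half_overlap_closed_form(self):
        # P = (0.5, 0.5), Q = (1, 0) -> sqrt(1 - sqrt(0.5))
        res = hellinger_distance(["a", "b"], ["a", "a"], "categorical")
        assert res.distance == pytest.approx(np.sqrt(1 - np.sqrt(0.5)), abs=1e-12)

    def test_numeric_shared_bins(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 4000)
        res = hellinger_distance(a, a.copy(), "numeric", bins=30)
        assert res.distance == 0.0

    def test_all_null_errors(self):
        with pytest.raises(ValueError, match="foo"):
            hellinger_distance([np.nan], [1.0], "numeric", variable="foo")

    def test_constant_both_sides(self):
        res = hellinger_distance([3.0] * 5, [3.0] * 7, "numeric")
        assert res.distance == 0.0
        assert res.note == "degenerate range"

    @given(
        st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
        st.lists(st.floats(0.01, 1), min_size=2, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, p, q):
        k = min(len(p), len(q))
        p = np.array(p[:k]) / sum(p[:k])
        q = np.array(q[:k]) / sum(q[:k])
        h1 = hellinger_from_probs(p, q)
        h2 = hellinger_from_probs(q, p)
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert 0.0 <= h1 <= 1.0


class TestHellingerTable:
    def test_copy_gives_all_zero(self, small_dataset):
        results = hellinger_table(small_dataset, small_dataset.copy())
        assert all(r.distance == pytest.approx(0.0, abs=1e-12) for r in results)
        assert len(results) == len(small_dataset.schema)

    def test_permuted_column_is_local(self, small_dataset):
        other = small_dataset.copy()
        rng = np.random.default_rng(0)
        # shuffling a column leaves its marginal unchanged; remapping levels changes it
        vals = other.static["stage"].astype(str).to_numpy()
        mapping = {"I": "IV", "II": "III", "III": "II", "IV": "I"}
        other.static["stage"] = [mapping[v] for v in vals]
        results = {r.variable: r.distance for r in hellinger_table(small_dataset, other)}
        assert results["stage"] > 0.05
        for name, d in results.items():
            if name != "stage":
                assert d == pytest.approx(0.0, abs=1e-12)

    def test_trained_generator_close(self, small_dataset, synth_sample):
        results = hellinger_table(small_dataset, synth_sample)
        assert np.mean([r.distance for r in results]) < 0.20  # reduced-scale run

    def test_schema_mismatch_errors(self, small_dataset, medium_dataset):
        bad = medium_dataset.copy()
        from ehrsynth.dataset import Schema, VariableSpec

        bad.schema = Schema(tuple(list(bad.schema.variables)[:-1]))
        bad.events = bad.events.drop(columns=[bad.schema.variables[-1].name], errors="ignore")
        with pytest.raises(ValueError, match="schema mismatch"):
            hellinger_table(small_dataset, bad)


class TestTstrTrts:
    def test_bootstrap_synth_agrees_with_trtr(self, medium_dataset):
        train, test = split_T_H(medium_dataset, 0.7, seed=1)
        rng = np.random.default_rng(2)
        boot_ids = rng.choice(train.patient_ids, train.n_patients, replace=True)
        # bootstrap with unique ids so subset() keeps duplicates collapsed is avoided
        boot = train.subset(np.unique(boot_ids))
        results = {r.direction: r.auc for r in tstr_trts(train, test, boot)}
        assert abs(results["TSTR"] - results["TRTR"]) <= 0.05
        assert abs(results["TRTS"] - results["TRTR"]) <= 0.08

    def test_no_signal_label_chance_auc(self, medium_dataset):
        scrambled = medium_dataset.copy()
        rng = np.random.default_rng(3)
        scrambled.static["dead"] = rng.permutation(scrambled.static["dead"].to_numpy())
        rest, test = split_T_H(scrambled, 0.7, seed=1)
        train, pseudo_synth = split_T_H(rest, 0.5, seed=2)  # disjoint stand-in synth
        results = {r.direction: r.auc for r in tstr_trts(train, test, pseudo_synth)}
        for auc in results.values():
            assert abs(auc - 0.5) < 0.12

    def test_single_class_side_errors(self, medium_dataset):
        train, test = split_T_H(medium_dataset, 0.7, seed=1)
        dead_only = test.subset(test.static.loc[test.static["dead"] == "1", "patient_id"])
        with pytest.raises(ValueError, match="single-class"):
            tstr_trts(train, dead_only, train.copy())


class TestPropensityMse:
    def test_constant_half_probs_give_zero(self):
        unscaled, scaled = propensity_from_probs(np.full(100, 0.5))
        assert unscaled == 0.0 and scaled == 0.0

    def test_perfect_discriminator(self):
        p = np.concatenate([np.zeros(50), np.ones(50)])
        unscaled, scaled = propensity_from_probs(p)
        assert unscaled == pytest.approx(0.25)
        assert scaled == pytest.approx(1.0)

    def test_three_quarters_probs(self):
        unscaled, scaled = propensity_from_probs(np.full(40, 0.75))
        assert scaled == pytest.approx(0.25)
        assert unscaled == pytest.approx(0.0625)

    def test_scaling_identity(self):
        rng = np.random.default_rng(0)
        unscaled, scaled = propensity_from_probs(rng.random(200))
        assert scaled == pytest.approx(unscaled / 0.25, rel=1e-12)

    def test_null_same_law_small(self, medium_dataset):
        """Two halves of one cohort are indistinguishable: scaled pMSE < 0.1."""
        from sklearn.linear_model import LogisticRegression

        a, b = split_T_H(medium_dataset, 0.5, seed=11)
        res = propensity_mse(a, b, classifier=LogisticRegression(max_iter=2000), seed=0)
        assert res.scaled_pmse < 0.1
        assert res.unscaled_pmse == pytest.approx(res.scaled_pmse * 0.25, rel=1e-9)

    def test_classifier_without_proba_rejected(self, medium_dataset):
        from sklearn.svm import LinearSVC

        a, b = split_T_H(medium_dataset, 0.5, seed=11)
        with pytest.raises(ValueError, match="predict_proba"):
            propensity_mse(a, b, classifier=LinearSVC())


class TestTsneDispersion:
    def test_identical_groups_equal_dispersion(self):
        rng = np.random.default_rng(0)
        codes = rng.normal(size=(120, 8))
        res = tsne_dispersion(codes, codes.copy(), seed=0, perplexity=20)
        assert res.embedding.shape == (240, 2)
        # identical point sets embed symmetrically: per-axis variances match closely
        r = np.array(res.dispersion["real"])
        s = np.array(res.dispersion["synth"])
        assert np.allclose(r, s, rtol=0.2)

    def test_contracted_synth_has_lower_dispersion(self):
        rng = np.random.default_rng(1)
        real = rng.normal(size=(150, 6))
        synth = real.mean(axis=0) + 0.3 * (real - real.mean(axis=0))
        res = tsne_dispersion(real, synth, seed=0, perplexity=25)
        assert sum(res.dispersion["synth"]) < sum(res.dispersion["real"])

    def test_too_few_points_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="perplexity"):
            tsne_dispersion(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)), perplexity=30)


class TestHistogramReport:
    def test_identical_datasets_identical_histograms(self, small_dataset):
        out = histogram_report(small_dataset, small_dataset.copy())
        for h in out:
            assert np.array_equal(h.real_counts, h.synth_counts)

    def test_counts_conserve_non_nulls(self, small_dataset, synth_sample):
        out = histogram_report(small_dataset, synth_sample)
        for h in out:
            spec = small_dataset.schema.get(h.variable)
            frame = small_dataset.static if spec.role == "static" else small_dataset.events
            assert h.real_counts.sum() == frame[h.variable].dropna().shape[0]

    def test_diff_histogram_matches_simulated_truth(self):
        """One-month-binned Diff distribution is recomputable from the cohort."""
        from ehrsynth.preprocess import select_cohort
        from ehrsynth.sim import SimConfig, generate_cohort

        cohort = generate_cohort(SimConfig(n_patients=800, seed=13))
        res = select_cohort(cohort)
        diffs = res.diff_values.dropna().to_numpy()
        counts, _ = np.histogram(diffs, bins=np.arange(0, 121, 30))
        assert counts.sum() == res.partition["target"] + res.partition["ge_cutoff"]
        assert counts[0] > counts[-1]  # treatment typically starts promptly
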