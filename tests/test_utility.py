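import itertools

import numpy as np
import pytest
from sksurv.metrics import concordance_index_censored

from ehrsynth.preprocess import split_T_H
from ehrsynth.utility import (
    brier_score,
    compare_utility,
    concordance_index,
    default_time_grid,
    fit_survival_model,
    integrated_brier_score,
    survival_outcomes,
    time_dependent_auc,
)


def brute_force_cindex(risk, times, events):
    """Exhaustive pair enumeration oracle (Harrell, 0.5 tie credit)."""
    num = den = 0.0
    for i, j in itertools.permutations(range(len(risk)), 2):
        if not events[i]:
            continue
        if not (times[i] < times[j] or (times[i] == times[j] and not events[j])):
            continue
        den += 1
        num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
    return num / den


class TestConcordanceIndex:
    def test_perfect_ranking(self):
        # risks reverse-ordered against event times -> full concordance
        assert concordance_index([0.9, 0.8, 0.1], [2, 4, 6], [1, 1, 1]) == 1.0

    def test_two_of_three_pairs(self):
        assert concordance_index([0.8, 0.9, 0.1], [2, 4, 6], [1, 1, 1]) == pytest.approx(2 / 3)

    def test_random_risks_near_half(self):
        rng = np.random.default_rng(0)
        n = 400
        c = concordance_index(rng.random(n), rng.exponential(1, n), np.ones(n))
        assert abs(c - 0.5) < 0.05

    def test_ties_get_half_credit(self):
        assert concordance_index([0.5, 0.5], [1, 2], [1, 1]) == 0.5

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([0.1, 0.2], [5, 5], [0, 0])

    def test_matches_bruteforce_and_sksurv_with_censoring(self):
        """Exhaustive oracle + independent library agree on small censored data."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(4, 9)
            times = rng.integers(1, 10, n).astype(float)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            risk = rng.random(n)
            try:
                ours = concordance_index(risk, times, events)
            except ValueError:
                continue
            assert ours == pytest.approx(brute_force_cindex(risk, times, events))
            sks = concordance_index_censored(events.astype(bool), times, risk)[0]
            assert ours == pytest.approx(sks, abs=1e-12)


class TestBrierScore:
    def test_constant_half_predictor_uncensored(self):
        times = np.array([5.0, 6.0, 1.0, 2.0])
        events = np.array([0, 0, 1, 1])  # statuses all known at t=4
        s = np.full(4, 0.5)
        assert brier_score(s, times, events, 4.0) == pytest.approx(0.25)

    def test_perfect_predictor_zero(self):
        times = np.array([5.0, 6.0, 1.0, 2.0])
        events = np.array([0, 0, 1, 1])
        s = np.array([1.0, 1.0, 0.0, 0.0])
        assert brier_score(s, times, events, 4.0) == 0.0

    def test_hand_computed_example(self):
        # statuses at t: alive, alive, dead, dead; preds 0.9 0.8 0.2 0.1
        times = np.array([9.0, 8.0, 2.0, 3.0])
        events = np.array([0, 0, 1, 1])
        s = np.array([0.9, 0.8, 0.2, 0.1])
        expect = np.mean([0.1**2, 0.2**2, 0.2**2, 0.1**2])
        assert brier_score(s, times, events, 5.0) == pytest.approx(expect)

    def test_equals_plain_mse_when_no_censoring_before_t(self):
        rng = np.random.default_rng(1)
        n = 50
        times = rng.integers(1, 100, n).astype(float)
        events = np.ones(n, dtype=int)  # no censoring at all
        s = rng.random(n)
        t = 40.0
        status = (times <= t).astype(float)
        plain = np.mean((1.0 - status - s) ** 2)
        assert brier_score(s, times, events, t) == pytest.approx(plain)

    def test_finite_under_heavy_censoring_fuzz(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(5, 30)
            times = rng.integers(1, 50, n).astype(float)
            events = (rng.random(n) < 0.2).astype(int)  # 80% censored
            if events.sum() == 0:
                events[np.argmax(times)] = 1
            t = float(np.quantile(times, 0.5))
            b = brier_score(rng.random(n), times, events, t)
            assert np.isfinite(b) and b >= 0.0


class TestIntegratedBrier:
    def test_flat_curve_equals_constant(self):
        times = np.array([9.0, 8.0, 2.0, 3.0])
        events = np.array([0, 0, 1, 1])
        grid = np.array([4.0, 5.0, 6.0])
        s = np.full((4, 3), 0.5)
        assert integrated_brier_score(s, times, events, grid) == pytest.approx(0.25)

    def test_two_point_trapezoid(self):
        # Brier curve (0, 0.2) over a 2-point grid -> 0.1
        times = np.array([10.0, 1.0])
        events = np.array([0, 1])
        s = np.array([[1.0, np.sqrt(0.8)], [0.0, np.sqrt(0.0)]])
        b0 = brier_score(s[:, 0], times, events, 2.0)
        b1 = brier_score(s[:, 1], times, events, 3.0)
        ibs = integrated_brier_score(s, times, events, np.array([2.0, 3.0]))
        assert ibs == pytest.approx((b0 + b1) / 2)

    def test_unsorted_grid_errors(self):
        with pytest.raises(ValueError, match="increasing"):
            integrated_brier_score(np.ones((2, 2)), np.array([1.0, 2.0]), np.array([1, 1]), np.array([3.0, 1.0]))


class TestSurvivalModel:
    def test_signal_recovery_on_holdout(self, split_medium):
        train, holdout = split_medium
        model = fit_survival_model(train, seed=0)
        times, events = survival_outcomes(holdout)
        c = concordance_index(model.predict_risk(holdout), times, events)
        assert c > 0.6  # age/stage drive the simulated hazard

    def test_survival_at_time_zero_is_one(self, split_medium):
        train, holdout = split_medium
        model = fit_survival_model(train, seed=0)
        s0 = model.predict_survival(holdout.subset(holdout.patient_ids[:10]), np.array([0.0]))
        assert np.allclose(s0, 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, split_medium):
        train, holdout = split_medium
        sub = holdout.subset(holdout.patient_ids[:20])
        a = fit_survival_model(train, seed=3).predict_risk(sub)
        b = fit_survival_model(train, seed=3).predict_risk(sub)
        assert np.array_equal(a, b)

    def test_no_events_errors(self, medium_dataset):
        alive = medium_dataset.subset(
            medium_dataset.static.loc[medium_dataset.static["dead"] == "0", "patient_id"][:50]
        )
        with pytest.raises(ValueError, match="no observed events"):
            fit_survival_model(alive)


class TestCompareUtility:
    def test_copy_synth_identical_rows(self, split_medium):
        train, holdout = split_medium
        grid = default_time_grid(*survival_outcomes(holdout), n_points=8)
        rep = compare_utility(train, train.copy(), holdout, t_grid=grid, seed=0)
        for key in ("c_index", "ibs", "brier_at_median_t"):
            assert rep.metrics["real"][key] == pytest.approx(rep.metrics["synthetic"][key])
        assert set(rep.metrics["real"]) == {"c_index", "ibs", "brier_at_median_t"}

    def test_label_permutation_destroys_signal(self, split_medium):
        train, holdout = split_medium
        rng = np.random.default_rng(4)
        scrambled = train.copy()
        perm = rng.permutation(len(scrambled.static))
        scrambled.static["dead"] = scrambled.static["dead"].to_numpy()[perm]
        scrambled.static["survival_days"] = scrambled.static["survival_days"].to_numpy()[perm]
        grid = default_time_grid(*survival_outcomes(holdout), n_points=8)
        rep = compare_utility(train, scrambled, holdout, t_grid=grid, seed=0)
        assert abs(rep.metrics["synthetic"]["c_index"] - 0.5) < 0.1
        assert rep.metrics["real"]["c_index"] > rep.metrics["synthetic"]["c_index"]

    def test_overlapping_holdout_rejected(self, split_medium):
        train, _ = split_medium
        with pytest.raises(ValueError, match="overlaps"):
            compare_utility(train, train.copy(), train)


class TestTimeDependentAuc:
    def test_informative_predictor_beats_chance(self, split_medium):
        train, holdout = split_medium
        model = fit_survival_model(train, seed=0)
        times, events = survival_outcomes(holdout)
        t = float(np.quantile(times[events.astype(bool)], 0.5))
        s = model.predict_survival(holdout, np.array([t]))[:, 0]
        assert time_dependent_auc(s, times, events, t) > 0.55
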