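"""Kaplan-Meier, time-dependent concordance and IPCW Brier score."""

import numpy as np
import pytest

from tallysurv import (
    SurvivalCurves,
    brier_at,
    concordance_td,
    integrated_brier_score,
    km_estimate,
)


def random_curves(rng, n, times):
    """Random valid survival curves (non-increasing rows in [0,1])."""
    steps = rng.uniform(0.0, 0.3, size=(n, len(times)))
    vals = np.clip(1.0 - np.cumsum(steps, axis=1), 0.0, 1.0)
    return SurvivalCurves(times=times, values=vals)


def concordance_oracle(curves, d, e):
    """Brute-force pair enumeration of the time-dependent concordance."""
    num = den = 0.0
    n = len(d)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (e[i] and d[i] < d[j]) or (e[i] and not e[j] and d[i] == d[j])
            if not comparable:
                continue
            si = curves.at(d[i])[i]
            sj = curves.at(d[i])[j]
            den += 1
            if si < sj:
                num += 1
            elif si == sj:
                num += 0.5
    return num / den


class TestKaplanMeier:
    def test_no_events_survival_is_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km(100.0) == 1.0

    def test_hand_computed_product_limit(self):
        # t=1 event (3 at risk), t=2 censored, t=3 event (1 at risk)
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(2 / 3)
        assert km(3.0) == pytest.approx(0.0)
        # left limits
        assert km.left(1.0) == 1.0
        assert km.left(3.0) == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical_survival(self, rng):
        d = rng.integers(1, 20, size=50).astype(float)
        km = km_estimate(d, np.ones(50))
        for t in np.linspace(0, 25, 40):
            assert km(float(t)) == pytest.approx((d > t).mean(), abs=1e-12)

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        d = rng.uniform(1, 50, size=80)
        e = rng.integers(0, 2, size=80)
        km = km_estimate(d, e)
        kmf = lifelines.KaplanMeierFitter().fit(d, e)
        for t in np.linspace(0, 55, 30):
            assert km(float(t)) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestConcordance:
    def test_identical_curves_give_half(self, rng):
        times = np.linspace(10, 100, 8)
        vals = np.tile(np.linspace(1, 0.3, 8), (6, 1))
        curves = SurvivalCurves(times, vals)
        d = rng.uniform(5, 90, size=6)
        e = np.ones(6)
        assert concordance_td(curves, d, e) == 0.5

    def test_perfectly_ordered_predictions_give_one(self):
        times = np.array([10.0, 20.0, 30.0, 40.0])
        d = np.array([12.0, 22.0, 32.0, 42.0])
        e = np.ones(4)
        # subject failing earlier always has lower predicted survival
        vals = np.array([[0.1, 0.05, 0.02, 0.01],
                         [0.5, 0.30, 0.20, 0.10],
                         [0.8, 0.60, 0.40, 0.30],
                         [0.95, 0.90, 0.80, 0.70]])
        assert concordance_td(SurvivalCurves(times, vals), d, e) == 1.0

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        times = np.linspace(5, 100, 10)
        for _ in range(50):
            n = 20
            curves = random_curves(rng, n, times)
            d = rng.uniform(1, 110, size=n)
            e = rng.integers(0, 2, size=n)
            e[rng.integers(n)] = 1
            assert concordance_td(curves, d, e) == pytest.approx(
                concordance_oracle(curves, d, e), abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        times = np.linspace(5, 100, 10)
        curves = random_curves(rng, 15, times)
        d = rng.uniform(1, 110, size=15)
        e = rng.integers(0, 2, size=15)
        e[0] = 1
        base = concordance_td(curves, d, e)
        warped = SurvivalCurves(times, np.sqrt(curves.values))  # strictly monotone
        assert concordance_td(warped, d, e) == pytest.approx(base, abs=1e-12)

    def test_reversing_order_maps_c_to_one_minus_c(self, rng):
        times = np.linspace(5, 100, 10)
        curves = random_curves(rng, 15, times)
        d = rng.uniform(1, 110, size=15)
        e = rng.integers(0, 2, size=15)
        e[0] = 1
        base = concordance_td(curves, d, e)
        flipped = SurvivalCurves(times, 1.0 - curves.values)
        assert concordance_td(flipped, d, e) == pytest.approx(1 - base, abs=1e-12)

    def test_no_comparable_pairs_is_error(self):
        curves = SurvivalCurves(np.array([10.0]), np.array([[0.5], [0.5]]))
        with pytest.raises(ValueError, match="undefined"):
            concordance_td(curves, [5.0, 5.0], [0, 0])


class TestBrier:
    def test_perfect_oracle_curves_score_zero(self, rng):
        d = np.array([10.0, 20.0, 30.0, 40.0])
        e = np.ones(4)
        # curve times coincide with the quadrature points so the step curves
        # represent the indicator 1{t < T_i} exactly where it is evaluated
        times = np.linspace(0, 40, 100)
        vals = np.vstack([(times < d_i).astype(float) for d_i in d])
        curves = SurvivalCurves(times, vals)
        km = km_estimate(d, 1 - e)
        for t in [5.0, 15.0, 25.0, 35.0]:
            assert brier_at(t, curves, d, e, km) == pytest.approx(0.0, abs=1e-12)
        assert integrated_brier_score(curves, d, e, (0.0, 40.0)) == pytest.approx(0.0, abs=1e-9)

    def test_constant_half_prediction_no_censoring_is_quarter(self):
        d = np.array([10.0, 20.0, 30.0])
        e = np.ones(3)
        times = np.array([0.0, 50.0])
        curves = SurvivalCurves(times, np.full((3, 2), 0.5))
        km = km_estimate(d, 1 - e)
        for t in [5.0, 15.0, 25.0]:
            assert brier_at(t, curves, d, e, km) == pytest.approx(0.25, abs=1e-12)
        assert integrated_brier_score(curves, d, e, (0.0, 30.0)) == pytest.approx(0.25, abs=1e-6)

    def test_no_censoring_reduces_to_mean_squared_error(self, rng):
        times = np.linspace(1, 60, 12)
        n = 25
        curves = random_curves(rng, n, times)
        d = rng.uniform(1, 70, size=n)
        e = np.ones(n)
        km = km_estimate(d, 1 - e)
        for t in [10.0, 30.0, 50.0]:
            S = curves.at(t)
            mse = np.mean((S - (d > t)) ** 2)
            assert brier_at(t, curves, d, e, km) == pytest.approx(mse, abs=1e-12)

    def test_hand_computed_weighted_sum_with_censoring(self):
        """3 subjects, one censored: every IPCW term written out by hand."""
        d = np.array([10.0, 20.0, 30.0])
        e = np.array([1, 0, 1])
        times = np.array([0.0, 40.0])
        S_vals = np.array([[0.8, 0.8], [0.6, 0.6], [0.9, 0.9]])
        curves = SurvivalCurves(times, S_vals)
        km_c = km_estimate(d, 1 - e)  # censoring KM: drop at t=20 (2 at risk)
        t = 25.0
        # subject 1: died before 25 -> S^2 / G(10-) = 0.64 / 1
        # subject 2: censored before 25 -> contributes 0
        # subject 3: alive at 25 -> (1-S)^2 / G(25) = 0.01 / 0.5
        expected = (0.64 / 1.0 + 0.0 + 0.01 / 0.5) / 3
        assert brier_at(t, curves, d, e, km_c) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scikit_survival(self, rng):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        n = 60
        times_grid = np.linspace(1, 80, 15)
        curves = random_curves(rng, n, times_grid)
        d = rng.uniform(1, 100, size=n)
        e = rng.integers(0, 2, size=n).astype(bool)
        e[d.argmax()] = True  # keep eval times within follower-up of events
        y = np.array(list(zip(e, d)), dtype=[("event", "?"), ("time", "<f8")])
        km_c = km_estimate(d, ~e)
        eval_ts = [20.0, 40.0, 60.0]
        preds = np.column_stack([curves.at(t) for t in eval_ts])
        _, sk_bs = sksurv_metrics.brier_score(y, y, preds, eval_ts)
        ours = [brier_at(t, curves, d, e, km_c) for t in eval_ts]
        np.testing.assert_allclose(ours, sk_bs, atol=1e-10)

    def test_integrated_score_matches_refined_quadrature(self, rng):
        times = np.linspace(1, 60, 12)
        n = 30
        curves = random_curves(rng, n, times)
        d = rng.uniform(1, 70, size=n)
        e = rng.integers(0, 2, size=n)
        e[0] = 1
        coarse = integrated_brier_score(curves, d, e, (0.0, 60.0), n_points=100)
        fine = integrated_brier_score(curves, d, e, (0.0, 60.0), n_points=1000)
        assert coarse == pytest.approx(fine, abs=1e-3)

    def test_zero_length_range_rejected(self, rng):
        curves = random_curves(rng, 3, np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="zero-length"):
            integrated_brier_score(curves, [1.0, 2.0, 3.0], [1, 1, 1], (5.0, 5.0))
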