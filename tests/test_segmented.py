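"""Level histograms, the Newton Poisson fitter and the segmentation LRT."""

import numpy as np
import pytest

from bpqc.segmented import (
    classify_all,
    level_counts,
    poisson_fit,
    poisson_loglik,
    segmented_design,
    segmented_threshold_test,
)
from bpqc.averaging import apply_protocol
from bpqc.simulate import SimConfig, simulate_cohort


class TestLevelCounts:
    def test_zero_filled_window(self):
        hist = level_counts([139, 139, 140, 141], threshold=140, window_halfwidth=5)
        assert hist.levels[0] == 135 and hist.levels[-1] == 145
        by_level = dict(zip(hist.levels, hist.counts))
        assert by_level[139] == 2 and by_level[140] == 1 and by_level[141] == 1
        assert hist.total == 4

    def test_half_integers_excluded_and_counted(self):
        hist = level_counts([139, 139.5, 140.5, 141], threshold=140, window_halfwidth=5)
        assert hist.total == 2
        assert hist.n_excluded_non_integer == 2

    def test_conservation_on_simulated_readings(self):
        rng = np.random.default_rng(3)
        v = rng.normal(140, 15, size=10_000).round()
        hist = level_counts(v, threshold=140, window_halfwidth=20)
        assert hist.total == int(((v >= 120) & (v <= 160)).sum())

    def test_empty_window_advises_widening(self):
        with pytest.raises(ValueError, match="widen"):
            level_counts([60, 61], threshold=140, window_halfwidth=5)

    def test_narrow_window_rejected(self):
        with pytest.raises(ValueError):
            level_counts([140], threshold=140, window_halfwidth=3)


class TestPoissonFit:
    def test_intercept_only_closed_form(self):
        X = np.ones((6, 1))
        y = np.full(6, 7.0)
        fit = poisson_fit(X, y)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(7.0), abs=1e-10)

    def test_saturated_two_level_closed_form(self):
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        fit = poisson_fit(X, np.array([2.0, 8.0]))
        assert fit.beta == pytest.approx([np.log(2), np.log(4)], abs=1e-8)

    def test_beats_brute_force_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            levels = np.arange(6, dtype=float)
            X = np.column_stack([np.ones(6), levels - 3])
            y = rng.poisson(np.exp(2.0 + 0.1 * (levels - 3))).astype(float)
            fit = poisson_fit(X, y)
            b0g, b1g = np.meshgrid(np.linspace(0, 4, 60), np.linspace(-1, 1, 60))
            grid_best = max(
                poisson_loglik(np.array([b0, b1]), X, y)
                for b0, b1 in zip(b0g.ravel(), b1g.ravel())
            )
            assert fit.loglik >= grid_best - 1e-9

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        levels = np.arange(120, 161)
        X, _ = segmented_design(levels, 140)
        y = rng.poisson(np.exp(4 - 0.02 * (levels - 140) - 0.4 * (levels >= 140))).astype(float)
        fit = poisson_fit(X, y)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.beta == pytest.approx(ref.params, abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_fitted_sum_matches_count_sum_with_intercept(self):
        rng = np.random.default_rng(6)
        levels = np.arange(120, 161)
        X, _ = segmented_design(levels, 140)
        y = rng.poisson(50.0, size=levels.size).astype(float)
        fit = poisson_fit(X, y)
        assert fit.fitted.sum() == pytest.approx(y.sum(), rel=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_fit(np.ones((3, 1)), np.array([1.0, -1.0, 2.0]))


class TestSegmentedThresholdTest:
    @staticmethod
    def _hist_from_counts(counts, threshold=140, w=20):
        levels = np.arange(threshold - w, threshold + w + 1)
        from bpqc.segmented import LevelHistogram

        return LevelHistogram(levels=levels, counts=np.asarray(counts), threshold=threshold)

    def test_exact_reduced_model_counts_give_zero_lrt(self):
        levels = np.arange(120, 161)
        counts = np.round(np.exp(4.0 - 0.01 * (levels - 140))).astype(int)
        res = segmented_threshold_test(self._hist_from_counts(counts))
        # the full model can only chase rounding noise here
        assert res.lrt_stat < 2.0
        assert res.direction == "none"
        assert res.full.loglik >= res.reduced.loglik - 1e-9

    def test_injected_drop_recovered_as_avoidance(self):
        rng = np.random.default_rng(7)
        levels = np.arange(120, 161)
        mu = np.exp(6.0 - 0.01 * (levels - 140) + np.log(0.5) * (levels >= 140))
        res = segmented_threshold_test(self._hist_from_counts(rng.poisson(mu)))
        assert res.direction == "avoidance"
        assert res.full.beta[2] == pytest.approx(np.log(0.5), abs=0.1)
        assert res.p_value < 1e-6

    def test_injected_excess_recovered_as_preference(self):
        rng = np.random.default_rng(8)
        levels = np.arange(120, 161)
        mu = np.exp(6.0 + np.log(1.6) * (levels >= 140))
        res = segmented_threshold_test(self._hist_from_counts(rng.poisson(mu)))
        assert res.direction == "preference"
        assert res.full.beta[2] > 0

    def test_step_only_variant_has_one_df(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(40, size=41)
        res = segmented_threshold_test(self._hist_from_counts(counts), step_only=True)
        assert res.df == 1

    def test_too_few_levels_per_side_rejected(self):
        from bpqc.segmented import LevelHistogram

        hist = LevelHistogram(
            levels=np.arange(138, 146), counts=np.ones(8, dtype=int), threshold=140
        )
        with pytest.raises(ValueError):
            segmented_threshold_test(hist)


class TestClassifyAll:
    def test_strata_layout_and_determinism(self):
        vt = simulate_cohort(SimConfig(n_visits=800, seed=21))
        avg = apply_protocol(vt)
        res = classify_all(vt, avg, window_halfwidth=20)
        assert "raw/sbp@140/SIM" in res and "averaged/dbp@90/pooled" in res
        # identical input passed twice gives identical results
        res2 = classify_all(vt, avg, window_halfwidth=20)
        assert res == res2

    def test_sbp_avoidance_detected_with_power(self):
        hits = 0
        for rep in range(5):
            vt = simulate_cohort(
                SimConfig(n_visits=4000, phi_avoid=0.7, mu_sbp=125, seed=400 + rep)
            )
            res = segmented_threshold_test(level_counts(vt["sbp"], 140, 20))
            hits += res.direction == "avoidance"
            assert res.full.beta[2] < -0.5  # strong negative step at the cut-off
        assert hits >= 4

    def test_sbp_displacement_never_touches_dbp_values(self):
        # the generator consumes a fixed randomness block per reading, so
        # enabling systolic threshold displacement leaves every diastolic
        # value identical — cross-talk into the dBP audits is exactly zero
        base = simulate_cohort(SimConfig(n_visits=600, mu_sbp=125, seed=77))
        shifted = simulate_cohort(SimConfig(n_visits=600, mu_sbp=125, phi_avoid=0.7, seed=77))
        first_two = lambda df: (
            df[df["reading_index"] <= 2]
            .sort_values(["participant_id", "reading_index"])["dbp"]
            .to_numpy()
        )
        assert (first_two(base) == first_two(shifted)).all()
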