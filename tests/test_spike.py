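"""Fisher exact test, relative risk and the Koopman score CI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bpqc.spike import (
    fisher_exact,
    koopman_chi2,
    koopman_ci,
    relative_risk,
    spike_audit,
    spike_proportion,
)


def enumeration_fisher(k1, n1, k2, n2):
    """Exact-integer-arithmetic two-sided Fisher oracle."""
    K = k1 + k2
    lo, hi = max(0, K - n2), min(K, n1)
    nums = [math.comb(n1, a) * math.comb(n2, K - a) for a in range(lo, hi + 1)]
    obs = nums[k1 - lo]
    return sum(x for x in nums if x <= obs) / sum(nums)


class TestSpikeProportion:
    def test_direct_count(self):
        assert spike_proportion([62, 62, 70, 80], 62) == (2, 4, 0.5)

    def test_empty_input_undefined_proportion(self):
        k, n, p = spike_proportion([], 62)
        assert (k, n) == (0, 0) and np.isnan(p)

    def test_half_integers_never_match_integer_target(self):
        k, n, _ = spike_proportion([61.5, 62.5, 62.0], 62)
        assert (k, n) == (1, 3)


class TestFisherExact:
    def test_identical_arms_p_one(self):
        assert fisher_exact(5, 10, 5, 10) == 1.0

    def test_extreme_small_table_full_enumeration(self):
        # (0/5 vs 5/5): only tables {0,5} are as improbable as observed,
        # each with probability 1/252 under the hypergeometric.
        assert fisher_exact(0, 5, 5, 5) == pytest.approx(2 / 252, abs=1e-15)

    def test_zero_margin_convention(self):
        assert fisher_exact(0, 10, 0, 20) == 1.0
        assert fisher_exact(10, 10, 20, 20) == 1.0

    @settings(deadline=None, max_examples=200)
    @given(st.data())
    def test_matches_enumeration_on_random_tables(self, data):
        n1 = data.draw(st.integers(1, 40))
        n2 = data.draw(st.integers(1, 60 - n1))
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        p = fisher_exact(k1, n1, k2, n2)
        assert p == pytest.approx(enumeration_fisher(k1, n1, k2, n2), abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_symmetric_under_arm_swap(self, data):
        n1 = data.draw(st.integers(1, 50))
        n2 = data.draw(st.integers(1, 50))
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        assert fisher_exact(k1, n1, k2, n2) == pytest.approx(
            fisher_exact(k2, n2, k1, n1), abs=1e-12
        )

    def test_large_counts_stable_in_log_space(self):
        # table at the scale of the motivating audits (~1e5 readings)
        p = fisher_exact(28_929, 437_446, 9_310, 195_349)
        assert 0 < p < 1e-100
        sp = stats.fisher_exact([[28_929, 437_446 - 28_929], [9_310, 195_349 - 9_310]])[1]
        assert np.isfinite(p) and p == pytest.approx(sp, rel=1e-6)


class TestRelativeRisk:
    def test_equal_proportions(self):
        assert relative_risk(10, 100, 20, 200) == 1.0

    def test_doubled_risk(self):
        assert relative_risk(20, 100, 10, 100) == 2.0

    def test_zero_reference_undefined(self):
        assert np.isnan(relative_risk(5, 10, 0, 10))

    def test_printed_pooled_counts_give_direct_ratio(self):
        # The ratio computed from the published pooled raw/averaged counts;
        # reported as computed, never back-filled from any printed summary.
        rr = relative_risk(28_929, 437_446, 9_310, 195_349)
        assert rr == pytest.approx((28_929 / 437_446) / (9_310 / 195_349))
        assert rr == pytest.approx(1.3876, abs=1e-4)


def grid_invert_bound(k1, n1, k2, n2, side, crit, tol=1e-8):
    """Grid-search inversion oracle: refine a bracket of the boundary of
    {rho: X2(rho) <= crit} by repeated 200-point grids."""
    rr = (k1 / n1) / (k2 / n2)
    if side == "lo":
        a, b = rr * 1e-4, rr
    else:
        a, b = rr, rr * 1e4
    for _ in range(12):
        grid = np.geomspace(a, b, 200)
        inside = np.array([koopman_chi2(r, k1, n1, k2, n2) <= crit for r in grid])
        idx = np.flatnonzero(inside[1:] != inside[:-1])
        i = idx[0] if side == "lo" else idx[-1]
        a, b = grid[i], grid[i + 1]
        if b - a < tol / 10:
            break
    return 0.5 * (a + b)


class TestKoopmanCI:
    def test_score_zero_at_point_estimate_keeps_one_inside(self):
        lo, hi = koopman_ci(10, 100, 10, 100)
        assert koopman_chi2(1.0, 10, 100, 10, 100) == 0.0
        assert lo < 1.0 < hi

    def test_matches_grid_search_inversion(self):
        crit = stats.chi2.ppf(0.95, 1)
        rng = np.random.default_rng(2026)
        for _ in range(100):
            n1, n2 = rng.integers(10, 400, size=2)
            k1 = rng.integers(1, n1)
            k2 = rng.integers(1, n2)
            lo, hi = koopman_ci(k1, n1, k2, n2)
            assert lo == pytest.approx(grid_invert_bound(k1, n1, k2, n2, "lo", crit), abs=1e-6)
            assert hi == pytest.approx(grid_invert_bound(k1, n1, k2, n2, "hi", crit), abs=1e-6)

    def test_point_inversion_consistency(self):
        k1, n1, k2, n2 = 20, 100, 10, 100
        crit = stats.chi2.ppf(0.95, 1)
        lo, hi = koopman_ci(k1, n1, k2, n2)
        for rho in np.geomspace(lo * 1.01, hi * 0.99, 25):
            assert koopman_chi2(rho, k1, n1, k2, n2) < crit
        for rho in (lo * 0.9, hi * 1.1):
            assert koopman_chi2(rho, k1, n1, k2, n2) > crit

    def test_zero_numerator_pins_lower_bound(self):
        lo, hi = koopman_ci(0, 50, 10, 50)
        assert lo == 0.0 and 0 < hi < 1

    def test_zero_reference_unbounded_above(self):
        lo, hi = koopman_ci(10, 50, 0, 50)
        assert lo > 0 and math.isinf(hi)

    def test_matches_statsmodels_koopman(self):
        # independent cross-check against the reference implementation
        from statsmodels.stats.proportion import confint_proportions_2indep

        for k1, n1, k2, n2 in [(20, 100, 10, 100), (5, 50, 8, 60), (100, 500, 80, 400)]:
            mine = koopman_ci(k1, n1, k2, n2)
            ref = confint_proportions_2indep(
                k1, n1, k2, n2, compare="ratio", method="score", correction=False
            )
            assert mine == pytest.approx(tuple(ref), rel=1e-7)

    def test_mn_correction_widens_interval(self):
        plain = koopman_ci(20, 100, 10, 100)
        corrected = koopman_ci(20, 100, 10, 100, mn_correction=True)
        assert corrected[0] < plain[0] < plain[1] < corrected[1]


class TestSpikeAudit:
    def test_assembles_components(self):
        raw = [62] * 20 + [70] * 80
        avg = [62] * 5 + [70.5] * 95
        res = spike_audit(raw, avg, target=62)
        assert (res.k_raw, res.n_raw, res.k_avg, res.n_avg) == (20, 100, 5, 100)
        assert res.rr == pytest.approx(4.0)
        assert res.fisher_p == pytest.approx(enumeration_fisher(20, 100, 5, 100), abs=1e-12)
        assert res.ci_low <= res.rr <= res.ci_high

    def test_raw_exceeds_averaged_with_artifact_on(self):
        # averaging destroys exact-62 equality unless both used readings hit it
        from bpqc.averaging import apply_protocol
        from bpqc.simulate import SimConfig, simulate_cohort

        hits = 0
        for rep in range(10):
            vt = simulate_cohort(SimConfig(n_visits=300, pi62=0.5, seed=900 + rep))
            avg = apply_protocol(vt)
            res = spike_audit(vt["dbp"], avg["dbp_avg"], target=62)
            hits += res.prop_raw > res.prop_avg
        assert hits >= 9
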