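"""MR estimators against hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutmr.estimators import (
    egger,
    ivw,
    mr_lasso,
    mr_presso,
    unweighted_mr,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from gutmr.summary_io import HarmonizedPair

from conftest import make_pairs, random_pairs


def brute_force_weighted_median(ratios, weights):
    """Independent cumulative-weight search with midpoint convention."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    below = np.flatnonzero(cum < 0.5)
    if len(below) == 0:
        return r[0]
    if len(below) == len(r):
        return r[-1]
    i = below[-1]
    return r[i] + (r[i + 1] - r[i]) * (0.5 - cum[i]) / (cum[i + 1] - cum[i])


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        (p,) = make_pairs([0.5], [0.1], [0.02])
        est = wald_ratio(p)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_identity_instrument(self):
        (p,) = make_pairs([1.0], [0.37], [0.11])
        est = wald_ratio(p)
        assert (est.beta, est.se) == (0.37, 0.11)

    def test_negative_exposure_beta(self):
        (p,) = make_pairs([-0.5], [0.1], [0.02])
        est = wald_ratio(p)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.04)  # se stays positive

    def test_zero_exposure_beta_rejected(self):
        (p,) = make_pairs([0.0], [0.1], [0.02])
        with pytest.raises(ValueError):
            wald_ratio(p)


class TestIVW:
    def test_homogeneous_pairs_fixed_equals_random(self):
        pairs = make_pairs([0.5, 0.5], [0.1, 0.1], [0.02, 0.02])
        fixed = ivw(pairs, "fixed")
        random = ivw(pairs, "random")
        assert fixed.beta == pytest.approx(0.2)
        assert fixed.beta == random.beta
        assert fixed.se == random.se  # Q=0: scale floored at 1

    def test_hand_computed_case(self):
        pairs = make_pairs([1, 1, 1], [1, 2, 3], [0.1, 0.1, 0.1])
        fixed = ivw(pairs, "fixed")
        assert fixed.beta == pytest.approx(2.0)
        assert fixed.se == pytest.approx(0.1 / np.sqrt(3))
        random = ivw(pairs, "random")
        assert random.se == pytest.approx(0.1 / np.sqrt(3) * np.sqrt(200 / 2))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_pairs([1], [1], [0.1]))

    def test_duplicated_pair_reproduces_wald(self):
        (p,) = make_pairs([0.4], [0.12], [0.03])
        dup = make_pairs([0.4, 0.4], [0.12, 0.12], [0.03, 0.03])
        assert ivw(dup).beta == pytest.approx(wald_ratio(p).beta)

    def test_matches_wls_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 11))
            bx = rng.normal(0.3, 0.2, k)
            bx[np.abs(bx) < 0.01] = 0.1
            by = rng.normal(0.1, 0.3, k)
            sy = rng.uniform(0.02, 0.3, k)
            est = ivw(make_pairs(bx, by, sy), "fixed")
            # oracle: weighted least squares through the origin via lstsq
            sw = 1.0 / sy
            beta_oracle = np.linalg.lstsq((bx * sw)[:, None], by * sw,
                                          rcond=None)[0][0]
            assert est.beta == pytest.approx(beta_oracle, abs=1e-8)


class TestEgger:
    def test_exact_fit_through_origin(self):
        slope, intercept = egger(make_pairs([1, 2, 3], [1, 2, 3], 0.1))
        assert slope.beta == pytest.approx(1.0)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_weighted_regression_oracle(self):
        slope, intercept = egger(make_pairs([1, 2, 3], [1.5, 2.5, 3.5], 0.1))
        assert slope.beta == pytest.approx(1.0)
        assert intercept.beta == pytest.approx(0.5)

    def test_orientation_invariance(self):
        base = make_pairs([1, 2, 3], [1.2, 2.7, 3.1], [0.1, 0.2, 0.15])
        flipped = make_pairs([1, -2, 3], [1.2, -2.7, 3.1], [0.1, 0.2, 0.15])
        s1, i1 = egger(base)
        s2, i2 = egger(flipped)
        assert s1.beta == pytest.approx(s2.beta)
        assert i1.beta == pytest.approx(i2.beta)
        assert s1.se == pytest.approx(s2.se)

    def test_matches_polyfit_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 11))
            bx = rng.uniform(0.1, 0.6, k)
            by = rng.normal(0.3 * bx, 0.1)
            sy = rng.uniform(0.05, 0.2, k)
            slope, intercept = egger(make_pairs(bx, by, sy))
            w = 1.0 / sy**2
            int_o, slope_o = np.polynomial.polynomial.polyfit(
                bx, by, 1, w=np.sqrt(w))
            assert slope.beta == pytest.approx(slope_o, abs=1e-8)
            assert intercept.beta == pytest.approx(int_o, abs=1e-8)

    def test_constrained_intercept_recovers_ivw(self, rng):
        """With the intercept constrained to zero, the slope is the IVW beta."""
        k = 8
        bx = rng.uniform(0.1, 0.5, k)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.05, 0.2, k)
        pairs = make_pairs(bx, by, sy)
        w = 1.0 / sy**2
        slope_constrained = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert ivw(pairs).beta == pytest.approx(slope_constrained, abs=1e-12)

    def test_too_few_or_collinear_rejected(self):
        with pytest.raises(ValueError):
            egger(make_pairs([1, 2], [1, 2], 0.1))
        with pytest.raises(ValueError):
            egger(make_pairs([1, 1, -1], [1, 1.2, -0.9], 0.1))


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        est = weighted_median(make_pairs([1, 2, 4], [0.3, 0.6, 1.2], 0.1),
                              n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_five_equal_weight_ratios(self):
        pairs = make_pairs([1] * 5, [1, 1, 1, 10, 10], 1.0)
        assert weighted_median(pairs, n_boot=50, seed=1).beta == pytest.approx(1.0)

    def test_three_equal_weight_ratios(self):
        pairs = make_pairs([1, 1, 1], [1, 2, 3], 1.0)
        assert weighted_median(pairs, n_boot=50, seed=1).beta == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 11))
            bx = rng.uniform(0.1, 0.6, k)
            by = rng.normal(0.3 * bx, 0.1)
            sy = rng.uniform(0.05, 0.2, k)
            est = weighted_median(make_pairs(bx, by, sy), n_boot=2, seed=0)
            expected = brute_force_weighted_median(by / bx, bx**2 / sy**2)
            assert est.beta == pytest.approx(expected, abs=1e-8)

    def test_bootstrap_reproducible(self, rng):
        pairs = random_pairs(rng, 6)
        a = weighted_median(pairs, n_boot=200, seed=7)
        b = weighted_median(pairs, n_boot=200, seed=7)
        assert a.se == b.se


class TestWeightedMode:
    def test_all_ratios_equal(self):
        est = weighted_mode(make_pairs([1, 2, 4], [0.5, 1.0, 2.0], 0.1),
                            n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_cluster_dominates_outlier(self):
        pairs = make_pairs([1, 1, 1, 1], [1.0, 1.1, 0.9, 5.0], 1.0)
        est = weighted_mode(pairs, n_boot=50, seed=1)
        assert abs(est.beta - 1.0) < 0.5

    def test_dominant_weight_pulls_estimate(self):
        # one ratio with overwhelming weight (tiny outcome SE)
        pairs = make_pairs([1, 1, 1], [1.0, 2.0, 3.0], [1.0, 1.0, 1e-4])
        est = weighted_mode(pairs, n_boot=50, seed=1)
        assert abs(est.beta - 3.0) < 0.2

    def test_density_grid_oracle(self, rng):
        from gutmr.estimators import (_ratios_weights, _silverman_bandwidth)
        k = 7
        bx = rng.uniform(0.2, 0.5, k)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.05, 0.1, k)
        est = weighted_mode(make_pairs(bx, by, sy), n_boot=2, seed=0)
        ratios, weights = _ratios_weights(bx, by, sy)
        h = _silverman_bandwidth(ratios, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
        dens = np.zeros_like(grid)
        for r, w in zip(ratios, weights):  # direct-sum oracle
            dens += w * np.exp(-0.5 * ((grid - r) / h) ** 2)
        assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=1e-12)


class TestRangeInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_median_and_mode_within_ratio_range(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))
        bx = rng.uniform(0.05, 0.8, k) * rng.choice([-1, 1], k)
        by = rng.normal(0, 0.5, k)
        sy = rng.uniform(0.02, 0.5, k)
        pairs = make_pairs(bx, by, sy)
        ratios = by / bx
        med = weighted_median(pairs, n_boot=2, seed=0).beta
        mode = weighted_mode(pairs, n_boot=2, seed=0).beta
        lo, hi = ratios.min(), ratios.max()
        assert lo - 1e-9 <= med <= hi + 1e-9
        # mode argmax sits on a 512-point grid: allow one grid step of slack
        from gutmr.estimators import _silverman_bandwidth
        h = _silverman_bandwidth(ratios, 1.0)
        step = (hi - lo + 6 * h) / 511 if np.isfinite(h) and h > 0 else 1e-9
        assert lo - step <= mode <= hi + step


class TestUnweightedMR:
    def test_scale_invariance_exact(self, rng):
        pairs = random_pairs(rng, 8)
        scaled = [HarmonizedPair(p.variant_id, 7.3 * p.beta_x, p.se_x,
                                 p.beta_y, p.se_y) for p in pairs]
        for model in ("fixed", "random"):
            a = unweighted_mr(pairs, model)
            b = unweighted_mr(scaled, model)
            assert a.beta == b.beta
            assert a.se == b.se

    def test_equal_weight_mean_oracle(self):
        pairs = make_pairs([0.5, 1.2, -0.7], [2, 4, -6], 1.0)
        est = unweighted_mr(pairs, "fixed")
        assert est.beta == pytest.approx(4.0)  # mean of sign-aligned betas

    def test_single_positive_pair_equals_beta_y(self):
        pairs = make_pairs([0.8, 0.8], [0.25, 0.25], 0.1)
        assert unweighted_mr(pairs).beta == pytest.approx(0.25)

    def test_zero_beta_x_excluded(self):
        pairs = make_pairs([0.5, 0.0, -0.5], [1, 9, -1], 1.0)
        est = unweighted_mr(pairs)
        assert est.k_snps == 2
        assert est.beta == pytest.approx(1.0)


class TestMRLasso:
    def test_homogeneous_selects_all(self, rng):
        pairs = random_pairs(rng, 8)
        est = mr_lasso(pairs)
        assert est.k_snps == 8
        assert est.beta == pytest.approx(ivw(pairs).beta)

    def test_planted_outlier_excluded(self, rng):
        pairs = random_pairs(rng, 10, outlier_idx=9, outlier_shift=10.0)
        est = mr_lasso(pairs)
        assert any("rs9" in n for n in est.notes if n.startswith("invalid"))
        assert abs(est.beta - 0.3) < 2 * est.se

    def test_requires_three(self, rng):
        with pytest.raises(ValueError):
            mr_lasso(random_pairs(rng, 2))


class TestMRPresso:
    def test_null_global_p_large(self, rng):
        pairs = random_pairs(rng, 10)
        res = mr_presso(pairs, n_sim=1000, seed=11)
        assert res.global_rss_p > 0.05
        assert res.outlier_set == []
        assert res.corrected is None

    def test_planted_outlier_flagged(self, rng):
        pairs = random_pairs(rng, 10, outlier_idx=4, outlier_shift=10.0)
        res = mr_presso(pairs, n_sim=1000, seed=11)
        assert "rs4" in res.outlier_set
        assert res.corrected is not None
        assert abs(res.corrected.beta - 0.3) < 3 * res.corrected.se
        assert res.distortion_p is not None

    def test_minimum_instruments_enforced(self, rng):
        with pytest.raises(ValueError):
            mr_presso(random_pairs(rng, 3))

    def test_bit_reproducible(self, rng):
        pairs = random_pairs(rng, 8)
        a = mr_presso(pairs, n_sim=300, seed=5)
        b = mr_presso(pairs, n_sim=300, seed=5)
        assert a.global_rss_p == b.global_rss_p
        assert a.per_snp_outlier_p == b.per_snp_outlier_p
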