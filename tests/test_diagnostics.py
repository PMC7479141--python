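"""Heterogeneity, instrument strength, Steiger filtering, Rucker, routing."""

import numpy as np
import pytest
from scipy import stats

from gutmr.diagnostics import (
    cochran_q,
    f_statistic,
    i2_gx,
    liability_r2,
    route_analysis,
    rucker_framework,
    steiger_filter,
    variant_r2,
)

from conftest import make_pairs, random_pairs


class TestVariantR2:
    def test_zero_beta(self):
        assert variant_r2(0.0, 0.02, 0.3, 1000) == 0.0

    def test_direct_arithmetic_oracle(self):
        beta, se, maf, n = 0.1, 0.02, 0.3, 1000
        num = 2 * beta**2 * maf * (1 - maf)
        expected = num / (num + se**2 * 2 * n * maf * (1 - maf))
        assert variant_r2(beta, se, maf, n) == pytest.approx(expected, rel=1e-12)

    def test_maf_invariance_at_fixed_z(self):
        """maf factors cancel: r2 depends only on beta/se and n."""
        values = [variant_r2(0.1, 0.02, maf, 1000)
                  for maf in (0.05, 0.2, 0.35, 0.49)]
        assert all(v == pytest.approx(values[0], rel=1e-12) for v in values)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            variant_r2(0.1, 0.02, 0.0, 1000)


class TestLiabilityR2:
    def test_closed_form_at_half(self):
        # K = P = 0.5: multiplier = 0.0625 / (phi(0)^2 * 0.25) = pi/2
        assert liability_r2(1.0, 0.5, 0.5) == pytest.approx(np.pi / 2, rel=1e-12)
        assert liability_r2(0.01, 0.5, 0.5) == pytest.approx(0.01 * np.pi / 2)

    def test_zero_observed(self):
        assert liability_r2(0.0, 0.1, 0.3) == 0.0

    def test_multiplier_increases_toward_rare_disease(self):
        """At P=K (unascertained), K(1-K)/z^2 grows as the disease gets rarer;
        at fixed P the K^2(1-K)^2/z^2 factor instead shrinks toward K=0."""
        grid = [0.5, 0.3, 0.2, 0.1, 0.05, 0.01]
        unascertained = [liability_r2(1.0, K, K) for K in grid]
        assert all(a < b for a, b in zip(unascertained, unascertained[1:]))
        fixed_p = [liability_r2(1.0, K, 0.3) for K in grid]
        assert all(a > b for a, b in zip(fixed_p, fixed_p[1:]))

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            liability_r2(0.1, 0.0, 0.3)
        with pytest.raises(ValueError):
            liability_r2(0.1, 0.2, 1.0)


class TestFStatistic:
    def test_null_r2_weak(self):
        s = f_statistic(0.0, 100)
        assert s.f_stat == 0.0 and s.weak_flag

    def test_formula_arithmetic(self):
        s = f_statistic(0.01, 1002)
        assert s.f_stat == pytest.approx(10.10101, rel=1e-5)
        assert not s.weak_flag

    def test_formula_inversion(self):
        # F = 10 at n = 912 solves to r2 = 10/920
        r2 = 10.0 / 920.0
        assert f_statistic(r2, 912).f_stat == pytest.approx(10.0, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)


class TestSteigerFilter:
    def pair(self):
        return make_pairs([0.3], [0.1], [0.02])[0]

    def test_exposure_dominates_keeps(self):
        v = steiger_filter(self.pair(), 0.02, 10_000, 0.001, 10_000)
        assert v.keep and v.direction == "exposure_to_outcome"
        assert v.p_steiger < 0.05

    def test_outcome_dominates_drops(self):
        v = steiger_filter(self.pair(), 0.001, 10_000, 0.02, 10_000)
        assert not v.keep and v.direction == "outcome_to_exposure"

    def test_equal_r2_keeps_with_p_one(self):
        v = steiger_filter(self.pair(), 0.01, 10_000, 0.01, 10_000)
        assert v.keep
        assert v.p_steiger == pytest.approx(1.0)

    def test_insignificant_reverse_keeps(self):
        # outcome r2 nominally higher but indistinguishable at small n
        v = steiger_filter(self.pair(), 0.010, 500, 0.011, 500)
        assert v.direction == "outcome_to_exposure" and v.keep


class TestCochranQ:
    def test_identical_ratios(self):
        het = cochran_q(make_pairs([1, 2, 4], [0.3, 0.6, 1.2], 0.1))
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.p == pytest.approx(1.0)
        assert het.i_squared == 0.0

    def test_hand_computed_case(self):
        het = cochran_q(make_pairs([1, 1, 1], [1, 2, 3], 0.1), beta_hat=2.0)
        assert het.Q == pytest.approx(200.0)
        assert het.df == 2
        assert het.i_squared == pytest.approx(99.0)

    def test_matches_direct_sum_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 11))
            bx = rng.uniform(0.1, 0.6, k)
            by = rng.normal(0.3 * bx, 0.1)
            sy = rng.uniform(0.05, 0.2, k)
            het = cochran_q(make_pairs(bx, by, sy))
            w = 1.0 / sy**2
            beta = np.sum(w * bx * by) / np.sum(w * bx**2)
            q_oracle = float(np.sum((bx**2 / sy**2) * (by / bx - beta) ** 2))
            assert het.Q == pytest.approx(q_oracle, abs=1e-8)

    def test_type_i_error_calibrated(self):
        """Q rejects ~5% of homogeneous summary-level draws (small version)."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            pairs = random_pairs(rng, 8, theta=0.3)
            if cochran_q(pairs).p < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


class TestRucker:
    def test_qprime_never_exceeds_q(self, rng):
        for _ in range(50):
            pairs = random_pairs(rng, int(rng.integers(3, 10)))
            d = rucker_framework(pairs)
            assert d.q_rucker.Q <= d.q_ivw.Q + 1e-9

    def test_homogeneous_selects_fixed(self, rng):
        picks = [rucker_framework(random_pairs(rng, 10)).selected_model
                 for _ in range(40)]
        assert picks.count("ivw_fixed") > 0.8 * len(picks)

    def test_balanced_pleiotropy_selects_random(self, rng):
        picks = []
        for _ in range(40):
            bx = rng.uniform(0.2, 0.5, 12)
            alpha = rng.normal(0.0, 0.1, 12)  # zero-mean intercept noise
            sy = np.full(12, 0.02)
            by = rng.normal(0.3 * bx + alpha, sy)
            picks.append(rucker_framework(make_pairs(bx, by, sy, sx=1e-4))
                         .selected_model)
        assert picks.count("ivw_random") > 0.5 * len(picks)

    def test_directional_pleiotropy_selects_egger(self, rng):
        picks = []
        for _ in range(40):
            k = 25
            bx = rng.uniform(0.1, 0.6, k)
            alpha = rng.normal(0.08, 0.02, k)  # nonzero-mean pleiotropy
            sy = np.full(k, 0.01)
            by = rng.normal(0.3 * bx + alpha, sy)
            picks.append(rucker_framework(make_pairs(bx, by, sy, sx=1e-4))
                         .selected_model)
        assert picks.count("egger") > 0.5 * len(picks)

    def test_two_snp_fallback(self, rng):
        d = rucker_framework(random_pairs(rng, 2))
        assert d.q_rucker is None
        assert d.selected_model in ("ivw_fixed", "ivw_random")


class TestI2GX:
    def test_precise_exposures_approach_100(self):
        pairs = make_pairs([0.1, 0.3, 0.5], [0.03, 0.09, 0.15], 0.05,
                           sx=1e-6)
        assert i2_gx(pairs) > 99.99

    def test_equal_betas_zero(self):
        pairs = make_pairs([0.3, 0.3, 0.3], [0.1, 0.1, 0.1], 0.05, sx=0.05)
        assert i2_gx(pairs) == 0.0

    def test_matches_direct_sum_oracle(self, rng):
        bx = rng.uniform(0.1, 0.6, 9)
        sx = rng.uniform(0.01, 0.05, 9)
        pairs = make_pairs(bx, np.zeros(9), 0.1, sx=sx)
        w = 1.0 / sx**2
        mean = np.sum(w * bx) / np.sum(w)
        q_gx = np.sum((bx - mean) ** 2 / sx**2)
        expected = max(0.0, (q_gx - 8) / q_gx) * 100
        assert i2_gx(pairs) == pytest.approx(expected, abs=1e-8)

    def test_zero_se_pairs_excluded(self, rng):
        pairs = random_pairs(rng, 5)
        pairs[0].se_x = 0.0
        # statistic computed on the 4 eligible pairs only
        assert i2_gx(pairs) == i2_gx(pairs[1:])


class TestRouter:
    @pytest.mark.parametrize("k", range(11))
    def test_exhaustive_plan_conformance(self, k):
        plan = route_analysis(k)
        if k == 0:
            assert plan == []
        elif k == 1:
            assert set(plan) == {"wald", "steiger", "f_statistic"}
            assert len(plan) == 3
        else:
            assert {"ivw_fe", "ivw_re", "cochran_q", "i_squared",
                    "unweighted"} <= set(plan)
            assert ("egger" in plan) == (k >= 3)
            assert ("weighted_median" in plan) == (k >= 3)
            assert ("lasso" in plan) == (k >= 3)
            assert ("presso" in plan) == (k >= 4)

    def test_pure_function_of_k(self):
        assert route_analysis(5) == route_analysis(5)
        with pytest.raises(ValueError):
            route_analysis(-1)
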