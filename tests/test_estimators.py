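"""Univariable MR estimators against independent oracles and known limits."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate import (InsufficientInstrumentsError, egger, ivw,
                       leave_one_out, max_likelihood, wald_ratio,
                       weighted_median, simulate, SimTruth, harmonize,
                       select_by_pvalue, f_statistics)
from mrmediate.estimators import EstimatorError, _ml_profile_negloglik

from conftest import make_pairs


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        est = wald_ratio(bx=0.5, sx=0.01, by=0.1, sy=0.02)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)
        assert est.ci_low < est.beta < est.ci_high

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(EstimatorError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)

    def test_se_matches_monte_carlo(self):
        """First-order delta SE vs the SD of simulated ratios (strong bx)."""
        rng = np.random.default_rng(0)
        bx = rng.normal(0.5, 0.01, size=1_000_000)
        by = rng.normal(0.1, 0.02, size=1_000_000)
        mc_sd = np.std(by / bx)
        est = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert est.se == pytest.approx(mc_sd, rel=0.05)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self, pair_factory):
        s = pair_factory([0.5], [0.01], [0.1], [0.02])
        est, het = ivw(s)
        ref = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert est.beta == ref.beta
        assert est.se == ref.se
        assert est.method == "ivw_mre"
        assert het.q == 0.0

    def test_homogeneous_ratios(self, pair_factory):
        bx = np.array([0.2, 0.4, 0.5])
        s = pair_factory(bx, 0.01 * np.ones(3), 0.3 * bx, [0.02, 0.03, 0.01])
        est, het = ivw(s)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.scale_factor == 1.0

    def test_matches_wls_oracle(self, pair_factory):
        """Coefficient and fixed-effect SE equal statsmodels WLS to 1e-10."""
        bx = np.array([0.21, -0.33, 0.45, 0.12, 0.5])
        by = np.array([0.05, -0.12, 0.16, 0.01, 0.13])
        sy = np.array([0.02, 0.05, 0.03, 0.04, 0.02])
        s = pair_factory(bx, 0.01 * np.ones(5), by, sy)
        est, het = ivw(s)
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales by residual MSE == Q/df; ours floors the factor at 1
        q = np.sum((1 / sy**2) * (by - est.beta * bx) ** 2)
        expected_se = fit.bse[0] / np.sqrt(q / 4) * het.scale_factor
        assert est.se == pytest.approx(expected_se, abs=1e-10)
        assert het.q == pytest.approx(q, abs=1e-10)

    def test_no_instruments_rejected(self, pair_factory):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(pair_factory([], [], [], []))

    def test_parameter_recovery_bias(self):
        """IVW on well-specified synthetic data: |mean bias| < 0.01, 500 reps."""
        est = []
        for s in range(500):
            ds = simulate(SimTruth(theta1=0.3, theta2=0.0, theta3=0.0,
                                   n_snp_mediator=0, n_exp=50_000,
                                   n_med=50_000, n_out=50_000, seed=s))
            # exposure -> mediator has true effect theta1 = 0.3
            iv_recs, _ = f_statistics(select_by_pvalue(ds.exposure, 1e-5))
            e, _ = ivw(harmonize(iv_recs, ds.mediator))
            est.append(e.beta)
        assert abs(np.mean(est) - 0.3) < 0.01


class TestMaxLikelihood:
    def test_approaches_ivw_as_exposure_error_vanishes(self, pair_factory):
        bx = np.array([0.2, 0.4, 0.5, 0.3])
        by = np.array([0.05, 0.13, 0.14, 0.10])
        sy = np.array([0.02, 0.03, 0.01, 0.02])
        s = pair_factory(bx, 1e-8 * np.ones(4), by, sy)
        ml = max_likelihood(s)
        ref, _ = ivw(s)
        assert ml.beta == pytest.approx(ref.beta, abs=1e-6)

    def test_recovers_true_effect(self):
        ds = simulate(SimTruth(theta1=0.3, theta2=0.0, theta3=0.0,
                               n_snp_exposure=20, n_snp_mediator=0,
                               n_exp=50_000, n_med=50_000, seed=11))
        iv_recs, _ = f_statistics(select_by_pvalue(ds.exposure, 1e-5))
        ml = max_likelihood(harmonize(iv_recs, ds.mediator))
        assert abs(ml.beta - 0.3) < 3 * ml.se

    def test_optimizer_matches_grid_search(self, pair_factory):
        bx = np.array([0.5, 0.3, -0.4])
        sx = np.array([0.05, 0.04, 0.06])
        by = np.array([0.12, 0.05, -0.11])
        sy = np.array([0.03, 0.02, 0.04])
        s = pair_factory(bx, sx, by, sy)
        ml = max_likelihood(s)
        grid = np.linspace(ml.beta - 0.5, ml.beta + 0.5, 400_001)
        vals = [_ml_profile_negloglik(b, bx, sx, by, sy) for b in grid]
        assert ml.beta == pytest.approx(grid[int(np.argmin(vals))], abs=1e-5)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self, pair_factory):
        s = pair_factory([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        est = weighted_median(s, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_robust_to_low_weight_outlier(self, pair_factory):
        clean = pair_factory([1.0, 1.0, 1.0], [0.01] * 3,
                             [0.1, 0.2, 0.3], [0.05] * 3)
        # outlier ratio 100 with < 25% of total weight
        dirty = pair_factory([1.0, 1.0, 1.0, 1.0], [0.01] * 4,
                             [0.1, 0.2, 0.3, 100.0], [0.05, 0.05, 0.05, 0.09])
        a = weighted_median(clean, seed=1)
        b = weighted_median(dirty, seed=1)
        assert b.beta == pytest.approx(a.beta, abs=0.06)

    def test_interpolation_matches_hand_calculation(self, pair_factory):
        """4 unequal weights: cumulative-weight interpolation done by hand."""
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.3, 0.4])
        sy = np.array([0.1, 0.05, 0.1, 0.2])
        w = bx**2 / sy**2              # 100, 400, 100, 25
        s = pair_factory(bx, [0.01] * 4, by, sy)
        est = weighted_median(s, seed=1)
        # sorted ratios .1,.2,.3,.4; standardized midpoints (cum - w/2)/W
        W = w.sum()
        mid = (np.cumsum(w) - w / 2) / W     # .08, .48, .88, .98
        # 0.5 falls between mid[1] and mid[2]: linear interpolation
        expected = 0.2 + (0.5 - mid[1]) / (mid[2] - mid[1]) * 0.1
        assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_requires_three_snps(self, pair_factory):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(pair_factory([1, 1], [0.01] * 2, [0.1, 0.2], [0.05] * 2))

    def test_bootstrap_seeded(self, pair_factory):
        s = pair_factory([1.0, 0.8, 1.2], [0.05] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        assert weighted_median(s, seed=7).se == weighted_median(s, seed=7).se


class TestEgger:
    def test_points_on_origin_line(self, pair_factory):
        bx = np.array([0.2, 0.4, 0.5, 0.1])
        s = pair_factory(bx, [0.01] * 4, 0.4 * bx, [0.02, 0.03, 0.01, 0.05])
        slope, intercept, _ = egger(s)
        assert abs(intercept.beta) < 1e-12
        assert slope.beta == pytest.approx(0.4, abs=1e-12)

    def test_detects_directional_pleiotropy(self):
        """Constant pleiotropy shifts the intercept, not the slope."""
        rng = np.random.default_rng(3)
        n = 50
        bx = rng.uniform(0.1, 0.5, n)
        sy = np.full(n, 0.01)
        noise = rng.normal(0, sy)
        delta = 0.05
        clean = make_pairs(bx, np.full(n, 1e-6), 0.3 * bx + noise, sy)
        shifted = make_pairs(bx, np.full(n, 1e-6), 0.3 * bx + delta + noise, sy)
        s_clean, _, _ = egger(clean)
        s_shift, i_shift, _ = egger(shifted)
        assert i_shift.beta == pytest.approx(delta, abs=0.01)
        assert s_shift.beta == pytest.approx(s_clean.beta, abs=1e-9)

    def test_matches_wls_oracle(self, pair_factory):
        bx = np.array([0.21, 0.33, 0.45, 0.12, 0.5, 0.27])
        by = np.array([0.05, 0.12, 0.16, 0.01, 0.13, 0.09])
        sy = np.array([0.02, 0.05, 0.03, 0.04, 0.02, 0.03])
        s = pair_factory(bx, 0.01 * np.ones(6), by, sy)
        slope, intercept, het = egger(s)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels SEs scale by sqrt(Q/df); ours floor that factor at 1
        adj = het.scale_factor / np.sqrt(het.q / het.df)
        assert slope.se == pytest.approx(fit.bse[1] * adj, abs=1e-10)
        assert intercept.se == pytest.approx(fit.bse[0] * adj, abs=1e-10)

    def test_orients_exposure_positive(self, pair_factory):
        """Negating some bx (and their by) leaves Egger unchanged."""
        bx = np.array([0.2, 0.4, 0.5, 0.1])
        by = np.array([0.07, 0.13, 0.18, 0.02])
        sy = np.array([0.02, 0.03, 0.01, 0.05])
        flip = np.array([1, -1, 1, -1])
        a = egger(pair_factory(bx, [0.01] * 4, by, sy))
        b = egger(pair_factory(bx * flip, [0.01] * 4, by * flip, sy))
        assert a[0].beta == pytest.approx(b[0].beta, abs=1e-12)
        assert a[1].beta == pytest.approx(b[1].beta, abs=1e-12)


class TestLeaveOneOut:
    def test_homogeneous_all_equal_full(self, pair_factory):
        bx = np.array([0.2, 0.4, 0.5, 0.3])
        s = pair_factory(bx, [0.01] * 4, 0.25 * bx, [0.02] * 4)
        full, _ = ivw(s)
        loo = leave_one_out(s)
        assert len(loo) == 4
        for _, est in loo:
            assert est.beta == pytest.approx(full.beta, abs=1e-12)

    def test_outlier_identified_by_largest_shift(self, pair_factory):
        bx = np.array([0.2, 0.4, 0.5, 0.3, 0.25])
        by = 0.25 * bx
        by[2] += 0.3  # gross outlier
        s = pair_factory(bx, [0.01] * 5, by, [0.02] * 5)
        full, _ = ivw(s)
        loo = leave_one_out(s)
        shifts = {snp: abs(est.beta - full.beta) for snp, est in loo}
        assert max(shifts, key=shifts.get) == "rs3"


class TestEquivariance:
    def _random_set(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.1, 0.5, n)
        by = 0.3 * bx + rng.normal(0, 0.02, n)
        return bx, rng.uniform(0.005, 0.02, n), by, rng.uniform(0.01, 0.04, n)

    @pytest.mark.parametrize("c", [2.5, 0.1])
    def test_outcome_scale_equivariance(self, c):
        """Rescaling outcome units rescales every estimate and SE by c."""
        bx, sx, by, sy = self._random_set()
        base = make_pairs(bx, sx, by, sy)
        scaled = make_pairs(bx, sx, c * by, c * sy)
        for fn in (lambda s: ivw(s)[0], max_likelihood,
                   lambda s: weighted_median(s, seed=2),
                   lambda s: egger(s)[0]):
            a, b = fn(base), fn(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-6)
            assert b.se == pytest.approx(c * a.se, rel=1e-5)

    def test_exposure_sign_equivariance(self):
        bx, sx, by, sy = self._random_set(seed=4)
        base = make_pairs(bx, sx, by, sy)
        negated = make_pairs(-bx, sx, by, sy)
        for fn in (lambda s: ivw(s)[0], max_likelihood,
                   lambda s: weighted_median(s, seed=2)):
            a, b = fn(base), fn(negated)
            assert b.beta == pytest.approx(-a.beta, rel=1e-6)
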