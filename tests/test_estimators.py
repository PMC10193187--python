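import numpy as np
import pytest
import statsmodels.api as sm
from scipy.interpolate import interp1d

from mrkit.errors import (InsufficientInstrumentsError, MulticollinearityError,
                          UndefinedRatioError)
from mrkit.estimators import (Z95, egger, ivw, mvmr, wald_ratio, weighted_median,
                              weighted_median_point)
from mrkit.harmonize import HarmonizedInstrument, MVHarmonizedSet, MVInstrument

from conftest import make_hset


def _inst(beta_exp=0.25, se_exp=0.01, beta_out=0.05, se_out=0.01):
    return HarmonizedInstrument("rs1", beta_exp, se_exp, beta_out, se_out, 0.3, 0.3)


class TestWaldRatio:
    def test_first_order_arithmetic(self):
        est = wald_ratio(_inst())
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_zero_numerator_keeps_se(self):
        est = wald_ratio(_inst(beta_out=0.0))
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.01 / 0.25)

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(_inst(beta_exp=0.0))

    def test_second_order_adds_exposure_term(self):
        est = wald_ratio(_inst(), second_order=True)
        expected = np.sqrt(0.01**2 / 0.25**2 + 0.05**2 * 0.01**2 / 0.25**4)
        assert est.se == pytest.approx(expected)
        assert est.se > wald_ratio(_inst()).se


class TestIVW:
    def test_single_instrument_degenerates_to_wald(self):
        hset = make_hset([0.25], [0.05], [0.01])
        est = ivw(hset)
        wald = wald_ratio(hset.instruments[0])
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_two_instrument_closed_form(self):
        # equal weights 1/0.01 on ratios 0.2 and 0.1: mean 0.15,
        # fixed se (sum w)^-1/2 = 1/sqrt(200), Q = 0.5
        hset = make_hset([1.0, 1.0], [0.2, 0.1], [0.1, 0.1])
        est = ivw(hset, model="fixed")
        assert est.beta == pytest.approx(0.15)
        assert est.se == pytest.approx(1 / np.sqrt(200))
        assert est.q_stat == pytest.approx(0.5)

    def test_homogeneous_ratios_give_zero_q_and_equal_ses(self):
        hset = make_hset([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], 0.01)
        fe, mre = ivw(hset, model="fixed"), ivw(hset)
        assert fe.beta == pytest.approx(0.2)
        assert fe.q_stat == pytest.approx(0.0, abs=1e-20)
        assert mre.se == pytest.approx(fe.se)

    def test_mre_never_narrower_than_fe(self, rng):
        for _ in range(30):
            n = rng.integers(2, 12)
            hset = make_hset(rng.normal(0.05, 0.02, n), rng.normal(0, 0.05, n),
                             rng.uniform(0.005, 0.05, n))
            fe, mre = ivw(hset, model="fixed"), ivw(hset)
            assert mre.se >= fe.se - 1e-15
            assert (mre.se > fe.se) == (fe.q_stat > n - 1)

    def test_agrees_with_zero_intercept_weighted_regression(self, rng):
        for _ in range(20):
            n = rng.integers(2, 12)
            bx = rng.normal(0.05, 0.02, n)
            by, sy = rng.normal(0, 0.05, n), rng.uniform(0.005, 0.05, n)
            res = sm.WLS(by, bx, weights=1 / sy**2).fit()
            est = ivw(make_hset(bx, by, sy), model="fixed")
            assert est.beta == pytest.approx(res.params[0], rel=1e-12)

    def test_empty_set_is_an_error(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_hset([], [], []))


class TestEgger:
    def test_exact_collinearity_through_origin(self):
        est = egger(make_hset([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], 0.05))
        assert est.beta == pytest.approx(0.1)
        assert est.intercept == pytest.approx(0.0, abs=1e-14)

    def test_exact_affine_data_recovers_intercept_and_slope(self):
        bx = np.array([1.0, 2.0, 3.0, 4.0])
        est = egger(make_hset(bx, 0.05 + 0.1 * bx, 0.03))
        assert est.intercept == pytest.approx(0.05)
        assert est.beta == pytest.approx(0.1)

    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(3, 12)
            bx = np.abs(rng.normal(0.05, 0.02, n)) + 0.01
            by, sy = rng.normal(0.01, 0.05, n), rng.uniform(0.005, 0.05, n)
            res = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
            scale = max(1.0, res.ssr / (n - 2))
            se_oracle = np.sqrt(scale * np.diag(res.normalized_cov_params))
            est = egger(make_hset(bx, by, sy))
            assert est.intercept == pytest.approx(res.params[0], rel=1e-10, abs=1e-14)
            assert est.beta == pytest.approx(res.params[1], rel=1e-10)
            assert est.intercept_se == pytest.approx(se_oracle[0], rel=1e-10)
            assert est.se == pytest.approx(se_oracle[1], rel=1e-10)

    def test_slope_invariant_to_allele_coding_flips(self, rng):
        n = 8
        bx = rng.normal(0.05, 0.02, n)
        by, sy = rng.normal(0.01, 0.03, n), rng.uniform(0.005, 0.05, n)
        base = egger(make_hset(bx, by, sy))
        sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        flipped = egger(make_hset(sign * bx, sign * by, sy))
        assert flipped.beta == pytest.approx(base.beta, rel=1e-12)
        assert flipped.intercept == pytest.approx(base.intercept, rel=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hset([0.1, 0.2], [0.01, 0.02], 0.01))


class TestWeightedMedian:
    def test_equal_weights_is_simple_median_interpolation(self):
        assert weighted_median_point(np.array([0.1, 0.2, 0.3]),
                                     np.ones(3)) == pytest.approx(0.2)

    def test_all_ratios_equal_returns_constant_with_tiny_bootstrap_se(self):
        hset = make_hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], 0.0001,
                         se_exp=1e-6)
        est = weighted_median(hset, n_boot=200, seed=7)
        assert est.beta == pytest.approx(0.5)
        assert est.se < 0.01

    def test_dominant_weight_pins_the_estimate_near_that_ratio(self):
        theta = np.array([0.05, 0.2, 0.4])
        w = np.array([0.7, 0.2, 0.1])
        # direct evaluation of the interpolation formula: s = (.35, .80, .95)
        expected = np.interp(0.5, [0.35, 0.80, 0.95], theta)
        assert weighted_median_point(theta, w) == pytest.approx(expected)
        assert abs(weighted_median_point(theta, w) - 0.05) < 0.06

    def test_matches_dense_quantile_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            theta = rng.normal(0.1, 0.3, n)
            w = rng.uniform(0.2, 2.0, n)
            order = np.argsort(theta)
            wn = w[order] / w.sum()
            s = np.cumsum(wn) - 0.5 * wn
            oracle = float(interp1d(s, theta[order], bounds_error=False,
                                    fill_value=(theta[order][0], theta[order][-1]))(0.5))
            assert weighted_median_point(theta, w) == pytest.approx(oracle, abs=1e-6)

    def test_estimate_within_ratio_range_and_deterministic(self, rng):
        bx = rng.normal(0.05, 0.01, 6)
        by, sy = rng.normal(0.005, 0.01, 6), rng.uniform(0.005, 0.02, 6)
        hset = make_hset(bx, by, sy, se_exp=0.002)
        est1 = weighted_median(hset, n_boot=300, seed=11)
        est2 = weighted_median(hset, n_boot=300, seed=11)
        ratios = by / bx
        assert ratios.min() <= est1.beta <= ratios.max()
        assert est1.se == est2.se

    def test_requires_seed_and_three_instruments(self):
        hset = make_hset([0.1, 0.2, 0.3], [0.01, 0.02, 0.03], 0.01)
        with pytest.raises(ValueError):
            weighted_median(hset, seed=None)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_hset([0.1], [0.01], 0.01), seed=1)


def _mvset(B, y, sy, names=("e1", "e2")):
    B, y = np.asarray(B, dtype=float), np.asarray(y, dtype=float)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), y.shape)
    insts = [MVInstrument(f"rs{i}", B[i], np.full(B.shape[1], 1e-4), y[i], sy[i])
             for i in range(len(y))]
    return MVHarmonizedSet(list(names), "out", instruments=insts)


class TestMVMR:
    def test_zero_signal_second_exposure_reduces_to_univariable_ivw(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.array([0.01, 0.025, 0.02, 0.05, 0.04])
        sy = np.full(5, 0.01)
        B = np.column_stack([bx, np.zeros(5)])
        res = mvmr(_mvset(B, y, sy))
        uni = ivw(make_hset(bx, y, sy), model="fixed")
        e1, e2 = res.exposures
        assert e1.beta == pytest.approx(uni.beta, rel=1e-12)
        assert e2.beta == 0.0 and not np.isfinite(e2.se)

    def test_matches_generalized_least_squares_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            B = rng.normal(0.05, 0.02, (n, 2))
            y = rng.normal(0.0, 0.03, n)
            sy = rng.uniform(0.005, 0.05, n)
            res_sm = sm.WLS(y, B, weights=1 / sy**2).fit()
            scale = max(1.0, res_sm.ssr / (n - 2))
            se_oracle = np.sqrt(scale * np.diag(res_sm.normalized_cov_params))
            res = mvmr(_mvset(B, y, sy))
            for est, b, se in zip(res.exposures, res_sm.params, se_oracle):
                assert est.beta == pytest.approx(b, rel=1e-10)
                assert est.se == pytest.approx(se, rel=1e-10)

    def test_duplicated_exposure_column_names_the_pair(self):
        bx = np.linspace(0.1, 0.5, 5)
        B = np.column_stack([bx, bx])
        with pytest.raises(MulticollinearityError, match="e1.*e2"):
            mvmr(_mvset(B, np.zeros(5) + 0.01, 0.01))

    def test_needs_more_instruments_than_exposures(self):
        with pytest.raises(InsufficientInstrumentsError):
            mvmr(_mvset(np.eye(2), [0.1, 0.2], 0.01))


def test_confidence_intervals_use_normal_multiplier():
    est = ivw(make_hset([1.0, 1.0], [0.2, 0.1], [0.1, 0.1]), model="fixed")
    assert est.ci_high - est.beta == pytest.approx(Z95 * est.se)
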