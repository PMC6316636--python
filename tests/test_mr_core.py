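"""Estimators: Wald ratios, IVW, weighted median, MR-Egger, heterogeneity."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit import (
    HarmonizedInstrument,
    RatioEstimate,
    cochran_q,
    ivw,
    mr_egger,
    wald_ratio,
    wald_ratios,
    weighted_median,
)
from mrkit.errors import (
    ConfigurationError,
    InsufficientInstrumentsError,
    OrientationError,
    UndefinedRatioError,
)

# values frozen from an independent spreadsheet-style recomputation of the
# packaged six-SNP instrument set (plain numpy formulas, no mrkit code)
IVW_ESTIMATE = 0.0647047910701639
IVW_SE = 0.0846880616496898
FIXTURE_Q = 3.1562530156488426
WM_POINT = 0.0813546825561097
EGGER_SLOPE = 0.1840594358090313
EGGER_INTERCEPT = -0.0063778950114537
EGGER_INTERCEPT_SE = 0.0065893726449720


def make_inst(rsid="rs1", bx=0.05, sx=0.002, by=0.005, sy=0.009):
    return HarmonizedInstrument(rsid=rsid, beta_exposure=bx, se_exposure=sx,
                                beta_outcome=by, se_outcome=sy)


def random_ratios(rng, n):
    theta = rng.normal(0.0, 0.5, n)
    se = rng.uniform(0.05, 0.5, n)
    return [RatioEstimate(rsid=f"r{j}", theta=t, se_theta=s) for j, (t, s) in enumerate(zip(theta, se))]


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx, by, sy, theta, se",
        [
            (2.0, 1.0, 0.5, 0.5, 0.25),
            (0.089, 0.009, 0.009, 0.009 / 0.089, 0.009 / 0.089),
            (0.05, 0.0, 0.01, 0.0, 0.2),
        ],
    )
    def test_ratio_and_first_order_se(self, bx, by, sy, theta, se):
        est = wald_ratio(make_inst(bx=bx, by=by, sy=sy))
        assert est.theta == pytest.approx(theta, rel=1e-12)
        assert est.se_theta == pytest.approx(se, rel=1e-12)
        assert est.weight == pytest.approx(se ** -2, rel=1e-12)

    def test_zero_exposure_beta_is_undefined(self):
        with pytest.raises(UndefinedRatioError, match="rs1"):
            wald_ratio(make_inst(bx=0.0))


class TestIvw:
    def test_equal_weights_reduce_to_simple_mean(self):
        ratios = [RatioEstimate("a", 0.2, 0.1), RatioEstimate("b", 0.6, 0.1)]
        assert ivw(ratios).estimate == pytest.approx(0.4, rel=1e-12)

    def test_single_instrument_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw([RatioEstimate("a", 0.2, 0.1)])

    def test_packaged_instruments_pooled_estimate(self, ratios):
        est = ivw(ratios)
        assert est.estimate == pytest.approx(IVW_ESTIMATE, rel=1e-12)
        assert est.se == pytest.approx(IVW_SE, rel=1e-12)
        assert est.ci_low == pytest.approx(est.estimate - 1.959964 * est.se, rel=1e-12)

    def test_multiplicative_model_floors_dispersion_at_fixed(self, ratios):
        # Q < df here, so the multiplicative model must coincide with fixed
        fixed, mre = ivw(ratios, "fixed"), ivw(ratios, "multiplicative")
        assert mre.se == fixed.se
        overdispersed = [RatioEstimate("a", -1.0, 0.1), RatioEstimate("b", 1.0, 0.1),
                         RatioEstimate("c", 3.0, 0.1)]
        assert ivw(overdispersed, "multiplicative").se > ivw(overdispersed, "fixed").se

    def test_ivw_equals_zero_intercept_weighted_regression(self):
        """Algebraic identity with the origin-constrained WLS slope."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            bx = rng.uniform(0.01, 0.1, 8)
            by = rng.normal(0.0, 0.02, 8)
            sy = rng.uniform(0.005, 0.02, 8)
            insts = [make_inst(rsid=f"r{j}", bx=bx[j], by=by[j], sy=sy[j]) for j in range(8)]
            est = ivw(wald_ratios(insts))
            slope = sm.WLS(by, bx[:, None], weights=sy ** -2).fit().params[0]
            assert est.estimate == pytest.approx(slope, abs=1e-12)


class TestCochranQ:
    def test_exact_two_point_case(self):
        ratios = [RatioEstimate("a", 0.0, 1.0), RatioEstimate("b", 2.0, 1.0)]
        het = cochran_q(ratios, pooled=1.0)
        assert het.q == pytest.approx(2.0, rel=1e-12)
        assert het.df == 1
        assert het.i_squared == pytest.approx(50.0, rel=1e-12)

    def test_identical_ratios_are_homogeneous(self):
        ratios = [RatioEstimate(f"r{j}", 0.3, 0.1) for j in range(4)]
        het = cochran_q(ratios, pooled=0.3)
        assert het.q == 0.0 and het.i_squared == 0.0

    def test_packaged_instruments_show_no_heterogeneity(self, ratios):
        het = ivw(ratios).heterogeneity
        assert het.q == pytest.approx(FIXTURE_Q, rel=1e-12)
        assert het.q < het.df
        assert het.i_squared == 0.0


class TestWeightedMedian:
    def test_equal_weights_odd_n_is_ordinary_median(self):
        ratios = [RatioEstimate("a", 1.0, 1.0), RatioEstimate("b", 2.0, 1.0),
                  RatioEstimate("c", 10.0, 1.0)]
        assert weighted_median(ratios, n_boot=10, seed=1).estimate == pytest.approx(2.0)

    def test_degenerate_identical_ratios(self):
        ratios = [RatioEstimate(f"r{j}", 0.7, s) for j, s in enumerate([0.1, 0.2, 0.3, 0.4])]
        for seed in (1, 2):
            assert weighted_median(ratios, n_boot=10, seed=seed).estimate == pytest.approx(0.7)

    def test_packaged_instruments_point_estimate(self, ratios):
        est = weighted_median(ratios, n_boot=10, seed=1)
        assert est.estimate == pytest.approx(WM_POINT, rel=1e-12)

    def test_bootstrap_deterministic_given_seed(self, ratios):
        a = weighted_median(ratios, n_boot=500, seed=42)
        b = weighted_median(ratios, n_boot=500, seed=42)
        c = weighted_median(ratios, n_boot=500, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_bootstrap_se_stable_in_replicate_count(self, ratios):
        a = weighted_median(ratios, n_boot=10_000, seed=11)
        b = weighted_median(ratios, n_boot=20_000, seed=11)
        assert abs(b.se - a.se) / a.se < 0.05

    @pytest.mark.parametrize(
        "theta, counts",
        [
            ([0.1, 0.4, 0.9], [1, 1, 3]),
            ([-0.5, 0.0, 0.2, 0.7], [2, 1, 3, 1]),
            ([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0], [1, 2, 3, 4, 3, 2, 1]),
        ],
    )
    def test_agrees_with_expanded_multiset_brute_force(self, theta, counts):
        """Small-integer weights: interpolated weighted median matches the
        midpoint quantile of the expanded equal-weight multiset."""
        ratios = [
            RatioEstimate(f"r{j}", t, 1.0 / np.sqrt(k))  # weight = k
            for j, (t, k) in enumerate(zip(theta, counts))
        ]
        est = weighted_median(ratios, n_boot=1, seed=0).estimate
        expanded = np.repeat(theta, counts)
        mids = (np.arange(expanded.size) + 0.5) / expanded.size
        brute = np.interp(0.5, mids, np.sort(expanded))
        step = np.max(np.diff(np.sort(np.unique(theta))))
        assert abs(est - brute) <= step / min(counts) + 1e-12

    def test_too_few_instruments_or_replicates(self, ratios):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(ratios[:2], n_boot=10, seed=1)
        with pytest.raises(ConfigurationError):
            weighted_median(ratios, n_boot=0, seed=1)


class TestMrEgger:
    def test_perfect_linear_data_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.02, 0.04, 0.05, 0.08])
        insts = [make_inst(rsid=f"r{j}", bx=b, by=0.3 * b, sy=0.01) for j, b in enumerate(bx)]
        res = mr_egger(insts)
        assert res.slope.estimate == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_packaged_instruments_slope_and_intercept(self, instruments):
        res = mr_egger(instruments)
        assert res.slope.estimate == pytest.approx(EGGER_SLOPE, rel=1e-12)
        assert res.intercept == pytest.approx(EGGER_INTERCEPT, rel=1e-12)
        assert res.intercept_se == pytest.approx(EGGER_INTERCEPT_SE, rel=1e-10)

    def test_normal_inference_option_changes_p_only(self, instruments):
        res_t = mr_egger(instruments, use_t=True)
        res_z = mr_egger(instruments, use_t=False)
        assert res_z.slope.estimate == res_t.slope.estimate
        assert res_z.intercept_pvalue < res_t.intercept_pvalue

    def test_constrained_intercept_reproduces_ivw(self):
        """Dropping the intercept (unit dispersion) gives the IVW estimate and SE."""
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.01, 0.1, 10)
        by = rng.normal(0.05 * bx, 0.01)
        sy = rng.uniform(0.005, 0.02, 10)
        insts = [make_inst(rsid=f"r{j}", bx=bx[j], by=by[j], sy=sy[j]) for j in range(10)]
        est = ivw(wald_ratios(insts))
        fit = sm.WLS(by, bx[:, None], weights=sy ** -2).fit()
        se_unit = float(fit.bse[0] / np.sqrt(fit.mse_resid))
        assert est.estimate == pytest.approx(float(fit.params[0]), abs=1e-12)
        assert est.se == pytest.approx(se_unit, abs=1e-12)

    def test_orientation_and_size_preconditions(self, instruments):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(instruments[:2])
        bad = list(instruments[:5]) + [make_inst(bx=-0.01)]
        with pytest.raises(OrientationError, match="rs1"):
            mr_egger(bad)


class TestScaleEquivariance:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        c=st.floats(min_value=0.01, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**20),
        n=st.integers(min_value=3, max_value=12),
    )
    def test_all_estimators_scale_with_q_and_p_invariant(self, c, seed, n):
        """Multiplying ratios and SEs by c scales estimates/SEs by c and
        leaves Q, I-squared and p-values unchanged."""
        rng = np.random.default_rng(seed)
        base = random_ratios(rng, n)
        scaled = [RatioEstimate(r.rsid, c * r.theta, c * r.se_theta) for r in base]
        e1, e2 = ivw(base), ivw(scaled)
        assert e2.estimate == pytest.approx(c * e1.estimate, rel=1e-9, abs=1e-12)
        assert e2.se == pytest.approx(c * e1.se, rel=1e-9)
        assert e2.pvalue == pytest.approx(e1.pvalue, rel=1e-9)
        h1, h2 = e1.heterogeneity, e2.heterogeneity
        assert h2.q == pytest.approx(h1.q, rel=1e-9, abs=1e-12)
        assert h2.i_squared == pytest.approx(h1.i_squared, rel=1e-9, abs=1e-9)
        assert 0.0 <= h2.i_squared <= 100.0 and h2.q >= 0.0
        w1 = weighted_median(base, n_boot=50, seed=5)
        w2 = weighted_median(scaled, n_boot=50, seed=5)
        assert w2.estimate == pytest.approx(c * w1.estimate, rel=1e-9, abs=1e-12)
        assert w2.se == pytest.approx(c * w1.se, rel=1e-9, abs=1e-12)
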