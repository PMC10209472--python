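import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrkit import estimators
from mrkit.estimators import (
    MREstimate,
    ivw,
    mr_egger,
    egger_simex,
    or_from_ci,
    p_from_or_ci,
    quadratic_extrapolate,
    to_odds_scale,
    wald_ratios,
    weighted_median,
    weighted_mode,
)

from conftest import make_hset, make_ratios, random_hset, ratio


class TestWaldRatios:
    def test_basic_division(self):
        hset = make_hset([0.1], [0.2], gy_se=[0.05])
        [r], excluded = wald_ratios(hset)
        assert r.ratio == pytest.approx(2.0)
        assert r.se == pytest.approx(0.5)
        assert r.weight == pytest.approx(4.0)
        assert excluded == []

    def test_negative_gx_flips_sign_not_se(self):
        hset = make_hset([-0.1], [0.2], gy_se=[0.05])
        [r], _ = wald_ratios(hset)
        assert r.ratio == pytest.approx(-2.0)
        assert r.se == pytest.approx(0.5)

    def test_second_order_se_matches_delta_oracle(self):
        # oracle: var = sy^2/gx^2 + gy^2*sx^2/gx^4
        hset = make_hset([0.1], [0.2], gx_se=[0.02], gy_se=[0.05])
        [r], _ = wald_ratios(hset, second_order=True)
        oracle = np.sqrt(0.05**2 / 0.1**2 + 0.2**2 * 0.02**2 / 0.1**4)
        assert r.se == pytest.approx(oracle, abs=1e-12)
        assert r.se == pytest.approx(0.6403124237432849)

    def test_zero_gx_excluded(self):
        hset = make_hset([0.0, 0.1], [0.2, 0.2])
        ratios, excluded = wald_ratios(hset)
        assert [r.variant_id for r in ratios] == ["rs1"]
        assert excluded == [("rs0", "zero_gx")]


class TestIvw:
    def test_equal_weights(self):
        est = ivw(make_ratios([1.0, 3.0], [1.0, 1.0]))
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(1 / np.sqrt(2))
        assert est.method == "IVW-FE"

    def test_unequal_weights(self):
        est = ivw(make_ratios([1.0, 2.0], [0.5, 1.0]))
        assert est.beta == pytest.approx(1.2)
        assert est.se == pytest.approx(1 / np.sqrt(5))

    def test_re_clamps_at_fe_when_homogeneous(self):
        ratios = make_ratios([1.5, 1.5, 1.5], [0.5, 0.4, 0.3])
        fe = ivw(ratios, mode="FE")
        re = ivw(ratios, mode="RE")
        assert re.beta == pytest.approx(fe.beta)
        assert re.se == pytest.approx(fe.se)

    def test_re_inflates_under_heterogeneity(self):
        ratios = make_ratios([0.0, 4.0, -3.0, 5.0], [0.2, 0.2, 0.2, 0.2])
        assert ivw(ratios, mode="RE").se > ivw(ratios, mode="FE").se

    def test_too_few_ratios(self):
        with pytest.raises(ValueError):
            ivw(make_ratios([1.0], [1.0]))

    def test_equivalent_to_origin_weighted_regression(self, rng):
        # oracle: slope of gy on gx through the origin, weights 1/gy_se^2
        hset = random_hset(rng, k=15)
        ratios, _ = wald_ratios(hset)
        est = ivw(ratios)
        gx, gy, w = hset.gx(), hset.gy(), 1.0 / hset.gy_se() ** 2
        slope = np.sum(w * gx * gy) / np.sum(w * gx * gx)
        se = 1.0 / np.sqrt(np.sum(w * gx * gx))
        assert est.beta == pytest.approx(slope, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_ci_and_p_consistent(self):
        est = ivw(make_ratios([1.0, 2.0], [0.5, 1.0]))
        assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se)
        assert est.ci_high == pytest.approx(est.beta + 1.96 * est.se)
        assert est.p == pytest.approx(2 * stats.norm.sf(abs(est.beta / est.se)))


class TestWeightedMedian:
    def test_equal_weights_is_middle(self):
        est = weighted_median(make_ratios([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]), B=100, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_interpolation_oracle_five_thirds(self):
        # weights (0.5, 0.25, 0.25) -> positions (0.25, 0.625, 0.875);
        # linear interpolation to 0.5 gives 1 + 0.25/0.375 = 5/3
        ratios = [
            ratio("a", 1.0, 1 / np.sqrt(2)),  # weight 2
            ratio("b", 2.0, 1.0),  # weight 1
            ratio("c", 3.0, 1.0),  # weight 1
        ]
        est = weighted_median(ratios, B=100, seed=1)
        assert est.beta == pytest.approx(5 / 3, abs=1e-12)

    def test_degenerate_identical_ratios(self):
        ratios = make_ratios([1.3, 1.3, 1.3], [0.5, 0.5, 0.5])
        est = weighted_median(ratios, B=1000, seed=2)
        assert est.beta == pytest.approx(1.3)
        # bootstrap sd consistent with the sampling sd of a median of three
        assert 0.1 < est.se < 0.8

    def test_reduces_to_plain_median_with_equal_weights(self, rng):
        values = rng.normal(1.0, 0.5, 9)
        ratios = make_ratios(values, [0.3] * 9)
        est = weighted_median(ratios, B=100, seed=3)
        assert est.beta == pytest.approx(np.median(values), abs=1e-12)

    def test_seed_reproducibility_and_stability(self):
        ratios = make_ratios([0.8, 1.1, 1.5, 2.0, 0.9], [0.3, 0.4, 0.5, 0.6, 0.3])
        a = weighted_median(ratios, B=1000, seed=7)
        b = weighted_median(ratios, B=1000, seed=7)
        assert a == b
        c = weighted_median(ratios, B=1000, seed=8)
        assert c.se == pytest.approx(a.se, rel=0.10)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            weighted_median(make_ratios([1.0, 2.0], [1.0, 1.0]), B=100, seed=0)
        with pytest.raises(ValueError):
            weighted_median(make_ratios([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]), B=10, seed=0)


class TestWeightedMode:
    def test_degenerate_identical(self):
        est = weighted_mode(make_ratios([2.0, 2.0, 2.0], [0.5, 0.3, 0.4]), B=100, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_robust_to_single_outlier(self):
        ratios = make_ratios([1.0, 1.1, 0.9, 5.0], [0.3, 0.3, 0.3, 0.3])
        est = weighted_mode(ratios, B=100, seed=1)
        assert 0.9 <= est.beta <= 1.1

    def test_grid_argmax_matches_dense_grid_oracle(self, rng):
        values = rng.normal(1.0, 0.8, 10)
        ses = rng.uniform(0.2, 0.6, 10)
        ratios = make_ratios(values, ses)
        est = weighted_mode(ratios, B=100, seed=1)
        # brute-force oracle on a 10^5-point grid
        b = np.array([r.ratio for r in ratios])
        w = np.array([r.weight for r in ratios])
        h = estimators._mode_bandwidth(b, 1.0)
        dense = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 100_000)
        wn = w / w.sum()
        dens = (wn[:, None] * np.exp(-0.5 * ((dense[None, :] - b[:, None]) / h) ** 2)).sum(0)
        oracle = dense[np.argmax(dens)]
        spacing = (b.max() - b.min() + 6 * h) / 511
        assert abs(est.beta - oracle) <= spacing

    def test_invalid_phi(self):
        with pytest.raises(ValueError):
            weighted_mode(make_ratios([1.0, 2.0, 3.0], [1.0] * 3), phi=0.0)


class TestMrEgger:
    def test_exact_linear_fit(self):
        gx = np.array([0.1, 0.2, 0.3, 0.4])
        gy = 0.05 + 2.0 * gx
        res = mr_egger(make_hset(gx, gy))
        assert res.slope.beta == pytest.approx(2.0, abs=1e-10)
        assert res.intercept_beta == pytest.approx(0.05, abs=1e-10)

    def test_orientation_flips_negative_gx(self):
        gx = np.array([-0.1, 0.2, 0.3])
        gy = np.array([-0.25, 0.45, 0.65])  # on gy = 0.05 + 2 gx after flip
        res = mr_egger(make_hset(gx, gy))
        assert res.slope.beta == pytest.approx(2.0, abs=1e-10)
        assert res.intercept_beta == pytest.approx(0.05, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        hset = random_hset(rng, k=12)
        res = mr_egger(hset)
        gx, gy = np.abs(hset.gx()), hset.gy() * np.sign(hset.gx())
        w = 1.0 / hset.gy_se() ** 2
        X = np.column_stack([np.ones_like(gx), gx])
        xtwx = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(xtwx, X.T @ (w * gy))
        assert res.intercept_beta == pytest.approx(coef[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(coef[1], abs=1e-10)
        resid = gy - X @ coef
        scale2 = max(1.0, float(np.sum(w * resid**2)) / (len(gx) - 2))
        cov = np.linalg.inv(xtwx) * scale2
        assert res.intercept_se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
        assert res.slope.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_t_reference_pvalues(self, rng):
        hset = random_hset(rng, k=6)
        res = mr_egger(hset)
        z = res.slope.beta / res.slope.se
        assert res.slope.p == pytest.approx(2 * stats.t.sf(abs(z), df=4))
        assert res.slope.df_note == "t(4)"

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            mr_egger(make_hset([0.1, 0.2], [0.2, 0.4]))


class TestEggerSimex:
    def test_no_measurement_error_returns_naive(self):
        gx = np.array([0.1, 0.2, 0.3, 0.4])
        gy = 0.05 + 2.0 * gx
        hset = make_hset(gx, gy, gx_se=[0.0] * 4)
        res = egger_simex(hset, seed=5)
        naive = mr_egger(hset)
        assert not res.simex_applied
        assert res.slope == naive.slope

    def test_quadratic_extrapolation_identity(self):
        lams = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        poly = lambda lam: 0.3 - 0.1 * lam + 0.02 * lam**2
        assert quadratic_extrapolate(lams, poly(lams)) == pytest.approx(
            poly(-1.0), abs=1e-12
        )

    def test_simex_metadata(self, rng):
        hset = random_hset(rng, k=10)
        res = egger_simex(hset, B=150, seed=3)
        assert res.simex_applied
        assert res.simex_B == 150
        assert res.simex_lambda_grid == (0.0, 0.5, 1.0, 1.5, 2.0)
        assert res.slope.method == "Egger-SIMEX"

    def test_seed_reproducible(self, rng):
        hset = random_hset(rng, k=10)
        assert egger_simex(hset, seed=4).slope == egger_simex(hset, seed=4).slope


class TestOddsScale:
    def test_headline_style_conversion(self):
        est = MREstimate(
            method="IVW-FE", beta=0.4762, se=0.2227,
            ci_low=0.4762 - 1.96 * 0.2227, ci_high=0.4762 + 1.96 * 0.2227,
            p=0.032, n_snps=59,
        )
        res = to_odds_scale(est)
        assert res.odds_ratio == pytest.approx(1.61, abs=0.005)
        assert res.or_ci_low == pytest.approx(1.04, abs=0.005)
        assert res.or_ci_high == pytest.approx(2.49, abs=0.005)

    def test_null_beta(self):
        est = MREstimate("IVW-FE", 0.0, 0.2, -0.392, 0.392, 1.0, 10)
        res = to_odds_scale(est)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.or_ci_low * res.or_ci_high == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_boundary_case(self):
        beta, se = np.log(2), np.log(2) / 1.96
        est = MREstimate("IVW-FE", beta, se, beta - 1.96 * se, beta + 1.96 * se,
                         2 * stats.norm.sf(1.96), 10)
        res = to_odds_scale(est)
        assert res.or_ci_low == pytest.approx(1.0)
        assert res.or_ci_high == pytest.approx(4.0)
        assert res.p == pytest.approx(0.05, abs=1e-3)

    def test_implied_p_and_point_estimate_helpers(self):
        assert p_from_or_ci(2.0, 1.0, 4.0) == pytest.approx(0.05, abs=1e-3)
        assert or_from_ci(1.0, 4.0) == pytest.approx(2.0)


class TestEstimatorProperties:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_sign_flip_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        hset = random_hset(rng, k=8)
        flip = rng.random(8) < 0.5
        flipped = make_hset(
            hset.gx() * np.where(flip, -1, 1),
            hset.gy() * np.where(flip, -1, 1),
            hset.gx_se(),
            hset.gy_se(),
        )
        r1, _ = wald_ratios(hset)
        r2, _ = wald_ratios(flipped)
        assert ivw(r1).beta == pytest.approx(ivw(r2).beta, abs=1e-12)
        assert mr_egger(hset).slope.beta == pytest.approx(
            mr_egger(flipped).slope.beta, abs=1e-12
        )
        assert weighted_median(r1, B=100, seed=1).beta == pytest.approx(
            weighted_median(r2, B=100, seed=1).beta, abs=1e-12
        )

    def test_outcome_scaling_equivariance(self, rng):
        hset = random_hset(rng, k=10)
        c = 3.7
        scaled = make_hset(hset.gx(), c * hset.gy(), hset.gx_se(), c * hset.gy_se())
        r1, _ = wald_ratios(hset)
        r2, _ = wald_ratios(scaled)
        for mode in ("FE", "RE"):
            a, b = ivw(r1, mode=mode), ivw(r2, mode=mode)
            assert b.beta == pytest.approx(c * a.beta, abs=1e-10)
            assert b.se == pytest.approx(c * a.se, abs=1e-10)
        wa = weighted_median(r1, B=500, seed=9)
        wb = weighted_median(r2, B=500, seed=9)
        assert wb.beta == pytest.approx(c * wa.beta, abs=1e-10)
        assert wb.se == pytest.approx(c * wa.se, rel=1e-6)
        ea, eb = mr_egger(hset), mr_egger(scaled)
        assert eb.slope.beta == pytest.approx(c * ea.slope.beta, abs=1e-10)
        assert eb.slope.se == pytest.approx(c * ea.slope.se, abs=1e-10)

    def test_egger_agrees_with_ivw_without_pleiotropy(self):
        from mrkit import simulate, sumstats

        cfg = simulate.SimConfig(
            k=40, beta_true=0.4, gamma_sd=0.15, gamma_floor=0.1,
            se_x_range=(0.003, 0.006), se_y_range=(0.02, 0.05), seed=77,
        )
        exposure, outcome, _ = simulate.simulate_two_sample(cfg)
        hset = sumstats.harmonise(exposure, outcome)
        ratios, _ = wald_ratios(hset)
        est_ivw = ivw(ratios)
        res = mr_egger(hset)
        assert res.slope.beta == pytest.approx(
            est_ivw.beta, abs=3 * np.hypot(res.slope.se, est_ivw.se)
        )
        assert abs(res.intercept_beta) < 3 * res.intercept_se
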