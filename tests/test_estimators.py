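import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.errors import DomainError, InsufficientInstrumentsError
from mrmediate.estimators import (
    ivw,
    mode_estimators,
    mr_egger,
    run_all_methods,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import make_hset


class TestWaldRatio:
    def test_null_numerator(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_arithmetic(self):
        est = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_frame_invariance(self):
        a = wald_ratio(0.1, 0.02, 0.05, 0.01)
        b = wald_ratio(-0.1, 0.02, -0.05, 0.01)
        assert a.beta == b.beta and a.se == b.se and a.pval == b.pval

    def test_zero_bx_raises(self):
        with pytest.raises(DomainError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)

    def test_second_order_se_larger(self):
        first = wald_ratio(0.1, 0.05, 0.05, 0.01)
        second = wald_ratio(0.1, 0.05, 0.05, 0.01, second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_two_snp_closed_form(self):
        # oracle: weighted LS through the origin, w = 1/seY^2
        # w=(1e4, 2.5e3); sum w bX bY = 90; sum w bX^2 = 200
        h = make_hset([0.1, 0.2], [0.05, 0.08], seY=[0.01, 0.02])
        est = ivw(h, effects_model="fixed")
        assert est.beta == pytest.approx(0.45, abs=1e-12)
        assert est.se == pytest.approx(200**-0.5, abs=1e-12)

    def test_oracle_equivalence_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        bX = rng.normal(0.1, 0.02, 30)
        bY = 0.3 * bX + rng.normal(0, 0.01, 30)
        seY = np.full(30, 0.01)
        h = make_hset(bX, bY, seY=seY)
        est = ivw(h, effects_model="fixed")
        fit = sm.WLS(bY, bX, weights=1 / seY**2).fit()
        assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-10)

    def test_consensus_limit(self):
        h = make_hset([0.1] * 5, [0.05] * 5)
        est = ivw(h)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_single_row_delegates_to_wald(self):
        h = make_hset([0.1], [0.05], seY=[0.01])
        est = ivw(h)
        w = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == w.beta and est.se == w.se

    def test_fixed_se_not_above_random(self, rng):
        bX = rng.normal(0.1, 0.02, 20)
        bY = 0.3 * bX + rng.normal(0, 0.05, 20)
        h = make_hset(bX, bY, seY=np.full(20, 0.01))
        assert ivw(h, "fixed").se <= ivw(h, "multiplicative_random").se

    def test_degenerate_instruments(self):
        h = make_hset([0.0, 0.0], [0.05, 0.02])
        with pytest.raises(DomainError):
            ivw(h)

    def test_null_rejection_rate(self):
        # fixed-seed Monte-Carlo: no effect, no pleiotropy
        rng = np.random.default_rng(99)
        k, reps = 100, 1000
        se_y = 0.01
        rejections = 0
        for _ in range(reps):
            a = rng.uniform(0.03, 0.08, k) * rng.choice([-1, 1], k)
            bX = a + rng.normal(0, 0.005, k)
            bY = rng.normal(0, se_y, k)
            h = make_hset(bX, bY, seX=np.full(k, 0.005), seY=np.full(k, se_y))
            rejections += ivw(h).pval < 0.05
        # exact binomial 95% band around 0.05 for 1000 draws: [37, 64]
        assert 37 <= rejections <= 64

    def test_frame_invariance(self, rng):
        bX = rng.normal(0.1, 0.02, 10)
        bY = 0.3 * bX + rng.normal(0, 0.01, 10)
        flip = rng.choice([-1.0, 1.0], 10)
        a = ivw(make_hset(bX, bY))
        b = ivw(make_hset(bX * flip, bY * flip))
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.se == pytest.approx(b.se, abs=1e-14)


class TestEgger:
    def test_exact_proportional_fit(self):
        bX = np.array([0.1, 0.2, 0.3])
        h = make_hset(bX, 0.5 * bX)
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extra["egger_intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_fit(self):
        bX = np.array([0.1, 0.2, 0.3])
        h = make_hset(bX, 0.01 + 0.5 * bX)
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extra["egger_intercept"] == pytest.approx(0.01, abs=1e-10)
        # zero-residual fit: p-value flagged missing, not a crash
        assert est.extra["egger_intercept_pval"] is None
        assert est.extra["degenerate_fit"] == 1.0

    def test_oracle_equivalence_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        bX = np.abs(rng.normal(0.1, 0.03, 20))
        bY = 0.005 + 0.4 * bX + rng.normal(0, 0.01, 20)
        seY = rng.uniform(0.008, 0.012, 20)
        h = make_hset(bX, bY, seY=seY)
        est = mr_egger(h)
        X = sm.add_constant(bX)
        fit = sm.WLS(bY, X, weights=1 / seY**2).fit()
        assert est.beta == pytest.approx(float(fit.params[1]), abs=1e-10)
        assert est.extra["egger_intercept"] == pytest.approx(float(fit.params[0]), abs=1e-10)

    def test_too_few_rows(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_hset([0.1, 0.2], [0.05, 0.1]))

    def test_directional_pleiotropy_recovery(self):
        # mean intercept over reps tracks the mean pleiotropic offset
        rng = np.random.default_rng(3)
        reps, k, offset = 500, 30, 0.002
        intercepts = np.empty(reps)
        for r in range(reps):
            bX = np.abs(rng.normal(0.1, 0.03, k)) + 0.02
            alpha = rng.normal(offset, 0.001, k)
            bY = alpha + 0.3 * bX + rng.normal(0, 0.005, k)
            intercepts[r] = mr_egger(make_hset(bX, bY, seY=np.full(k, 0.005))).extra[
                "egger_intercept"
            ]
        mc_se = intercepts.std(ddof=1) / np.sqrt(reps)
        assert abs(intercepts.mean() - offset) < 3 * mc_se


class TestWeightedMedian:
    def test_consensus(self):
        bX = np.array([0.1, 0.2, 0.4])
        est = weighted_median(make_hset(bX, 0.5 * bX), n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_middle_element_equal_weights(self):
        bX = np.array([0.1, 0.1, 0.1])
        bY = np.array([0.01, 0.05, 0.09])  # theta = 0.1, 0.5, 0.9
        est = weighted_median(make_hset(bX, bY), n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_oracle_equivalence_interpolation(self):
        # independent implementation of the cumulative-weight interpolation
        bX = np.array([0.1, 0.2, 0.15, 0.3])
        bY = np.array([0.03, 0.11, 0.05, 0.2])
        seY = np.array([0.01, 0.02, 0.015, 0.01])
        theta = bY / bX
        w = bX**2 / seY**2
        order = np.argsort(theta)
        th, wt = theta[order], w[order] / w.sum()
        cum = np.cumsum(wt) - 0.5 * wt
        i = np.searchsorted(cum, 0.5, side="right") - 1
        expected = th[i] + (th[i + 1] - th[i]) * (0.5 - cum[i]) / (cum[i + 1] - cum[i])
        est = weighted_median(make_hset(bX, bY, seY=seY), n_boot=50, seed=1)
        assert est.beta == pytest.approx(expected, abs=1e-10)

    def test_dominant_weight_instrument(self):
        bX = np.array([1.0, 0.1, 0.1])
        bY = np.array([0.7, 0.02, 0.03])
        seY = np.array([0.001, 0.1, 0.1])  # first holds nearly all weight
        est = weighted_median(make_hset(bX, bY, seY=seY), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.7, abs=1e-5)

    def test_robust_to_forty_percent_invalid(self):
        rng = np.random.default_rng(4)
        reps, k, truth = 100, 20, 0.2
        wm = np.empty(reps)
        iv = np.empty(reps)
        for r in range(reps):
            bX = np.abs(rng.normal(0.1, 0.02, k)) + 0.05
            bY = truth * bX + rng.normal(0, 0.001, k)
            bY[: int(0.4 * k)] += 0.05  # large pleiotropic offsets
            h = make_hset(bX, bY, seY=np.full(k, 0.001))
            wm[r] = weighted_median(h, n_boot=20, seed=r).beta
            iv[r] = ivw(h).beta
        mc_se = wm.std(ddof=1) / np.sqrt(reps)
        assert abs(np.median(wm) - truth) < 3 * mc_se + 0.01
        assert abs(iv.mean() - truth) > abs(wm.mean() - truth)

    def test_seed_reproducible(self):
        h = make_hset([0.1, 0.2, 0.3], [0.05, 0.11, 0.14])
        a = weighted_median(h, n_boot=200, seed=7)
        b = weighted_median(h, n_boot=200, seed=7)
        assert a.se == b.se


class TestModes:
    def test_dominant_cluster(self):
        bX = np.array([0.1, 0.1, 0.1, 0.1])
        bY = np.array([0.05, 0.05, 0.05, 0.5])  # theta: 0.5 x3, 5.0 outlier
        simple, weighted = mode_estimators(make_hset(bX, bY), n_boot=50, seed=1)
        assert simple.beta == pytest.approx(0.5, abs=0.05)
        assert weighted.beta == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("phi", [0.5, 1.0, 2.0])
    def test_all_equal_any_phi(self, phi):
        bX = np.array([0.1, 0.2, 0.3])
        simple, weighted = mode_estimators(
            make_hset(bX, 0.5 * bX), phi=phi, n_boot=20, seed=1
        )
        assert simple.beta == pytest.approx(0.5, abs=1e-12)
        assert weighted.beta == pytest.approx(0.5, abs=1e-12)

    def test_valid_majority_recovery(self):
        rng = np.random.default_rng(5)
        reps, k, truth = 60, 30, 0.3
        vals = np.empty(reps)
        for r in range(reps):
            bX = np.abs(rng.normal(0.1, 0.02, k)) + 0.05
            bY = truth * bX + rng.normal(0, 0.002, k)
            bY[:5] += 0.04
            simple, _ = mode_estimators(
                make_hset(bX, bY, seY=np.full(k, 0.002)), n_boot=20, seed=r
            )
            vals[r] = simple.beta
        mc_se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - truth) < 3 * mc_se + 0.01


class TestToOddsRatio:
    def test_null(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_zero_variance(self):
        or_, lo, hi = to_odds_ratio(np.log(2), 0.0)
        assert or_ == pytest.approx(2.0) and lo == hi == pytest.approx(2.0)

    def test_reported_protective_metabolite(self):
        # published strongest protective association: OR 0.99898 (0.99828-0.99969)
        or_, lo, hi = to_odds_ratio(-0.00102, 0.00036)
        assert or_ == pytest.approx(0.99898, abs=5e-6)
        assert lo == pytest.approx(0.99828, abs=5e-6)
        assert hi == pytest.approx(0.99969, abs=5e-6)

    @given(
        beta=st.floats(-2, 2, allow_nan=False),
        se=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_ordering_property(self, beta, se):
        or_, lo, hi = to_odds_ratio(beta, se)
        assert lo <= or_ <= hi
        assert or_ == pytest.approx(np.exp(beta), rel=1e-12)


class TestRunAllMethods:
    def test_single_snp_wald_primary(self):
        res = run_all_methods(make_hset([0.1], [0.05]))
        assert set(res.estimates) == {"wald_ratio"}
        assert res.primary_method == "wald_ratio"

    def test_two_snps_ivw_only(self):
        res = run_all_methods(make_hset([0.1, 0.2], [0.05, 0.1]))
        assert set(res.estimates) == {"ivw"}

    def test_consensus_all_five_equal(self):
        bX = np.array([0.1, 0.2, 0.3])
        res = run_all_methods(make_hset(bX, 0.5 * bX), n_boot=50, seed=1)
        assert set(res.estimates) == {
            "ivw", "egger", "weighted_median", "simple_mode", "weighted_mode",
        }
        for est in res.estimates.values():
            assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_methods_agree_without_pleiotropy(self, rng):
        k, truth = 100, 0.25
        bX = np.abs(rng.normal(0.1, 0.02, k)) + 0.05
        bY = truth * bX + rng.normal(0, 0.003, k)
        res = run_all_methods(make_hset(bX, bY, seY=np.full(k, 0.003)), n_boot=200, seed=1)
        ref = res.estimates["ivw"]
        for est in res.estimates.values():
            tol = 3 * max(est.se, ref.se)
            assert abs(est.beta - ref.beta) < tol

    def test_frame_invariance_all_methods(self, rng):
        k = 10
        bX = rng.normal(0.1, 0.03, k)
        bY = 0.3 * bX + rng.normal(0, 0.01, k)
        flip = rng.choice([-1.0, 1.0], k)
        a = run_all_methods(make_hset(bX, bY), n_boot=50, seed=3)
        b = run_all_methods(make_hset(bX * flip, bY * flip), n_boot=50, seed=3)
        for m in a.estimates:
            assert a.estimates[m].beta == pytest.approx(b.estimates[m].beta, abs=1e-9)
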