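"""Causal estimators against hand-traced and independent least-squares
oracles, plus their algebraic invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmr.estimators import (
    EstimationError,
    ivw,
    mr_egger,
    multivariable_mr,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from lipidmr.instruments import scale_effects
from lipidmr.simulate import (
    OutcomeSpec,
    PleiotropySpec,
    SimulationConfig,
    scenario_suite,
    simulate_panel,
)

from conftest import make_panel


class TestWaldRatio:
    def test_direct_formula(self):
        assert wald_ratio(0.1, 0.01, 0.05, 0.02) == pytest.approx((0.5, 0.2))

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02)[0] == 0.0

    def test_zero_exposure_effect_undefined(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_sign_follows_outcome_when_exposure_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            bx = rng.uniform(0.01, 0.2)
            by = rng.normal(0, 0.1)
            ratio, _ = wald_ratio(bx, 0.01, by, 0.01)
            assert np.sign(ratio) == np.sign(by)


class TestIVW:
    def test_hand_traced_three_variant_instrument(self, toy_ivw_panel):
        est = ivw(toy_ivw_panel, "chd", "fixed")
        assert est.theta == pytest.approx(59 / 141, abs=1e-12)
        assert est.se_theta == pytest.approx(141**-0.5, abs=1e-12)
        assert est.q_statistic == pytest.approx(1.3120567375886523, abs=1e-8)
        assert est.q_df == 2
        # Q/df < 1, so the random-effects SE equals the fixed one
        est_re = ivw(toy_ivw_panel, "chd", "random_multiplicative")
        assert est_re.se_theta == pytest.approx(est.se_theta, abs=1e-12)

    def test_single_variant_fixed_reduces_to_wald_ratio(self):
        panel = make_panel([0.1], beta_y=[0.05], se_y=[0.02])
        est = ivw(panel, "chd", "fixed")
        assert (est.theta, est.se_theta) == pytest.approx((0.5, 0.2))

    def test_matches_wls_through_origin_oracle(self):
        """IVW equals statsmodels WLS of beta_y on beta_x without constant."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.02, 0.1, 25)
        by = 0.4 * bx + rng.normal(0, 0.02, 25)
        sy = rng.uniform(0.01, 0.03, 25)
        panel = make_panel(bx, beta_y=by, se_y=sy)
        est = ivw(panel, "chd", "fixed")
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert est.theta == pytest.approx(fit.params[0], abs=1e-10)

    def test_equals_weighted_mean_of_wald_ratios(self):
        """Algebraic identity with first-order ratio weights b_x^2/se_y^2."""
        rng = np.random.default_rng(8)
        for seed in range(5):
            r = np.random.default_rng(seed)
            bx = r.uniform(0.02, 0.1, 12)
            by = r.normal(0.04, 0.03, 12)
            sy = r.uniform(0.005, 0.03, 12)
            panel = make_panel(bx, beta_y=by, se_y=sy)
            ratios = by / bx
            w = bx**2 / sy**2
            assert ivw(panel, "chd", "fixed").theta == pytest.approx(
                np.sum(w * ratios) / np.sum(w), abs=1e-10
            )

    def test_random_effects_never_narrower_than_fixed(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.02, 0.1, 20)
        by = 0.3 * bx + rng.normal(0, 0.05, 20)  # strong heterogeneity
        panel = make_panel(bx, beta_y=by, se_y=np.full(20, 0.01))
        fe = ivw(panel, "chd", "fixed")
        re = ivw(panel, "chd", "random_multiplicative")
        assert re.se_theta >= fe.se_theta
        assert re.theta == pytest.approx(fe.theta)

    def test_too_few_variants_fatal(self):
        panel = make_panel([0.1], beta_y=[0.05], se_y=[0.02])
        with pytest.raises(EstimationError):
            ivw(panel, "chd", "random_multiplicative")


class TestMREgger:
    def test_exact_fit_on_collinear_points(self):
        panel = make_panel(
            [0.05, 0.10, 0.20],
            beta_y=[0.035, 0.060, 0.110],
            se_y=[0.01, 0.01, 0.01],
        )
        est = mr_egger(panel, "chd")
        assert est.theta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.01, abs=1e-10)
        assert est.q_statistic == pytest.approx(0.0, abs=1e-16)

    def test_matches_wls_with_intercept_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        bx = rng.uniform(0.02, 0.1, 30)
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.02, 30)
        sy = rng.uniform(0.01, 0.03, 30)
        panel = make_panel(bx, beta_y=by, se_y=sy)
        est = mr_egger(panel, "chd")
        X = np.column_stack([np.ones(30), bx])
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.theta == pytest.approx(fit.params[1], abs=1e-10)

    def test_approaches_ivw_on_noise_free_proportional_data(self):
        bx = np.linspace(0.02, 0.1, 10)
        by = 0.4 * bx
        panel = make_panel(bx, beta_y=by, se_y=np.full(10, 1e-6))
        est = mr_egger(panel, "chd")
        ivw_est = ivw(panel, "chd", "fixed")
        assert est.theta == pytest.approx(ivw_est.theta, abs=1e-6)
        assert est.intercept == pytest.approx(0.0, abs=1e-8)

    def test_rejects_negative_exposure_orientation(self):
        panel = make_panel([-0.05, 0.1, 0.2], beta_y=[0, 0, 0.1], se_y=[0.01] * 3)
        with pytest.raises(EstimationError, match="orient"):
            mr_egger(panel, "chd")

    def test_identical_exposure_betas_singular(self):
        panel = make_panel([0.05] * 4, beta_y=[0.01, 0.02, 0.03, 0.04], se_y=[0.01] * 4)
        with pytest.raises(EstimationError, match="singular"):
            mr_egger(panel, "chd")


class TestWeightedMedian:
    def test_degenerate_equal_ratios(self):
        bx = np.array([0.05, 0.1, 0.2])
        panel = make_panel(bx, beta_y=0.3 * bx, se_y=[0.01, 0.02, 0.03])
        est = weighted_median(panel, "chd", n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.3, abs=1e-12)

    def test_hand_traced_interpolation(self):
        """Ratios (0.2, 0.5, 0.6) with normalized weights (0.25, 0.25, 0.5)
        interpolate to 0.5 + 0.1*(0.5-0.375)/0.375."""
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.2, 0.5, 0.6])
        sy = 1.0 / np.sqrt(np.array([0.25, 0.25, 0.5]))  # w = bx^2/sy^2
        panel = make_panel(bx, beta_y=by, se_y=sy)
        est = weighted_median(panel, "chd", n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.5 + 0.1 * (0.5 - 0.375) / 0.375, abs=1e-10)

    def test_point_estimate_independent_of_seed_se_reproducible(self, toy_ivw_panel):
        a = weighted_median(toy_ivw_panel, "chd", n_boot=200, seed=1)
        b = weighted_median(toy_ivw_panel, "chd", n_boot=200, seed=99)
        c = weighted_median(toy_ivw_panel, "chd", n_boot=200, seed=1)
        assert a.theta == b.theta == c.theta
        assert a.se_theta == c.se_theta
        assert a.se_theta != b.se_theta  # different bootstrap draws

    def test_robust_to_forty_percent_invalid_instruments(self):
        """With 40% of variants carrying large directional pleiotropy the
        weighted median stays near truth while IVW drifts. Homogeneous
        variants (equal frequency and effect) keep the invalid weight share
        at exactly 40% < 50%, and a large outcome study keeps Wald-ratio
        noise from masking the median's robustness."""
        theta = 0.4
        wm_err = np.empty(500)
        ivw_err = np.empty(500)
        for rep in range(500):
            cfg = SimulationConfig(
                n_variants=20,
                seed=10_000 + rep,
                exposure_effect_range=(0.06, 0.06),
                eaf_range=(0.3, 0.3),
                outcomes={"o": OutcomeSpec(500_000, 500_000, theta)},
            )
            panel, _, truth = simulate_panel(cfg)
            blk = panel.outcomes["o"]
            blk.beta = blk.beta.copy()
            blk.beta[:8] += 0.05  # invalid minority, large positive pleiotropy
            wm_err[rep] = weighted_median(panel, "o", n_boot=16, seed=rep).theta - theta
            ivw_err[rep] = ivw(panel, "o", "fixed").theta - theta
        assert abs(wm_err.mean()) < 0.2 * abs(ivw_err.mean())


class TestMultivariable:
    def test_zero_secondary_reduces_to_ivw(self, toy_ivw_panel):
        import dataclasses

        from lipidmr.summary_io import TraitBlock

        panel = dataclasses.replace(
            toy_ivw_panel,
            secondary={
                "hdl": TraitBlock(np.zeros(3), np.full(3, 0.01), np.ones(3)),
                "tg": TraitBlock(np.zeros(3), np.full(3, 0.01), np.ones(3)),
            },
        )
        est = multivariable_mr(panel, "chd")
        assert est.theta == pytest.approx(59 / 141, abs=1e-12)

    def test_matches_wls_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12)
        j = 25
        bx = rng.uniform(0.02, 0.1, j)
        bh = rng.normal(0, 0.03, j)
        bt = rng.normal(0, 0.03, j)
        sy = rng.uniform(0.01, 0.03, j)
        by = 0.4 * bx - 0.2 * bh + 0.1 * bt + rng.normal(0, 0.01, j)
        panel = make_panel(
            bx, beta_y=by, se_y=sy,
            secondary={"hdl": (bh, np.full(j, 0.01)), "tg": (bt, np.full(j, 0.01))},
        )
        est = multivariable_mr(panel, "chd")
        X = np.column_stack([bx, bh, bt])
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        assert est.theta == pytest.approx(fit.params[0], abs=1e-10)

    def test_recovers_direct_effect_under_mediated_pleiotropy(self):
        """HDL-mediated pleiotropy biases univariable IVW; the multivariable
        fit recovers the direct LDL effect within Monte-Carlo error. The
        lipid GWAS is made large so covariate measurement error (which
        dilutes any summary-data multivariable fit) is negligible."""
        theta = 0.4
        mv = np.empty(500)
        uv = np.empty(500)
        for rep in range(500):
            cfg = SimulationConfig(
                n_variants=30,
                seed=20_000 + rep,
                n_exposure=5_000_000,
                outcomes={"o": OutcomeSpec(20_000, 60_000, theta)},
                secondary_traits={"hdl": 0.5},
                secondary_theta={"hdl": -0.3},
            )
            panel, _, _ = simulate_panel(cfg)
            mv[rep] = multivariable_mr(panel, "o").theta
            uv[rep] = ivw(panel, "o", "fixed").theta
        mcse = mv.std(ddof=1) / np.sqrt(500)
        assert abs(mv.mean() - theta) < 3 * mcse
        assert abs(uv.mean() - theta) > 5 * mcse  # univariable visibly biased

    def test_variant_order_invariance(self):
        rng = np.random.default_rng(3)
        j = 10
        bx = rng.uniform(0.02, 0.1, j)
        bh = rng.normal(0, 0.03, j)
        by = 0.4 * bx - 0.2 * bh + rng.normal(0, 0.01, j)
        sy = rng.uniform(0.01, 0.03, j)
        perm = rng.permutation(j)
        p1 = make_panel(bx, beta_y=by, se_y=sy, secondary={"hdl": (bh, np.full(j, 0.01))})
        p2 = make_panel(
            bx[perm], beta_y=by[perm], se_y=sy[perm],
            secondary={"hdl": (bh[perm], np.full(j, 0.01))},
        )
        assert multivariable_mr(p1, "chd").theta == pytest.approx(
            multivariable_mr(p2, "chd").theta, abs=1e-12
        )


class TestOddsRatio:
    @pytest.mark.parametrize("theta,expected", [(0.0, 1.0), (np.log(2), 2.0)])
    def test_exponentiation(self, theta, expected, toy_ivw_panel):
        est = ivw(toy_ivw_panel, "chd", "fixed")
        est.theta, est.ci_low, est.ci_high = theta, theta - 0.1, theta + 0.1
        or_, lo, hi = to_odds_ratio(est)
        assert or_ == pytest.approx(expected)
        assert lo < or_ < hi


@given(factor=st.floats(min_value=0.2, max_value=5.0))
@settings(max_examples=25, deadline=None)
def test_all_estimators_equivariant_under_exposure_rescaling(factor):
    """Scaling beta_x by f divides every causal estimate by f."""
    rng = np.random.default_rng(17)
    j = 12
    bx = rng.uniform(0.02, 0.1, j)
    by = 0.4 * bx + rng.normal(0, 0.02, j)
    sy = rng.uniform(0.01, 0.03, j)
    panel = make_panel(bx, beta_y=by, se_y=sy, secondary={"hdl": (rng.normal(0, 0.02, j), np.full(j, 0.01))})
    scaled = scale_effects(panel, factor)
    for fn in (
        lambda p: ivw(p, "chd", "random_multiplicative").theta,
        lambda p: mr_egger(p, "chd").theta,
        lambda p: weighted_median(p, "chd", n_boot=10, seed=0).theta,
        lambda p: multivariable_mr(p, "chd").theta,
    ):
        assert fn(scaled) == pytest.approx(fn(panel) / factor, rel=1e-9)


def test_unbiasedness_and_coverage_without_pleiotropy():
    """Under valid instruments each estimator's mean error is within 3 MCSE
    and the random-effects IVW 95% CI covers truth 93-97% of the time."""
    theta = 0.4
    n_reps = 1000
    ivw_t = np.empty(n_reps)
    egger_t = np.empty(n_reps)
    wm_t = np.empty(n_reps)
    covered = 0
    for rep in range(n_reps):
        cfg = scenario_suite("causal", seed=30_000 + rep)
        panel, _, _ = simulate_panel(cfg)
        est = ivw(panel, "outcome", "random_multiplicative")
        ivw_t[rep] = est.theta
        egger_t[rep] = mr_egger(panel, "outcome").theta
        wm_t[rep] = weighted_median(panel, "outcome", n_boot=8, seed=rep).theta
        covered += est.ci_low <= theta <= est.ci_high
    for vals in (ivw_t, egger_t, wm_t):
        mcse = vals.std(ddof=1) / np.sqrt(n_reps)
        assert abs(vals.mean() - theta) < 3 * mcse
    assert 0.93 <= covered / n_reps <= 0.97


def test_egger_intercept_recovers_directional_pleiotropy_mean():
    """InSIDE-satisfying directional pleiotropy with mean 0.01 is recovered
    by the Egger intercept within Monte-Carlo error."""
    n_reps = 400
    intercepts = np.empty(n_reps)
    for rep in range(n_reps):
        panel, _, _ = simulate_panel(scenario_suite("directional", seed=40_000 + rep))
        intercepts[rep] = mr_egger(panel, "outcome").intercept
    mcse = intercepts.std(ddof=1) / np.sqrt(n_reps)
    assert abs(intercepts.mean() - 0.01) < 3 * mcse


def test_egger_slope_biased_upward_when_inside_violated():
    """Pleiotropy positively correlated with instrument strength drags the
    Egger slope above the generating causal effect."""
    n_reps = 300
    slopes = np.empty(n_reps)
    for rep in range(n_reps):
        panel, _, truth = simulate_panel(
            scenario_suite("inside_violated", seed=50_000 + rep)
        )
        slopes[rep] = mr_egger(panel, "outcome").theta
    mcse = slopes.std(ddof=1) / np.sqrt(n_reps)
    assert slopes.mean() - 0.4 > 3 * mcse
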