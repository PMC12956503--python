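"""Recommendation stage: adjusted limits, mixture density, and the sampler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.special import expit

from nutrirec.diet_inference import (
    InfeasibleConstraint,
    RecommendationConfig,
    RecommendationProblem,
    adjusted_limits,
    compute_adjusted_limits,
    confidence_check,
    constraint_logdensity,
    intake_prior_logdensity,
    limit_score,
    max_preference_error,
    mixture_weight,
    personal_lambda,
    predict_expected,
    preference_error,
    preference_logdensity,
    safe_lambda,
    sample_recommendation,
)
from nutrirec.personal_models import PersonalModel, baseline_and_contributions
from nutrirec.study_data import NutrientSpec
from nutrirec.synthetic_cohort import PersonalModelConfig, simulate_personal_model


def canonical_pm():
    """Deterministic feasible instance: moderate, well-conditioned effects,
    current diet mid-box and mapped to the middle of the adjusted limits."""
    specs = [NutrientSpec(f"nutrient_{i + 1}", 10.0, 30.0, 20.0, "g/d")
             for i in range(3)]
    effects = np.array([[1.2, -0.8, 0.6],
                        [-0.5, 1.0, 1.4]])
    pm = PersonalModel(
        subject_id="demo", concentrations=["conc_1", "conc_2"],
        nutrients=[s.name for s in specs],
        alpha=np.full(2, 200.0), baseline=np.zeros(2), effects=effects,
        current_intake=np.array([18.0, 22.0, 21.0]),
        intake_mean=np.full(3, 20.0), intake_sd=np.full(3, 5.0),
        units=["g/d"] * 3,
    )
    targets = {"conc_1": (8.0, 12.0), "conc_2": (8.0, 12.0)}
    lims = compute_adjusted_limits(pm, targets, 0.9)
    pm.baseline = (lims.mu_lower + lims.mu_upper) / 2 - pm.effects @ pm.current_z()
    return pm, specs, targets, lims


class TestAdjustedLimits:
    def test_zero_noise_limit(self):
        ml, mu = adjusted_limits(1e6, 4.0, 6.0, 0.9)
        assert ml == pytest.approx(4.0, rel=0.01)
        assert mu == pytest.approx(6.0, rel=0.01)

    def test_scale_property_formula(self):
        alpha, c = 100.0, 0.9
        ml, mu = adjusted_limits(alpha, 4.0, 6.0, c)
        q05 = stats.gamma.ppf(0.05, a=alpha, scale=1 / alpha)
        q95 = stats.gamma.ppf(0.95, a=alpha, scale=1 / alpha)
        assert ml == pytest.approx(4.0 / q05, abs=1e-12)
        assert mu == pytest.approx(6.0 / q95, abs=1e-12)
        assert 4.0 < ml < mu < 6.0

    def test_tail_probabilities_at_limits(self, rng):
        ml, mu = adjusted_limits(100.0, 4.0, 6.0, 0.9)
        y = rng.gamma(100.0, ml / 100.0, size=200_000)
        assert np.mean(y < 4.0) == pytest.approx(0.05, abs=0.002)
        y = rng.gamma(100.0, mu / 100.0, size=200_000)
        assert np.mean(y > 6.0) == pytest.approx(0.05, abs=0.002)

    def test_narrow_range_infeasible(self):
        with pytest.raises(InfeasibleConstraint, match="glucose"):
            adjusted_limits(25.0, 4.0, 6.0, 0.9, name="glucose")

    def test_nonstrict_flags_instead_of_raising(self):
        pm, _, _, _ = canonical_pm()
        pm.alpha = np.array([25.0, 200.0])
        lims = compute_adjusted_limits(
            pm, {"conc_1": (4.0, 6.0), "conc_2": (8.0, 12.0)}, 0.9,
            strict=False)
        assert not lims.feasible[0] and lims.feasible[1]


class TestLimitScore:
    def test_half_at_lower_limit(self):
        s = limit_score(1.0, 1.0, 1e9, 8.0)
        assert s == pytest.approx(1.5, abs=1e-6)

    def test_saturates_at_two_deep_inside(self):
        assert round(float(limit_score(50.0, 0.0, 100.0, 8.0)), 6) == 2.0

    def test_direct_arithmetic_oracle(self):
        got = limit_score(0.9, 1.0, 2.0, 8.0)
        oracle = expit(8.0 * (0.9 - 1.0)) + expit(8.0 * (2.0 - 0.9))
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got == pytest.approx(expit(-0.8) + expit(8.8), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(1, 30))
    def test_bounded_in_open_interval(self, mu, lam1):
        b = float(limit_score(mu, -1.0, 1.0, lam1))
        assert 0.0 < b < 2.0


class TestConstraintDensity:
    def test_maximal_when_deep_inside(self):
        pm, _, _, lims = canonical_pm()
        mid = (lims.mu_lower + lims.mu_upper) / 2
        lp_in = constraint_logdensity(mid, lims, 8.0, 15.0)
        lp_out = constraint_logdensity(lims.mu_lower - 1.0, lims, 8.0, 15.0)
        assert lp_in > lp_out
        # at the midpoint the limit scores are not exactly saturated (the
        # logistic deficits are ~1e-3), so compare with a loose tolerance
        assert lp_in == pytest.approx(
            stats.norm.logpdf(0.0, scale=1 / 15.0), abs=0.01)

    def test_one_violated_limit_costs_half_lambda2_squared(self):
        pm, _, _, lims = canonical_pm()
        mid = (lims.mu_lower + lims.mu_upper) / 2
        lp_max = constraint_logdensity(mid, lims, 8.0, 15.0)
        # push conc_1 far below: its score loses the lower-limit half (b ~ 1)
        mu = mid.copy()
        mu[0] = lims.mu_lower[0] - 5.0
        lp_bad = constraint_logdensity(mu, lims, 8.0, 15.0)
        assert lp_max - lp_bad == pytest.approx(0.5 * 15.0**2, rel=0.01)

    def test_empty_errors(self):
        pm, _, _, lims = canonical_pm()
        with pytest.raises(ValueError):
            constraint_logdensity(np.array([]), lims, 8.0, 15.0)


class TestMixtureWeight:
    def test_all_limits_satisfied(self):
        assert mixture_weight(4.0, 2, 30.0) == pytest.approx(expit(3.0))
        assert mixture_weight(4.0, 2, 30.0) == pytest.approx(0.952574, abs=1e-6)

    def test_saturation_when_violated(self):
        assert mixture_weight(0.0, 3, 30.0) < 1e-70

    def test_exactly_half_at_offset(self):
        assert mixture_weight(2 * 2 - 0.1, 2, 30.0) == pytest.approx(0.5)


class TestPreference:
    def test_zero_at_current_diet(self):
        u = preference_error([10.0, 20.0], [10.0, 20.0],
                             np.array([[0.5, -1.0]]), 2.0)
        assert u == 0.0

    def test_hand_arithmetic_oracle(self):
        # M=1, R=2: (|10-12|/12 * 1/(1+0.5*2) + |20-18|/18 * 1/(1+1*2)) / 2
        u = preference_error([10.0, 20.0], [12.0, 18.0],
                             np.array([[0.5, -1.0]]), 2.0)
        oracle = ((2 / 12) * (1 / 2) + (2 / 18) * (1 / 3)) / 2
        assert u == pytest.approx(oracle, abs=1e-12)
        assert u == pytest.approx(0.060185, abs=1e-6)

    def test_strong_effects_are_free_to_move(self):
        u = preference_error([10.0], [20.0], np.array([[1e9]]), 2.0)
        assert u < 1e-8

    def test_max_error_matches_endpoint_brute_force(self, rng):
        for _ in range(20):
            R = rng.integers(2, 5)
            lo = rng.uniform(1, 10, R)
            hi = lo + rng.uniform(5, 30, R)
            specs = [NutrientSpec(f"n{r}", lo[r], hi[r]) for r in range(R)]
            x = rng.uniform(lo, hi)
            th = rng.normal(size=(2, R))
            e = max_preference_error(x, specs, th, 2.0)
            floors = 1e-3 * (hi - lo)
            best = max(
                preference_error(x, q, th, 2.0, floors=floors)
                for q in ([np.where(m, lo, hi) for m in
                           (np.arange(2**R)[:, None] >> np.arange(R)) % 2 == 1])
            )
            assert e == pytest.approx(best, rel=1e-10)

    def test_max_error_bounds_error_on_the_box(self, rng):
        pm, specs, _, _ = canonical_pm()
        e = max_preference_error(pm.current_intake, specs, pm.effects, 2.0)
        lo = np.array([s.lower for s in specs])
        hi = np.array([s.upper for s in specs])
        floors = 1e-3 * (hi - lo)
        for _ in range(200):
            q = rng.uniform(lo, hi)
            assert preference_error(pm.current_intake, q, pm.effects, 2.0,
                                    floors=floors) <= e + 1e-12


class TestSafeLambda:
    @pytest.mark.parametrize("e", [0.2, 0.5, 1.0, 2.0, 5.0])
    @pytest.mark.parametrize("eps", [1e-12, 1e-8, 1e-4])
    def test_defining_identity(self, e, eps):
        lam = safe_lambda(e, eps)
        assert lam * np.exp(-lam * e) == pytest.approx(eps, abs=1e-10)

    def test_larger_root_matches_bisection_oracle(self):
        # lam * exp(-lam) = 1e-8 has its larger root near 21.5
        lam = safe_lambda(1.0, 1e-8)
        lo_b, hi_b = 1.0, 100.0
        for _ in range(200):
            mid = (lo_b + hi_b) / 2
            if mid * np.exp(-mid) > 1e-8:
                lo_b = mid
            else:
                hi_b = mid
        assert lam == pytest.approx((lo_b + hi_b) / 2, abs=1e-8)
        assert 21.0 < lam < 22.0

    def test_tangency_case(self):
        e = 2.0
        eps = 1.0 / (np.e * e)  # e * eps = 1/e exactly
        lam = safe_lambda(e, eps)
        assert lam == pytest.approx(1.0 / e, rel=1e-6)

    def test_no_real_solution_errors(self):
        with pytest.raises(ValueError, match="no real solution"):
            safe_lambda(1.0, 1.0)

    def test_personal_lambda_scaling(self):
        lam_safe = safe_lambda(0.5, 1e-8)
        assert personal_lambda(lam_safe, 0.0, 0.5) == lam_safe
        inc1 = personal_lambda(lam_safe, 30.0, 0.5) - lam_safe
        inc2 = personal_lambda(lam_safe, 60.0, 0.5) - lam_safe
        assert inc2 == pytest.approx(2 * inc1)
        assert inc1 == pytest.approx(60.0)

    def test_preference_density_floor_by_construction(self):
        e, eps = 0.8, 1e-8
        lam_safe = safe_lambda(e, eps)
        assert preference_logdensity(e, lam_safe) == pytest.approx(
            np.log(eps), abs=1e-8)
        assert preference_logdensity(0.0, lam_safe) == pytest.approx(
            np.log(lam_safe))
        u = np.linspace(0, e, 50)
        dens = [preference_logdensity(v, lam_safe) for v in u]
        assert np.all(np.diff(dens) < 0)


class TestIntakePrior:
    SPEC = NutrientSpec("fiber", 20.0, 55.0, 30.0, "g/d")

    def test_outside_support(self):
        assert intake_prior_logdensity(19.9, self.SPEC, 10.0) == -np.inf
        assert intake_prior_logdensity(55.1, self.SPEC, 10.0) == -np.inf

    def test_integrates_to_one(self):
        val, err = quad(
            lambda q: np.exp(intake_prior_logdensity(q, self.SPEC, 10.0)),
            20.0, 55.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_flat_limit(self):
        lp = intake_prior_logdensity(33.3, self.SPEC, 0.0)
        assert lp == pytest.approx(-np.log(35.0))

    def test_missing_recommended_point_errors(self):
        spec = NutrientSpec("epa", 0.0, 2.5)
        with pytest.raises(ValueError, match="recommended"):
            intake_prior_logdensity(1.0, spec, 10.0)


class TestPredictExpected:
    def test_current_diet_reproduces_personal_prediction(self):
        pm, _, _, lims = canonical_pm()
        mu = predict_expected(pm, pm.current_intake)
        assert np.allclose(mu, (lims.mu_lower + lims.mu_upper) / 2, atol=1e-10)
        dec = baseline_and_contributions(pm, pm.current_intake)
        assert np.allclose(mu, dec.total, atol=1e-12)

    def test_zero_effects_gives_baseline(self, rng):
        pm, _, _, _ = canonical_pm()
        pm.effects = np.zeros_like(pm.effects)
        for _ in range(5):
            q = rng.uniform(10, 30, size=3)
            assert np.allclose(predict_expected(pm, q), pm.baseline)

    def test_dot_product_oracle(self, rng):
        pm, _, _, _ = canonical_pm()
        q = rng.uniform(10, 30, size=3)
        z = (q - pm.intake_mean) / pm.intake_sd
        oracle = [pm.baseline[m] + sum(pm.effects[m, r] * z[r] for r in range(3))
                  for m in range(2)]
        assert np.allclose(predict_expected(pm, q), oracle, atol=1e-12)


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self, rng):
        pm, specs, _, lims = canonical_pm()
        cfg = RecommendationConfig(seed=1)
        prob = RecommendationProblem(pm, specs, lims, cfg)
        for _ in range(25):
            q = rng.uniform(prob.lo + 0.02 * prob.width,
                            prob.hi - 0.02 * prob.width)
            _, g = prob.logpost_grad(q)
            h = 1e-6 * prob.width
            for i in range(len(q)):
                qp, qm = q.copy(), q.copy()
                qp[i] += h[i]
                qm[i] -= h[i]
                fd = (prob.logpost_grad(qp)[0] - prob.logpost_grad(qm)[0]) / (2 * h[i])
                assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_preference_orders_equal_constraint_diets(self):
        # two diets with identical expected concentrations (same constraint
        # score): the stationary density prefers the one closer to the
        # current diet
        pm, specs, _, lims = canonical_pm()
        cfg = RecommendationConfig(lam6=0.0, seed=1)
        prob = RecommendationProblem(pm, specs, lims, cfg)
        null = np.linalg.svd(pm.effects / pm.intake_sd)[2][-1]  # R=3, M=2
        q1 = pm.current_intake.copy()
        q2 = q1 + 2.0 * null
        assert np.allclose(predict_expected(pm, q1), predict_expected(pm, q2),
                           atol=1e-8)
        assert prob.logpost(q1) > prob.logpost(q2)

    def test_weight_saturation_regimes(self):
        pm, specs, _, lims = canonical_pm()
        cfg = RecommendationConfig(seed=1)
        M = pm.M
        mid = (lims.mu_lower + lims.mu_upper) / 2
        b_in = float(limit_score(mid, lims.mu_lower, lims.mu_upper,
                                 cfg.lam1).sum())
        assert mixture_weight(b_in, M, cfg.lam4) > 0.9
        b_out = float(limit_score(lims.mu_lower - 3, lims.mu_lower,
                                  lims.mu_upper, cfg.lam1).sum())
        assert mixture_weight(b_out, M, cfg.lam4) < 1e-10


class TestSampler:
    def test_draws_stay_in_guideline_box(self):
        pm, info = simulate_personal_model(PersonalModelConfig(), seed=3)
        cfg = RecommendationConfig(seed=4, chains=1, draws=400, warmup=300)
        res = sample_recommendation(pm, info["specs"], info["targets"], cfg)
        lo = np.array([s.lower for s in info["specs"]])
        hi = np.array([s.upper for s in info["specs"]])
        assert np.all(res.intake_draws >= lo - 1e-9)
        assert np.all(res.intake_draws <= hi + 1e-9)

    def test_feasible_model_reaches_adjusted_limits(self):
        pm, info = simulate_personal_model(PersonalModelConfig(), seed=23)
        cfg = RecommendationConfig(seed=5, chains=1, draws=500, warmup=400)
        res = sample_recommendation(pm, info["specs"], info["targets"], cfg)
        assert res.feasible
        assert res.concentration_report["within_adjusted"].all()
        # confidence semantics at the returned diet
        for _, row in res.concentration_report.iterrows():
            assert row.prob_in_clinical_range >= cfg.confidence - 0.02

    def test_lambda6_zero_reproduces_current_diet(self):
        pm, specs, targets, _ = canonical_pm()
        cfg = RecommendationConfig(lam6=0.0, seed=2, chains=2, draws=800,
                                   warmup=500)
        res = sample_recommendation(pm, specs, targets, cfg)
        rel = np.abs(res.recommended - pm.current_intake) / pm.current_intake
        assert np.all(rel < 0.05)

    def test_violated_limit_moves_intake_in_restoring_direction(self):
        # one dominant positive effect; baseline below the lower limit, so the
        # recommendation must raise that nutrient's intake
        specs = [NutrientSpec("n1", 10.0, 30.0, 20.0)]
        pm = PersonalModel(
            subject_id="d", concentrations=["c1"], nutrients=["n1"],
            alpha=np.array([200.0]), baseline=np.array([9.0]),
            effects=np.array([[2.0]]), current_intake=np.array([15.0]),
            intake_mean=np.array([20.0]), intake_sd=np.array([5.0]),
        )
        targets = {"c1": (10.0, 14.0)}
        # current diet: mu = 9 + 2*(-1) = 7, below the range
        cfg = RecommendationConfig(seed=7, chains=1, draws=500, warmup=400)
        res = sample_recommendation(pm, specs, targets, cfg)
        assert res.recommended[0] > pm.current_intake[0]
        mu = predict_expected(pm, res.recommended)
        assert res.limits.mu_lower[0] <= mu[0] <= res.limits.mu_upper[0]

    def test_infeasible_model_flagged_and_near_grid_optimum(self):
        pm, info = simulate_personal_model(
            PersonalModelConfig(n_nutrients=2, feasible=False), seed=9)
        cfg = RecommendationConfig(seed=11, chains=2, draws=600, warmup=400)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            res = sample_recommendation(pm, info["specs"], info["targets"], cfg)
        assert not res.feasible
        assert res.infeasible_concentrations
        lims = res.limits

        def deficit(q):
            b = limit_score(predict_expected(pm, q), lims.mu_lower,
                            lims.mu_upper, cfg.lam1)
            return 2 * pm.M - float(b.sum())

        lo = np.array([s.lower for s in info["specs"]])
        hi = np.array([s.upper for s in info["specs"]])
        g = np.linspace(0, 1, 50)
        grid = np.stack(np.meshgrid(lo[0] + g * (hi[0] - lo[0]),
                                    lo[1] + g * (hi[1] - lo[1])), -1).reshape(-1, 2)
        best = min(deficit(q) for q in grid)
        assert deficit(res.recommended) <= best * 1.05 + 1e-3

    def test_same_seed_reproduces_summaries(self):
        pm, info = simulate_personal_model(PersonalModelConfig(), seed=31)
        cfg = RecommendationConfig(seed=8, chains=1, draws=200, warmup=200)
        r1 = sample_recommendation(pm, info["specs"], info["targets"], cfg)
        r2 = sample_recommendation(pm, info["specs"], info["targets"], cfg)
        assert np.array_equal(r1.intake_draws, r2.intake_draws)
        assert r1.summary.equals(r2.summary)

    def test_rw_fallback_agrees_with_hmc(self):
        pm, info = simulate_personal_model(PersonalModelConfig(), seed=13)
        hmc = sample_recommendation(
            pm, info["specs"], info["targets"],
            RecommendationConfig(seed=1, chains=1, draws=600, warmup=400))
        rw = sample_recommendation(
            pm, info["specs"], info["targets"],
            RecommendationConfig(seed=2, chains=1, draws=3000, warmup=2000,
                                 sampler="rw"))
        # same stationary distribution: posterior means agree loosely
        sd = hmc.intake_draws.std(axis=0)
        assert np.all(np.abs(hmc.recommended - rw.recommended) < 0.5 * sd + 0.5)


class TestConfidenceCheck:
    def test_monte_carlo_matches_gamma_cdf(self):
        p = confidence_check(150.0, 5.0, 4.0, 6.0, n=400_000, seed=1)
        oracle = (stats.gamma.cdf(6.0, a=150.0, scale=5.0 / 150.0)
                  - stats.gamma.cdf(4.0, a=150.0, scale=5.0 / 150.0))
        assert p == pytest.approx(oracle, abs=0.005)
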