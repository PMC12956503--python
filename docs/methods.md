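# Methods

This note documents the statistical models implemented in `nutrirec`, the
choices that were genuinely open, the numerical decisions, and what the
synthetic-data experiments do and do not establish.

## Observation model

Plasma concentrations are strictly positive and right-skewed; we model
observation `i` of concentration `m` for subject `k` as

    Y_kmi ~ Gamma(shape = alpha_m, rate = alpha_m / mu_kmi),

so `E[Y] = mu` and `Var[Y] = mu^2 / alpha_m`: `alpha_m` is a per-concentration
noise parameter (roughly, `1/sqrt(alpha)` is the coefficient of variation).
The mean follows an additive identity-link predictor with population fixed
effects, plus subject-specific deviations for the intercept and every varying
(nutrient) predictor.  The identity link preserves additivity — each
nutrient's contribution is expressed directly in concentration units — at the
cost of an unconstrained mean: proposals with `mu <= 0` receive a log
density of `-inf` (a rejection signal, not an error), and intercepts are
initialized at observed concentration means so sampling starts in the valid
region.

Cross-concentration dependence enters through the subject effects: the
stacked vector `b_k` (dimension `M*(J+1)` for `M` concentrations and `J`
varying predictors) is drawn from one multivariate normal with covariance
`Sigma = T C T`, a diagonal matrix of scales times a full correlation matrix.
This is a seemingly-unrelated-regressions structure — equations are tied by
correlated random effects rather than correlated residuals — and it lets the
data reveal, e.g., that subjects whose insulin responds strongly to a
nutrient also tend to show a particular glucose response.  An optional nested
group-level block (`g_g ~ N(0, Sigma_g)` on the same predictors, its own
`T_g`, `C_g`) represents treatment-modality hierarchies; it is off by
default.

All predictors are standardized before estimation (sample mean/sd, ddof=1);
binary covariates are passed through unchanged by default because z-scored
indicators lose their interpretation (a switch restores literal z-scoring).
Concentrations are never standardized: the Gamma likelihood and the clinical
target ranges live in natural units.  Visits are exchangeable repeated
measures — the predictor has no time term.

### Priors

The defaults are weakly informative on the standardized scale and are all
configurable (`PriorConfig`): `N(0, 2.5)` on fixed effects, `N(mean(Y_m),
2*sd(Y_m))` on intercepts, half-`N(0, 1)` on random-effect scales,
`Exponential(0.1)` on the Gamma shapes, and LKJ(2) on the correlation matrix.
The LKJ prior is implemented through the canonical-partial-correlation
(C-vine) representation: the CPC at vine tree level `k` of a `d`-dimensional
correlation matrix follows a scaled `Beta(eta + (d-1-k)/2, ·)` on (-1, 1),
independently across CPCs.  This gives exact prior evaluation and sampling
with no matrix Jacobian; the equivalence is checked in the test suite against
the known LKJ marginal variance `Var(C_ij) = 1/(2(eta - 1 + d/2) + 1)`.

### Posterior sampling

The package ships its own blocked adaptive Metropolis-within-Gibbs sampler:

* coordinate-wise random-walk updates of fixed effects with single-column
  incremental likelihoods, plus an adaptive-Metropolis joint move whose
  proposal covariance is the running empirical covariance of the fixed-effect
  draws (correlated pairs such as intercept-vs-binary-covariate mix poorly
  under coordinate moves alone);
* parallel per-subject updates of `b_k`, preconditioned by the current
  Cholesky factor of `Sigma` (subjects are conditionally independent, so all
  K proposals are evaluated vectorized and accepted independently); three
  sweeps per iteration, since every other block conditions on `b`;
* likelihood-invariant *translation* moves that shift one population
  coefficient and subtract the same amount from every subject's deviation,
  decoupling the two levels;
* centered (prior-only) coordinate updates of the scales and CPCs with
  row-local Cholesky updates, and *non-centered* (interweaved) counterparts
  that hold the whitened subject effects fixed while rescaling — the standard
  remedy for the funnel geometry when per-subject data are weak.  A
  non-centered scale move changes exactly one column of the subject-effect
  matrix, so it costs one single-column likelihood evaluation.

All proposal scales adapt by Robbins-Monro during warmup only and freeze
afterwards, keeping the retained chain Markovian (the adaptive-Metropolis
covariance keeps updating, which is valid under diminishing adaptation).
Chains are seeded through `numpy.random.SeedSequence`; a seed is mandatory.

Convergence is reported with rank-normalized split R-hat and bulk/tail ESS
(computed by `arviz`), flagged at the usual thresholds (R-hat < 1.01 good,
> 1.05 failure; ESS target 400 per chain).  R-hat above 1.05 produces a
warning naming the parameters, not an error.  Divergence counts and E-BFMI
are included in the report shape for familiarity but are trivially 0 / None:
the estimation sampler is not Hamiltonian.  At the small test settings
(2 chains, ~800 draws) the fixed effects and shapes typically reach R-hat
≤ 1.05 while the correlation parameters can sit near 1.1–1.2; production
analyses should run 4 chains and several thousand draws.

Fit quality is scored by NRMSE (RMSE divided by the mean observed value) and
posterior predictive p-values: replicate datasets are drawn from the Gamma
model at randomly chosen posterior draws, and `p` is the fraction of
replicates whose statistic (mean, sd per concentration) exceeds the observed
one — near 0.5 indicates calibration.

## Personal models

For recommendation, one subject's information is collapsed to a *personal
model*: combined coefficients `theta_kmj = beta_mj + b_kmj` (plus any group
effect), point-summarized by the posterior mean (median optional; for the
mean the summary distributes exactly over the sum), the Gamma shapes, the
subject's current diet, and the baseline — intercept, fixed covariates, and
unmodified nutrients evaluated at the most recent record ("current diet" =
latest record; a config alternative uses the per-subject mean).  Coefficient
uncertainty is deliberately not propagated into the recommendation stage:
predictive uncertainty enters through the shapes `alpha_m`, which is what the
adjusted-limit construction consumes.  Personal models serialize to GraphML
(nutrient and concentration nodes, directed effect edges carrying the
coefficient; the attribute vocabulary is fixed in
`nutrirec/personal_models.py`), so sensitivity analyses and counterfactual
queries run without the cohort data.

The prediction decomposes exactly as `baseline + sum_r z(Q_r) * theta_mr`;
the reporting stage emits this as waterfall data ordered by mean absolute
contribution, and the conservation identity is enforced to 1e-10 in tests.

## Recommendation posterior

Writing `b(mu) = logistic(lam1 (mu - mu_l)) + logistic(lam1 (mu_u - mu))` for
the two-sided smooth limit score (each term is 0.5 exactly at its limit; the
supremum is 2), the unnormalized posterior over the modifiable intakes `Q`
is

    p(Q) ∝ p_Q(Q) * [ (1 - w) * N(sum_m b_m | 2M, 1/lam2) + w * lam_k e^{-lam_k u(Q)} ],
    w = logistic(lam4 * (sum_m b_m - (2M - 0.1))),

with the guideline prior `p_Q` per nutrient an equal mixture of
`Uniform(Q_l, Q_u)` and a normal at the recommended point with sd
`(Q_u - Q_l)/lam6`, truncated to the range.  The preference error

    u(Q) = (1/M) sum_m (1/R) sum_r |X_r - Q_r| / max(Q_r, floor_r) * 1/(1 + |theta_mr| lam5)

is the effect-weighted mean relative deviation from the current diet `X`:
nutrients with strong effects are cheap to move, weak-effect nutrients are
held close.  It is computed on the natural intake scale (relative differences
are meaningless on z-scores) with denominators floored at `1e-3` of the range
width.  The exponential rate is personalized: the worst-case error `e` over
the intake box is evaluated at the per-nutrient range endpoints (the ratio is
monotone on either side of the current intake, so the endpoint maximum is the
box maximum), and the largest rate that keeps the density above a numerical
floor `eps` solves `lam e^{-lam e} = eps` — the W_{-1} Lambert branch,
`lam_safe = -W_{-1}(-e*eps)/e`.  Note the *larger* of the two real roots is
the binding one; at the branch point the roots coincide at `1/e`, which the
implementation returns exactly.  A configurable bonus `lam3/e` is added on
the same scale.

Default hyperparameters: `lam1 = 8`, `lam2 = 15` (acting as the precision of
the constraint normal — a larger value enforces stricter adherence; a config
switch restores the literal-sd convention), `lam3 = 30`, `lam4 = 30`,
`lam5 = 2.0`, `lam6 = 10`, `c = 0.9`, `eps = 1e-8`.

### Adjusted limits

Clinical ranges constrain raw concentrations, not expected values.  Because
`Y/mu` is a pivot for the Gamma family (`Y/mu ~ Gamma(alpha, alpha)`),
requiring `P(Y < Y_l) = (1-c)/2` at the lower limit gives
`mu_l = Y_l / q_{(1-c)/2}(Gamma(alpha, alpha))` and symmetrically above.  Any
expected value inside `[mu_l, mu_u]` therefore keeps the raw concentration in
its clinical range with probability at least `c`.  When the range is too
narrow for the noise level the adjusted limits cross; the strict API raises
`InfeasibleConstraint`, while the sampler proceeds on the (still proper)
smooth density and flags the result as closest-achievable.  The same flag
covers targets that are arithmetically feasible but unreachable from within
the guideline intake box.

### Sampling and multimodality

The log posterior is smooth inside the box and its gradient is implemented
analytically (verified against central finite differences to 1e-5); the
sampler is an HMC on the logit-reparameterized open box with dual-averaged
step size and jittered path lengths (an adaptive random-walk fallback is
available).  The mixture can be genuinely multimodal: the preference
component spikes at the current diet even when that diet violates the limits
(its gate weight `w` is tiny but the constraint density is tinier), while the
constraint component peaks wherever the limits are met, and the two modes can
be separated by tens of nats.  Chains are therefore initialized at the best
point of a coarse seeded scan of the box (≥256 quasi-random points plus the
current diet and the box center), which reliably lands them in the dominant
mode; split R-hat across chains is reported and warned on.

### A property of the published defaults worth knowing

The gate never fully closes: at full limit satisfaction
`w = logistic(0.1 * lam4) ≈ 0.95`, so the constraint component keeps ~5%
weight and forms a plateau across the feasible region.  When the guideline
pull is off (`lam6 = 0`) and the current diet already satisfies the limits,
the posterior mean reproduces the current diet *provided* the preference peak
carries much more mass than that plateau — which holds when nutrient effects
are moderately strong and well-conditioned (so the feasible set is a thin
slab) and the current diet is not pressed against a box edge.  With weak or
nearly collinear effects the plateau can pull individual posterior-mean
intakes several percent away from the current diet.  This is a property of
the mixture with these defaults, not a sampler artifact; raising `lam4`
sharpens the gate if exact reproduction is wanted.

## Synthetic data

The cohort generator is the exact generative mirror of the estimation model:
standard-normal nutrient intakes (Bernoulli(0.5) binaries for fixed
covariates), LKJ-correlated subject effects, Gamma observations, with a
positivity margin on every generated expected value (violating effect draws
are regenerated, with an error after bounded retries).  Effect magnitudes
scale with the concentration intercepts so one relative setting serves all
outcome units.  Two presets emulate the structure of the target studies — a
prediabetes-style cohort (106 subjects × 4 visits, 5 concentrations, 15
nutrients, natural-unit intake distributions) and a dialysis-style cohort
(37 × 2, 3 concentrations, 13 nutrients, nested treatment groups).  Preset
Gamma shapes are chosen to mimic the *ranking* of predictive error across
outcomes (glucose-like tight, phosphate-like loose), not any particular
reported value.

The personal-model generator constructs recommendation-stage instances with
feasibility known by construction: a recorded diet mapping to the midpoint of
every adjusted limit pair (feasible preset) or a baseline shifted so the
best diet in the box still falls short on one concentration (infeasible
preset).  Its default effect scale (unit normal) reflects the magnitude range
of subject-level nutrient effects reported for such cohorts (roughly 0.3–8 on
the standardized scale).

What the synthetic experiments show: the samplers target the correct
posteriors (parameter recovery with calibrated interval coverage; posterior
predictive calibration on self-simulated data) and the recommendation stage
honors its constraint/preference semantics.  What they do not show: that the
linear-additive, visit-exchangeable model is adequate for real food-record
data — real diets have correlated intakes (an optional correlated-intake mode
exists for stress tests), measurement error, and non-linear physiology that
the generator deliberately omits.

## Problem sizes used in the test suite

The replicated recovery study runs 12 fits at K=30 subjects × 4 visits,
M=2 concentrations, R=3 nutrients, 2 chains × (600 warmup + 500 draws),
pooling 120 coverage indicators for the fixed effects; the aggregate 90%
interval coverage is required to land in [80%, 98%] and at least 98% of
coefficients within 3 posterior sd of truth (at ~120 checks, a perfectly
calibrated sampler exceeds 3 sd somewhere about a quarter of the time, so the
literal all-coefficients form would reject a correct implementation).
Behavioral checks of the recommendation sampler use 20 seeded feasible
instances, a deterministic canonical instance for the current-diet
reproduction property, and R=2 infeasible instances compared against a 50×50
grid-search oracle.  These sizes keep the full suite around five minutes on
one CPU while leaving the statistical assertions well-powered.
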