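"""Personalized diet inference: the conditional constraint/preference mixture.

Given one subject's personal model (combined nutrient effects, Gamma shapes,
current diet), this module samples the posterior over modifiable intakes
``Q_r`` that keeps every expected plasma concentration inside *adjusted*
limits with confidence ``c`` while deviating minimally from the current diet.

The unnormalized posterior over ``Q`` factorizes as

    p(Q) ∝ p_Q(Q) * [ (1 - w(Q)) * p_c(Q) + w(Q) * p_u(Q) ]

* ``p_Q``: guideline prior per nutrient — an equal mixture of a Uniform over
  the healthy range and a Normal centered at the general recommendation with
  sd (range width) / lambda6, truncated to the range.
* ``p_c``: concentration-constraint component — a Normal on the summed smooth
  limit score ``sum_m b_m`` with mean ``2M`` (all limits satisfied) and sd
  ``1 / lambda2``; each ``b_m`` is a pair of inverse-logit transitions of
  steepness ``lambda1`` at the adjusted limits.
* ``p_u``: preference component — Exponential(lambda_k) in the preference
  error ``u(Q)``, the effect-weighted mean relative deviation from the
  current diet; ``lambda_k`` is the largest rate keeping the density above a
  numerical floor ``eps`` at the worst-case error (a Lambert-W root), plus a
  configurable bonus ``lambda3 / e``.
* ``w``: smooth gate (steepness ``lambda4``) that hands the posterior over to
  the preference component once all limits are satisfied.

Clinical ranges constrain raw concentrations, which are Gamma-distributed
around their expected values; the adjusted limits tighten the clinical range
via standardized Gamma quantiles so that an expected value inside
``[mu_ml, mu_mu]`` guarantees the raw concentration stays inside
``[Y_ml, Y_mu]`` with probability >= c.

Everything is smooth inside the intake box, and the log posterior has a
hand-derived analytic gradient, so sampling uses Hamiltonian Monte Carlo on a
logit reparameterization of the box (a seeded random-walk fallback is
available via ``sampler="rw"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, lambertw, ndtr

from ._mcmc import StepSizeAdapter
from .personal_models import PersonalModel
from .study_data import ConcentrationSpec, NutrientSpec

__all__ = [
    "RecommendationConfig",
    "AdjustedLimits",
    "PreferenceState",
    "RecommendationResult",
    "InfeasibleConstraint",
    "adjusted_limits",
    "compute_adjusted_limits",
    "limit_score",
    "constraint_logdensity",
    "mixture_weight",
    "preference_error",
    "max_preference_error",
    "safe_lambda",
    "personal_lambda",
    "preference_logdensity",
    "intake_prior_logdensity",
    "predict_expected",
    "RecommendationProblem",
    "recommendation_logposterior",
    "sample_recommendation",
    "confidence_check",
]


class InfeasibleConstraint(Exception):
    """A concentration's clinical range is too narrow for its noise level."""

    def __init__(self, name: str, mu_lower: float, mu_upper: float):
        self.name = name
        self.mu_lower = mu_lower
        self.mu_upper = mu_upper
        super().__init__(
            f"adjusted limits for {name!r} are crossed "
            f"(mu_lower={mu_lower:.4g} >= mu_upper={mu_upper:.4g}); the target "
            "range is too narrow for the estimated concentration noise"
        )


@dataclass(frozen=True)
class RecommendationConfig:
    """Hyperparameters of the recommendation posterior and its sampler.

    Defaults follow the published configuration: lam1=8 (limit steepness),
    lam2=15 (limit strictness, acts as precision), lam3=30 (preference
    strength), lam4=30 (mixture-gate steepness), lam5=2.0 (preference-error
    penalization), lam6=10 (pull toward general recommendations), c=0.9.
    """

    lam1: float = 8.0
    lam2: float = 15.0
    lam3: float = 30.0
    lam4: float = 30.0
    lam5: float = 2.0
    lam6: float = 10.0
    confidence: float = 0.9
    eps: float = 1e-8
    chains: int = 2
    draws: int = 1000
    warmup: int = 500
    seed: int | None = None
    sampler: str = "hmc"           # "hmc" or "rw"
    lam2_is_precision: bool = True  # sd of the constraint Normal = 1/lam2

    def __post_init__(self):
        for nm in ["lam1", "lam2", "lam3", "lam4", "lam5", "lam6"]:
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if not 0 < self.eps < 1e-2:
            raise ValueError("eps must be a small positive likelihood floor")

    @property
    def constraint_sd(self) -> float:
        return 1.0 / self.lam2 if self.lam2_is_precision else self.lam2


@dataclass
class AdjustedLimits:
    """Expected-value limits per concentration implied by the clinical ranges."""

    names: list[str]
    y_lower: np.ndarray
    y_upper: np.ndarray
    mu_lower: np.ndarray
    mu_upper: np.ndarray
    q_lower: np.ndarray   # standardized Gamma quantiles used
    q_upper: np.ndarray
    feasible: np.ndarray  # bool per concentration

    @property
    def all_feasible(self) -> bool:
        return bool(np.all(self.feasible))


@dataclass(frozen=True)
class PreferenceState:
    """Worst-case preference error and the derived personal Exponential rates."""

    e: float
    lam_safe: float
    lam_k: float

    def __post_init__(self):
        if self.e <= 0:
            raise ValueError("maximum preference error must be positive")
        if not self.lam_k >= self.lam_safe > 0:
            raise ValueError("need lam_k >= lam_safe > 0")


# ---------------------------------------------------------------------------
# Adjusted limits (Gamma quantile scaling)
# ---------------------------------------------------------------------------

def adjusted_limits(alpha_m: float, y_lower: float, y_upper: float,
                    c: float, name: str = "") -> tuple[float, float]:
    """Tighten a clinical range into limits on the *expected* concentration.

    For Y ~ Gamma(shape a, rate a/mu), Y/mu is a pivot with a fixed Gamma(a, a)
    law; requiring P(Y < y_lower) = (1-c)/2 at mu = mu_lower therefore gives
    mu_lower = y_lower / q_{(1-c)/2} of Gamma(a, a), and symmetrically above.
    Raises :class:`InfeasibleConstraint` when the adjusted limits cross.
    """
    if alpha_m <= 0:
        raise ValueError("Gamma shape must be positive")
    if not y_lower < y_upper:
        raise ValueError("need y_lower < y_upper")
    if not 0 < c < 1:
        raise ValueError("confidence must be in (0, 1)")
    tail = (1.0 - c) / 2.0
    q_lo = stats.gamma.ppf(tail, a=alpha_m, scale=1.0 / alpha_m)
    q_hi = stats.gamma.ppf(1.0 - tail, a=alpha_m, scale=1.0 / alpha_m)
    mu_l = y_lower / q_lo
    mu_u = y_upper / q_hi
    if mu_l >= mu_u:
        raise InfeasibleConstraint(name or "concentration", mu_l, mu_u)
    return float(mu_l), float(mu_u)


def compute_adjusted_limits(
    pm: PersonalModel,
    targets: Mapping[str, tuple[float, float]] | Sequence[ConcentrationSpec],
    c: float,
    subject_attrs: Mapping | None = None,
    strict: bool = True,
) -> AdjustedLimits:
    """Adjusted limits for every concentration of a personal model.

    ``targets`` is either a name -> (lower, upper) mapping or a list of
    :class:`ConcentrationSpec` resolved with ``subject_attrs``.  With
    ``strict=False`` crossed limits are flagged instead of raised (the smooth
    limit scores remain well defined), enabling closest-achievable inference.
    """
    if not isinstance(targets, Mapping):
        targets = {s.name: s.resolve(subject_attrs) for s in targets}
    missing = [m for m in pm.concentrations if m not in targets]
    if missing:
        raise KeyError(f"no clinical target range for {missing}")
    yl, yu, ml, mu_, ql, qh, feas = [], [], [], [], [], [], []
    tail = (1.0 - c) / 2.0
    for mi, m in enumerate(pm.concentrations):
        lo, hi = targets[m]
        a = pm.alpha[mi]
        q_lo = stats.gamma.ppf(tail, a=a, scale=1.0 / a)
        q_hi = stats.gamma.ppf(1.0 - tail, a=a, scale=1.0 / a)
        m_l, m_u = lo / q_lo, hi / q_hi
        if m_l >= m_u and strict:
            raise InfeasibleConstraint(m, m_l, m_u)
        yl.append(lo), yu.append(hi), ml.append(m_l), mu_.append(m_u)
        ql.append(q_lo), qh.append(q_hi), feas.append(m_l < m_u)
    return AdjustedLimits(
        names=list(pm.concentrations),
        y_lower=np.array(yl), y_upper=np.array(yu),
        mu_lower=np.array(ml), mu_upper=np.array(mu_),
        q_lower=np.array(ql), q_upper=np.array(qh),
        feasible=np.array(feas),
    )


# ---------------------------------------------------------------------------
# Density components
# ---------------------------------------------------------------------------

def limit_score(mu_hat, mu_lower, mu_upper, lam1: float):
    """Two-sided smooth limit satisfaction in (0, 2); 2 means both satisfied.

    Each term is an inverse logit of steepness lam1, worth exactly 0.5 at its
    limit and ~1 deep inside it.
    """
    mu_hat = np.asarray(mu_hat, float)
    return expit(lam1 * (mu_hat - mu_lower)) + expit(lam1 * (mu_upper - mu_hat))


def constraint_logdensity(mu_hat, limits: AdjustedLimits, lam1: float,
                          lam2: float, lam2_is_precision: bool = True) -> float:
    """Log N(sum_m b_m | 2M, sd); maximal when every limit score saturates."""
    mu_hat = np.asarray(mu_hat, float)
    M = mu_hat.size
    if M < 1:
        raise ValueError("need at least one concentration (M >= 1)")
    b = limit_score(mu_hat, limits.mu_lower, limits.mu_upper, lam1)
    sd = 1.0 / lam2 if lam2_is_precision else lam2
    return float(stats.norm.logpdf(b.sum(), loc=2.0 * M, scale=sd))


def mixture_weight(b_total: float, M: int, lam4: float) -> float:
    """Smooth gate in (0,1): ~1 once all 2M limit half-scores are satisfied."""
    return float(expit(lam4 * (b_total - (2.0 * M - 0.1))))


def preference_error(current, proposed, effects, lam5: float,
                     floors=None) -> float:
    """Effect-weighted mean relative deviation of a proposed diet (u >= 0).

    u = (1/M) sum_m (1/R) sum_r |X_r - Q_r| / max(Q_r, floor_r)
        * 1 / (1 + |theta_mr| * lam5)

    Nutrients with strong effects (large |theta|) are cheap to move; u = 0
    iff the proposal equals the current diet.
    """
    x = np.asarray(current, float)
    q = np.asarray(proposed, float)
    th = np.atleast_2d(np.asarray(effects, float))
    w = np.mean(1.0 / (1.0 + np.abs(th) * lam5), axis=0)  # (R,)
    den = q if floors is None else np.maximum(q, np.asarray(floors, float))
    return float(np.mean(np.abs(x - q) / den * w))


def max_preference_error(current, specs: Sequence[NutrientSpec], effects,
                         lam5: float) -> float:
    """Worst-case preference error over the guideline intake box.

    The relative deviation |X - Q| / max(Q, floor) is monotone on either side
    of the current intake, so the per-nutrient maximum sits at a range
    endpoint; floors are 1e-3 of the range width (division guard).
    """
    x = np.asarray(current, float)
    th = np.atleast_2d(np.asarray(effects, float))
    lo = np.array([s.lower for s in specs], float)
    hi = np.array([s.upper for s in specs], float)
    floors = 1e-3 * (hi - lo)
    w = np.mean(1.0 / (1.0 + np.abs(th) * lam5), axis=0)
    r_lo = np.abs(x - lo) / np.maximum(lo, floors)
    r_hi = np.abs(x - hi) / np.maximum(hi, floors)
    return float(np.mean(np.maximum(r_lo, r_hi) * w))


def safe_lambda(e: float, eps: float) -> float:
    """Largest rate with lam * exp(-lam * e) = eps (real iff e*eps <= 1/e).

    Of the two roots of the defining identity the larger one is the "highest
    safe" rate; it is the W_{-1} Lambert branch, -W_{-1}(-e*eps) / e.
    """
    if e <= 0 or eps <= 0:
        raise ValueError("need e > 0 and eps > 0")
    arg = -e * eps
    branch_point = -np.exp(-1.0)
    if arg < branch_point * (1.0 + 1e-12):
        raise ValueError(
            f"no real solution: e*eps = {e * eps:.3g} exceeds 1/e; "
            "lower eps or the worst-case error"
        )
    lam = -np.real(lambertw(max(arg, branch_point), k=-1)) / e
    if not np.isfinite(lam):  # tangency: the two roots coincide at 1/e
        lam = 1.0 / e
    return float(lam)


def personal_lambda(lam_safe: float, lam3: float, e: float) -> float:
    """Add the configurable preference bonus on the natural 1/e scale."""
    if lam3 < 0:
        raise ValueError("lam3 must be >= 0")
    return float(lam_safe + lam3 / e)


def preference_logdensity(u: float, lam_k: float) -> float:
    """log Exponential(u | rate lam_k); maximal at u = 0."""
    if lam_k <= 0:
        raise ValueError("lam_k must be positive")
    return float(np.log(lam_k) - lam_k * u)


def intake_prior_logdensity(q: float, spec: NutrientSpec, lam6: float) -> float:
    """Guideline prior: ½ Uniform(range) + ½ Normal(recommended, width/lam6).

    The Normal is truncated to the range, so the mixture is a proper density
    with support exactly [lower, upper]; lam6 = 0 degenerates to the flat
    prior.  -inf outside the range.
    """
    lo, hi = spec.lower, spec.upper
    if q < lo or q > hi:
        return -np.inf
    width = hi - lo
    if lam6 == 0:
        return float(-np.log(width))
    if spec.recommended is None:
        raise ValueError(
            f"{spec.name}: lam6 > 0 needs a recommended point in the spec"
        )
    sigma = width / lam6
    a, b = (lo - spec.recommended) / sigma, (hi - spec.recommended) / sigma
    znorm = ndtr(b) - ndtr(a)
    dens = (0.5 / width
            + 0.5 * stats.norm.pdf((q - spec.recommended) / sigma) / sigma / znorm)
    return float(np.log(dens))


def predict_expected(pm: PersonalModel, intakes) -> np.ndarray:
    """Expected concentrations under a proposed natural-unit diet."""
    q = np.asarray(intakes, float).reshape(pm.R)
    return pm.baseline + pm.effects @ pm.z(q)


# ---------------------------------------------------------------------------
# The joint posterior
# ---------------------------------------------------------------------------

class RecommendationProblem:
    """Precomputed pieces of one subject's recommendation posterior.

    Orders the nutrient specs to the personal model, derives the adjusted
    limits, the worst-case preference error, and the personal Exponential
    rate, and exposes the log posterior and its analytic gradient in the
    natural intake units.
    """

    def __init__(self, pm: PersonalModel, specs: Sequence[NutrientSpec],
                 limits: AdjustedLimits, cfg: RecommendationConfig):
        by_name = {s.name: s for s in specs}
        missing = [n for n in pm.nutrients if n not in by_name]
        if missing:
            raise KeyError(f"no guideline spec for nutrients {missing}")
        self.pm = pm
        self.cfg = cfg
        self.limits = limits
        self.specs = [by_name[n] for n in pm.nutrients]
        self.lo = np.array([s.lower for s in self.specs], float)
        self.hi = np.array([s.upper for s in self.specs], float)
        self.width = self.hi - self.lo
        self.rec = np.array(
            [np.nan if s.recommended is None else s.recommended
             for s in self.specs], float)
        if cfg.lam6 > 0 and np.any(np.isnan(self.rec)):
            bad = [s.name for s in self.specs if s.recommended is None]
            raise ValueError(f"lam6 > 0 needs recommended points for {bad}")
        self.floors = 1e-3 * self.width
        # effect weights of the preference error, (R,)
        self.wpref = np.mean(1.0 / (1.0 + np.abs(pm.effects) * cfg.lam5), axis=0)
        e = max_preference_error(pm.current_intake, self.specs, pm.effects,
                                 cfg.lam5)
        lam_safe = safe_lambda(e, cfg.eps)
        self.pref = PreferenceState(
            e=e, lam_safe=lam_safe,
            lam_k=personal_lambda(lam_safe, cfg.lam3, e),
        )
        # truncated-normal part of the guideline prior
        if cfg.lam6 > 0:
            self.sigma_r = self.width / cfg.lam6
            a = (self.lo - self.rec) / self.sigma_r
            b = (self.hi - self.rec) / self.sigma_r
            self.znorm = ndtr(b) - ndtr(a)

    # -- prior ---------------------------------------------------------------
    def _prior_logpdf_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        cfg = self.cfg
        if cfg.lam6 == 0:
            return float(-np.sum(np.log(self.width))), np.zeros_like(q)
        zn = (q - self.rec) / self.sigma_r
        norm_pdf = np.exp(-0.5 * zn**2) / np.sqrt(2 * np.pi) / self.sigma_r
        dens = 0.5 / self.width + 0.5 * norm_pdf / self.znorm
        grad = 0.5 * norm_pdf * (-zn / self.sigma_r) / self.znorm / dens
        return float(np.sum(np.log(dens))), grad

    # -- full log posterior and gradient in natural units ---------------------
    def logpost_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        pm, cfg, lim = self.pm, self.cfg, self.limits
        q = np.asarray(q, float)
        M, R = pm.M, pm.R

        lp_prior, g_prior = self._prior_logpdf_grad(q)

        mu = pm.baseline + pm.effects @ ((q - pm.intake_mean) / pm.intake_sd)
        dmu_dq = pm.effects / pm.intake_sd[None, :]           # (M, R)

        s_l = expit(cfg.lam1 * (mu - lim.mu_lower))
        s_u = expit(cfg.lam1 * (lim.mu_upper - mu))
        b = s_l + s_u
        db_dmu = cfg.lam1 * (s_l * (1 - s_l) - s_u * (1 - s_u))  # (M,)
        b_tot = b.sum()
        dbtot_dq = db_dmu @ dmu_dq                             # (R,)

        sd = cfg.constraint_sd
        lp_c = (-0.5 * ((b_tot - 2.0 * M) / sd) ** 2
                - np.log(sd) - 0.5 * np.log(2 * np.pi))
        dlpc_dbtot = -(b_tot - 2.0 * M) / sd**2

        t = cfg.lam4 * (b_tot - (2.0 * M - 0.1))
        log_w = -np.logaddexp(0.0, -t)       # log sigmoid(t)
        log_1mw = -np.logaddexp(0.0, t)
        dlogw_dbtot = cfg.lam4 * expit(-t)
        dlog1mw_dbtot = -cfg.lam4 * expit(t)

        x = pm.current_intake
        den = np.maximum(q, self.floors)
        num = np.abs(x - q)
        u = float(np.mean(num / den * self.wpref))
        # d/dq of |x-q|/max(q,floor): quotient rule where q is the denominator
        sgn = np.sign(q - x)
        dratio = np.where(q > self.floors,
                          (sgn * den - num) / den**2,
                          sgn / den)
        du_dq = self.wpref * dratio / R

        lam_k = self.pref.lam_k
        lp_u = np.log(lam_k) - lam_k * u
        dlpu_dq = -lam_k * du_dq

        a_c = log_1mw + lp_c
        a_u = log_w + lp_u
        mix = np.logaddexp(a_c, a_u)
        wa = np.exp(a_c - mix)
        wb = np.exp(a_u - mix)
        da_c = (dlog1mw_dbtot + dlpc_dbtot) * dbtot_dq
        da_u = dlogw_dbtot * dbtot_dq + dlpu_dq
        dmix = wa * da_c + wb * da_u

        return float(lp_prior + mix), g_prior + dmix

    def logpost(self, q: np.ndarray) -> float:
        q = np.asarray(q, float)
        if np.any(q < self.lo) or np.any(q > self.hi):
            return -np.inf
        return self.logpost_grad(q)[0]

    # -- logit box reparameterization -----------------------------------------
    def q_of_y(self, y: np.ndarray) -> np.ndarray:
        return self.lo + self.width * expit(y)

    def y_of_q(self, q: np.ndarray) -> np.ndarray:
        p = np.clip((q - self.lo) / self.width, 1e-9, 1 - 1e-9)
        return np.log(p) - np.log1p(-p)

    def logpost_grad_y(self, y: np.ndarray) -> tuple[float, np.ndarray]:
        s = expit(y)
        q = self.lo + self.width * s
        lp, g = self.logpost_grad(q)
        # log|dq/dy| in overflow-safe form: log w - softplus(y) - softplus(-y)
        log_jac = (np.log(self.width) - np.logaddexp(0.0, y)
                   - np.logaddexp(0.0, -y))
        lp += float(np.sum(log_jac))
        return lp, g * self.width * s * (1 - s) + (1.0 - 2.0 * s)


def recommendation_logposterior(
    q, pm: PersonalModel, limits: AdjustedLimits, cfg: RecommendationConfig,
    specs: Sequence[NutrientSpec], grad: bool = False,
):
    """Unnormalized log posterior of a proposed natural-unit diet.

    With ``grad=True`` returns ``(logp, dlogp/dq)``; the gradient is analytic
    and matches central finite differences at interior points.
    """
    prob = RecommendationProblem(pm, specs, limits, cfg)
    return prob.logpost_grad(np.asarray(q, float)) if grad else prob.logpost(q)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _hmc_chain(prob: RecommendationProblem, rng: np.random.Generator,
               n_warmup: int, n_draws: int, y0: np.ndarray):
    """HMC with unit mass and dual-averaged step size on the open box."""
    y = y0.copy()
    lp, g = prob.logpost_grad_y(y)
    # dual averaging (target acceptance 0.8)
    eps = 0.1
    log_eps_bar, h_bar, mu_da = 0.0, 0.0, np.log(10 * eps)
    gamma_da, t0, kappa = 0.05, 10.0, 0.75
    draws = np.empty((n_draws, y.size))
    accept_count = 0
    total = n_warmup + n_draws
    for it in range(total):
        n_leap = int(rng.integers(8, 24))
        p = rng.normal(size=y.size)
        h0 = lp - 0.5 * p @ p
        y_new, g_new = y.copy(), g.copy()
        p = p + 0.5 * eps * g_new
        lp_new = lp
        diverged = False
        for _ in range(n_leap):
            y_new = y_new + eps * p
            lp_new, g_new = prob.logpost_grad_y(y_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            p = p + eps * g_new
        if not diverged:
            p = p - 0.5 * eps * g_new
            h1 = lp_new - 0.5 * p @ p
            log_acc = min(0.0, h1 - h0)
        else:
            log_acc = -np.inf
        acc_prob = np.exp(log_acc)
        if np.log(rng.uniform()) < log_acc:
            y, lp, g = y_new, lp_new, g_new
            if it >= n_warmup:
                accept_count += 1
        if it < n_warmup:
            frac = 1.0 / (it + 1 + t0)
            h_bar = (1 - frac) * h_bar + frac * (0.8 - acc_prob)
            log_eps = mu_da - np.sqrt(it + 1) / gamma_da * h_bar
            eta = (it + 1) ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = y
    return draws, accept_count / max(n_draws, 1)


def _rw_chain(prob: RecommendationProblem, rng: np.random.Generator,
              n_warmup: int, n_draws: int, y0: np.ndarray):
    """Adaptive random-walk Metropolis fallback on the open box."""
    y = y0.copy()
    lp = prob.logpost_grad_y(y)[0]
    ad = StepSizeAdapter(0.2, target=0.25)
    draws = np.empty((n_draws, y.size))
    acc_post = 0
    for it in range(n_warmup + n_draws):
        y_new = y + ad.scale * rng.normal(size=y.size)
        lp_new = prob.logpost_grad_y(y_new)[0]
        ok = np.log(rng.uniform()) < lp_new - lp
        if ok:
            y, lp = y_new, lp_new
        if it < n_warmup:
            ad.update(float(ok))
            if it == n_warmup - 1:
                ad.freeze()
        else:
            draws[it - n_warmup] = y
            acc_post += int(ok)
    return draws, acc_post / max(n_draws, 1)


@dataclass
class RecommendationResult:
    """Joint posterior over a subject's modifiable intakes and concentrations."""

    subject_id: str
    nutrients: list[str]
    concentrations: list[str]
    intake_draws: np.ndarray          # (S, R) natural units
    intake_draws_z: np.ndarray        # (S, R) standardized
    mu_draws: np.ndarray              # (S, M)
    summary: pd.DataFrame             # per-nutrient recommendation table
    concentration_report: pd.DataFrame
    limits: AdjustedLimits
    preference: PreferenceState
    feasible: bool                       # limits usable AND targets achieved
    limits_feasible: bool                # no adjusted limit pair crossed
    infeasible_concentrations: list[str]
    config: RecommendationConfig
    n_chains: int = 1
    accept_rate: float = float("nan")
    max_rhat: float = float("nan")

    @property
    def recommended(self) -> np.ndarray:
        return self.summary["recommended"].to_numpy()


def sample_recommendation(
    pm: PersonalModel,
    nutrient_specs: Sequence[NutrientSpec],
    concentration_targets,
    cfg: RecommendationConfig,
    subject_attrs: Mapping | None = None,
) -> RecommendationResult:
    """Sample the joint posterior of intakes Q and expected concentrations.

    ``concentration_targets`` is a list of :class:`ConcentrationSpec`
    (resolved with ``subject_attrs``) or a name -> (lower, upper) mapping.
    Crossed adjusted limits do not abort: sampling proceeds on the smooth
    density (which stays proper) and the result is flagged
    closest-achievable.  The per-nutrient recommendation is the posterior
    mean; the central 90% credible interval spans the intakes still predicted
    to reach the targets.
    """
    if cfg.seed is None:
        raise ValueError("RecommendationConfig.seed is mandatory")
    limits = compute_adjusted_limits(pm, concentration_targets, cfg.confidence,
                                     subject_attrs, strict=False)
    prob = RecommendationProblem(pm, nutrient_specs, limits, cfg)

    # the mixture can be multimodal: the preference component spikes at the
    # current diet even when that diet violates the limits, while the
    # constraint component peaks wherever the limits are met.  A coarse
    # global scan picks the dominant mode as the chains' starting point.
    ss = np.random.SeedSequence(cfg.seed)
    scan_rng = np.random.default_rng(ss.spawn(1)[0])
    candidates = [np.clip(pm.current_intake, prob.lo + 0.05 * prob.width,
                          prob.hi - 0.05 * prob.width)]
    candidates.append(prob.lo + 0.5 * prob.width)
    candidates.extend(prob.lo + scan_rng.random((max(256, 64 * pm.R), pm.R))
                      * prob.width)
    q0 = max(candidates, key=prob.logpost)
    chain_draws, accs = [], []
    runner = _hmc_chain if cfg.sampler == "hmc" else _rw_chain
    for child in ss.spawn(cfg.chains):
        rng = np.random.default_rng(child)
        y0 = prob.y_of_q(q0) + 0.1 * rng.normal(size=pm.R)
        d, a = runner(prob, rng, cfg.warmup, cfg.draws, y0)
        chain_draws.append(d)
        accs.append(a)

    max_rhat = float("nan")
    if cfg.chains >= 2:
        import arviz as az
        arr = np.stack(chain_draws)  # (C, S, R)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            max_rhat = float(np.nanmax(np.asarray(
                az.rhat(az.from_dict(posterior={"y": arr}), method="rank")["y"])))
        if np.isfinite(max_rhat) and max_rhat > 1.05:
            warnings.warn(
                f"recommendation sampler may not have converged "
                f"(max R-hat {max_rhat:.3f})", stacklevel=2)

    y_all = np.concatenate(chain_draws, axis=0)
    q_all = prob.q_of_y(y_all)
    z_all = (q_all - pm.intake_mean) / pm.intake_sd
    mu_all = pm.baseline + z_all @ pm.effects.T

    q_mean = q_all.mean(axis=0)
    mu_at_mean = predict_expected(pm, q_mean)
    rows = []
    for ri, n in enumerate(pm.nutrients):
        cur = pm.current_intake[ri]
        rec = q_mean[ri]
        pct = (rec - cur) / cur * 100.0 if cur != 0 else np.inf
        rows.append(dict(
            nutrient=n, units=pm.units[ri], current=cur, recommended=rec,
            ci5=np.quantile(q_all[:, ri], 0.05),
            ci95=np.quantile(q_all[:, ri], 0.95),
            percent_change=pct,
            large_change=bool(abs(rec - cur) / abs(cur) > 0.30) if cur != 0 else True,
        ))
    summary = pd.DataFrame(rows)

    crows = []
    for mi, m in enumerate(pm.concentrations):
        inside = (mu_all[:, mi] >= limits.mu_lower[mi]) & \
                 (mu_all[:, mi] <= limits.mu_upper[mi])
        a = pm.alpha[mi]
        mu_hat = max(mu_at_mean[mi], 1e-12)
        p_clin = float(stats.gamma.cdf(limits.y_upper[mi], a=a, scale=mu_hat / a)
                       - stats.gamma.cdf(limits.y_lower[mi], a=a, scale=mu_hat / a))
        crows.append(dict(
            concentration=m,
            expected=mu_at_mean[mi],
            mu_lower=limits.mu_lower[mi], mu_upper=limits.mu_upper[mi],
            y_lower=limits.y_lower[mi], y_upper=limits.y_upper[mi],
            within_adjusted=bool(limits.mu_lower[mi] <= mu_at_mean[mi]
                                 <= limits.mu_upper[mi]),
            satisfaction_prob=float(inside.mean()),
            prob_in_clinical_range=p_clin,
            feasible=bool(limits.feasible[mi]),
        ))
    conc_report = pd.DataFrame(crows)

    # a concentration is problematic if its adjusted limits are crossed or the
    # sampled diet cannot place its expected value inside them ("closest
    # achievable" reporting)
    achieved = conc_report["within_adjusted"].to_numpy()
    infeasible = [m for m, f, a in zip(limits.names, limits.feasible, achieved)
                  if not (f and a)]
    return RecommendationResult(
        subject_id=pm.subject_id,
        nutrients=list(pm.nutrients), concentrations=list(pm.concentrations),
        intake_draws=q_all, intake_draws_z=z_all, mu_draws=mu_all,
        summary=summary, concentration_report=conc_report,
        limits=limits, preference=prob.pref,
        feasible=bool(limits.all_feasible and achieved.all()),
        limits_feasible=limits.all_feasible,
        infeasible_concentrations=infeasible,
        config=cfg, n_chains=cfg.chains,
        accept_rate=float(np.mean(accs)), max_rhat=max_rhat,
    )


def confidence_check(alpha_m: float, mu_hat: float, y_lower: float,
                     y_upper: float, n: int = 1_000_000,
                     seed: int = 0) -> float:
    """Monte Carlo P(Y in clinical range) for Y ~ Gamma(alpha, alpha/mu_hat)."""
    rng = np.random.default_rng(seed)
    y = rng.gamma(shape=alpha_m, scale=mu_hat / alpha_m, size=n)
    return float(np.mean((y >= y_lower) & (y <= y_upper)))
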