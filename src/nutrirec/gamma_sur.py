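"""Hierarchical multivariate Gamma regression with identity link (estimation stage).

Each plasma concentration ``Y_kmi`` (observation ``i`` of concentration ``m``
for subject ``k``) is modeled as

    Y_kmi ~ Gamma(alpha_m, alpha_m / mu_kmi)

so that ``E[Y] = mu`` and ``Var[Y] = mu^2 / alpha_m``.  The mean follows an
additive (identity-link) hierarchical linear predictor with population fixed
effects, and subject-specific deviations for the intercept and every varying
predictor.  The subject-effect vectors ``b_k`` (length ``M * (J + 1)`` with
``J`` varying predictors) share one multivariate normal distribution,

    b_k ~ N(0, Sigma),    Sigma = T C T,

whose correlation matrix ``C`` links effects *across* concentrations — a
seemingly-unrelated-regressions structure in which cross-equation dependence
enters through correlated random effects rather than correlated errors.  An
optional nested group-level block (e.g. dialysis modality) adds group effects
``g_g ~ N(0, Sigma_g)`` on the same predictors.

Posterior sampling uses a blocked adaptive Metropolis-within-Gibbs scheme:

* coordinate-wise random-walk updates of the fixed effects with incremental
  likelihood evaluation,
* joint per-subject random-walk updates of ``b_k`` preconditioned by the
  current Cholesky factor of ``Sigma`` (subjects are conditionally
  independent, so all K proposals are evaluated and accepted in parallel),
* likelihood-invariant "translation" moves that shift a population coefficient
  and compensate in every subject effect, decorrelating the two levels,
* centered and non-centered (interweaved) updates of the scale/correlation
  hyperparameters, which removes the usual funnel pathology when per-subject
  data are weak.

All proposal scales adapt by Robbins-Monro during warmup only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import gammaln

from ._mcmc import (
    StepSizeAdapter,
    VectorStepAdapter,
    cpc_to_chol,
    lkj_cpc_logprior,
    n_cpc,
)
from .study_data import CohortTable

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "ModelSpec",
    "HierarchicalPosterior",
    "DiagnosticsReport",
    "linear_predictor",
    "gamma_identity_loglik",
    "build_covariance",
    "fit_hierarchical",
    "diagnostics",
    "nrmse",
    "posterior_predictive_pvalues",
]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative defaults for standardized predictors.

    ``beta_sd``: sd of the N(0, .) prior on standardized-scale fixed effects.
    ``intercept_sd_scale``: intercept prior is N(mean(Y_m), scale * sd(Y_m)).
    ``sigma_scale``: half-Normal(0, scale) on every random-effect sd.
    ``lkj_eta``: LKJ shape on the random-effect correlation matrix.
    ``alpha_rate``: Exponential(rate) on each Gamma shape.
    """

    beta_sd: float = 2.5
    intercept_sd_scale: float = 2.0
    sigma_scale: float = 1.0
    lkj_eta: float = 2.0
    alpha_rate: float = 0.1


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    thin: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.draws < 1 or self.warmup < 0 or self.chains < 1:
            raise ValueError("chains/draws/warmup must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible fits")


@dataclass(frozen=True)
class ModelSpec:
    concentrations: tuple[str, ...]
    varying_predictors: tuple[str, ...]
    fixed_predictors: tuple[str, ...] = ()
    group_level: bool = False
    priors: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(seed=0))

    def __post_init__(self):
        object.__setattr__(self, "concentrations", tuple(self.concentrations))
        object.__setattr__(self, "varying_predictors", tuple(self.varying_predictors))
        object.__setattr__(self, "fixed_predictors", tuple(self.fixed_predictors))
        if len(self.concentrations) < 1:
            raise ValueError("need at least one concentration (M >= 1)")
        if len(self.varying_predictors) < 1:
            raise ValueError("need at least one varying predictor")

    @property
    def M(self) -> int:
        return len(self.concentrations)

    @property
    def F(self) -> int:
        return len(self.fixed_predictors)

    @property
    def J(self) -> int:
        return len(self.varying_predictors)

    @property
    def n_coef(self) -> int:  # columns of beta: intercept + fixed + varying
        return 1 + self.F + self.J

    @property
    def d_b(self) -> int:  # length of one subject-effect vector
        return self.M * (self.J + 1)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def linear_predictor(betas: np.ndarray, b_k: np.ndarray,
                     X_row: np.ndarray, Z_row: np.ndarray) -> np.ndarray:
    """Expected concentrations for one record (identity link).

    ``betas`` has shape (M, 1 + F + J): intercept, fixed, varying columns.
    ``b_k`` has shape (M, 1 + J): subject intercept and varying deviations.
    """
    betas = np.atleast_2d(np.asarray(betas, float))
    b_k = np.atleast_2d(np.asarray(b_k, float))
    X_row = np.asarray(X_row, float).ravel()
    Z_row = np.asarray(Z_row, float).ravel()
    M = betas.shape[0]
    F, J = X_row.size, Z_row.size
    if betas.shape[1] != 1 + F + J or b_k.shape != (M, 1 + J):
        raise ValueError("non-conformable coefficient/predictor dimensions")
    return (betas[:, 0] + b_k[:, 0]
            + betas[:, 1:1 + F] @ X_row
            + (betas[:, 1 + F:] + b_k[:, 1:]) @ Z_row)


def gamma_identity_loglik(y, alpha, mu):
    """Log density of Gamma(shape=alpha, rate=alpha/mu); -inf where mu <= 0.

    The -inf return is the rejection signal used by the sampler when an
    identity-link proposal drives an expected value non-positive.
    """
    y = np.asarray(y, float)
    alpha = np.asarray(alpha, float)
    mu = np.asarray(mu, float)
    ok = mu > 0
    mu_safe = np.where(ok, mu, 1.0)
    ll = (alpha * np.log(alpha) - gammaln(alpha) + (alpha - 1.0) * np.log(y)
          - alpha * np.log(mu_safe) - alpha * y / mu_safe)
    return np.where(ok, ll, -np.inf) if ll.ndim else (float(ll) if ok else -np.inf)


def build_covariance(T_diag: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Sigma = T C T from sds ``T_diag`` and correlation matrix ``C``."""
    t = np.asarray(T_diag, float).ravel()
    C = np.asarray(C, float)
    if C.shape != (t.size, t.size):
        raise ValueError("dimension mismatch between T and C")
    if np.any(t <= 0):
        raise ValueError("standard deviations must be positive")
    if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0):
        raise ValueError("C is not a correlation matrix")
    np.linalg.cholesky(C)  # raises LinAlgError if not PD
    return C * np.outer(t, t)


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalPosterior:
    """Posterior draws, dimension (chains, draws, ...) per parameter block."""

    spec: ModelSpec
    subject_ids: list
    beta: np.ndarray          # (C, S, M, 1+F+J)
    b: np.ndarray             # (C, S, K, M, 1+J)
    alpha: np.ndarray         # (C, S, M)
    sigma: np.ndarray         # (C, S, d_b)
    cpc: np.ndarray           # (C, S, n_cpc) partial correlations in (-1,1)
    group_ids: list | None = None
    g: np.ndarray | None = None        # (C, S, G, M, 1+J)
    sigma_g: np.ndarray | None = None  # (C, S, d_b)
    cpc_g: np.ndarray | None = None    # (C, S, n_cpc)
    seed: int | None = None
    accept_stats: dict | None = None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Chain-stacked draws: shape (chains * draws, ...)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def corr_matrix(self, chain: int, draw: int, group: bool = False) -> np.ndarray:
        z = (self.cpc_g if group else self.cpc)[chain, draw]
        L = cpc_to_chol(z, self.spec.d_b)
        return L @ L.T

    def covariance(self, chain: int, draw: int, group: bool = False) -> np.ndarray:
        s = (self.sigma_g if group else self.sigma)[chain, draw]
        return build_covariance(s, self.corr_matrix(chain, draw, group=group))

    def predictor_names(self) -> list[str]:
        return (["intercept"] + list(self.spec.fixed_predictors)
                + list(self.spec.varying_predictors))

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd and central 90% interval of beta and alpha."""
        rows = []
        beta = self.stacked("beta")
        for mi, m in enumerate(self.spec.concentrations):
            for pi, p in enumerate(self.predictor_names()):
                d = beta[:, mi, pi]
                rows.append(dict(parameter=f"beta[{m},{p}]", mean=d.mean(),
                                 sd=d.std(ddof=1), q5=np.quantile(d, 0.05),
                                 q95=np.quantile(d, 0.95)))
        alpha = self.stacked("alpha")
        for mi, m in enumerate(self.spec.concentrations):
            d = alpha[:, mi]
            rows.append(dict(parameter=f"alpha[{m}]", mean=d.mean(),
                             sd=d.std(ddof=1), q5=np.quantile(d, 0.05),
                             q95=np.quantile(d, 0.95)))
        return pd.DataFrame(rows)

    def to_inference_data(self, include_subject_effects: bool = False):
        import arviz as az

        post = {"beta": self.beta, "alpha": self.alpha, "sigma": self.sigma,
                "cpc": self.cpc}
        if include_subject_effects:
            post["b"] = self.b
        return az.from_dict(posterior=post)

    # -- plain-text persistence ----------------------------------------------
    def save(self, directory) -> None:
        """Persist draws as one wide CSV plus JSON metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols: dict[str, np.ndarray] = {}
        C, S = self.n_chains, self.n_draws
        cols["chain"] = np.repeat(np.arange(C), S)
        cols["draw"] = np.tile(np.arange(S), C)

        def flat(name):
            arr = self.stacked(name)
            flat2 = arr.reshape(arr.shape[0], -1)
            for i in range(flat2.shape[1]):
                idx = np.unravel_index(i, arr.shape[1:])
                cols[f"{name}[{','.join(map(str, idx))}]"] = flat2[:, i]

        for nm in ["beta", "b", "alpha", "sigma", "cpc"]:
            flat(nm)
        if self.g is not None:
            for nm in ["g", "sigma_g", "cpc_g"]:
                flat(nm)
        pd.DataFrame(cols).to_csv(directory / "draws.csv", index=False)
        meta = {
            "concentrations": list(self.spec.concentrations),
            "fixed_predictors": list(self.spec.fixed_predictors),
            "varying_predictors": list(self.spec.varying_predictors),
            "group_level": self.spec.group_level,
            "subject_ids": [str(s) for s in self.subject_ids],
            "group_ids": None if self.group_ids is None
                          else [str(g) for g in self.group_ids],
            "chains": C, "draws": S, "seed": self.seed,
            "priors": asdict(self.spec.priors),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "HierarchicalPosterior":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        df = pd.read_csv(directory / "draws.csv")
        spec = ModelSpec(
            concentrations=tuple(meta["concentrations"]),
            varying_predictors=tuple(meta["varying_predictors"]),
            fixed_predictors=tuple(meta["fixed_predictors"]),
            group_level=meta["group_level"],
            priors=PriorConfig(**meta["priors"]),
            sampler=SamplerConfig(seed=meta["seed"] if meta["seed"] is not None else 0,
                                  chains=meta["chains"], draws=meta["draws"]),
        )
        C, S = meta["chains"], meta["draws"]
        K = len(meta["subject_ids"])
        M, F, J = spec.M, spec.F, spec.J

        def unflat(name, shape):
            pref = f"{name}["
            cs = [c for c in df.columns if c.startswith(pref)]
            arr = df[cs].to_numpy().reshape((C, S) + shape)
            return arr

        g = sg = cg = None
        if meta["group_level"] and meta["group_ids"]:
            G = len(meta["group_ids"])
            g = unflat("g", (G, M, 1 + J))
            sg = unflat("sigma_g", (spec.d_b,))
            cg = unflat("cpc_g", (n_cpc(spec.d_b),))
        return cls(
            spec=spec, subject_ids=meta["subject_ids"],
            beta=unflat("beta", (M, 1 + F + J)),
            b=unflat("b", (K, M, 1 + J)),
            alpha=unflat("alpha", (M,)),
            sigma=unflat("sigma", (spec.d_b,)),
            cpc=unflat("cpc", (n_cpc(spec.d_b),)),
            group_ids=meta["group_ids"], g=g, sigma_g=sg, cpc_g=cg,
            seed=meta["seed"],
        )


# ---------------------------------------------------------------------------
# Model data and likelihood machinery
# ---------------------------------------------------------------------------

class _ModelData:
    def __init__(self, data: CohortTable, spec: ModelSpec):
        for c in (*spec.concentrations, *spec.fixed_predictors,
                  *spec.varying_predictors):
            if c not in data.data.columns:
                raise KeyError(f"column {c!r} not in cohort table")
        self.Y = data.data[list(spec.concentrations)].to_numpy(float)
        self.X = (data.data[list(spec.fixed_predictors)].to_numpy(float)
                  if spec.fixed_predictors else np.empty((len(data.data), 0)))
        self.Z = data.data[list(spec.varying_predictors)].to_numpy(float)
        self.sidx = data.subject_index()
        self.subject_ids = data.subject_ids
        self.K = len(self.subject_ids)
        gi = data.group_index() if spec.group_level else None
        if spec.group_level and gi is None:
            raise ValueError("group_level=True but the cohort schema has no group column")
        self.gidx, self.group_ids = (gi if gi is not None else (None, None))
        self.G = 0 if self.group_ids is None else len(self.group_ids)
        self.N = self.Y.shape[0]
        self.log_y = np.log(self.Y)
        self.ybar = self.Y.mean(axis=0)
        self.ysd = self.Y.std(axis=0, ddof=1) if self.N > 1 else np.ones_like(self.ybar)
        self.ysd = np.where(self.ysd > 0, self.ysd, 1.0)


def _obs_ll(md: _ModelData, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-observation, per-concentration log likelihood; -inf where mu<=0."""
    ok = mu > 0
    mu_safe = np.where(ok, mu, 1.0)
    ll = (alpha * np.log(alpha) - gammaln(alpha) + (alpha - 1.0) * md.log_y
          - alpha * np.log(mu_safe) - alpha * md.Y / mu_safe)
    return np.where(ok, ll, -np.inf)


def _col_ll(md, mu_col, alpha_m, m):
    ok = mu_col > 0
    mu_safe = np.where(ok, mu_col, 1.0)
    ll = (alpha_m * np.log(alpha_m) - gammaln(alpha_m)
          + (alpha_m - 1.0) * md.log_y[:, m]
          - alpha_m * np.log(mu_safe) - alpha_m * md.Y[:, m] / mu_safe)
    return np.where(ok, ll, -np.inf)


class _State:
    __slots__ = ("beta", "b", "g", "log_alpha", "log_sigma", "y_cpc",
                 "log_sigma_g", "y_cpc_g")

    def __init__(self, beta, b, g, log_alpha, log_sigma, y_cpc,
                 log_sigma_g=None, y_cpc_g=None):
        self.beta = beta
        self.b = b
        self.g = g
        self.log_alpha = log_alpha
        self.log_sigma = log_sigma
        self.y_cpc = y_cpc
        self.log_sigma_g = log_sigma_g
        self.y_cpc_g = y_cpc_g


def _compute_mu(md: _ModelData, spec: ModelSpec, st: _State) -> np.ndarray:
    F = spec.F
    mu = (st.beta[:, 0][None, :]
          + md.X @ st.beta[:, 1:1 + F].T
          + md.Z @ st.beta[:, 1 + F:].T
          + st.b[md.sidx, :, 0]
          + np.einsum("nj,nmj->nm", md.Z, st.b[md.sidx][:, :, 1:]))
    if st.g is not None:
        mu = (mu + st.g[md.gidx, :, 0]
              + np.einsum("nj,nmj->nm", md.Z, st.g[md.gidx][:, :, 1:]))
    return mu


def _chol_sigma(log_sigma: np.ndarray, y_cpc: np.ndarray, d: int) -> np.ndarray:
    return np.exp(log_sigma)[:, None] * cpc_to_chol(np.tanh(y_cpc), d)


def _mvn_logpdf_rows(Bflat: np.ndarray, L: np.ndarray) -> np.ndarray:
    """N(0, L L^T) log density per row (constants dropped)."""
    u = solve_triangular(L, Bflat.T, lower=True, check_finite=False)
    return -0.5 * np.sum(u * u, axis=0) - np.sum(np.log(np.diag(L)))


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

def _run_chain(md: _ModelData, spec: ModelSpec, rng: np.random.Generator):
    M, F, J = spec.M, spec.F, spec.J
    P, K, d_b = spec.n_coef, md.K, spec.d_b
    pc = spec.priors
    warmup, draws = spec.sampler.warmup, spec.sampler.draws
    thin = spec.sampler.thin
    has_group = spec.group_level and md.G > 0

    # priors on beta coordinates
    prior_mean = np.zeros((M, P))
    prior_mean[:, 0] = md.ybar
    prior_sd = np.full((M, P), pc.beta_sd)
    prior_sd[:, 0] = pc.intercept_sd_scale * md.ysd

    # initial state: intercepts at observed means so mu > 0 initially
    alpha0 = np.clip(md.ybar**2 / np.maximum(md.ysd**2, 1e-12), 0.5, 1e4)
    st = _State(
        beta=prior_mean * (np.arange(P) == 0) + 0.01 * rng.normal(size=(M, P)),
        b=0.01 * rng.normal(size=(K, M, 1 + J)),
        g=(0.01 * rng.normal(size=(md.G, M, 1 + J)) if has_group else None),
        log_alpha=np.log(alpha0) + 0.1 * rng.normal(size=M),
        log_sigma=np.log(0.3) + 0.1 * rng.normal(size=d_b),
        y_cpc=np.zeros(n_cpc(d_b)),
        log_sigma_g=(np.log(0.3) + 0.1 * rng.normal(size=d_b)) if has_group else None,
        y_cpc_g=np.zeros(n_cpc(d_b)) if has_group else None,
    )
    st.beta[:, 0] = np.maximum(st.beta[:, 0], 0.1 * md.ybar)

    mu = _compute_mu(md, spec, st)
    alpha = np.exp(st.log_alpha)
    col_ll = np.array([_col_ll(md, mu[:, m], alpha[m], m).sum() for m in range(M)])

    # adapters
    n_hyper = d_b + n_cpc(d_b)  # log sds then unconstrained CPCs
    ad_beta = VectorStepAdapter(M * P, init_scale=0.05, target=0.44)
    ad_am = StepSizeAdapter(1.0, target=0.25)
    am_stats = [0.0, np.zeros(M * P), np.zeros((M * P, M * P))]  # n, mean, scatter
    ad_b = VectorStepAdapter(K, init_scale=0.3, target=0.25)
    ad_tr = VectorStepAdapter(M * (1 + J), init_scale=0.05, target=0.44)
    ad_alpha = VectorStepAdapter(M, init_scale=0.1, target=0.44)
    ad_hc = VectorStepAdapter(n_hyper, init_scale=0.2, target=0.44)
    ad_hns = VectorStepAdapter(d_b, init_scale=0.3, target=0.44)
    ad_hn = StepSizeAdapter(0.1, target=0.25)
    ad_g = StepSizeAdapter(0.3, target=0.25) if has_group else None
    ad_hcg = VectorStepAdapter(n_hyper, init_scale=0.2, target=0.44) if has_group else None
    ad_hng = StepSizeAdapter(0.1, target=0.25) if has_group else None

    def beta_logprior(beta):
        return -0.5 * np.sum(((beta - prior_mean) / prior_sd) ** 2)

    def hyper_logprior(log_sigma, y_cpc):
        sig = np.exp(log_sigma)
        # half-N(0, sigma_scale) + log-Jacobian, and LKJ on the CPCs
        lp = np.sum(-0.5 * (sig / pc.sigma_scale) ** 2 + log_sigma)
        return lp + lkj_cpc_logprior(y_cpc, d_b, pc.lkj_eta)

    cpc_rows, cpc_cols = np.tril_indices(d_b, -1)
    a_lkj = pc.lkj_eta + (d_b - 2 - cpc_cols) / 2.0

    def centered_hyper_sweep(log_sigma, y_cpc, L, Bflat, adapter, rng):
        """Coordinate-wise prior-only updates of (log sds, CPCs).

        A log-sd move rescales one row of the covariance Cholesky; a CPC move
        rebuilds only the affected row of the correlation Cholesky — both are
        O(d) updates followed by one triangular solve for the quad form.
        """
        log_sigma = log_sigma.copy()
        y_cpc = y_cpc.copy()
        L = L.copy()
        zmat = np.zeros((d_b, d_b))
        zmat[cpc_rows, cpc_cols] = np.tanh(y_cpc)
        quad = _mvn_logpdf_rows(Bflat, L).sum()
        scales = adapter.scale
        accepted = np.zeros(n_hyper)
        for idx in rng.permutation(n_hyper):
            L_new = L.copy()
            if idx < d_b:
                i = idx
                ls_new = log_sigma[i] + scales[idx] * rng.normal()
                L_new[i, :] *= np.exp(ls_new - log_sigma[i])
                s_old, s_new = np.exp(log_sigma[i]), np.exp(ls_new)
                dprior = (-0.5 * (s_new**2 - s_old**2) / pc.sigma_scale**2
                          + ls_new - log_sigma[i])
            else:
                j = idx - d_b
                i = cpc_rows[j]
                y_new = y_cpc[j] + scales[idx] * rng.normal()
                z_new = np.tanh(y_new)
                z_old = zmat[i, cpc_cols[j]]
                zrow = zmat[i, :i].copy()
                zrow[cpc_cols[j]] = z_new
                f = 1.0 - zrow**2
                rem = np.concatenate(([1.0], np.cumprod(f)))
                lc_row = np.zeros(d_b)
                lc_row[:i] = zrow * np.sqrt(rem[:i])
                lc_row[i] = np.sqrt(rem[i])
                L_new[i, :] = np.exp(log_sigma[i]) * lc_row
                dprior = a_lkj[j] * (np.log1p(-z_new**2) - np.log1p(-z_old**2))
            quad_new = _mvn_logpdf_rows(Bflat, L_new).sum()
            if np.log(rng.uniform()) < quad_new - quad + dprior:
                L, quad = L_new, quad_new
                if idx < d_b:
                    log_sigma[idx] = ls_new
                else:
                    y_cpc[idx - d_b] = y_new
                    zmat[cpc_rows[idx - d_b], cpc_cols[idx - d_b]] = z_new
                accepted[idx] = 1.0
        adapter.update(accepted)
        return log_sigma, y_cpc, L

    L = _chol_sigma(st.log_sigma, st.y_cpc, d_b)
    Lg = _chol_sigma(st.log_sigma_g, st.y_cpc_g, d_b) if has_group else None

    out = {nm: [] for nm in
           ["beta", "b", "alpha", "sigma", "cpc", "g", "sigma_g", "cpc_g"]}
    acc = {"beta": 0.0, "b": 0.0, "alpha": 0.0, "n": 0}

    total = warmup + draws * thin

    for it in range(total):
        # ---- 1. fixed effects, coordinate-wise with incremental likelihood
        scales = ad_beta.scale
        accepted = np.zeros(M * P)
        order = rng.permutation(M * P)
        for flat in order:
            m, c = divmod(flat, P)
            delta = scales[flat] * rng.normal()
            if c == 0:
                xcol = 1.0
            elif c <= F:
                xcol = md.X[:, c - 1]
            else:
                xcol = md.Z[:, c - 1 - F]
            mu_m_new = mu[:, m] + delta * xcol
            new_ll = _col_ll(md, mu_m_new, alpha[m], m).sum()
            dlp = (-0.5 * ((st.beta[m, c] + delta - prior_mean[m, c]) ** 2
                           - (st.beta[m, c] - prior_mean[m, c]) ** 2)
                   / prior_sd[m, c] ** 2)
            if np.log(rng.uniform()) < new_ll - col_ll[m] + dlp:
                st.beta[m, c] += delta
                mu[:, m] = mu_m_new
                col_ll[m] = new_ll
                accepted[flat] = 1.0
        ad_beta.update(accepted)
        acc["beta"] += accepted.mean()

        # ---- 1b. joint beta move with empirical proposal covariance
        # (coordinate moves stall on correlated pairs such as intercept vs a
        # binary covariate; the adaptive block move handles those directions)
        bvec = st.beta.ravel()
        n_am, mean_am = am_stats[0] + 1.0, am_stats[1]
        d_vec = bvec - mean_am
        mean_am = mean_am + d_vec / n_am
        am_stats[0] = n_am
        am_stats[1] = mean_am
        am_stats[2] = am_stats[2] + np.outer(d_vec, bvec - mean_am)
        if it >= 100:
            cov = am_stats[2] / max(n_am - 1.0, 1.0)
            try:
                Lam = np.linalg.cholesky(cov + 1e-10 * np.eye(M * P))
            except np.linalg.LinAlgError:
                Lam = None
        else:
            Lam = None
        for _ in range(2 if Lam is not None else 0):
            bvec = st.beta.ravel()
            prop_vec = bvec + ad_am.scale * (Lam @ rng.normal(size=M * P))
            beta_new = prop_vec.reshape(M, P)
            beta_save = st.beta
            st.beta = beta_new
            mu_new = _compute_mu(md, spec, st)
            st.beta = beta_save
            ll_new_cols = np.array([
                _col_ll(md, mu_new[:, m], alpha[m], m).sum()
                for m in range(M)])
            dlp = (ll_new_cols.sum() - col_ll.sum()
                   + beta_logprior(beta_new) - beta_logprior(st.beta))
            ok = np.isfinite(dlp) and np.log(rng.uniform()) < dlp
            if ok:
                st.beta = beta_new
                mu = mu_new
                col_ll = ll_new_cols
            ad_am.update(float(ok))

        # ---- 2. subject effects, all subjects in parallel (several sweeps:
        # every other block conditions on b, so b mixing paces the chain)
        for rep in range(3):
            Bflat = st.b.reshape(K, d_b)
            eps = rng.normal(size=(K, d_b))
            prop = Bflat + ad_b.scale[:, None] * (eps @ L.T)
            st_b_new = prop.reshape(K, M, 1 + J)
            b_old = st.b
            st.b = st_b_new
            mu_new = _compute_mu(md, spec, st)
            st.b = b_old
            ll_new = np.bincount(md.sidx, weights=_obs_ll(md, mu_new, alpha).sum(1),
                                 minlength=K)
            ll_old = np.bincount(md.sidx, weights=_obs_ll(md, mu, alpha).sum(1),
                                 minlength=K)
            lp_new = _mvn_logpdf_rows(prop, L)
            lp_old = _mvn_logpdf_rows(Bflat, L)
            accept = np.log(rng.uniform(size=K)) < (ll_new - ll_old + lp_new - lp_old)
            if np.any(accept):
                Bflat[accept] = prop[accept]
                st.b = Bflat.reshape(K, M, 1 + J)
                mu = _compute_mu(md, spec, st)
            ad_b.update(accept)
            acc["b"] += accept.mean() / 3.0
        col_ll = np.array([_col_ll(md, mu[:, m], alpha[m], m).sum()
                           for m in range(M)])

        # ---- 3. translation moves (likelihood-invariant): shift one
        # population coefficient and compensate in every subject effect
        acc_tr = np.zeros(M * (1 + J))
        quad = _mvn_logpdf_rows(st.b.reshape(K, d_b), L).sum()
        for flat in rng.permutation(M * (1 + J)):
            m, j = divmod(flat, 1 + J)
            c = 0 if j == 0 else F + j  # paired beta column
            delta = ad_tr.scale[flat] * rng.normal()
            b_new = st.b.copy()
            b_new[:, m, j] -= delta
            quad_new = _mvn_logpdf_rows(b_new.reshape(K, d_b), L).sum()
            bc = st.beta[m, c]
            dlp = (quad_new - quad
                   - 0.5 * ((bc + delta - prior_mean[m, c]) ** 2
                            - (bc - prior_mean[m, c]) ** 2) / prior_sd[m, c] ** 2)
            if np.log(rng.uniform()) < dlp:
                st.beta[m, c] += delta
                st.b = b_new
                quad = quad_new
                acc_tr[flat] = 1.0
        ad_tr.update(acc_tr)

        # ---- 4. Gamma shapes, coordinate-wise
        acc_a = np.zeros(M)
        for m in range(M):
            la_new = st.log_alpha[m] + ad_alpha.scale[m] * rng.normal()
            a_new = np.exp(la_new)
            ll_new = _col_ll(md, mu[:, m], a_new, m).sum()
            dlp = (ll_new - col_ll[m]
                   - pc.alpha_rate * (a_new - alpha[m]) + la_new - st.log_alpha[m])
            if np.log(rng.uniform()) < dlp:
                st.log_alpha[m], col_ll[m] = la_new, ll_new
                alpha = np.exp(st.log_alpha)
                acc_a[m] = 1.0
        ad_alpha.update(acc_a)
        acc["alpha"] += acc_a.mean()

        # ---- 5. hyperparameters, centered (prior-only), coordinate-wise
        st.log_sigma, st.y_cpc, L = centered_hyper_sweep(
            st.log_sigma, st.y_cpc, L, st.b.reshape(K, d_b), ad_hc, rng)

        # ---- 6a. non-centered sweep over the sd coordinates (funnel-buster):
        # holding the whitened subject effects fixed, rescaling sigma_i moves
        # only column i of the subject-effect matrix, i.e. one concentration's
        # mu — so each coordinate move costs one single-column likelihood.
        Bflat = st.b.reshape(K, d_b)
        zk = solve_triangular(L, Bflat.T, lower=True, check_finite=False)
        Lc = L / np.exp(st.log_sigma)[:, None]
        acc_s = np.zeros(d_b)
        for i in rng.permutation(d_b):
            ls_new = st.log_sigma[i] + ad_hns.scale[i] * rng.normal()
            col_new = np.exp(ls_new) * (Lc[i, :i + 1] @ zk[:i + 1])
            delta_col = col_new - Bflat[:, i]
            m_i, j_i = divmod(i, 1 + J)
            xcol = 1.0 if j_i == 0 else md.Z[:, j_i - 1]
            mu_m_new = mu[:, m_i] + delta_col[md.sidx] * xcol
            ll_new = _col_ll(md, mu_m_new, alpha[m_i], m_i).sum()
            s_old, s_new = np.exp(st.log_sigma[i]), np.exp(ls_new)
            dlp = (ll_new - col_ll[m_i]
                   - 0.5 * (s_new**2 - s_old**2) / pc.sigma_scale**2
                   + ls_new - st.log_sigma[i])
            if np.isfinite(dlp) and np.log(rng.uniform()) < dlp:
                st.log_sigma[i] = ls_new
                Bflat[:, i] = col_new
                mu[:, m_i] = mu_m_new
                col_ll[m_i] = ll_new
                L[i, :] = s_new * Lc[i, :]
                acc_s[i] = 1.0
        st.b = Bflat.reshape(K, M, 1 + J)
        ad_hns.update(acc_s)

        # ---- 6b. non-centered CPC moves (interweaved; likelihood moves)
        # joint proposal on a random subset of coordinates keeps acceptance
        # workable as the hyper dimension grows
        zk = solve_triangular(L, st.b.reshape(K, d_b).T, lower=True,
                              check_finite=False)  # (d_b, K)
        for _ in range(4):
            mask = rng.random(n_hyper) < max(6, n_hyper // 4) / n_hyper
            if not mask.any():
                mask[rng.integers(n_hyper)] = True
            step = np.where(mask, ad_hn.scale * rng.normal(size=n_hyper), 0.0)
            ls_new = st.log_sigma + step[:d_b]
            yc_new = st.y_cpc + step[d_b:]
            L_new = _chol_sigma(ls_new, yc_new, d_b)
            b_new = (L_new @ zk).T.reshape(K, M, 1 + J)
            b_old = st.b
            st.b = b_new
            mu_new = _compute_mu(md, spec, st)
            st.b = b_old
            dlp = (_obs_ll(md, mu_new, alpha).sum() - _obs_ll(md, mu, alpha).sum()
                   + hyper_logprior(ls_new, yc_new)
                   - hyper_logprior(st.log_sigma, st.y_cpc))
            ok = np.isfinite(dlp) and np.log(rng.uniform()) < dlp
            if ok:
                st.log_sigma, st.y_cpc, L = ls_new, yc_new, L_new
                st.b = b_new
                mu = mu_new
                col_ll = np.array([_col_ll(md, mu[:, m], alpha[m], m).sum()
                                   for m in range(M)])
                zk = solve_triangular(L, st.b.reshape(K, d_b).T, lower=True)
            ad_hn.update(float(ok))

        # ---- 7. group-level block
        if has_group:
            Gflat = st.g.reshape(md.G, d_b)
            prop = Gflat + ad_g.scale * rng.normal(size=(md.G, d_b)) @ Lg.T
            g_old = st.g
            st.g = prop.reshape(md.G, M, 1 + J)
            mu_new = _compute_mu(md, spec, st)
            st.g = g_old
            ll_new = np.bincount(md.gidx, weights=_obs_ll(md, mu_new, alpha).sum(1),
                                 minlength=md.G)
            ll_old = np.bincount(md.gidx, weights=_obs_ll(md, mu, alpha).sum(1),
                                 minlength=md.G)
            lp_new = _mvn_logpdf_rows(prop, Lg)
            lp_old = _mvn_logpdf_rows(Gflat, Lg)
            accept = np.log(rng.uniform(size=md.G)) < (ll_new - ll_old
                                                       + lp_new - lp_old)
            if np.any(accept):
                Gflat[accept] = prop[accept]
                st.g = Gflat.reshape(md.G, M, 1 + J)
                mu = _compute_mu(md, spec, st)
                col_ll = np.array([_col_ll(md, mu[:, m], alpha[m], m).sum()
                                   for m in range(M)])
            ad_g.update(float(accept.mean()))

            # centered hyper update for the group block
            st.log_sigma_g, st.y_cpc_g, Lg = centered_hyper_sweep(
                st.log_sigma_g, st.y_cpc_g, Lg, st.g.reshape(md.G, d_b),
                ad_hcg, rng)

            # non-centered hyper update for the group block
            zg = solve_triangular(Lg, st.g.reshape(md.G, d_b).T, lower=True)
            ls_new = st.log_sigma_g + ad_hng.scale * rng.normal(size=d_b)
            yc_new = st.y_cpc_g + ad_hng.scale * rng.normal(size=n_cpc(d_b))
            Lg_new = _chol_sigma(ls_new, yc_new, d_b)
            g_new = (Lg_new @ zg).T.reshape(md.G, M, 1 + J)
            g_old = st.g
            st.g = g_new
            mu_new = _compute_mu(md, spec, st)
            st.g = g_old
            dlp = (_obs_ll(md, mu_new, alpha).sum() - _obs_ll(md, mu, alpha).sum()
                   + hyper_logprior(ls_new, yc_new)
                   - hyper_logprior(st.log_sigma_g, st.y_cpc_g))
            if np.isfinite(dlp) and np.log(rng.uniform()) < dlp:
                st.log_sigma_g, st.y_cpc_g, Lg = ls_new, yc_new, Lg_new
                st.g = g_new
                mu = mu_new
                col_ll = np.array([_col_ll(md, mu[:, m], alpha[m], m).sum()
                                   for m in range(M)])
                ad_hng.update(1.0)
            else:
                ad_hng.update(0.0)

        acc["n"] += 1

        if it == warmup - 1:
            for a in [ad_beta, ad_am, ad_b, ad_tr, ad_alpha, ad_hc, ad_hns,
                      ad_hn, ad_g, ad_hcg, ad_hng]:
                if a is not None:
                    a.freeze()

        if it >= warmup and (it - warmup) % thin == 0:
            out["beta"].append(st.beta.copy())
            out["b"].append(st.b.copy())
            out["alpha"].append(alpha.copy())
            out["sigma"].append(np.exp(st.log_sigma))
            out["cpc"].append(np.tanh(st.y_cpc))
            if has_group:
                out["g"].append(st.g.copy())
                out["sigma_g"].append(np.exp(st.log_sigma_g))
                out["cpc_g"].append(np.tanh(st.y_cpc_g))

    res = {k: np.array(v) for k, v in out.items() if v}
    res["_acc"] = {k: v / max(acc["n"], 1) for k, v in acc.items() if k != "n"}
    return res


def fit_hierarchical(data: CohortTable, spec: ModelSpec) -> HierarchicalPosterior:
    """Fit the hierarchical multivariate Gamma regression by blocked MCMC.

    ``data`` must be a validated cohort with standardized predictors.  Returns
    chains of posterior draws; non-convergence (rank-normalized split R-hat
    above 1.05 on any monitored parameter) raises a warning naming the worst
    parameters.
    """
    if not data.standardized:
        warnings.warn("cohort table is not flagged as standardized; the default "
                      "priors assume z-scored predictors", stacklevel=2)
    md = _ModelData(data, spec)
    ss = np.random.SeedSequence(spec.sampler.seed)
    chains = []
    for child in ss.spawn(spec.sampler.chains):
        chains.append(_run_chain(md, spec, np.random.default_rng(child)))

    def stack(name):
        if name not in chains[0]:
            return None
        return np.stack([c[name] for c in chains])

    post = HierarchicalPosterior(
        spec=spec, subject_ids=md.subject_ids,
        beta=stack("beta"), b=stack("b"), alpha=stack("alpha"),
        sigma=stack("sigma"), cpc=stack("cpc"),
        group_ids=md.group_ids, g=stack("g"),
        sigma_g=stack("sigma_g"), cpc_g=stack("cpc_g"),
        seed=spec.sampler.seed,
        accept_stats={k: float(np.mean([c["_acc"][k] for c in chains]))
                      for k in chains[0]["_acc"]},
    )
    if spec.sampler.chains >= 2:
        rep = diagnostics(post, warn=True)
        post.accept_stats["max_rhat"] = rep.max_rhat
    return post


# ---------------------------------------------------------------------------
# Diagnostics and fit scores
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    table: pd.DataFrame            # per parameter: rhat, ess_bulk, ess_tail, flag
    max_rhat: float
    min_ess_bulk: float
    min_ess_tail: float
    n_chains: int
    ess_target: float              # 400 per chain
    divergences: int = 0           # the estimation sampler is not Hamiltonian
    e_bfmi: float | None = None

    @property
    def converged(self) -> bool:
        return bool(np.isnan(self.max_rhat) or self.max_rhat < 1.05)

    def failing_parameters(self) -> list[str]:
        t = self.table
        return list(t.loc[t["rhat"] > 1.05, "parameter"])


def diagnostics(post: HierarchicalPosterior, warn: bool = True) -> DiagnosticsReport:
    """Rank-normalized split R-hat and bulk/tail ESS for the monitored blocks.

    Flags follow the usual thresholds: R-hat < 1.01 good, > 1.05 failure; the
    ESS target is 400 per chain.  Constant (degenerate) parameters yield NaN
    diagnostics rather than an error.
    """
    import arviz as az

    if post.n_chains < 2:
        warnings.warn("R-hat requires at least 2 chains; diagnostics unavailable",
                      stacklevel=2)
        return DiagnosticsReport(table=pd.DataFrame(), max_rhat=float("nan"),
                                 min_ess_bulk=float("nan"),
                                 min_ess_tail=float("nan"),
                                 n_chains=post.n_chains,
                                 ess_target=400.0 * post.n_chains)
    idata = post.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-parameter NaNs
        rhat = az.rhat(idata, method="rank")
        essb = az.ess(idata, method="bulk")
        esst = az.ess(idata, method="tail")
    rows = []
    for var in rhat.data_vars:
        r = np.asarray(rhat[var]).ravel()
        eb = np.asarray(essb[var]).ravel()
        et = np.asarray(esst[var]).ravel()
        for i in range(r.size):
            idx = np.unravel_index(i, np.asarray(rhat[var]).shape) if r.size > 1 else ()
            name = f"{var}[{','.join(map(str, idx))}]" if idx else var
            rows.append(dict(parameter=name, rhat=r[i], ess_bulk=eb[i],
                             ess_tail=et[i]))
    table = pd.DataFrame(rows)
    target = 400.0 * post.n_chains
    table["flag"] = np.select(
        [table["rhat"] > 1.05, table["rhat"] > 1.01],
        ["fail", "warn"], default="good",
    )
    table.loc[table["rhat"].isna(), "flag"] = "undefined"
    def _nanreduce(fun, col):
        vals = table[col].to_numpy() if len(table) else np.array([np.nan])
        return float(fun(vals)) if np.any(np.isfinite(vals)) else float("nan")

    rep = DiagnosticsReport(
        table=table,
        max_rhat=_nanreduce(np.nanmax, "rhat"),
        min_ess_bulk=_nanreduce(np.nanmin, "ess_bulk"),
        min_ess_tail=_nanreduce(np.nanmin, "ess_tail"),
        n_chains=post.n_chains,
        ess_target=target,
    )
    if warn and not rep.converged:
        bad = rep.failing_parameters()
        warnings.warn(f"possible non-convergence: R-hat > 1.05 for {bad[:10]}",
                      stacklevel=2)
    return rep


def nrmse(observed, predicted) -> float | np.ndarray:
    """Root mean squared error normalized by the mean observed value.

    1-D inputs give a scalar; (N, M) inputs give one score per column.
    """
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    if o.size == 0:
        raise ValueError("empty input")
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal shapes")
    rmse = np.sqrt(np.mean((o - p) ** 2, axis=0))
    return rmse / np.mean(o, axis=0)


def fitted_values(post: HierarchicalPosterior, data: CohortTable,
                  max_draws: int = 200) -> np.ndarray:
    """Posterior-mean expected concentrations, one row per record."""
    md = _ModelData(data, post.spec)
    beta = post.stacked("beta")
    b = post.stacked("b")
    g = post.stacked("g") if post.g is not None else None
    S = beta.shape[0]
    take = np.linspace(0, S - 1, min(max_draws, S)).astype(int)
    acc = np.zeros((md.N, post.spec.M))
    for s in take:
        st = _State(beta=beta[s], b=b[s], g=(g[s] if g is not None else None),
                    log_alpha=None, log_sigma=None, y_cpc=None)
        acc += _compute_mu(md, post.spec, st)
    return acc / take.size


def posterior_predictive_pvalues(
    post: HierarchicalPosterior,
    data: CohortTable,
    statistics: Sequence[str] = ("mean", "sd"),
    n_rep: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior predictive p-values per (concentration, statistic).

    Each replication draws one retained posterior sample, simulates a full
    replicate dataset from the Gamma observation model at that sample's
    parameters, and compares the replicate statistic with the observed one:
    p = fraction of replicates with statistic >= observed.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    stat_funs = {"mean": lambda a: a.mean(axis=0),
                 "sd": lambda a: a.std(axis=0, ddof=1)}
    for s in statistics:
        if s not in stat_funs:
            raise KeyError(f"unknown statistic {s!r}")
    md = _ModelData(data, post.spec)
    rng = np.random.default_rng(seed)
    beta, b, alpha = post.stacked("beta"), post.stacked("b"), post.stacked("alpha")
    g = post.stacked("g") if post.g is not None else None
    S = beta.shape[0]
    take = rng.integers(0, S, size=n_rep)
    obs = {s: stat_funs[s](md.Y) for s in statistics}
    ge_counts = {s: np.zeros(post.spec.M) for s in statistics}
    for s_idx in take:
        st = _State(beta=beta[s_idx], b=b[s_idx],
                    g=(g[s_idx] if g is not None else None),
                    log_alpha=None, log_sigma=None, y_cpc=None)
        mu = _compute_mu(md, post.spec, st)
        mu = np.maximum(mu, 1e-9)
        rep = rng.gamma(shape=alpha[s_idx], scale=mu / alpha[s_idx])
        for s in statistics:
            ge_counts[s] += stat_funs[s](rep) >= obs[s]
    rows = []
    for s in statistics:
        for mi, m in enumerate(post.spec.concentrations):
            rows.append(dict(concentration=m, statistic=s,
                             p_value=ge_counts[s][mi] / n_rep))
    return pd.DataFrame(rows)
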