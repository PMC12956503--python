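"""Synthetic cohorts and personal models with known ground truth.

The cohort generator is the exact generative mirror of the estimation model:
predictors are drawn i.i.d. standard normal (binary covariates Bernoulli),
subject-effect vectors from a multivariate normal with a T*C*T covariance
(C ~ LKJ), and concentrations from the identity-link Gamma observation model.
Two presets emulate the structure of the studies the method targets: a
prediabetes-style cohort (106 subjects x 4 visits, 5 concentrations, 15
nutrients) and a dialysis-style cohort (37 subjects x 2 visits, 3
concentrations, 13 nutrients, nested treatment groups).  Per-concentration
Gamma shapes in the presets are chosen to mimic the *ranking* of predictive
error across outcomes (tight for glucose-like, loose for phosphate-like), not
any particular reported value.

The personal-model generator builds recommendation-stage inference units with
controlled feasibility: a recorded diet Q* whose expected concentrations sit
inside all adjusted limits (feasible preset), or a baseline shifted so no diet
in the guideline box can reach one concentration's limits (infeasible preset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._mcmc import sample_lkj
from .diet_inference import compute_adjusted_limits
from .gamma_sur import HierarchicalPosterior, build_covariance
from .personal_models import PersonalModel
from .study_data import CohortTable, ColumnSchema, NutrientSpec, from_frame

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "simulate_cohort",
    "sysdimet_like_config",
    "dialysis_like_config",
    "PersonalModelConfig",
    "simulate_personal_model",
    "recovery_report",
]


@dataclass(frozen=True)
class CohortConfig:
    """Dimensions and effect scales of a simulated cohort.

    Effect magnitudes are relative to the concentration intercepts so the same
    config works for unit-scale and natural-unit outcomes: a fixed or varying
    coefficient has sd ``rel_effect * intercept_m`` and a random-effect sd is
    ``rel_sigma * intercept_m``.
    """

    n_subjects: int = 30
    n_visits: int = 4
    n_concentrations: int = 2
    n_nutrients: int = 3
    n_fixed: int = 1
    n_groups: int = 0
    rel_effect: float = 0.05
    rel_sigma: float = 0.03
    rel_group_sigma: float = 0.02
    alpha: tuple[float, ...] | float = 100.0
    intercepts: tuple[float, ...] | float = 10.0
    lkj_eta: float = 2.0
    concentration_names: tuple[str, ...] | None = None
    nutrient_names: tuple[str, ...] | None = None
    fixed_names: tuple[str, ...] | None = None
    # natural-unit mapping for nutrient columns; None keeps them standardized
    nutrient_means: tuple[float, ...] | None = None
    nutrient_sds: tuple[float, ...] | None = None
    positivity_margin: float = 0.05   # reject draws with mu < margin*intercept
    max_retries: int = 20

    def names(self):
        concs = self.concentration_names or tuple(
            f"conc_{i + 1}" for i in range(self.n_concentrations))
        nuts = self.nutrient_names or tuple(
            f"nutrient_{i + 1}" for i in range(self.n_nutrients))
        fixed = self.fixed_names or tuple(
            f"fixed_{i + 1}" for i in range(self.n_fixed))
        return concs, nuts, fixed


@dataclass
class GroundTruth:
    """Everything the generator used, for parameter-recovery comparisons."""

    beta: np.ndarray        # (M, 1+F+J)
    b: np.ndarray           # (K, M, 1+J)
    alpha: np.ndarray       # (M,)
    sigma: np.ndarray       # (d_b,)
    corr: np.ndarray        # (d_b, d_b)
    Sigma: np.ndarray       # (d_b, d_b)
    g: np.ndarray | None = None
    sigma_g: np.ndarray | None = None
    corr_g: np.ndarray | None = None
    config: CohortConfig | None = None
    seed: int | None = None


def simulate_cohort(config: CohortConfig, seed: int) -> tuple[CohortTable, GroundTruth]:
    """Simulate a cohort from the hierarchical Gamma model with known truth.

    The generator enforces a positivity margin on every expected value
    (identity link): effect sets that drive any mu below
    ``positivity_margin * intercept`` are redrawn, and after ``max_retries``
    failures an error is raised.
    """
    rng = np.random.default_rng(seed)
    K, n, M = config.n_subjects, config.n_visits, config.n_concentrations
    J, F, G = config.n_nutrients, config.n_fixed, config.n_groups
    concs, nuts, fixed = config.names()
    inter = np.broadcast_to(np.atleast_1d(np.asarray(config.intercepts, float)),
                            (M,)).copy()
    alpha = np.broadcast_to(np.atleast_1d(np.asarray(config.alpha, float)),
                            (M,)).copy()
    d_b = M * (J + 1)
    N = K * n

    # binary fixed covariates in {0,1} (sex / medication style)
    X_subj = rng.integers(0, 2, size=(K, F)).astype(float) if F else np.zeros((K, 0))
    Z = rng.normal(size=(N, J))
    sidx = np.repeat(np.arange(K), n)
    gidx_subj = (np.arange(K) % G) if G else None

    for attempt in range(config.max_retries):
        beta = np.zeros((M, 1 + F + J))
        beta[:, 0] = inter
        beta[:, 1:] = rng.normal(size=(M, F + J)) * (config.rel_effect * inter)[:, None]

        # a tiny floor keeps the covariance factorization valid when the
        # requested random-effect scale is zero (noise-free limit)
        sigma = np.maximum(
            config.rel_sigma * np.repeat(inter, J + 1)
            * rng.uniform(0.5, 1.5, size=d_b), 1e-9 * np.repeat(inter, J + 1))
        corr = sample_lkj(d_b, config.lkj_eta, rng)
        Sigma = build_covariance(sigma, corr)
        b_flat = rng.multivariate_normal(np.zeros(d_b), Sigma, size=K,
                                         method="cholesky")
        b = b_flat.reshape(K, M, J + 1)

        g = sigma_g = corr_g = None
        if G:
            sigma_g = (config.rel_group_sigma * np.repeat(inter, J + 1)
                       * rng.uniform(0.5, 1.5, size=d_b))
            corr_g = sample_lkj(d_b, config.lkj_eta, rng)
            g = rng.multivariate_normal(
                np.zeros(d_b), build_covariance(sigma_g, corr_g), size=G,
                method="cholesky").reshape(G, M, J + 1)

        mu = (beta[:, 0][None, :] + X_subj[sidx] @ beta[:, 1:1 + F].T
              + Z @ beta[:, 1 + F:].T + b[sidx, :, 0]
              + np.einsum("nj,nmj->nm", Z, b[sidx][:, :, 1:]))
        if G:
            gi = gidx_subj[sidx]
            mu += g[gi, :, 0] + np.einsum("nj,nmj->nm", Z, g[gi][:, :, 1:])
        if np.all(mu > config.positivity_margin * inter[None, :]):
            break
    else:
        raise RuntimeError(
            "could not satisfy the positivity margin; lower rel_effect or "
            "rel_sigma, or raise the intercepts")

    Y = rng.gamma(shape=alpha[None, :], scale=mu / alpha[None, :])

    data = {"subject": [f"S{k + 1:03d}" for k in sidx],
            "visit": np.tile(np.arange(1, n + 1), K)}
    if G:
        data["group"] = [f"G{gidx_subj[k] + 1}" for k in sidx]
    for fi, name in enumerate(fixed):
        data[name] = X_subj[sidx, fi]
    natural = config.nutrient_means is not None
    for ji, name in enumerate(nuts):
        col = Z[:, ji]
        if natural:
            col = config.nutrient_means[ji] + config.nutrient_sds[ji] * col
        data[name] = col
    for mi, name in enumerate(concs):
        data[name] = Y[:, mi]

    schema = ColumnSchema(
        subject="subject", visit="visit", group=("group" if G else None),
        fixed=fixed, nutrients=nuts, concentrations=concs,
    )
    table = from_frame(pd.DataFrame(data), schema)
    table.standardized = not natural
    truth = GroundTruth(beta=beta, b=b, alpha=alpha, sigma=sigma, corr=corr,
                        Sigma=Sigma, g=g, sigma_g=sigma_g, corr_g=corr_g,
                        config=config, seed=seed)
    return table, truth


def sysdimet_like_config() -> CohortConfig:
    """Prediabetes-style preset: K=106, 4 visits, M=5, R=15, 2 fixed covariates.

    Nutrient means/sds follow the published study summaries; Gamma shapes are
    ranked to give a tight glucose-like fit and a looser insulin-like fit.
    """
    return CohortConfig(
        n_subjects=106, n_visits=4, n_concentrations=5, n_nutrients=15,
        n_fixed=2, n_groups=0,
        concentration_names=("hdl_cholesterol", "ldl_cholesterol",
                             "total_cholesterol", "insulin", "glucose"),
        nutrient_names=("protein", "carbohydrates", "sucrose", "fiber", "safa",
                        "mufa", "pufa", "linoleic_acid", "alpha_linolenic_acid",
                        "epa", "dha", "cholesterol", "folate", "vitamin_d",
                        "vitamin_c"),
        fixed_names=("sex", "cholesterol_medication"),
        nutrient_means=(18.5, 47.4, 6.0, 19.0, 11.8, 9.7, 4.7, 3.3, 0.7, 0.1,
                        0.2, 247.0, 229.0, 6.7, 101.0),
        nutrient_sds=(3.0, 6.1, 2.6, 5.6, 2.9, 2.7, 1.5, 1.1, 0.3, 0.1, 0.2,
                      99.0, 74.0, 3.5, 66.0),
        intercepts=(1.45, 3.2, 5.2, 12.1, 6.0),
        alpha=(400.0, 400.0, 400.0, 50.0, 1100.0),
        rel_effect=0.03, rel_sigma=0.02,
    )


def dialysis_like_config() -> CohortConfig:
    """Kidney-dysfunction-style preset: K=37, 2 visits, M=3, R=13, nested groups."""
    return CohortConfig(
        n_subjects=37, n_visits=2, n_concentrations=3, n_nutrients=13,
        n_fixed=7, n_groups=2,
        concentration_names=("potassium", "phosphate", "albumin"),
        nutrient_names=("protein", "carbohydrates", "sucrose", "fiber", "safa",
                        "mufa", "pufa", "potassium_intake", "phosphorus",
                        "calcium", "salt", "water", "vitamin_d"),
        fixed_names=("sex", "lipid_medication", "phosphate_binder",
                     "diabetes_medication", "renavit", "calcifediol",
                     "age_std"),
        nutrient_means=(15.1, 43.6, 9.2, 16.7, 13.7, 14.7, 7.1, 2785.0, 1042.0,
                        570.0, 6560.0, 1804.0, 7.6),
        nutrient_sds=(3.0, 7.7, 4.4, 6.2, 4.1, 3.6, 2.4, 961.0, 379.0, 301.0,
                      3099.0, 607.0, 5.0),
        intercepts=(4.4, 1.66, 34.0),
        alpha=(45.0, 10.0, 31.0),
        rel_effect=0.03, rel_sigma=0.02,
    )


# ---------------------------------------------------------------------------
# Direct personal-model construction (inference-only tests)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersonalModelConfig:
    """Controlled-feasibility construction of a recommendation-stage unit."""

    n_concentrations: int = 2
    n_nutrients: int = 3
    alpha: tuple[float, ...] | float = 200.0
    targets: tuple[tuple[float, float], ...] | None = None  # (Yml, Ymu) per m
    specs: tuple[NutrientSpec, ...] | None = None
    # published personal fits report normalized effects from ~0.3 up to ~7.7;
    # unit-scale draws put the synthetic models in that regime
    effect_scale: float = 1.0
    confidence: float = 0.9
    feasible: bool = True
    infeasible_gap: float = 0.5   # shortfall of the best b-score sum, in mu units

    def resolved_specs(self) -> tuple[NutrientSpec, ...]:
        if self.specs is not None:
            return self.specs
        return tuple(
            NutrientSpec(name=f"nutrient_{r + 1}", lower=10.0, upper=30.0,
                         recommended=20.0, units="g/d")
            for r in range(self.n_nutrients)
        )

    def resolved_targets(self) -> tuple[tuple[float, float], ...]:
        if self.targets is not None:
            return self.targets
        return tuple((8.0, 12.0) for _ in range(self.n_concentrations))


def simulate_personal_model(
    config: PersonalModelConfig, seed: int
) -> tuple[PersonalModel, dict]:
    """Build a personal model whose feasibility is known by construction.

    Feasible preset: a recorded diet Q* (drawn inside the guideline box) maps
    exactly to the midpoint of every adjusted limit pair.  Infeasible preset:
    the first concentration's baseline is shifted so even the most favorable
    diet in the box stays ``infeasible_gap`` below its adjusted lower limit.
    Returns the model and an info dict with Q*, the adjusted limits, and the
    targets.
    """
    rng = np.random.default_rng(seed)
    M, R = config.n_concentrations, config.n_nutrients
    specs = config.resolved_specs()
    targets = config.resolved_targets()
    if len(targets) != M:
        raise ValueError("one (Yml, Ymu) pair per concentration required")
    alpha = np.broadcast_to(np.atleast_1d(np.asarray(config.alpha, float)),
                            (M,)).copy()

    lo = np.array([s.lower for s in specs])
    hi = np.array([s.upper for s in specs])
    mean = (lo + hi) / 2.0
    sd = (hi - lo) / 4.0
    effects = rng.normal(size=(M, R)) * config.effect_scale
    current = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))

    # adjusted limits depend only on alpha and the targets
    dummy = PersonalModel(
        subject_id="synthetic", concentrations=[f"conc_{m + 1}" for m in range(M)],
        nutrients=[s.name for s in specs], alpha=alpha,
        baseline=np.ones(M), effects=effects, current_intake=current,
        intake_mean=mean, intake_sd=sd,
    )
    target_map = {m: t for m, t in zip(dummy.concentrations, targets)}
    lims = compute_adjusted_limits(dummy, target_map, config.confidence,
                                   strict=False)
    if not lims.all_feasible:
        raise ValueError("target ranges are infeasible for the given shapes; "
                         "widen the targets or raise alpha")

    q_star = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
    z_star = (q_star - mean) / sd
    mid = (lims.mu_lower + lims.mu_upper) / 2.0
    baseline = mid - effects @ z_star

    if not config.feasible:
        # push concentration 0 out of reach: even the best diet in the box
        # falls short of its adjusted lower limit by infeasible_gap
        z_lo, z_hi = (lo - mean) / sd, (hi - mean) / sd
        best = np.sum(np.maximum(effects[0] * z_lo, effects[0] * z_hi))
        baseline[0] = lims.mu_lower[0] - config.infeasible_gap - best

    pm = PersonalModel(
        subject_id="synthetic",
        concentrations=dummy.concentrations, nutrients=dummy.nutrients,
        alpha=alpha, baseline=baseline, effects=effects,
        current_intake=current, intake_mean=mean, intake_sd=sd,
        units=[s.units for s in specs],
    )
    info = {"q_star": q_star, "limits": lims, "targets": target_map,
            "specs": list(specs), "seed": seed}
    return pm, info


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------

def recovery_report(truth: GroundTruth, post: HierarchicalPosterior) -> pd.DataFrame:
    """Bias, RMSE and 50%/90% interval coverage per recovered parameter.

    Covers fixed effects (beta), Gamma shapes, and random-effect sds.  Raises
    on dimension mismatch.
    """
    rows = []

    def add(name, true_val, draws):
        mean = draws.mean()
        rows.append(dict(
            parameter=name, truth=true_val, post_mean=mean,
            post_sd=draws.std(ddof=1),
            bias=mean - true_val, rmse=np.sqrt(np.mean((draws - true_val) ** 2)),
            cover50=bool(np.quantile(draws, 0.25) < true_val
                         < np.quantile(draws, 0.75)),
            cover90=bool(np.quantile(draws, 0.05) < true_val
                         < np.quantile(draws, 0.95)),
        ))

    beta = post.stacked("beta")
    if beta.shape[1:] != truth.beta.shape:
        raise ValueError("posterior/truth dimension mismatch for beta")
    names = post.predictor_names()
    for mi, m in enumerate(post.spec.concentrations):
        for pi, p in enumerate(names):
            add(f"beta[{m},{p}]", truth.beta[mi, pi], beta[:, mi, pi])
    alpha = post.stacked("alpha")
    for mi, m in enumerate(post.spec.concentrations):
        add(f"alpha[{m}]", truth.alpha[mi], alpha[:, mi])
    sigma = post.stacked("sigma")
    if sigma.shape[1] != truth.sigma.size:
        raise ValueError("posterior/truth dimension mismatch for sigma")
    for i in range(truth.sigma.size):
        add(f"sigma[{i}]", truth.sigma[i], sigma[:, i])
    return pd.DataFrame(rows)
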