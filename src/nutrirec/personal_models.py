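"""Per-subject inference units extracted from the fitted hierarchical posterior.

A personal model collapses the posterior into what the recommendation stage
needs for one subject: combined nutrient effects (population + subject
deviation) per concentration, the Gamma shape parameters that carry predictive
uncertainty, the subject's current intake, and the baseline contribution of
everything that is not modified during inference.  It is serializable to
GraphML — nutrient and concentration nodes with directed effect edges — so
recommendations and sensitivity analyses can run without the original cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .gamma_sur import HierarchicalPosterior
from .study_data import CohortTable, StandardizationParams

__all__ = [
    "PersonalModel",
    "ContributionDecomposition",
    "extract_personal_model",
    "baseline_and_contributions",
    "write_graphml",
    "read_graphml",
]


@dataclass
class PersonalModel:
    """One subject's nutrient-response model, sufficient for diet inference.

    ``effects[m, r]`` is the combined (population + subject) coefficient of
    modifiable nutrient ``r`` on concentration ``m`` on the standardized
    intake scale.  ``baseline[m]`` is the contribution of the intercepts,
    fixed covariates, and unmodified nutrients evaluated at the subject's
    current record, so that the expected concentration under a proposed diet
    Q is ``baseline + effects @ z(Q)``.
    """

    subject_id: str
    concentrations: list[str]
    nutrients: list[str]                 # modifiable nutrients (R)
    alpha: np.ndarray                    # (M,) Gamma shapes
    baseline: np.ndarray                 # (M,)
    effects: np.ndarray                  # (M, R) on z-scale
    current_intake: np.ndarray           # (R,) natural units
    intake_mean: np.ndarray              # (R,) standardization means
    intake_sd: np.ndarray                # (R,) standardization sds (> 0)
    units: list[str] = field(default_factory=list)
    summary: str = "mean"

    def __post_init__(self):
        M, R = len(self.concentrations), len(self.nutrients)
        self.alpha = np.asarray(self.alpha, float).reshape(M)
        self.baseline = np.asarray(self.baseline, float).reshape(M)
        self.effects = np.asarray(self.effects, float).reshape(M, R)
        self.current_intake = np.asarray(self.current_intake, float).reshape(R)
        self.intake_mean = np.asarray(self.intake_mean, float).reshape(R)
        self.intake_sd = np.asarray(self.intake_sd, float).reshape(R)
        if not self.units:
            self.units = [""] * R
        if np.any(self.alpha <= 0):
            raise ValueError("Gamma shapes must be positive")
        if np.any(self.intake_sd <= 0):
            raise ValueError("intake standardization sds must be positive")

    @property
    def M(self) -> int:
        return len(self.concentrations)

    @property
    def R(self) -> int:
        return len(self.nutrients)

    def z(self, intakes: np.ndarray) -> np.ndarray:
        """Natural-unit intakes -> standardized scale."""
        return (np.asarray(intakes, float) - self.intake_mean) / self.intake_sd

    def current_z(self) -> np.ndarray:
        return self.z(self.current_intake)


@dataclass
class ContributionDecomposition:
    """Exact additive split of a prediction: baseline + one term per nutrient."""

    concentrations: list[str]
    nutrients: list[str]
    baseline: np.ndarray        # (M,)
    contributions: np.ndarray   # (M, R) signed
    total: np.ndarray           # (M,) == baseline + contributions.sum(1)


def extract_personal_model(
    post: HierarchicalPosterior,
    data: CohortTable,
    params: StandardizationParams,
    subject_id,
    modifiable: list[str],
    summary: str = "mean",
) -> PersonalModel:
    """Point-summarize one subject's combined effects from the posterior.

    The subject's "current diet" is their most recent observed record.  With a
    mean summary the combined coefficient equals summary(beta) + summary(b)
    exactly; for the median the sum is summarized jointly (medians do not
    distribute over sums).
    """
    spec = post.spec
    if subject_id not in data.subject_ids:
        raise KeyError(f"unknown subject {subject_id!r}")
    k = post.subject_ids.index(subject_id)
    unknown = [n for n in modifiable if n not in spec.varying_predictors]
    if unknown:
        raise KeyError(f"modifiable nutrients not in the model: {unknown}")

    summarize = {"mean": lambda a: a.mean(axis=0),
                 "median": lambda a: np.median(a, axis=0)}[summary]

    beta = post.stacked("beta")       # (S, M, 1+F+J)
    b_k = post.stacked("b")[:, k]     # (S, M, 1+J)
    alpha_hat = summarize(post.stacked("alpha"))

    F = spec.F
    varying = list(spec.varying_predictors)
    mod_idx = [varying.index(n) for n in modifiable]
    unmod_idx = [j for j in range(len(varying)) if j not in mod_idx]

    # combined coefficients theta = beta + b, summarized draw-wise
    theta_draws = np.concatenate(
        [beta[:, :, :1] + b_k[:, :, :1],                     # intercept
         beta[:, :, 1 + F:] + b_k[:, :, 1:]], axis=2)        # varying
    if post.g is not None and data.schema.group:
        grp = data.subject_rows(subject_id).iloc[0][data.schema.group]
        gi = post.group_ids.index(str(grp)) if isinstance(post.group_ids[0], str) \
            else post.group_ids.index(grp)
        g_k = post.stacked("g")[:, gi]
        theta_draws = theta_draws + np.concatenate(
            [g_k[:, :, :1], g_k[:, :, 1:]], axis=2)
    theta = summarize(theta_draws)                           # (M, 1+J)
    beta_fixed = summarize(beta[:, :, 1:1 + F])              # (M, F)

    row = data.latest_record(subject_id)
    x_fixed = row[list(spec.fixed_predictors)].to_numpy(float) if F else np.zeros(0)
    z_all = row[varying].to_numpy(float)  # data is standardized

    baseline = theta[:, 0].copy()
    if F:
        baseline += beta_fixed @ x_fixed
    if unmod_idx:
        baseline += theta[:, 1:][:, unmod_idx] @ z_all[unmod_idx]

    sub = params.subset(modifiable)
    mean = np.array([sub.mean[n] for n in modifiable])
    sd = np.array([sub.sd[n] for n in modifiable])
    current_nat = np.array([
        params.inverse(n, z_all[varying.index(n)]) for n in modifiable
    ])

    return PersonalModel(
        subject_id=str(subject_id),
        concentrations=list(spec.concentrations),
        nutrients=list(modifiable),
        alpha=alpha_hat,
        baseline=baseline,
        effects=theta[:, 1:][:, mod_idx],
        current_intake=current_nat,
        intake_mean=mean,
        intake_sd=sd,
        summary=summary,
    )


def baseline_and_contributions(pm: PersonalModel, intakes) -> ContributionDecomposition:
    """Decompose the prediction at given natural-unit intakes.

    Conservation holds exactly: baseline + sum of contributions == prediction.
    """
    if isinstance(intakes, dict):
        missing = [n for n in pm.nutrients if n not in intakes]
        if missing:
            raise KeyError(f"missing intake values for {missing}")
        q = np.array([intakes[n] for n in pm.nutrients], float)
    else:
        q = np.asarray(intakes, float).reshape(pm.R)
    contrib = pm.effects * pm.z(q)[None, :]
    total = pm.baseline + contrib.sum(axis=1)
    return ContributionDecomposition(
        concentrations=list(pm.concentrations), nutrients=list(pm.nutrients),
        baseline=pm.baseline.copy(), contributions=contrib, total=total,
    )


# ---------------------------------------------------------------------------
# GraphML serialization
# ---------------------------------------------------------------------------
# Attribute vocabulary (fixed so files interoperate):
#   graph:  subject_id, summary, concentration_order, nutrient_order (JSON lists)
#   concentration node: kind="concentration", alpha, baseline
#   nutrient node: kind="nutrient", current_intake, intake_mean, intake_sd, units
#   edge nutrient -> concentration: effect

def _to_graph(pm: PersonalModel) -> nx.DiGraph:
    G = nx.DiGraph(
        subject_id=pm.subject_id,
        summary=pm.summary,
        concentration_order=json.dumps(pm.concentrations),
        nutrient_order=json.dumps(pm.nutrients),
    )
    for mi, m in enumerate(pm.concentrations):
        G.add_node(m, kind="concentration", alpha=float(pm.alpha[mi]),
                   baseline=float(pm.baseline[mi]))
    for ri, r in enumerate(pm.nutrients):
        G.add_node(r, kind="nutrient",
                   current_intake=float(pm.current_intake[ri]),
                   intake_mean=float(pm.intake_mean[ri]),
                   intake_sd=float(pm.intake_sd[ri]),
                   units=pm.units[ri])
    for ri, r in enumerate(pm.nutrients):
        for mi, m in enumerate(pm.concentrations):
            G.add_edge(r, m, effect=float(pm.effects[mi, ri]))
    return G


def write_graphml(pm: PersonalModel, path) -> None:
    nx.write_graphml(_to_graph(pm), Path(path))


def read_graphml(path) -> PersonalModel:
    """Load a personal model; missing required attributes raise a named error."""
    G = nx.read_graphml(Path(path))
    try:
        concs = json.loads(G.graph["concentration_order"])
        nuts = json.loads(G.graph["nutrient_order"])
    except KeyError as e:  # pragma: no cover - malformed file
        raise ValueError(f"graph attribute {e} missing from {path}") from e

    def node_attr(n, key):
        try:
            return G.nodes[n][key]
        except KeyError:
            raise ValueError(f"node {n!r} in {path} is missing attribute {key!r}")

    alpha = [node_attr(m, "alpha") for m in concs]
    baseline = [node_attr(m, "baseline") for m in concs]
    current = [node_attr(r, "current_intake") for r in nuts]
    mean = [node_attr(r, "intake_mean") for r in nuts]
    sd = [node_attr(r, "intake_sd") for r in nuts]
    units = [G.nodes[r].get("units", "") for r in nuts]
    effects = np.zeros((len(concs), len(nuts)))
    for ri, r in enumerate(nuts):
        for mi, m in enumerate(concs):
            try:
                effects[mi, ri] = G.edges[r, m]["effect"]
            except KeyError:
                raise ValueError(f"edge {r!r}->{m!r} in {path} missing 'effect'")
    return PersonalModel(
        subject_id=G.graph.get("subject_id", ""),
        concentrations=concs, nutrients=nuts,
        alpha=np.asarray(alpha), baseline=np.asarray(baseline), effects=effects,
        current_intake=np.asarray(current), intake_mean=np.asarray(mean),
        intake_sd=np.asarray(sd), units=units,
        summary=G.graph.get("summary", "mean"),
    )
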