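"""Tabular outputs of the recommendation pipeline.

Produces the recommendation summary table (current intake, recommended intake,
90% credible interval, direction and >30%-change flag) and per-subject
waterfall data: the expected concentration built up from the baseline through
one ordered contribution per nutrient, whose cumulative sum reproduces the
predicted value exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .diet_inference import RecommendationResult
from .personal_models import PersonalModel, baseline_and_contributions

__all__ = ["recommendation_table", "waterfall_table", "report_recommendations"]


def recommendation_table(results: Sequence[RecommendationResult]) -> pd.DataFrame:
    """Stack per-subject recommendation summaries into one table."""
    frames = []
    for res in results:
        df = res.summary.copy()
        df.insert(0, "subject_id", res.subject_id)
        df["direction"] = np.where(df["recommended"] > df["current"],
                                   "increase", "decrease")
        df.loc[np.isclose(df["recommended"], df["current"], rtol=1e-3),
               "direction"] = "keep"
        df["feasible"] = res.feasible
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def waterfall_table(res: RecommendationResult, pm: PersonalModel) -> pd.DataFrame:
    """Ordered contribution breakdown at the posterior-mean diet.

    One block of rows per concentration: baseline, one row per nutrient in
    decreasing order of mean absolute contribution, and the final expected
    value.  The cumulative column reproduces the prediction exactly.
    """
    if list(pm.nutrients) != list(res.nutrients):
        raise ValueError("personal model and result describe different nutrients")
    q_mean = res.summary["recommended"].to_numpy()
    dec = baseline_and_contributions(pm, q_mean)
    order = np.argsort(-np.mean(np.abs(dec.contributions), axis=0))
    rows = []
    for mi, m in enumerate(pm.concentrations):
        cum = dec.baseline[mi]
        rows.append(dict(subject_id=res.subject_id, concentration=m,
                         step="baseline", contribution=dec.baseline[mi],
                         cumulative=cum,
                         mu_lower=res.limits.mu_lower[mi],
                         mu_upper=res.limits.mu_upper[mi]))
        for r in order:
            cum += dec.contributions[mi, r]
            rows.append(dict(subject_id=res.subject_id, concentration=m,
                             step=pm.nutrients[r],
                             contribution=dec.contributions[mi, r],
                             cumulative=cum,
                             mu_lower=res.limits.mu_lower[mi],
                             mu_upper=res.limits.mu_upper[mi]))
        rows.append(dict(subject_id=res.subject_id, concentration=m,
                         step="final", contribution=0.0, cumulative=cum,
                         mu_lower=res.limits.mu_lower[mi],
                         mu_upper=res.limits.mu_upper[mi]))
    return pd.DataFrame(rows)


def report_recommendations(
    results: Sequence[RecommendationResult], pms: Sequence[PersonalModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recommendation table plus stacked waterfall data for all subjects."""
    table = recommendation_table(results)
    wf = pd.concat([waterfall_table(r, p) for r, p in zip(results, pms)],
                   ignore_index=True)
    return table, wf
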