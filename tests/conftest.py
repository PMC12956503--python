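"""Shared fixtures: one small fitted model reused across the estimation tests."""

import warnings

import numpy as np
import pytest

from nutrirec.gamma_sur import ModelSpec, SamplerConfig, fit_hierarchical
from nutrirec.synthetic_cohort import CohortConfig, simulate_cohort


SMALL_CFG = CohortConfig(
    n_subjects=30, n_visits=4, n_concentrations=2, n_nutrients=3, n_fixed=1,
    rel_effect=0.05, rel_sigma=0.03, alpha=100.0, intercepts=10.0,
)


@pytest.fixture(scope="session")
def small_cohort():
    table, truth = simulate_cohort(SMALL_CFG, seed=7)
    return table, truth


@pytest.fixture(scope="session")
def small_model_spec():
    concs, nuts, fixed = SMALL_CFG.names()
    return ModelSpec(
        concentrations=concs, varying_predictors=nuts, fixed_predictors=fixed,
        sampler=SamplerConfig(chains=2, draws=800, warmup=800, seed=11),
    )


@pytest.fixture(scope="session")
def fitted(small_cohort, small_model_spec):
    """One fitted posterior shared by the estimation-stage tests."""
    table, truth = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit_hierarchical(table, small_model_spec)
    return post, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
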