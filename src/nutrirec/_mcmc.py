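"""Low-level MCMC utilities shared by the estimation and recommendation stages.

Correlation matrices are parameterized through canonical partial correlations
(CPCs) of the C-vine: an unconstrained vector ``y`` maps through ``tanh`` to
partial correlations in (-1, 1) and then to the Cholesky factor of a valid
correlation matrix.  Under this map the LKJ(eta) prior factorizes into
independent scaled-Beta densities, one per CPC, with the Beta parameter
depending only on the vine tree level — which makes prior evaluation and exact
prior sampling trivial.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "n_cpc",
    "cpc_to_chol",
    "chol_to_corr",
    "lkj_cpc_logprior",
    "sample_lkj",
    "StepSizeAdapter",
]


def n_cpc(d: int) -> int:
    return d * (d - 1) // 2


def _cpc_matrix(z_vec: np.ndarray, d: int) -> np.ndarray:
    """Unpack the flat CPC vector into a strictly-lower-triangular matrix."""
    z = np.zeros((d, d))
    z[np.tril_indices(d, -1)] = z_vec
    return z


def cpc_to_chol(z_vec: np.ndarray, d: int) -> np.ndarray:
    """Cholesky factor of the correlation matrix implied by CPCs in (-1,1).

    Row ``i`` of the result has unit Euclidean norm, so ``L @ L.T`` is a
    correlation matrix for any CPC vector.
    """
    z = _cpc_matrix(np.asarray(z_vec, float), d)
    # rem[i, j] = prod_{k < j} (1 - z[i, k]^2), the remaining squared row norm
    f = np.ones((d, d))
    il = np.tril_indices(d, -1)
    f[il] = 1.0 - z[il] ** 2
    rem = np.ones((d, d))
    rem[:, 1:] = np.cumprod(f[:, :-1], axis=1)
    L = np.tril(z) * np.sqrt(rem)
    L[np.diag_indices(d)] = np.sqrt(rem[np.diag_indices(d)])
    return L


def chol_to_corr(L: np.ndarray) -> np.ndarray:
    return L @ L.T


def _tree_level_beta_params(d: int, eta: float) -> np.ndarray:
    """Beta(a, a) parameter per CPC, ordered like tril_indices(d, -1).

    A CPC in column ``j`` (0-based) of the lower triangle sits at vine tree
    level ``j + 1``; under LKJ(eta) it follows 2*Beta(a, a) - 1 with
    ``a = eta + (d - 2 - j) / 2``.
    """
    rows, cols = np.tril_indices(d, -1)
    return eta + (d - 2 - cols) / 2.0


def lkj_cpc_logprior(y_vec: np.ndarray, d: int, eta: float = 2.0) -> float:
    """Log prior of unconstrained CPCs ``y`` (z = tanh(y)) under LKJ(eta).

    Includes the tanh Jacobian; constant Beta normalizers are dropped.
    """
    a = _tree_level_beta_params(d, eta)
    z = np.tanh(np.asarray(y_vec, float))
    # (a-1)*log(1-z^2) from the scaled Beta + log(1-z^2) Jacobian
    return float(np.sum(a * np.log1p(-z**2)))


def sample_lkj(d: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta) via the C-vine construction."""
    a = _tree_level_beta_params(d, eta)
    z = 2.0 * rng.beta(a, a) - 1.0
    return chol_to_corr(cpc_to_chol(z, d))


class StepSizeAdapter:
    """Robbins-Monro adaptation of a log step size toward a target acceptance.

    Adaptation is frozen once :meth:`freeze` is called (end of warmup), which
    keeps the chain Markovian afterwards.
    """

    def __init__(self, init_scale: float = 0.1, target: float = 0.25,
                 kappa: float = 0.6):
        self.log_scale = float(np.log(init_scale))
        self.target = target
        self.kappa = kappa
        self.t = 0
        self.frozen = False

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accept_rate: float) -> None:
        if self.frozen:
            return
        self.t += 1
        gamma = self.t ** (-self.kappa)
        self.log_scale += gamma * (accept_rate - self.target)
        self.log_scale = float(np.clip(self.log_scale, -15.0, 5.0))

    def freeze(self) -> None:
        self.frozen = True


class VectorStepAdapter:
    """Per-coordinate Robbins-Monro step sizes (for coordinate-wise moves)."""

    def __init__(self, dim: int, init_scale: float = 0.1, target: float = 0.44,
                 kappa: float = 0.6):
        self.log_scale = np.full(dim, np.log(init_scale))
        self.target = target
        self.kappa = kappa
        self.t = 0
        self.frozen = False

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted: np.ndarray) -> None:
        if self.frozen:
            return
        self.t += 1
        gamma = self.t ** (-self.kappa)
        self.log_scale += gamma * (np.asarray(accepted, float) - self.target)
        np.clip(self.log_scale, -15.0, 5.0, out=self.log_scale)

    def freeze(self) -> None:
        self.frozen = True
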