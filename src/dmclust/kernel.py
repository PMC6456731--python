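"""Numerically stable Dirichlet-multinomial computations.

Everything here works in log space through ``gammaln``; realistic per-cell UMI
totals (10^3-10^4) overflow any linear-space evaluation of the collapsed
multinomial-Dirichlet mass, so ratios Gamma(x+a)/Gamma(a) are always formed as
log-gamma differences.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "DirichletParamBlock",
    "MixingProportions",
    "log_dm_pmf",
    "assignment_log_weights",
    "normalize_log_weights",
    "log_joint",
    "log_prior_alpha",
]


class DirichletParamBlock:
    """Per-individual, per-cluster Dirichlet concentrations.

    Parameters
    ----------
    alpha : ndarray of shape (L, K, G)
        Strictly positive concentration ``alpha[l, k, i]`` for gene ``i``,
        individual ``l``, cluster ``k``.

    Notes
    -----
    ``gammaln(alpha)`` and ``gammaln(alpha_sums)`` are cached because every
    assignment weight and likelihood evaluation reuses them; any in-place
    mutation of ``alpha`` must be followed by :meth:`invalidate`.
    """

    def __init__(self, alpha: np.ndarray):
        alpha = np.ascontiguousarray(alpha, dtype=float)
        if alpha.ndim != 3:
            raise ValueError("alpha must have shape (L, K, G)")
        if not np.all(alpha > 0) or not np.all(np.isfinite(alpha)):
            raise ValueError("all Dirichlet concentrations must be finite and > 0")
        self.alpha = alpha
        self.invalidate()

    @property
    def L(self) -> int:
        return self.alpha.shape[0]

    @property
    def K(self) -> int:
        return self.alpha.shape[1]

    @property
    def G(self) -> int:
        return self.alpha.shape[2]

    def invalidate(self) -> None:
        """Recompute cached totals and log-gamma tables after mutating alpha."""
        if not np.all(self.alpha > 0):
            raise ValueError("all Dirichlet concentrations must be > 0")
        self.alpha_sums = self.alpha.sum(axis=2)
        self.lgamma_alpha = gammaln(self.alpha)
        self.lgamma_alpha_sums = gammaln(self.alpha_sums)

    def copy(self) -> "DirichletParamBlock":
        return DirichletParamBlock(self.alpha.copy())


class MixingProportions:
    """Per-individual cluster weights pi[l, k]; rows live on the simplex."""

    def __init__(self, pi: np.ndarray):
        pi = np.ascontiguousarray(pi, dtype=float)
        if pi.ndim != 2:
            raise ValueError("pi must have shape (L, K)")
        if np.any(pi < 0):
            raise ValueError("mixing proportions must be non-negative")
        rows = pi.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("each row of pi must sum to 1")
        self.pi = pi

    @property
    def L(self) -> int:
        return self.pi.shape[0]

    @property
    def K(self) -> int:
        return self.pi.shape[1]

    def log(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.pi)

    def copy(self) -> "MixingProportions":
        return MixingProportions(self.pi.copy())


def log_multinomial_coeff(x: np.ndarray) -> float:
    """log T! - sum_i log x_i! for a count vector, via gammaln."""
    x = np.asarray(x)
    return float(gammaln(x.sum() + 1) - gammaln(x + 1).sum())


def log_dm_pmf(x, alpha, include_multinomial_coefficient: bool = True) -> float:
    """Log Dirichlet-multinomial mass of count vector ``x`` under ``alpha``.

    This is the multinomial likelihood with its probability vector integrated
    against Dirichlet(alpha):

        log T! - sum log x_i!
        + sum_i [lgamma(x_i + a_i) - lgamma(a_i)]
        + lgamma(|a|) - lgamma(T + |a|)

    With ``include_multinomial_coefficient=False`` the (cluster-independent)
    coefficient is dropped, which is exact for assignment-probability ratios.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise ValueError("x and alpha must have the same length")
    if np.any(alpha <= 0):
        raise ValueError("alpha entries must be > 0")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("x must contain non-negative integers")
    a_sum = alpha.sum()
    t = x.sum()
    out = (
        gammaln(x + alpha).sum()
        - gammaln(alpha).sum()
        + gammaln(a_sum)
        - gammaln(t + a_sum)
    )
    if include_multinomial_coefficient:
        out += gammaln(t + 1) - gammaln(x + 1).sum()
    return float(out)


def assignment_log_weights(
    x,
    params: DirichletParamBlock,
    pi: MixingProportions,
    individual: int,
) -> np.ndarray:
    """Unnormalized log posterior weights over clusters for one cell.

    Entry ``k`` is ``log pi[l, k] + log DM(x | alpha[l, k])`` with the
    multinomial coefficient omitted (it cancels on normalization). A zero
    mixing weight yields ``-inf`` for that cluster, which is legitimate.
    """
    x = np.asarray(x, dtype=float)
    l = individual
    if not 0 <= l < params.L:
        raise IndexError("individual index out of range")
    a = params.alpha[l]  # (K, G)
    t = x.sum()
    w = (
        gammaln(x[None, :] + a).sum(axis=1)
        - params.lgamma_alpha[l].sum(axis=1)
        + params.lgamma_alpha_sums[l]
        - gammaln(t + params.alpha_sums[l])
    )
    return w + pi.log()[l]


def normalize_log_weights(w) -> np.ndarray:
    """Softmax of a log-weight vector; invariant to additive shifts."""
    w = np.asarray(w, dtype=float)
    if not np.any(np.isfinite(w)):
        raise FloatingPointError("all log weights are -inf; cannot normalize")
    return np.exp(w - logsumexp(w))


def log_joint(dataset, labels, params: DirichletParamBlock) -> float:
    """Joint log probability of counts and labels given alpha.

    Sum over individuals and cells of the collapsed Dirichlet-multinomial
    log-mass of each cell under its assigned cluster, multinomial coefficients
    included; individuals and cells are independent given the parameters.
    """
    total = 0.0
    for l, mat in enumerate(dataset.matrices):
        x = mat.T.astype(float)  # (C_l, G)
        z = np.asarray(labels.labels[l]) - 1
        if np.any(z < 0) or np.any(z >= params.K):
            raise ValueError("label outside 1..K")
        t = x.sum(axis=1)
        a = params.alpha[l][z]  # (C_l, G)
        total += float(
            gammaln(x + a).sum()
            - params.lgamma_alpha[l][z].sum()
            + params.lgamma_alpha_sums[l][z].sum()
            - gammaln(t + params.alpha_sums[l][z]).sum()
            + gammaln(t + 1).sum()
            - gammaln(x + 1).sum()
        )
    return total


def log_prior_alpha(params: DirichletParamBlock, mu: np.ndarray, sigma2: np.ndarray) -> float:
    """Log of the log-normal hierarchy on the concentrations.

    Each ``alpha[l, k, i]`` is log-normal with gene/cluster-level mean
    ``mu[i, k]`` and variance ``sigma2[i, k]`` shared across individuals.
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 entries must be > 0")
    la = np.log(params.alpha)  # (L, K, G)
    m = mu.T[None, :, :]  # (1, K, G)
    s2 = sigma2.T[None, :, :]
    dens = -la - 0.5 * np.log(2 * np.pi * s2) - (la - m) ** 2 / (2 * s2)
    return float(dens.sum())
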