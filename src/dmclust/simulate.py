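"""Model-based simulator for multi-individual droplet scRNA-seq counts.

Data are generated from the same hierarchy the sampler fits: gene/cluster
log-mean concentrations, per-individual concentrations drawn log-normally
around them (the variance is the individual-level heterogeneity), per-cell
Dirichlet probability vectors, and multinomial UMI counts at a specified
depth. Ground-truth labels and parameters are retained for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Union

import numpy as np

from .data import CountDataset, LabelSet, ValidationError
from .kernel import DirichletParamBlock

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "StudyDesign",
    "make_mu",
    "simulate_dataset",
    "heterogeneity_level",
    "study_design",
]


@dataclass
class SimulationConfig:
    """Generative settings.

    ``sigma2`` is the individual-level heterogeneity: the variance of the
    log-normal spread of per-individual concentrations around the
    gene/cluster mean. ``depth_model`` is either ``("fixed", T)`` or
    ``("lognormal", median, sd_of_log)`` for per-cell totals.
    """

    G: int = 100
    K: int = 3
    L: int = 10
    cells_per_individual: Union[int, Sequence[int]] = 400
    separation: float = 2.0
    mu: Optional[np.ndarray] = None            # (G, K); built from separation if None
    sigma2: Union[float, np.ndarray] = 0.1     # scalar or (G, K)
    pi_true: Optional[np.ndarray] = None       # (L, K); uniform if None
    depth_model: tuple = ("fixed", 1000)
    seed: int = 0

    def cells(self) -> List[int]:
        c = self.cells_per_individual
        if np.isscalar(c):
            return [int(c)] * self.L
        c = list(c)
        if len(c) != self.L:
            raise ValidationError("cells_per_individual length must equal L")
        return [int(v) for v in c]

    def validate(self) -> None:
        if self.G < 1 or self.K < 1 or self.L < 1:
            raise ValidationError("G, K, L must be >= 1")
        if np.any(np.asarray(self.sigma2) < 0):
            raise ValidationError("sigma2 must be >= 0")
        if min(self.cells()) < 1:
            raise ValidationError("every individual needs >= 1 cell")
        kind = self.depth_model[0]
        if kind not in ("fixed", "lognormal"):
            raise ValidationError(f"unknown depth model {kind!r}")
        if self.depth_model[1] < 1:
            raise ValidationError("depths must be >= 1")


@dataclass
class SimulatedDataset:
    dataset: CountDataset
    true_labels: LabelSet
    true_alpha: DirichletParamBlock
    true_mu: np.ndarray
    true_sigma2: np.ndarray
    true_pi: np.ndarray
    true_p: Optional[np.ndarray] = None  # pooled cells x G, if retained


def make_mu(G: int, K: int, separation: float,
            rng: np.random.Generator) -> np.ndarray:
    """Gene/cluster log-mean concentrations with disjoint signature blocks.

    A shared baseline (standard normal scaled to sd 0.5) is drawn per gene;
    each cluster then receives ``ceil(G / (2K))`` dedicated signature genes
    whose log-concentration is shifted upward by ``separation``. Zero
    separation leaves all columns identical.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    base = 0.5 * rng.standard_normal(G)
    mu = np.tile(base[:, None], (1, K))
    m = -(-G // (2 * K))  # ceil
    for k in range(K):
        lo = k * m
        hi = min(lo + m, G)
        mu[lo:hi, k] += separation
    return mu


def _draw_depths(rng: np.random.Generator, model: tuple, n: int) -> np.ndarray:
    if model[0] == "fixed":
        return np.full(n, int(model[1]))
    median, sd = model[1], model[2]
    t = np.exp(np.log(median) + sd * rng.standard_normal(n))
    return np.maximum(np.round(t), 1).astype(int)


def simulate_dataset(config: SimulationConfig,
                     keep_probabilities: bool = False) -> SimulatedDataset:
    """Draw a full synthetic cohort from the hierarchical model.

    For every gene/individual/cluster the concentration is
    ``exp(mu[i, k] + sigma[i, k] * eps)``; each cell draws a cluster label
    from its individual's mixing proportions, a gene-probability vector from
    the matching Dirichlet, and multinomial counts at its depth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, K, L = config.G, config.K, config.L

    mu = config.mu
    if mu is None:
        mu = make_mu(G, K, config.separation, rng)
    mu = np.asarray(mu, dtype=float)
    sig2 = np.broadcast_to(np.asarray(config.sigma2, dtype=float), (G, K)).copy()
    sig = np.sqrt(sig2)

    alpha = np.exp(
        mu.T[None, :, :] + sig.T[None, :, :] * rng.standard_normal((L, K, G)))
    pi = config.pi_true
    if pi is None:
        pi = np.full((L, K), 1.0 / K)
    pi = np.asarray(pi, dtype=float)

    cells = config.cells()
    matrices, labels, probs = [], [], []
    for l in range(L):
        c = cells[l]
        z = rng.choice(K, size=c, p=pi[l])
        t = _draw_depths(rng, config.depth_model, c)
        x = np.empty((c, G), dtype=np.int64)
        for j in range(c):
            p = rng.dirichlet(alpha[l, z[j]])
            x[j] = rng.multinomial(t[j], p)
            if keep_probabilities:
                probs.append(p)
        matrices.append(x.T)
        labels.append(z + 1)

    gene_ids = [f"gene{i + 1}" for i in range(G)]
    cell_ids = [[f"cell{l + 1}_{j + 1}" for j in range(cells[l])] for l in range(L)]
    indiv_ids = [f"indiv{l + 1}" for l in range(L)]
    return SimulatedDataset(
        dataset=CountDataset(matrices, gene_ids, cell_ids, indiv_ids),
        true_labels=LabelSet(labels, K),
        true_alpha=DirichletParamBlock(alpha),
        true_mu=mu,
        true_sigma2=sig2,
        true_pi=pi,
        true_p=np.vstack(probs) if keep_probabilities else None,
    )


def heterogeneity_level(x) -> float:
    """Overall individual-level heterogeneity: the mean of sigma2 over genes
    and clusters, or — given sampled concentrations — the mean over (gene,
    cluster) of the empirical across-individual variance of log alpha."""
    if isinstance(x, DirichletParamBlock):
        if x.L < 2:
            raise ValidationError("empirical heterogeneity needs >= 2 individuals")
        la = np.log(x.alpha)  # (L, K, G)
        return float(la.var(axis=0, ddof=1).mean())
    return float(np.mean(np.asarray(x, dtype=float)))


@dataclass
class StudyDesign:
    """A preset simulation plus the parameter swept across replicates."""

    base: SimulationConfig
    sweep_param: str
    sweep_values: list


_DESIGNS = {
    # clustering accuracy vs. individual-level heterogeneity:
    # 10 individuals, 400 cells each, sigma2 swept
    "heterogeneity-sweep": dict(
        base=dict(L=10, cells_per_individual=400),
        sweep_param="sigma2", sweep_values=[0.01, 0.1, 0.5, 1.0]),
    # clustering accuracy vs. cohort size: heterogeneity fixed at 0.1
    "individuals-sweep": dict(
        base=dict(sigma2=0.1, cells_per_individual=400),
        sweep_param="L", sweep_values=[2, 5, 10]),
    # supervised mode: training fraction swept at fixed cohort
    "training-fraction-sweep": dict(
        base=dict(L=10, cells_per_individual=400, sigma2=0.1),
        sweep_param="train_fraction",
        sweep_values=[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]),
}


def study_design(name: str, **overrides) -> StudyDesign:
    """Preset simulation designs for the benchmark experiments.

    Desk-scale defaults (G=100, K=3) apply unless overridden; any
    :class:`SimulationConfig` field may be overridden by keyword.
    """
    if name not in _DESIGNS:
        raise ValidationError(
            f"unknown design {name!r}; choose from {sorted(_DESIGNS)}")
    spec = _DESIGNS[name]
    base = SimulationConfig(**spec["base"])
    base = replace(base, **overrides)
    base.validate()
    return StudyDesign(base=base, sweep_param=spec["sweep_param"],
                       sweep_values=list(spec["sweep_values"]))
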