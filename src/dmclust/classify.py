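"""Supervised acceleration: fit on a per-individual subset, classify the rest.

For very large cohorts the sampler is run on a random subset of cells from
each individual; the remaining cells are then assigned in closed form from the
fitted concentrations and mixing proportions. Classification of cells from an
individual absent from training is deliberately unsupported — the
concentrations are individual-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.special import gammaln

from .data import CountDataset, LabelSet, ValidationError
from .gibbs import ClusteringResult, SamplerConfig, run_mcmc
from .kernel import DirichletParamBlock, MixingProportions

__all__ = [
    "TrainedModel",
    "split_train_test",
    "split_indices",
    "fit_training",
    "classify_cells",
    "supervised_pipeline",
]


@dataclass
class TrainedModel:
    """Fitted parameters sufficient for closed-form classification."""

    alpha_hat: DirichletParamBlock
    pi_hat: MixingProportions
    K: int
    gene_ids: List[str]
    individual_ids: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.gene_ids:
            raise ValidationError("trained model needs a nonempty gene universe")
        if self.alpha_hat.G != len(self.gene_ids) or self.alpha_hat.K != self.K:
            raise ValidationError("trained model dimensions inconsistent")


def split_indices(dataset: CountDataset, train_fraction: float, seed: int):
    """Per-individual train/test column indices: ceil(fraction * C_l) cells
    sampled without replacement into training, order preserved within each
    part."""
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in dataset.cells_per_individual:
        n_train = math.ceil(train_fraction * c)
        perm = rng.permutation(c)
        train_idx.append(np.sort(perm[:n_train]))
        test_idx.append(np.sort(perm[n_train:]))
    return train_idx, test_idx


def split_train_test(dataset: CountDataset, train_fraction: float, seed: int):
    """Seeded per-individual split; the gene universe is untouched. With
    fraction 1 the test part has zero cells in every individual."""
    train_idx, test_idx = split_indices(dataset, train_fraction, seed)
    train = dataset.subset_cells(train_idx)
    test = None
    if any(len(i) for i in test_idx):
        test = dataset.subset_cells(
            [i if len(i) else np.array([], dtype=int) for i in test_idx])
    return train, test


def _model_from_result(result: ClusteringResult, train: CountDataset,
                       K: int) -> TrainedModel:
    return TrainedModel(
        alpha_hat=result.alpha_hat,
        pi_hat=result.pi_hat,
        K=K,
        gene_ids=list(train.gene_ids),
        individual_ids=list(train.individual_ids),
    )


def fit_training(train: CountDataset, config: SamplerConfig) -> TrainedModel:
    """Run the sampler on the training cells and keep the post-burn-in
    aligned means of the concentrations and mixing proportions."""
    result = run_mcmc(train, config)
    return _model_from_result(result, train, config.K)


def classify_cells(test: CountDataset, model: TrainedModel):
    """Closed-form posterior over clusters for every test cell.

    ``posterior[cell, k]`` is proportional to the collapsed
    Dirichlet-multinomial mass of the cell under that individual's fitted
    cluster-k concentrations, weighted by the fitted mixing proportion. Labels
    are the argmax, ties to the smallest cluster index. Purely deterministic.
    """
    if list(test.gene_ids) != list(model.gene_ids):
        raise ValidationError("test gene universe differs from training model")
    params, K = model.alpha_hat, model.K
    logpi = model.pi_hat.log()
    posts, labels = [], []
    for l, mat in enumerate(test.matrices):
        x = mat.T.astype(float)
        t = x.sum(axis=1)
        w = np.empty((x.shape[0], K))
        for k in range(K):
            w[:, k] = (
                gammaln(x + params.alpha[l, k]).sum(axis=1)
                - params.lgamma_alpha[l, k].sum()
                + params.lgamma_alpha_sums[l, k]
                - gammaln(t + params.alpha_sums[l, k])
            )
        w += logpi[l]
        w -= w.max(axis=1, keepdims=True)
        p = np.exp(w)
        p /= p.sum(axis=1, keepdims=True)
        posts.append(p)
        labels.append(p.argmax(axis=1) + 1)
    return np.concatenate(posts, axis=0), LabelSet(labels, K)


def supervised_pipeline(dataset: CountDataset, train_fraction: float,
                        config: SamplerConfig) -> ClusteringResult:
    """Split, fit on the training cells, classify the rest, recombine.

    Training cells keep their sampler labels and posteriors; test cells get
    closed-form posteriors. The returned result covers every cell in the
    original order; ``test_mask`` marks (pooled order) which cells were
    classified rather than sampled. With fraction 1 this is exactly a full
    sampler run.
    """
    if train_fraction == 1:
        result = run_mcmc(dataset, config)
        result.test_mask = np.zeros(dataset.total_cells, dtype=bool)
        return result

    train_idx, test_idx = split_indices(dataset, train_fraction, config.seed)
    train = dataset.subset_cells(train_idx)
    test = dataset.subset_cells(test_idx)
    train_result = run_mcmc(train, config)
    model = _model_from_result(train_result, train, config.K)
    test_post, test_labels = classify_cells(test, model)

    K = config.K
    posterior = np.zeros((dataset.total_cells, K))
    labels_out = []
    test_mask = np.zeros(dataset.total_cells, dtype=bool)
    off = 0           # pooled offset into the combined result
    tr_off = 0        # pooled offset into training posteriors
    te_off = 0
    for l, c in enumerate(dataset.cells_per_individual):
        z = np.empty(c, dtype=int)
        n_tr, n_te = len(train_idx[l]), len(test_idx[l])
        posterior[off + train_idx[l]] = train_result.posterior[tr_off:tr_off + n_tr]
        z[train_idx[l]] = train_result.final_labels.labels[l]
        posterior[off + test_idx[l]] = test_post[te_off:te_off + n_te]
        z[test_idx[l]] = test_labels.labels[l]
        test_mask[off + test_idx[l]] = True
        labels_out.append(z)
        off += c
        tr_off += n_tr
        te_off += n_te

    return ClusteringResult(
        final_labels=LabelSet(labels_out, K),
        posterior=posterior,
        alpha_hat=model.alpha_hat,
        pi_hat=model.pi_hat,
        mu_hat=train_result.mu_hat,
        sigma2_hat=train_result.sigma2_hat,
        log_posterior_trace=train_result.log_posterior_trace,
        log_lik_trace=train_result.log_lik_trace,
        gene_ids=list(dataset.gene_ids),
        cell_ids=[list(c) for c in dataset.cell_ids],
        individual_ids=list(dataset.individual_ids),
        config=config,
        alpha_acceptance=train_result.alpha_acceptance,
        sigma2_acceptance=train_result.sigma2_acceptance,
        test_mask=test_mask,
    )
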