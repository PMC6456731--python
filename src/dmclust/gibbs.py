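"""Metropolis-within-Gibbs inference for the hierarchical mixture.

One sweep updates, in order: cell labels (exact categorical conditional),
Dirichlet concentrations (per-gene Metropolis step on the log scale),
gene/cluster hyper-parameters (closed-form mean for mu, Metropolis for
sigma2 against its Gamma hyper-prior) and per-individual mixing proportions
(conjugate Dirichlet draw). Label switching across retained sweeps is
resolved by greedy maximum-overlap matching to the first post-burn-in sweep
before posterior averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.special import gammaln

from .data import CountDataset, LabelSet, ValidationError
from .kernel import DirichletParamBlock, MixingProportions, log_prior_alpha

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "ModelState",
    "ClusteringResult",
    "initialize_state",
    "update_labels",
    "update_alpha",
    "update_hyperparams",
    "update_pi",
    "run_mcmc",
    "information_criteria",
]

_ALPHA_FLOOR = 1e-2
_PI_FLOOR = 1e-3


@dataclass
class SamplerConfig:
    """Sampler settings; defaults follow the method's stated conventions
    (burn-in 100) with weakly informative hyper-priors."""

    K: int
    n_iter: int = 1000
    burn_in: int = 100
    seed: int = 0
    proposal_sd: float = 0.1
    hyper_a: float = 1.0
    hyper_b: float = 1.0
    init_method: str = "kmeans-proportions"

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")
        if self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ValueError("Gamma hyper-prior parameters must be > 0")
        if self.init_method not in ("random", "kmeans-proportions"):
            raise ValueError(f"unknown init_method {self.init_method!r}")


@dataclass
class ModelState:
    """One MCMC configuration of all unknowns."""

    labels: LabelSet
    params: DirichletParamBlock
    pi: MixingProportions
    mu: np.ndarray          # (G, K)
    sigma2: np.ndarray      # (G, K)
    iteration: int = 0
    alpha_accepts: int = 0
    alpha_proposals: int = 0
    sigma2_accepts: int = 0
    sigma2_proposals: int = 0


@dataclass
class ClusteringResult:
    """Posterior summaries of one run.

    ``posterior[cell, k]`` is the fraction of retained, label-aligned sweeps
    in which the cell sat in cluster ``k`` (pooled cell order: individuals in
    input order, cells in column order). Parameter estimates are aligned
    posterior means.
    """

    final_labels: LabelSet
    posterior: np.ndarray
    alpha_hat: DirichletParamBlock
    pi_hat: MixingProportions
    mu_hat: np.ndarray
    sigma2_hat: np.ndarray
    log_posterior_trace: np.ndarray
    log_lik_trace: np.ndarray
    gene_ids: List[str]
    cell_ids: List[List[str]]
    individual_ids: List[str]
    config: SamplerConfig
    alpha_acceptance: float = float("nan")
    sigma2_acceptance: float = float("nan")
    test_mask: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# precomputation


def _prep(dataset: CountDataset):
    """Per-individual views and constants reused across sweeps.

    ``Xi_off`` pre-offsets each integer count into the flattened per-cluster
    log-gamma tables (see :func:`_count_table`), so every likelihood
    evaluation is a gather instead of a fresh ``gammaln`` call.
    """
    prep = []
    for mat in dataset.matrices:
        x = np.ascontiguousarray(mat.T, dtype=float)  # (C, G)
        xi = np.ascontiguousarray(mat.T, dtype=np.int64)
        t = x.sum(axis=1)
        logcoef = float((gammaln(t + 1) - gammaln(x + 1).sum(axis=1)).sum())
        xmax = int(xi.max()) if xi.size else 0
        g = xi.shape[1]
        xi_off = xi + (np.arange(g, dtype=np.int64) * (xmax + 1))[None, :]
        tu, tinv = np.unique(t, return_inverse=True)
        prep.append({
            "X": x, "Xi_off": xi_off, "T": t, "logcoef": logcoef,
            "xmax": xmax, "tu": tu, "tinv": tinv,
        })
    return prep


def _count_table(alpha_lk: np.ndarray, xmax: int) -> np.ndarray:
    """Flattened table ``T[i*(xmax+1) + v] = lgamma(v + a_i) - lgamma(a_i)``
    built as cumulative sums of ``log(a_i + m)`` (exact rising factorial)."""
    g = alpha_lk.shape[0]
    cs = np.zeros((g, xmax + 1))
    if xmax:
        np.cumsum(
            np.log(alpha_lk[:, None] + np.arange(xmax, dtype=float)[None, :]),
            axis=1, out=cs[:, 1:])
    return cs.ravel()


def _build_tables(params: DirichletParamBlock, prep):
    return [
        [_count_table(params.alpha[l, k], prep[l]["xmax"])
         for k in range(params.K)]
        for l in range(params.L)
    ]


# ---------------------------------------------------------------------------
# initialization


def initialize_state(dataset: CountDataset, config: SamplerConfig,
                     rng: Optional[np.random.Generator] = None) -> ModelState:
    """Build a starting configuration.

    ``"kmeans-proportions"`` clusters the pooled per-cell gene-proportion
    vectors with seeded k-means; ``"random"`` assigns labels uniformly.
    Concentrations start at per-cluster mean proportions scaled by the mean
    per-cell depth (floored at a small positive constant), mixing proportions
    at within-individual label frequencies, ``mu`` at log of the initial
    concentrations and ``sigma2`` at the hyper-prior mean.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G, K, L = dataset.n_genes, config.K, dataset.n_individuals
    prep = _prep(dataset)
    props = np.concatenate(
        [p["X"] / np.maximum(p["T"], 1.0)[:, None] for p in prep], axis=0)
    n_cells = props.shape[0]

    if config.init_method == "kmeans-proportions" and 1 < K <= n_cells:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=K, n_init=10,
                    random_state=int(config.seed) % (2 ** 31))
        z_pooled = km.fit_predict(props).astype(int)
    elif K == 1:
        z_pooled = np.zeros(n_cells, dtype=int)
    else:
        z_pooled = rng.integers(0, K, size=n_cells)

    # repair: every cluster must start with at least one cell
    for k in range(K):
        if not np.any(z_pooled == k):
            j = int(rng.integers(0, n_cells))
            logger.info("init: cluster %d empty, reassigning cell %d", k + 1, j)
            z_pooled[j] = k

    mean_t = float(np.mean(np.concatenate([p["T"] for p in prep])))
    global_pbar = props.mean(axis=0)
    alpha0 = np.empty((K, G))
    for k in range(K):
        members = props[z_pooled == k]
        # fewer cells than clusters leaves some clusters empty even after
        # repair; those start from the pooled mean profile
        pbar = members.mean(axis=0) if members.size else global_pbar
        alpha0[k] = np.maximum(pbar * max(mean_t, 1.0), _ALPHA_FLOOR)
    alpha = np.broadcast_to(alpha0, (L, K, G)).copy()

    labels, pi = [], np.empty((L, K))
    off = 0
    for l, p in enumerate(prep):
        c = p["X"].shape[0]
        z_l = z_pooled[off:off + c]
        off += c
        labels.append(z_l + 1)
        freq = np.bincount(z_l, minlength=K).astype(float) / c
        freq = np.maximum(freq, _PI_FLOOR)
        pi[l] = freq / freq.sum()

    mu = np.log(alpha0).T  # (G, K)
    sigma2 = np.full((G, K), config.hyper_a / config.hyper_b)
    return ModelState(
        labels=LabelSet(labels, K),
        params=DirichletParamBlock(alpha),
        pi=MixingProportions(pi),
        mu=mu,
        sigma2=sigma2,
    )


# ---------------------------------------------------------------------------
# conditional updates


def update_labels(state: ModelState, dataset: CountDataset,
                  rng: np.random.Generator, _prep_cache=None,
                  _tables=None) -> ModelState:
    """Redraw every cell label from its exact categorical conditional,
    proportional to pi[l, k] times the collapsed Dirichlet-multinomial mass."""
    prep = _prep_cache if _prep_cache is not None else _prep(dataset)
    params, K = state.params, state.params.K
    tables = _tables if _tables is not None else _build_tables(params, prep)
    logpi = state.pi.log()
    for l, p in enumerate(prep):
        xi_off = p["Xi_off"]
        w = np.empty((xi_off.shape[0], K))
        for k in range(K):
            depth = gammaln(p["tu"] + params.alpha_sums[l, k])
            w[:, k] = (
                tables[l][k][xi_off].sum(axis=1)
                + params.lgamma_alpha_sums[l, k]
                - depth[p["tinv"]]
            )
        w += logpi[l]
        w -= w.max(axis=1, keepdims=True)
        prob = np.exp(w)
        prob /= prob.sum(axis=1, keepdims=True)
        u = rng.random(xi_off.shape[0])
        z = (prob.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        state.labels.labels[l] = z + 1
    return state


def update_alpha(state: ModelState, dataset: CountDataset,
                 rng: np.random.Generator, proposal_sd: float = 0.1,
                 _prep_cache=None, _tables=None) -> ModelState:
    """One Metropolis sweep over every concentration ``alpha[l, k, i]``.

    The proposal is a Gaussian random walk on ``log alpha`` (symmetric on that
    scale; the log-normal prior becomes a plain normal there, so no extra
    Jacobian appears in the ratio). Gene-specific likelihood terms are
    precomputed in bulk; the coupling through the concentration total is
    handled sequentially with a scalar running sum, using the unique per-cell
    depths of the block to keep each step O(#unique depths).
    """
    prep = _prep_cache if _prep_cache is not None else _prep(dataset)
    params = state.params
    alpha = params.alpha
    L, K, G = alpha.shape
    tables = _tables if _tables is not None else _build_tables(params, prep)
    lgamma = math.lgamma
    mu_t = state.mu.T      # (K, G)
    s2_t = state.sigma2.T  # (K, G)

    for l in range(L):
        z0 = state.labels.labels[l] - 1
        t_l, xmax = prep[l]["T"], prep[l]["xmax"]
        xi_off = prep[l]["Xi_off"]
        for k in range(K):
            cells = np.flatnonzero(z0 == k)
            n = cells.size
            theta = np.log(alpha[l, k])
            theta_prop = theta + proposal_sd * rng.standard_normal(G)
            a_prop = np.exp(theta_prop)
            logu = np.log(rng.random(G))

            d_prior = (
                -(theta_prop - mu_t[k]) ** 2 + (theta - mu_t[k]) ** 2
            ) / (2.0 * s2_t[k])
            if n:
                sub = xi_off[cells]
                table_prop = _count_table(a_prop, xmax)
                a_gene = table_prop[sub].sum(axis=0) - tables[l][k][sub].sum(axis=0)
                tu, tc = np.unique(t_l[cells], return_counts=True)
                tu = tu.tolist()
                tc = tc.tolist()
            else:
                a_gene = np.zeros(G)
                tu, tc = [], []
            delta = d_prior + a_gene

            cur = alpha[l, k].copy()
            s = float(cur.sum())

            def _f(total: float) -> float:
                # depth-dependent part of the block log-likelihood
                out = n * lgamma(total)
                for t_val, cnt in zip(tu, tc):
                    out -= cnt * lgamma(t_val + total)
                return out

            f_cur = _f(s)
            acc = 0
            for i in range(G):
                s_new = s - cur[i] + a_prop[i]
                f_new = _f(s_new)
                if logu[i] < delta[i] + f_new - f_cur:
                    cur[i] = a_prop[i]
                    s = s_new
                    f_cur = f_new
                    acc += 1
            alpha[l, k] = cur
            if acc:
                tables[l][k] = _count_table(cur, xmax)
            state.alpha_accepts += acc
            state.alpha_proposals += G
    params.invalidate()
    return state


def update_hyperparams(state: ModelState, config: SamplerConfig,
                       rng: np.random.Generator) -> ModelState:
    """Update mu (closed form) and sigma2 (Metropolis vs. the Gamma prior).

    ``mu[i, k]`` is set to the across-individual mean of ``log alpha`` — the
    model's stated estimator under its noninformative prior. ``sigma2[i, k]``
    takes one Metropolis step on the log scale targeting
    Gamma(a, b) x Normal likelihood of the L values of ``log alpha``.
    """
    la = np.log(state.params.alpha)          # (L, K, G)
    L = la.shape[0]
    mu = la.mean(axis=0).T                   # (G, K)
    state.mu = mu
    ss = ((la - mu.T[None]) ** 2).sum(axis=0).T  # (G, K)

    a, b = config.hyper_a, config.hyper_b
    phi = np.log(state.sigma2)
    phi_prop = phi + config.proposal_sd * rng.standard_normal(phi.shape)

    def _logtarget(p):
        s2 = np.exp(p)
        # Gamma(a,b) prior on sigma2 plus log-scale Jacobian plus normal lik
        return a * p - b * s2 - 0.5 * L * p - ss / (2.0 * s2)

    d = _logtarget(phi_prop) - _logtarget(phi)
    accept = np.log(rng.random(phi.shape)) < d
    phi = np.where(accept, phi_prop, phi)
    state.sigma2 = np.exp(phi)
    state.sigma2_accepts += int(accept.sum())
    state.sigma2_proposals += accept.size
    return state


def update_pi(state: ModelState, rng: np.random.Generator) -> ModelState:
    """Conjugate redraw of each individual's mixing proportions from
    Dirichlet(1 + cluster occupancy) — a symmetric Dirichlet(1) prior."""
    K = state.params.K
    pi = np.empty((state.params.L, K))
    for l, z in enumerate(state.labels.labels):
        counts = np.bincount(z - 1, minlength=K)
        pi[l] = rng.dirichlet(1.0 + counts)
    pi = np.maximum(pi, 1e-300)
    pi /= pi.sum(axis=1, keepdims=True)
    state.pi = MixingProportions(pi)
    return state


# ---------------------------------------------------------------------------
# traces and the full run


def _log_lik(state: ModelState, prep, tables=None) -> float:
    """Joint log-likelihood of counts and labels given alpha (multinomial
    coefficients included)."""
    params = state.params
    if tables is None:
        tables = _build_tables(params, prep)
    total = 0.0
    for l, p in enumerate(prep):
        z = state.labels.labels[l] - 1
        for k in range(params.K):
            cells = np.flatnonzero(z == k)
            if cells.size:
                total += float(tables[l][k][p["Xi_off"][cells]].sum())
        total += float(
            params.lgamma_alpha_sums[l][z].sum()
            - gammaln(p["T"] + params.alpha_sums[l][z]).sum()
        )
        total += p["logcoef"]
    return total


def _log_posterior(state: ModelState, config: SamplerConfig, loglik: float) -> float:
    """Unnormalized joint log posterior at the current state."""
    lp = loglik
    logpi = state.pi.log()
    for l, z in enumerate(state.labels.labels):
        lp += float(logpi[l][z - 1].sum())
    lp += log_prior_alpha(state.params, state.mu, state.sigma2)
    a, b = config.hyper_a, config.hyper_b
    lp += float(((a - 1.0) * np.log(state.sigma2) - b * state.sigma2).sum())
    return lp


def _greedy_match(z: np.ndarray, z_ref: np.ndarray, K: int) -> np.ndarray:
    """Permutation mapping current cluster index -> reference index by
    greedily taking the largest overlaps in the contingency table."""
    m = np.zeros((K, K))
    np.add.at(m, (z, z_ref), 1.0)
    perm = np.full(K, -1, dtype=int)
    m = m.copy()
    for _ in range(K):
        k, r = np.unravel_index(np.argmax(m), m.shape)
        perm[k] = r
        m[k, :] = -1.0
        m[:, r] = -1.0
    return perm


def run_mcmc(dataset: CountDataset, config: SamplerConfig) -> ClusteringResult:
    """Run the full sampler and summarize the retained sweeps.

    Cluster identities of each retained sweep are aligned to the first
    retained sweep by greedy maximum-overlap matching before averaging, so
    posterior probabilities and parameter means refer to one consistent
    labelling. Identical dataset, configuration and seed give bit-identical
    results.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    prep = _prep(dataset)
    state = initialize_state(dataset, config, rng=rng)
    K, L, G = config.K, dataset.n_individuals, dataset.n_genes
    n_cells = dataset.total_cells

    ll_trace = np.empty(config.n_iter)
    lp_trace = np.empty(config.n_iter)
    label_counts = np.zeros((n_cells, K))
    alpha_acc = np.zeros((L, K, G))
    pi_acc = np.zeros((L, K))
    mu_acc = np.zeros((G, K))
    s2_acc = np.zeros((G, K))
    z_ref = None
    n_ret = 0

    tables = _build_tables(state.params, prep)
    for it in range(config.n_iter):
        update_labels(state, dataset, rng, _prep_cache=prep, _tables=tables)
        update_alpha(state, dataset, rng, proposal_sd=config.proposal_sd,
                     _prep_cache=prep, _tables=tables)
        update_hyperparams(state, config, rng)
        update_pi(state, rng)
        state.iteration = it + 1

        ll = _log_lik(state, prep, tables=tables)
        ll_trace[it] = ll
        lp_trace[it] = _log_posterior(state, config, ll)

        if it >= config.burn_in:
            z = state.labels.pooled() - 1
            if z_ref is None:
                z_ref = z.copy()
                perm = np.arange(K)
            else:
                perm = _greedy_match(z, z_ref, K)
            label_counts[np.arange(n_cells), perm[z]] += 1.0
            alpha_acc[:, perm, :] += state.params.alpha
            pi_acc[:, perm] += state.pi.pi
            mu_acc[:, perm] += state.mu
            s2_acc[:, perm] += state.sigma2
            n_ret += 1
        if (it + 1) % 100 == 0:
            logger.info("sweep %d/%d: log-posterior %.2f", it + 1,
                        config.n_iter, lp_trace[it])

    posterior = label_counts / n_ret
    z_final = posterior.argmax(axis=1)  # argmax ties -> lowest index
    labels, off = [], 0
    for c in dataset.cells_per_individual:
        labels.append(z_final[off:off + c] + 1)
        off += c

    pi_hat = pi_acc / n_ret
    pi_hat /= pi_hat.sum(axis=1, keepdims=True)
    return ClusteringResult(
        final_labels=LabelSet(labels, K),
        posterior=posterior,
        alpha_hat=DirichletParamBlock(alpha_acc / n_ret),
        pi_hat=MixingProportions(pi_hat),
        mu_hat=mu_acc / n_ret,
        sigma2_hat=s2_acc / n_ret,
        log_posterior_trace=lp_trace,
        log_lik_trace=ll_trace,
        gene_ids=list(dataset.gene_ids),
        cell_ids=[list(c) for c in dataset.cell_ids],
        individual_ids=list(dataset.individual_ids),
        config=config,
        alpha_acceptance=state.alpha_accepts / max(state.alpha_proposals, 1),
        sigma2_acceptance=state.sigma2_accepts / max(state.sigma2_proposals, 1),
    )


def information_criteria(result: ClusteringResult, dataset: CountDataset):
    """AIC and BIC at the best retained joint log-likelihood.

    The likelihood is the conditional joint of counts and sampled labels given
    alpha, maximized over retained sweeps; the parameter count is
    G*L*K concentrations plus L*(K-1) free mixing proportions.
    """
    cfg = result.config
    retained = result.log_lik_trace[cfg.burn_in:]
    if retained.size == 0:
        raise ValueError("no retained iterations in trace")
    llmax = float(retained.max())
    G, L = dataset.n_genes, dataset.n_individuals
    p = G * L * cfg.K + L * (cfg.K - 1)
    n = dataset.total_cells
    aic = 2.0 * p - 2.0 * llmax
    bic = p * math.log(n) - 2.0 * llmax
    return aic, bic
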