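import numpy as np
import pytest

from dmclust import (
    ClusteringResult, DirichletParamBlock, LabelSet, MixingProportions,
    SamplerConfig, SimulationConfig, adjusted_rand_index, information_criteria,
    initialize_state, run_mcmc, simulate_dataset, update_alpha,
    update_hyperparams, update_labels, update_pi,
)
from dmclust.data import CountDataset


def _tiny_sim(seed=0, **kw):
    kw.setdefault("G", 40)
    kw.setdefault("K", 2)
    kw.setdefault("L", 2)
    kw.setdefault("cells_per_individual", 60)
    kw.setdefault("sigma2", 0.05)
    kw.setdefault("depth_model", ("fixed", 400))
    return simulate_dataset(SimulationConfig(seed=seed, **kw))


class TestInitialize:
    def test_seed_determinism(self, small_sim):
        cfg = SamplerConfig(K=3, n_iter=10, burn_in=1, seed=4)
        a = initialize_state(small_sim.dataset, cfg)
        b = initialize_state(small_sim.dataset, cfg)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.labels.labels, b.labels.labels))
        assert np.array_equal(a.params.alpha, b.params.alpha)
        assert np.array_equal(a.pi.pi, b.pi.pi)

    def test_single_cluster_degenerate(self, small_sim):
        cfg = SamplerConfig(K=1, n_iter=10, burn_in=1, seed=0)
        st = initialize_state(small_sim.dataset, cfg)
        assert all((z == 1).all() for z in st.labels.labels)
        assert np.allclose(st.pi.pi, 1.0)

    def test_kmeans_init_beats_random(self):
        """On separated clusters the proportion k-means start should agree
        with truth much better than a uniform-random start (median of 5)."""
        gains = []
        for seed in range(5):
            sim = _tiny_sim(seed=seed)
            km = initialize_state(sim.dataset, SamplerConfig(
                K=2, n_iter=10, burn_in=1, seed=seed,
                init_method="kmeans-proportions"))
            rnd = initialize_state(sim.dataset, SamplerConfig(
                K=2, n_iter=10, burn_in=1, seed=seed, init_method="random"))
            truth = sim.true_labels.pooled()
            gains.append(
                adjusted_rand_index(np.concatenate(km.labels.labels), truth)
                - adjusted_rand_index(np.concatenate(rnd.labels.labels), truth))
        assert np.median(gains) > 0.5


class TestUpdateLabels:
    def test_symmetric_parameters_split_evenly(self):
        """Two identical clusters: assignment frequencies hit 1/2 within
        three binomial standard errors."""
        x = np.full((5, 200), 2)
        ds = CountDataset([x], [f"g{i}" for i in range(5)],
                          [[f"c{j}" for j in range(200)]], ["d1"])
        cfg = SamplerConfig(K=2, n_iter=10, burn_in=1, seed=0)
        st = initialize_state(ds, cfg, rng=np.random.default_rng(0))
        st.params = DirichletParamBlock(np.ones((1, 2, 5)))
        st.pi = MixingProportions(np.array([[0.5, 0.5]]))
        rng = np.random.default_rng(1)
        draws = []
        for _ in range(50):
            update_labels(st, ds, rng)
            draws.append((st.labels.labels[0] == 1).mean())
        n = 50 * 200
        se = np.sqrt(0.25 / n)
        assert abs(np.mean(draws) - 0.5) < 3 * se

    def test_conditional_matches_brute_force(self):
        """Empirical assignment frequencies match the exact normalized
        Dirichlet-multinomial masses on a hand-sized instance."""
        from dmclust.kernel import log_dm_pmf

        x = np.array([[2], [1]])  # one cell, counts (2, 1)
        ds = CountDataset([x], ["g1", "g2"], [["c1"]], ["d1"])
        cfg = SamplerConfig(K=2, n_iter=10, burn_in=1, seed=0)
        st = initialize_state(ds, cfg, rng=np.random.default_rng(0))
        alpha = np.array([[[3.0, 1.0], [1.0, 3.0]]])
        st.params = DirichletParamBlock(alpha)
        st.pi = MixingProportions(np.array([[0.4, 0.6]]))
        p1 = 0.4 * np.exp(log_dm_pmf([2, 1], [3.0, 1.0], False))
        p2 = 0.6 * np.exp(log_dm_pmf([2, 1], [1.0, 3.0], False))
        target = p1 / (p1 + p2)
        rng = np.random.default_rng(2)
        hits = sum(
            (update_labels(st, ds, rng).labels.labels[0][0] == 1)
            for _ in range(4000))
        se = np.sqrt(target * (1 - target) / 4000)
        assert abs(hits / 4000 - target) < 3 * se


class TestUpdateAlpha:
    def test_prior_only_sampling_for_empty_cluster(self):
        """With no cells assigned to a cluster its concentrations follow the
        log-normal prior; the chain's long-run mean of log alpha approaches
        mu."""
        x = np.array([[3], [1]])
        ds = CountDataset([x], ["g1", "g2"], [["c1"]], ["d1"])
        cfg = SamplerConfig(K=2, n_iter=10, burn_in=1, seed=0)
        st = initialize_state(ds, cfg, rng=np.random.default_rng(0))
        st.labels = LabelSet([np.array([1])], K=2)  # cluster 2 empty
        st.mu = np.array([[0.0, 1.2], [0.0, 1.2]])
        st.sigma2 = np.full((2, 2), 0.25)
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(3000):
            update_alpha(st, ds, rng, proposal_sd=0.6)
            vals.append(np.log(st.params.alpha[0, 1]).copy())
        mean_la = np.mean(vals[500:], axis=0)
        assert np.allclose(mean_la, 1.2, atol=0.1)

    def test_acceptance_bookkeeping(self, small_sim):
        cfg = SamplerConfig(K=3, n_iter=10, burn_in=1, seed=0)
        st = initialize_state(small_sim.dataset, cfg)
        update_alpha(st, small_sim.dataset, np.random.default_rng(0))
        assert st.alpha_proposals == 3 * 3 * 50
        assert 0 <= st.alpha_accepts <= st.alpha_proposals


class TestUpdateHyperparams:
    def _state_with_alpha(self, alpha, a=1.0, b=1.0):
        L, K, G = alpha.shape
        x = np.ones((G, 2), dtype=int)
        ds = CountDataset([x] * L, [f"g{i}" for i in range(G)],
                          [["c1", "c2"]] * L, [f"d{l}" for l in range(L)])
        cfg = SamplerConfig(K=K, n_iter=10, burn_in=1, seed=0,
                            hyper_a=a, hyper_b=b)
        st = initialize_state(ds, cfg, rng=np.random.default_rng(0))
        st.params = DirichletParamBlock(alpha)
        return st, cfg

    def test_mu_is_mean_of_logs(self):
        alpha = np.array([[[np.e]], [[np.e ** 3]]])  # L=2, K=1, G=1
        st, cfg = self._state_with_alpha(alpha)
        update_hyperparams(st, cfg, np.random.default_rng(0))
        assert st.mu[0, 0] == pytest.approx(2.0)

    def test_equal_alphas_give_exact_mu(self):
        alpha = np.full((3, 1, 2), 0.7)
        st, cfg = self._state_with_alpha(alpha)
        update_hyperparams(st, cfg, np.random.default_rng(0))
        assert np.allclose(st.mu, np.log(0.7))

    def test_sigma2_recovery(self):
        """With many individuals the sigma2 chain concentrates near the true
        across-individual variance of log alpha."""
        rng = np.random.default_rng(7)
        la = 0.5 * rng.standard_normal((50, 1, 20))  # var 0.25
        st, cfg = self._state_with_alpha(np.exp(la))
        chain_rng = np.random.default_rng(8)
        draws = []
        for _ in range(800):
            update_hyperparams(st, cfg, chain_rng)
            draws.append(st.sigma2.copy())
        post_mean = np.mean(draws[200:], axis=0).mean()
        assert abs(post_mean - 0.25) / 0.25 < 0.2


class TestUpdatePi:
    def test_posterior_mean(self):
        x = np.ones((2, 4), dtype=int)
        ds = CountDataset([x], ["g1", "g2"], [[f"c{j}" for j in range(4)]], ["d1"])
        cfg = SamplerConfig(K=2, n_iter=10, burn_in=1, seed=0)
        st = initialize_state(ds, cfg, rng=np.random.default_rng(0))
        st.labels = LabelSet([np.array([1, 1, 1, 2])], K=2)  # counts (3, 1)
        rng = np.random.default_rng(5)
        draws = [update_pi(st, rng).pi.pi[0, 0] for _ in range(4000)]
        # Dirichlet(1+3, 1+1) posterior mean of the first component
        assert np.mean(draws) == pytest.approx(4 / 6, abs=0.01)

    def test_single_cluster(self):
        x = np.ones((2, 3), dtype=int)
        ds = CountDataset([x], ["g1", "g2"], [["a", "b", "c"]], ["d1"])
        st = initialize_state(ds, SamplerConfig(K=1, n_iter=5, burn_in=1, seed=0))
        update_pi(st, np.random.default_rng(0))
        assert np.allclose(st.pi.pi, 1.0)


class TestRunMcmc:
    def test_seed_determinism(self):
        sim = _tiny_sim(seed=3)
        cfg = SamplerConfig(K=2, n_iter=60, burn_in=20, seed=9)
        a = run_mcmc(sim.dataset, cfg)
        b = run_mcmc(sim.dataset, cfg)
        assert np.array_equal(a.posterior, b.posterior)
        assert np.array_equal(a.alpha_hat.alpha, b.alpha_hat.alpha)
        assert np.array_equal(a.log_posterior_trace, b.log_posterior_trace)

    def test_single_cluster_forced(self):
        sim = _tiny_sim(seed=1, K=1)
        res = run_mcmc(sim.dataset, SamplerConfig(K=1, n_iter=30, burn_in=10, seed=0))
        assert (res.final_labels.pooled() == 1).all()
        assert np.allclose(res.posterior, 1.0)

    def test_invalid_iteration_counts(self, small_sim):
        with pytest.raises(ValueError):
            run_mcmc(small_sim.dataset,
                     SamplerConfig(K=2, n_iter=10, burn_in=10, seed=0))

    def test_posterior_rows_and_trace(self, small_result):
        assert np.allclose(small_result.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.isfinite(small_result.log_posterior_trace))
        assert np.all(np.isfinite(small_result.log_lik_trace))
        assert small_result.log_posterior_trace.size == small_result.config.n_iter

    def test_recovers_separated_clusters(self, small_sim, small_result):
        ari = adjusted_rand_index(small_result.final_labels.pooled(),
                                  small_sim.true_labels.pooled())
        assert ari >= 0.95

    def test_duplicated_individual_matches_single(self):
        """With identical data, clustering one individual and clustering the
        same data presented as two individuals agree on every cell."""
        sim = _tiny_sim(seed=5, L=1)
        mat = sim.dataset.matrices[0]
        dup = CountDataset([mat, mat.copy()], list(sim.dataset.gene_ids),
                           [list(sim.dataset.cell_ids[0])] * 2, ["d1", "d2"])
        cfg = SamplerConfig(K=2, n_iter=120, burn_in=40, seed=2)
        one = run_mcmc(sim.dataset, cfg)
        two = run_mcmc(dup, cfg)
        c = mat.shape[1]
        assert adjusted_rand_index(one.final_labels.pooled(),
                                   two.final_labels.pooled()[:c]) == 1.0
        assert adjusted_rand_index(two.final_labels.pooled()[:c],
                                   two.final_labels.pooled()[c:]) == 1.0

    def test_alpha_recovery_correlation(self, small_sim, small_result):
        """Aligned posterior-mean log concentrations track the generative
        ones (clusters matched by best label overlap)."""
        from scipy.optimize import linear_sum_assignment

        truth = small_sim.true_labels.pooled()
        pred = small_result.final_labels.pooled()
        m = np.zeros((3, 3))
        np.add.at(m, (pred - 1, truth - 1), 1.0)
        rows, cols = linear_sum_assignment(m, maximize=True)
        perm = dict(zip(rows, cols))
        est = np.log(small_result.alpha_hat.alpha)
        true = np.log(small_sim.true_alpha.alpha)
        r = np.corrcoef(
            np.concatenate([est[:, k].ravel() for k in range(3)]),
            np.concatenate([true[:, perm[k]].ravel() for k in range(3)]))[0, 1]
        assert r >= 0.9


class TestInformationCriteria:
    def test_determinism(self, small_sim):
        cfg = SamplerConfig(K=2, n_iter=40, burn_in=10, seed=1)
        a = run_mcmc(small_sim.dataset, cfg)
        b = run_mcmc(small_sim.dataset, cfg)
        assert information_criteria(a, small_sim.dataset) == \
            information_criteria(b, small_sim.dataset)

    def test_hand_arithmetic(self, small_sim, small_result):
        aic, bic = information_criteria(small_result, small_sim.dataset)
        cfg = small_result.config
        llmax = small_result.log_lik_trace[cfg.burn_in:].max()
        p = 50 * 3 * 3 + 3 * (3 - 1)
        n = small_sim.dataset.total_cells
        assert aic == pytest.approx(2 * p - 2 * llmax)
        assert bic == pytest.approx(p * np.log(n) - 2 * llmax)

    def test_empty_trace_errors(self, small_sim, small_result):
        broken = ClusteringResult(**{**small_result.__dict__})
        broken.log_lik_trace = np.array([])
        broken.config = SamplerConfig(K=3, n_iter=1, burn_in=0, seed=0)
        with pytest.raises(ValueError):
            information_criteria(broken, small_sim.dataset)
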