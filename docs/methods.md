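# Methods

## Model

`dmclust` clusters UMI count matrices from several individuals (donors,
mice, samples) simultaneously. For cell *j* of individual *l*, the count
vector **x**<sub>·jl</sub> over *G* genes is multinomial with total
*T*<sub>jl</sub> and probability vector **p**<sub>·jl</sub>. Each cell
carries a discrete cluster label *z*<sub>jl</sub> ∈ {1..K}; given
*z*<sub>jl</sub> = *k*, **p**<sub>·jl</sub> ~ Dirichlet(**α**<sub>·lk</sub>)
with an individual-specific concentration vector. Integrating **p** out
gives the collapsed Dirichlet-multinomial likelihood

    P(x | z=k, α) = T!/∏x_i! · ∏_i Γ(x_i+α_ilk)/Γ(α_ilk) · Γ(|α_·lk|)/Γ(T+|α_·lk|),

which the package only ever evaluates in log space via log-gamma
(`kernel.log_dm_pmf`); at realistic depths (T ≈ 10³–10⁴) any linear-space
evaluation overflows.

Individual-level batch heterogeneity is the hierarchy's middle layer:
α<sub>ilk</sub> is log-normal LN(μ<sub>ik</sub>, σ²<sub>ik</sub>) across
individuals, so all donors share a cell-type profile (μ) while each deviates
from it with gene/cluster-specific variance (σ²). The mean of σ²<sub>ik</sub>
over genes and clusters is the scalar heterogeneity summary used throughout
(`simulate.heterogeneity_level`). σ²<sub>ik</sub> carries a Gamma(a, b)
hyper-prior so that variance information is pooled across genes; μ has a
noninformative prior. Mixing proportions π<sub>l·</sub> are per-individual
with a symmetric Dirichlet(1) prior (the model is agnostic here; this is the
weakest proper conjugate choice).

Assumptions worth stating: clusters are discrete and exhaustive (no
continuum, no doublets); cells and individuals are independent given the
parameters; there is no explicit zero-inflation component — excess zeros are
handled only insofar as the low-expression filter removes mostly-zero genes.

## Inference

Metropolis-within-Gibbs, one sweep = four blocks:

1. **Labels.** Each *z*<sub>jl</sub> is redrawn exactly from the categorical
   conditional ∝ π<sub>lk</sub> · DM(x | α<sub>·lk</sub>). The multinomial
   coefficient cancels and is omitted here; it is included in the joint
   likelihood used for traces and information criteria.
2. **Concentrations.** Each α<sub>ilk</sub> takes one Metropolis step with a
   Gaussian random walk on log α (scale `proposal_sd`, default 0.1). On the
   log scale the log-normal prior is a plain normal and the proposal is
   symmetric, so no Jacobian appears. The likelihood ratio factorizes into a
   gene-specific part (precomputed for the whole gene vector in one pass)
   and a coupling through the concentration total |α<sub>·lk</sub>|, handled
   sequentially with a scalar running total; the per-cell depth terms are
   grouped by unique depth so each gene's step costs O(#unique depths).
3. **Hyper-parameters.** μ<sub>ik</sub> is set to the across-individual mean
   of log α<sub>ilk</sub> (the closed-form estimator under the
   noninformative prior — a deterministic update). σ²<sub>ik</sub> takes one
   vectorized Metropolis step on log σ² targeting Gamma(a, b) prior ×
   normal likelihood of the L log-concentrations; defaults a = b = 1.
4. **Mixing proportions.** Conjugate redraw π<sub>l·</sub> ~
   Dirichlet(1 + occupancy counts).

All likelihood work shares one representation: tables of
lgamma(v + α<sub>i</sub>) − lgamma(α<sub>i</sub>) built as cumulative sums of
log(α<sub>i</sub> + m) over integer offsets v, gathered by the (integer)
counts. This is exact (a rising factorial) and replaces per-sweep `gammaln`
calls over the full count matrix with cheap gathers; the public kernel
functions use direct `gammaln` and the two paths agree to ~1e-11, which the
tests assert.

**Initialization** (`init_method="kmeans-proportions"`, default): seeded
k-means on per-cell gene-proportion vectors pooled over individuals; labels
from k-means, concentrations from per-cluster mean proportions scaled by the
mean depth (floored at 0.01), π from within-individual label frequencies
(floored at 1e-3 and renormalized), μ = log of the initial concentrations,
σ² = the hyper-prior mean. A `"random"` start is available; on separated
data the k-means start converges much faster and the tests quantify the gap.
Empty clusters at initialization get one random cell (and, if there are
fewer cells than clusters, the pooled mean profile); empty clusters during
sampling are allowed — their concentrations then follow the prior.

**Label switching.** Mixture labels are only identified up to permutation.
Each retained sweep is aligned to the first post-burn-in sweep by greedy
maximum-overlap matching of the K×K label contingency table before
accumulating posteriors and parameter means. Greedy matching equals the
optimal (Hungarian) matching whenever the overlap matrix is unambiguous,
which is the regime where averaging across sweeps is meaningful at all.
Final labels are the per-cell posterior argmax, ties to the smallest cluster
index.

**Defaults and reproducibility.** `n_iter=1000`, `burn_in=100`,
`proposal_sd=0.1`, `hyper_a=hyper_b=1`; one seeded NumPy generator drives
everything, sweeps visit individuals and cells in index order, and identical
data/config/seed give bit-identical results. Acceptance rates for the α and
σ² steps are recorded on the result (α acceptance is typically 0.4–0.7 at
the default scale on desk-size problems).

**Model choice.** AIC/BIC use the best retained joint log-likelihood of
counts and sampled labels given α (a conditional, not marginal, likelihood —
the marginal over z is not available in closed form and the conditional
ranks K adequately in the tests), with parameter count G·L·K + L·(K−1).

## Supervised mode

For large cohorts the sampler runs on a per-individual random subset
(⌈fraction·C_l⌉ cells, ceiling so every individual stays represented at
small fractions); remaining cells are classified in closed form:
posterior ∝ DM(x | α̂<sub>·lk</sub>) · π̂<sub>lk</sub> with the post-burn-in
aligned means. Because α̂ is individual-specific, classifying cells of an
individual absent from training is unsupported by construction.

## Simulator

`simulate_dataset` draws from exactly the generative hierarchy above:
α<sub>ilk</sub> = exp(μ<sub>ik</sub> + σ<sub>ik</sub>ε), z ~
Categorical(π<sub>l·</sub>), p ~ Dirichlet(α<sub>·l,z</sub>), x ~
Multinomial(T, p). μ comes from `make_mu`: a shared per-gene baseline
(normal, sd 0.5) plus disjoint signature blocks of ⌈G/(2K)⌉ genes per
cluster shifted up by the `separation` parameter on the log scale.
Defaults — G=100, K=3, L=10, 400 cells/individual, σ²=0.1, separation 2.0,
fixed depth 1000 — are the desk-scale study conditions used by the presets
(`study_design`): a heterogeneity sweep over σ² ∈ {0.01, 0.1, 0.5, 1.0} at
L=10 × 400 cells, an individuals sweep at σ²=0.1, and a training-fraction
sweep (10%→100%) for the supervised mode. Separation 2.0 makes signature
genes e² ≈ 7× concentrated, which produces clearly separated clusters —
deliberately: the recovery experiments measure the machinery, not the limit
of detectability, and the heterogeneity sweep then isolates the effect of
σ².

What the simulator does *not* emulate about real droplet data: zero
inflation and dropout beyond multinomial sampling, ambient RNA, doublets,
cell-to-cell depth correlation with cell type, and mis-specified (non-DM)
expression noise. Passing recovery tests therefore demonstrate correctness
of the inference under the model's own assumptions, not robustness to their
violation.

## Evaluation

ARI is the Hubert–Arabie adjusted Rand index (delegated to scikit-learn;
the hand-computed contingency-table values in the tests pin the convention).
Matched accuracy maximizes the correctly-placed fraction over one-to-one
cluster matchings via optimal assignment. APN follows the co-membership
definition: for observation o and reduced clustering r,
1 − |C_full(o) ∩ C_r(o)|/|C_full(o)|, averaged over observations and
reductions (each reduction is expected to re-remove a fresh random gene
subset). Silhouette uses a precomputed distance matrix — by default
Euclidean on per-cell gene proportions — with singleton clusters scored 0
and a single overall cluster returning zeros with a warning. Cells whose
largest posterior probability is strictly below 0.95 are flagged "vague".

## Problem sizes in the shipped experiments

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen once: label recovery at G=100, K=3, L=5, 200 cells/individual,
σ²=0.05, 500 sweeps × 20 seeds; the heterogeneity sweep at 100
cells/individual, 300 sweeps × 10 seeds; the supervised saturation check at
L=10 × 400 cells, 300 sweeps × 5 seeds; the K-selection scan at 100
cells/individual, 150 sweeps × 10 seeds. These sizes keep a full run on one
CPU in minutes while leaving the qualitative behaviour (recovery,
degradation with heterogeneity, supervised saturation, K selection)
clearly measurable.

## Known limitations

- No zero-inflation; heavy dropout beyond the DM noise will bias α.
- K is fixed per run (scan + AIC/BIC for guidance); no split-merge moves.
- Greedy label alignment can misalign when clusters are heavily confused
  across sweeps; posteriors are then conservative (spread over clusters).
- The supervised mode cannot discover clusters absent from training and may
  miss rare populations if the training fraction is small.
- Runtime scales linearly in cells, genes, individuals and K; no
  parallelism or GPU path.
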