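# dmclust

Bayesian clustering of droplet scRNA-seq UMI counts from **multiple
individuals at once**. Cohort-scale single-cell studies pool cells from
several donors, and donor-level batch effects (library preparation, depth,
biology) distort any clustering that treats the pooled matrix as one sample.
`dmclust` models that heterogeneity instead of correcting it away: it works
directly on raw counts, with no normalization or transformation, and is
aimed at analysts clustering cohort scRNA-seq data and at methodologists who
need a faithful generative simulator for it.

## Model

Counts **x**<sub>·jl</sub> of cell *j* in individual *l* are multinomial
over *G* genes; given cluster label *z*<sub>jl</sub> = *k* the probability
vector is Dirichlet(**α**<sub>·lk</sub>), giving the collapsed
Dirichlet-multinomial likelihood

P(**x** | z=k, **α**) = (T!/∏ᵢxᵢ!) · ∏ᵢ Γ(xᵢ+α<sub>ilk</sub>)/Γ(α<sub>ilk</sub>) · Γ(|**α**<sub>·lk</sub>|)/Γ(T+|**α**<sub>·lk</sub>|).

Across individuals, α<sub>ilk</sub> ~ LN(μ<sub>ik</sub>, σ²<sub>ik</sub>):
a shared cell-type profile with donor-specific log-normal deviations whose
variance *is* the individual-level heterogeneity. Inference is
Metropolis-within-Gibbs over labels, concentrations, hyper-parameters and
per-individual mixing proportions; a supervised mode fits on a per-donor
subsample and classifies the remaining cells in closed form. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from dmclust import (SimulationConfig, SamplerConfig, simulate_dataset,
                     run_mcmc, supervised_pipeline, adjusted_rand_index,
                     flag_vague_cells)

# 5 donors x 200 cells, 100 genes, 3 cell types, modest donor heterogeneity
sim = simulate_dataset(SimulationConfig(G=100, K=3, L=5,
                                        cells_per_individual=200,
                                        sigma2=0.05, seed=1))
res = run_mcmc(sim.dataset, SamplerConfig(K=3, n_iter=500, burn_in=100, seed=1))

print("ARI vs truth:", adjusted_rand_index(res.final_labels.pooled(),
                                           sim.true_labels.pooled()))
print("vague cells :", int(flag_vague_cells(res.posterior).sum()))

sup = supervised_pipeline(sim.dataset, 0.5, SamplerConfig(K=3, n_iter=500,
                                                          burn_in=100, seed=1))
m = sup.test_mask
print("supervised test ARI:",
      adjusted_rand_index(sup.final_labels.pooled()[m],
                          sim.true_labels.pooled()[m]))
```

prints

```
ARI vs truth: 1.0
vague cells : 0
supervised test ARI: 1.0
```

— the sampler recovers the generative labels exactly on this well-separated
cohort, no cell has maximum posterior probability below 0.95, and training
on half the cells per donor classifies the held-out half just as well.

The same workflows are available from the shell:

```sh
dmclust simulate --g 100 --k 3 --l 5 --cells 200 --sigma2 0.05 --seed 1 --out sim/
dmclust cluster sim/indiv* --k 3 --n-iter 500 --seed 1 --out run/
dmclust evaluate --labels run/labels.tsv --truth sim/truth_labels.tsv --out eval/
```

Use `--scan-k MIN:MAX` to sweep cluster numbers and report AIC/BIC, and
`dmclust classify --model run/model_params.json ...` to label new cells of
the same individuals from a saved fit.

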