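# coaldelim

Coalescent species delimitation for multi-individual, multi-locus
datasets: single-threshold **GMYC** on ultrametric gene trees, **guided
Bayesian delimitation under the multispecies coalescent (MSC)** by
reversible-jump MCMC over collapse/split models on a guide tree, and an
**integrative-evidence** stage that compares partitions across loci and
methods, tests trait associations, and applies a conservative
all-priors support rule.  A synthetic MSC data generator reproduces the
statistical structure of a lichen-scale study system (about 8 candidate
species, 4 loci with a mitochondrial locus at heredity 1/4, ~63
unevenly sampled individuals), so every stage can be validated against
known truth without any external data.

## The models

**GMYC** places one threshold age T on an ultrametric single-locus tree:
branching older than T is speciation under a Yule process with rate
`lam1 * n^p1`; the maximal subtrees at or below T are independent
coalescent clusters, cluster j coalescing at rate
`lam2 * (n_j (n_j - 1))^p2`.  The threshold is profiled over the
observed node ages; the candidate at the root age is the one-species
null of the likelihood-ratio test.  Delimited entities are the clusters
plus the tips attaching above T.

**Guided MSC delimitation** fixes a rooted guide tree over candidate
species and samples the posterior over all collapse/split assignments of
its internal nodes (a node may be split only if its parent is split;
an 8-species guide of the shape used in the examples admits 21 models).
Gene trees are data: the likelihood is the censored-coalescent density
with per-population `theta = 4 Ne u`, per-locus heredity scalars and
relative rates, and divergence times `tau`; theta is integrated out
analytically under its InvGamma(2, beta) prior (or sampled, as a
cross-check).  Priors on theta and the root tau use means on the grid
{0.1, 0.01}; a split counts as *well supported* only at posterior
probability > 0.95 under **all four** prior combinations.

See `docs/methods.md` for the full model statements, conventions,
numerical choices and validation experiments.

## Worked example

```python
from coaldelim import (GuideTree, PriorConfig, SpeciesDelimitation,
                       fit_gmyc)
from coaldelim.mcmc import MCMCConfig
from coaldelim.simulate import SimScenario, simulate_dataset

scenario = SimScenario(s=4, n_per_species=(6, 5, 4, 3), n_loci=2,
                       heredity=(0.25, 1.0), tau_root=0.1,
                       theta_scale=0.01, seed=3)
bundle = simulate_dataset(scenario)
guide = GuideTree.from_tree(bundle.species_tree)

print(fit_gmyc(bundle.gene_trees[0]).summary())

model = SpeciesDelimitation(bundle.gene_trees, bundle.taxon_map, guide,
                            heredity=scenario.heredity,
                            locus_rates=bundle.locus_rates)
res = model.fit(config=MCMCConfig(generations=20000, pre_burnin=2000, seed=7),
                prior=PriorConfig(tau_mean=0.1, theta_mean=0.01))
print(res.summary())
```

Output:

```
GMYC single-threshold fit
========================================
tips                 18
ML threshold age     0.00298031
entities (CI)        4 (4-4)
logL / logL0         113.7210 / 105.7169
LR = 16.008, df = 3, p = 0.0001986 ***
lam1=31.19 p1=0.000  lam2=414.3 p2=1.138

Guided MSC species delimitation (rjMCMC)
================================================
runs                  2  (samples: 10000, 10000)
best model            4 species, PP = 1.000
delimited units       sp1; sp2; sp3; sp4
dual-run max |dPP|    0.0000 (converged at 0.05)

 node           clade  pp_split  pp[run1]  pp[run2]
    3         sp1+sp4       1.0       1.0       1.0
    5     sp1+sp2+sp4       1.0       1.0       1.0
    6 sp1+sp2+sp3+sp4       1.0       1.0       1.0
```

The GMYC fit finds the maximum-likelihood threshold at age ~0.003,
delimiting 4 entities (the simulated truth) with a 2-log-likelihood
confidence interval of 4-4 and a significant departure from the
one-species null (`***`).  The guided MSC posterior, merged over two
independent chains, puts probability 1.0 on the fully split 4-species
model; the per-split table shows each internal guide node's posterior
probability of being a real speciation event, per run and averaged.

Prior-grid scans (`model.prior_sensitivity(...)`), the exhaustive
posterior oracle for small guide trees (`model.fit_exhaustive(...)`),
and the end-to-end pipeline (`coaldelim run --config cfg.yaml`, which
adds trait-association tests and the all-priors support rule) follow
the same pattern.  A command-line interface mirrors the library:
`coaldelim simulate | gmyc | msc-delimit | concord | run`.

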