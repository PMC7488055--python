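# Methods

`coaldelim` implements two complementary coalescent species-delimitation
methods and the machinery to compare, stress-test and integrate their
results: single-threshold GMYC on individual ultrametric gene trees, and
guided Bayesian delimitation under the multispecies coalescent (MSC) by
reversible-jump MCMC over collapse/split models on a guide tree.  A
synthetic-data generator reproduces the statistical structure of a
multi-individual, multi-locus fungal study system so every stage can be
validated against known truth.  This note records the models, the
conventions, and the design choices that were genuinely open.

## Units and conventions

All times are expressed in expected substitutions per site, so the
population-scaled mutation parameter theta (= 4 Ne u) and the divergence
times tau live on a common scale and the inverse-gamma priors apply to
both directly.  Node ages are measured from the present (tips at age 0);
a branch's length is the parent's age minus the child's.  Trees are
strictly bifurcating; a polytomy resolver (`resolve_polytomies`) exists
for input sanitation but analyses reject polytomies by default.
Ultrametricity is validated with a default relative tolerance of 1e-6 on
the spread of root-to-tip path lengths, after which ages are snapped so
tips sit exactly at zero.

## The single-threshold GMYC model

One threshold age T is placed on an ultrametric gene tree.  Above T,
branching is speciation under a Yule process with rate
`lam1 * n^p1`, where n counts the contemporaneous diversification
lineages.  The maximal subtrees whose roots are at or below T are
independent coalescent clusters; cluster j with n_j extant lineages
coalesces at total rate `lam2 * (n_j (n_j - 1))^p2`.  The scaling
exponents p1, p2 relax the strict Yule/Kingman shapes (population growth,
lineage-specific rates); they are estimated within [0, 5] by default and
can be fixed at 1.

The likelihood treats the ordered branching times as a sequence of
exponential waiting times at the total rate of the processes active in
each inter-node interval, conditioning on the observed root age.  Each
branching event is scored with the rate of the interval directly above
it: Yule events by the diversification component, coalescent events by
the summed cluster rates.  Two structural points deserve emphasis
because they decide the model's behavior:

* **The diversification process survives below the threshold.**  After
  the threshold, the n_entities species lineages persist to the present
  with no further observed speciation, so the Yule process contributes
  survival `exp(-lam1 * n_ent^p1 * T)` over the entire sub-threshold era.
  Without this term a threshold deep in the tree buys cheap extra "Yule"
  events for free and the fit degenerates; with it, the threshold is
  anchored where the branching regime genuinely changes.
* **The null is a profile point, not a separate model.**  The candidate
  threshold at the root age makes the whole tree a single coalescent
  cluster, which is exactly the one-species null of the likelihood-ratio
  test.  Candidate thresholds are the observed internal-node ages
  (exactly tied ages are separated by a deterministic relative-1e-9
  nudge, parents kept older than children), so the profile always
  contains the null and the maximized log-likelihood can never fall
  below it.

For fixed exponents the rate scalars have closed-form ML values, leaving
one-dimensional searches in p1 and p2 per candidate threshold (a coarse
grid plus a bounded polish; the p1 objective is concave, the p2 objective
need not be).  The ML solution's entities are the coalescent clusters
plus the tips attaching above the threshold (singletons count as
entities); the confidence set collects the entity counts of all
candidates within `delta` (default 2) log-likelihood units of the
maximum, so its width is non-decreasing in `delta` by construction.

**The LR test is non-regular.**  Under the one-species null, `lam1` sits
on the boundary of its parameter space and p1 and T are unidentified, so
the classical chi-square with df = 3 (five parameters against two, the
threshold profiled out) does not describe the null distribution of
`LR = 2 (logL - logL0)`.  Simulated single-coalescent nulls (20-60 tips)
put a point mass of roughly 0.2 at LR = 0 with a continuous part between
chi-square(1) and chi-square(2); p-values therefore default to the
boundary-mixture reference `0.5 chi2(1) + 0.5 chi2(2)`, which yields
empirical size close to the nominal 0.05.  The plain chi-square
convention remains available (`lrt_null='chi2'`, `df=` configurable) and
is markedly conservative for this likelihood.  Significance stars follow
the usual `* / ** / ***` thresholds at 0.05 / 0.01 / 0.001.

## Guided MSC delimitation

A guide tree fixes a rooted binary topology over candidate species; a
delimitation model assigns split/collapsed flags to its internal nodes,
with a node splittable only if its parent is split.  The number of such
models obeys `f(tip) = 1`, `f(v) = 1 + f(left) f(right)`; the 8-species
guide shape used throughout the examples (a two-species clade sister to
two three-species subclades) admits 21 models.  Each maximal collapsed
clade is one panmictic population from the present back to its parent's
divergence; each split node v is an ancestral population on
`[tau_v, tau_parent(v))`.

**Gene trees are data.**  The likelihood is the censored-coalescent
density of fixed ultrametric gene trees (one per locus) given the
populations: lineages coalesce only within the population they currently
occupy, pairs coalescing at rate `2 / (h_l theta_p)` with h_l the
per-locus heredity scalar (1/4 for a maternally inherited haploid locus
against nuclear loci; a `diploid` flag doubles every scalar for the
sensitivity variant).  Locus l's node ages are divided by its relative
rate r_l (mean 1 across loci) before statistics are accumulated.  Each
population contributes through two sufficient statistics per locus: the
number of coalescences c and the integral B of n(n-1) dt over its
lifetime.  A configuration in which any coalescence joins lineages of
two different populations is censoring-infeasible and carries likelihood
zero; equivalently, each split node's tau must not exceed the youngest
gene-tree coalescence joining its two sides (minimized over loci), a
bound the samplers exploit directly.

**Analytic theta integration.**  With `theta_p ~ InvGamma(alpha, beta)`
(`alpha = 2` so the mean is `beta`), each population's likelihood
integrates in closed form to
`2^C prod_l h_l^(-c_l) * beta^alpha Gamma(alpha + C) /
[Gamma(alpha) (beta + B~)^(alpha + C)]`,
with `C = sum_l c_l` and `B~ = sum_l B_l / h_l`.  Populations never
containing two lineages contribute exactly 1 and carry no theta
parameter.  The identity is verified against one-dimensional quadrature
to 1e-8 relative error in the test suite.  When theta is instead kept in
the chain, its conditional posterior given the model and taus is
`InvGamma(alpha + C, beta + B~)`, which also provides exact
conditional draws for reporting theta even in integrated runs.

**Priors.**  Theta and the root tau carry inverse-gamma priors with
shape 2 and means on the study grid {0.1, 0.01} (four tau/theta
combinations).  Conditional on the root tau R, the non-root taus are
flat over the order-compatible region (every child younger than its
parent).  That region's volume is `R^k / prod_v s_v`, where s_v counts
the split nodes in v's clade (a hook-length identity), so the density
`prod_v s_v / R^k` is exact per model — a requirement for valid
cross-dimension jumps; the normalization is Monte-Carlo-verified in the
tests.  Model priors: prior 1 is uniform over all delimitation models;
prior 0 weights each model by the labelled-history count of its induced
species tree, `k! / prod_v s_v`, favouring balanced trees.

**The rjMCMC sampler.**  The chain state is the model, its taus, and
(optionally) its thetas.  A split move picks a splittable node uniformly
and proposes its tau on `(0, U)` with `U = min(parent tau, feasibility
bound)` — uniformly under algorithm 0, or as `U * z, z ~ Beta(1, 3)`
(favouring shallow splits) under algorithm 1; the join move is the exact
reverse; Hastings factors include the move-type probabilities, the
proposal densities, and the change in the tau-prior normalization.  New
populations' thetas are proposed from the prior, which cancels exactly.
Within-model moves are multiplier updates of the root tau, a 50:50
mixture of full-window independence draws and local Gaussian steps for
non-root taus, and multiplier updates of thetas when sampled.  The
likelihood is maintained incrementally: any single move touches at most
three populations, whose statistics are recomputed from per-clade
precomputed event tables in O(log) time, so a generation costs
microseconds.  Chains start from the fully collapsed model, which is
always feasible.  Dual runs with derived seeds are the default; their
per-split posterior discrepancies are reported and never silently
averaged away (the merged probabilities are plain means, the per-run
values retained, and a convergence flag raised at a 0.05 threshold).
The sampler always conditions on the guide-tree topology (the guided,
fixed-tree flavour); unguided topology search is deliberately out of
scope and flagged as unsupported wherever the full analysis grid
(guided/unguided x species caps x four priors x two runs = 32 chains)
is materialized.

**Exhaustive oracle.**  For guide trees of at most four species the
posterior is also computable directly: per model, the marginal
likelihood is integrated over its taus by segment-wise Gauss-Legendre
quadrature with segment boundaries at the gene-tree coalescence ages
(the integrand is smooth between them and kinked at them), theta
integrated analytically throughout, and the root dimension additionally
anchored on its prior quantiles.  The sampler is validated against this
oracle (total-variation distance at most 0.05), against the analytic
model prior when run with zero loci, and against itself across the
theta-integrated/theta-sampled and algorithm-0/1 variants.

## Synthetic data

The generator draws a Yule species tree (uniform lineage splitting)
rescaled so the root divergence equals `tau_root`; per-population thetas
from InvGamma(2, mean `theta_scale`); censored-coalescent gene trees per
locus (heredity and rate aware); JC69 alignments; and a categorical
trait whose level equals the species' modal level with probability
`trait_fidelity`, otherwise uniform over the rest.  The default scenario
mirrors the study system's scale: 8 species, 63 individuals with uneven
sampling including a singleton species, 4 loci with the first
(mitochondrial) at heredity 1/4, theta mean 0.05, root divergence 0.1,
locus rates Dirichlet-distributed with mean exactly 1, and a
three-level trait at fidelity 0.9.  Two scenario variants used in
validation: a strongly separated K-species scenario (Yule draws
conditioned on every divergence at least 20 theta, the regime where a
single threshold can separate species cleanly), and single-population
null scenarios for test calibration.

What the generator does *not* emulate: gene flow and migration after
divergence, recombination within loci, alignment error, model
misspecification of the clock, and gene-tree estimation error (gene
trees are handed to the methods exactly; in real analyses they are
estimates).  Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness
to their violation — the known sensitivities of both methods to
incomplete sampling and gene flow are unchanged.

## Validation experiments and their scales

The test suite runs every stage at sizes chosen for a laptop-class
single-CPU budget while keeping the statistical assertions meaningful:

* GMYC size: 500 single-coalescent simulations (40 tips, theta 0.05);
  empirical rejection at alpha = 0.05 must fall in [0.03, 0.08].
  Observed: ~0.04 with the default mixture reference.
* GMYC recovery: 100 replicates of the separated 5-species scenario
  (4 individuals per species, one locus); at least 90% must delimit
  exactly 5 entities.  Observed: ~0.99.
* Sampler validity: five 3-species scenarios, 30,000 generations each,
  TV <= 0.05 against the exhaustive posterior; zero-locus prior recovery
  within 3 conservative (autocorrelation-discounted) standard errors;
  theta integrated vs sampled per-split posterior differences <= 0.02.
* Parameter recovery: 100 study-shaped replicates at the true (fully
  split) model with the root divergence drawn from its prior (Bayesian
  coverage is only interpretable when the truth is prior-distributed;
  with the root fixed, its interval-identified posterior hugs the
  censoring bound and nominal coverage is unattainable by any correct
  sampler).  Pooled 95% credible-interval coverage of tau and of theta
  must each reach 0.85; observed ~0.92 and ~0.96.

## Evidence integration

Partitions from different loci and methods are compared with the
adjusted Rand index (permutation-model chance correction; 1 iff
identical).  Association between a delimitation and an independent
categorical trait is tested by the chi-square statistic of the
units-by-levels table with a permutation null (trait values shuffled
across individuals; add-one p-value), dropping individuals with missing
values and reporting how many.  Finally, the conservative support rule:
a split is *well supported* only when its posterior probability strictly
exceeds 0.95 under **every** prior combination; splits clearing the bar
under some but not all combinations are flagged prior-sensitive with
their support range.  This quantifies an integrative-taxonomy practice
that is usually applied informally.

## Known limitations

* Gene trees are treated as known; uncertainty from their estimation is
  not propagated (no site-level likelihood, by design — it keeps every
  stage exact and desk-scale).
* The guided sampler cannot propose topology changes; a wrong guide tree
  constrains the reachable delimitations.
* Divergence times are only interval-identified given fixed gene trees;
  their posteriors lean toward the censoring bound and should be read as
  such.
* The GMYC p-value reference is simulation-anchored; for tree sizes far
  outside 20-60 tips the mixture approximation has not been checked.
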