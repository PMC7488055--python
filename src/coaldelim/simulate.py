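"""Synthetic multispecies-coalescent data.

Generates the study-shaped inputs every downstream stage needs: a Yule
species tree with divergence times (tau), per-locus gene trees under the
censored multispecies coalescent with per-population theta (= 4*Ne*u),
per-locus heredity scalars and relative rates, JC69 sequence alignments,
and categorical traits whose fidelity to species identity is tunable.

Times are expressed directly in expected substitutions per site, so theta
and tau live on the same scale as the inverse-gamma priors used downstream;
there is no generation-time bookkeeping.  The default scenario mirrors the
shape of the study system: 8 species, 4 loci with a maternally inherited
locus at heredity 1/4, 63 individuals unevenly spread over species
(including a singleton), theta drawn from InvGamma(2, .) with mean 0.05,
root divergence 0.1, and a three-level trait at fidelity 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import Alignment, TaxonMap, TraitTable
from .trees import Node, UltrametricTree

__all__ = [
    "SimScenario",
    "TruthBundle",
    "simulate_species_tree",
    "simulate_gene_trees",
    "simulate_alignment",
    "simulate_traits",
    "simulate_dataset",
    "rostania_like",
]


@dataclass
class SimScenario:
    """Parameters of one simulated study.

    ``theta_scale`` is the mean of the InvGamma(2, beta) from which
    per-population theta values are drawn (beta = theta_scale, since the
    mean of InvGamma(a, b) is b/(a-1)).  ``locus_rates`` must average
    exactly 1, matching the convention that relative locus rates are
    normalized to mean 1.
    """

    s: int = 8
    tau_root: float = 0.1
    theta_scale: float = 0.05
    n_per_species: tuple[int, ...] = (15, 12, 10, 8, 7, 6, 4, 1)
    n_loci: int = 4
    heredity: tuple[float, ...] = (0.25, 1.0, 1.0, 1.0)
    locus_rates: tuple[float, ...] | None = None
    alignment_lengths: tuple[int, ...] = (825, 624, 621, 1962)
    trait_levels: tuple[str, ...] = ("clusters", "short chains", "long chains")
    trait_fidelity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("need at least one species")
        if len(self.n_per_species) != self.s:
            raise ValueError("n_per_species must have one entry per species")
        if any(n < 1 for n in self.n_per_species):
            raise ValueError("every species needs at least one individual")
        if len(self.heredity) != self.n_loci:
            raise ValueError("heredity must have one scalar per locus")
        if any(h <= 0 for h in self.heredity):
            raise ValueError("heredity scalars must be positive")
        if self.tau_root <= 0 or self.theta_scale <= 0:
            raise ValueError("tau_root and theta_scale must be positive")
        if not 0.0 <= self.trait_fidelity <= 1.0:
            raise ValueError("trait_fidelity must lie in [0, 1]")
        if self.locus_rates is not None:
            rates = np.asarray(self.locus_rates, dtype=float)
            if len(rates) != self.n_loci:
                raise ValueError("locus_rates must have one rate per locus")
            if abs(rates.mean() - 1.0) > 1e-12:
                raise ValueError("locus_rates must average exactly 1")


@dataclass
class TruthBundle:
    """A simulated dataset together with its generating truth."""

    scenario: SimScenario
    species_tree: UltrametricTree
    thetas: dict[str, float]          # per population label (tip or node id)
    taxon_map: TaxonMap
    locus_rates: np.ndarray
    gene_trees: list[UltrametricTree]
    alignments: list[Alignment] = field(default_factory=list)
    traits: TraitTable | None = None

    @property
    def true_partition(self) -> dict[str, str]:
        return dict(self.taxon_map.assignments)


def simulate_species_tree(
    s: int, tau_root: float, seed: int | np.random.Generator = 0
) -> UltrametricTree:
    """Yule species tree over ``s`` labelled species, rescaled to root age.

    Splits are generated by the pure-birth process (each extant lineage
    equally likely to split), then all node ages are rescaled so the root
    divergence equals ``tau_root`` exactly.  With s=1 the tree is a single
    tip; with s=2 the one divergence sits at tau_root.
    """
    if s < 1:
        raise ValueError("need at least one species")
    rng = _as_rng(seed)
    labels = [f"sp{i + 1}" for i in range(s)]
    if s == 1:
        return UltrametricTree(Node(label=labels[0], age=0.0))
    # forward simulation: split times measured from the root
    t = 0.0
    split_times = [0.0]
    for k in range(2, s):
        t += rng.exponential(1.0 / k)
        split_times.append(t)
    t_present = t + rng.exponential(1.0 / s)
    scale = tau_root / t_present
    ages = [(t_present - st) * scale for st in split_times]

    lineages: list[Node] = [Node(age=ages[0]), Node(age=ages[0])]
    root = Node(age=ages[0])
    root.add_child(lineages[0])
    root.add_child(lineages[1])
    for k in range(1, s - 1):
        idx = int(rng.integers(len(lineages)))
        node = lineages.pop(idx)
        node.age = ages[k]
        a, b = Node(age=ages[k]), Node(age=ages[k])
        node.add_child(a)
        node.add_child(b)
        lineages.extend([a, b])
    order = rng.permutation(len(lineages))
    for lab, idx in zip(labels, order):
        lineages[idx].label = lab
        lineages[idx].age = 0.0
    return UltrametricTree(root)


def assign_population_labels(species_tree: UltrametricTree) -> dict[int, str]:
    """Stable labels for every population: tips keep their species label,
    ancestral nodes get the sorted concatenation of descendant species."""
    labels: dict[int, str] = {}
    clades: dict[int, list[str]] = {}
    for node in species_tree.nodes:
        if node.is_tip:
            clades[node.index] = [node.label]
            labels[node.index] = node.label
        else:
            members = sorted(
                x for c in node.children for x in clades[c.index]
            )
            clades[node.index] = members
            labels[node.index] = "+".join(members)
    return labels


def draw_thetas(
    species_tree: UltrametricTree,
    theta_scale: float,
    rng: np.random.Generator,
    alpha: float = 2.0,
) -> dict[str, float]:
    """Per-population theta drawn from InvGamma(alpha, beta=theta_scale*(alpha-1))."""
    labels = assign_population_labels(species_tree)
    beta = theta_scale * (alpha - 1.0)
    draws = stats.invgamma.rvs(
        alpha, scale=beta, size=len(labels), random_state=rng
    )
    return {labels[i]: float(x) for i, x in zip(sorted(labels), draws)}


def draw_locus_rates(n_loci: int, rng: np.random.Generator, concentration: float = 10.0) -> np.ndarray:
    """Relative locus rates with mean exactly 1 (Dirichlet times n_loci)."""
    if n_loci == 1:
        return np.ones(1)
    rates = rng.dirichlet(np.full(n_loci, concentration)) * n_loci
    # normalize away floating error so the mean-1 invariant holds exactly
    rates = rates / rates.mean()
    return rates


def simulate_gene_trees(
    species_tree: UltrametricTree,
    thetas: dict[str, float],
    n_per_species: Sequence[int],
    n_loci: int,
    heredity: Sequence[float] | None = None,
    locus_rates: Sequence[float] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[UltrametricTree], TaxonMap]:
    """Censored-coalescent gene trees within a species tree.

    Within population ``p`` at locus ``l`` each lineage pair coalesces at
    rate ``2 / (h_l * theta_p)``; lineages enter the ancestral population
    at the divergence time tau of each species-tree node, so no
    between-species coalescence can be younger than the species pair's
    divergence.  Node ages are finally multiplied by the locus rate ``r_l``
    to express each gene tree on its own substitution scale.
    """
    rng = _as_rng(seed)
    heredity = list(heredity) if heredity is not None else [1.0] * n_loci
    if locus_rates is None:
        rates = np.ones(n_loci)
    else:
        rates = np.asarray(locus_rates, dtype=float)
    if len(heredity) != n_loci or len(rates) != n_loci:
        raise ValueError("heredity and locus_rates must have one entry per locus")
    pop_labels = assign_population_labels(species_tree)
    for idx, lab in pop_labels.items():
        if lab not in thetas:
            raise ValueError(f"missing theta for population {lab!r}")
    tips = species_tree.tips
    if len(n_per_species) != len(tips):
        raise ValueError("n_per_species must match the species-tree tips")
    assignments: dict[str, str] = {}
    for tip, n in zip(tips, n_per_species):
        for j in range(n):
            assignments[f"{tip.label}_{j + 1}"] = tip.label
    taxon_map = TaxonMap(assignments)

    gene_trees = []
    for locus in range(n_loci):
        h, r = heredity[locus], float(rates[locus])
        root = _censored_coalescent(
            species_tree, thetas, pop_labels, taxon_map, h, rng
        )
        if r != 1.0:
            for node in root.postorder():
                node.age *= r
        gene_trees.append(UltrametricTree(root))
    return gene_trees, taxon_map


def _censored_coalescent(
    species_tree: UltrametricTree,
    thetas: dict[str, float],
    pop_labels: dict[int, str],
    taxon_map: TaxonMap,
    h: float,
    rng: np.random.Generator,
) -> Node:
    """One gene tree; lineages coalesce only within their current population."""

    def run_population(
        lineages: list[Node], theta_eff: float, t_start: float, t_end: float
    ) -> list[Node]:
        t = t_start
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / theta_eff
            t_next = t + rng.exponential(1.0 / rate)
            if t_next >= t_end:
                return lineages
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            parent = Node(age=t_next)
            parent.add_child(a)
            parent.add_child(b)
            lineages = [x for x in lineages if x is not a and x is not b]
            lineages.append(parent)
            t = t_next
        return lineages

    pending: dict[int, list[Node]] = {}
    for tip in species_tree.tips:
        pending[tip.index] = [
            Node(label=ind, age=0.0)
            for ind in taxon_map.individuals_of(tip.label)
        ]
    # process species-tree nodes young-to-old so children are done first
    order = sorted(species_tree.nodes, key=lambda n: (n.age, n.index))
    for node in order:
        if node.is_tip:
            lineages = pending[node.index]
            t_start = 0.0
        else:
            lineages = []
            for child in node.children:
                lineages.extend(pending.pop(child.index))
            t_start = node.age
        theta_eff = h * thetas[pop_labels[node.index]]
        t_end = node.parent.age if node.parent is not None else np.inf
        pending[node.index] = run_population(lineages, theta_eff, t_start, t_end)
    survivors = pending[species_tree.root.index]
    assert len(survivors) == 1
    return survivors[0]


def simulate_alignment(
    gene_tree: UltrametricTree, length: int, seed: int | np.random.Generator = 0
) -> Alignment:
    """JC69 alignment of ``length`` sites evolved over the gene tree."""
    if length < 1:
        raise ValueError("alignment length must be positive")
    rng = _as_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[int, np.ndarray] = {}
    rows: dict[str, str] = {}
    for node in reversed(list(gene_tree.root.postorder())):  # preorder
        if node.parent is None:
            state = rng.integers(4, size=length)
        else:
            d = node.parent.age - node.age
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            state = seqs[node.parent.index].copy()
            hit = rng.random(length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # jump to one of the three other nucleotides, uniformly
                state[hit] = (state[hit] + rng.integers(1, 4, size=n_hit)) % 4
        seqs[node.index] = state
        if node.is_tip:
            rows[node.label] = alphabet[state].tobytes().decode()
    taxa = gene_tree.tip_labels
    return Alignment(taxa=taxa, rows=[rows[t] for t in taxa])


def simulate_traits(
    partition: dict[str, str],
    trait_levels: Sequence[str],
    trait_fidelity: float,
    seed: int | np.random.Generator = 0,
    trait_name: str = "morphotype",
) -> TraitTable:
    """Categorical trait with probability ``trait_fidelity`` of the species'
    modal level, else uniform over the remaining levels.

    Modal levels are assigned to species round-robin over ``trait_levels``
    in sorted species order, so with at most ``len(trait_levels)`` species
    and fidelity 1 the trait partition matches the species partition.
    """
    levels = list(trait_levels)
    if len(levels) < 2 and trait_fidelity < 1.0:
        raise ValueError("need at least two levels when fidelity < 1")
    rng = _as_rng(seed)
    species = sorted(set(partition.values()))
    modal = {sp: levels[i % len(levels)] for i, sp in enumerate(species)}
    values: dict[str, dict[str, str | None]] = {}
    for ind, sp in partition.items():
        if rng.random() < trait_fidelity:
            level = modal[sp]
        else:
            others = [lv for lv in levels if lv != modal[sp]]
            level = others[int(rng.integers(len(others)))]
        values[ind] = {trait_name: level}
    return TraitTable(values, levels={trait_name: set(levels)})


def simulate_dataset(
    scenario: SimScenario, with_alignments: bool = False
) -> TruthBundle:
    """Generate a full dataset (species tree, gene trees, traits, truth)."""
    rng = np.random.default_rng(scenario.seed)
    species_tree = simulate_species_tree(scenario.s, scenario.tau_root, rng)
    thetas = draw_thetas(species_tree, scenario.theta_scale, rng)
    if scenario.locus_rates is not None:
        rates = np.asarray(scenario.locus_rates, dtype=float)
    else:
        rates = draw_locus_rates(scenario.n_loci, rng)
    gene_trees, taxon_map = simulate_gene_trees(
        species_tree,
        thetas,
        scenario.n_per_species,
        scenario.n_loci,
        heredity=scenario.heredity,
        locus_rates=rates,
        seed=rng,
    )
    alignments: list[Alignment] = []
    if with_alignments:
        for locus, tree in enumerate(gene_trees):
            length = scenario.alignment_lengths[locus % len(scenario.alignment_lengths)]
            aln = simulate_alignment(tree, length, rng)
            aln.locus_name = f"locus{locus + 1}"
            alignments.append(aln)
    traits = simulate_traits(
        dict(taxon_map.assignments),
        scenario.trait_levels,
        scenario.trait_fidelity,
        rng,
    )
    return TruthBundle(
        scenario=scenario,
        species_tree=species_tree,
        thetas=thetas,
        taxon_map=taxon_map,
        locus_rates=rates,
        gene_trees=gene_trees,
        alignments=alignments,
        traits=traits,
    )


def rostania_like(seed: int = 0, **overrides) -> SimScenario:
    """The default study-shaped scenario (see module docstring)."""
    return SimScenario(seed=seed, **overrides)


def simulate_separated_species_tree(
    s: int,
    tau_root: float,
    theta: float,
    min_ratio: float = 20.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 10_000,
) -> UltrametricTree:
    """Yule species tree conditioned on clear species separation.

    Draws are rejected until every divergence time is at least
    ``min_ratio * theta``, giving the canonical strongly separated
    multi-species scenario (e.g. 5 species with every split at least
    20 theta deep) used to benchmark single-threshold delimitation.
    """
    rng = _as_rng(seed)
    for _ in range(max_tries):
        tree = simulate_species_tree(s, tau_root, rng)
        if s == 1 or min(n.age for n in tree.internal_nodes) >= min_ratio * theta:
            return tree
    raise RuntimeError(
        f"no species tree with all divergences >= {min_ratio} * theta "
        f"found in {max_tries} draws; lower theta or min_ratio"
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
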