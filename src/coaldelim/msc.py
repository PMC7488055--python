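"""Multispecies-coalescent model layer for guided species delimitation.

A *guide tree* is a fixed rooted binary tree over candidate species.  A
*delimitation model* assigns a split/collapsed flag to each internal node,
with a node splittable only if its parent is split; every maximal collapsed
clade is then a single panmictic population, and each split node is an
ancestral population spanning the time between its own divergence (tau) and
its parent's.  Gene trees are treated as observed data: the model's
likelihood is the censored-coalescent density of the gene trees given the
populations, with a per-population theta (= 4*Ne*u) that is either sampled
or integrated out analytically under its inverse-gamma prior.

Per population p the gene trees enter only through sufficient statistics:
``c_p`` coalescent events inside p and ``B_p = sum over time slices of
n (n - 1) dt`` within p.  The within-population density is
``prod (2 / theta)**c * exp(-B / theta)``, and under theta ~ InvGamma(a, b)
the marginal is ``2**c * b**a * Gamma(a + c) / (Gamma(a) (b + B)**(a + c))``
-- heredity scalars rescale theta per locus, and locus rates rescale gene
tree time, before the statistics are pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

import dendropy

from .io import TaxonMap
from .trees import Node, TreeError, UltrametricTree

__all__ = [
    "GuideTree",
    "DelimitationModel",
    "MSCParams",
    "PriorConfig",
    "PopulationSummary",
    "InfeasibleError",
    "enumerate_delimitation_models",
    "count_delimitation_models",
    "labelled_history_count",
    "model_prior_log",
    "coalescent_summaries",
    "msc_loglik",
    "msc_loglik_integrated",
    "prior_logpdf",
    "log_tau_prior",
    "MSCLikelihood",
]

_LN2 = math.log(2.0)


class InfeasibleError(ValueError):
    """A gene-tree coalescence violates the censoring constraint."""


# ======================================================================
# guide tree and model space
# ======================================================================

class GuideTree:
    """Rooted binary tree over candidate-species labels.

    Node ages are optional (a guide tree fixes only the topology); when
    built from a dated species tree the ages are kept for reference.
    """

    def __init__(self, root: Node):
        from .trees import _collapse_unifurcations

        _collapse_unifurcations(root)
        self.root = root
        self.nodes: list[Node] = list(root.postorder())
        for i, node in enumerate(self.nodes):
            node.index = i
        self.tips = [n for n in self.nodes if n.is_tip]
        self.internal_nodes = [n for n in self.nodes if n.children]
        for node in self.internal_nodes:
            if len(node.children) != 2:
                raise TreeError(
                    f"guide tree must be binary; node has {len(node.children)} children"
                )
        labels = [t.label for t in self.tips]
        if any(lab is None for lab in labels) or len(set(labels)) != len(labels):
            raise TreeError("guide-tree tip labels must be present and unique")
        self.parent_index: list[int | None] = [
            (n.parent.index if n.parent is not None else None) for n in self.nodes
        ]
        self._clades: list[frozenset[str]] = []
        for node in self.nodes:
            if node.is_tip:
                self._clades.append(frozenset([node.label]))
            else:
                self._clades.append(
                    frozenset().union(*(self._clades[c.index] for c in node.children))
                )
        self.tip_index = {t.label: t.index for t in self.tips}
        self._label_index = {self.clade_label(i): i for i in range(len(self.nodes))}

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "GuideTree":
        dtree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def from_newick_file(cls, path) -> "GuideTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def from_tree(cls, tree: UltrametricTree) -> "GuideTree":
        def convert(node: Node) -> Node:
            new = Node(label=node.label, age=node.age)
            for child in node.children:
                new.add_child(convert(child))
            return new

        return cls(convert(tree.root))

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    def clade(self, index: int) -> frozenset[str]:
        return self._clades[index]

    def clade_label(self, index: int) -> str:
        return "+".join(sorted(self._clades[index]))

    def index_of(self, clade_label: str) -> int:
        return self._label_index[clade_label]

    def mrca_index(self, species: Iterable[str]) -> int:
        want = frozenset(species)
        start = self.tip_index[next(iter(want))]
        i = start
        while not want <= self._clades[i]:
            i = self.parent_index[i]
            if i is None:  # pragma: no cover - want validated upstream
                raise TreeError(f"species {sorted(want)} not all in guide tree")
        return i

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                return node.label
            return "(" + ",".join(fmt(c) for c in node.children) + ")"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"GuideTree({self.to_newick()})"


@dataclass(frozen=True)
class DelimitationModel:
    """Split/collapsed flags over the guide tree's internal nodes.

    ``split_nodes`` holds the indices of internal nodes flagged as real
    speciation events; a node may appear only if its parent does (the root
    needs no licence).  The induced species partition keeps each maximal
    collapsed clade as one species.
    """

    guide: GuideTree = field(repr=False)
    split_nodes: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        internal = {n.index for n in self.guide.internal_nodes}
        for v in self.split_nodes:
            if v not in internal:
                raise ValueError(f"node {v} is not an internal guide node")
            parent = self.guide.parent_index[v]
            if parent is not None and parent not in self.split_nodes:
                raise ValueError(
                    f"node {v} cannot be split while its parent {parent} is collapsed"
                )

    def is_split(self, index: int) -> bool:
        return index in self.split_nodes

    @property
    def key(self) -> tuple[int, ...]:
        return tuple(sorted(self.split_nodes))

    @property
    def n_species(self) -> int:
        return 1 + len(self.split_nodes)

    def unit_roots(self) -> list[int]:
        """Indices of the maximal collapsed clades (the extant species units)."""
        if not self.split_nodes:
            return [self.guide.root.index]
        out = []
        for node in self.guide.nodes:
            if node.index in self.split_nodes:
                continue
            parent = self.guide.parent_index[node.index]
            if parent is None or parent in self.split_nodes:
                out.append(node.index)
        return out

    def population_roots(self) -> list[int]:
        """Unit roots plus ancestral (split) populations."""
        return sorted(self.unit_roots() + list(self.split_nodes))

    def species_partition(self) -> dict[str, str]:
        """Candidate species label -> delimited unit label."""
        out: dict[str, str] = {}
        for u in self.unit_roots():
            unit = self.guide.clade_label(u)
            for sp in self.guide.clade(u):
                out[sp] = unit
        return out

    def splittable_nodes(self) -> list[int]:
        """Collapsed internal nodes whose parent is split (or the root)."""
        out = []
        for node in self.guide.internal_nodes:
            if node.index in self.split_nodes:
                continue
            parent = self.guide.parent_index[node.index]
            if parent is None or parent in self.split_nodes:
                out.append(node.index)
        return sorted(out)

    def joinable_nodes(self) -> list[int]:
        """Split nodes with no split child (removable without orphaning)."""
        out = []
        for v in self.split_nodes:
            children = [c.index for c in self.guide.nodes[v].children]
            if not any(c in self.split_nodes for c in children):
                out.append(v)
        return sorted(out)

    def split(self, index: int) -> "DelimitationModel":
        return DelimitationModel(self.guide, self.split_nodes | {index})

    def join(self, index: int) -> "DelimitationModel":
        return DelimitationModel(self.guide, self.split_nodes - {index})


def enumerate_delimitation_models(guide: GuideTree) -> list[DelimitationModel]:
    """All collapse/split flag assignments obeying the ancestor-split rule.

    Includes the fully collapsed (one species) and fully split models.
    """

    def configs(node: Node) -> list[frozenset[int]]:
        if node.is_tip:
            return [frozenset()]
        below = [frozenset()]
        for combo in _iterproduct(*(configs(c) for c in node.children)):
            below.append(frozenset({node.index}).union(*combo))
        return below

    return [DelimitationModel(guide, flags) for flags in configs(guide.root)]


def count_delimitation_models(guide: GuideTree) -> int:
    """Closed-form count: f(tip) = 1, f(v) = 1 + f(left) * f(right)."""

    memo: dict[int, int] = {}
    for node in guide.nodes:  # postorder
        if node.is_tip:
            memo[node.index] = 1
        else:
            prod = 1
            for c in node.children:
                prod *= memo[c.index]
            memo[node.index] = 1 + prod
    return memo[guide.root.index]


def labelled_history_count(tree) -> int:
    """Number of labelled histories of a rooted binary tree.

    Equals ``(n - 1)! / prod over internal nodes v of m(v)`` where ``m(v)``
    counts the internal nodes inside v's clade (a hook-length formula, so
    the division is exact).
    """
    root = tree.root
    sizes: list[int] = []

    def walk(node) -> int:
        if not node.children:
            return 0
        m = 1 + sum(walk(c) for c in node.children)
        sizes.append(m)
        return m

    n_internal = walk(root)
    num = math.factorial(n_internal)
    den = 1
    for m in sizes:
        den *= m
    return num // den


class ModelSpace:
    """Enumerated model space of a guide tree with cached log priors.

    ``prior_id`` 1 puts equal probability on every delimitation model;
    ``prior_id`` 0 weights each model by the number of labelled histories
    of its induced (collapsed) species tree, favouring balanced trees.
    """

    def __init__(self, guide: GuideTree, prior_id: int = 1):
        if prior_id not in (0, 1):
            raise ValueError("model prior must be 0 or 1")
        self.guide = guide
        self.prior_id = prior_id
        self.models = enumerate_delimitation_models(guide)
        self.index = {m.key: i for i, m in enumerate(self.models)}
        if prior_id == 1:
            logp = np.full(len(self.models), -math.log(len(self.models)))
        else:
            weights = np.array(
                [float(self._induced_history_count(m)) for m in self.models]
            )
            logp = np.log(weights) - math.log(weights.sum())
        self.log_prior = logp

    @staticmethod
    def _induced_history_count(model: DelimitationModel) -> int:
        k = len(model.split_nodes)
        num = math.factorial(k)
        den = 1
        for v in model.split_nodes:
            den *= _split_descendant_count(model, v)
        return num // den

    def log_prior_of(self, model: DelimitationModel) -> float:
        return float(self.log_prior[self.index[model.key]])


def _split_descendant_count(model: DelimitationModel, v: int) -> int:
    """Number of split nodes in the clade of v, v included."""
    guide = model.guide
    count = 0
    stack = [guide.nodes[v]]
    while stack:
        node = stack.pop()
        if node.index in model.split_nodes:
            count += 1
            stack.extend(node.children)
    return count


def model_prior_log(
    model: DelimitationModel, guide: GuideTree, prior_id: int = 1
) -> float:
    """Normalized log prior probability of one delimitation model."""
    return ModelSpace(guide, prior_id).log_prior_of(model)


# ======================================================================
# priors and parameters
# ======================================================================

@dataclass(frozen=True)
class PriorConfig:
    """Inverse-gamma prior system for theta and the root tau.

    Shape ``alpha`` defaults to 2 (a diffuse choice whose mean is
    ``beta / (alpha - 1) = beta``); ``theta_mean`` and ``tau_mean`` are the
    prior means, the study's grid being {0.1, 0.01} for each.  Non-root
    divergence times have a flat joint density over the order-compatible
    region below the root tau, normalized exactly per model (see
    :func:`log_tau_prior`).
    """

    theta_mean: float = 0.1
    tau_mean: float = 0.1
    alpha: float = 2.0
    model_prior: int = 1
    integrate_theta: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 for the prior mean to exist")
        if self.theta_mean <= 0 or self.tau_mean <= 0:
            raise ValueError("prior means must be positive")

    @property
    def beta_theta(self) -> float:
        return self.theta_mean * (self.alpha - 1.0)

    @property
    def beta_tau(self) -> float:
        return self.tau_mean * (self.alpha - 1.0)

    @property
    def label(self) -> str:
        return f"tau({self.tau_mean:g}), theta({self.theta_mean:g})"


def prior_logpdf(kind: str, x: float, prior: PriorConfig) -> float:
    """Inverse-gamma log-density for theta or the root divergence time."""
    if x <= 0:
        raise ValueError(f"{kind} must be positive, got {x}")
    if kind == "theta":
        beta = prior.beta_theta
    elif kind == "tau_root":
        beta = prior.beta_tau
    else:
        raise ValueError("kind must be 'theta' or 'tau_root'")
    return float(stats.invgamma.logpdf(x, prior.alpha, scale=beta))


def log_tau_prior(
    model: DelimitationModel, taus: Mapping[int, float], prior: PriorConfig
) -> float:
    """Joint log prior of the divergence times of a delimitation model.

    The root tau carries the inverse-gamma prior; conditional on it the
    non-root taus are flat over the order-compatible region (child younger
    than parent), whose volume is ``R**k / prod s_v`` with ``s_v`` the
    number of split nodes in v's clade -- so the density is
    ``prod s_v / R**k`` inside the region and 0 outside.
    """
    split = model.split_nodes
    if not split:
        return 0.0
    guide = model.guide
    root_idx = guide.root.index
    if root_idx not in split:  # pragma: no cover - excluded by the constraint
        raise ValueError("a model with split nodes must split the root")
    R = taus[root_idx]
    if R <= 0:
        return -math.inf
    total = prior_logpdf("tau_root", R, prior)
    for v in split:
        if v == root_idx:
            continue
        tau_v = taus[v]
        parent = guide.parent_index[v]
        if not 0.0 < tau_v < taus[parent]:
            return -math.inf
        total += math.log(_split_descendant_count(model, v))
    total -= (len(split) - 1) * math.log(R)
    return total


@dataclass
class MSCParams:
    """Explicit MSC parameters (used when theta is sampled, not integrated).

    ``thetas`` and ``taus`` are keyed by population clade label (tip label,
    or '+'-joined sorted tip labels for ancestral nodes).
    """

    thetas: dict[str, float]
    taus: dict[str, float]
    heredity: Sequence[float] | None = None
    locus_rates: Sequence[float] | None = None


# ======================================================================
# censored-coalescent sufficient statistics
# ======================================================================

@dataclass
class PopulationSummary:
    """Per-population coalescent statistics for one gene tree.

    ``c[p]`` counts coalescences inside population p; ``B[p]`` accumulates
    ``n (n - 1) dt`` over p's lifetime.  Populations are keyed by clade
    label.  Time has already been divided by the locus rate; heredity
    scalars act later, on theta.
    """

    c: dict[str, int]
    B: dict[str, float]

    @property
    def total_events(self) -> int:
        return sum(self.c.values())


def coalescent_summaries(
    gene_tree: UltrametricTree,
    taxon_map: TaxonMap,
    model: DelimitationModel,
    taus: Mapping[int, float] | Mapping[str, float],
    locus_rate: float = 1.0,
) -> PopulationSummary:
    """Sweep one gene tree through the populations of a delimitation model.

    Raises :class:`InfeasibleError` when a coalescence joins lineages that
    sit in two different populations at its age (the censoring constraint
    the rjMCMC maps to a log-likelihood of -inf).
    """
    guide = model.guide
    taus_idx = _normalize_taus(guide, taus)
    pops = model.population_roots()
    unit_of_species: dict[str, int] = {}
    for u in model.unit_roots():
        for sp in guide.clade(u):
            unit_of_species[sp] = u

    c = {p: 0 for p in pops}
    B = {p: 0.0 for p in pops}
    lineage_pop: dict[int, int] = {}
    pop_counts = {p: 0 for p in pops}

    gene_nodes = sorted(gene_tree.nodes, key=lambda n: (n.age, n.index))
    for tip in gene_tree.tips:
        sp = taxon_map.species_of(tip.label)
        if sp not in unit_of_species:
            raise KeyError(f"species {sp!r} not in the guide tree")
        pop = unit_of_species[sp]
        lineage_pop[tip.index] = pop
        pop_counts[pop] += 1

    # merge schedule: at tau_v the two child-side populations pour into v
    merges = sorted(
        ((taus_idx[v], v) for v in model.split_nodes), key=lambda x: x[0]
    )
    events = [
        (node.age / locus_rate, node)
        for node in gene_nodes
        if node.children
    ]
    queue = sorted(
        [(t, 0, v) for t, v in merges] + [(t, 1, n) for t, n in events],
        key=lambda x: (x[0], x[1]),
    )
    t_prev = 0.0
    pop_alias: dict[int, int] = {p: p for p in pops}

    def resolve(p: int) -> int:
        while pop_alias[p] != p:
            p = pop_alias[p]
        return p

    for t, kind, payload in queue:
        dt = t - t_prev
        if dt > 0:
            for p in pops:
                n = pop_counts[p]
                if resolve(p) == p and n >= 2:
                    B[p] += n * (n - 1) * dt
        t_prev = t
        if kind == 0:
            v = payload
            # children of a split node are population roots themselves
            # (split nodes or maximal collapsed clades)
            for childnode in guide.nodes[v].children:
                cp = resolve(childnode.index)
                if cp != v:
                    pop_alias[cp] = v
                    pop_counts[v] += pop_counts[cp]
                    pop_counts[cp] = 0
        else:
            node = payload
            pa, pb = (resolve(lineage_pop[ch.index]) for ch in node.children)
            if pa != pb:
                raise InfeasibleError(
                    f"coalescence at age {t:.6g} joins lineages in populations "
                    f"{guide.clade_label(pa)!r} and {guide.clade_label(pb)!r} "
                    "before those populations have merged"
                )
            c[pa] += 1
            pop_counts[pa] -= 1
            lineage_pop[node.index] = pa
    return PopulationSummary(
        c={guide.clade_label(p): c[p] for p in pops},
        B={guide.clade_label(p): B[p] for p in pops},
    )


def _normalize_taus(guide: GuideTree, taus) -> dict[int, float]:
    out: dict[int, float] = {}
    for key, val in taus.items():
        idx = key if isinstance(key, (int, np.integer)) else guide.index_of(key)
        out[int(idx)] = float(val)
    return out


# ======================================================================
# fast likelihood engine
# ======================================================================

@dataclass
class _NodeProfile:
    """Within-clade coalescent profile of one guide node at one locus."""

    events: np.ndarray      # sorted ages of events with home inside the clade
    bp: np.ndarray          # breakpoints [0] + events
    cum: np.ndarray         # cumulative integral of n (n - 1) at breakpoints
    n0: int                 # lineages at time 0

    def integral(self, lo: float, hi: float) -> float:
        return self._eval(hi) - self._eval(lo)

    def _eval(self, t: float) -> float:
        if t <= 0:
            return 0.0
        if math.isinf(t):
            n_final = self.n0 - len(self.events)
            if n_final > 1:
                return math.inf
            return float(self.cum[-1])
        j = int(np.searchsorted(self.bp, t, side="right")) - 1
        n = self.n0 - j
        if n < 1:
            n = 1
        return float(self.cum[j]) + (t - float(self.bp[j])) * n * (n - 1)

    def count(self, lo: float, hi: float) -> int:
        return int(
            np.searchsorted(self.events, hi, side="left")
            - np.searchsorted(self.events, lo, side="left")
        )


class MSCLikelihood:
    """Censored-coalescent likelihood of fixed gene trees on a guide tree.

    Precomputes, per locus and per guide node, the within-clade coalescent
    profile (event ages, lineage counts, cumulative ``n (n - 1) dt``), so
    that the log-likelihood of any delimitation model with any divergence
    times is a handful of array lookups per population.  This is the
    workhorse behind the rjMCMC sampler and the exhaustive-posterior
    oracle.

    Parameters
    ----------
    gene_trees
        One ultrametric tree per locus (node ages on the locus's own
        substitution scale).  An empty list is allowed: the likelihood is
        then identically 0 and the posterior equals the prior.
    heredity
        Per-locus multiplier on effective theta (1/4 for a haploid
        maternally inherited locus against nuclear loci).
    locus_rates
        Per-locus relative substitution rates, mean 1; gene-tree ages are
        divided by the rate before statistics are accumulated.
    diploid
        Doubles every heredity scalar, for the sensitivity analysis that
        treats nuclear loci as diploid (mtDNA then sits at one half).
    """

    def __init__(
        self,
        gene_trees: Sequence[UltrametricTree],
        taxon_map: TaxonMap,
        guide: GuideTree,
        heredity: Sequence[float] | None = None,
        locus_rates: Sequence[float] | None = None,
        diploid: bool = False,
    ):
        self.guide = guide
        self.taxon_map = taxon_map
        self.n_loci = len(gene_trees)
        h = list(heredity) if heredity is not None else [1.0] * self.n_loci
        r = list(locus_rates) if locus_rates is not None else [1.0] * self.n_loci
        if len(h) != self.n_loci or len(r) != self.n_loci:
            raise ValueError("heredity and locus_rates must match the locus count")
        if diploid:
            h = [2.0 * x for x in h]
        self.heredity = h
        self.locus_rates = r
        self._log_h = [math.log(x) for x in h]

        n_nodes = len(guide.nodes)
        self._profiles: list[list[_NodeProfile]] = []
        self._min_home_age = np.full(n_nodes, math.inf)
        masks = self._clade_masks()
        for locus, tree in enumerate(gene_trees):
            self._profiles.append(
                self._build_locus(tree, masks, r[locus], locus)
            )

    # ------------------------------------------------------------------
    def _clade_masks(self) -> list[int]:
        guide = self.guide
        masks = [0] * len(guide.nodes)
        for node in guide.nodes:
            if node.is_tip:
                masks[node.index] = 1 << guide.tip_index[node.label]
            else:
                m = 0
                for c in node.children:
                    m |= masks[c.index]
                masks[node.index] = m
        return masks

    def _build_locus(
        self, tree: UltrametricTree, masks: list[int], rate: float, locus: int
    ) -> list[_NodeProfile]:
        guide = self.guide
        tipmask: dict[int, int] = {}
        home_events: dict[int, list[float]] = {}
        tips_in_clade = [0] * len(guide.nodes)
        for tip in tree.tips:
            sp = self.taxon_map.species_of(tip.label)
            if sp not in guide.tip_index:
                raise KeyError(f"species {sp!r} is not a guide-tree tip")
            tipmask[tip.index] = 1 << guide.tip_index[sp]
            i = guide.tip_index[sp]
            while i is not None:
                tips_in_clade[i] += 1
                i = guide.parent_index[i]
        for node in tree.nodes:  # postorder
            if node.is_tip:
                continue
            m = 0
            for c in node.children:
                m |= tipmask[c.index]
            tipmask[node.index] = m
            # home: smallest guide clade containing all involved species
            lowest = (m & -m).bit_length() - 1
            i = lowest
            while masks[i] & m != m:
                i = guide.parent_index[i]
            age = node.age / rate
            home_events.setdefault(i, []).append(age)
            if age < self._min_home_age[i]:
                self._min_home_age[i] = age

        profiles: list[_NodeProfile] = []
        collected: list[list[float]] = [[] for _ in guide.nodes]
        for node in guide.nodes:  # postorder: children first
            own = list(home_events.get(node.index, []))
            for c in node.children:
                own.extend(collected[c.index])
            collected[node.index] = own
        for node in guide.nodes:
            ages = np.sort(np.asarray(collected[node.index], dtype=float))
            n0 = tips_in_clade[node.index]
            bp = np.concatenate([[0.0], ages])
            if len(ages):
                counts = n0 - np.arange(len(ages))  # lineages in segment j
                seg = counts * (counts - 1) * np.diff(bp)
                cum = np.concatenate([[0.0], np.cumsum(seg)])
            else:
                cum = np.array([0.0])
            profiles.append(_NodeProfile(events=ages, bp=bp, cum=cum, n0=n0))
        return profiles

    # ------------------------------------------------------------------
    def feasibility_bound(self, v: int) -> float:
        """Youngest coalescence joining the two sides of guide node v,
        minimized over loci; any tau_v at or below it is censoring-feasible."""
        return float(self._min_home_age[v])

    def feasible(self, model: DelimitationModel, taus: Mapping[int, float]) -> bool:
        return all(taus[v] <= self._min_home_age[v] for v in model.split_nodes)

    def _windows(
        self, model: DelimitationModel, taus: Mapping[int, float]
    ) -> list[tuple[int, float, float]]:
        guide = self.guide
        out = []
        for p in model.population_roots():
            lo = taus[p] if p in model.split_nodes else 0.0
            parent = guide.parent_index[p]
            hi = taus[parent] if parent is not None else math.inf
            out.append((p, lo, hi))
        return out

    def summaries(
        self, model: DelimitationModel, taus: Mapping[int, float]
    ) -> dict[int, tuple[int, float, float]]:
        """Pooled statistics per population root: (C, B_tilde, sum c ln h).

        ``B_tilde`` already divides each locus's integral by its heredity
        scalar, so the population density is ``(2/theta)**C exp(-B_tilde /
        theta) * exp(-sum c ln h)`` -- ready for analytic integration.
        """
        out: dict[int, tuple[int, float, float]] = {}
        for p, lo, hi in self._windows(model, taus):
            C, Bt, hlog = 0, 0.0, 0.0
            for locus in range(self.n_loci):
                prof = self._profiles[locus][p]
                cc = prof.count(lo, hi)
                bb = max(prof.integral(lo, hi), 0.0)
                C += cc
                Bt += bb / self.heredity[locus]
                hlog += cc * self._log_h[locus]
            out[p] = (C, Bt, hlog)
        return out

    def loglik_integrated(
        self,
        model: DelimitationModel,
        taus: Mapping[int, float],
        prior: PriorConfig,
    ) -> float:
        """Log marginal likelihood with every population theta integrated
        out under its InvGamma(alpha, beta) prior."""
        if not self.feasible(model, taus):
            return -math.inf
        alpha, beta = prior.alpha, prior.beta_theta
        total = 0.0
        for p, (C, Bt, hlog) in self.summaries(model, taus).items():
            if C == 0 and Bt == 0.0:
                continue
            total += (
                C * _LN2
                - hlog
                + alpha * math.log(beta)
                + gammaln(alpha + C)
                - gammaln(alpha)
                - (alpha + C) * math.log(beta + Bt)
            )
        return float(total)

    def loglik_sampled(
        self,
        model: DelimitationModel,
        taus: Mapping[int, float],
        thetas: Mapping[int, float],
    ) -> float:
        """Log-likelihood at explicit per-population theta values."""
        if not self.feasible(model, taus):
            return -math.inf
        total = 0.0
        for p, (C, Bt, hlog) in self.summaries(model, taus).items():
            if C == 0 and Bt == 0.0:
                continue
            theta = thetas[p]
            total += C * (_LN2 - math.log(theta)) - hlog - Bt / theta
        return float(total)

    def conditional_theta(
        self,
        model: DelimitationModel,
        taus: Mapping[int, float],
        prior: PriorConfig,
        rng: np.random.Generator,
    ) -> dict[int, float]:
        """Exact draw of each population theta from its conditional
        posterior InvGamma(alpha + C, beta + B_tilde) given model and taus."""
        out: dict[int, float] = {}
        for p, (C, Bt, _) in self.summaries(model, taus).items():
            out[p] = float(
                stats.invgamma.rvs(
                    prior.alpha + C, scale=prior.beta_theta + Bt, random_state=rng
                )
            )
        return out

    def event_ages(self) -> np.ndarray:
        """All rescaled coalescence ages across loci (quadrature breakpoints)."""
        ages: list[float] = []
        root = self.guide.root.index
        for locus in range(self.n_loci):
            ages.extend(self._profiles[locus][root].events.tolist())
        return np.sort(np.asarray(ages))


# ======================================================================
# functional wrappers
# ======================================================================

def msc_loglik(
    gene_trees: Sequence[UltrametricTree],
    taxon_map: TaxonMap,
    guide: GuideTree,
    model: DelimitationModel,
    params: MSCParams,
) -> float:
    """Censored-coalescent log-likelihood at explicit theta values."""
    engine = MSCLikelihood(
        gene_trees, taxon_map, guide,
        heredity=params.heredity, locus_rates=params.locus_rates,
    )
    taus = _normalize_taus(guide, params.taus)
    thetas = {guide.index_of(k): v for k, v in params.thetas.items()}
    try:
        return engine.loglik_sampled(model, taus, thetas)
    except KeyError as exc:
        raise ValueError(f"missing parameter for population: {exc}") from exc


def msc_loglik_integrated(
    gene_trees: Sequence[UltrametricTree],
    taxon_map: TaxonMap,
    guide: GuideTree,
    model: DelimitationModel,
    taus: Mapping[int, float] | Mapping[str, float],
    prior: PriorConfig,
    heredity: Sequence[float] | None = None,
    locus_rates: Sequence[float] | None = None,
) -> float:
    """Log marginal likelihood with theta integrated out analytically."""
    engine = MSCLikelihood(
        gene_trees, taxon_map, guide, heredity=heredity, locus_rates=locus_rates
    )
    return engine.loglik_integrated(model, _normalize_taus(guide, taus), prior)
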