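"""Guided reversible-jump MCMC over species-delimitation models.

The sampler walks the collapse/split model space of a guide tree (the
guided, fixed-topology flavour of Bayesian MSC delimitation).  Its state is
the delimitation model plus the divergence times (tau) of its split nodes,
and optionally per-population theta values when theta is not integrated
out.  Moves:

* split: pick a splittable node v uniformly and propose its tau from
  ``(0, U)`` with ``U = min(parent tau, feasibility bound)`` -- the
  feasibility bound is the youngest gene-tree coalescence joining the two
  sides of v across loci, so proposals land in the censoring-feasible
  region.  Algorithm 0 proposes uniformly on ``(0, U)``; algorithm 1 draws
  ``U * z`` with ``z ~ Beta(1, 3)``, favouring shallow divergences.  The
  join move is the exact reverse; both carry full Hastings corrections,
  including the cross-dimension tau-prior normalization.
* within-model: uniform redraws of each non-root tau inside its order
  window, multiplier updates of the root tau, and (when sampled)
  multiplier updates of each theta.

A small exhaustive-posterior oracle integrates the marginal likelihood of
every model by segment-wise Gauss-Legendre quadrature (guide trees up to 4
tips), which validates the sampler on cases where both are computable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from numpy.polynomial.legendre import leggauss

from .io import TaxonMap
from .msc import (
    DelimitationModel,
    GuideTree,
    MSCLikelihood,
    ModelSpace,
    PriorConfig,
    count_delimitation_models,
    log_tau_prior,
    prior_logpdf,
)
from .trees import UltrametricTree

__all__ = [
    "MCMCConfig",
    "PosteriorSummary",
    "DelimitationResults",
    "SpeciesDelimitation",
    "run_rjmcmc",
    "exhaustive_posterior",
    "summarize_posterior",
    "prior_sensitivity_scan",
    "build_config_matrix",
    "total_variation",
    "PRIOR_GRID",
]

_LN2 = math.log(2.0)

#: the four (tau mean, theta mean) combinations of the prior grid
PRIOR_GRID: tuple[tuple[float, float], ...] = (
    (0.1, 0.1), (0.1, 0.01), (0.01, 0.1), (0.01, 0.01)
)


@dataclass
class MCMCConfig:
    """Run schedule and sampling options for the rjMCMC chain.

    The default schedule (10,000 pre-burn-in generations, then 200,000
    generations sampled every second one) suits an 8-candidate-species
    guide tree; larger model spaces want longer chains.  ``algorithm``
    selects the split-proposal variant (0 or 1), ``fixed_model`` pins the
    chain to one delimitation model (no dimension moves), and
    ``sample_thetas`` records exact conditional-posterior theta draws even
    when theta is integrated out of the chain state.
    """

    generations: int = 200_000
    sample_every: int = 2
    pre_burnin: int = 10_000
    seed: int = 0
    algorithm: int = 0
    prior: PriorConfig = field(default_factory=PriorConfig)
    integrate_theta: bool | None = None
    heredity: Sequence[float] | None = None
    locus_rates: Sequence[float] | None = None
    diploid: bool = False
    fixed_model: DelimitationModel | None = None
    sample_thetas: bool = False
    root_tau_step: float = 0.8
    theta_step: float = 1.0
    run_label: str = "run1"

    def __post_init__(self) -> None:
        if self.generations <= 0 or self.sample_every < 1 or self.pre_burnin < 0:
            raise ValueError("invalid schedule")
        if self.algorithm not in (0, 1):
            raise ValueError("algorithm must be 0 or 1")

    @property
    def theta_integrated(self) -> bool:
        if self.integrate_theta is None:
            return self.prior.integrate_theta
        return self.integrate_theta


class _ModelPrior:
    """Log prior over delimitation models, lazily enumerated for prior 0."""

    def __init__(self, guide: GuideTree, prior_id: int):
        self.prior_id = prior_id
        if prior_id == 1:
            self._const = -math.log(count_delimitation_models(guide))
            self._space = None
        else:
            self._space = ModelSpace(guide, prior_id)

    def log(self, model: DelimitationModel) -> float:
        if self._space is None:
            return self._const
        return self._space.log_prior_of(model)


# ======================================================================
# the sampler
# ======================================================================

class _Chain:
    def __init__(
        self,
        engine: MSCLikelihood,
        guide: GuideTree,
        config: MCMCConfig,
    ):
        self.engine = engine
        self.guide = guide
        self.config = config
        self.prior = config.prior
        self.rng = np.random.default_rng(config.seed)
        self.integrated = config.theta_integrated
        self.model_prior = _ModelPrior(guide, self.prior.model_prior)
        self.model = (config.fixed_model
                      if config.fixed_model is not None
                      else DelimitationModel(guide, frozenset()))
        self.taus: dict[int, float] = {}
        if self.model.split_nodes:
            self._init_taus()
        self.thetas: dict[int, float] = {}
        if not self.integrated:
            for p in self.model.population_roots():
                self.thetas[p] = self._draw_theta_prior()
        # per-population sufficient statistics and likelihood contributions
        self.stats: dict[int, tuple[int, float, float]] = {}
        self.contrib: dict[int, float] = {}
        for p in self.model.population_roots():
            self._refresh_pop(p)
        self.accept = {"split": [0, 0], "join": [0, 0],
                       "tau": [0, 0], "theta": [0, 0]}

    # ------------------------------------------------------------------
    def _init_taus(self) -> None:
        """Feasible starting taus for a fixed (pre-split) model."""
        # assign bottom-up: each node above its split children, below bounds
        for v in sorted(self.model.split_nodes, key=self._depth, reverse=True):
            lo = max(
                (self.taus[c.index] for c in self.guide.nodes[v].children
                 if c.index in self.model.split_nodes),
                default=0.0,
            )
            ub = self.engine.feasibility_bound(v)
            if math.isinf(ub):
                ub = 4.0 * self.prior.tau_mean + lo
            self.taus[v] = lo + 0.5 * (ub - lo)
        # enforce parent > child strictly
        for v in sorted(self.model.split_nodes, key=self._depth):
            for c in self.guide.nodes[v].children:
                if c.index in self.model.split_nodes:
                    if self.taus[c.index] >= self.taus[v]:
                        self.taus[c.index] = 0.5 * self.taus[v]

    def _depth(self, v: int) -> int:
        d, i = 0, v
        while self.guide.parent_index[i] is not None:
            i = self.guide.parent_index[i]
            d += 1
        return d

    def _draw_theta_prior(self) -> float:
        return float(stats.invgamma.rvs(
            self.prior.alpha, scale=self.prior.beta_theta, random_state=self.rng
        ))

    # ------------------------------------------------------------------
    def _pop_stats(self, p: int, model=None, taus=None) -> tuple[int, float, float]:
        model = model or self.model
        taus = taus if taus is not None else self.taus
        lo = taus[p] if p in model.split_nodes else 0.0
        parent = self.guide.parent_index[p]
        hi = taus[parent] if parent is not None else math.inf
        C, Bt, hlog = 0, 0.0, 0.0
        eng = self.engine
        for locus in range(eng.n_loci):
            prof = eng._profiles[locus][p]
            cc = prof.count(lo, hi)
            bb = prof.integral(lo, hi)
            if bb < 0.0:
                bb = 0.0
            C += cc
            Bt += bb / eng.heredity[locus]
            hlog += cc * eng._log_h[locus]
        return C, Bt, hlog

    def _contrib_of(self, p: int, stats_p: tuple[int, float, float]) -> float:
        C, Bt, hlog = stats_p
        if C == 0 and Bt == 0.0:
            return 0.0
        if self.integrated:
            a, b = self.prior.alpha, self.prior.beta_theta
            return (C * _LN2 - hlog + a * math.log(b)
                    + gammaln(a + C) - gammaln(a)
                    - (a + C) * math.log(b + Bt))
        theta = self.thetas[p]
        return C * (_LN2 - math.log(theta)) - hlog - Bt / theta

    def _refresh_pop(self, p: int) -> None:
        s = self._pop_stats(p)
        self.stats[p] = s
        self.contrib[p] = self._contrib_of(p, s)

    def loglik(self) -> float:
        return float(sum(self.contrib.values()))

    # ------------------------------------------------------------------
    # move machinery
    # ------------------------------------------------------------------
    def _move_probs(self, model: DelimitationModel) -> tuple[float, float, int, int]:
        n_sp = len(model.splittable_nodes())
        n_jo = len(model.joinable_nodes())
        if n_sp and n_jo:
            return 0.5, 0.5, n_sp, n_jo
        if n_sp:
            return 1.0, 0.0, n_sp, n_jo
        if n_jo:
            return 0.0, 1.0, n_sp, n_jo
        return 0.0, 0.0, 0, 0

    def _split_upper(self, v: int, model: DelimitationModel,
                     taus: Mapping[int, float]) -> float:
        parent = self.guide.parent_index[v]
        ub = self.engine.feasibility_bound(v)
        if parent is not None:
            ub = min(ub, taus[parent])
        if math.isinf(ub):
            ub = 4.0 * self.prior.tau_mean
        return ub

    def _tau_proposal_logpdf(self, tau: float, upper: float) -> float:
        if not 0.0 < tau < upper:
            return -math.inf
        if self.config.algorithm == 0:
            return -math.log(upper)
        z = tau / upper
        return math.log(3.0) + 2.0 * math.log1p(-z) - math.log(upper)

    def _draw_tau_proposal(self, upper: float) -> float:
        if self.config.algorithm == 0:
            return float(self.rng.uniform(0.0, upper))
        return float(upper * self.rng.beta(1.0, 3.0))

    def rj_move(self) -> None:
        p_split, p_join, n_sp, n_jo = self._move_probs(self.model)
        if n_sp == 0 and n_jo == 0:
            return
        if self.rng.random() < p_split:
            self._split_move(p_split, n_sp)
        else:
            self._join_move(p_join, n_jo)

    def _split_move(self, p_split: float, n_sp: int) -> None:
        rec = self.accept["split"]
        rec[1] += 1
        nodes = self.model.splittable_nodes()
        v = nodes[int(self.rng.integers(n_sp))]
        upper = self._split_upper(v, self.model, self.taus)
        if upper <= 0.0:
            return
        tau_new = self._draw_tau_proposal(upper)
        new_model = self.model.split(v)
        c1, c2 = (c.index for c in self.guide.nodes[v].children)

        old_tp = log_tau_prior(self.model, self.taus, self.prior)
        self.taus[v] = tau_new
        new_tp = log_tau_prior(new_model, self.taus, self.prior)

        new_thetas: dict[int, float] = {}
        if not self.integrated:
            new_thetas = {c1: self._draw_theta_prior(),
                          c2: self._draw_theta_prior()}
            self.thetas.update(new_thetas)

        new_stats = {p: self._pop_stats(p, model=new_model)
                     for p in (v, c1, c2)}
        new_contrib = {p: self._contrib_of(p, s) for p, s in new_stats.items()}
        delta_ll = sum(new_contrib.values()) - self.contrib[v]
        delta_mp = self.model_prior.log(new_model) - self.model_prior.log(self.model)

        _, p_join_new, _, n_jo_new = self._move_probs(new_model)
        log_fwd = math.log(p_split) - math.log(n_sp) \
            + self._tau_proposal_logpdf(tau_new, upper)
        log_rev = (math.log(p_join_new) - math.log(n_jo_new)
                   if n_jo_new else -math.inf)

        log_acc = delta_ll + delta_mp + (new_tp - old_tp) + log_rev - log_fwd
        if math.log(self.rng.random()) < log_acc:
            rec[0] += 1
            self.model = new_model
            for p, s in new_stats.items():
                self.stats[p] = s
                self.contrib[p] = new_contrib[p]
        else:
            del self.taus[v]
            for p in new_thetas:
                del self.thetas[p]

    def _join_move(self, p_join: float, n_jo: int) -> None:
        rec = self.accept["join"]
        rec[1] += 1
        nodes = self.model.joinable_nodes()
        v = nodes[int(self.rng.integers(n_jo))]
        c1, c2 = (c.index for c in self.guide.nodes[v].children)
        new_model = self.model.join(v)
        tau_old = self.taus[v]

        old_tp = log_tau_prior(self.model, self.taus, self.prior)
        saved_tau = self.taus.pop(v)
        new_tp = log_tau_prior(new_model, self.taus, self.prior)

        new_stats = {v: self._pop_stats(v, model=new_model)}
        new_contrib = {v: self._contrib_of(v, new_stats[v])}
        delta_ll = (new_contrib[v]
                    - self.contrib[v] - self.contrib[c1] - self.contrib[c2])
        delta_mp = self.model_prior.log(new_model) - self.model_prior.log(self.model)

        p_split_new, _, n_sp_new, _ = self._move_probs(new_model)
        upper_rev = self._split_upper(v, new_model, self.taus)
        log_rev = (math.log(p_split_new) - math.log(n_sp_new)
                   + self._tau_proposal_logpdf(tau_old, upper_rev))
        log_fwd = math.log(p_join) - math.log(n_jo)

        log_acc = delta_ll + delta_mp + (new_tp - old_tp) + log_rev - log_fwd
        if math.log(self.rng.random()) < log_acc:
            rec[0] += 1
            self.model = new_model
            self.stats[v] = new_stats[v]
            self.contrib[v] = new_contrib[v]
            for p in (c1, c2):
                del self.stats[p]
                del self.contrib[p]
                self.thetas.pop(p, None)
        else:
            self.taus[v] = saved_tau

    # ------------------------------------------------------------------
    def tau_move(self, v: int) -> None:
        rec = self.accept["tau"]
        rec[1] += 1
        guide = self.guide
        parent = guide.parent_index[v]
        children = [c.index for c in guide.nodes[v].children]
        split_children = [c for c in children if c in self.model.split_nodes]
        lo = max((self.taus[c] for c in split_children), default=0.0)
        old = self.taus[v]
        if parent is None:
            new = old * math.exp(self.config.root_tau_step
                                 * (self.rng.random() - 0.5))
            hastings = math.log(new / old)
            if new <= lo:
                return
            delta_prior = (
                prior_logpdf("tau_root", new, self.prior)
                - prior_logpdf("tau_root", old, self.prior)
                - (len(self.model.split_nodes) - 1)
                * (math.log(new) - math.log(old))
            )
        else:
            hi = self.taus[parent]
            if hi <= lo:
                return
            if self.rng.random() < 0.5:
                # independence draw over the full order window
                new = float(self.rng.uniform(lo, hi))
            else:
                # local symmetric walk for fine mixing near sharp modes
                new = old + float(self.rng.normal(0.0, 0.1 * (hi - lo)))
                if not lo < new < hi:
                    return
            hastings = 0.0
            delta_prior = 0.0  # flat within the order region
        if new > self.engine.feasibility_bound(v):
            return
        affected = [v] + children
        old_stats = {p: self.stats[p] for p in affected}
        old_contrib = {p: self.contrib[p] for p in affected}
        self.taus[v] = new
        new_stats = {p: self._pop_stats(p) for p in affected}
        new_contrib = {p: self._contrib_of(p, new_stats[p]) for p in affected}
        delta_ll = sum(new_contrib.values()) - sum(old_contrib.values())
        if math.log(self.rng.random()) < delta_ll + delta_prior + hastings:
            rec[0] += 1
            self.stats.update(new_stats)
            self.contrib.update(new_contrib)
        else:
            self.taus[v] = old

    def theta_move(self, p: int) -> None:
        rec = self.accept["theta"]
        rec[1] += 1
        old = self.thetas[p]
        new = old * math.exp(self.config.theta_step * (self.rng.random() - 0.5))
        delta_prior = (prior_logpdf("theta", new, self.prior)
                       - prior_logpdf("theta", old, self.prior))
        self.thetas[p] = new
        new_contrib = self._contrib_of(p, self.stats[p])
        delta = new_contrib - self.contrib[p] + delta_prior + math.log(new / old)
        if math.log(self.rng.random()) < delta:
            rec[0] += 1
            self.contrib[p] = new_contrib
        else:
            self.thetas[p] = old

    # ------------------------------------------------------------------
    def sweep(self) -> None:
        if self.config.fixed_model is None:
            self.rj_move()
        for v in sorted(self.model.split_nodes):
            self.tau_move(v)
        if not self.integrated:
            for p in list(self.model.population_roots()):
                self.theta_move(p)

    def conditional_thetas(self) -> dict[int, float]:
        out = {}
        a, b = self.prior.alpha, self.prior.beta_theta
        for p in self.model.population_roots():
            C, Bt, _ = self.stats[p]
            out[p] = float(stats.invgamma.rvs(a + C, scale=b + Bt,
                                              random_state=self.rng))
        return out


@dataclass
class PosteriorSummary:
    """Posterior sample summary of one rjMCMC run.

    ``model_probs`` maps a model key (sorted tuple of split-node indices)
    to its posterior probability; ``split_probs`` gives, per internal guide
    node, the probability that it is split (a real speciation event).
    """

    guide: GuideTree = field(repr=False)
    model_probs: dict[tuple[int, ...], float]
    split_probs: dict[int, float]
    n_species_probs: dict[int, float]
    n_samples: int
    run_label: str = "run1"
    prior: PriorConfig | None = None
    tau_samples: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    theta_samples: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def best_model(self) -> tuple[tuple[int, ...], float]:
        key = max(self.model_probs, key=self.model_probs.get)
        return key, self.model_probs[key]

    def split_table(self) -> pd.DataFrame:
        rows = [
            {"node": v, "clade": self.guide.clade_label(v), "pp_split": pp}
            for v, pp in sorted(self.split_probs.items())
        ]
        return pd.DataFrame(rows)

    def credible_interval(self, which: str, key: int, level: float = 0.95):
        """Equal-tailed credible interval of a tau or theta trace."""
        samples = (self.tau_samples if which == "tau" else self.theta_samples)[key]
        vals = samples[~np.isnan(samples)]
        if len(vals) == 0:
            raise ValueError(f"no samples for {which}[{key}]")
        a = (1.0 - level) / 2.0
        return float(np.quantile(vals, a)), float(np.quantile(vals, 1.0 - a))


def run_rjmcmc(
    gene_trees: Sequence[UltrametricTree],
    taxon_map: TaxonMap,
    guide_tree: GuideTree,
    config: MCMCConfig,
) -> PosteriorSummary:
    """Sample the delimitation posterior by reversible-jump MCMC.

    The chain starts at the fully collapsed model (always feasible) unless
    ``config.fixed_model`` pins it.  Samples are recorded every
    ``sample_every`` generations after ``pre_burnin``.
    """
    engine = MSCLikelihood(
        gene_trees, taxon_map, guide_tree,
        heredity=config.heredity, locus_rates=config.locus_rates,
        diploid=config.diploid,
    )
    return _run_chain(engine, guide_tree, config)


def _run_chain(
    engine: MSCLikelihood, guide_tree: GuideTree, config: MCMCConfig
) -> PosteriorSummary:
    chain = _Chain(engine, guide_tree, config)
    internal = [n.index for n in guide_tree.internal_nodes]
    model_counts: dict[tuple[int, ...], int] = {}
    split_counts = {v: 0 for v in internal}
    nsp_counts: dict[int, int] = {}
    tau_trace: dict[int, list[float]] = {v: [] for v in internal}
    theta_trace: dict[int, list[float]] = {i: [] for i in range(len(guide_tree.nodes))}
    want_theta = (not chain.integrated) or config.sample_thetas

    total = config.pre_burnin + config.generations
    n_rec = 0
    for gen in range(total):
        chain.sweep()
        if gen < config.pre_burnin or (gen - config.pre_burnin) % config.sample_every:
            continue
        n_rec += 1
        key = chain.model.key
        model_counts[key] = model_counts.get(key, 0) + 1
        nsp = chain.model.n_species
        nsp_counts[nsp] = nsp_counts.get(nsp, 0) + 1
        for v in key:
            split_counts[v] += 1
        for v in internal:
            tau_trace[v].append(chain.taus.get(v, math.nan))
        if want_theta:
            thetas = (chain.thetas if not chain.integrated
                      else chain.conditional_thetas())
            for i in theta_trace:
                theta_trace[i].append(thetas.get(i, math.nan))

    return PosteriorSummary(
        guide=guide_tree,
        model_probs={k: c / n_rec for k, c in sorted(model_counts.items())},
        split_probs={v: split_counts[v] / n_rec for v in internal},
        n_species_probs={k: c / n_rec for k, c in sorted(nsp_counts.items())},
        n_samples=n_rec,
        run_label=config.run_label,
        prior=config.prior,
        tau_samples={v: np.asarray(t) for v, t in tau_trace.items()},
        theta_samples=({i: np.asarray(t) for i, t in theta_trace.items() if t}
                       if want_theta else {}),
        acceptance={k: (a / n if n else math.nan)
                    for k, (a, n) in chain.accept.items()},
    )


# ======================================================================
# exhaustive posterior (tiny-case oracle)
# ======================================================================

def exhaustive_posterior(
    gene_trees: Sequence[UltrametricTree],
    taxon_map: TaxonMap,
    guide_tree: GuideTree,
    prior: PriorConfig,
    heredity: Sequence[float] | None = None,
    locus_rates: Sequence[float] | None = None,
    gl_points: int = 10,
) -> dict[tuple[int, ...], float]:
    """Exact (quadrature) posterior over all delimitation models.

    Only guide trees with at most 4 candidate species are accepted: the
    per-model marginal likelihood is integrated over up to three divergence
    times by segment-wise Gauss-Legendre quadrature with segment boundaries
    at the gene-tree coalescence ages (the likelihood is smooth between
    them), with theta integrated analytically throughout.  Larger spaces
    need the rjMCMC sampler.
    """
    if guide_tree.n_tips > 4:
        raise ValueError(
            "exhaustive posterior supports at most 4 candidate species; "
            "use run_rjmcmc for larger guide trees"
        )
    engine = MSCLikelihood(
        gene_trees, taxon_map, guide_tree,
        heredity=heredity, locus_rates=locus_rates,
    )
    space = ModelSpace(guide_tree, prior.model_prior)
    breakpoints = engine.event_ages()
    log_posts = {}
    for i, model in enumerate(space.models):
        logml = _log_marginal(engine, model, prior, breakpoints, gl_points)
        log_posts[model.key] = float(space.log_prior[i]) + logml
    keys = list(log_posts)
    vals = np.array([log_posts[k] for k in keys])
    norm = logsumexp(vals)
    return {k: float(np.exp(v - norm)) for k, v in zip(keys, vals)}


def _log_marginal(
    engine: MSCLikelihood,
    model: DelimitationModel,
    prior: PriorConfig,
    breakpoints: np.ndarray,
    gl_points: int,
) -> float:
    guide = engine.guide
    split = sorted(model.split_nodes)
    if not split:
        return engine.loglik_integrated(model, {}, prior)
    # order split nodes root-first so parents are assigned before children
    depth = {}
    for v in split:
        d, i = 0, v
        while guide.parent_index[i] is not None:
            i = guide.parent_index[i]
            d += 1
        depth[v] = d
    order = sorted(split, key=lambda v: depth[v])
    nodes_gl, weights_gl = leggauss(gl_points)
    terms: list[float] = []
    taus: dict[int, float] = {}

    def upper_bound(v: int) -> float:
        parent = guide.parent_index[v]
        ub = engine.feasibility_bound(v)
        if parent is not None:
            ub = min(ub, taus[parent])
        if math.isinf(ub):
            # no coalescence constrains the root: integrate essentially all
            # of the prior mass
            ub = float(stats.invgamma.ppf(1.0 - 1e-9, prior.alpha,
                                          scale=prior.beta_tau))
        return ub

    def recurse(i: int, logw: float) -> None:
        if i == len(order):
            ll = engine.loglik_integrated(model, taus, prior)
            if math.isfinite(ll):
                tp = log_tau_prior(model, taus, prior)
                if math.isfinite(tp):
                    terms.append(logw + ll + tp)
            return
        v = order[i]
        ub = upper_bound(v)
        if ub <= 0.0:
            return
        inner = breakpoints[(breakpoints > 0) & (breakpoints < ub)]
        if guide.parent_index[v] is None:
            # anchor the root grid on the prior's quantiles as well, so an
            # unconstrained root (e.g. zero loci) is still integrated well
            qs = stats.invgamma.ppf(
                np.linspace(0.02, 0.98, 13), prior.alpha, scale=prior.beta_tau
            )
            inner = np.unique(np.concatenate([inner, qs[(qs > 0) & (qs < ub)]]))
        bps = np.concatenate([[0.0], inner, [ub]])
        for a, b in zip(bps[:-1], bps[1:]):
            if b <= a:
                continue
            half = 0.5 * (b - a)
            mid = 0.5 * (a + b)
            for xg, wg in zip(nodes_gl, weights_gl):
                taus[v] = mid + half * xg
                recurse(i + 1, logw + math.log(wg * half))
        taus.pop(v, None)

    recurse(0, 0.0)
    if not terms:
        return -math.inf
    return float(logsumexp(np.asarray(terms)))


def total_variation(
    p: Mapping[tuple[int, ...], float], q: Mapping[tuple[int, ...], float]
) -> float:
    """Total-variation distance between two model posteriors."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


# ======================================================================
# summaries, sensitivity scan, config matrix
# ======================================================================

@dataclass
class DelimitationResults:
    """Merged posterior over one or more rjMCMC runs on one model space.

    Per-run values are retained for convergence reporting; the merged
    probabilities are plain across-run means (the convention of averaging
    dual runs).
    """

    guide: GuideTree = field(repr=False)
    runs: list[PosteriorSummary] = field(repr=False)
    model_probs: dict[tuple[int, ...], float] = field(default_factory=dict)
    split_probs: dict[int, float] = field(default_factory=dict)
    n_species_probs: dict[int, float] = field(default_factory=dict)
    convergence_threshold: float = 0.05

    @property
    def best_model(self) -> tuple[tuple[int, ...], float]:
        key = max(self.model_probs, key=self.model_probs.get)
        return key, self.model_probs[key]

    @property
    def max_split_discrepancy(self) -> float:
        if len(self.runs) < 2:
            return 0.0
        worst = 0.0
        for v in self.split_probs:
            vals = [r.split_probs.get(v, 0.0) for r in self.runs]
            worst = max(worst, max(vals) - min(vals))
        return worst

    @property
    def converged(self) -> bool:
        return self.max_split_discrepancy <= self.convergence_threshold

    def split_table(self) -> pd.DataFrame:
        rows = []
        for v, pp in sorted(self.split_probs.items()):
            row = {"node": v, "clade": self.guide.clade_label(v), "pp_split": pp}
            for r in self.runs:
                row[f"pp[{r.run_label}]"] = r.split_probs.get(v, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        key, pp = self.best_model
        model = DelimitationModel(self.guide, frozenset(key))
        units = sorted(set(model.species_partition().values()))
        lines = [
            "Guided MSC species delimitation (rjMCMC)",
            "=" * 48,
            f"runs                  {len(self.runs)}  "
            f"(samples: {', '.join(str(r.n_samples) for r in self.runs)})",
            f"best model            {model.n_species} species, PP = {pp:.3f}",
            f"delimited units       {'; '.join(units)}",
            f"dual-run max |dPP|    {self.max_split_discrepancy:.4f} "
            f"({'converged' if self.converged else 'NOT converged'} at "
            f"{self.convergence_threshold})",
            "",
            self.split_table().to_string(index=False),
        ]
        return "\n".join(lines)


def summarize_posterior(runs: Sequence[PosteriorSummary]) -> DelimitationResults:
    """Average per-model and per-split posterior probabilities across runs."""
    if not runs:
        raise ValueError("need at least one run")
    guide = runs[0].guide
    for r in runs[1:]:
        if r.guide.tip_labels != guide.tip_labels or \
           r.guide.to_newick() != guide.to_newick():
            raise ValueError("runs summarize different model spaces")
    model_keys = sorted({k for r in runs for k in r.model_probs})
    model_probs = {
        k: float(np.mean([r.model_probs.get(k, 0.0) for r in runs]))
        for k in model_keys
    }
    split_probs = {
        v: float(np.mean([r.split_probs.get(v, 0.0) for r in runs]))
        for v in runs[0].split_probs
    }
    nsp = sorted({k for r in runs for k in r.n_species_probs})
    nsp_probs = {
        k: float(np.mean([r.n_species_probs.get(k, 0.0) for r in runs]))
        for k in nsp
    }
    return DelimitationResults(
        guide=guide, runs=list(runs),
        model_probs=model_probs, split_probs=split_probs,
        n_species_probs=nsp_probs,
    )


@dataclass
class SensitivityScan:
    """Per-split posterior support across the prior grid.

    ``table`` has one row per internal guide node and one column per prior
    combination; a split is flagged prior-sensitive when it clears the
    support threshold under some but not all combinations.
    """

    guide: GuideTree = field(repr=False)
    results: dict[str, DelimitationResults] = field(repr=False, default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    threshold: float = 0.95

    def sensitive_splits(self) -> list[str]:
        out = []
        for clade, row in self.table.iterrows():
            above = row > self.threshold
            if above.any() and not above.all():
                out.append(clade)
        return out

    def best_models(self) -> dict[str, tuple[tuple[int, ...], float]]:
        return {label: res.best_model for label, res in self.results.items()}


def prior_sensitivity_scan(
    gene_trees: Sequence[UltrametricTree],
    taxon_map: TaxonMap,
    guide_tree: GuideTree,
    base_config: MCMCConfig,
    prior_means: Sequence[tuple[float, float]] = PRIOR_GRID,
    runs_per: int = 2,
) -> SensitivityScan:
    """Run the delimitation under each (tau mean, theta mean) combination.

    Each combination is run ``runs_per`` times with distinct derived seeds
    and averaged; the scan reports per-split support per combination and
    flags splits whose support is sensitive to the prior.
    """
    engine = MSCLikelihood(
        gene_trees, taxon_map, guide_tree,
        heredity=base_config.heredity, locus_rates=base_config.locus_rates,
        diploid=base_config.diploid,
    )
    results: dict[str, DelimitationResults] = {}
    for combo_idx, (tau_mean, theta_mean) in enumerate(prior_means):
        prior = replace(base_config.prior, tau_mean=tau_mean,
                        theta_mean=theta_mean)
        runs = []
        for run_idx in range(runs_per):
            seed = derive_seed(base_config.seed, combo_idx, run_idx)
            cfg = replace(base_config, prior=prior, seed=seed,
                          run_label=f"run{run_idx + 1}")
            runs.append(_run_chain(engine, guide_tree, cfg))
        results[prior.label] = summarize_posterior(runs)
    internal = [n.index for n in guide_tree.internal_nodes]
    table = pd.DataFrame(
        {
            label: [res.split_probs.get(v, 0.0) for v in internal]
            for label, res in results.items()
        },
        index=[guide_tree.clade_label(v) for v in internal],
    )
    return SensitivityScan(guide=guide_tree, results=results, table=table)


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic sub-seed below 2**31 from a base seed and indices."""
    ss = np.random.SeedSequence([int(base_seed)] + [int(i) for i in indices])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_config_matrix(
    base_config: MCMCConfig,
    guide_modes: Sequence[str] = ("guided", "unguided"),
    max_species: Sequence[int] = (8, 13),
    prior_means: Sequence[tuple[float, float]] = PRIOR_GRID,
    runs_per: int = 2,
) -> list[dict]:
    """The full analysis grid: guide modes x species caps x prior grid,
    each expanded into ``runs_per`` seeded configurations.

    Unguided (topology-searching) entries are marked unsupported by the
    core sampler, which always conditions on a guide tree; they stay in
    the matrix so the bookkeeping mirrors the full design.
    """
    if not guide_modes or not max_species or not prior_means or runs_per < 1:
        raise ValueError("option sets must be non-empty")
    out = []
    analysis_id = 0
    for mode in guide_modes:
        for cap in max_species:
            for tau_mean, theta_mean in prior_means:
                analysis_id += 1
                for run_idx in range(runs_per):
                    prior = replace(base_config.prior, tau_mean=tau_mean,
                                    theta_mean=theta_mean)
                    cfg = replace(
                        base_config,
                        prior=prior,
                        seed=derive_seed(base_config.seed, analysis_id, run_idx),
                        run_label=f"run{run_idx + 1}",
                    )
                    out.append(
                        {
                            "analysis_id": analysis_id,
                            "guide_mode": mode,
                            "max_species": cap,
                            "prior": prior.label,
                            "run": run_idx + 1,
                            "config": cfg,
                            "supported": mode == "guided",
                        }
                    )
    return out


# ======================================================================
# model-style front end
# ======================================================================

class SpeciesDelimitation:
    """Guided Bayesian species delimitation under the MSC.

    Statsmodels-style front end: construct the model from data (gene
    trees, individual-to-species map, guide tree, per-locus heredity and
    rates), then ``fit()`` to obtain :class:`DelimitationResults`.

    Examples
    --------
    >>> model = SpeciesDelimitation(gene_trees, taxon_map, guide,
    ...                             heredity=[0.25, 1, 1, 1])   # doctest: +SKIP
    >>> res = model.fit(prior=PriorConfig(tau_mean=0.1, theta_mean=0.01))
    ... # doctest: +SKIP
    >>> print(res.summary())                                    # doctest: +SKIP
    """

    def __init__(
        self,
        gene_trees: Sequence[UltrametricTree],
        taxon_map: TaxonMap,
        guide_tree: GuideTree,
        heredity: Sequence[float] | None = None,
        locus_rates: Sequence[float] | None = None,
        diploid: bool = False,
    ):
        self.gene_trees = list(gene_trees)
        self.taxon_map = taxon_map
        self.guide = guide_tree
        self.heredity = heredity
        self.locus_rates = locus_rates
        self.diploid = diploid
        self.engine = MSCLikelihood(
            gene_trees, taxon_map, guide_tree,
            heredity=heredity, locus_rates=locus_rates, diploid=diploid,
        )

    def _config(self, config: MCMCConfig | None, prior: PriorConfig | None,
                **overrides) -> MCMCConfig:
        cfg = config if config is not None else MCMCConfig()
        if prior is not None:
            cfg = replace(cfg, prior=prior)
        cfg = replace(cfg, heredity=self.heredity,
                      locus_rates=self.locus_rates, diploid=self.diploid)
        if overrides:
            cfg = replace(cfg, **overrides)
        return cfg

    def fit(
        self,
        config: MCMCConfig | None = None,
        prior: PriorConfig | None = None,
        n_runs: int = 2,
        **overrides,
    ) -> DelimitationResults:
        """Run ``n_runs`` rjMCMC chains with derived seeds and merge them."""
        cfg = self._config(config, prior, **overrides)
        runs = []
        for run_idx in range(n_runs):
            run_cfg = replace(
                cfg,
                seed=derive_seed(cfg.seed, run_idx) if n_runs > 1 else cfg.seed,
                run_label=f"run{run_idx + 1}",
            )
            runs.append(_run_chain(self.engine, self.guide, run_cfg))
        return summarize_posterior(runs)

    def fit_exhaustive(self, prior: PriorConfig | None = None,
                       gl_points: int = 10) -> dict[tuple[int, ...], float]:
        """Quadrature posterior (guide trees of at most 4 species)."""
        return exhaustive_posterior(
            self.gene_trees, self.taxon_map, self.guide,
            prior if prior is not None else PriorConfig(),
            heredity=self.heredity, locus_rates=self.locus_rates,
            gl_points=gl_points,
        )

    def prior_sensitivity(
        self,
        base_config: MCMCConfig | None = None,
        prior_means: Sequence[tuple[float, float]] = PRIOR_GRID,
        runs_per: int = 2,
    ) -> SensitivityScan:
        cfg = self._config(base_config, None)
        return prior_sensitivity_scan(
            self.gene_trees, self.taxon_map, self.guide, cfg,
            prior_means=prior_means, runs_per=runs_per,
        )
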