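import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from coaldelim.io import TaxonMap
from coaldelim.msc import (
    DelimitationModel,
    GuideTree,
    InfeasibleError,
    MSCLikelihood,
    MSCParams,
    ModelSpace,
    PriorConfig,
    coalescent_summaries,
    count_delimitation_models,
    enumerate_delimitation_models,
    labelled_history_count,
    log_tau_prior,
    model_prior_log,
    msc_loglik,
    msc_loglik_integrated,
    prior_logpdf,
)
from coaldelim.trees import UltrametricTree


def brute_force_model_count(guide: GuideTree) -> int:
    """Independent oracle: filter all flag assignments by the rule that a
    split node's parent must be split."""
    internal = [n.index for n in guide.internal_nodes]
    count = 0
    for flags in itertools.product([False, True], repeat=len(internal)):
        split = {v for v, f in zip(internal, flags) if f}
        ok = all(
            guide.parent_index[v] is None or guide.parent_index[v] in split
            for v in split
        )
        count += ok
    return count


def random_guide(n_tips: int, seed: int) -> GuideTree:
    rng = np.random.default_rng(seed)
    labels = [f"S{i}" for i in range(n_tips)]
    groups = [lab for lab in labels]
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), 2, replace=False))
        b = groups.pop(j)
        a = groups.pop(i)
        groups.append(f"({a},{b})")
    return GuideTree.from_newick(groups[0] + ";")


class TestModelSpace:
    def test_two_tip_guide(self):
        g = GuideTree.from_newick("(A,B);")
        models = enumerate_delimitation_models(g)
        assert len(models) == 2
        assert {m.n_species for m in models} == {1, 2}

    def test_three_tip_guide(self):
        g = GuideTree.from_newick("((A,B),C);")
        assert len(enumerate_delimitation_models(g)) == 3

    def test_study_shape_has_21_models(self, fig3_guide):
        assert count_delimitation_models(fig3_guide) == 21
        assert len(enumerate_delimitation_models(fig3_guide)) == 21

    def test_caterpillar_and_balanced_counts(self):
        cat = GuideTree.from_newick("(((((((A,B),C),D),E),F),G),H);")
        bal = GuideTree.from_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        assert count_delimitation_models(cat) == 8
        assert count_delimitation_models(bal) == 26

    @pytest.mark.parametrize("n_tips", [2, 3, 4, 5, 6, 7, 8])
    def test_count_matches_brute_force(self, n_tips):
        for seed in range(3):
            g = random_guide(n_tips, seed + 10 * n_tips)
            assert count_delimitation_models(g) == brute_force_model_count(g)
            assert len(enumerate_delimitation_models(g)) == \
                count_delimitation_models(g)

    def test_ancestor_constraint_enforced(self):
        g = GuideTree.from_newick("((A,B),C);")
        inner = next(n.index for n in g.internal_nodes if n is not g.root)
        with pytest.raises(ValueError):
            DelimitationModel(g, frozenset({inner}))

    def test_species_partition_and_roots(self, fig3_guide):
        g = fig3_guide
        full = DelimitationModel(
            g, frozenset(n.index for n in g.internal_nodes)
        )
        assert full.n_species == 8
        collapsed = DelimitationModel(g, frozenset())
        assert collapsed.n_species == 1
        assert set(collapsed.species_partition().values()) == {
            g.clade_label(g.root.index)
        }


def brute_force_labelled_histories(guide: GuideTree) -> int:
    """Count total orderings of internal nodes compatible with the tree."""
    internal = [n.index for n in guide.internal_nodes]
    parent = guide.parent_index
    count = 0
    for perm in itertools.permutations(internal):
        rank = {v: i for i, v in enumerate(perm)}
        ok = all(
            parent[v] is None or rank[parent[v]] < rank[v] for v in internal
        )
        count += ok
    return count


class TestLabelledHistories:
    @pytest.mark.parametrize(
        "newick, expected",
        [("(A,B);", 1), ("((A,B),(C,D));", 2), ("(((A,B),C),D);", 1)],
    )
    def test_examples(self, newick, expected):
        assert labelled_history_count(GuideTree.from_newick(newick)) == expected

    @pytest.mark.parametrize("n_tips", [3, 4, 5, 6])
    def test_matches_enumeration(self, n_tips):
        g = random_guide(n_tips, 99 + n_tips)
        assert labelled_history_count(g) == brute_force_labelled_histories(g)


class TestModelPrior:
    @pytest.mark.parametrize("prior_id", [0, 1])
    def test_normalizes(self, fig3_guide, prior_id):
        space = ModelSpace(fig3_guide, prior_id)
        assert np.exp(space.log_prior).sum() == pytest.approx(1.0, abs=1e-12)

    def test_prior1_uniform_over_21(self, fig3_guide):
        models = enumerate_delimitation_models(fig3_guide)
        for m in models[:5]:
            assert model_prior_log(m, fig3_guide, 1) == pytest.approx(
                -math.log(21)
            )

    def test_prior0_two_tips_uniform(self):
        g = GuideTree.from_newick("(A,B);")
        for m in enumerate_delimitation_models(g):
            assert model_prior_log(m, g, 0) == pytest.approx(math.log(0.5))

    def test_prior0_balanced_four_tips_weights(self):
        """The fully split balanced tree admits 2 labelled histories and
        gets twice the weight of single-history models."""
        g = GuideTree.from_newick("((A,B),(C,D));")
        space = ModelSpace(g, 0)
        full = frozenset(n.index for n in g.internal_nodes)
        weights = {
            m.key: math.exp(lp) for m, lp in zip(space.models, space.log_prior)
        }
        full_key = tuple(sorted(full))
        other = [w for k, w in weights.items() if k != full_key]
        assert weights[full_key] == pytest.approx(2 * other[0])
        assert len(set(np.round(other, 12))) == 1


class TestSummaries:
    def test_two_lineages_single_population(self):
        g = GuideTree.from_newick("(X);")
        gt = UltrametricTree.from_newick("(x1:0.05,x2:0.05);")
        tm = TaxonMap({"x1": "X", "x2": "X"})
        s = coalescent_summaries(gt, tm, DelimitationModel(g, frozenset()), {})
        assert s.c == {"X": 1}
        assert s.B["X"] == pytest.approx(0.1)

    def test_three_lineages_piecewise_integral(self, one_species_map):
        g = GuideTree.from_newick("(X);")
        gt = UltrametricTree.from_newick("((x1:0.02,x2:0.02):0.03,x3:0.05);")
        s = coalescent_summaries(
            gt, one_species_map, DelimitationModel(g, frozenset()), {}
        )
        assert s.c == {"X": 2}
        assert s.B["X"] == pytest.approx(6 * 0.02 + 2 * 0.03)

    def test_censoring_violation_raises(self):
        g = GuideTree.from_newick("(A,B);")
        gt = UltrametricTree.from_newick("(a1:0.08,b1:0.08);")
        tm = TaxonMap({"a1": "A", "b1": "B"})
        model = DelimitationModel(g, frozenset({g.root.index}))
        with pytest.raises(InfeasibleError):
            coalescent_summaries(gt, tm, model, {g.root.index: 0.1})

    def test_sweep_matches_fast_engine(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        full = DelimitationModel(
            guide, frozenset(n.index for n in guide.internal_nodes)
        )
        engine = MSCLikelihood(gene_trees, taxon_map, guide)
        taus = {
            v: 0.9 * engine.feasibility_bound(v) for v in full.split_nodes
        }
        root = guide.root.index
        taus[root] = max(taus.values())
        for v in full.split_nodes:
            if v != root and taus[v] >= taus[root]:
                taus[v] = 0.5 * taus[root]
        stats_engine = engine.summaries(full, taus)
        pooled_c = {}
        pooled_b = {}
        for gt in gene_trees:
            s = coalescent_summaries(gt, taxon_map, full, taus)
            for key in s.c:
                pooled_c[key] = pooled_c.get(key, 0) + s.c[key]
                pooled_b[key] = pooled_b.get(key, 0.0) + s.B[key]
        for p, (C, Bt, _) in stats_engine.items():
            label = guide.clade_label(p)
            assert C == pooled_c[label]
            assert Bt == pytest.approx(pooled_b[label], rel=1e-9)

    def test_lineage_conservation(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        model = DelimitationModel(guide, frozenset())
        for gt in gene_trees:
            s = coalescent_summaries(gt, taxon_map, model, {})
            assert s.total_events == gt.n_tips - 1


class TestLoglik:
    def test_two_lineage_closed_form(self):
        g = GuideTree.from_newick("(X);")
        gt = UltrametricTree.from_newick("(x1:0.05,x2:0.05);")
        tm = TaxonMap({"x1": "X", "x2": "X"})
        params = MSCParams(thetas={"X": 0.1}, taus={})
        ll = msc_loglik([gt], tm, g, DelimitationModel(g, frozenset()), params)
        assert ll == pytest.approx(math.log(20) - 1)

    def test_two_identical_loci_double(self):
        g = GuideTree.from_newick("(X);")
        gt = UltrametricTree.from_newick("(x1:0.05,x2:0.05);")
        tm = TaxonMap({"x1": "X", "x2": "X"})
        params = MSCParams(thetas={"X": 0.1}, taus={})
        m = DelimitationModel(g, frozenset())
        one = msc_loglik([gt], tm, g, m, params)
        two = msc_loglik([gt, gt], tm, g, m, params)
        assert two == pytest.approx(2 * one)

    def test_heredity_scales_theta(self):
        g = GuideTree.from_newick("(X);")
        gt = UltrametricTree.from_newick("(x1:0.05,x2:0.05);")
        tm = TaxonMap({"x1": "X", "x2": "X"})
        m = DelimitationModel(g, frozenset())
        quarter = MSCParams(thetas={"X": 0.4}, taus={}, heredity=[0.25])
        full = MSCParams(thetas={"X": 0.1}, taus={})
        assert msc_loglik([gt], tm, g, m, quarter) == pytest.approx(
            msc_loglik([gt], tm, g, m, full)
        )

    def test_density_normalizes_by_importance_sampling(self):
        """exp(msc_loglik) is a proper density of the coalescence time:
        E_f0[f1(T)/f0(T)] = 1 when T ~ f0, with f evaluated through the
        package and f0 the known two-lineage exponential."""
        from coaldelim.trees import Node

        theta0, theta1 = 0.08, 0.06
        g = GuideTree.from_newick("(X);")
        tm = TaxonMap({"x1": "X", "x2": "X"})
        m = DelimitationModel(g, frozenset())
        rng = np.random.default_rng(12)
        draws = rng.exponential(theta0 / 2, size=3000)
        ratios = []
        for t in draws:
            root = Node(age=float(t))
            root.add_child(Node(label="x1", age=0.0))
            root.add_child(Node(label="x2", age=0.0))
            tree = UltrametricTree(root)
            ll1 = msc_loglik([tree], tm, g, m,
                             MSCParams(thetas={"X": theta1}, taus={}))
            ll0 = math.log(2 / theta0) - 2 * t / theta0
            ratios.append(math.exp(ll1 - ll0))
        est = float(np.mean(ratios))
        se = float(np.std(ratios)) / math.sqrt(len(ratios))
        assert abs(est - 1.0) < 3 * se


class TestIntegratedLoglik:
    def test_single_event_closed_form(self):
        g = GuideTree.from_newick("(X);")
        gt = UltrametricTree.from_newick("(x1:0.05,x2:0.05);")
        tm = TaxonMap({"x1": "X", "x2": "X"})
        m = DelimitationModel(g, frozenset())
        prior = PriorConfig(theta_mean=0.1, tau_mean=0.1)
        ll = msc_loglik_integrated([gt], tm, g, m, {}, prior)
        # 2 beta^a Gamma(a+1) / Gamma(a) / (beta + B)^(a+1) with a=2, beta=0.1,
        # B = 0.1: 2 * 0.01 * 2 / 0.008 = 5
        assert ll == pytest.approx(math.log(5.0), abs=1e-12)

    def test_empty_population_contributes_nothing(self):
        g = GuideTree.from_newick("(X,Y);")
        gt = UltrametricTree.from_newick("(x1:0.05,x2:0.05);")
        tm = TaxonMap({"x1": "X", "x2": "X"})
        prior = PriorConfig(theta_mean=0.1, tau_mean=0.1)
        m = DelimitationModel(g, frozenset())
        ll = msc_loglik_integrated([gt], tm, g, m, {}, prior)
        assert np.isfinite(ll)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadrature_random_cases(self, seed):
        """Analytic theta integration equals 1-D quadrature of the sampled
        likelihood against the inverse-gamma prior, population by
        population, to 1e-8 relative."""
        data = _random_small_case(seed)
        gene_trees, taxon_map, guide, model, taus, heredity = data
        prior = PriorConfig(theta_mean=0.05, tau_mean=0.1)
        engine = MSCLikelihood(gene_trees, taxon_map, guide, heredity=heredity)
        analytic = engine.loglik_integrated(model, taus, prior)
        total = 0.0
        for p, (C, Bt, hlog) in engine.summaries(model, taus).items():
            if C == 0 and Bt == 0.0:
                continue

            def integrand(theta, C=C, Bt=Bt, hlog=hlog):
                return math.exp(
                    C * math.log(2.0 / theta) - hlog - Bt / theta
                ) * stats.invgamma.pdf(theta, prior.alpha, scale=prior.beta_theta)

            val, err = integrate.quad(integrand, 0, np.inf, limit=200)
            total += math.log(val)
        assert analytic == pytest.approx(total, rel=1e-8)

    def test_infeasible_taus_give_minus_inf(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        engine = MSCLikelihood(gene_trees, taxon_map, guide)
        root = guide.root.index
        model = DelimitationModel(guide, frozenset({root}))
        too_old = engine.feasibility_bound(root) * 1.01
        prior = PriorConfig()
        assert engine.loglik_integrated(model, {root: too_old}, prior) == -math.inf


def _random_small_case(seed):
    from .conftest import make_three_species_data

    gene_trees, taxon_map, guide = make_three_species_data(
        seed=seed + 40, theta=0.02, n_per=2, n_loci=2
    )
    full = DelimitationModel(guide, frozenset(n.index for n in guide.internal_nodes))
    engine = MSCLikelihood(gene_trees, taxon_map, guide, heredity=[0.25, 1.0])
    root = guide.root.index
    taus = {}
    for v in sorted(full.split_nodes, key=lambda v: v != root):
        bound = engine.feasibility_bound(v)
        taus[v] = 0.8 * bound if np.isfinite(bound) else 0.05
    for v in full.split_nodes:
        if v != root and taus[v] >= taus[root]:
            taus[v] = 0.5 * taus[root]
    return gene_trees, taxon_map, guide, full, taus, [0.25, 1.0]


class TestPriors:
    def test_invgamma_mean(self):
        prior = PriorConfig(theta_mean=0.1, tau_mean=0.01)
        assert stats.invgamma.mean(
            prior.alpha, scale=prior.beta_theta
        ) == pytest.approx(0.1)
        assert stats.invgamma.mean(
            prior.alpha, scale=prior.beta_tau
        ) == pytest.approx(0.01)

    def test_pdf_normalizes(self):
        prior = PriorConfig(theta_mean=0.1, tau_mean=0.1)
        val, _ = integrate.quad(
            lambda x: math.exp(prior_logpdf("theta", x, prior)), 0, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_logpdf_closed_form(self):
        prior = PriorConfig(theta_mean=0.1, tau_mean=0.1)
        expected = 2 * math.log(0.1) - 3 * math.log(0.05) - 0.1 / 0.05
        assert prior_logpdf("theta", 0.05, prior) == pytest.approx(expected)

    def test_nonpositive_x_rejected(self):
        with pytest.raises(ValueError):
            prior_logpdf("theta", 0.0, PriorConfig())

    @pytest.mark.parametrize("s", [3, 4, 5])
    def test_tau_prior_normalizes_by_monte_carlo(self, s):
        """Conditional on the root tau, the non-root tau density integrates
        to 1 over the order-compatible region (Monte Carlo within 3 SE)."""
        g = random_guide(s, seed=7 * s)
        full = DelimitationModel(g, frozenset(n.index for n in g.internal_nodes))
        prior = PriorConfig(tau_mean=0.1)
        root = g.root.index
        R = 0.1
        k = len(full.split_nodes) - 1
        if k == 0:
            return
        rng = np.random.default_rng(s)
        n_mc = 40_000
        draws = rng.uniform(0, R, size=(n_mc, k))
        non_root = sorted(v for v in full.split_nodes if v != root)
        root_lp = prior_logpdf("tau_root", R, prior)
        vals = np.zeros(n_mc)
        for i in range(n_mc):
            taus = {root: R}
            taus.update({v: draws[i, j] for j, v in enumerate(non_root)})
            lp = log_tau_prior(full, taus, prior)
            vals[i] = 0.0 if lp == -math.inf else math.exp(lp - root_lp)
        # E over Uniform(0,R)^k of density * R^k = 1
        estimate = vals.mean() * R ** k
        se = vals.std() * R ** k / math.sqrt(n_mc)
        assert abs(estimate - 1.0) < 3 * max(se, 1e-4)
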