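import math

import numpy as np
import pytest

from coaldelim.io import TaxonMap
from coaldelim.mcmc import (
    MCMCConfig,
    PRIOR_GRID,
    SpeciesDelimitation,
    build_config_matrix,
    derive_seed,
    exhaustive_posterior,
    prior_sensitivity_scan,
    run_rjmcmc,
    summarize_posterior,
    total_variation,
)
from coaldelim.msc import (
    DelimitationModel,
    GuideTree,
    ModelSpace,
    PriorConfig,
)

from .conftest import make_three_species_data


PRIOR = PriorConfig(tau_mean=0.1, theta_mean=0.1)


def short_config(seed=1, **kw):
    base = dict(generations=20_000, pre_burnin=2_000, sample_every=2,
                seed=seed, prior=PRIOR)
    base.update(kw)
    return MCMCConfig(**base)


class TestSampler:
    def test_deterministic_given_seed(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        cfg = short_config(generations=4000, pre_burnin=500)
        a = run_rjmcmc(gene_trees, taxon_map, guide, cfg)
        b = run_rjmcmc(gene_trees, taxon_map, guide, cfg)
        assert a.model_probs == b.model_probs
        assert a.split_probs == b.split_probs

    def test_matches_exhaustive_posterior(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        exact = exhaustive_posterior(gene_trees, taxon_map, guide, PRIOR)
        res = run_rjmcmc(gene_trees, taxon_map, guide, short_config(seed=3))
        assert total_variation(exact, res.model_probs) <= 0.05

    def test_model_probs_sum_to_one(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        res = run_rjmcmc(gene_trees, taxon_map, guide,
                         short_config(generations=4000, pre_burnin=500))
        assert sum(res.model_probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_collapsed_truth_recovered(self):
        """Data simulated as a single panmictic species: the fully
        collapsed model should dominate the posterior."""
        gene_trees, taxon_map, guide = make_three_species_data(
            seed=21, theta=0.05, tau_root=0.002, n_per=3, n_loci=3
        )
        res = run_rjmcmc(gene_trees, taxon_map, guide, short_config(seed=4))
        assert res.model_probs.get((), 0.0) == max(res.model_probs.values())

    def test_split_truth_recovered(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        res = run_rjmcmc(gene_trees, taxon_map, guide, short_config(seed=5))
        full = tuple(sorted(n.index for n in guide.internal_nodes))
        assert res.model_probs.get(full, 0.0) > 0.9

    def test_fixed_model_never_jumps(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        full = DelimitationModel(
            guide, frozenset(n.index for n in guide.internal_nodes)
        )
        cfg = short_config(generations=3000, pre_burnin=300,
                           fixed_model=full, sample_thetas=True,
                           sample_every=10)
        res = run_rjmcmc(gene_trees, taxon_map, guide, cfg)
        assert res.model_probs == {full.key: 1.0}
        for v in full.split_nodes:
            assert np.isfinite(res.tau_samples[v]).all()

    def test_zero_loci_recovers_model_prior(self):
        guide = GuideTree.from_newick("((A,B),C);")
        cfg = short_config(generations=30_000, pre_burnin=1000,
                           sample_every=10, seed=6)
        res = run_rjmcmc([], TaxonMap({}), guide, cfg)
        space = ModelSpace(guide, 1)
        for i, m in enumerate(space.models):
            assert res.model_probs.get(m.key, 0.0) == pytest.approx(
                math.exp(space.log_prior[i]), abs=0.05
            )

    def test_algorithms_agree(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        r0 = run_rjmcmc(gene_trees, taxon_map, guide,
                        short_config(seed=7, algorithm=0))
        r1 = run_rjmcmc(gene_trees, taxon_map, guide,
                        short_config(seed=8, algorithm=1))
        assert total_variation(r0.model_probs, r1.model_probs) <= 0.05


class TestExhaustive:
    def test_no_data_returns_model_prior(self):
        guide = GuideTree.from_newick("((A,B),C);")
        post = exhaustive_posterior([], TaxonMap({}), guide, PRIOR)
        space = ModelSpace(guide, 1)
        for i, m in enumerate(space.models):
            assert post[m.key] == pytest.approx(
                math.exp(space.log_prior[i]), abs=0.01
            )

    def test_posterior_sums_to_one(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        post = exhaustive_posterior(gene_trees, taxon_map, guide, PRIOR)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_strong_two_species_split(self):
        gene_trees, taxon_map, guide = make_three_species_data(
            seed=33, theta=0.005, tau_root=0.08, n_per=3, n_loci=2
        )
        post = exhaustive_posterior(gene_trees, taxon_map, guide, PRIOR)
        full = tuple(sorted(n.index for n in guide.internal_nodes))
        assert post[full] > 0.95

    def test_large_guide_rejected(self, fig3_guide):
        with pytest.raises(ValueError, match="run_rjmcmc"):
            exhaustive_posterior([], TaxonMap({}), fig3_guide, PRIOR)


class TestSummaries:
    def test_mean_of_identical_runs_is_identity(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        cfg = short_config(generations=3000, pre_burnin=300)
        run = run_rjmcmc(gene_trees, taxon_map, guide, cfg)
        merged = summarize_posterior([run, run])
        assert merged.model_probs == pytest.approx(run.model_probs)
        assert merged.max_split_discrepancy == 0.0

    def test_split_pp_equals_sum_of_model_pps(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        run = run_rjmcmc(gene_trees, taxon_map, guide,
                         short_config(generations=4000, pre_burnin=400))
        for v, pp in run.split_probs.items():
            total = sum(p for key, p in run.model_probs.items() if v in key)
            assert pp == pytest.approx(total, abs=1e-12)

    def test_parent_split_pp_at_least_child(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        run = run_rjmcmc(gene_trees, taxon_map, guide,
                         short_config(generations=4000, pre_burnin=400))
        for node in guide.internal_nodes:
            parent = guide.parent_index[node.index]
            if parent is not None:
                assert run.split_probs[parent] >= run.split_probs[node.index] - 1e-12

    def test_summary_text(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        model = SpeciesDelimitation(gene_trees, taxon_map, guide)
        res = model.fit(config=short_config(generations=3000, pre_burnin=300),
                        n_runs=2)
        text = res.summary()
        assert "best model" in text and "runs" in text
        assert len(res.runs) == 2


class TestThetaHandling:
    def test_integrated_vs_sampled_split_pps_close(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        ri = run_rjmcmc(gene_trees, taxon_map, guide,
                        short_config(seed=9, integrate_theta=True))
        rs = run_rjmcmc(gene_trees, taxon_map, guide,
                        short_config(seed=10, integrate_theta=False))
        for v in ri.split_probs:
            assert abs(ri.split_probs[v] - rs.split_probs[v]) <= 0.02

    def test_conditional_theta_draws_recorded(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        full = DelimitationModel(
            guide, frozenset(n.index for n in guide.internal_nodes)
        )
        cfg = short_config(generations=2000, pre_burnin=200, sample_every=10,
                           fixed_model=full, sample_thetas=True)
        res = run_rjmcmc(gene_trees, taxon_map, guide, cfg)
        for p in full.population_roots():
            draws = res.theta_samples[p]
            assert np.isfinite(draws).all() and (draws > 0).all()


class TestScanAndMatrix:
    def test_prior_grid_has_four_combinations(self):
        assert len(PRIOR_GRID) == 4
        assert set(PRIOR_GRID) == {(0.1, 0.1), (0.1, 0.01),
                                   (0.01, 0.1), (0.01, 0.01)}

    def test_sensitivity_scan_shape(self, three_species_data):
        gene_trees, taxon_map, guide = three_species_data
        scan = prior_sensitivity_scan(
            gene_trees, taxon_map, guide,
            short_config(generations=2000, pre_burnin=200), runs_per=2,
        )
        assert scan.table.shape == (len(guide.internal_nodes), 4)
        assert len(scan.results) == 4
        for res in scan.results.values():
            assert len(res.runs) == 2

    def test_strong_signal_not_prior_sensitive(self):
        gene_trees, taxon_map, guide = make_three_species_data(
            seed=55, theta=0.004, tau_root=0.09, n_per=3, n_loci=3
        )
        scan = prior_sensitivity_scan(
            gene_trees, taxon_map, guide,
            short_config(generations=6000, pre_burnin=600), runs_per=2,
        )
        assert scan.sensitive_splits() == []
        assert (scan.table > 0.95).all().all()

    def test_config_matrix_mirrors_study_design(self):
        matrix = build_config_matrix(short_config(generations=100))
        assert len(matrix) == 32                       # 16 analyses x 2 runs
        assert len({e["analysis_id"] for e in matrix}) == 16
        seeds = [e["config"].seed for e in matrix]
        assert len(set(seeds)) == len(seeds)
        unsupported = [e for e in matrix if not e["supported"]]
        assert all(e["guide_mode"] == "unguided" for e in unsupported)

    def test_derived_seeds_distinct_and_bounded(self):
        seeds = {derive_seed(0, i) for i in range(50)}
        assert len(seeds) == 50
        assert all(0 <= s < 2 ** 31 for s in seeds)
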