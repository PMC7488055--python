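import math

import numpy as np
import pytest

from coaldelim.evidence import Partition, adjusted_rand_index
from coaldelim.simulate import (
    SimScenario,
    assign_population_labels,
    draw_locus_rates,
    rostania_like,
    simulate_alignment,
    simulate_dataset,
    simulate_gene_trees,
    simulate_separated_species_tree,
    simulate_species_tree,
    simulate_traits,
)


class TestSpeciesTree:
    def test_single_species_degenerate(self):
        tree = simulate_species_tree(1, 0.1, seed=0)
        assert tree.n_tips == 1 and tree.root.is_tip

    def test_two_species_root_at_tau(self):
        tree = simulate_species_tree(2, 0.07, seed=1)
        assert tree.n_tips == 2
        assert tree.root_age == pytest.approx(0.07)

    def test_zero_species_error(self):
        with pytest.raises(ValueError):
            simulate_species_tree(0, 0.1, seed=0)

    def test_taus_decrease_from_root(self):
        tree = simulate_species_tree(8, 0.1, seed=2)
        assert tree.root_age == pytest.approx(0.1)
        for node in tree.internal_nodes:
            for child in node.children:
                if child.children:
                    assert child.age < node.age

    def test_balanced_vs_caterpillar_shape_frequencies(self):
        """Uniform splitting reproduces the Yule label-history bias: among
        4-species trees, balanced shapes arise with probability 1/3."""
        rng = np.random.default_rng(3)
        balanced = 0
        reps = 3000
        for _ in range(reps):
            tree = simulate_species_tree(4, 0.1, rng)
            depths = sorted(len(n.tips()) for n in tree.internal_nodes)
            balanced += depths == [2, 2, 4]
        # P(balanced | Yule, 4 tips) = 1/3; 3 SE binomial window
        se = (1 / 3 * 2 / 3 / reps) ** 0.5
        assert abs(balanced / reps - 1 / 3) < 3 * se

    def test_separated_tree_respects_ratio(self):
        theta = 0.002
        tree = simulate_separated_species_tree(5, 0.1, theta, 20.0, seed=4)
        assert min(n.age for n in tree.internal_nodes) >= 20 * theta


class TestGeneTrees:
    def test_pairwise_coalescence_mean(self):
        """E[T2] = h * theta / 2 within one population."""
        sp = simulate_species_tree(1, 0.1, seed=0)
        rng = np.random.default_rng(5)
        for h, expected in [(1.0, 0.05), (0.25, 0.0125)]:
            times = []
            for _ in range(4000):
                gts, _ = simulate_gene_trees(
                    sp, {"sp1": 0.1}, [2], 1, heredity=[h], seed=rng
                )
                times.append(gts[0].root_age)
            assert np.mean(times) == pytest.approx(expected, rel=0.06)

    def test_single_population_matches_msprime(self):
        """With one species the censored simulator reduces to the standard
        coalescent: tree-height mean and variance match msprime within 3 SE
        (theta = 0.1 maps to a haploid population size of theta / 2)."""
        import msprime
        sp = simulate_species_tree(1, 0.1, seed=0)
        rng = np.random.default_rng(17)
        reps = 2000
        ours = []
        for _ in range(reps):
            gts, _ = simulate_gene_trees(sp, {"sp1": 0.1}, [6], 1, seed=rng)
            ours.append(gts[0].root_age)
        theirs = [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=[msprime.SampleSet(6, ploidy=1)], ploidy=1,
                population_size=0.05, num_replicates=reps, random_seed=9,
            )
        ]
        ours, theirs = np.asarray(ours), np.asarray(theirs)
        se_mean = math.hypot(ours.std() / reps ** 0.5, np.std(theirs) / reps ** 0.5)
        assert abs(ours.mean() - np.mean(theirs)) < 3 * se_mean
        # variances within 3 SE of the difference of sample variances
        se_var = math.hypot(
            np.std((ours - ours.mean()) ** 2) / reps ** 0.5,
            np.std((theirs - np.mean(theirs)) ** 2) / reps ** 0.5,
        )
        assert abs(ours.var() - np.var(theirs)) < 3 * se_var

    def test_censoring_no_interspecies_coalescence_below_tau(self):
        rng = np.random.default_rng(6)
        sp = simulate_species_tree(2, 0.1, rng)
        labels = assign_population_labels(sp)
        thetas = {lab: 0.05 for lab in labels.values()}
        for _ in range(200):
            gts, tm = simulate_gene_trees(sp, thetas, [3, 3], 1, seed=rng)
            for node in gts[0].internal_nodes:
                species = {tm.species_of(t.label) for t in node.tips()}
                if len(species) > 1:
                    assert node.age >= 0.1

    def test_locus_rate_scales_ages(self):
        sp = simulate_species_tree(1, 0.1, seed=0)
        gts_fast, _ = simulate_gene_trees(
            sp, {"sp1": 0.1}, [4], 2, locus_rates=[0.5, 1.5], seed=9
        )
        # both loci drawn from the same process; rates multiply ages, so a
        # rerun with unit rates and the same seed gives proportional trees
        gts_unit, _ = simulate_gene_trees(
            sp, {"sp1": 0.1}, [4], 2, locus_rates=[1.0, 1.0], seed=9
        )
        for fast, unit, rate in zip(gts_fast, gts_unit, [0.5, 1.5]):
            assert fast.root_age == pytest.approx(unit.root_age * rate)

    def test_missing_theta_error(self):
        sp = simulate_species_tree(2, 0.1, seed=0)
        with pytest.raises(ValueError, match="theta"):
            simulate_gene_trees(sp, {"sp1": 0.1, "sp2": 0.1}, [2, 2], 1, seed=0)


class TestAlignment:
    def test_zero_branch_lengths_identical(self):
        from coaldelim.trees import Node, UltrametricTree

        root = Node(age=0.0)
        for lab in ("a", "b"):
            root.add_child(Node(label=lab, age=0.0))
        aln = simulate_alignment(UltrametricTree(root), 50, seed=0)
        assert aln.rows[0] == aln.rows[1]

    def test_jc69_expected_divergence(self):
        from coaldelim.trees import Node, UltrametricTree

        root = Node(age=0.05)
        for lab in ("a", "b"):
            root.add_child(Node(label=lab, age=0.0))
        length = 10_000
        aln = simulate_alignment(UltrametricTree(root), length, seed=1)
        p = np.mean([x != y for x, y in zip(aln.rows[0], aln.rows[1])])
        expected = 0.75 * (1 - np.exp(-4 * 0.1 / 3))
        se = (expected * (1 - expected) / length) ** 0.5
        assert abs(p - expected) < 3 * se

    def test_length_and_errors(self):
        sp = simulate_species_tree(1, 0.1, seed=0)
        gts, _ = simulate_gene_trees(sp, {"sp1": 0.05}, [3], 1, seed=0)
        assert simulate_alignment(gts[0], 825, seed=0).column_count == 825
        with pytest.raises(ValueError):
            simulate_alignment(gts[0], 0, seed=0)


class TestTraits:
    def test_full_fidelity_matches_species_partition(self):
        partition = {f"i{k}": f"sp{k % 3}" for k in range(30)}
        tt = simulate_traits(partition, ["x", "y", "z"], 1.0, seed=0)
        trait_part = Partition({i: v["morphotype"] for i, v in tt.values.items()})
        assert adjusted_rand_index(Partition(partition), trait_part) == pytest.approx(1.0)

    def test_modal_frequency_matches_fidelity(self):
        partition = {f"i{k}": "sp1" for k in range(8000)}
        tt = simulate_traits(partition, ["x", "y", "z"], 0.5, seed=1)
        vals = [v["morphotype"] for v in tt.values.values()]
        modal = max(set(vals), key=vals.count)
        freq = vals.count(modal) / len(vals)
        se = (0.5 * 0.5 / 8000) ** 0.5
        assert abs(freq - 0.5) < 3 * se

    def test_single_level_with_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_traits({"i1": "sp1"}, ["only"], 0.5, seed=0)


class TestScenario:
    def test_rostania_like_defaults(self):
        sc = rostania_like()
        assert sc.s == 8 and sum(sc.n_per_species) == 63
        assert sc.n_loci == 4 and sc.heredity[0] == 0.25
        assert min(sc.n_per_species) == 1  # singleton species, as sampled

    def test_locus_rates_mean_one(self):
        rates = draw_locus_rates(4, np.random.default_rng(0))
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)

    def test_dataset_bundle_consistency(self):
        sc = SimScenario(s=3, n_per_species=(3, 2, 2), n_loci=2,
                         heredity=(0.25, 1.0), seed=11)
        bundle = simulate_dataset(sc, with_alignments=True)
        assert len(bundle.gene_trees) == 2
        assert len(bundle.taxon_map) == 7
        assert bundle.alignments[0].column_count == sc.alignment_lengths[0]
        assert set(bundle.gene_trees[0].tip_labels) == set(bundle.taxon_map.individuals)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            SimScenario(s=2, n_per_species=(3,))
        with pytest.raises(ValueError):
            SimScenario(s=2, n_per_species=(3, 2), n_loci=2, heredity=(1.0,))
        with pytest.raises(ValueError):
            SimScenario(s=2, n_per_species=(3, 2), n_loci=2,
                        heredity=(1.0, 1.0), locus_rates=(0.5, 1.0))
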