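import numpy as np
import pytest

from coaldelim import GuideTree, TaxonMap, UltrametricTree
from coaldelim.simulate import (
    assign_population_labels,
    simulate_gene_trees,
    simulate_species_tree,
)


@pytest.fixture
def balanced_tree() -> UltrametricTree:
    return UltrametricTree.from_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def six_tip_tree() -> UltrametricTree:
    # two young cherries, two tips attaching deep
    return UltrametricTree.from_newick(
        "(((a:0.01,b:0.01):0.99,(c:0.012,d:0.012):0.988):0.5,(e:0.8,f:0.8):0.7);"
    )


@pytest.fixture
def fig3_guide() -> GuideTree:
    """Guide tree shaped as one 2-species clade sister to two 3-species clades."""
    return GuideTree.from_newick("((A,B),(((C,D),E),((F,G),H)));")


def make_three_species_data(seed: int, theta: float = 0.01, tau_root: float = 0.08,
                            n_per: int = 2, n_loci: int = 2):
    """Small, strongly structured 3-species dataset plus its guide tree."""
    rng = np.random.default_rng(seed)
    sp = simulate_species_tree(3, tau_root, rng)
    labels = assign_population_labels(sp)
    thetas = {lab: theta for lab in labels.values()}
    gene_trees, taxon_map = simulate_gene_trees(
        sp, thetas, [n_per] * 3, n_loci, seed=rng
    )
    return gene_trees, taxon_map, GuideTree.from_tree(sp)


@pytest.fixture
def three_species_data():
    return make_three_species_data(seed=7)


@pytest.fixture
def one_species_map() -> TaxonMap:
    return TaxonMap({"x1": "X", "x2": "X", "x3": "X"})
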