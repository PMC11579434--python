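import numpy as np
import pytest

from introscan.simulate import (
    HybridEdge,
    SpeciesNetwork,
    attach_outgroup,
    random_ultrametric_tree,
    simulate_alignments,
    simulate_gene_trees,
)
from introscan.treeio import TripletSpec, parse_newick


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar5():
    return parse_newick("(A:4,(B:3,(C:2,(D:1,E:1):1):1):1);")


@pytest.fixture
def triplet_base():
    """Ultrametric ((P1,P2),P3) + distant outgroup, coalescent units."""
    return parse_newick("(((P1:0.5,P2:0.5):1.0,P3:1.5):8.5,OUT:10.0);")


@pytest.fixture
def triplet_spec():
    return TripletSpec("P1", "P2", "P3", "OUT")


@pytest.fixture(scope="session")
def planted_10taxon():
    """10-taxon ultrametric tree + outgroup with one planted hybrid edge
    (donor sp10 -> recipient sp03, gamma 0.3), simulated gene trees and
    alignments.  Session-scoped: several tests read it."""
    ingroup = random_ultrametric_tree(10, seed=5, height=3.0)
    tree = attach_outgroup(ingroup, "OUT", 10.0)
    edge = HybridEdge("sp10", "sp03", 0.16, 0.3)
    net = SpeciesNetwork(tree, [edge])
    gts = simulate_gene_trees(net, 500, seed=7)
    alns = simulate_alignments(gts, 800, 0.01, seed=7)
    return net, edge, gts, alns


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary rooted topology with random lengths, as Newick."""
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        la, lb = rng.random(2).round(4)
        nodes.append(f"({a}:{la},{b}:{lb})")
    return nodes[0] + ";"
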