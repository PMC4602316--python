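import pytest

from triplenet.gene_tree import GeneTree
from triplenet.network import parse_network


@pytest.fixture
def three_taxon_tree():
    """Species tree ((A,B):1,C) with one coalescent unit above the cherry."""
    return parse_network("((A:1,B:1):1,C:2);")


@pytest.fixture
def one_retic_network():
    return parse_network("((A:1,(B:1)#H1:1::0.7):1,(#H1:0::0.3,C:1):1);")


def random_gene_tree(rng, species, max_alleles=3, p_polytomy=0.25):
    """A random rooted gene tree: random allele counts per species (possibly
    zero), random topology, occasional polytomies."""
    alleles = []
    for sp in species:
        for i in range(int(rng.integers(0, max_alleles + 1))):
            alleles.append(f"{sp}_{i}")
    while len(alleles) < 2:       # keep at least two leaves
        sp = species[int(rng.integers(len(species)))]
        alleles.append(f"{sp}_{len(alleles) + 17}")
    nodes = [a for a in alleles]
    while len(nodes) > 1:
        if len(nodes) > 2 and rng.random() < p_polytomy:
            k = int(rng.integers(3, min(len(nodes), 4) + 1))
        else:
            k = 2
        picks = rng.choice(len(nodes), size=k, replace=False)
        merged = tuple(nodes[int(i)] for i in picks)
        nodes = [n for j, n in enumerate(nodes) if j not in set(int(i) for i in picks)]
        nodes.append(merged)
    phi = {a: a.split("_")[0] for a in alleles}
    top = nodes[0] if isinstance(nodes[0], tuple) else (nodes[0],)
    return GeneTree.from_nested(top, phi)


@pytest.fixture
def gene_tree_factory():
    return random_gene_tree
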