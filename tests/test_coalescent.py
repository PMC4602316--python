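"""Exact triple probabilities under the network coalescent, and the
triple-system equating solver."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from triplenet.coalescent import equate_triple_systems, triple_probabilities
from triplenet.examples import (LEAF_RETIC_EDGES, LEAF_RETIC_PARAMS,
                                clade_reticulation_network,
                                leaf_reticulation_network,
                                rival_six_taxon_network,
                                unique_six_taxon_network)
from triplenet.network import (TripleTopology, parse_network,
                               restrict_network)
from triplenet.simulate import random_network


def msc_tree_probs(tau):
    """Closed-form rooted-triple probabilities for a species tree whose
    cherry is separated from the outgroup by an internal path of length tau
    (coalescent units)."""
    minor = math.exp(-tau) / 3.0
    return 1.0 - 2.0 * minor, minor


class TestSpeciesTreeLimit:
    @pytest.mark.parametrize("tau", [0.0, 0.1, 1.0, 2.5, 10.0])
    def test_three_taxon_closed_form(self, tau):
        tree = parse_network(f"((A:1,B:1):{tau},C:2);")
        d = triple_probabilities(tree, ("A", "B", "C"))
        major, minor = msc_tree_probs(tau)
        assert d[TripleTopology.binary("A", "B", "C")] == pytest.approx(
            major, abs=1e-10)
        assert d[TripleTopology.binary("A", "C", "B")] == pytest.approx(
            minor, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_arbitrary_trees_path_sum(self, seed):
        """On any species tree the concordant-triple probability is
        1 − (2/3)e^{−τ} with τ the internal path separating the cherry pair
        from the outgroup; τ is recomputed independently from root
        distances."""
        rng = np.random.default_rng(500 + seed)
        tree = random_network(int(rng.integers(4, 9)), 0, rng=rng)
        g = tree.graph
        dist = {tree.root: 0.0}
        depth = {tree.root: 0}
        for v in nx.topological_sort(g):
            for _u, w, k in g.out_edges(v, keys=True):
                dist[w] = dist[v] + g.edges[v, w, k]["length"]
                depth[w] = depth[v] + 1
        label = {g.nodes[v]["label"]: v for v in tree.leaves}

        def mrca(a, b):
            while a != b:
                if depth[a] < depth[b]:
                    b = next(iter(g.predecessors(b)))
                else:
                    a = next(iter(g.predecessors(a)))
            return a

        for subset in itertools.combinations(tree.taxa, 3):
            x, y, z = subset
            nodes = {p: mrca(label[p[0]], label[p[1]])
                     for p in [(x, y), (x, z), (y, z)]}
            deepest = max(nodes.values(), key=lambda v: dist[v])
            shallowest = min(nodes.values(), key=lambda v: dist[v])
            tau = dist[deepest] - dist[shallowest]
            cherry = next(p for p, v in nodes.items() if v == deepest)
            major, minor = msc_tree_probs(tau)
            d = triple_probabilities(tree, subset)
            assert d[TripleTopology.binary(cherry[0], cherry[1],
                                           (set(subset) - set(cherry)).pop())
                     ] == pytest.approx(major, abs=1e-10)


class TestNetworks:
    def test_degenerate_gamma_equals_displayed_tree(self):
        net = parse_network("((A:1,(B:1)#H1:1::1.0):1,(#H1:0::0.0,C:1):1);")
        tree = parse_network("((A:1,B:2):1,C:2);")
        for subset in [("A", "B", "C")]:
            assert np.allclose(
                list(triple_probabilities(net, subset)),
                list(triple_probabilities(tree, subset)), atol=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_distributions_are_probabilities(self, seed):
        rng = np.random.default_rng(700 + seed)
        net = random_network(int(rng.integers(4, 9)),
                             int(rng.integers(0, 4)), rng=rng)
        for subset in itertools.combinations(net.taxa, 3):
            p = np.array(list(triple_probabilities(net, subset)))
            assert np.all(p >= -1e-15)
            assert p.sum() == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_pendant_lengths_are_irrelevant(self, seed):
        rng = np.random.default_rng(900 + seed)
        net = random_network(5, int(rng.integers(0, 3)), rng=rng)
        perturbed = net.copy()
        for leaf in perturbed.leaves:
            (e,) = perturbed.graph.in_edges(leaf, keys=True)
            perturbed.set_length(e, float(rng.uniform(0.01, 20.0)))
        for subset in itertools.combinations(net.taxa, 3):
            assert np.allclose(
                list(triple_probabilities(net, subset)),
                list(triple_probabilities(perturbed, subset)), atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_restriction_preserves_distributions(self, seed):
        rng = np.random.default_rng(1100 + seed)
        net = random_network(int(rng.integers(5, 9)),
                             int(rng.integers(1, 4)), rng=rng)
        subsets = list(itertools.combinations(net.taxa, 3))
        for subset in subsets[:: max(1, len(subsets) // 6)]:
            r = restrict_network(net, subset)
            assert np.allclose(
                list(triple_probabilities(net, subset)),
                list(triple_probabilities(r, subset)), atol=1e-12)


class TestTripleEquivalentPair:
    def test_printed_parameterizations_agree(self):
        """The two 4-taxon topologies with the worked parameter sets induce
        identical triple distributions on every 3-subset."""
        ref = clade_reticulation_network()
        tgt = leaf_reticulation_network(**LEAF_RETIC_PARAMS)
        for subset in itertools.combinations("ABCD", 3):
            assert np.allclose(
                list(triple_probabilities(ref, subset)),
                list(triple_probabilities(tgt, subset)), atol=1e-5)


class TestEquate:
    def test_self_consistency(self):
        ref = clade_reticulation_network()
        res = equate_triple_systems(ref, clade_reticulation_network(
            b1=0.5, b2=0.5, b3=0.5, b4=0.5, b5=0.5, alpha=0.5), seed=1)
        assert res.converged
        assert res.residual < 1e-12

    def test_recovers_worked_parameters(self):
        res = equate_triple_systems(clade_reticulation_network(),
                                    leaf_reticulation_network(), seed=1)
        assert res.residual < 1e-8
        assert res.lengths[LEAF_RETIC_EDGES["l1"]] == pytest.approx(
            LEAF_RETIC_PARAMS["l1"], abs=1e-3)
        assert res.lengths[LEAF_RETIC_EDGES["l2"]] == pytest.approx(
            LEAF_RETIC_PARAMS["l2"], abs=1e-3)
        assert res.lengths[LEAF_RETIC_EDGES["l3"]] == pytest.approx(
            LEAF_RETIC_PARAMS["l3"], abs=1e-3)
        assert res.gammas[LEAF_RETIC_EDGES["beta"]] == pytest.approx(
            LEAF_RETIC_PARAMS["beta"], abs=1e-3)

    def test_unique_network_rejects_rival(self):
        """A network uniquely encoded by its triples cannot be matched by a
        different topology: the residual stays bounded away from zero."""
        res = equate_triple_systems(unique_six_taxon_network(),
                                    rival_six_taxon_network(), seed=1,
                                    n_starts=6)
        assert not res.converged
        assert res.residual > 1e-3
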