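"""Network representation, extended-Newick I/O, displayed trees, triple
systems and restriction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from triplenet.examples import (clade_reticulation_network,
                                leaf_reticulation_network)
from triplenet.network import (NetworkParseError, NetworkValidationError,
                               PhyloNetwork, TripleTopology, canonical_form,
                               displayed_trees, induced_triple_set,
                               networks_isomorphic, parse_network,
                               restrict_network, write_network)
from triplenet.simulate import random_network


class TestParsing:
    def test_one_reticulation_network(self, one_retic_network):
        net = one_retic_network
        assert net.taxa == ["A", "B", "C"]
        assert net.n_reticulations == 1
        (h,) = net.reticulations
        gammas = sorted(net.gamma(e) for e in net.reticulation_edges(h))
        assert gammas == pytest.approx([0.3, 0.7])

    def test_plain_tree_has_no_reticulations(self):
        net = parse_network("((A:1,B:1):1,C:2);")
        assert net.n_reticulations == 0
        assert net.taxa == ["A", "B", "C"]

    def test_gamma_inferred_on_second_occurrence(self):
        net = parse_network("((A:1,(B:1)#H1:1::0.7):1,(#H1:0,C:1):1);")
        (h,) = net.reticulations
        total = sum(net.gamma(e) for e in net.reticulation_edges(h))
        assert total == pytest.approx(1.0)

    def test_worked_parameterization_parses(self):
        # the 4-taxon identifiability example (b1=1, b2=1, b3=2, b4=1, b5=0,
        # α=0.1), written by hand
        net = parse_network(
            "((A:1,(B:1,((C:1,D:1):1)#H1:0::0.1):1):1,#H1:2::0.9);")
        assert net.taxa == ["A", "B", "C", "D"]
        assert net.n_reticulations == 1
        assert networks_isomorphic(net, clade_reticulation_network())

    @pytest.mark.parametrize("text,exc", [
        ("((A:1,B:1):1;", NetworkParseError),                # unbalanced
        ("((A:1,B:1):1,C:1);x", NetworkParseError),          # trailing junk
        ("((A:1,(B:1)#H1:1::0.7):1,(#H1:0::0.5,C:1):1);",
         NetworkValidationError),                            # γ sum != 1
        ("((A:1,B:1,C:1):1,D:1);", NetworkValidationError),  # trifurcation
        ("((A:1,B:1):1,A:1);", NetworkValidationError),      # duplicate label
        ("((A:1,(B:1)#H1:1::0.7):1,C:2);", NetworkParseError),  # tag once
        ("((A:1,(B:1)#H1:1):1,(#H1:0,C:1):1);", NetworkParseError),  # no γ
    ])
    def test_errors(self, text, exc):
        with pytest.raises(exc):
            parse_network(text)

    def test_missing_length_warns_and_reads_zero(self):
        with pytest.warns(UserWarning, match="missing"):
            net = parse_network("((A,B:1):1,C:1);")
        leaf_a = net.leaf_for("A")
        (e,) = net.graph.in_edges(leaf_a, keys=True)
        assert net.length(e) == 0.0

    def test_negative_length_rejected(self):
        with pytest.raises(NetworkValidationError):
            parse_network("((A:1,B:-0.5):1,C:1);")


class TestWriting:
    def test_tree_has_no_hash_tokens(self, three_taxon_tree):
        assert "#" not in write_network(three_taxon_tree)

    def test_one_reticulation_has_two_hybrid_tags(self, one_retic_network):
        text = write_network(one_retic_network)
        assert text.count("#H") == 2

    @pytest.mark.parametrize("seed", range(50))
    def test_round_trip_isomorphism_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        k = int(rng.integers(0, 4))
        net = random_network(n, k, rng=rng)
        back = parse_network(write_network(net))
        assert networks_isomorphic(net, back, compare_params=True)

    def test_round_trip_many_small(self):
        # bulk round-trip sweep (cheap per network)
        rng = np.random.default_rng(2024)
        for _ in range(950):
            net = random_network(int(rng.integers(3, 7)),
                                 int(rng.integers(0, 3)), rng=rng)
            back = parse_network(write_network(net))
            assert networks_isomorphic(net, back, compare_params=True)

    def test_canonical_form_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        net = random_network(6, 2, rng=rng)
        perm = {v: f"n{v}x" for v in net.graph.nodes}
        relabeled = PhyloNetwork(nx.relabel_nodes(net.graph, perm),
                                 perm[net.root])
        assert canonical_form(net) == canonical_form(relabeled)
        assert write_network(net, canonical=True) == \
            write_network(relabeled, canonical=True)


class TestDisplayedTrees:
    def test_species_tree_displays_itself(self, three_taxon_tree):
        [(tree, w)] = displayed_trees(three_taxon_tree)
        assert w == 1.0
        assert networks_isomorphic(tree, three_taxon_tree)

    def test_one_reticulation_weights(self, one_retic_network):
        trees = displayed_trees(one_retic_network)
        assert sorted(w for _t, w in trees) == pytest.approx([0.3, 0.7])

    def test_worked_example_displays_expected_pair(self):
        net = clade_reticulation_network()
        shown = {canonical_form(t): w for t, w in displayed_trees(net)}
        t1 = parse_network("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_network("(A:1,(B:1,(C:1,D:1):1):1);")
        assert shown.keys() == {canonical_form(t1), canonical_form(t2)}
        # weight of the minor (below-B) routing is α = 0.1
        assert shown[canonical_form(t2)] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(20))
    def test_weights_sum_to_one(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(int(rng.integers(4, 9)),
                             int(rng.integers(1, 4)), rng=rng)
        trees = displayed_trees(net)
        assert len(trees) <= 2 ** net.n_reticulations
        assert sum(w for _t, w in trees) == pytest.approx(1.0, abs=1e-12)


class TestTripleSystem:
    def test_tree_triple(self, three_taxon_tree):
        assert induced_triple_set(three_taxon_tree) == \
            {TripleTopology.binary("A", "B", "C")}

    def test_four_taxon_pair_share_printed_system(self):
        expected = {
            TripleTopology.binary("B", "C", "A"),
            TripleTopology.binary("A", "B", "C"),
            TripleTopology.binary("B", "D", "A"),
            TripleTopology.binary("A", "B", "D"),
            TripleTopology.binary("C", "D", "A"),
            TripleTopology.binary("C", "D", "B"),
        }
        assert induced_triple_set(clade_reticulation_network()) == expected
        assert induced_triple_set(leaf_reticulation_network()) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_system_size_and_coverage(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(4, 8))
        net = random_network(n, int(rng.integers(0, 3)), rng=rng)
        system = induced_triple_set(net)
        n_subsets = len(list(itertools.combinations(range(n), 3)))
        assert n_subsets <= len(system) <= 3 * n_subsets
        covered = {frozenset(t.taxa) for t in system}
        assert len(covered) == n_subsets

    def test_fewer_than_three_taxa_rejected(self):
        pair = parse_network("(A:1,B:1);")
        with pytest.raises(ValueError):
            induced_triple_set(pair)


class TestRestriction:
    def test_identity_on_own_taxa(self, one_retic_network):
        r = restrict_network(one_retic_network, {"A", "B", "C"})
        assert networks_isomorphic(r, one_retic_network, compare_params=True)

    def test_path_sum(self):
        net = parse_network("((A:1,B:1):2,(C:1,D:1):1);")
        r = restrict_network(net, {"A", "B", "C"})
        assert canonical_form(r) == canonical_form(
            parse_network("((A:1,B:1):2,C:2);"))
        cherry_parent = next(v for v in r.graph
                             if r.graph.out_degree(v) == 2 and v != r.root)
        (e,) = r.graph.in_edges(cherry_parent, keys=True)
        assert r.length(e) == pytest.approx(2.0)

    def test_disconnected_reticulation_gives_tree(self):
        # hybrid ancestry affects only E; restriction to {A,B,C} is a tree
        net = parse_network(
            "(((A:1,(E:1)#H1:1::0.6):1,(#H1:1::0.4,B:2):1):1,C:4);")
        r = restrict_network(net, {"A", "B", "C"})
        assert r.n_reticulations == 0
        assert sorted(r.taxa) == ["A", "B", "C"]

    def test_triple_system_invariant_under_restriction_union(self):
        rng = np.random.default_rng(11)
        net = random_network(6, 1, rng=rng)
        whole = induced_triple_set(net)
        pieces = set()
        for subset in itertools.combinations(net.taxa, 3):
            pieces |= induced_triple_set(restrict_network(net, subset))
        assert pieces == whole

    def test_unknown_taxon_rejected(self, three_taxon_tree):
        with pytest.raises(ValueError):
            restrict_network(three_taxon_tree, {"A", "B", "Z"})
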