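"""Pseudo-likelihood scoring and parameter optimization."""

import itertools
import math

import numpy as np
import pytest

from triplenet.coalescent import TripleEngine
from triplenet.examples import (clade_reticulation_network,
                                leaf_reticulation_network)
from triplenet.likelihood import log_pseudo_likelihood, optimize_parameters
from triplenet.network import parse_network
from triplenet.simulate import SimConfig, simulate_gene_trees
from triplenet.triples import TripleTable, build_triple_table


def expected_table(net, n=1000.0):
    """An idealized (infinite-data, scaled) table whose weights are the
    exact coalescent triple probabilities times n."""
    eng = TripleEngine(net)
    table = TripleTable(net.taxa)
    for i, s in enumerate(table.subsets):
        table.weights[i] = n * np.array(list(eng.distribution(s)))
    return table


def all_rooted_trees(taxa):
    """All rooted binary labeled topologies (15 for four taxa)."""
    def build(subset):
        if len(subset) == 1:
            yield subset[0]
            return
        first = subset[0]
        rest = subset[1:]
        for r in range(len(rest) + 1):
            for left_rest in itertools.combinations(rest, r):
                left = (first,) + left_rest
                right = tuple(t for t in rest if t not in left_rest)
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(right):
                        yield (lt, rt)

    def to_newick(t):
        if isinstance(t, str):
            return f"{t}:1"
        return "(" + ",".join(to_newick(c) for c in t) + "):1"

    return [parse_network(to_newick(t)[: -2] + ";")
            for t in build(tuple(taxa))]


class TestScoring:
    def test_single_subset_value(self):
        tree = parse_network("((A:1,B:1):2,C:2);")
        table = TripleTable(["A", "B", "C"], weights=[[10.0, 0.0, 0.0]])
        score = log_pseudo_likelihood(tree, table)
        p_major = 1 - (2 / 3) * math.exp(-2)
        assert score.log_value == pytest.approx(10 * math.log(p_major),
                                                abs=1e-10)

    def test_all_mass_on_a_discordant_triple(self):
        tree = parse_network("((A:1,B:1):30,C:2);")
        # all mass on a triple with probability e^{-30}/3 > 0: finite,
        # 5 * ln(e^{-30}/3) ~ -155.5 (triples with zero weight contribute 0)
        table = TripleTable(["A", "B", "C"], weights=[[0.0, 5.0, 0.0]])
        s = log_pseudo_likelihood(tree, table)
        assert s.log_value == pytest.approx(5 * (-30 - math.log(3.0)),
                                            abs=1e-6)

    def test_additivity_over_subsets(self):
        net = clade_reticulation_network()
        table = expected_table(net, 100.0)
        full = log_pseudo_likelihood(net, table)
        assert full.log_value == pytest.approx(
            sum(full.contributions.values()))
        # zeroing one subset removes exactly its contribution
        victim = table.subsets[1]
        reduced = TripleTable(table.taxa, weights=table.weights.copy())
        reduced.weights[1] = 0.0
        partial = log_pseudo_likelihood(net, reduced)
        assert partial.log_value == pytest.approx(
            full.log_value - full.contributions[victim], abs=1e-9)

    def test_taxon_mismatch_rejected(self):
        tree = parse_network("((A:1,B:1):2,C:2);")
        table = TripleTable(["A", "B", "Z"])
        with pytest.raises(ValueError):
            log_pseudo_likelihood(tree, table)

    def test_score_invariant_to_pendant_lengths(self):
        net = clade_reticulation_network()
        table = expected_table(net, 500.0)
        base = log_pseudo_likelihood(net, table).log_value
        jittered = clade_reticulation_network(pendant=7.7)
        assert log_pseudo_likelihood(jittered, table).log_value == \
            pytest.approx(base, abs=1e-9)

    def test_truth_is_a_stationary_maximum(self):
        """On a table exactly proportional to P(·|Ψ,γ), perturbing any
        internal branch length or inheritance probability cannot increase
        the score (multinomial maximum at the true frequencies)."""
        net = clade_reticulation_network()
        table = expected_table(net, 1000.0)
        base = log_pseudo_likelihood(net, table).log_value
        for e in net.internal_edges():
            for factor in (0.8, 1.25):
                cand = net.copy()
                cand.set_length(e, max(net.length(e) * factor, 1e-4))
                assert log_pseudo_likelihood(cand, table).log_value <= \
                    base + 1e-9
        (h,) = net.reticulations
        e = net.reticulation_edges(h)[0]
        for delta in (-0.05, 0.05):
            cand = net.copy()
            cand.set_gamma(e, min(max(net.gamma(e) + delta, 1e-3), 1 - 1e-3))
            assert log_pseudo_likelihood(cand, table).log_value <= base + 1e-9


class TestOptimization:
    def test_recovers_internal_branch_lengths(self):
        tree = parse_network("((A:1,B:1):1.0,(C:1,D:1):1.5);")
        trees = simulate_gene_trees(SimConfig(tree, n_loci=2000, seed=5))
        table = build_triple_table(trees, taxa=tree.taxa)
        start = parse_network("((A:1,B:1):0.3,(C:1,D:1):0.3);")
        opt = optimize_parameters(start, table, seed=0)
        fitted = sorted(v for e, v in opt.lengths.items()
                        if opt.network.graph.out_degree(e[1]) > 0)
        assert fitted[0] == pytest.approx(1.0, rel=0.1)
        assert fitted[1] == pytest.approx(1.5, rel=0.1)

    def test_score_never_below_input(self):
        net = clade_reticulation_network()
        table = expected_table(net, 200.0)
        opt = optimize_parameters(net, table, seed=3, n_starts=2)
        assert opt.score.log_value >= \
            log_pseudo_likelihood(net, table).log_value - 1e-9

    def test_true_tree_is_global_optimum_among_all_topologies(self):
        """With idealized data from a species tree, the generating topology
        attains the best optimized score over all 15 rooted 4-taxon trees
        (trees are uniquely encoded by their triple systems)."""
        truth = parse_network("((A:1,B:1):0.8,(C:1,D:1):1.2);")
        table = expected_table(truth, 500.0)
        scores = {}
        for cand in all_rooted_trees(["A", "B", "C", "D"]):
            opt = optimize_parameters(cand, table, seed=0, n_starts=3)
            scores[cand.newick(canonical=True, decimals=0)] = \
                opt.score.log_value
        best = max(scores, key=scores.get)
        assert best == truth.newick(canonical=True, decimals=0)
        others = sorted(scores.values())[:-1]
        assert max(others) < scores[best] - 1.0

    def test_triple_equivalent_topologies_reach_equal_optima(self):
        """The identifiability failure: with idealized data generated from
        one 4-taxon reticulate topology, the triple-equivalent alternative
        topology attains the same optimized pseudo-likelihood."""
        ref = clade_reticulation_network()
        table = expected_table(ref, 1000.0)
        o1 = optimize_parameters(ref, table, seed=0, tol=1e-14,
                                 max_evaluations=8000)
        o2 = optimize_parameters(leaf_reticulation_network(), table, seed=0,
                                 tol=1e-14, max_evaluations=8000)
        assert abs(o1.score.log_value - o2.score.log_value) < 1e-6

    def test_flat_inheritance_probability_flagged(self):
        """A reticulation whose hybrid descendant is absent from the data
        leaves γ unidentifiable; the optimizer reports it."""
        net = parse_network(
            "(((A:1,(E:1)#H1:1::0.6):1,(#H1:1::0.4,B:2):1):1,C:4);")
        trees = simulate_gene_trees(SimConfig(
            parse_network("((A:1,B:1):1,C:2);"), n_loci=200, seed=9))
        table = build_triple_table(trees, taxa=["A", "B", "C", "E"])
        opt = optimize_parameters(net, table, seed=0, n_starts=2)
        assert len(opt.unidentifiable_gammas) == 1
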