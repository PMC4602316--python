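"""Simulated-annealing search over phylogenetic-network space.

The search maximizes the log pseudo-likelihood of a network given a fixed
triple table.  Each iteration draws one of six moves according to preset
weights:

1. perturb one or more branch lengths (multiplicative lognormal step);
2. perturb one or more inheritance probabilities (uniform window, clipped);
3. add a reticulation edge (rejected at the reticulation cap, or when it
   would create a cycle or parallel edge);
4. delete a reticulation edge;
5. relocate the head of a reticulation edge;
6. relocate the tail of an edge.

Improvements are always accepted; a worse candidate is accepted with
probability exp(Δlog L / T_k) under the cooling schedule T_k = T0/(1 + c·k).
The best k distinct topologies seen are archived; at termination their
branch lengths and inheritance probabilities are optimized under the
pseudo-likelihood criterion and the archive is re-ranked, since parameters
are only sampled, never optimized, during the annealing itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .coalescent import TripleEngine
from .likelihood import (GAMMA_BOUNDS, LENGTH_BOUNDS, log_pseudo_likelihood,
                         optimize_parameters)
from .network import PhyloNetwork, canonical_form
from .triples import TripleTable

__all__ = ["SearchConfig", "SearchResult", "propose_move", "run_search"]


@dataclass
class SearchConfig:
    """Tuning knobs of the annealing search.

    ``cooling`` defaults to the value for which the temperature reaches 0.01
    at 80% of ``max_iterations``.  ``move_weights`` follow the move numbering
    above; they need not be normalized.
    """

    max_reticulations: int = 0
    move_weights: tuple = (0.15, 0.15, 0.10, 0.10, 0.25, 0.25)
    initial_temperature: float = 1.0
    cooling: float | None = None
    max_iterations: int = 5000
    stagnation_window: int = 2000
    top_k: int = 5
    n_runs: int = 5
    seed: int = 0
    length_step_sigma: float = 0.3
    gamma_step_window: float = 0.1

    def __post_init__(self):
        if len(self.move_weights) != 6 or any(w < 0 for w in self.move_weights) \
                or not any(self.move_weights):
            raise ValueError("move_weights must be six nonnegative values, "
                             "not all zero")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")

    def temperature(self, k: int) -> float:
        c = self.cooling
        if c is None:
            c = (self.initial_temperature / 0.01 - 1.0) / max(
                1.0, 0.8 * self.max_iterations)
        return self.initial_temperature / (1.0 + c * k)


@dataclass
class SearchResult:
    """Ranked archive after post-optimization.

    ``ranked`` holds (network, log score) pairs, best first, pairwise
    non-isomorphic topologies.  ``traces`` holds one (iteration, accepted,
    score) list per independent run.
    """

    ranked: list
    traces: list = field(repr=False, default_factory=list)

    @property
    def best(self) -> PhyloNetwork:
        return self.ranked[0][0]

    @property
    def best_score(self) -> float:
        return self.ranked[0][1]


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

def _with_int_ids(net: PhyloNetwork) -> PhyloNetwork:
    g = net.graph
    mapping = {v: i for i, v in enumerate(g.nodes)}
    h = nx.relabel_nodes(g, mapping, copy=True)
    return PhyloNetwork(h, mapping[net.root], validate=False)


def _next_id(g) -> int:
    return max(g.nodes) + 1


def _perturb_lengths(net, config, rng):
    cand = net.copy()
    edges = cand.internal_edges()
    if not edges:
        return cand, False
    n = int(rng.integers(1, len(edges) + 1))
    picks = rng.choice(len(edges), size=n, replace=False)
    for i in np.atleast_1d(picks):
        e = edges[int(i)]
        val = cand.length(e) * math.exp(config.length_step_sigma * rng.normal())
        cand.set_length(e, min(max(val, LENGTH_BOUNDS[0]), LENGTH_BOUNDS[1]))
    return cand, False


def _perturb_gammas(net, config, rng):
    cand = net.copy()
    retics = sorted(cand.reticulations)
    if not retics:
        return cand, False               # vacuous on a tree
    n = int(rng.integers(1, len(retics) + 1))
    picks = rng.choice(len(retics), size=n, replace=False)
    for i in np.atleast_1d(picks):
        h = retics[int(i)]
        e = cand.reticulation_edges(h)[0]
        val = cand.gamma(e) + rng.uniform(-config.gamma_step_window,
                                          config.gamma_step_window)
        cand.set_gamma(e, min(max(val, GAMMA_BOUNDS[0]), GAMMA_BOUNDS[1]))
    return cand, False


def _split_edge(g, edge, frac, new_node):
    """Subdivide edge at fraction ``frac``; γ of the original edge stays on
    the lower segment (whose head may be a reticulation)."""
    u, v, k = edge
    data = dict(g.edges[u, v, k])
    g.remove_edge(u, v, k)
    g.add_node(new_node)
    g.add_edge(u, new_node, length=data["length"] * frac, gamma=1.0)
    g.add_edge(new_node, v, length=data["length"] * (1.0 - frac),
               gamma=data["gamma"])
    return new_node


def _add_reticulation(net, config, rng):
    if net.n_reticulations >= config.max_reticulations:
        return None
    cand = net.copy()
    g = cand.graph
    edges = sorted(g.edges(keys=True))
    if len(edges) < 2:
        return None
    i, j = rng.choice(len(edges), size=2, replace=False)
    e1, e2 = edges[int(i)], edges[int(j)]        # new edge runs e1 -> e2
    if e2[1] == e1[0] or (e2[1] in g and nx.has_path(g, e2[1], e1[0])):
        return None
    m1 = _split_edge(g, e1, float(rng.uniform(0.2, 0.8)), _next_id(g))
    m2 = _split_edge(g, e2, float(rng.uniform(0.2, 0.8)), _next_id(g))
    gam = float(rng.uniform(0.05, 0.95))
    g.add_edge(m1, m2, length=float(rng.exponential(0.5)), gamma=gam)
    for u, v, k in g.in_edges(m2, keys=True):
        if u != m1:
            g.edges[u, v, k]["gamma"] = 1.0 - gam
    return cand, True


def _cleanup(g, root):
    """Restore binaryness after an edge deletion: drop childless non-leaves,
    suppress unary nodes, trim unary root chains.  Returns the new root."""
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v == root:
                continue
            if g.out_degree(v) == 0 and "label" not in g.nodes[v]:
                g.remove_node(v)
                changed = True
            elif g.in_degree(v) == 1 and g.out_degree(v) == 1:
                (pu, _1, pk), = g.in_edges(v, keys=True)
                (_2, cv, ck), = g.out_edges(v, keys=True)
                din, dout = g.edges[pu, v, pk], g.edges[v, cv, ck]
                g.add_edge(pu, cv, length=din["length"] + dout["length"],
                           gamma=din["gamma"] * dout["gamma"])
                g.remove_node(v)
                changed = True
    while g.out_degree(root) == 1:
        (child,) = g.successors(root)
        g.remove_node(root)
        root = child
    return root


def _delete_reticulation(net, config, rng):
    retics = sorted(net.reticulations)
    if not retics:
        return None
    cand = net.copy()
    g = cand.graph
    h = retics[int(rng.integers(len(retics)))]
    edges = cand.reticulation_edges(h)
    drop = edges[int(rng.integers(2))]
    keep = edges[1 - edges.index(drop)]
    g.edges[keep]["gamma"] = 1.0
    g.remove_edge(*drop)
    cand.root = _cleanup(g, cand.root)
    return cand, True


def _relocate_reticulation_head(net, config, rng):
    """Detach one hybrid edge from its reticulation node and re-attach it to
    a new reticulation node subdividing another edge."""
    retics = sorted(net.reticulations)
    if not retics:
        return None
    cand = net.copy()
    g = cand.graph
    h = retics[int(rng.integers(len(retics)))]
    edges = cand.reticulation_edges(h)
    moved = edges[int(rng.integers(2))]
    other = edges[1 - edges.index(moved)]
    s = moved[0]
    # a relocated hybrid edge plays a new role: resample its inheritance
    # probability rather than dragging along the old, adapted value
    gam = float(rng.uniform(0.05, 0.95))
    length = g.edges[moved]["length"]
    anchors = {other[0], next(iter(g.successors(h)))}
    g.edges[other]["gamma"] = 1.0
    g.remove_edge(*moved)
    cand.root = _cleanup(g, cand.root)
    if s not in g:
        return None
    targets = sorted(e for e in g.edges(keys=True) if e[0] != s and e[1] != s)
    if not targets:
        return None
    t = _pick_target(targets, anchors, g, rng)
    if nx.has_path(g, t[1], s):
        return None
    h2 = _split_edge(g, t, float(rng.uniform(0.2, 0.8)), _next_id(g))
    g.add_edge(s, h2, length=length, gamma=gam)
    for u, v, k in g.in_edges(h2, keys=True):
        if u != s:
            g.edges[u, v, k]["gamma"] = 1.0 - gam
    return cand, True


def _relocate_tail(net, config, rng):
    """Prune the tail of an edge from its current position and regraft it
    onto another edge (rooted SPR on the tail node)."""
    cand = net.copy()
    g = cand.graph
    movable = sorted(
        (u, v, k) for u, v, k in g.edges(keys=True)
        if u != cand.root and g.in_degree(u) == 1 and g.out_degree(u) == 2)
    if not movable:
        return None
    u, v, k = movable[int(rng.integers(len(movable)))]
    (p, _1, pk), = g.in_edges(u, keys=True)
    other_children = [(a, b, c) for a, b, c in g.out_edges(u, keys=True)
                      if (a, b, c) != (u, v, k)]
    (ou, oc, ok), = other_children
    din, dout = g.edges[p, u, pk], g.edges[ou, oc, ok]
    g.remove_edge(p, u, pk)
    g.remove_edge(ou, oc, ok)
    g.add_edge(p, oc, length=din["length"] + dout["length"],
               gamma=din["gamma"] * dout["gamma"])
    targets = sorted(e for e in g.edges(keys=True)
                     if e[0] != u and e[1] != u and e != (u, v, k))
    if not targets:
        return None
    t = _pick_target(targets, {p, oc}, g, rng)
    if nx.has_path(g, v, t[0]) or t[0] == v:
        return None
    a, b, tk = t
    data = dict(g.edges[a, b, tk])
    g.remove_edge(a, b, tk)
    frac = float(rng.uniform(0.2, 0.8))
    g.add_edge(a, u, length=data["length"] * frac, gamma=1.0)
    g.add_edge(u, b, length=data["length"] * (1.0 - frac),
               gamma=data["gamma"])
    return cand, True


def _pick_target(targets, anchors, g, rng, local_bias: float = 0.5):
    """Choose a re-attachment edge: with probability ``local_bias`` slide to
    an edge adjacent to the detachment site (cheap local refinement of an
    attachment point), otherwise uniform over all legal edges."""
    anchors = {a for a in anchors if a in g}
    local = [e for e in targets if e[0] in anchors or e[1] in anchors]
    if local and rng.random() < local_bias:
        return local[int(rng.integers(len(local)))]
    return targets[int(rng.integers(len(targets)))]


_MOVES = (_perturb_lengths, _perturb_gammas, _add_reticulation,
          _delete_reticulation, _relocate_reticulation_head, _relocate_tail)


def propose_move(net: PhyloNetwork, config: SearchConfig, rng
                 ) -> tuple:
    """Draw one valid move; rejected proposals (cap reached, cycle, parallel
    edge, failed validation) are resampled.  Returns (candidate network,
    topology_changed flag)."""
    weights = np.asarray(config.move_weights, dtype=float)
    probs = weights / weights.sum()
    for _attempt in range(200):
        mv = int(rng.choice(6, p=probs))
        out = _MOVES[mv](net, config, rng)
        if out is None:
            continue
        cand, changed = out
        try:
            cand.validate(strict=True)
        except Exception:
            continue
        return cand, changed
    # overwhelmingly unlikely fallback: pure parameter jitter
    cand, changed = _perturb_lengths(net, config, rng)
    return cand, changed


# ---------------------------------------------------------------------------
# Annealing
# ---------------------------------------------------------------------------

class _Archive:
    """Top-k distinct topologies by the best score seen for each."""

    def __init__(self, k: int):
        self.k = k
        self.entries: dict = {}      # canonical topology -> (score, network)

    def offer(self, key, score, net):
        cur = self.entries.get(key)
        if cur is None or score > cur[0]:
            self.entries[key] = (score, net.copy())
        if len(self.entries) > self.k:
            worst = min(self.entries, key=lambda kk: self.entries[kk][0])
            del self.entries[worst]

    def __contains__(self, key):
        return key in self.entries


def _anneal(table, start, config, seed):
    rng = np.random.default_rng(seed)
    current = _with_int_ids(start)
    engine = TripleEngine(current, taxa=table.taxa)
    cur_score = log_pseudo_likelihood(current, table, engine=engine).log_value
    cur_key = canonical_form(current)
    archive = _Archive(config.top_k)
    archive.offer(cur_key, cur_score, current)
    trace = [(0, True, cur_score)]
    stagnant = 0
    for it in range(1, config.max_iterations + 1):
        cand, changed = propose_move(current, config, rng)
        if changed:
            cand_engine = TripleEngine(cand, taxa=table.taxa)
            cand_key = canonical_form(cand)
        else:
            cand_engine = engine
            cand_key = cur_key
        cand_score = log_pseudo_likelihood(cand, table,
                                           engine=cand_engine).log_value
        archive.offer(cand_key, cand_score, cand)
        accept = cand_score > cur_score
        if not accept:
            T = config.temperature(it)
            delta = cand_score - cur_score
            if delta > -math.inf and T > 0:
                accept = rng.random() < math.exp(max(delta / T, -700.0))
        if accept:
            current, engine = cand, cand_engine
            cur_score, cur_key = cand_score, cand_key
        trace.append((it, accept, cur_score))
        stagnant = stagnant + 1 if cur_key in archive else 0
        if stagnant >= config.stagnation_window:
            break
    return archive, trace


def run_search(table: TripleTable, start: PhyloNetwork,
               config: SearchConfig | None = None) -> SearchResult:
    """Search for the maximum pseudo-likelihood network.

    Runs ``config.n_runs`` independent annealing chains from the starting
    network (seeds derived from ``config.seed``), merges their archives,
    optimizes the branch lengths and inheritance probabilities of the
    archived topologies, and ranks by the post-optimized score.  With a
    fixed seed the whole procedure is deterministic.
    """
    if config is None:
        config = SearchConfig()
    if not table.subsets:
        raise ValueError("empty triple table")
    if float(np.sum(table.weights)) == 0.0:
        raise ValueError("triple table carries no weight (no gene trees?)")
    merged = _Archive(config.top_k)
    traces = []
    for run in range(config.n_runs):
        archive, trace = _anneal(table, start, config,
                                 seed=(config.seed + 1009 * run) % (2**31))
        traces.append(trace)
        for key, (score, net) in archive.entries.items():
            merged.offer(key, score, net)
    ranked = []
    for key, (raw_score, net) in merged.entries.items():
        opt = optimize_parameters(net, table, seed=config.seed)
        ranked.append((opt.network, opt.score.log_value))
    ranked.sort(key=lambda pair: -pair[1])
    return SearchResult(ranked=ranked, traces=traces)
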