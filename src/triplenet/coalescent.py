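"""Exact rooted-triple topology probabilities under the network multispecies
coalescent.

One lineage is sampled at each of three leaves of a phylogenetic network.
Moving rootward, lineages sharing an edge coalesce at rate 1 per pair over the
edge's branch length (coalescent units); at a reticulation node every lineage
cluster independently follows one of the two parent edges, with probability
given by that edge's inheritance probability (a cluster that has already
coalesced routes as a single unit); any lineages surviving to the root
coalesce above it, the first merging pair being uniform among those present.

The computation is a small dynamic program over the network restricted to the
three leaves, tracking the partition state of the (at most three) lineages on
each edge.  The per-edge transition probabilities for a branch of length τ
are: two lineages stay apart with probability e^{-τ}; three lineages all stay
apart with probability e^{-3τ}, exactly one (uniform) pair merges with total
probability (3/2)(e^{-τ}-e^{-3τ}), and the remainder is full coalescence with
the first merging pair uniform.
"""

from __future__ import annotations

import itertools
import math
import weakref
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import least_squares

from .network import PhyloNetwork, TripleTopology, binary_triples_of

__all__ = [
    "TripleDistribution",
    "TripleEngine",
    "triple_probabilities",
    "all_triple_distributions",
    "equate_triple_systems",
    "EquateResult",
]

# branch lengths beyond this are effectively infinite (e^{-30} < 1e-13)
MAX_EFFECTIVE_LENGTH = 30.0


@dataclass(frozen=True)
class TripleDistribution:
    """Probabilities of the three binary triples on a 3-subset of taxa.

    ``probs`` follows the canonical order (XY|Z, XZ|Y, YZ|X) for sorted taxa
    (X, Y, Z).
    """

    taxa: tuple
    probs: tuple

    def __post_init__(self):
        if len(self.taxa) != 3 or len(self.probs) != 3:
            raise ValueError("a triple distribution has 3 taxa and 3 probabilities")

    def __getitem__(self, triple: TripleTopology) -> float:
        for t, p in zip(binary_triples_of(self.taxa), self.probs):
            if t == triple:
                return p
        raise KeyError(triple)

    def as_dict(self) -> dict:
        return dict(zip(binary_triples_of(self.taxa), self.probs))

    def __iter__(self):
        return iter(self.probs)


# ---------------------------------------------------------------------------
# Restriction with parameter provenance
# ---------------------------------------------------------------------------

def _restricted_program(net: PhyloNetwork, taxa):
    """Restrict ``net`` to three taxa, keeping track of which original edges
    contribute to each restricted edge.

    Returns (order, in_edges, root, leaf_taxon) where ``in_edges[v]`` is a
    list of (parent, length_sources, gamma_sources) for the edges along which
    a lineage at v ascends, ``order`` processes children before parents, and
    ``leaf_taxon`` maps leaf nodes to taxon indices 0..2 (sorted labels).
    """
    g = net.graph
    taxa = sorted(taxa)
    leaves = {net.leaf_for(t): i for i, t in enumerate(taxa)}
    keep = set()
    stack = list(leaves)
    while stack:
        v = stack.pop()
        if v in keep:
            continue
        keep.add(v)
        stack.extend(g.predecessors(v))

    h = nx.MultiDiGraph()
    h.add_nodes_from(keep)
    retics = {v for v in g if g.in_degree(v) == 2}
    for u, v, k in g.edges(keys=True):
        if u in keep and v in keep:
            h.add_edge(u, v, srcs=((u, v, k),),
                       gsrcs=((u, v, k),) if v in retics else ())

    root = net.root
    # suppress unary nodes, concatenating sources
    changed = True
    while changed:
        changed = False
        for v in list(h.nodes):
            if v == root or v in leaves:
                continue
            if h.in_degree(v) == 1 and h.out_degree(v) == 1:
                (pu, _1, pk), = h.in_edges(v, keys=True)
                (_2, cv, ck), = h.out_edges(v, keys=True)
                din, dout = h.edges[pu, v, pk], h.edges[v, cv, ck]
                h.add_edge(pu, cv, srcs=din["srcs"] + dout["srcs"],
                           gsrcs=din["gsrcs"] + dout["gsrcs"])
                h.remove_node(v)
                changed = True
    # lineages above the topmost coalescence opportunity see unbounded time;
    # unary root chains can therefore be dropped exactly
    while h.out_degree(root) == 1:
        (child,) = h.successors(root)
        h.remove_node(root)
        root = child

    order = [v for v in reversed(list(nx.topological_sort(h)))]
    in_edges = {v: [(u, h.edges[u, v, k]["srcs"], h.edges[u, v, k]["gsrcs"])
                    for u, _w, k in h.in_edges(v, keys=True)]
                for v in h.nodes}
    return order, in_edges, root, leaves


# ---------------------------------------------------------------------------
# Cluster algebra (masks over taxon indices 0, 1, 2)
# ---------------------------------------------------------------------------
# A cluster is (members_mask, cherry_mask); cherry_mask records the first
# pair that coalesced (it determines the final triple topology).

_SINGLETONS = ((1, 0), (2, 0), (4, 0))


def _merge(c1, c2):
    m = c1[0] | c2[0]
    if c1[0].bit_count() == 1 and c2[0].bit_count() == 1:
        return (m, m)
    return (m, c1[1] if c1[0].bit_count() == 2 else c2[1])


def _evolve(clusters, length):
    """Coalescence outcomes for a set of clusters travelling one edge.

    Returns a list of (tuple_of_clusters, probability).
    """
    k = len(clusters)
    if k <= 1:
        return [(tuple(clusters), 1.0)]
    t = min(length, MAX_EFFECTIVE_LENGTH)
    if k == 2:
        p_apart = math.exp(-t)
        c1, c2 = clusters
        return [((c1, c2), p_apart), ((_merge(c1, c2),), 1.0 - p_apart)]
    # three clusters on one edge are necessarily three singletons
    e1, e3 = math.exp(-t), math.exp(-3.0 * t)
    p_all_apart = e3
    p_one_each = 0.5 * (e1 - e3)                  # a specific pair merges
    p_full_each = (1.0 - e3 - 3.0 * p_one_each) / 3.0
    c1, c2, c3 = clusters
    out = [((c1, c2, c3), p_all_apart)]
    for (a, b), c in (((c1, c2), c3), ((c1, c3), c2), ((c2, c3), c1)):
        out.append(((_merge(a, b), c), p_one_each))
        out.append(((_merge(_merge(a, b), c),), p_full_each))
    return out


class TripleEngine:
    """Precomputed triple-probability evaluator for one network topology.

    The restriction of the network to every 3-subset of taxa is computed once;
    evaluations then substitute current branch lengths and inheritance
    probabilities, so the engine can be reused across parameter changes (but
    not across topology changes).
    """

    def __init__(self, net: PhyloNetwork, taxa=None):
        self.net = net
        self.taxa = sorted(taxa) if taxa is not None else net.taxa
        if len(self.taxa) < 3:
            raise ValueError("triple probabilities require at least 3 taxa")
        self.subsets = [tuple(s) for s in
                        itertools.combinations(self.taxa, 3)]
        self._programs = {s: _restricted_program(net, s) for s in self.subsets}

    # -- parameter plumbing --------------------------------------------------

    def current_params(self):
        """(lengths, gammas) dicts keyed by full-network edge triples."""
        g = self.net.graph
        lengths = {}
        gammas = {}
        for u, v, k, data in g.edges(keys=True, data=True):
            lengths[(u, v, k)] = data["length"]
            gammas[(u, v, k)] = data["gamma"]
        return lengths, gammas

    # -- evaluation ----------------------------------------------------------

    def distribution(self, subset, lengths=None, gammas=None) -> TripleDistribution:
        subset = tuple(sorted(subset))
        if lengths is None or gammas is None:
            cl, cg = self.current_params()
            lengths = cl if lengths is None else lengths
            gammas = cg if gammas is None else gammas
        probs = self._run(subset, lengths, gammas)
        return TripleDistribution(subset, tuple(probs))

    def all_distributions(self, lengths=None, gammas=None) -> dict:
        if lengths is None or gammas is None:
            cl, cg = self.current_params()
            lengths = cl if lengths is None else lengths
            gammas = cg if gammas is None else gammas
        return {s: TripleDistribution(s, tuple(self._run(s, lengths, gammas)))
                for s in self.subsets}

    def probability_vector(self, lengths, gammas) -> np.ndarray:
        """Concatenated distributions over all subsets (for optimizers)."""
        return np.concatenate([self._run(s, lengths, gammas)
                               for s in self.subsets])

    def _run(self, subset, lengths, gammas):
        order, in_edges, root, leaves = self._programs[subset]
        # initial state: one singleton cluster at each leaf
        init = frozenset((v, _SINGLETONS[i]) for v, i in leaves.items())
        state = {init: 1.0}
        for v in order:
            if v == root:
                break
            edges = in_edges[v]
            new_state: dict = {}
            for cfg, p in state.items():
                here = tuple(sorted(c for (n, c) in cfg if n == v))
                if not here:
                    new_state[cfg] = new_state.get(cfg, 0.0) + p
                    continue
                rest = tuple((n, c) for (n, c) in cfg if n != v)
                for placed, q in self._ascend(v, here, edges, lengths, gammas):
                    key = frozenset(rest + placed)
                    new_state[key] = new_state.get(key, 0.0) + p * q
            state = new_state
        # finalize above the root
        probs = np.zeros(3)
        x, y, z = 0, 1, 2
        cherry_index = {3: 0, 5: 1, 6: 2}   # {x,y}, {x,z}, {y,z}
        for cfg, p in state.items():
            clusters = [c for (_n, c) in cfg]
            full = [c for c in clusters if c[0] == 7]
            if full:
                probs[cherry_index[full[0][1]]] += p
            elif len(clusters) == 2:
                pair = next(c for c in clusters if c[0].bit_count() == 2)
                probs[cherry_index[pair[1]]] += p
            else:  # three singletons: first pair above the root is uniform
                probs += p / 3.0
        return probs

    def _ascend(self, v, here, edges, lengths, gammas):
        """All ways the clusters at node v travel its parent edge(s)."""
        if len(edges) == 1:
            parent, srcs, _g = edges[0]
            L = sum(lengths[e] for e in srcs)
            return [(tuple((parent, c) for c in cs), q)
                    for cs, q in _evolve(here, L)]
        # reticulation: each cluster routes independently
        probs_edge = []
        for parent, srcs, gsrcs in edges:
            gp = 1.0
            for e in gsrcs:
                gp *= gammas[e]
            L = sum(lengths[e] for e in srcs)
            probs_edge.append((parent, gp, L))
        total = sum(gp for _p, gp, _L in probs_edge)
        out = []
        for routing in itertools.product(range(len(edges)), repeat=len(here)):
            rp = 1.0
            groups = [[] for _ in edges]
            for c, r in zip(here, routing):
                rp *= probs_edge[r][1] / total if total > 0 else 0.0
                groups[r].append(c)
            if rp == 0.0:
                continue
            evolved = [_evolve(tuple(gcs), probs_edge[i][2])
                       for i, gcs in enumerate(groups)]
            for combo in itertools.product(*evolved):
                placed = []
                q = rp
                for i, (cs, qq) in enumerate(combo):
                    q *= qq
                    placed.extend((probs_edge[i][0], c) for c in cs)
                out.append((tuple(placed), q))
        return out


_ENGINES: "weakref.WeakKeyDictionary[PhyloNetwork, TripleEngine]" = \
    weakref.WeakKeyDictionary()


def _engine_for(net: PhyloNetwork) -> TripleEngine:
    eng = _ENGINES.get(net)
    if eng is None:
        eng = TripleEngine(net)
        _ENGINES[net] = eng
    return eng


def triple_probabilities(net: PhyloNetwork, taxa) -> TripleDistribution:
    """Exact probabilities of the three binary triples on ``taxa`` under the
    multispecies coalescent on the network (one lineage per species).

    The restriction machinery is memoized per network object; parameter
    (branch length / γ) changes on the same object are picked up, topology
    changes require a new object.
    """
    return _engine_for(net).distribution(tuple(taxa))


def all_triple_distributions(net: PhyloNetwork) -> dict:
    """Triple distributions for every 3-subset of the network's taxa."""
    return _engine_for(net).all_distributions()


# ---------------------------------------------------------------------------
# Equating two triple systems
# ---------------------------------------------------------------------------

@dataclass
class EquateResult:
    """Outcome of fitting one network's parameters to match another's triple
    distributions."""

    lengths: dict
    gammas: dict
    residual: float
    converged: bool
    network: PhyloNetwork = field(repr=False, default=None)


def _free_parameters(net: PhyloNetwork):
    """Free parameters of a topology: internal branch lengths (pendant edges
    cannot affect triple topologies) and one γ per reticulation node."""
    free_lengths = net.internal_edges()
    free_gammas = [net.reticulation_edges(h)[0] for h in sorted(net.reticulations)]
    return free_lengths, free_gammas


def equate_triple_systems(reference: PhyloNetwork, target: PhyloNetwork,
                          n_starts: int = 8, seed: int = 0,
                          tol: float = 1e-14) -> EquateResult:
    """Find branch lengths and inheritance probabilities for ``target`` that
    reproduce the triple distributions of ``reference``.

    Minimizes the sum of squared differences between the two networks' triple
    distributions over all 3-subsets of the shared taxon set, over the
    target's internal branch lengths (log scale) and inheritance
    probabilities (logit scale), with multi-start least squares.  A residual
    near zero certifies that the two topologies are equivalent under rooted
    triples for the reference parameterization; a residual bounded away from
    zero certifies they are not.
    """
    if sorted(reference.taxa) != sorted(target.taxa):
        raise ValueError("reference and target must share the same taxa")
    rng = np.random.default_rng(seed)
    ref_eng = TripleEngine(reference)
    rl, rg = ref_eng.current_params()
    ref_vec = ref_eng.probability_vector(rl, rg)

    tgt = target.copy()
    eng = TripleEngine(tgt)
    free_lengths, free_gammas = _free_parameters(tgt)
    base_lengths, base_gammas = eng.current_params()
    gamma_partner = {}
    for e in free_gammas:
        h = e[1]
        e1, e2 = tgt.reticulation_edges(h)
        gamma_partner[e] = e2 if e == e1 else e1

    nl = len(free_lengths)

    def unpack(x):
        lengths = dict(base_lengths)
        gammas = dict(base_gammas)
        for e, xi in zip(free_lengths, x[:nl]):
            lengths[e] = math.exp(xi)
        for e, xi in zip(free_gammas, x[nl:]):
            gam = 1.0 / (1.0 + math.exp(-xi))
            gammas[e] = gam
            gammas[gamma_partner[e]] = 1.0 - gam
        return lengths, gammas

    def resid(x):
        lengths, gammas = unpack(x)
        return eng.probability_vector(lengths, gammas) - ref_vec

    starts = []
    x0 = np.concatenate([
        [math.log(max(base_lengths[e], 1e-3)) for e in free_lengths],
        [math.log(base_gammas[e] / max(1.0 - base_gammas[e], 1e-12))
         if 0 < base_gammas[e] < 1 else 0.0 for e in free_gammas]])
    starts.append(x0)
    for _ in range(n_starts - 1):
        starts.append(np.concatenate([
            rng.normal(0.0, 1.0, size=nl),
            rng.normal(0.0, 1.5, size=len(free_gammas))]))

    best = None
    for s in starts:
        try:
            sol = least_squares(resid, s, method="lm", xtol=1e-15, ftol=1e-15)
        except Exception:
            continue
        ssq = float(np.sum(sol.fun ** 2))
        if best is None or ssq < best[0]:
            best = (ssq, sol.x)
        if ssq < tol:
            break
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    ssq, x = best
    lengths, gammas = unpack(x)
    for e in free_lengths:
        tgt.set_length(e, lengths[e])
    for e in free_gammas:
        tgt.set_gamma(e, gammas[e])
    fitted_lengths = {e: lengths[e] for e in free_lengths}
    fitted_gammas = {e: gammas[e] for e in free_gammas}
    return EquateResult(fitted_lengths, fitted_gammas, ssq,
                        converged=ssq < tol, network=tgt)
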