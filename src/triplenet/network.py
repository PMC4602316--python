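"""Rooted binary phylogenetic networks with branch lengths and inheritance probabilities.

A phylogenetic network is a rooted, directed, acyclic graph in which the root
has in-degree 0 and out-degree 2, leaves have in-degree 1 and out-degree 0,
internal tree nodes have in-degree 1 and out-degree 2, and reticulation
(hybrid) nodes have in-degree 2 and out-degree 1.  Every edge carries a branch
length in coalescent units; the two edges entering a reticulation node carry
inheritance probabilities summing to one, and all other edges have inheritance
probability one.

Networks are stored as :class:`networkx.MultiDiGraph` objects (restrictions of
a network to a leaf subset can create parallel edges, which are meaningful for
the coalescent process and therefore preserved).  Edges are addressed as
``(tail, head, key)`` triples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "PhyloNetwork",
    "TripleTopology",
    "NetworkParseError",
    "NetworkValidationError",
    "parse_network",
    "write_network",
    "displayed_trees",
    "induced_triple_set",
    "restrict_network",
    "networks_isomorphic",
]

GAMMA_TOL = 1e-6


class NetworkParseError(ValueError):
    """Raised on malformed (extended) Newick input."""


class NetworkValidationError(ValueError):
    """Raised when a graph violates the phylogenetic-network invariants."""


@dataclass(frozen=True)
class TripleTopology:
    """A rooted topology on an unordered set of three species.

    ``cherry`` is the 2-subset of taxa that are closer to each other than to
    the third ("xy|z" places x and y in the cherry); ``cherry is None``
    denotes the unresolved star topology.
    """

    taxa: frozenset
    cherry: frozenset | None = None

    def __post_init__(self):
        if len(self.taxa) != 3:
            raise ValueError("a triple is defined on exactly three taxa")
        if self.cherry is not None:
            if len(self.cherry) != 2 or not self.cherry <= self.taxa:
                raise ValueError("cherry must be a 2-subset of the taxa")

    @property
    def is_binary(self) -> bool:
        return self.cherry is not None

    @property
    def outgroup(self):
        """The taxon separated from the cherry (binary triples only)."""
        if self.cherry is None:
            raise ValueError("star triple has no outgroup")
        (out,) = self.taxa - self.cherry
        return out

    @classmethod
    def binary(cls, a, b, c) -> "TripleTopology":
        """The triple ab|c."""
        return cls(frozenset((a, b, c)), frozenset((a, b)))

    @classmethod
    def star(cls, a, b, c) -> "TripleTopology":
        return cls(frozenset((a, b, c)), None)

    def __str__(self) -> str:
        if self.cherry is None:
            return "".join(sorted(self.taxa))
        return "".join(sorted(self.cherry)) + "|" + self.outgroup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TripleTopology({self})"


def binary_triples_of(subset):
    """The three binary triples on a 3-subset, in canonical order.

    For sorted taxa (X, Y, Z) the order is (XY|Z, XZ|Y, YZ|X); this ordering
    is used consistently by the triple table and the coalescent module.
    """
    x, y, z = sorted(subset)
    return (
        TripleTopology.binary(x, y, z),
        TripleTopology.binary(x, z, y),
        TripleTopology.binary(y, z, x),
    )


class PhyloNetwork:
    """A rooted binary phylogenetic network.

    Parameters
    ----------
    graph:
        MultiDiGraph whose leaf nodes carry a ``label`` attribute and whose
        edges carry ``length`` (coalescent units) and ``gamma`` attributes.
    root:
        The unique in-degree-0 node.
    validate:
        If true (default), check all structural invariants on construction.
    strict:
        Strict validation additionally forbids parallel edges and requires
        the root to have out-degree 2; restrictions of a network use
        ``strict=False``.
    """

    def __init__(self, graph: nx.MultiDiGraph, root=None, validate: bool = True,
                 strict: bool = True):
        if not isinstance(graph, nx.MultiDiGraph):
            g = nx.MultiDiGraph()
            g.add_nodes_from(graph.nodes(data=True))
            for u, v, data in graph.edges(data=True):
                g.add_edge(u, v, **data)
            graph = g
        self.graph = graph
        if root is None:
            roots = [v for v in graph if graph.in_degree(v) == 0]
            if len(roots) != 1:
                raise NetworkValidationError(
                    f"expected exactly one root, found {len(roots)}")
            root = roots[0]
        self.root = root
        self.strict = strict
        if validate:
            self.validate(strict=strict)

    # -- basic interrogation -------------------------------------------------

    @property
    def leaves(self):
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    @property
    def taxa(self):
        return sorted(self.graph.nodes[v]["label"] for v in self.leaves)

    @property
    def tree_nodes(self):
        g = self.graph
        return [v for v in g
                if g.in_degree(v) <= 1 and g.out_degree(v) >= 2 and v != self.root]

    @property
    def reticulations(self):
        g = self.graph
        return [v for v in g if g.in_degree(v) == 2]

    @property
    def n_reticulations(self) -> int:
        return len(self.reticulations)

    def leaf_for(self, label):
        for v in self.leaves:
            if self.graph.nodes[v]["label"] == label:
                return v
        raise KeyError(label)

    def edges(self):
        """All edges as (tail, head, key) triples."""
        return list(self.graph.edges(keys=True))

    def length(self, edge) -> float:
        u, v, k = edge
        return self.graph.edges[u, v, k]["length"]

    def gamma(self, edge) -> float:
        u, v, k = edge
        return self.graph.edges[u, v, k]["gamma"]

    def set_length(self, edge, value: float) -> None:
        u, v, k = edge
        self.graph.edges[u, v, k]["length"] = float(value)

    def set_gamma(self, edge, value: float) -> None:
        """Set γ on a reticulation edge and 1-γ on its partner edge."""
        u, v, k = edge
        if self.graph.in_degree(v) != 2:
            raise NetworkValidationError(f"edge into node {v} is not a reticulation edge")
        self.graph.edges[u, v, k]["gamma"] = float(value)
        for pu, pv, pk in self.graph.in_edges(v, keys=True):
            if (pu, pv, pk) != (u, v, k):
                self.graph.edges[pu, pv, pk]["gamma"] = 1.0 - float(value)

    def reticulation_edges(self, node):
        """The two in-edges of a reticulation node, in a deterministic order."""
        edges = sorted(self.graph.in_edges(node, keys=True))
        if len(edges) != 2:
            raise NetworkValidationError(f"node {node} is not a reticulation node")
        return edges

    def internal_edges(self):
        """Edges whose head is not a leaf (the edges that can affect triple
        topology probabilities)."""
        g = self.graph
        return [(u, v, k) for u, v, k in g.edges(keys=True) if g.out_degree(v) > 0]

    def copy(self) -> "PhyloNetwork":
        return PhyloNetwork(self.graph.copy(), self.root, validate=False,
                            strict=self.strict)

    # -- validation ----------------------------------------------------------

    def validate(self, strict: bool | None = None) -> None:
        """Check all structural invariants; raise NetworkValidationError."""
        if strict is None:
            strict = self.strict
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise NetworkValidationError("graph contains a directed cycle")
        roots = [v for v in g if g.in_degree(v) == 0]
        if roots != [self.root] and set(roots) != {self.root}:
            raise NetworkValidationError(
                f"expected unique root {self.root}, found in-degree-0 nodes {roots}")
        labels = []
        for v in g:
            din, dout = g.in_degree(v), g.out_degree(v)
            if v == self.root:
                if dout != 2 and strict:
                    raise NetworkValidationError(
                        f"root {v} must have out-degree 2, has {dout}")
            elif dout == 0:
                if din != 1:
                    raise NetworkValidationError(
                        f"leaf {v!r} must have in-degree 1, has {din}")
                if "label" not in g.nodes[v]:
                    raise NetworkValidationError(f"leaf {v!r} has no taxon label")
                labels.append(g.nodes[v]["label"])
            elif din == 1:
                if dout != 2:
                    raise NetworkValidationError(
                        f"tree node {v!r} must have out-degree 2, has {dout}")
            elif din == 2:
                if dout != 1:
                    raise NetworkValidationError(
                        f"reticulation node {v!r} must have out-degree 1, has {dout}")
            else:
                raise NetworkValidationError(
                    f"node {v!r} has unsupported degrees (in={din}, out={dout})")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NetworkValidationError(f"duplicate leaf labels: {dupes}")
        for u, v, k, data in g.edges(keys=True, data=True):
            if data.get("length", 0.0) < 0:
                raise NetworkValidationError(
                    f"negative branch length on edge {(u, v)}")
            if not (0.0 <= data.get("gamma", 1.0) <= 1.0):
                raise NetworkValidationError(
                    f"inheritance probability outside [0,1] on edge {(u, v)}")
        for v in g:
            if g.in_degree(v) == 2:
                ins = list(g.in_edges(v, keys=True, data=True))
                total = sum(d.get("gamma", 1.0) for *_e, d in ins)
                if abs(total - 1.0) > GAMMA_TOL:
                    raise NetworkValidationError(
                        f"inheritance probabilities into node {v!r} sum to "
                        f"{total}, expected 1")
                if strict and len({(u, v) for u, v, _k, _d in ins}) == 1:
                    raise NetworkValidationError(
                        f"parallel reticulation edges into node {v!r}")
            elif g.in_degree(v) == 1:
                (_u, _v, _k, d), = g.in_edges(v, keys=True, data=True)
                if abs(d.get("gamma", 1.0) - 1.0) > GAMMA_TOL:
                    raise NetworkValidationError(
                        f"edge into non-reticulation node {v!r} must have γ=1")

    # -- convenience ---------------------------------------------------------

    def __repr__(self) -> str:
        return (f"<PhyloNetwork taxa={self.taxa} "
                f"reticulations={self.n_reticulations}>")

    def newick(self, canonical: bool = False, decimals: int | None = None) -> str:
        return write_network(self, canonical=canonical, decimals=decimals)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_LABEL_END = set(":,();#[]")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.nodes = []       # list of dicts
        self.missing_lengths = 0

    def error(self, msg):
        raise NetworkParseError(f"{msg} at position {self.pos} in {self.text!r}")

    def peek(self):
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, ch):
        if self.peek() != ch:
            self.error(f"expected {ch!r}, found {self.peek()!r}")
        self.pos += 1

    def label(self):
        self.peek()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in _LABEL_END \
                and not self.text[self.pos].isspace():
            self.pos += 1
        return self.text[start:self.pos]

    def number(self, what):
        tok = self.label()
        if not tok:
            return None
        try:
            return float(tok)
        except ValueError:
            self.error(f"invalid {what} {tok!r}")

    def subtree(self):
        node = {"children": [], "name": "", "hybrid": None,
                "length": None, "gamma": None}
        if self.peek() == "(":
            self.take("(")
            node["children"].append(self.subtree())
            while self.peek() == ",":
                self.take(",")
                node["children"].append(self.subtree())
            self.take(")")
        node["name"] = self.label()
        if self.peek() == "#":
            self.take("#")
            tag = self.label()
            if not tag:
                self.error("empty hybrid tag after '#'")
            node["hybrid"] = tag
        if self.peek() == ":":
            self.take(":")
            node["length"] = self.number("branch length")
            if self.peek() == ":":          # support slot (ignored)
                self.take(":")
                self.number("support value")
                if self.peek() == ":":
                    self.take(":")
                    node["gamma"] = self.number("inheritance probability")
        return node

    def parse(self):
        top = self.subtree()
        if self.peek() == ";":
            self.take(";")
        if self.peek():
            self.error(f"unexpected trailing text {self.peek()!r}")
        return top


def parse_network(text: str) -> PhyloNetwork:
    """Parse an extended-Newick string into a :class:`PhyloNetwork`.

    Hybrid nodes are tagged ``#H<tag>`` and must appear exactly twice; the
    annotation order is ``:length:support:gamma`` with the support slot left
    empty.  γ may be given on one occurrence only, the other being inferred
    as its complement.  Plain Newick (no ``#`` tags) yields a species tree.
    A missing branch length is taken as 0 (with a warning).
    """
    top = _Parser(text).parse()

    g = nx.MultiDiGraph()
    counter = itertools.count()
    hybrids: dict[str, int] = {}
    hybrid_occurrences: dict[str, list[dict]] = {}
    missing = [0]

    def build(tmp, parent):
        if tmp["hybrid"] is not None:
            tag = tmp["hybrid"]
            if tag not in hybrids:
                hybrids[tag] = next(counter)
                g.add_node(hybrids[tag])
                hybrid_occurrences[tag] = []
            node = hybrids[tag]
            hybrid_occurrences[tag].append(tmp)
            if tmp["children"] and any(o is not tmp and o["children"]
                                       for o in hybrid_occurrences[tag]):
                raise NetworkParseError(
                    f"hybrid node #{tag} has children at more than one occurrence")
        else:
            node = next(counter)
            g.add_node(node)
            if not tmp["children"]:
                if not tmp["name"]:
                    raise NetworkParseError("leaf without a taxon label")
                g.nodes[node]["label"] = tmp["name"]
        if parent is not None:
            length = tmp["length"]
            if length is None:
                missing[0] += 1
                length = 0.0
            g.add_edge(parent, node, length=float(length),
                       gamma=tmp["gamma"], _tmp=tmp["hybrid"])
        for child in tmp["children"]:
            build(child, node)

    build(top, None)
    root = [v for v in g if g.in_degree(v) == 0]
    if len(root) != 1:
        raise NetworkParseError("input does not describe a single rooted network")
    root = root[0]

    if missing[0]:
        warnings.warn(
            f"{missing[0]} branch length(s) missing; parsed as 0",
            stacklevel=2)

    # resolve inheritance probabilities
    for tag, occs in hybrid_occurrences.items():
        if len(occs) != 2:
            raise NetworkParseError(
                f"hybrid tag #{tag} appears {len(occs)} time(s); expected 2")
    for u, v, k, data in g.edges(keys=True, data=True):
        data.pop("_tmp", None)
    for v in g:
        if g.in_degree(v) == 2:
            ins = list(g.in_edges(v, keys=True))
            gammas = [g.edges[e]["gamma"] for e in ins]
            given = [x for x in gammas if x is not None]
            if not given:
                raise NetworkParseError(
                    f"no inheritance probability given for hybrid node {v}")
            if len(given) == 2 and abs(sum(given) - 1.0) > GAMMA_TOL:
                raise NetworkValidationError(
                    f"inheritance probabilities {given} for hybrid node {v} "
                    f"do not sum to 1")
            if len(given) == 1:
                for e, x in zip(ins, gammas):
                    if x is None:
                        g.edges[e]["gamma"] = 1.0 - given[0]
        else:
            for e in g.in_edges(v, keys=True):
                if g.edges[e]["gamma"] is None:
                    g.edges[e]["gamma"] = 1.0

    return PhyloNetwork(g, root)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_length(x: float, decimals: int | None) -> str:
    if decimals is not None:
        s = f"{x:.{decimals}f}".rstrip("0").rstrip(".")
        return s if s else "0"
    return repr(float(x))   # shortest exact round-trip


def write_network(net: PhyloNetwork, canonical: bool = False,
                  decimals: int | None = None) -> str:
    """Serialize a network to extended Newick.

    With ``canonical=True`` children are ordered by their smallest descendant
    taxon label and hybrid tags are renumbered in traversal order, giving a
    deterministic string usable as a topology identity key.
    """
    g = net.graph

    min_label: dict = {}

    def compute_min(v):
        if v in min_label:
            return min_label[v]
        if g.out_degree(v) == 0:
            min_label[v] = g.nodes[v]["label"]
        else:
            min_label[v] = min(compute_min(c) for c in g.successors(v))
        return min_label[v]

    compute_min(net.root)

    hybrid_tags: dict = {}
    tag_counter = itertools.count(1)
    written: set = set()

    def render(v, in_edge) -> str:
        is_hybrid = g.in_degree(v) == 2
        annot = ""
        if in_edge is not None:
            data = g.edges[in_edge]
            annot = ":" + _format_length(data["length"], decimals)
            if is_hybrid:
                annot += "::" + _format_length(data["gamma"], decimals)
        if is_hybrid:
            if v not in hybrid_tags:
                hybrid_tags[v] = next(tag_counter)
            tag = f"#H{hybrid_tags[v]}"
            if v in written:
                return tag + annot
            written.add(v)
            body = render_children(v)
            return body + tag + annot
        if g.out_degree(v) == 0:
            return g.nodes[v]["label"] + annot
        return render_children(v) + annot

    def render_children(v) -> str:
        edges = list(g.out_edges(v, keys=True))
        if canonical:
            edges.sort(key=lambda e: (min_label[e[1]], e[2]))
        parts = [render(e[1], e) for e in edges]
        return "(" + ",".join(parts) + ")"

    return render(net.root, None) + ";"


def canonical_form(net: PhyloNetwork, with_params: bool = False) -> str:
    """Canonical string identifying the network topology (optionally with
    rounded branch lengths and inheritance probabilities)."""
    return write_network(net, canonical=True, decimals=10 if with_params else 0) \
        if with_params else _topology_form(net)


def _topology_form(net: PhyloNetwork) -> str:
    g = net.graph
    memo: dict = {}

    def key(v):
        if v in memo:
            return memo[v]
        if g.out_degree(v) == 0:
            k = g.nodes[v]["label"]
        elif g.in_degree(v) == 2:
            # hybrid: embed full substructure at both parents
            (c,) = g.successors(v)
            k = "#(" + key(c) + ")"
        else:
            k = "(" + ",".join(sorted(key(c) for c in g.successors(v))) + ")"
        memo[v] = k
        return k

    return key(net.root)


def networks_isomorphic(a: PhyloNetwork, b: PhyloNetwork,
                        compare_params: bool = False,
                        atol: float = 1e-9) -> bool:
    """Topological (optionally parameter-preserving) isomorphism test."""
    if canonical_form(a) != canonical_form(b):
        return False
    if not compare_params:
        return True
    return write_network(a, canonical=True, decimals=9) == \
        write_network(b, canonical=True, decimals=9)


# ---------------------------------------------------------------------------
# Displayed trees and induced triples
# ---------------------------------------------------------------------------

def displayed_trees(net: PhyloNetwork):
    """All trees displayed by the network with their inheritance weights.

    Each tree keeps exactly one incoming edge per reticulation node; its
    weight is the product of γ over the kept reticulation edges.  Weights sum
    to 1 over the 2^k combinations (k = number of reticulations).
    """
    retics = sorted(net.reticulations)
    choices = [net.reticulation_edges(h) for h in retics]
    out = []
    for kept in itertools.product(*choices) if retics else [()]:
        g = net.graph.copy()
        weight = 1.0
        for h, edge in zip(retics, kept):
            weight *= net.gamma(edge)
            for e in list(g.in_edges(h, keys=True)):
                if e != edge:
                    g.remove_edge(*e)
        tree = _suppress_unary(g, net.root)
        out.append((tree, weight))
    return out


def _suppress_unary(g: nx.MultiDiGraph, root) -> PhyloNetwork:
    """Suppress in-degree-1/out-degree-1 nodes (summing lengths, multiplying
    γ) and unary root chains; returns a relaxed-validation network."""
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v == root:
                continue
            if g.out_degree(v) == 0 and "label" not in g.nodes[v]:
                # dangling internal node (e.g. a reticulation chain whose
                # child kept its other parent in a displayed tree)
                g.remove_node(v)
                changed = True
            elif g.in_degree(v) == 1 and g.out_degree(v) == 1:
                (pu, _pv, pk), = g.in_edges(v, keys=True)
                (_cu, cv, ck), = g.out_edges(v, keys=True)
                din = g.edges[pu, v, pk]
                dout = g.edges[v, cv, ck]
                g.add_edge(pu, cv,
                           length=din["length"] + dout["length"],
                           gamma=din["gamma"] * dout["gamma"])
                g.remove_node(v)
                changed = True
    while g.out_degree(root) == 1 and g.number_of_nodes() > 1:
        (child,) = g.successors(root)
        g.remove_node(root)
        root = child
    return PhyloNetwork(g, root, validate=False, strict=False)


def tree_triples(tree: PhyloNetwork) -> set:
    """The set of binary triples induced by a (binary) rooted tree."""
    g = tree.graph
    order = list(nx.topological_sort(g))
    depth = {}
    for v in order:
        preds = list(g.predecessors(v))
        depth[v] = 0 if not preds else max(depth[p] for p in preds) + 1
    leafset = {}
    mrca_depth = {}
    for v in reversed(order):
        if g.out_degree(v) == 0:
            leafset[v] = {g.nodes[v]["label"]}
        else:
            sets = [leafset[c] for c in g.successors(v)]
            # v is the MRCA of every cross pair of its children's leaf sets
            for s1, s2 in itertools.combinations(sets, 2):
                for a, b in itertools.product(s1, s2):
                    mrca_depth[frozenset((a, b))] = depth[v]
            leafset[v] = set().union(*sets)
    all_taxa = leafset[tree.root]
    triples = set()
    # cherry of {x,y,z} = the pair whose MRCA is strictly below the others'
    for subset in itertools.combinations(sorted(all_taxa), 3):
        x, y, z = subset
        dxy = mrca_depth[frozenset((x, y))]
        dxz = mrca_depth[frozenset((x, z))]
        dyz = mrca_depth[frozenset((y, z))]
        m = max(dxy, dxz, dyz)
        if dxy == m and dxz < m and dyz < m:
            triples.add(TripleTopology.binary(x, y, z))
        elif dxz == m and dxy < m and dyz < m:
            triples.add(TripleTopology.binary(x, z, y))
        elif dyz == m and dxy < m and dxz < m:
            triples.add(TripleTopology.binary(y, z, x))
        # ties cannot occur in a binary tree
    return triples


def induced_triple_set(net: PhyloNetwork) -> set:
    """The triple system of the network: the union, over displayed trees, of
    each tree's induced binary triples."""
    if len(net.taxa) < 3:
        raise ValueError("triple system requires at least 3 taxa")
    triples = set()
    for tree, _w in displayed_trees(net):
        triples |= tree_triples(tree)
    return triples


# ---------------------------------------------------------------------------
# Restriction
# ---------------------------------------------------------------------------

def restrict_network(net: PhyloNetwork, taxa) -> PhyloNetwork:
    """Restrict the network to a subset of taxa.

    Keeps the retained leaves and every node with a directed path to one of
    them (the only nodes a coalescing lineage started at a retained leaf can
    ever occupy), then suppresses unary nodes by summing branch lengths and
    multiplying inheritance probabilities along merged paths.  Triple
    topology probabilities computed on the restriction equal those computed
    on the full network.  The result may contain parallel reticulation edges
    and is therefore validated in relaxed mode.
    """
    taxa = set(taxa)
    if not taxa <= set(net.taxa):
        raise ValueError(f"taxa {sorted(taxa - set(net.taxa))} not in network")
    g = net.graph
    keep = set()
    stack = [net.leaf_for(t) for t in taxa]
    while stack:
        v = stack.pop()
        if v in keep:
            continue
        keep.add(v)
        stack.extend(g.predecessors(v))
    h = nx.MultiDiGraph()
    for v in keep:
        h.add_node(v, **g.nodes[v])
    for u, v, k, data in g.edges(keys=True, data=True):
        if u in keep and v in keep:
            h.add_edge(u, v, **data)
    return _suppress_unary(h, net.root)
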