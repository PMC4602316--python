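"""Built-in example networks.

The centrepiece is a pair of 4-taxon, 1-reticulation networks that are
*triple-equivalent*: they have different topologies but induce the same
rooted-triple system {BC|A, AB|C, BD|A, AB|D, CD|A, CD|B}, and for any
parameterization of one there exist branch lengths and inheritance
probabilities for the other giving identical triple distributions on every
3-subset.  This is the canonical demonstration that phylogenetic networks,
unlike trees, need not be identifiable from rooted-triple frequencies.

Both networks display exactly the two trees ((A,B),(C,D)) and
(A,(B,(C,D))):

* In the *clade-reticulation* network the hybrid node is the parent of the
  (C,D) clade, which attaches either at the root (major parent) or below B
  (minor parent).  Its five internal branch lengths are denoted b1..b5 and
  the inheritance probability of the inner (below-B) hybrid edge is α.
* In the *leaf-reticulation* network the hybrid node is the parent of leaf
  B, attaching either below A or on the (C,D) stem.  Only three of its
  internal branch lengths can affect triple topologies (the two hybrid
  edges each carry a single lineage and are inert); these are denoted
  l1 (the (C,D) stem), l2 (root edge towards A) and l3 (root edge towards
  (C,D)), and β is the inheritance probability of the hybrid edge from A's
  parent.

With b1=1, b2=1, b3=2, b4=1, b5=0, α=0.1 the matching leaf-reticulation
parameters are l1≈1.841435, l2≈1.951019, l3≈0.207841, β≈0.6631633.
"""

from __future__ import annotations

import networkx as nx

from .network import PhyloNetwork

__all__ = [
    "clade_reticulation_network",
    "leaf_reticulation_network",
    "CLADE_RETIC_PARAMS",
    "LEAF_RETIC_PARAMS",
    "LEAF_RETIC_EDGES",
    "unique_six_taxon_network",
]

#: The worked parameterization of the clade-reticulation network.
CLADE_RETIC_PARAMS = {"b1": 1.0, "b2": 1.0, "b3": 2.0, "b4": 1.0, "b5": 0.0,
                      "alpha": 0.1}

#: The triple-equivalent parameters of the leaf-reticulation network
#: (obtainable by :func:`triplenet.coalescent.equate_triple_systems`).
LEAF_RETIC_PARAMS = {"l1": 1.841435, "l2": 1.951019, "l3": 0.207841,
                     "beta": 0.6631633}


def clade_reticulation_network(b1=1.0, b2=1.0, b3=2.0, b4=1.0, b5=0.0,
                               alpha=0.1, pendant=1.0) -> PhyloNetwork:
    """4-taxon network whose hybrid node is the parent of the (C,D) clade.

    Structure: root -> u (length b1) and root -> h (length b3, the major
    hybrid edge); u -> A, u -> v (length b2); v -> B, v -> h (length b5, the
    minor hybrid edge, inheritance probability ``alpha``); h -> w (length
    b4); w -> C, w -> D.  Pendant branch lengths never affect triple
    probabilities and default to 1.
    """
    g = nx.MultiDiGraph()
    edges = [
        ("r", "u", b1, 1.0),
        ("u", "A", pendant, 1.0),
        ("u", "v", b2, 1.0),
        ("v", "B", pendant, 1.0),
        ("v", "h", b5, alpha),
        ("r", "h", b3, 1.0 - alpha),
        ("h", "w", b4, 1.0),
        ("w", "C", pendant, 1.0),
        ("w", "D", pendant, 1.0),
    ]
    for u, v, length, gamma in edges:
        g.add_edge(u, v, length=float(length), gamma=float(gamma))
    for leaf in "ABCD":
        g.nodes[leaf]["label"] = leaf
    return PhyloNetwork(g, "r")


def leaf_reticulation_network(l1=1.0, l2=1.0, l3=1.0, beta=0.5,
                              hybrid_edge_length=0.5,
                              pendant=1.0) -> PhyloNetwork:
    """4-taxon network whose hybrid node is the parent of leaf B.

    Structure: root -> x (length l2) and root -> y (length l3); x -> A,
    x -> h (hybrid edge, inheritance probability ``beta``); y -> h (hybrid
    edge), y -> w (length l1); h -> B; w -> C, w -> D.  The two hybrid
    edges carry a single lineage and their lengths are inert
    (``hybrid_edge_length`` is arbitrary), as are pendant lengths.
    """
    g = nx.MultiDiGraph()
    edges = [
        ("r", "x", l2, 1.0),
        ("x", "A", pendant, 1.0),
        ("x", "h", hybrid_edge_length, beta),
        ("r", "y", l3, 1.0),
        ("y", "h", hybrid_edge_length, 1.0 - beta),
        ("y", "w", l1, 1.0),
        ("h", "B", pendant, 1.0),
        ("w", "C", pendant, 1.0),
        ("w", "D", pendant, 1.0),
    ]
    for u, v, length, gamma in edges:
        g.add_edge(u, v, length=float(length), gamma=float(gamma))
    for leaf in "ABCD":
        g.nodes[leaf]["label"] = leaf
    return PhyloNetwork(g, "r")


#: Edge triples of :func:`leaf_reticulation_network` carrying the named
#: parameters (for extracting fitted values from an equate solve).
LEAF_RETIC_EDGES = {
    "l1": ("y", "w", 0),
    "l2": ("r", "x", 0),
    "l3": ("r", "y", 0),
    "beta": ("x", "h", 0),
}


def unique_six_taxon_network(gamma=0.3) -> PhyloNetwork:
    """A 6-taxon, 1-reticulation network that is uniquely encoded by its
    triple distributions (used as a recoverability fixture).

    Leaf D receives a cross-clade hybrid edge: its major parent is sister
    to E, its minor parent (inheritance probability ``gamma``) sits on the
    stem of the (A,B) clade below the C join, and O is an outgroup.
    Unlike the 4-taxon pair above — where a hybrid attaching to adjacent
    or nested edges can be slid around without changing any triple
    distribution — the witnesses on both sides of this reticulation pin it
    down: fitting any single-reticulation rival topology to this network's
    triple distributions leaves a residual bounded away from zero (see
    :func:`rival_six_taxon_network` for the closest rival).
    """
    from .network import parse_network
    text = ("(((((A:1,B:1):1,#H1:1.0::{g}):1,C:2):1,"
            "((D:1)#H1:0.8::{h},E:2):1):1,O:5);").format(g=gamma, h=1 - gamma)
    return parse_network(text)


def rival_six_taxon_network(gamma=0.3) -> PhyloNetwork:
    """The closest rival to :func:`unique_six_taxon_network`: the minor
    parent of D attaches one edge lower, as sister to C instead of sister
    to the (A,B) clade.  Its triple system cannot be made to match the
    reference's for any parameter values."""
    from .network import parse_network
    text = ("((((A:1,B:1):1,(C:1,#H1:1.0::{g}):1):1,"
            "((D:1)#H1:0.8::{h},E:2):1):1,O:5);").format(g=gamma, h=1 - gamma)
    return parse_network(text)
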