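"""Rooted gene trees with allele-to-species maps.

A gene tree is a rooted tree (not necessarily binary) whose leaves are
labelled by allele names; a map φ sends each allele to its species.  Several
alleles of one species may appear in a single tree, and a tree may sample no
allele at all from some species.  Branch lengths play no role in the
triple-frequency method and are discarded on input.

Trees are stored in a flat parent/children representation tuned for the
high-volume triple counting done by :mod:`triplenet.triples`; Newick I/O goes
through dendropy.
"""

from __future__ import annotations

import re

import dendropy

from .network import TripleTopology

__all__ = [
    "GeneTree",
    "parse_gene_tree",
    "read_gene_trees",
    "read_allele_map",
    "default_species_for_allele",
    "AlleleMapError",
]

_SUFFIX_RE = re.compile(r"^(.*?)(?:_?\d+)$")


class AlleleMapError(ValueError):
    """Raised when leaf labels cannot be mapped to species."""


def default_species_for_allele(label: str) -> str:
    """Default naming rule: strip a trailing numeric suffix (with optional
    underscore); ``a_1 -> a``, ``x12 -> x``, ``Homo -> Homo``."""
    m = _SUFFIX_RE.match(label)
    if m and m.group(1):
        return m.group(1)
    return label


class GeneTree:
    """A rooted, possibly nonbinary gene tree with multi-labelled leaves.

    Parameters
    ----------
    children:
        ``children[i]`` lists the child node ids of node ``i``; leaves have
        an empty list.  Node 0 need not be the root.
    labels:
        mapping from leaf node id to allele label (unique per tree).
    root:
        root node id.
    phi:
        mapping from allele label to species name; must cover every leaf.
    """

    __slots__ = ("children", "labels", "root", "phi", "_pair_depth",
                 "_species_alleles")

    def __init__(self, children, labels, root, phi):
        self.children = children
        self.labels = dict(labels)
        self.root = root
        values = list(self.labels.values())
        if len(set(values)) != len(values):
            dupes = sorted({v for v in values if values.count(v) > 1})
            raise AlleleMapError(f"duplicate allele labels in gene tree: {dupes}")
        missing = [a for a in values if a not in phi]
        if missing:
            raise AlleleMapError(
                f"alleles with no species mapping: {sorted(missing)}")
        self.phi = {a: phi[a] for a in values}
        self._pair_depth = None
        self._species_alleles = None

    # -- construction --------------------------------------------------------

    @classmethod
    def from_nested(cls, nested, phi) -> "GeneTree":
        """Build from nested tuples of allele labels, e.g. ``(("a1","b1"),"c1")``."""
        children: list[list[int]] = []
        labels: dict[int, str] = {}

        def build(item) -> int:
            idx = len(children)
            children.append([])
            if isinstance(item, tuple):
                for sub in item:
                    children[idx].append(build(sub))
            else:
                labels[idx] = str(item)
            return idx

        # reserve slot order: build root last-first is fine since ids are local
        root = build(nested)
        return cls(children, labels, root, phi)

    # -- basic interrogation -------------------------------------------------

    @property
    def leaves(self):
        return sorted(self.labels)

    @property
    def allele_labels(self):
        return sorted(self.labels.values())

    @property
    def species(self):
        return sorted(set(self.phi.values()))

    def alleles_of(self, species: str):
        """a(g, X): the alleles of a species labelling leaves of this tree
        (possibly empty)."""
        if self._species_alleles is None:
            table: dict = {}
            for allele, sp in self.phi.items():
                table.setdefault(sp, []).append(allele)
            self._species_alleles = {sp: sorted(v) for sp, v in table.items()}
        return self._species_alleles.get(species, [])

    # -- triple extraction ---------------------------------------------------

    def pair_mrca_depths(self) -> dict:
        """Depth (root = 0) of the MRCA of every pair of leaves, keyed by
        frozenset of allele labels.  Computed once per tree."""
        if self._pair_depth is not None:
            return self._pair_depth
        depth_of: dict = {}
        sets: dict = {}
        pair: dict = {}
        order: list[tuple[int, int]] = []
        stack = [(self.root, 0)]
        while stack:
            v, d = stack.pop()
            order.append((v, d))
            for c in self.children[v]:
                stack.append((c, d + 1))
        for v, d in reversed(order):
            kids = self.children[v]
            if not kids:
                sets[v] = [self.labels[v]]
                continue
            merged: list[str] = []
            for c in kids:
                for a in merged:
                    for b in sets[c]:
                        pair[frozenset((a, b))] = d
                merged.extend(sets[c])
            sets[v] = merged
        self._pair_depth = pair
        return pair

    def induced_triple(self, alleles) -> TripleTopology:
        """The rooted topology induced by three leaves, with leaf labels
        replaced by species names (φ(g|{x,y,z})).

        Binary if one pair's MRCA is strictly deeper than the other two
        (which then coincide), the star otherwise; pruning other leaves
        first gives the same answer.
        """
        x, y, z = alleles
        for a in (x, y, z):
            if a not in self.phi:
                raise KeyError(f"allele {a!r} not in gene tree")
        depths = self.pair_mrca_depths()
        dxy = depths[frozenset((x, y))]
        dxz = depths[frozenset((x, z))]
        dyz = depths[frozenset((y, z))]
        sx, sy, sz = self.phi[x], self.phi[y], self.phi[z]
        m = max(dxy, dxz, dyz)
        if dxy == m and dxz < m and dyz < m:
            return TripleTopology.binary(sx, sy, sz)
        if dxz == m and dxy < m and dyz < m:
            return TripleTopology.binary(sx, sz, sy)
        if dyz == m and dxy < m and dxz < m:
            return TripleTopology.binary(sy, sz, sx)
        return TripleTopology.star(sx, sy, sz)

    # -- rooting convenience -------------------------------------------------

    def rerooted_at_outgroup(self, outgroup_allele: str) -> "GeneTree":
        """Re-root on the edge above an outgroup leaf (convenience for trees
        rooted arbitrarily on input)."""
        target = next((v for v, lab in self.labels.items()
                       if lab == outgroup_allele), None)
        if target is None:
            raise KeyError(outgroup_allele)
        adj: dict[int, list[int]] = {i: list(cs) for i, cs in
                                     enumerate(self.children)}
        parent: dict[int, int] = {}
        for v, cs in adj.items():
            for c in cs:
                parent[c] = v
        undirected: dict[int, set[int]] = {i: set() for i in adj}
        for c, p in parent.items():
            undirected[c].add(p)
            undirected[p].add(c)
        # drop an old root of degree 2 (it is a rooting artefact)
        old_root = self.root
        if len(undirected[old_root]) == 2 and old_root != target:
            a, b = undirected[old_root]
            undirected[a].discard(old_root)
            undirected[b].discard(old_root)
            undirected[a].add(b)
            undirected[b].add(a)
            del undirected[old_root]
        new_root = max(undirected) + 1
        p = next(iter(undirected[target]))
        undirected[target].discard(p)
        undirected[p].discard(target)
        undirected[new_root] = {target, p}
        children: list[list[int]] = [[] for _ in range(new_root + 1)]
        labels = {}
        seen = {new_root}
        stack = [new_root]
        while stack:
            v = stack.pop()
            for n in undirected[v]:
                if n not in seen:
                    seen.add(n)
                    children[v].append(n)
                    stack.append(n)
            if not children[v] and v in self.labels:
                labels[v] = self.labels[v]
        return GeneTree(children, labels, new_root, self.phi)

    # -- I/O -----------------------------------------------------------------

    def newick(self) -> str:
        def render(v) -> str:
            if not self.children[v]:
                return self.labels[v]
            return "(" + ",".join(render(c) for c in self.children[v]) + ")"
        return render(self.root) + ";"

    def __repr__(self) -> str:
        return f"<GeneTree {len(self.labels)} alleles, {len(self.species)} species>"


def _from_dendropy(tree: dendropy.Tree, allele_map) -> GeneTree:
    children: list[list[int]] = []
    labels: dict[int, str] = {}
    ids: dict = {}

    for node in tree.preorder_node_iter():
        idx = len(children)
        ids[node] = idx
        children.append([])
        if node.parent_node is not None:
            children[ids[node.parent_node]].append(idx)
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                raise AlleleMapError("leaf without a label in gene tree")
            labels[idx] = label

    if allele_map is None:
        phi = {a: default_species_for_allele(a) for a in labels.values()}
    elif callable(allele_map):
        phi = {a: allele_map(a) for a in labels.values()}
    else:
        missing = sorted(a for a in labels.values() if a not in allele_map)
        if missing:
            raise AlleleMapError(
                f"alleles with no species mapping: {missing}")
        phi = dict(allele_map)
    return GeneTree(children, labels, 0, phi)


def parse_gene_tree(text: str, allele_map=None) -> GeneTree:
    """Parse a rooted Newick gene tree.

    ``allele_map`` may be a dict (allele -> species), a callable, or None to
    use the default trailing-numeric-suffix naming rule.  Branch lengths and
    internal node labels are parsed and discarded (the method uses topologies
    only).
    """
    tree = dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True,
                             suppress_leaf_node_taxa=True)
    return _from_dendropy(tree, allele_map)


def read_gene_trees(path, allele_map=None) -> list:
    """Read a multi-tree Newick file (one tree per line or a tree list)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True,
                                  suppress_leaf_node_taxa=True)
    return [_from_dendropy(t, allele_map) for t in trees]


def read_allele_map(path) -> dict:
    """Read a two-column tab-separated allele→species map."""
    phi = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlleleMapError(
                    f"{path}:{line_no}: expected two tab-separated columns")
            phi[parts[0]] = parts[1]
    return phi
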