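"""Aggregated rooted-triple weights ρ(t, G) from a collection of gene trees.

For a binary triple t = XY|Z and a gene tree g, ρ(t, g) is the number of
allele choices (one allele per species) whose induced triple equals t, with a
nonbinary (star) induced triple contributing 1/3 to each of the three binary
resolutions, normalized by the total number of allele choices
|a(g,X)|·|a(g,Y)|·|a(g,Z)|.  If a species has no allele in g the value is 0.
Summing over a gene-tree collection G gives ρ(t, G); every gene tree covering
a 3-subset of species contributes exactly 1 in total across the subset's
three binary triples, so the table's per-subset totals count covering trees.

The table is computed once per data set and reused for every subsequent
pseudo-likelihood evaluation.
"""

from __future__ import annotations

import itertools

import numpy as np

from .network import TripleTopology, binary_triples_of

__all__ = ["TripleTable", "rho_single", "build_triple_table"]


def _subset_weights(g, species_triplet):
    """Contribution of one gene tree to the three binary-triple weights of a
    sorted species triplet, by exhaustive enumeration of allele choices.
    Returns None if some species has no allele in g."""
    sx, sy, sz = species_triplet
    ax, ay, az = g.alleles_of(sx), g.alleles_of(sy), g.alleles_of(sz)
    denom = len(ax) * len(ay) * len(az)
    if denom == 0:
        return None
    depths = g.pair_mrca_depths()
    w = np.zeros(3)
    third = 1.0 / 3.0
    for x in ax:
        for y in ay:
            dxy = depths[frozenset((x, y))]
            for z in az:
                dxz = depths[frozenset((x, z))]
                dyz = depths[frozenset((y, z))]
                if dxy > dxz and dxy > dyz:
                    w[0] += 1.0
                elif dxz > dxy and dxz > dyz:
                    w[1] += 1.0
                elif dyz > dxy and dyz > dxz:
                    w[2] += 1.0
                else:  # unresolved: 1/3 to each binary resolution
                    w += third
    return w / denom


def rho_single(t: TripleTopology, g) -> float:
    """ρ(t, g) for one binary triple and one gene tree."""
    if not t.is_binary:
        raise ValueError("only binary triples are scored; got the star topology")
    triplet = tuple(sorted(t.taxa))
    w = _subset_weights(g, triplet)
    if w is None:
        return 0.0
    for trip, val in zip(binary_triples_of(triplet), w):
        if trip == t:
            return float(val)
    raise AssertionError("unreachable")


class TripleTable:
    """ρ(t, G) for every 3-subset of a taxon list.

    ``weights[i]`` holds (ρ(XY|Z,G), ρ(XZ|Y,G), ρ(YZ|X,G)) for the i-th
    3-subset of the sorted taxon list, in lexicographic subset order; the
    per-subset effective count (the number of gene trees with at least one
    allele of each of the three species) is the row sum.
    """

    def __init__(self, taxa, weights=None):
        self.taxa = sorted(taxa)
        if len(self.taxa) < 3:
            raise ValueError("a triple table requires at least 3 taxa")
        self.subsets = [tuple(s) for s in itertools.combinations(self.taxa, 3)]
        self._index = {s: i for i, s in enumerate(self.subsets)}
        if weights is None:
            weights = np.zeros((len(self.subsets), 3))
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.shape != (len(self.subsets), 3):
            raise ValueError("weights shape does not match the taxon list")

    # -- access --------------------------------------------------------------

    def subset_weights(self, subset) -> np.ndarray:
        """The three weights of a 3-subset, canonical (XY|Z, XZ|Y, YZ|X) order."""
        return self.weights[self._index[tuple(sorted(subset))]]

    def weight(self, t: TripleTopology) -> float:
        row = self.subset_weights(t.taxa)
        for trip, val in zip(binary_triples_of(t.taxa), row):
            if trip == t:
                return float(val)
        raise KeyError(t)

    @property
    def effective_counts(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def add_gene_tree(self, g) -> None:
        present = [sp for sp in self.taxa if g.alleles_of(sp)]
        for triplet in itertools.combinations(present, 3):
            w = _subset_weights(g, triplet)
            if w is not None:
                self.weights[self._index[triplet]] += w

    def add_gene_trees(self, gene_trees, batch: int = 20000) -> None:
        """Add many gene trees, using a vectorized path for trees that
        sample at most one allele per species (the common case, where every
        triple weight is 0, 1 or 1/3)."""
        single, general = [], []
        for g in gene_trees:
            (single if len(g.labels) == len(set(g.phi.values())) else
             general).append(g)
        for g in general:
            self.add_gene_tree(g)
        sp_ix = {s: i for i, s in enumerate(self.taxa)}
        n = len(self.taxa)
        subset_ix = np.array([[sp_ix[x], sp_ix[y], sp_ix[z]]
                              for (x, y, z) in self.subsets])
        for lo in range(0, len(single), batch):
            chunk = single[lo:lo + batch]
            b = len(chunk)
            D = np.full((b, n, n), -1, dtype=np.int32)
            present = np.zeros((b, n), dtype=bool)
            for ti, g in enumerate(chunk):
                _fill_depths(g, sp_ix, D[ti], present[ti])
            i, j, k = subset_ix[:, 0], subset_ix[:, 1], subset_ix[:, 2]
            a = D[:, i, j]           # (b, n_subsets)
            c2 = D[:, i, k]
            c3 = D[:, j, k]
            valid = present[:, i] & present[:, j] & present[:, k]
            star = valid & (a == c2) & (a == c3)
            self.weights[:, 0] += (valid & (a > c2) & (a > c3)).sum(axis=0)
            self.weights[:, 1] += (valid & (c2 > a) & (c2 > c3)).sum(axis=0)
            self.weights[:, 2] += (valid & (c3 > a) & (c3 > c2)).sum(axis=0)
            self.weights += (star.sum(axis=0) / 3.0)[:, None]

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("X\tY\tZ\trho_XY|Z\trho_XZ|Y\trho_YZ|X\n")
            for (x, y, z), row in zip(self.subsets, self.weights):
                fh.write(f"{x}\t{y}\t{z}\t{row[0]:.12g}\t{row[1]:.12g}\t{row[2]:.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "TripleTable":
        subsets = []
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("X\t"):
                raise ValueError(f"{path}: not a triple-table TSV")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                subsets.append(tuple(parts[:3]))
                rows.append([float(v) for v in parts[3:6]])
        taxa = sorted({t for s in subsets for t in s})
        table = cls(taxa)
        for s, row in zip(subsets, rows):
            table.weights[table._index[tuple(sorted(s))]] = row
        return table

    def __repr__(self) -> str:
        return (f"<TripleTable {len(self.taxa)} taxa, "
                f"{len(self.subsets)} subsets, "
                f"total weight {self.weights.sum():.3f}>")


def _fill_depths(g, sp_ix, D, present):
    """MRCA depths between species for a single-allele gene tree, written
    into a preallocated (n, n) matrix (depth of root = 0, -1 = undefined)."""
    order = []
    stack = [(g.root, 0)]
    while stack:
        v, d = stack.pop()
        order.append((v, d))
        for c in g.children[v]:
            stack.append((c, d + 1))
    sets: dict = {}
    for v, d in reversed(order):
        kids = g.children[v]
        if not kids:
            si = sp_ix.get(g.phi[g.labels[v]])
            if si is None:
                sets[v] = []
            else:
                present[si] = True
                sets[v] = [si]
            continue
        merged: list = []
        for c in kids:
            sub = sets.pop(c)
            for a in merged:
                for b in sub:
                    D[a, b] = d
                    D[b, a] = d
            merged.extend(sub)
        sets[v] = merged


def build_triple_table(gene_trees, taxa=None) -> TripleTable:
    """Aggregate ρ(t, G) over a gene-tree collection.

    ``taxa`` defaults to the union of species over all trees; trees may cover
    arbitrary subsets of it.  The computation is order-invariant in G.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("empty gene-tree collection")
    if taxa is None:
        taxa = sorted(set().union(*(set(g.species) for g in gene_trees)))
    table = TripleTable(taxa)
    table.add_gene_trees(gene_trees)
    return table
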