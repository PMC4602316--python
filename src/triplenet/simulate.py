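"""Gene-tree simulation under the network multispecies coalescent, and
random network generation.

For every locus, the configured number of allele lineages starts at each
leaf.  Moving rootward in topological order, lineage clusters within an edge
coalesce at rate 1 per pair over the edge's branch length (coalescent
units); at a reticulation node each cluster independently follows a parent
edge with probability equal to that edge's inheritance probability; any
clusters surviving to the root coalesce above it until one lineage remains.
The emitted gene trees are rooted, binary, topology-only, with allele labels
``<species>_<index>`` and the corresponding allele→species map.

This simulator doubles as the independent Monte-Carlo oracle for the exact
triple-probability computation: empirical triple frequencies converge to the
coalescent probabilities at the usual O(n_loci^{-1/2}) rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .gene_tree import GeneTree
from .network import PhyloNetwork

__all__ = ["SimConfig", "simulate_gene_trees", "random_network"]


@dataclass
class SimConfig:
    """Settings for a gene-tree simulation.

    ``alleles_per_species`` may be an int (same for all species) or a
    mapping species→count; zero is allowed, but at least three species must
    have at least one allele for the data to carry triple information.
    """

    network: PhyloNetwork
    n_loci: int = 100
    alleles_per_species: object = 1
    seed: int | None = None

    def allele_counts(self) -> dict:
        taxa = self.network.taxa
        if isinstance(self.alleles_per_species, dict):
            counts = {t: int(self.alleles_per_species.get(t, 0)) for t in taxa}
        else:
            counts = {t: int(self.alleles_per_species) for t in taxa}
        if any(c < 0 for c in counts.values()):
            raise ValueError("allele counts must be nonnegative")
        if sum(1 for c in counts.values() if c > 0) < 3:
            raise ValueError("at least three species need one or more alleles")
        return counts

    def __post_init__(self):
        if self.n_loci < 1:
            raise ValueError("n_loci must be at least 1")


def _prepare(net: PhyloNetwork):
    """Flatten the network into arrays for the per-locus loop."""
    g = net.graph
    order = [v for v in reversed(list(nx.topological_sort(g)))]
    node_ix = {v: i for i, v in enumerate(order)}
    in_edges = []
    labels = {}
    for v in order:
        ins = [(node_ix[u], g.edges[u, v, k]["length"], g.edges[u, v, k]["gamma"])
               for u, _w, k in g.in_edges(v, keys=True)]
        in_edges.append(ins)
        if g.out_degree(v) == 0:
            labels[node_ix[v]] = g.nodes[v]["label"]
    return order, in_edges, labels, node_ix[net.root]


def _coalesce_within(clusters, length, rng):
    """Sequential pairwise coalescence among clusters over a branch."""
    k = len(clusters)
    t = 0.0
    while k >= 2:
        rate = k * (k - 1) / 2.0
        t += rng.exponential(1.0 / rate)
        if t >= length:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = clusters[i], clusters[j]
        merged = (a, b)
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
        k -= 1
    return clusters


def simulate_gene_trees(config: SimConfig) -> list:
    """Simulate rooted gene trees within the branches of a network.

    Seeded determinism: identical configurations (including the seed)
    produce identical output.
    """
    net = config.network
    counts = config.allele_counts()
    rng = np.random.default_rng(config.seed)
    order, in_edges, labels, root_ix = _prepare(net)
    phi = {f"{sp}_{i}": sp for sp, c in counts.items() for i in range(c)}

    out = []
    for _ in range(config.n_loci):
        at: list = [[] for _ in order]
        for leaf_ix, sp in labels.items():
            at[leaf_ix] = [f"{sp}_{i}" for i in range(counts[sp])]
        for ix in range(len(order)):
            clusters = at[ix]
            ins = in_edges[ix]
            if not ins:                      # root: coalesce to completion
                while len(clusters) >= 2:
                    i, j = rng.choice(len(clusters), size=2, replace=False)
                    merged = (clusters[i], clusters[j])
                    clusters = [c for t, c in enumerate(clusters)
                                if t not in (i, j)]
                    clusters.append(merged)
                at[ix] = clusters
                break
            if len(ins) == 1:
                parent, length, _gam = ins[0]
                survivors = _coalesce_within(clusters, length, rng) \
                    if len(clusters) >= 2 else clusters
                at[parent].extend(survivors)
            else:
                (p1, l1, g1), (p2, l2, _g2) = ins
                side1, side2 = [], []
                if clusters:
                    draws = rng.random(len(clusters))
                    for c, d in zip(clusters, draws):
                        (side1 if d < g1 else side2).append(c)
                for parent, length, side in ((p1, l1, side1), (p2, l2, side2)):
                    survivors = _coalesce_within(side, length, rng) \
                        if len(side) >= 2 else side
                    at[parent].extend(survivors)
        (nested,) = at[root_ix]
        out.append(GeneTree.from_nested(nested, phi))
    return out


def random_network(n_taxa: int, n_reticulations: int, rng=None,
                   taxa=None, max_tries: int = 1000) -> PhyloNetwork:
    """Generate a random fixture network.

    The backbone is a random birth-process (Yule-shape) tree with
    exponential(1) branch lengths.  Each reticulation is added by choosing
    two edges uniformly at random and connecting their midpoints from the
    higher one (closer to the root, measured as longest path time from the
    root) to the lower one, which guarantees acyclicity; the inheritance
    probability at the new reticulation node is uniform on (0, 1).
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if taxa is None:
        taxa = [f"T{i+1}" for i in range(n_taxa)]
    if len(taxa) != n_taxa:
        raise ValueError("taxa list length must equal n_taxa")

    g = nx.MultiDiGraph()
    counter = [0]

    def new_node():
        counter[0] += 1
        return counter[0]

    root = new_node()
    tips = []
    for _ in range(2):
        v = new_node()
        g.add_edge(root, v, length=float(rng.exponential(1.0)), gamma=1.0)
        tips.append(v)
    while len(tips) < n_taxa:
        tip = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            v = new_node()
            g.add_edge(tip, v, length=float(rng.exponential(1.0)), gamma=1.0)
            tips.append(v)
    labels = list(taxa)
    for tip, label in zip(tips, labels):
        g.nodes[tip]["label"] = label

    def depths():
        d = {}
        for v in nx.topological_sort(g):
            preds = list(g.in_edges(v, keys=True))
            d[v] = 0.0 if not preds else max(
                d[u] + g.edges[u, v, k]["length"] for u, _w, k in preds)
        return d

    for _ in range(n_reticulations):
        for _try in range(max_tries):
            d = depths()
            edges = list(g.edges(keys=True))
            i, j = rng.choice(len(edges), size=2, replace=False)
            e1, e2 = edges[int(i)], edges[int(j)]
            mids = [0.5 * (d[u] + d[v]) for (u, v, k) in (e1, e2)]
            hi, lo = (e1, e2) if mids[0] < mids[1] else (e2, e1)
            d_hi, d_lo = min(mids), max(mids)
            if d_lo - d_hi <= 1e-9:
                continue
            gam = float(rng.uniform(0.0, 1.0))
            trial = g.copy()
            m1, m2 = new_node(), new_node()
            for (u, v, k), m in ((hi, m1), (lo, m2)):
                data = trial.edges[u, v, k]
                trial.remove_edge(u, v, k)
                trial.add_edge(u, m, length=data["length"] / 2.0, gamma=1.0)
                trial.add_edge(m, v, length=data["length"] / 2.0,
                               gamma=data["gamma"])
            trial.add_edge(m1, m2, length=d_lo - d_hi, gamma=gam)
            # the other edge into m2 carries the complement
            for u, v, k in trial.in_edges(m2, keys=True):
                if u != m1:
                    trial.edges[u, v, k]["gamma"] = 1.0 - gam
            if not nx.is_directed_acyclic_graph(trial):
                continue
            g = trial
            break
        else:
            raise RuntimeError(
                "could not place a reticulation after bounded retries")

    return PhyloNetwork(g, root)
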