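# triplenet

Maximum pseudo-likelihood inference of **phylogenetic networks** — topology,
branch lengths in coalescent units, and inheritance probabilities γ at
reticulation nodes — from collections of **rooted gene-tree topologies**,
modelling hybridization and incomplete lineage sorting (ILS) jointly under
the network multispecies coalescent.

It is aimed at phylogenomics practitioners who have rooted gene trees for
hundreds to thousands of loci and suspect that both ILS and gene flow shaped
their history: full network likelihoods are intractable beyond a handful of
taxa, while triple frequencies can be scored in milliseconds at any
realistic data size.

## The model

A binary phylogenetic network Ψ is a rooted DAG: leaves are labelled by
species, tree nodes have one parent and two children, and reticulation
nodes have two parents and one child.  Every edge *e* carries a branch
length λ(*e*) in coalescent units; the two edges into a reticulation node
carry inheritance probabilities γ summing to 1.

For a gene tree *g* and a binary rooted triple *t = XY|Z*, the weight

ρ(t, g) = Σ<sub>x∈a(g,X), y∈a(g,Y), z∈a(g,Z)</sub>
[ 𝕀(φ(g|{x,y,z}) = XY|Z) + ⅓·𝕀(φ(g|{x,y,z}) = XYZ) ]
/ (|a(g,X)|·|a(g,Y)|·|a(g,Z)|)

averages the induced triple over all allele choices (a(g,X) is the set of
alleles of species X in g; φ maps alleles to species; an unresolved triple
contributes ⅓ to each binary resolution; ρ = 0 if a species is unsampled).
Summed over the collection G, the weights ρ(t, G) of the three binary
triples of each 3-subset are treated as a multinomial sample from the exact
coalescent triple probabilities P(t | Ψ, γ), giving the log pseudo-likelihood

log L(Ψ, γ | G) = Σ<sub>{X,Y,Z}⊆𝒳</sub> Σ<sub>i=1..3</sub>
ρ(t<sub>i</sub>, G) · ln P(t<sub>i</sub> | Ψ, γ)

(the multinomial coefficient is constant in Ψ and γ and is dropped).
P(t | Ψ, γ) is computed exactly by a small dynamic program on the network
restricted to the three species: lineages coalesce at rate 1 per pair
within each edge and route independently through reticulations with
probability γ.  A simulated-annealing search over network space — six
moves: perturb lengths, perturb γ, add / delete a reticulation edge,
relocate a hybrid-edge head, relocate an edge tail — maximizes the score,
archives the top-k topologies, and re-optimizes their parameters at the end.

A caveat inherent to the method: unlike trees, networks are **not always
uniquely encoded** by their triple system.  `triplenet` ships a 4-taxon
example pair (`triplenet.examples`) demonstrating the failure, a solver
(`equate_triple_systems`) that decides whether one topology can imitate
another, and a top-k archive so that equivalent optima are reported rather
than silently collapsed.

## Worked example

```python
from triplenet import (SimConfig, simulate_gene_trees, build_triple_table,
                       log_pseudo_likelihood, parse_network)

net = parse_network(
    "(((((A:1,B:1):1,#H1:1.0::0.3):1,C:2):1,((D:1)#H1:0.8::0.7,E:2):1):1,O:5);")
genes = simulate_gene_trees(SimConfig(net, n_loci=2000, seed=77))
table = build_triple_table(genes, taxa=net.taxa)
print(round(table.subset_weights(("A", "B", "C"))[0], 2))
print(round(log_pseudo_likelihood(net, table).log_value, 2))
```

prints

```
1812.0
-24230.15
```

— 1812 of the 2000 loci induce the triple AB|C, and the generating
network scores −24230.15 log pseudo-likelihood units on its own data
(comparable only within this data set, since the multinomial constant is
dropped).  The same pipeline is available from the shell:

```sh
triplenet simulate --network net.enwk --loci 2000 --seed 77 --out genes.nwk
triplenet triples  --gene-trees genes.nwk --out table.tsv
triplenet score    --network net.enwk --table table.tsv
triplenet infer    --gene-trees genes.nwk --max-ret 1 --seed 1 --out ranked.enwk
```

Networks are written in extended Newick: a hybrid node is tagged `#H<n>`
and appears twice, with annotations `:length:support:gamma` (the support
slot stays empty), e.g. `(B:1)#H1:1::0.7`.

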