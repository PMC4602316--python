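# Methods

## Model

`triplenet` scores a binary rooted phylogenetic network Ψ with branch
lengths λ (coalescent units) and inheritance probabilities γ against a set
G of rooted gene-tree topologies through the frequencies of rooted triples.
For every 3-subset of species, the aggregated weights ρ(t, G) of the three
binary triples are treated as an independent multinomial draw from the
exact coalescent triple probabilities P(t | Ψ, γ); the product of these
multinomials over all 3-subsets is the pseudo-likelihood.  The multinomial
coefficient is dropped throughout: it is constant in (Ψ, γ) for a fixed
data set, and with multiple alleles the ρ weights are fractional, so the
coefficient is not even well defined.  Scores are therefore comparable
only within one data set.

The pseudo-likelihood deliberately ignores the dependence between
overlapping triples.  It is a composite-likelihood estimator: consistent
where the triple system identifies the network, much cheaper than the full
gene-tree likelihood (cost is driven by C(n,3), nearly independent of the
number of reticulations — see the complexity test), but its curvature does
not estimate standard errors.

## Exact triple probabilities

P(t | Ψ, γ) is computed by dynamic programming on the network restricted
to the three species.  The restriction keeps exactly the nodes with a
directed path to one of the three leaves — the only nodes a rootward-moving
sampled lineage can ever occupy — and suppresses in-degree-1/out-degree-1
nodes, summing lengths and multiplying γ along merged paths; unary root
chains are dropped (time above the last coalescence opportunity is
absorbed into the infinite time above the root).  All of these steps are
exact, so triple probabilities on the restriction equal those on the full
network (tested).  A restriction can legitimately carry *parallel*
reticulation edges (two parents merged onto the same tail); these are kept
and handled by the dynamic program, which is why networks are stored as
multigraphs even though user-facing networks forbid parallel edges.

The program processes restricted nodes children-first, tracking a
distribution over configurations of lineage clusters.  Within an edge of
length τ, two clusters remain separate with probability e^(−τ); three
clusters (necessarily singletons) all remain with probability e^(−3τ),
exactly one specific pair merges with probability (e^(−τ) − e^(−3τ))/2,
and complete coalescence takes the remainder with the first merging pair
uniform.  At a reticulation node each cluster independently follows a
parent edge with probability γ; a coalesced cluster routes as one unit
(the standard network-MSC independence assumption; the same convention is
built into the simulator, and the 4-taxon worked example below provides an
external check).  Above the root the first merging pair is uniform among
those present.  The final triple topology is determined by whichever pair
coalesced first.  Branch lengths above 30 coalescent units are treated as
30 (e^(−30) ≈ 9·10⁻¹⁴ is below double-precision noise for these sums).

Restrictions are precomputed once per topology (`TripleEngine`) with each
restricted edge remembering which original edges sum into its length and γ;
branch-length and γ changes then re-evaluate without touching the graph.

## The 4-taxon identifiability pair

Trees are uniquely encoded by their triple systems; networks are not.
`triplenet.examples` ships two 4-taxon, 1-reticulation topologies that both
display the trees ((A,B),(C,D)) and (A,(B,(C,D))) and hence share the
triple system {BC|A, AB|C, BD|A, AB|D, CD|A, CD|B}:

* **clade-reticulation**: the hybrid node is the parent of the (C,D)
  clade; five internal lengths b1…b5 matter (b1 root→(A,B)-side, b2 the
  inner edge, b3 the root-side hybrid edge, b4 the (C,D) stem, b5 the
  below-B hybrid edge) plus α = γ(below-B edge).
* **leaf-reticulation**: the hybrid node is the parent of leaf B; only
  three lengths matter (l1 the (C,D) stem, l2 root→A-parent, l3
  root→(C,D)-parent) plus β = γ(hybrid edge from A's parent) — the two
  hybrid edges carry a single lineage and are inert.

With b = (1, 1, 2, 1, 0) and α = 0.1, solving for the leaf-reticulation
parameters that equate all four triple distributions gives
l1 ≈ 1.841435, l2 ≈ 1.951019, l3 ≈ 0.207841, β ≈ 0.6631633; l1 also has
the closed form b2 + b4 + b5 − ln(α·e^(b2) + (1−α)·e^(b5)).  The solver
(`equate_triple_systems`) minimizes the summed squared differences of
triple probabilities over the target's internal lengths (log scale) and γ
(logit scale) with multi-start Levenberg–Marquardt; a residual at numerical
zero certifies triple-equivalence, a residual bounded away from zero
certifies its absence.  `scripts/acceptance.py` reruns exactly this solve.

## Triple counting

ρ(t, g) enumerates allele choices exhaustively (one allele per species),
which is exact and cheap at realistic sampling depths (a few alleles per
species); induced triples come from pairwise MRCA depths computed in one
post-order pass per gene tree.  Every gene tree containing at least one
allele of each of three species contributes exactly 1.0 in total to that
subset (unresolved triples split ⅓/⅓/⅓), so per-subset table totals count
covering gene trees — a property-tested invariant.  For the dominant
single-allele-per-species case the table is filled by a vectorized batch
path (per-tree MRCA-depth matrices, numpy comparisons across loci);
both paths are tested for equality.

## Parameter optimization

`optimize_parameters` maximizes the score over internal branch lengths
(log scale, bounds [10⁻⁶, 30]) and inheritance probabilities (logit scale,
bounds [10⁻⁶, 1−10⁻⁶]) with bounded L-BFGS-B, 5 starts by default
(current values plus random restarts), convergence 10⁻⁸ in relative score,
2000 evaluations per restart.  Pendant edges are excluded — they cannot
affect triple topologies (tested), and leaving them in creates flat
directions.  γ parameters whose ±1-logit perturbation leaves the optimum
unchanged are reported as unidentifiable (e.g. a reticulation whose hybrid
descendants never co-occur with data).

## Search

Simulated annealing over network space with six moves drawn by preset
weights (defaults 0.15, 0.15, 0.10, 0.10, 0.25, 0.25): multiplicative
lognormal length steps (σ = 0.3), ±0.1 uniform γ steps, add-reticulation
(two random edges subdivided, connected tail→head, rejected on cycles or
at the reticulation cap), delete-reticulation (with unary-node cleanup),
relocate a hybrid-edge head, relocate an edge tail (rooted SPR).  Two
kernel choices matter in practice and are this package's own design:
relocations re-attach to an edge *adjacent* to the detachment site with
probability ½ (local refinement of an attachment point is the common
escape from near-optimal basins), and a relocated hybrid edge's γ is
resampled rather than inherited (its old value was adapted to a different
role and systematically mis-scores the new placement).  Invalid proposals
are resampled.

Candidates improving the score are always accepted; worse ones with
probability exp(Δ/T_k) under T_k = T0/(1 + c·k).  The default schedule
(T0 = 1, c set so T hits 0.01 at 80% of the iteration budget) is a
conservative, nearly greedy hill-climber; because pseudo-likelihood
differences between neighbouring topologies grow linearly with the number
of loci, searches on large data sets should raise T0 to the typical
score gap (tens) and slow the cooling — the recovery test uses T0 = 25,
c = 3.5·10⁻⁴.  Every evaluated candidate (accepted or not) is offered to a
top-k archive of distinct topologies keyed by canonical form; the search
stops at the iteration cap or after a stagnation window spent only on
archived topologies.  Because parameters are sampled rather than optimized
during the search, the archived networks' branch lengths and γ are
re-optimized at the end and the archive re-ranked — this post-optimization
step regularly promotes the true topology past rivals whose sampled
parameters happened to fit better.  Multiple independent chains
(`n_runs`) merge their archives before post-optimization.  With a fixed
seed the entire procedure, traces included, is bit-reproducible.

## Simulator

The built-in simulator is a native implementation of the network
multispecies coalescent: per locus, the configured alleles start at the
leaves, clusters coalesce sequentially (rate 1 per pair) within each edge,
route independently at reticulations, and finish above the root.  Time is
measured directly in coalescent units, so no 2N/4N rescaling is exposed
(external coalescent simulators often use 4N-scaled time; comparisons must
convert).  Gene trees are emitted topology-only, as the method consumes
topologies.  Random fixture networks grow a Yule-shape tree with
exponential(1) branch lengths, then add reticulations by connecting the
midpoints of two random edges from the higher (nearer the root, by longest
path) to the lower, with uniform γ — verified acyclic and binary by
property test.

What the simulator deliberately does *not* emulate: sequence evolution and
gene-tree estimation error (real pipelines estimate gene trees from finite
alignments; their errors inflate triple-frequency noise beyond the
multinomial floor), recombination within loci, per-locus variation in γ,
and gene-tree rooting error.  Passing tests therefore demonstrate
correctness of the coalescent machinery and the inference under the model's
own assumptions, not robustness to estimation error in real data.

## Test-scale choices

The test suite runs at desk scale: Monte-Carlo checks use 10⁵ loci per
network (4-standard-error agreement between simulated frequencies and the
exact probabilities over a 20-network suite of 4–8 taxa, 0–3
reticulations); convergence is checked at 100/1000/10000 loci; the
recovery study uses a 6-taxon, 1-reticulation fixture, 2000 true gene
trees and five seeded two-stage searches (a tree-restricted stage, then
three annealing chains of 4500 iterations with merged archives).  The
recovery fixture was chosen to be uniquely encoded by its triple
distributions — a cross-clade reticulation into leaf D with witnesses on
both sides and an outgroup — and its uniqueness was verified by driving
the equating solver from the truth to rival topologies (residuals stay
above 10⁻³, against ~10⁻³² for self-fits).  Earlier candidate fixtures
with a hybrid attached between nested edges turned out to be
triple-equivalent to rivals, a direct generalization of the 4-taxon
example, and were rejected.

## Known limitations

* Rooted, binary networks only; gene trees must be rooted on input (a
  reroot-at-outgroup helper is provided, but rooting quality is the
  user's responsibility).
* Non-identifiability is intrinsic: when the triple system does not encode
  the network uniquely, the search returns an equivalence class member;
  inspect the whole ranked archive, not just the top entry.
* The annealing defaults are conservative; data-set-scale-aware
  temperature settings materially affect search success.
* Model selection over the number of reticulations is left to the user
  (run with increasing caps and compare optimized scores; the score does
  not penalize complexity on its own).
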