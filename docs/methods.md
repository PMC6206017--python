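# Methods

## Substrate–product network model

A taxon's metabolism is read as a list of reactions, each with a set of
substrates, a set of products and a direction. The network has one node
per distinct metabolite and an unweighted arc s → p for every
(substrate, product) pair of every left-to-right reaction; a
right-to-left reaction contributes p → s, and a reversible reaction
contributes both orientations as two separate arcs. Repeated
metabolites and repeated arcs collapse (node and edge sets are sets).
Self-pairs (a metabolite on both sides of one reaction) produce no arc
by default — loops distort degree and clustering and are conventionally
dropped in substrate–product models — but the metabolite remains a
listed (possibly isolated) node, so the metabolite count N always
equals the number of distinct metabolites in the reaction file. A
`keep_self_loops` flag retains loops for sensitivity analysis. Node
order is lexicographic, making the adjacency layout deterministic.

Before network construction, reaction files pass four normalization
steps: transcoding to UTF-8 (invalid bytes replaced), removal of
byte-identical duplicate lines, per-name normalization (a leading
stoichiometric coefficient — integer, decimal, fraction or symbolic
"n" — is stripped, then a synonym map is applied; the built-in map
contains the single standardization NADP(H) → NADPH and can be extended
from a two-column file), and removal of reactions identical in
(substrates, products, direction). Name comparison is exact,
case-sensitive string equality after normalization: biochemical names
are case-significant and no case folding is assumed. Protonation
states, compartments and generic compound classes are treated as
resolved upstream by whatever curation produced the input files.

## Topological metrics: conventions and numerics

* **Average path length.** L sums directed geodesic lengths over all
  N(N−1) ordered pairs and divides by N(N−1), with unreachable pairs
  contributing 0. This zero-for-unreachable convention shrinks L on
  fragmented digraphs relative to the more common
  reachable-pairs-only average; it is kept deliberately because it is
  the convention the feature pipeline is defined with.
* **Local clustering** is directed-literal: kᵢ is the total degree
  (in + out, a bidirectional arc counting twice) and eᵢ counts ordered
  neighbor pairs (u, w), u ≠ w, with an arc u → w; Cᵢ = eᵢ/(kᵢ(kᵢ−1)),
  and Cᵢ = 0 for kᵢ ≤ 1. An undirected-projection variant
  (`undirected=True`) is provided for sensitivity analysis; the
  directed form is the default.
* **Local efficiency.** A literal reading of the printed global/local
  efficiency formula makes the "local" quantity independent of the
  node, since the node index is reused as a summation variable; the
  quantity its prose describes — tolerance of the network to removal of
  node i — is the standard neighbor-subgraph local efficiency, which is
  what is implemented: Fᵢ is the mean reciprocal directed geodesic
  distance inside the subgraph induced by vᵢ's (in ∪ out) neighbors,
  with unreachable pairs contributing 0, and Fᵢ = 0 for nodes with
  fewer than two neighbors. Global efficiency uses the same reciprocal
  convention on the whole graph.
* **HITS** iterates A(v_j) = Σ_{i→j} H(v_i), H(v_i) = Σ_{i→j} A(v_j)
  from the all-ones start, renormalizing both vectors to unit Euclidean
  norm each sweep, until the max absolute change falls below 1e−8
  (max 1000 sweeps; non-convergence returns the last iterate with a
  warning). The fixed points are the principal eigenvectors of AAᵀ and
  AᵀA, which is how the tests validate them.
* **Betweenness** is directed shortest-path betweenness over ordered
  endpoint pairs, endpoints excluded, normalized by (N−1)(N−2); values
  lie in [0, 1]. The Brandes implementation in networkx matches this
  normalization exactly and is used as-is, with a brute-force
  path-enumeration oracle in the tests.
* **Eigencentrality** is the principal eigenpair of the OR-symmetrized
  adjacency. The substrate–product digraph has large acyclic regions
  where the directed spectral radius is 0 and the directed eigenvector
  equation is degenerate; symmetrization guarantees a Perron vector.
  Power iteration runs on A_sym + I: the shift leaves eigenvectors
  unchanged while breaking the +λ/−λ tie of bipartite components that
  would otherwise make the iteration oscillate. Tolerance 1e−10 on the
  iterate, max 10000 sweeps.
* **Power-law exponents** are discrete maximum-likelihood estimates
  with x_min = 1 on the nonzero in-degree (resp. out-degree) sample:
  γ̂ maximizes −n log ζ(γ) − γ Σ log k, solved by bounded scalar
  minimization on (1, 20]. Samples with fewer than 10 nonzero values,
  constant samples, or fits sticking to the upper search bound are
  reported as not estimable (None) rather than guessed. γ is not used
  downstream in the feature pipeline.

## Feature vectors and distances

Characters are metabolite names from the common set (intersection of
node sets; no missing entries by construction) or the full set (union;
a taxon lacking a character scores 0 in every metric — the value any
connectivity-derived metric takes for an absent node). Feature matrices
are taxa × m with rows φ_P. No z-scoring is applied by default; the
only normalization step offered is PCA. Distances are Euclidean, by
default on full-rank PCA scores, which are distance-identical to the
raw centered vectors (so the default is equivalent to raw distances
while exposing the explained-variance decomposition); a reduced
component count can be requested, with a deterministic sign convention
(largest-magnitude loading positive) for reproducible coordinates.

## UPGMA, CPCC, bootstrap

UPGMA repeatedly merges the closest pair of clusters; the inter-cluster
distance is the unweighted arithmetic mean of member-pair distances
(updated by the size-weighted recurrence), the new node's height is
half the merge distance, and ties are broken lexicographically by
smallest member label so trees are identical across platforms. The
cophenetic distance between two leaves is twice the height of their
lowest common ancestor, i.e. exactly the distance at which their
clusters merged; on ultrametric inputs UPGMA reproduces the input
matrix exactly, and its output always satisfies the three-point
condition. Newick output encodes branch lengths as height differences,
so leaf-to-ancestor path length equals half the cophenetic distance.

CPCC is the Pearson correlation of the strictly-upper-triangle entries
of two distance structures after aligning taxa by label. The default
comparison correlates a topology dendrogram's *cophenetic* matrix with
the reference distance matrix; correlating the raw topological distance
matrix instead is also reported by the pipeline, since either reading
of "consistency between the two distance matrices" is defensible.
Reference phylogenies are consumed as PHYLIP-style square matrices or
Newick trees (heights reconstructed from branch lengths), with an
optional label-mapping table.

Bootstrap support resamples characters *without* replacement by default
("random combinations" of m characters; a with-replacement flag gives
the classical bootstrap), rebuilds a UPGMA tree per replicate, and
scores each reference clade by the percentage of replicate trees
containing its exact leaf set as a cluster. Support is computed
directly as rooted-clade frequency over the replicate dendrograms —
all trees here are rooted and ultrametric, so no external
maximum-likelihood machinery is involved. One master seed spawns an
independent child RNG per (size, replicate) cell via
`SeedSequence(master, spawn_key=(size_index, replicate))`, making every
cell reproducible and independent.

## Synthetic data generator

The generator exists to give the pipeline a known ground truth. A
universe of candidate reactions (default 2000 over a 400-metabolite
pool) is drawn with 1–3 substrates and 1–3 products per reaction, sides
disjoint; metabolite choice is preferential with probability ∝
(1 + usage)^bias (default bias 1.0), producing the heavy-tailed
metabolite reuse real substrate–product networks show; 10% of reactions
are reversible. A root repertoire (default 600 reactions) evolves along
a supplied ultrametric tree with Poisson(gain·length) gains from the
universe complement and Poisson(loss·length) uniform losses per branch
(defaults 30 and 10 events per unit length; an emptied repertoire is
refloored to size 1 with a warning). `clade_signal_config` encodes the
noiseless recovery regime: losses off, branch lengths sized so every
branch carries ≥ ~20 expected gains, keeping Poisson noise small
relative to the clade-disjoint signal.

What the generator does *not* emulate: real compound chemistry, pathway
organization, correlated gain/loss of whole pathways, database
curation noise, or annotation-depth differences between taxa. Passing
recovery tests therefore shows the pipeline is correct and sensitive to
tree-structured repertoire divergence; it does not by itself establish
how strong that signal is in any real database.

Under the recovery regime, UPGMA on any connectivity-derived metric
returns the generating topology exactly (rooted clade-set difference
0). The cophenetic correlation against the generating tree is high but
not 1: merge heights are estimated from stochastic event counts, so
they cannot equal the generating heights exactly even when the topology
is perfect (observed ≈ 0.96–0.99 across seeds).

## Problem sizes

The shipped test and acceptance runs use 12 taxa (4 clades × 3 leaves)
with leaf networks of roughly 350–400 metabolites, 100 bootstrap
replicates over a 4-point ensemble-size grid, 500 random ≤7-node
digraphs for oracle comparison, and 1000 random matrices for the
ultrametricity property — sizes chosen so the full validation runs in
about a minute on one CPU while every stage (including betweenness, the
most expensive metric) is exercised at realistic density. The published
17-taxon study (networks of 2433–3546 metabolites, common set 1880,
full set 4583, common reactions 1149) is the intended production scale;
its curated reaction exports are distributed with the original
publication and are consumed through the same `RunConfig` interface
when available.

## Known limitations

* The directed-literal clustering and symmetrized eigencentrality are
  one of several defensible conventions; both alternatives are exposed
  where offered, but published per-metric values obtained under an
  unstated convention may differ.
* L's zero-for-unreachable convention makes path lengths of networks
  with different reachability structure only loosely comparable.
* Bootstrap support is rooted-clade frequency over UPGMA replicates; it
  is not comparable numerically to maximum-likelihood bootstrap
  percentages from sequence data.
* The pipeline assumes one reaction file per taxon with consistent
  metabolite naming across taxa; cross-database name reconciliation is
  out of scope beyond the synonym map.
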