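# Methods

This note documents the models and procedures implemented in
`ppicohort`, the parameters that matter, the numerical conventions, and
what the synthetic benchmark does and does not demonstrate.

## Per-sample network construction

A sample's seed proteins are its top-*N* genes ranked by expression
z-score — descending for the upregulated direction, ascending for
downregulated. Genes with missing z-scores are excluded *before*
ranking (a missing measurement is never treated as 0); ties on z break
toward the lexicographically smaller symbol so that repeated runs give
identical seed lists, and seed lists are prefix-stable in *N*. Seeds
absent from the interactome remain part of the seed set (they are a
property of the expression data) but contribute nothing to the graph
and are logged.

With maximum path length 1, the sample network is the interactome
subgraph induced on its seeds, minus isolated nodes. With the default
of 2, a seed pair lacking a direct interaction may be joined through a
single intermediary: a common interactome neighbour, tagged *imputed*
when it was not itself a seed. Two connector policies exist:

- **best** (default): exactly one connector per unlinked pair, the
  common neighbour *w* maximising min(conf(u,w), conf(w,v)); ties break
  by larger conf(u,w)+conf(w,v), then the lexicographically smallest
  symbol. This bounds graph size and is fully deterministic.
- **all**: every common neighbour. Provided for sensitivity analysis;
  the best-mode graph is always a subgraph of the all-mode graph.

Isolated nodes are removed after construction so graph comparison
reflects connected interaction content only; removals are recorded.
Every edge of a sample network exists in the interactome with its
confidence unchanged.

## Distances, clustering, cluster significance

Samples are compared by Jaccard distance over network **node sets**
(seeds and imputed proteins alike); an edge-set mode is available behind
`jaccard_mode = edges` for sensitivity. Two empty networks get distance
0 with a warning. Node-set Jaccard is a metric, so the distance matrix
is symmetric with a zero diagonal and entries in [0, 1].

UPGMA is implemented directly (not delegated to a library routine)
because cohort matrices contain exact ties and reproducible dendrograms
need a defined tie-break: among equally close cluster pairs, the pair
whose smallest member sample ID is lexicographically least (then the
other cluster's smallest member) merges first. Merge heights are the
average inter-cluster distances, updated as size-weighted means; the
tree is ultrametric by construction. The naive O(n³) average-linkage
definition serves as the independent oracle in the test suite. The
cophenetic correlation — Pearson correlation between the n(n−1)/2 input
distances and the tree's lowest-common-ancestor heights — is the
diagnostic for choosing the seed count *N*: `seed_count_sweep` reruns
the front half of the pipeline over candidate *N* values and reports one
coefficient per *N*, leaving the stability judgement to the user
(no numeric stability criterion is imposed). Zero-variance inputs make
the coefficient undefined; a flagged NaN is returned.

Cluster candidates are the leaf sets of internal dendrogram nodes with
at least `min_cluster_size` (default 2) leaves and height at most the
meta-cluster threshold (default 0.8), which acts as a tree cut. Each
candidate gets a two-sided Fisher exact test on the 2×2 table
(in-cluster / out-of-cluster) × (group 1 / group 2), defined as the sum
of hypergeometric probabilities of all tables with the observed margins
that do not exceed the observed table's probability (ties included).
Raw p-values below `alpha` (default 0.001) are significant; the
returned list keeps only maximal clusters (no reported cluster is a
subset of another) sorted by p. Raw p-values are primary; a Bonferroni
value over the number of tested branches is attached for reference
only. Bootstrapping is not implemented: `bootstrapping_rounds` is
accepted in configuration for compatibility but must be 0.

## Consensus networks, hubs, modularity

Within a significant cluster, each group's member networks merge into a
consensus network. Default mode `union_count` keeps nodes occurring in
at least `min_count` member networks (automatic default:
max(2, ⌈members/2⌉), a recurrence filter that suppresses networks
private to single samples) and the member edges whose endpoints both
survive, with occurrence counts on nodes and edges. The alternative
`pooled_seeds` mode pools every member's seed genes and rebuilds one
network from the pooled set; which reading matches a given external
tool cannot be decided in general, so both are implemented and the
choice is echoed in the manifest. A consensus node is *imputed* only if
it was never a seed in any contributing sample. Specificity labels
(`unique_to_A` / `unique_to_B` / `shared`) partition the union of the
two groups' consensus node sets.

Hubs are the top-*k* (default 5) consensus nodes by degree, ties
lexicographic; a tie group straddling rank *k* is returned whole and
flagged rather than truncated arbitrarily. Community structure uses the
Louvain greedy modularity optimisation (via networkx, seeded, hence
deterministic) scored by the Newman–Girvan modularity
Q = Σ_c [ℓ_c/m − (d_c/2m)²]; edges are unweighted by default, with an
option to weight by edge occurrence counts. An edgeless network yields
singleton modules with Q = 0.

The `max_vertices_to_render` setting (default 50) truncates only the
GraphML export (top nodes by degree, ties lexicographic) — analysis is
never truncated. `repulsion_constant` is a layout-only parameter,
recorded in the manifest with no analysis effect.

## Separation score

s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2 over unweighted shortest-path hop
distances in the interactome (confidences are ignored here). ⟨d_AA⟩
averages, over members of A present in the interactome, the distance to
the nearest *other* member of A; ⟨d_AB⟩ averages the nearest cross-set
distance over all members of both sets, counting a protein belonging to
both sets as distance 0 — which is what produces the negative scores
that signal overlap. Members absent from the interactome or unreachable
from every relevant target are excluded from the means and reported in
an exclusion count; exclusion is the only treatment that keeps the
means finite. The score is exactly symmetric in A and B. In the
pipeline it compares the two groups' unique (group-specific) consensus
proteins whenever a significant cluster contains members of both
groups.

## Synthetic cohorts

The generator emulates the pipeline's study conditions with known
ground truth:

- **Interactome**: preferential attachment starting from a single
  edge, each new node attaching `edges_per_new_node` (default 3)
  degree-proportional edges — giving 1 + Σᵢ min(m, i) edges, a
  connected graph, and the heavy-tailed degree distribution of real PPI
  networks (hubs must exist for hub-recovery benchmarks to be
  meaningful; an Erdős–Rényi background would have none). Confidences
  are uniform on [0.6, 1.0]; everything is deterministic given
  `rng_seed`.
- **Disease modules**: two connected breadth-first balls around
  high-degree anchors, sized 15/15 by default, with a target Jaccard
  overlap (default 0 — disjoint; B then grows avoiding A from an anchor
  outside A's neighbourhood). Positive targets grow B outward from a
  connected shared prefix of A; generation fails loudly if 100 anchor
  retries cannot land within ±0.1 of the target.
- **Expression**: every cell starts N(0, 1); each group-1 sample
  redraws a fresh random 80% (`frac_module_active`) of module-A genes
  from N(3, 1) (`effect_mu`, `effect_sigma`), group-2 samples likewise
  with module B. Partial activation models patient heterogeneity: it
  keeps within-group Jaccard distances strictly between 0 and 1, so
  clustering is a real task rather than an identity check. Cohort size
  defaults to 30+30.

These defaults were chosen as a realistic difficulty level — a z-shift
of 3 against a standard-normal background with 80% penetrance is a
strong but not saturating signal, comparable to a clearly dysregulated
pathway — and the benchmark (25 seed genes per sample, generator seeds
1–20) recovers a significant enriched cluster in 20/20 runs with about
two thirds of top-5 consensus hubs inside the implanted modules.

What the generator does **not** emulate: correlated co-expression
within modules beyond shared mean shifts, gene-level variance
differences, batch effects, dropout patterns of real RNA-seq, overlap
between the background's top z-scores and biological pathways, or
interactome false positives/negatives. Passing the recovery benchmark
therefore shows the machinery is correct and sensitive under its own
model, not that any particular real cohort will stratify.

## Numerical and formatting conventions

- Confidences normalise to [0, 1] on input regardless of dialect;
  duplicate edge records collapse to the maximum confidence; self-loops
  are dropped with a warning; edge TSV output uses 4 decimal places and
  a sorted (A < B) pair order, making write→read round trips exact.
- All tie-breaks in the analysis path (seed ranking, UPGMA merges,
  connector choice, hub ordering, largest-component selection) are
  lexicographic, so identical inputs give byte-identical artifacts;
  reruns differ only in log timestamps.
- The Newick export writes quoted leaf names with branch lengths as
  parent-minus-child heights; patristic leaf distances in the exported
  tree equal twice the cophenetic heights.
- Problem sizes in the test and acceptance suites (500-protein
  interactomes, 60-sample cohorts, 20 benchmark replicates, 200 label
  shuffles, oracle sweeps over all ≤30-total contingency tables) were
  chosen to exercise every code path at cohort-like scale while keeping
  a full run in the low minutes on one CPU.

## Known limitations

- Only two-group phenotypes are supported; multi-group designs need
  pairwise runs.
- Gene-to-protein identifier mapping is a plain alias table applied at
  read time; no web-service resolution.
- The meta-cluster threshold is interpreted as a dendrogram height cut;
  other tools may define it differently, so the value is explicit in
  every config echo.
- s_AB significance (degree-preserving randomisation z-scores) is not
  computed; the score is reported with its components and exclusion
  counts only.
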