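# Methods

This note documents the models, algorithms and design decisions
behind `srfkit`, what the synthetic data emulates, and what the test
suite does and does not establish.

## Founder graphs and the semi-repeat-free property

A gapped alignment `MSA[1..m, 1..n]` over Σ ∪ {-} and a partition of
its columns into consecutive segments induce a blocked, node-labeled
DAG: block `V_k` holds one node per distinct gap-free string
(`spell`) that the rows take on segment k, and `(v, w)` is an edge
iff some row spells `ℓ(v)ℓ(w)` across the two segments. Height
`H(G)` is the largest block, `L(G)` the longest label. The graph is
*semi-repeat-free* (srf) when every occurrence of a node label
`ℓ(v)`, as a subpath spelling anywhere in the graph, starts at offset
1 of a node of v's own block. Three consequences, each checked
directly by the validator: labels are globally distinct; no label is
a proper suffix of another; every edge label `ℓ(uv)` occurs only from
the beginning of u. All validators are exhaustive-search based and
are the final authority in every construction pipeline.

Coordinates are 1-based inclusive throughout the library; GAF output
converts to 0-based half-open. `N` is indexed like any symbol but
never matches during search, so seeds are always real sequence.

## Construction

`is_valid_segment(x, y)` is the MSA-level surrogate for the srf
condition: no row spells ε on `[x..y]`, and each row's segment string
occurs in every spelled row only at the position where column x lands
in that row. `compute_f_exact` finds, per column j, the minimal y
with `[j..y]` valid (∞ if none) by direct scan — O(n²) segment
checks, each a handful of C-speed substring searches; adequate for
the alignment sizes this package targets (n up to a few hundred).
The row-partition approximation shuffles rows under a seed, splits
them into k contiguous chunks, computes chunk-restricted f values and
takes the elementwise maximum; since each chunk sees fewer
constraints the result can under-estimate f, so the built graph is
*repaired*: any block flagged by the graph-level validator (or
spelling an empty string) is merged with its right neighbor (the
last block merges left) until validation passes — the block count
strictly decreases, so this terminates.

The segmentation DP selects, among partitions whose segments all
satisfy `y ≥ f[x]`, one minimizing the maximum block height, breaking
ties toward more blocks and then toward the lexicographically
smallest list of segment end columns (a fully deterministic output).
Alternative objectives (`length`: minimize the longest spelled block;
`maxblocks`) are selectable. Whether validity is closed under right
extension is not assumed anywhere: with exact f the DP only uses
blocks at their minimal extents' right side, and the repair loop is
the safety net for the approximation.

## Indexing and exact matching

The index is a plain suffix array (numpy prefix-doubling) over
`T_edges · $` with collation `$ < # < A < C < G < N < T`, plus the
BWT with per-symbol rank prefix tables, giving O(1) `left_extend`
(backward-search step) and O(1) `edge_locate` (text position →
(edge, offset)) after O(|T_edges|) preprocessing. One-block graphs
have no edges; the text falls back to `#`-separated node labels so
within-node matching still works.

Matching a query Q proceeds in two regimes:

1. **≤ 2 nodes.** Backward-search Q in `T_edges`; any hit lies inside
   one edge label and converts directly to a witness subpath.
2. **≥ 3 nodes.** Such an occurrence decomposes at the boundary after
   its second-to-last-but-one node: `Q[1..f']` ends at a node
   boundary and `Q[f'+1..]` is a prefix of an edge label. Edge-prefix
   suffixes are detected by extending the suffix interval with `#`;
   boundary occurrences of prefixes are found by a memoized
   right-to-left walk that matches whole node labels — by the srf
   uniqueness properties at most one label can end at a given query
   position, so the walk is near-deterministic; the walk's first node
   may be entered mid-label. Candidate joins are tested against the
   actual edge set, and the returned witness is minimal under
   (block of first node, node id, start offset, path).

The exhaustive DFS over all (node, offset) starts serves as the
independent oracle; the randomized equivalence suite (≥1000 trials on
pipeline-built graphs, queries drawn from true row spellings, mutated
spellings, and uniform random strings) asserts agreement on the
found/not-found bit and re-spells every witness. The
longest-matching-suffix primitive exploits that suffix occurrence is
monotone in the start position and binary-searches with the exact
matcher as predicate.

## Seeding

A seed is an anchor whose subpath spans at least one full node:
k > 2; or k = 1 with i = 1 and j = ‖u1‖; or k = 2 with i = 1 or
j = ‖u2‖. The greedy seeder repeatedly finds the longest matching
suffix of the remaining prefix, reports it if it passes the
predicate, and continues left of the match; failing matches still
truncate the query. When no nonempty suffix matches at all, one
trailing character is dropped — the uncovered case in the loop's
specification; this guarantees termination within |Q| iterations.
Greedy seeds are therefore pairwise disjoint in the query. The
expansion mode (`-o X`) ranks the greedy pass's recorded matches by
length (ties toward smaller query start), takes X of them, and emits
*every* graph occurrence of each; the srf filter is relaxed for these
by default (`keep_nonsrf`), since the mode exists to recover
sensitivity. Full-node seeds — all anchors `([x..y], (1, v, ‖v‖))` —
come from a hand-built Aho–Corasick automaton over the node labels
and double as the exhaustive reference seeder. Reads are seeded on
both strands; minus-strand seeds keep query coordinates on the
original read while the subpath stays on the forward graph.

## Chaining on the EDS relaxation

Chaining deliberately ignores the edge set: conceptually all
consecutive-block pairs are connected (the elastic-degenerate-string
relaxation), which makes precedence and cost O(1) after precomputing
each node's block index and prefix sums `S[i]` of per-block minimum
label lengths. Multi-node seeds are first split into node anchors.
For node anchors `Ap`, `Aq` (same strand), `Ap` precedes `Aq` iff the
query intervals are ordered and either both sit in the same node with
ordered offset intervals, or `B[up] < B[uq]`. The connect cost is
gap + |query overlap − graph overlap| where the gap is the maximum of
the query gap and the graph gap; within one node the graph gap and
overlap use the offset intervals, across nodes the graph overlap is 0
and the gap is `‖up‖ − jp + (S[B[uq]−1] − S[B[up]]) + (iq − 1)` —
the shortest EDS walk between the anchor endpoints.

Global chaining adds two virtual terminal anchors charging both the
query end gaps and the graph end gaps (via the same prefix sums);
semi-global mode zeroes the graph side, the natural objective for
reads contained in a larger graph. With these terminals, the minimum
global chain cost over a full common-substring anchor set equals the
anchored edit distance (zero-cost matches only at anchor-covered
pairs, unit-cost substitutions/indels everywhere) — the test suite
verifies this equality, and its agreement with plain edit distance,
on 300 random pairs. Note the max-of-gaps cost presumes substitutions
are available: with no anchors at all the optimum is
max(|T1|, |T2|), not |T1| + |T2|.

Two solvers: the O(n²) DP (always optimal, the oracle) and the
iterative solver that admits a transition only when the *gap* between
the anchors is at most the current window B, ramping `B ← B·α` while
the best cost exceeds B. Windowing on the gap rather than on
start-position distance restores exactness: every gap along an
optimal chain is bounded by its total cost, so once B ≥ OPT the
restricted DP finds OPT and the exit condition fires. Defaults
B₁ = 128, α = 4; an optional coverage guess β·(|Q| − c) replaces B₁.
Chains are computed per strand in the frame where query order and
block order agree (minus-strand anchors are flipped into the
reverse-complement frame and back); the lower-cost strand is
reported, ties toward '+'.

**Chain-implied subpath.** For evaluation and GAF reporting the chain
is completed into a concrete EDS subpath: skipped blocks between
consecutive anchors are bridged by filler nodes, and the subpath is
extended through neighboring blocks to cover the query flanks before
the first and after the last anchor. When the read is available the
fillers are chosen to minimize edit distance against the
corresponding read window (jointly over a gap's blocks when the
combination count is ≤128, greedily otherwise) — a light-weight
stand-in for a base-level extension stage; without a read, fillers
default to gap-length/minimum-length heuristics.

## Synthetic data

`random_msa` emulates the input this workflow is designed for:
haplotype alignments derived from a reference plus called variants.
Rows are haplotypes of one random ancestor with *shared variant
loci*: substitution loci at `mutation_rate` per column (default
0.05), indel loci covering `gap_rate` of the columns (default 0.1,
geometric event length with mean 2), each locus carrying a uniform
allele frequency in [0.2, 0.8], and conserved flanks of
min(5, n//4) columns at both alignment boundaries (alignment
boundaries of reference-anchored data fall in shared context, and
indel representation retains an anchor base). Independent per-row
gap runs were deliberately rejected: they routinely produce rows
whose spelling recurs inside other rows, i.e. alignments that admit
*no* semi-repeat-free segmentation — a degeneracy of the generator,
not of the method. The generator does not model sequencing
platform-specific error spectra, repeat expansions, structural
variants, or realistic linkage between loci; passing tests therefore
demonstrate correctness of the algorithms under idealized haplotype
structure, not robustness to every real pangenome.

`simulate_read` samples a source-to-sink path uniformly (by the
path-count DP), takes a window of its spelling at a uniform start
(clipped to full length when possible), applies iid errors
(substitution/insertion/deletion each at rate/3, default total 5%),
and reverse-complements with probability ½. Alignment correctness is
scored by three criteria: base-level overlap of reported vs true
subpath positions ≥ δ·|truth| (per-base (node, offset) sets); edit
distance of reported vs true sequence ≤ σ_truth·|truth|; edit
distance of read vs reported sequence ≤ σ_read·|read| (edlib).

## Problem sizes and numerical choices

The test and acceptance workloads use alignments with m ≤ 6 rows and
n ≤ 200 columns, reads of length 100 at 5% error, ≥1000 matching
trials, 200 chaining instances and 300 anchored-distance pairs —
sizes at which every brute-force oracle in the suite is itself
exhaustive and fast. End-to-end regression gates (≥95% of reads
chained on the correct strand; ≥90% passing the σ_read = 0.1
criterion) are repository gates over these synthetic conditions.
Across independent graph draws the read-criterion rate typically
lands between ~88% and ~98%: the residue is split between reads
whose error draw already exceeds the 10% budget against the truth
itself and imperfect filler choices in gap-dense chains.

Determinism: all randomness is `random.Random(seed)`-driven; node ids
are assigned per block in label order; edges are indexed in
(source block, source label, target label) order; witness and
tie-break orders are total. Two runs with equal seeds produce
byte-identical outputs.

## Known limitations

* Exact matching is specified for semi-repeat-free graphs; on
  non-indexable graphs only the brute-force oracle is meaningful.
* `compute_f_exact` is quadratic in n and not suited to
  chromosome-scale alignments; the architecture (approximation +
  repair) is the scalable path, the desk-scale implementation is not.
* The chain is scored on the EDS relaxation; a chain need not be a
  walk of the true edge set, and the implied subpath is an EDS
  subpath. This mirrors the design choice of chaining on the
  relaxation for speed and simplicity.
* The iterative chainer's optimality argument relies on the gap-check
  window; anchors overlapping in the query are accepted but carry no
  optimality guarantee (asserted only never to beat the DP).
* No base-level extension/alignment stage is included; an external
  extender can be invoked on the emitted GAF (`--extend-cmd`), and
  the read-guided filler in the implied subpath is only a light proxy.
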