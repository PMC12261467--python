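# srfkit

Seed–chain alignment on **indexable elastic founder graphs** (iEFGs).

Pangenome graphs trade reference bias for a hard computational
problem: exact pattern matching in a general labeled graph cannot be
done in subquadratic time. Elastic founder graphs sidestep this. An
EFG is built from a multiple sequence alignment of haplotypes by
partitioning the alignment columns into consecutive *blocks*; each
block's nodes are the distinct gap-free strings its rows spell, and
edges record which strings co-occur on a row. When every node label
ℓ(v) occurs in the graph only starting at the beginning of nodes of
its own block — the *semi-repeat-free* (srf) property — the graph is
*indexable*: a classical text index over the concatenated edge labels

    T_edges = # · Π_{(u,v)∈E} ℓ(u)ℓ(v) · #

answers exact queries without any graph traversal on the hot path.

`srfkit` implements the full workflow around that idea, for
researchers working on sequence-to-graph alignment methods:

* **Construction** — semi-repeat-free segmentation of a gapped MSA:
  minimal right-extensions `f(j)` (exact, or approximated from a row
  partition and repaired by block merging), a segmentation DP
  minimizing the graph height `H(G)`, and graph materialization with
  brute-force validators for the srf property and its uniqueness
  consequences.
* **Indexing & exact matching** — suffix-array/BWT backward search
  over `T_edges` with O(1) `left_extend` and `edge_locate`
  primitives; occurrences spanning many nodes are reassembled from a
  node-boundary prefix walk and an edge-label suffix, exploiting the
  uniqueness of srf labels.
* **Seeding** — greedy right-to-left decomposition of a read into
  longest matching suffixes, keeping anchors that span at least one
  full node (srf seeds); an expansion mode re-reporting all
  occurrences of the X longest matches; Aho–Corasick full-node seeds
  as the exhaustive reference.
* **Chaining** — co-linear chaining of node anchors on the graph's
  elastic-degenerate-string relaxation with the gap + overlap-difference
  connect cost, computable in O(1) from block tables and prefix sums
  of per-block minimum label lengths. Both the provably optimal
  O(n²) DP and the iterative gap-windowed solver with geometric
  ramp-up are provided; the minimum global chain cost equals the
  anchored edit distance between read and graph.
* **Simulation & evaluation** — a variant-locus MSA generator, a
  noisy-read sampler over uniform graph paths, and the three standard
  correctness criteria (path overlap δ, truth edit distance σ_truth,
  read edit distance σ_read).

## Worked example

```python
from srfkit import (build_edge_text_index, exact_match, graph_stats,
                    random_msa, segment_msa, validate_efg)

msa = random_msa(m=6, n=80, mutation_rate=0.05, gap_rate=0.1, seed=11)
segmentation, graph = segment_msa(msa)
print(graph_stats(graph))
# GraphStats(b=15, n_nodes=21, n_edges=29, height=3, max_label_len=8,
#            total_label_len=112, n_paths=48)
print(validate_efg(graph).is_iefg)   # True

idx = build_edge_text_index(graph)
hit = exact_match(graph, idx, "CGGT")
```

The six simulated haplotypes segment into 15 blocks; the widest locus
offers 3 alternative strings (`height`), the longest node label is 8 bp,
and the graph expresses 48 source-to-sink recombinations. `exact_match`
returns a witness subpath `(i, u1…uk, j)` spelling the query, or
not-found — always in agreement with the exhaustive DFS oracle.

Running `python examples/seed_chain_reads.py` seeds and chains 20
simulated 80 bp reads (5 % error) and prints, per read, the chosen
strand, the chain cost (an upper proxy for the read's edit distance
to the graph) and the evaluation verdicts, ending with a line such as
`19/20 reads pass the 10% read-edit-distance criterion`.

The same functionality is exposed as a thin CLI:

```sh
srfkit segment msa.fa graph.gfa          # MSA -> iEFG (GFA1, bl:i block tags)
srfkit stats graph.gfa --json
srfkit seed graph.gfa reads.fq seeds.gaf # greedy srf seeds (GAF)
srfkit chain graph.gfa seeds.gaf out.gaf # EDS co-linear chaining
srfkit align graph.gfa reads.fq out.gaf  # seed + chain pipeline
srfkit simulate / evaluate               # synthetic reads & accuracy
```

## Layout

```
src/srfkit/      graph.py gfa.py msa.py index.py matching.py
                 seeding.py chaining.py simulate.py evaluate.py
                 pipeline.py cli.py
tests/           unit, property and end-to-end suites
examples/        narrative scripts, one per capability
docs/methods.md  models, parameters, design choices, limitations
```
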