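"""Full workflow: simulate noisy reads, seed, chain, evaluate.

Seeds each read greedily with semi-repeat-free matches (anchors
spanning at least one full node), chains the per-node anchors on the
graph's elastic-degenerate-string relaxation, and scores the
chain-implied subpath against the simulated truth.
"""

from srfkit import (build_edge_text_index, random_msa, revcomp, segment_msa,
                    simulate_reads)
from srfkit.chaining import (BlockTables, ChainConfig, chain_implied_subpath,
                             chain_read)
from srfkit.evaluate import evaluate_alignment
from srfkit.seeding import seed_read

msa = random_msa(m=6, n=150, mutation_rate=0.05, gap_rate=0.1, seed=21)
_, g = segment_msa(msa)
idx = build_edge_text_index(g)
tables = BlockTables.from_graph(g)

reads = simulate_reads(g, count=20, length=80, error_rate=0.05, seed=3)
cfg = ChainConfig(mode="semiglobal")

n_ok = 0
for r in reads:
    seeds = seed_read(g, idx, r.read_id, r.sequence)
    strand, result = chain_read(seeds, tables, len(r.sequence), cfg)
    read_fwd = r.sequence if strand == "+" else revcomp(r.sequence)
    reported = chain_implied_subpath(result.chain, tables, read=read_fwd)
    path_ok, truth_ok, read_ok = evaluate_alignment(
        tables, reported, r.truth_subpath, read_fwd
    )
    n_ok += int(read_ok)
    print(
        f"{r.read_id}: strand={strand} (truth {r.strand}) seeds={len(seeds)} "
        f"chain_cost={result.cost} path_ok={path_ok} read_ed_ok={read_ok}"
    )

# chain cost approximates the read's edit distance to the graph;
# read_ed_ok marks reads whose reported subpath spells a sequence
# within 10% edit distance of the read
print(f"\n{n_ok}/{len(reads)} reads pass the 10% read-edit-distance criterion")
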