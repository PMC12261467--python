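"""Build an indexable founder graph from a small gapped alignment.

Segments a six-row synthetic haplotype alignment into blocks whose
strings occur nowhere else in the rows (the semi-repeat-free
condition), materializes the blocked graph, and prints its shape.
"""

from srfkit import graph_stats, random_msa, segment_msa, validate_efg

msa = random_msa(m=6, n=80, mutation_rate=0.05, gap_rate=0.1, seed=11)
print("alignment rows:")
for name, row in zip(msa.names, msa.rows):
    print(f"  {name:6s} {row}")

segmentation, graph = segment_msa(msa)
print(f"\nsegments: {segmentation.segments}")

stats = graph_stats(graph)
print(
    f"graph: b={stats.b} blocks, |V|={stats.n_nodes}, |E|={stats.n_edges}, "
    f"H={stats.height}, L={stats.max_label_len}, paths={stats.n_paths}"
)
# H is the widest block (number of alternative strings at one locus),
# L the longest node label, paths the number of haplotype recombinations
# the graph expresses.
report = validate_efg(graph)
print(f"indexable (semi-repeat-free): {report.is_iefg}")
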