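"""Exact pattern matching in a founder graph via the edge-label text.

Indexes the '#'-separated concatenation of edge labels for backward
search and matches queries against the graph without any graph
traversal on the hot path; a brute-force DFS cross-checks the result.
"""

from srfkit import (EFGraph, brute_force_match, build_edge_text_index,
                    exact_match)

g = EFGraph(
    [["v1", "v2"], ["v3"], ["v4", "v5"]],
    {"v1": "AC", "v2": "CA", "v3": "GG", "v4": "TT", "v5": "TA"},
    [("v1", "v3"), ("v2", "v3"), ("v3", "v4"), ("v3", "v5")],
)
idx = build_edge_text_index(g)
print(f"edge-label text: {idx.text}")

for q in ["CGGT", "ACGGTA", "AA"]:
    res = exact_match(g, idx, q)
    oracle, _ = brute_force_match(g, q)
    assert res.found == oracle.found
    if res.found:
        w = res.witness
        print(f"{q}: found as (i={w.start_offset}, {'->'.join(w.nodes)}, j={w.end_offset})")
        # the witness subpath spells the query exactly
        assert g.spell(w) == q
    else:
        print(f"{q}: does not occur in the graph")
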