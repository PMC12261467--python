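"""GFA1 serialization of founder graphs.

S-lines carry node id, label, and the 1-based block index as a
``bl:i:<k>`` tag; L-lines use 0M overlaps.  On read, missing block
tags are inferred as the longest-path level from in-degree-0 nodes,
then checked against the consecutive-block edge requirement.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .graph import EFGraph, GraphError


class GFAParseError(ValueError):
    """Malformed GFA input; carries the offending line number."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def write_gfa(g: EFGraph, path: str) -> None:
    """Serialize ``g`` as GFA1 with bl:i block tags.

    Node order is (block, label) so output is reproducible regardless
    of construction order.
    """
    if g.b == 0:  # EFGraph construction already forbids this
        raise GraphError("cannot serialize an empty graph")
    lines = ["H\tVN:Z:1.0"]
    for v in g.sorted_nodes():
        lines.append(f"S\t{v}\t{g.labels[v]}\tbl:i:{g.block_of(v)}")
    for u, v in sorted(g.edges):
        lines.append(f"L\t{u}\t+\t{v}\t+\t0M")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_gfa(path: str) -> EFGraph:
    """Parse a GFA1 file into an :class:`EFGraph`.

    Raises :class:`GFAParseError` naming the line for malformed input
    and :class:`GraphError` for structural violations (empty labels,
    duplicate ids, edges between non-consecutive blocks).
    """
    labels: Dict[str, str] = {}
    block_tag: Dict[str, int] = {}
    edges: List[Tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line[0] in "H#":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise GFAParseError(lineno, "S-line needs id and label")
                name, lab = fields[1], fields[2]
                if name in labels:
                    raise GraphError(f"duplicate node id {name!r}")
                if not lab or lab == "*":
                    raise GraphError(f"empty label for node {name!r}")
                labels[name] = lab
                for tag in fields[3:]:
                    if tag.startswith("bl:i:"):
                        try:
                            block_tag[name] = int(tag[5:])
                        except ValueError:
                            raise GFAParseError(lineno, f"bad block tag {tag!r}")
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise GFAParseError(lineno, "L-line needs 5 fields")
                if fields[2] != "+" or fields[4] != "+":
                    raise GFAParseError(lineno, "only forward links supported")
                if fields[5] not in ("0M", "*"):
                    raise GFAParseError(lineno, "only 0M overlaps supported")
                edges.append((fields[1], fields[3]))
            elif fields[0] in ("P", "W"):
                continue  # path lines ignored
            else:
                raise GFAParseError(lineno, f"unparseable record {fields[0]!r}")
    if not labels:
        raise GFAParseError(0, "no S-lines found")
    for u, v in edges:
        if u not in labels or v not in labels:
            raise GraphError(f"edge ({u},{v}) references unknown node")

    if len(block_tag) != len(labels):
        block_tag = _infer_blocks(labels, edges)

    b = max(block_tag.values())
    if min(block_tag.values()) != 1:
        raise GraphError("block indices must start at 1")
    blocks: List[List[str]] = [[] for _ in range(b)]
    for v in labels:
        blocks[block_tag[v] - 1].append(v)
    try:
        return EFGraph(blocks, labels, edges)
    except GraphError as e:
        if "consecutive" in str(e):
            raise GraphError(f"non-consecutive blocks: {e}") from e
        raise


def _infer_blocks(labels: Dict[str, str], edges: List[Tuple[str, str]]) -> Dict[str, int]:
    """Longest-path level from in-degree-0 nodes (1-based)."""
    indeg = {v: 0 for v in labels}
    succ: Dict[str, List[str]] = {v: [] for v in labels}
    for u, v in edges:
        indeg[v] += 1
        succ[u].append(v)
    level = {v: 1 for v in labels}
    order = [v for v in labels if indeg[v] == 0]
    remaining = dict(indeg)
    i = 0
    while i < len(order):
        u = order[i]
        i += 1
        for v in succ[u]:
            level[v] = max(level[v], level[u] + 1)
            remaining[v] -= 1
            if remaining[v] == 0:
                order.append(v)
    if len(order) != len(labels):
        raise GraphError("cycle detected while inferring block levels")
    return level
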