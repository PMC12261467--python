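"""Core domain types for blocked, node-labeled founder graphs.

An elastic founder graph (EFG) is a DAG whose nodes are partitioned
into consecutive *blocks* V1..Vb; every node carries a nonempty label,
labels are distinct within a block, and edges only connect a block to
the next one.  A graph is *semi-repeat-free* (srf), hence *indexable*
(an iEFG), when every node label occurs in the graph only starting at
the beginning of nodes of its own block.  Dropping the edge set and
conceptually connecting every consecutive-block pair yields the
elastic-degenerate-string (EDS) relaxation used for chaining.

All coordinates in this package are 1-based and inclusive, matching
the standard notation of the founder-graph literature; GAF output
converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple


class GraphError(ValueError):
    """Structural violation of the founder-graph invariants."""


@dataclass(frozen=True)
class SubPath:
    """A subpath ``(i, u1..uk, j)``: a walk through consecutive blocks
    entering the first node at label offset ``i`` and leaving the last
    at offset ``j`` (both 1-based inclusive)."""

    start_offset: int
    nodes: Tuple[str, ...]
    end_offset: int

    def __post_init__(self) -> None:
        if not self.nodes:
            raise GraphError("subpath must contain at least one node")
        if self.start_offset < 1 or self.end_offset < 1:
            raise GraphError("subpath offsets are 1-based and positive")
        if len(self.nodes) == 1 and self.start_offset > self.end_offset:
            raise GraphError("single-node subpath requires i <= j")


@dataclass(frozen=True)
class Anchor:
    """An exact-match anchor: query interval [x..y] paired with a graph
    subpath spelling the same string (on the stated strand)."""

    query_start: int
    query_end: int
    subpath: SubPath
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


class EFGraph:
    """Blocked, node-labeled DAG.

    Parameters
    ----------
    blocks:
        Ordered list of node-id collections, one per block.
    labels:
        Map node id -> nonempty label string.
    edges:
        Iterable of (u, v) node-id pairs; u must sit one block before v.
    """

    def __init__(
        self,
        blocks: Sequence[Iterable[str]],
        labels: Dict[str, str],
        edges: Iterable[Tuple[str, str]] = (),
    ) -> None:
        self.blocks: List[List[str]] = [list(b) for b in blocks]
        self.labels: Dict[str, str] = dict(labels)
        self.edges: Set[Tuple[str, str]] = set(edges)
        self._block_of: Dict[str, int] = {}
        self._validate_structure()
        self._out: Dict[str, List[str]] = {v: [] for v in self.labels}
        self._in: Dict[str, List[str]] = {v: [] for v in self.labels}
        for u, v in sorted(self.edges):
            self._out[u].append(v)
            self._in[v].append(u)

    # -- structural invariants (Definition-1 level) --------------------
    def _validate_structure(self) -> None:
        if not self.blocks:
            raise GraphError("graph must have at least one block")
        seen: Set[str] = set()
        for k, block in enumerate(self.blocks, start=1):
            if not block:
                raise GraphError(f"block {k} is empty")
            labs = set()
            for v in block:
                if v in seen:
                    raise GraphError(f"duplicate node id {v!r}")
                seen.add(v)
                lab = self.labels.get(v)
                if not lab:
                    raise GraphError(f"empty label for node {v!r}")
                if lab in labs:
                    raise GraphError(
                        f"duplicate label {lab!r} within block {k}"
                    )
                labs.add(lab)
                self._block_of[v] = k
        if seen != set(self.labels):
            raise GraphError("labels must cover exactly the block nodes")
        for u, v in self.edges:
            if u not in seen or v not in seen:
                raise GraphError(f"edge ({u},{v}) references unknown node")
            if self._block_of[v] != self._block_of[u] + 1:
                raise GraphError(
                    f"edge ({u},{v}) does not join consecutive blocks"
                )

    # -- basic accessors ----------------------------------------------
    @property
    def b(self) -> int:
        return len(self.blocks)

    def block_of(self, v: str) -> int:
        return self._block_of[v]

    def label(self, v: str) -> str:
        return self.labels[v]

    def node_len(self, v: str) -> int:
        return len(self.labels[v])

    def successors(self, v: str) -> List[str]:
        return self._out[v]

    def predecessors(self, v: str) -> List[str]:
        return self._in[v]

    def nodes(self) -> Iterator[str]:
        for block in self.blocks:
            yield from block

    def height(self) -> int:
        """H(G): maximum number of nodes in a block."""
        return max(len(b) for b in self.blocks)

    def max_label_len(self) -> int:
        """L(G): maximum node-label length."""
        return max(len(self.labels[v]) for v in self.labels)

    def spell(self, sp: SubPath) -> str:
        """String spelled by a subpath: suffix of the first label,
        whole middle labels, prefix of the last."""
        nodes = sp.nodes
        if sp.start_offset > self.node_len(nodes[0]):
            raise GraphError("start offset exceeds first node length")
        if sp.end_offset > self.node_len(nodes[-1]):
            raise GraphError("end offset exceeds last node length")
        for a, bnode in zip(nodes, nodes[1:]):
            if (a, bnode) not in self.edges:
                raise GraphError(f"({a},{bnode}) is not an edge")
        if len(nodes) == 1:
            return self.labels[nodes[0]][sp.start_offset - 1 : sp.end_offset]
        parts = [self.labels[nodes[0]][sp.start_offset - 1 :]]
        parts.extend(self.labels[v] for v in nodes[1:-1])
        parts.append(self.labels[nodes[-1]][: sp.end_offset])
        return "".join(parts)

    def sorted_nodes(self) -> List[str]:
        """Deterministic node order: by (block, label)."""
        out: List[str] = []
        for block in self.blocks:
            out.extend(sorted(block, key=lambda v: self.labels[v]))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EFGraph):
            return NotImplemented
        return (
            [sorted(b) for b in self.blocks] == [sorted(b) for b in other.blocks]
            and self.labels == other.labels
            and self.edges == other.edges
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"EFGraph(b={self.b}, |V|={len(self.labels)}, |E|={len(self.edges)})"


@dataclass
class EDS:
    """EDS relaxation: blocks and labels only; every consecutive-block
    node pair is conceptually connected."""

    blocks: List[List[str]]
    labels: Dict[str, str]

    @property
    def b(self) -> int:
        return len(self.blocks)


def eds_relaxation(g: EFGraph) -> EDS:
    """Drop the edge set, keeping blocks and labels."""
    return EDS([list(b) for b in g.blocks], dict(g.labels))


# ---------------------------------------------------------------------
# Exhaustive occurrence enumeration (shared by the validators and by the
# brute-force matching oracle).
# ---------------------------------------------------------------------

def occurrences(g: EFGraph, q: str) -> List[SubPath]:
    """All occurrences of ``q`` in ``g`` as subpaths, by exhaustive DFS
    from every (node, offset) start.  Exponential in the worst case;
    intended for validation and as a test oracle, not the hot path."""
    if not q:
        raise ValueError("query must be nonempty")
    found: List[SubPath] = []
    for block in g.blocks:
        for v in sorted(block):
            lab = g.labels[v]
            for i in range(1, len(lab) + 1):
                _dfs_match(g, q, 0, v, i, i, [v], found)
    return found


def _dfs_match(
    g: EFGraph,
    q: str,
    qpos: int,
    node: str,
    offset: int,
    start_offset: int,
    path: List[str],
    found: List[SubPath],
) -> None:
    lab = g.labels[node]
    k = offset - 1
    while qpos < len(q) and k < len(lab):
        if lab[k] != q[qpos]:
            return
        qpos += 1
        k += 1
    if qpos == len(q):
        found.append(SubPath(start_offset, tuple(path), k))
        return
    for w in sorted(g.successors(node)):
        _dfs_match(g, q, qpos, w, 1, start_offset, path + [w], found)


@dataclass
class SrfViolation:
    """A node label occurring somewhere other than the start of a node
    of its own block."""

    node: str
    subpath: SubPath

    def __str__(self) -> str:  # pragma: no cover
        return f"label of {self.node} occurs at {self.subpath}"


def check_semi_repeat_free(g: EFGraph) -> List[SrfViolation]:
    """Semi-repeat-free check by exhaustive subpath search: for every
    node v of block Vk, each occurrence of its label must start at
    offset 1 of a node of Vk.  Returns the violations (empty = iEFG)."""
    out: List[SrfViolation] = []
    for v in g.nodes():
        kv = g.block_of(v)
        for occ in occurrences(g, g.labels[v]):
            if occ.start_offset != 1 or g.block_of(occ.nodes[0]) != kv:
                out.append(SrfViolation(v, occ))
    return out


@dataclass
class ValidationReport:
    """Result of the full iEFG validation."""

    structure_ok: bool
    srf_violations: List[SrfViolation] = field(default_factory=list)
    lemma_distinct_labels: bool = True
    lemma_no_proper_suffix: bool = True
    lemma_edge_label_start: bool = True
    notes: List[str] = field(default_factory=list)

    @property
    def is_iefg(self) -> bool:
        return (
            self.structure_ok
            and not self.srf_violations
            and self.lemma_distinct_labels
            and self.lemma_no_proper_suffix
            and self.lemma_edge_label_start
        )


def validate_efg(g: EFGraph) -> ValidationReport:
    """Full report: block structure, the semi-repeat-free property, and
    the three uniqueness consequences (distinct labels; no node label a
    proper suffix of another; every edge label occurring only from the
    beginning of its source node), each checked directly by brute force.
    """
    rep = ValidationReport(structure_ok=True)
    rep.srf_violations = check_semi_repeat_free(g)

    labs = [g.labels[v] for v in g.nodes()]
    if len(set(labs)) != len(labs):
        rep.lemma_distinct_labels = False
        rep.notes.append("two distinct nodes share a label")

    nodes = list(g.nodes())
    for u in nodes:
        lu = g.labels[u]
        for v in nodes:
            if u == v:
                continue
            lv = g.labels[v]
            if len(lu) < len(lv) and lv.endswith(lu):
                rep.lemma_no_proper_suffix = False
                rep.notes.append(
                    f"label of {u} is a proper suffix of label of {v}"
                )

    for u, v in sorted(g.edges):
        lab = g.labels[u] + g.labels[v]
        for occ in occurrences(g, lab):
            if occ.start_offset != 1 or occ.nodes[0] != u:
                rep.lemma_edge_label_start = False
                rep.notes.append(
                    f"edge label of ({u},{v}) occurs away from start of {u}"
                )
    return rep


@dataclass
class GraphStats:
    b: int
    n_nodes: int
    n_edges: int
    height: int
    max_label_len: int
    total_label_len: int
    n_paths: int


def graph_stats(g: EFGraph) -> GraphStats:
    """Summary statistics; the path count is the number of block-1 to
    block-b paths, computed by forward DP over blocks (exact integer)."""
    counts: Dict[str, int] = {}
    for v in g.blocks[0]:
        counts[v] = 1
    for block in g.blocks[1:]:
        for v in block:
            counts[v] = sum(counts.get(u, 0) for u in g.predecessors(v))
    n_paths = sum(counts.get(v, 0) for v in g.blocks[-1])
    if g.b == 1:
        n_paths = len(g.blocks[0])
    return GraphStats(
        b=g.b,
        n_nodes=len(g.labels),
        n_edges=len(g.edges),
        height=g.height(),
        max_label_len=g.max_label_len(),
        total_label_len=sum(len(s) for s in g.labels.values()),
        n_paths=n_paths,
    )
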