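"""Building indexable founder graphs from gapped multiple sequence
alignments.

The construction pipeline is: compute, for every column j, the minimal
right extension f(j) such that columns [j..f(j)] induce a semi-repeat-
free block (exactly, or approximately from a partition of the rows);
run a segmentation DP over the valid blocks; materialize the graph;
and, when the approximation was used, repair the segmentation by
merging blocks that violate indexability.  Final authority on validity
is always the graph-level validator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .graph import EFGraph, check_semi_repeat_free

INF = float("inf")


def spell(row: str) -> str:
    """Remove gap characters from an aligned row (or row segment)."""
    return row.replace("-", "")


@dataclass
class MSA:
    """Gapped alignment matrix: m equal-length rows over Σ ∪ {-}."""

    rows: List[str]
    names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA needs at least one row")
        n = len(self.rows[0])
        if n < 1 or any(len(r) != n for r in self.rows):
            raise ValueError("all MSA rows must share a positive length")
        if any(not spell(r) for r in self.rows):
            raise ValueError("every row must spell a nonempty sequence")
        if self.names is None:
            self.names = [f"row{i+1}" for i in range(len(self.rows))]

    @property
    def m(self) -> int:
        return len(self.rows)

    @property
    def n(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class Segmentation:
    """Partition of the columns [1..n] into consecutive intervals,
    stored as (start, end) pairs, 1-based inclusive."""

    segments: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("segmentation must be nonempty")
        if segs[0][0] != 1:
            raise ValueError("first segment must start at column 1")
        for (x1, y1), (x2, _) in zip(segs, segs[1:]):
            if x2 != y1 + 1:
                raise ValueError("segments must tile the columns")

    @property
    def b(self) -> int:
        return len(self.segments)

    @property
    def n(self) -> int:
        return self.segments[-1][1]


def _gapless_prefix_counts(row: str) -> List[int]:
    """cum[x] = number of non-gap symbols in row[0:x]."""
    cum = [0]
    c = 0
    for ch in row:
        if ch != "-":
            c += 1
        cum.append(c)
    return cum


class _MsaView:
    """Precomputed spelled rows and column->sequence-position maps."""

    def __init__(self, msa: MSA, row_idx: Optional[Sequence[int]] = None):
        idx = list(row_idx) if row_idx is not None else list(range(msa.m))
        self.rows = [msa.rows[i] for i in idx]
        self.spelled = [spell(r) for r in self.rows]
        self.cum = [_gapless_prefix_counts(r) for r in self.rows]

    def segment_string(self, i: int, x: int, y: int) -> str:
        # spelled content of row i between columns x..y (1-based)
        return self.spelled[i][self.cum[i][x - 1] : self.cum[i][y]]

    def aligned_pos(self, i: int, x: int) -> int:
        """1-based position in the spelled row i where column x lands
        (i.e. the position that a block starting at column x begins at)."""
        return self.cum[i][x - 1] + 1


def _segment_valid(view: _MsaView, x: int, y: int) -> bool:
    m = len(view.rows)
    strings = [view.segment_string(i, x, y) for i in range(m)]
    if any(not s for s in strings):
        return False
    for s in set(strings):
        for ip in range(m):
            target = view.spelled[ip]
            want = view.aligned_pos(ip, x) - 1  # 0-based expected start
            start = target.find(s)
            while start != -1:
                if start != want:
                    return False
                start = target.find(s, start + 1)
    return True


def is_valid_segment(msa: MSA, x: int, y: int) -> bool:
    """Semi-repeat-free validity of columns [x..y] at MSA level: no row
    spells ε, and each row's segment string occurs in every spelled row
    only at the position where column x lands in that row."""
    if not (1 <= x <= y <= msa.n):
        raise ValueError("need 1 <= x <= y <= n")
    return _segment_valid(_MsaView(msa), x, y)


def _compute_f(view: _MsaView, n: int) -> List[float]:
    f: List[float] = []
    for j in range(1, n + 1):
        val: float = INF
        for y in range(j, n + 1):
            if _segment_valid(view, j, y):
                val = y
                break
        f.append(val)
    return f


def compute_f_exact(msa: MSA) -> List[float]:
    """f[j] (1-indexed list, position j-1): the smallest y >= j such
    that [j..y] is a valid block, or inf when no such y exists."""
    return _compute_f(_MsaView(msa), msa.n)


def compute_f_approx(msa: MSA, k: int, seed: int = 0) -> List[float]:
    """Row-partition approximation: shuffle the rows (seeded), split
    into k contiguous chunks, compute f on each chunk-restricted MSA
    and take the elementwise maximum.  Not guaranteed valid for the
    full MSA; downstream repair is required."""
    if not (1 <= k <= msa.m):
        raise ValueError("need 1 <= k <= m")
    rng = random.Random(seed)
    order = list(range(msa.m))
    rng.shuffle(order)
    size = (msa.m + k - 1) // k
    chunks = [order[i : i + size] for i in range(0, msa.m, size)]
    best = [float("-inf")] * msa.n
    for chunk in chunks:
        view = _MsaView(msa, chunk)
        fk = _compute_f(view, msa.n)
        for j in range(msa.n):
            best[j] = max(best[j], fk[j])
    return best


class SegmentationError(ValueError):
    pass


def optimal_segmentation(
    f: Sequence[float],
    n: int,
    objective: str = "height",
    msa: Optional[MSA] = None,
) -> Segmentation:
    """Segmentation DP over valid blocks (a block [x..y] is usable when
    y >= f[x]).

    Objectives: ``height`` minimizes the maximum block height of the
    induced graph (requires ``msa``), ``length`` minimizes the maximum
    spelled block length, ``maxblocks`` maximizes the block count.
    Ties always prefer more blocks, then the lexicographically smallest
    list of segment end columns.
    """
    if len(f) != n:
        raise ValueError("f must have one entry per column")
    if f[0] == INF:
        raise SegmentationError("no valid segmentation: column 1 not startable")
    if objective in ("height", "length") and msa is None:
        raise ValueError(f"objective {objective!r} requires the MSA")

    view = _MsaView(msa) if msa is not None else None
    m = msa.m if msa is not None else 0

    def seg_score(x: int, y: int) -> int:
        if objective == "maxblocks":
            return 0
        assert view is not None
        strings = {view.segment_string(i, x, y) for i in range(m)}
        if objective == "height":
            return len(strings)
        return max(len(s) for s in strings)

    # best[y] = (max_score, -b, ends_tuple) over valid segmentations of [1..y]
    best: List[Optional[Tuple[int, int, Tuple[int, ...]]]] = [None] * (n + 1)
    best[0] = (0, 0, ())
    for y in range(1, n + 1):
        cand: Optional[Tuple[int, int, Tuple[int, ...]]] = None
        for x in range(1, y + 1):
            prev = best[x - 1]
            if prev is None or f[x - 1] == INF or f[x - 1] > y:
                continue
            entry = (
                max(prev[0], seg_score(x, y)),
                prev[1] - 1,
                prev[2] + (y,),
            )
            if cand is None or entry < cand:
                cand = entry
        best[y] = cand
    if best[n] is None:
        raise SegmentationError("no valid segmentation of [1..n] exists")
    ends = best[n][2]
    segs = []
    x = 1
    for y in ends:
        segs.append((x, y))
        x = y + 1
    return Segmentation(tuple(segs))


def build_efg(msa: MSA, seg: Segmentation) -> EFGraph:
    """Materialize the founder graph induced by a segmentation: one
    node per distinct spelled block string, edges from consecutive row
    co-occurrence.  Node ids are assigned per block in label order."""
    if seg.n != msa.n:
        raise ValueError("segmentation does not cover the MSA columns")
    view = _MsaView(msa)
    blocks: List[List[str]] = []
    labels: Dict[str, str] = {}
    node_of: List[Dict[str, str]] = []
    counter = 1
    for k, (x, y) in enumerate(seg.segments, start=1):
        strings = sorted({view.segment_string(i, x, y) for i in range(msa.m)})
        if any(not s for s in strings):
            raise ValueError(f"empty label in block {k}")
        mapping: Dict[str, str] = {}
        block_nodes: List[str] = []
        for s in strings:
            vid = f"v{counter}"
            counter += 1
            mapping[s] = vid
            labels[vid] = s
            block_nodes.append(vid)
        blocks.append(block_nodes)
        node_of.append(mapping)
    edges = set()
    for i in range(msa.m):
        for k in range(len(seg.segments) - 1):
            x1, y1 = seg.segments[k]
            x2, y2 = seg.segments[k + 1]
            u = node_of[k][view.segment_string(i, x1, y1)]
            v = node_of[k + 1][view.segment_string(i, x2, y2)]
            edges.add((u, v))
    return EFGraph(blocks, labels, edges)


def repair_segmentation(msa: MSA, seg: Segmentation) -> Segmentation:
    """Merge blocks violating indexability with their right neighbor
    (the last block merges left) until the built graph validates.
    Terminates because the block count strictly decreases."""
    current = list(seg.segments)
    while True:
        bad: Optional[int] = None  # 0-based block index to merge
        try:
            g = build_efg(msa, Segmentation(tuple(current)))
        except ValueError as e:
            # empty label in block k
            msg = str(e)
            if "empty label in block" not in msg:
                raise
            bad = int(msg.rsplit(" ", 1)[1]) - 1
        else:
            viols = check_semi_repeat_free(g)
            if not viols:
                return Segmentation(tuple(current))
            bad = g.block_of(viols[0].node) - 1
        if len(current) == 1:
            raise SegmentationError("irreparable: single-block graph invalid")
        if bad == len(current) - 1:
            bad -= 1  # last block merges with its left neighbor
        merged = (current[bad][0], current[bad + 1][1])
        current = current[:bad] + [merged] + current[bad + 2 :]


def segment_msa(
    msa: MSA,
    approx_k: Optional[int] = None,
    objective: str = "height",
    seed: int = 0,
) -> Tuple[Segmentation, EFGraph]:
    """Convenience pipeline: f values (exact, or strategy-(b) approx
    with repair), segmentation DP, graph construction."""
    if approx_k is None or approx_k <= 1:
        f = compute_f_exact(msa)
        seg = optimal_segmentation(f, msa.n, objective=objective, msa=msa)
    else:
        f = compute_f_approx(msa, approx_k, seed=seed)
        seg = optimal_segmentation(f, msa.n, objective=objective, msa=msa)
        seg = repair_segmentation(msa, seg)
    return seg, build_efg(msa, seg)
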