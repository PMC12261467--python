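"""Edge-label text index supporting backward search and edge locate.

The indexed text is ``'#' · Π ℓ(uv) '#'`` over a fixed edge order
(sorted by source block, source label, target label): every non-#
position corresponds to exactly one (edge, offset) pair and vice
versa.  One-block graphs have no edges; the text falls back to the
concatenated node labels so matching within single nodes still works.

Backward search runs on the BWT of the text with per-symbol rank
tables, giving O(1) left extension; the plain suffix array is kept
for locate queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .alphabet import CHAR_ORDER
from .graph import EFGraph

#: half-open suffix-array interval; empty when lo >= hi
Interval = Tuple[int, int]

EMPTY: Interval = (0, 0)


def suffix_array(ranks: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort)."""
    n = len(ranks)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = ranks.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        new_rank = np.empty(n, dtype=np.int64)
        changed = (rank[order[1:]] != rank[order[:-1]]) | (
            key2[order[1:]] != key2[order[:-1]]
        )
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


@dataclass
class EdgeTextIndex:
    """Suffix-array/BWT index over the edge-label text of a graph."""

    graph: EFGraph
    text: str                      # includes leading/trailing '#', no '$'
    edges: List[Tuple[str, Optional[str]]]  # fixed edge order; (v, None) in 1-block fallback
    sa: np.ndarray                 # suffix array of text + '$'
    _occ: np.ndarray               # (sigma, n+1) rank prefix table over BWT
    _cbefore: np.ndarray           # C array: suffixes starting with smaller symbol
    _edge_idx: np.ndarray          # text pos -> edge index (-1 at '#')
    _edge_off: np.ndarray          # text pos -> 1-based offset in edge label

    @property
    def n(self) -> int:
        return len(self.text) + 1  # with terminator

    def full_interval(self) -> Interval:
        return (0, self.n)

    def left_extend(self, interval: Interval, c: str) -> Interval:
        """Backward-search step: interval of c·S given the interval of S.

        Raises ValueError for symbols outside the indexed alphabet.
        """
        code = CHAR_ORDER.get(c)
        if code is None:
            raise ValueError(f"symbol {c!r} outside indexed alphabet")
        lo, hi = interval
        if lo >= hi:
            return EMPTY
        lo2 = self._cbefore[code] + self._occ[code, lo]
        hi2 = self._cbefore[code] + self._occ[code, hi]
        return (lo2, hi2) if lo2 < hi2 else EMPTY

    def edge_locate(self, sa_pos: int) -> Tuple[str, Optional[str], int]:
        """Map a suffix-array index to its (u, v, i) edge coordinates,
        i 1-based within ℓ(uv).  Errors on '#' or terminator suffixes."""
        tpos = int(self.sa[sa_pos])
        if tpos >= len(self.text) or self.text[tpos] == "#":
            raise ValueError("suffix does not start inside an edge label")
        e = self.edges[int(self._edge_idx[tpos])]
        return (e[0], e[1], int(self._edge_off[tpos]))

    def locate_all(self, interval: Interval) -> List[Tuple[str, Optional[str], int]]:
        lo, hi = interval
        out = []
        for p in range(lo, hi):
            tpos = int(self.sa[p])
            if tpos < len(self.text) and self.text[tpos] != "#":
                out.append(self.edge_locate(p))
        return out

    def count(self, interval: Interval) -> int:
        return max(0, interval[1] - interval[0])


def edge_order(g: EFGraph) -> List[Tuple[str, Optional[str]]]:
    """Deterministic edge order: (source block, source label, target label).
    One-block graphs fall back to (node, None) pseudo-edges in label order."""
    if g.b == 1:
        return [(v, None) for v in sorted(g.blocks[0], key=lambda v: g.labels[v])]
    return sorted(
        g.edges,
        key=lambda e: (g.block_of(e[0]), g.labels[e[0]], g.labels[e[1]]),
    )


def build_edge_text_index(g: EFGraph) -> EdgeTextIndex:
    """Build the '#'-separated edge-label text and its search structures."""
    order = edge_order(g)
    parts = ["#"]
    edge_idx: List[int] = [-1]
    edge_off: List[int] = [0]
    for idx, (u, v) in enumerate(order):
        lab = g.labels[u] + (g.labels[v] if v is not None else "")
        parts.append(lab)
        parts.append("#")
        edge_idx.extend([idx] * len(lab) + [-1])
        edge_off.extend(list(range(1, len(lab) + 1)) + [0])
    text = "".join(parts)

    ranks = np.fromiter(
        (CHAR_ORDER[c] for c in text + "$"), dtype=np.int64, count=len(text) + 1
    )
    sa = suffix_array(ranks)
    n = len(ranks)
    bwt = ranks[(sa - 1) % n]
    sigma = max(CHAR_ORDER.values()) + 1
    occ = np.zeros((sigma, n + 1), dtype=np.int64)
    for code in range(sigma):
        occ[code, 1:] = np.cumsum(bwt == code)
    counts = np.bincount(ranks, minlength=sigma)
    cbefore = np.concatenate(([0], np.cumsum(counts)))[:sigma]
    return EdgeTextIndex(
        graph=g,
        text=text,
        edges=order,
        sa=sa,
        _occ=occ,
        _cbefore=cbefore,
        _edge_idx=np.asarray(edge_idx, dtype=np.int64),
        _edge_off=np.asarray(edge_off, dtype=np.int64),
    )


def left_extend(idx: EdgeTextIndex, interval: Interval, c: str) -> Interval:
    """Module-level convenience wrapper around :meth:`EdgeTextIndex.left_extend`."""
    return idx.left_extend(interval, c)


def edge_locate(idx: EdgeTextIndex, sa_pos: int) -> Tuple[str, Optional[str], int]:
    """Module-level convenience wrapper around :meth:`EdgeTextIndex.edge_locate`."""
    return idx.edge_locate(sa_pos)


def backward_search(idx: EdgeTextIndex, q: str) -> Interval:
    """Interval of all occurrences of ``q`` in the edge text."""
    itv = idx.full_interval()
    for c in reversed(q):
        itv = idx.left_extend(itv, c)
        if itv == EMPTY:
            return EMPTY
    return itv
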