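"""Exact pattern matching in an indexable founder graph.

The fast path avoids whole-graph search: occurrences spanning at most
one edge are found by plain backward search on the edge-label text;
longer occurrences are decomposed as

    Q[1..f'] ending at a node boundary  +  Q[f'+1..] a prefix of an
    edge label,

joined over an actual graph edge.  The boundary occurrence of a query
prefix is found by a right-to-left walk matching whole node labels;
by the uniqueness properties of semi-repeat-free graphs at most one
full label can end at any query position, so the walk is (essentially)
deterministic and memoizable.  A brute-force DFS oracle over all
(node, offset) starts is provided for testing and for all-occurrence
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

from .alphabet import is_dna
from .graph import EFGraph, SubPath, occurrences
from .index import EMPTY, EdgeTextIndex, Interval


@dataclass
class MatchResult:
    found: bool
    witness: Optional[SubPath] = None


def match_suffix_in_edge(idx: EdgeTextIndex, q: str) -> Tuple[int, Interval]:
    """Subroutine F: smallest f such that Q[f..] is a prefix of some
    edge label, tracked by left-extending the suffix interval and
    testing '#'-alignment.  Returns (|Q|+1, empty) when no suffix
    qualifies; otherwise the interval is that of '#'·Q[f..]."""
    if not q:
        raise ValueError("query must be nonempty")
    best_f = len(q) + 1
    best: Interval = EMPTY
    itv = idx.full_interval()
    for f in range(len(q), 0, -1):
        itv = idx.left_extend(itv, q[f - 1])
        if itv == EMPTY:
            break
        probe = idx.left_extend(itv, "#")
        if probe != EMPTY:
            best_f, best = f, probe
    return best_f, best


def _suffix_intervals(idx: EdgeTextIndex, q: str) -> Dict[int, Interval]:
    """Intervals of every occurring suffix Q[p..] (1-based p)."""
    out: Dict[int, Interval] = {}
    itv = idx.full_interval()
    for p in range(len(q), 0, -1):
        itv = idx.left_extend(itv, q[p - 1])
        if itv == EMPTY:
            break
        out[p] = itv
    return out


def _edge_prefix_edges(idx: EdgeTextIndex, probe: Interval) -> List[Tuple[str, Optional[str]]]:
    """Edges whose label has the probed string as a prefix (the probe
    interval is that of '#'·S, so each hit sits on a separator)."""
    lo, hi = probe
    hits = []
    text_len = len(idx.text)
    for p in range(lo, hi):
        tpos = int(idx.sa[p])
        nxt = tpos + 1
        if nxt >= text_len:
            continue
        ei = int(idx._edge_idx[nxt])
        if ei >= 0:
            hits.append(idx.edges[ei])
    # deterministic order by edge position in the fixed edge order
    pos = {e: i for i, e in enumerate(idx.edges)}
    hits = sorted(set(hits), key=pos.__getitem__)
    return hits


class _BoundaryWalker:
    """Occurrences of Q[1..pos] that end exactly at a node boundary.

    Walks right-to-left matching whole node labels; the first node of
    an occurrence may be entered mid-label.  Memoized per position.
    """

    def __init__(self, g: EFGraph, q: str) -> None:
        self.g = g
        self.q = q
        self.by_label: Dict[str, str] = {}
        for v in g.nodes():
            self.by_label.setdefault(g.labels[v], v)
        self.lengths = sorted({g.node_len(v) for v in g.nodes()})
        self._memo: Dict[int, List[Tuple[int, Tuple[str, ...]]]] = {}

    def ends_at(self, pos: int) -> List[Tuple[int, Tuple[str, ...]]]:
        """List of (start offset i, node path) witnesses for boundary
        occurrences of Q[1..pos]."""
        if pos in self._memo:
            return self._memo[pos]
        self._memo[pos] = []  # guards (impossible) cycles
        g, q = self.g, self.q
        out: List[Tuple[int, Tuple[str, ...]]] = []
        # whole-label matches ending at pos (srf uniqueness: at most
        # one per position on an iEFG, but tolerate more)
        for d in self.lengths:
            if d > pos:
                break
            w = self.by_label.get(q[pos - d : pos])
            if w is None or g.node_len(w) != d:
                continue
            if d == pos:
                out.append((1, (w,)))
            else:
                for i, path in self.ends_at(pos - d):
                    if (path[-1], w) in g.edges:
                        out.append((i, path + (w,)))
        # occurrence consisting of a single node entered mid-label
        for v in g.nodes():
            lab = g.labels[v]
            if len(lab) > pos and lab.endswith(q[:pos]):
                out.append((len(lab) - pos + 1, (v,)))
        out.sort(key=lambda t: (self.g.block_of(t[1][0]), t[1][0], t[0]))
        self._memo[pos] = out
        return out


def _witness_key(g: EFGraph, sp: SubPath):
    # primary key per the determinism contract; full path breaks ties
    return (g.block_of(sp.nodes[0]), sp.nodes[0], sp.start_offset,
            sp.nodes, sp.end_offset)


def _within_edge_witnesses(
    g: EFGraph, idx: EdgeTextIndex, q: str, itv: Interval
) -> List[SubPath]:
    out = set()
    for u, v, i in idx.locate_all(itv):
        end = i + len(q) - 1
        lu = g.node_len(u)
        if v is None or end <= lu:
            out.add(SubPath(i, (u,), end))
        elif i > lu:
            out.add(SubPath(i - lu, (v,), end - lu))
        else:
            out.add(SubPath(i, (u, v), end - lu))
    return sorted(out, key=lambda sp: _witness_key(g, sp))


def exact_match(g: EFGraph, idx: EdgeTextIndex, q: str) -> MatchResult:
    """Find one occurrence of ``q`` in ``g`` (deterministic witness:
    minimal under (block of first node, node id, start offset)).
    Symbols outside {A,C,G,T} never match."""
    if not q:
        raise ValueError("query must be nonempty")
    if not is_dna(q):
        return MatchResult(False)
    from .index import backward_search

    # occurrences spanning at most one edge
    itv = backward_search(idx, q)
    if itv != EMPTY:
        wits = _within_edge_witnesses(g, idx, q, itv)
        if wits:
            return MatchResult(True, wits[0])

    if g.b == 1:
        return MatchResult(False)

    # occurrences spanning >= 3 nodes: boundary prefix + edge-label suffix
    sufs = _suffix_intervals(idx, q)
    walker = _BoundaryWalker(g, q)
    candidates: List[SubPath] = []

    # whole query ending at a node boundary
    for i, path in walker.ends_at(len(q)):
        candidates.append(SubPath(i, path, g.node_len(path[-1])))

    for p in sorted(sufs):
        if p < 2:
            continue
        probe = idx.left_extend(sufs[p], "#")
        if probe == EMPTY:
            continue
        tails = _edge_prefix_edges(idx, probe)
        if not tails:
            continue
        suffix_len = len(q) - p + 1
        for i, path in walker.ends_at(p - 1):
            w = path[-1]
            for u, v in tails:
                if (w, u) not in g.edges:
                    continue
                lu = g.node_len(u)
                if suffix_len <= lu:
                    cand = SubPath(i, path + (u,), suffix_len)
                else:
                    assert v is not None
                    cand = SubPath(i, path + (u, v), suffix_len - lu)
                candidates.append(cand)
        if candidates:
            break  # smallest split already yields the minimal-key witness set

    for cand in sorted(set(candidates), key=lambda sp: _witness_key(g, sp)):
        if g.spell(cand) == q:  # insurance; always true by construction
            return MatchResult(True, cand)
    return MatchResult(False)


def brute_force_match(
    g: EFGraph, q: str, all_occurrences: bool = False
) -> Tuple[MatchResult, List[SubPath]]:
    """Exhaustive DFS oracle over every (node, offset) start.  Works on
    any blocked graph, semi-repeat-free or not.  Returns the match
    result (first witness in (block, node id, offset) order) and, when
    requested, the list of all occurrences."""
    if not q:
        raise ValueError("query must be nonempty")
    occs = occurrences(g, q)
    occs.sort(key=lambda sp: _witness_key(g, sp))
    res = MatchResult(bool(occs), occs[0] if occs else None)
    return res, (occs if all_occurrences else [])


def longest_matching_suffix(
    g: EFGraph, idx: EdgeTextIndex, q: str
) -> Tuple[int, Optional[SubPath]]:
    """Smallest y such that Q[y..] occurs in the graph, with one
    witness; (|Q|+1, None) when no nonempty suffix occurs.  Uses the
    monotonicity of suffix occurrence for a binary search over y."""
    if not q:
        raise ValueError("query must be nonempty")
    n = len(q)

    cache: Dict[int, MatchResult] = {}

    def probe(y: int) -> MatchResult:
        if y not in cache:
            cache[y] = exact_match(g, idx, q[y - 1 :])
        return cache[y]

    if not probe(n).found:
        return n + 1, None
    lo, hi = 1, n
    while lo < hi:
        mid = (lo + hi) // 2
        if probe(mid).found:
            hi = mid
        else:
            lo = mid + 1
    return lo, probe(lo).witness
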