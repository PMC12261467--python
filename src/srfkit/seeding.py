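"""Semi-repeat-free seeding.

A seed is an exact-match anchor whose subpath spans at least one full
node (the srf predicate).  The greedy seeder repeatedly takes the
longest matching suffix of the remaining read prefix, reports it when
it passes the predicate, and restarts on the prefix left of the match;
matches failing the predicate still truncate the read, and when no
suffix matches at all one trailing character is dropped so the loop
always terminates.  The ``-o X`` expansion mode re-reports all graph
occurrences of the X longest substrings recorded by the greedy pass.
Full-node seeds (every node label occurring in the read) are found
with an Aho–Corasick automaton over the node labels.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .alphabet import revcomp
from .graph import Anchor, EFGraph, SubPath
from .index import EdgeTextIndex
from .matching import brute_force_match, longest_matching_suffix


@dataclass(frozen=True)
class Seed:
    """An anchor annotated with its read of origin."""

    read_id: str
    anchor: Anchor

    @property
    def length(self) -> int:
        return self.anchor.length

    @property
    def strand(self) -> str:
        return self.anchor.strand


def is_srf_seed(g: EFGraph, a: Anchor) -> bool:
    """Does the anchor's subpath span at least one full node?
    k>2; or k=1 with i=1 and j=||u1||; or k=2 with i=1 or j=||u2||."""
    sp = a.subpath
    k = len(sp.nodes)
    if k > 2:
        return True
    if k == 1:
        return sp.start_offset == 1 and sp.end_offset == g.node_len(sp.nodes[0])
    return sp.start_offset == 1 or sp.end_offset == g.node_len(sp.nodes[-1])


def _greedy_matches(
    g: EFGraph, idx: EdgeTextIndex, q: str
) -> List[Anchor]:
    """One greedy right-to-left pass; returns every recorded match
    (srf or not) as an anchor on the '+' strand of ``q``."""
    matches: List[Anchor] = []
    end = len(q)
    while end >= 1:
        prefix = q[:end]
        y, witness = longest_matching_suffix(g, idx, prefix)
        if witness is None:
            end -= 1  # dead end: drop one trailing character
            continue
        matches.append(Anchor(y, end, witness, "+"))
        end = y - 1
    return matches


def greedy_srf_seeds(
    g: EFGraph,
    idx: EdgeTextIndex,
    q: str,
    read_id: str = "read",
    strand: str = "+",
    min_length: int = 1,
) -> List[Seed]:
    """Greedy pass keeping only matches that pass the srf predicate.
    Emitted seeds are pairwise disjoint in the query (right-to-left)."""
    seeds = []
    for a in _greedy_matches(g, idx, q):
        if a.length >= min_length and is_srf_seed(g, a):
            anchor = Anchor(a.query_start, a.query_end, a.subpath, strand)
            seeds.append(Seed(read_id, anchor))
    return seeds


def top_x_expand(
    g: EFGraph,
    idx: EdgeTextIndex,
    q: str,
    x: int,
    read_id: str = "read",
    strand: str = "+",
    keep_nonsrf: bool = True,
) -> List[Seed]:
    """Expansion mode: select the X longest substrings matched by the
    greedy pass (ties broken by smaller query start) and report every
    graph occurrence of each.  By default the srf filter is relaxed
    for the selected substrings; ``keep_nonsrf=False`` restores it."""
    if x < 1:
        raise ValueError("X must be >= 1")
    recorded = _greedy_matches(g, idx, q)
    recorded.sort(key=lambda a: (-a.length, a.query_start))
    seeds: List[Seed] = []
    for a in recorded[:x]:
        sub = q[a.query_start - 1 : a.query_end]
        _, occs = brute_force_match(g, sub, all_occurrences=True)
        for sp in occs:
            anchor = Anchor(a.query_start, a.query_end, sp, strand)
            if keep_nonsrf or is_srf_seed(g, anchor):
                seeds.append(Seed(read_id, anchor))
    return seeds


# ---------------------------------------------------------------------
# Aho-Corasick multi-pattern matching over the node labels
# ---------------------------------------------------------------------

class AhoCorasick:
    """Minimal goto/fail/output automaton for a set of patterns."""

    def __init__(self, patterns: Iterable[str]) -> None:
        self.goto: List[Dict[str, int]] = [{}]
        self.out: List[List[str]] = [[]]
        self.fail: List[int] = [0]
        for pat in patterns:
            self._add(pat)
        self._build_failure()

    def _add(self, pat: str) -> None:
        s = 0
        for c in pat:
            nxt = self.goto[s].get(c)
            if nxt is None:
                nxt = len(self.goto)
                self.goto.append({})
                self.out.append([])
                self.fail.append(0)
                self.goto[s][c] = nxt
            s = nxt
        self.out[s].append(pat)

    def _build_failure(self) -> None:
        queue = deque()
        for s in self.goto[0].values():
            self.fail[s] = 0
            queue.append(s)
        while queue:
            r = queue.popleft()
            for c, s in self.goto[r].items():
                queue.append(s)
                f = self.fail[r]
                while f and c not in self.goto[f]:
                    f = self.fail[f]
                self.fail[s] = self.goto[f].get(c, 0) if self.goto[f].get(c, 0) != s else 0
                self.out[s] = self.out[s] + self.out[self.fail[s]]

    def finditer(self, text: str):
        """Yield (end_position_0based_exclusive, pattern)."""
        s = 0
        for i, c in enumerate(text):
            while s and c not in self.goto[s]:
                s = self.fail[s]
            s = self.goto[s].get(c, 0)
            for pat in self.out[s]:
                yield i + 1, pat


def full_node_seeds(g: EFGraph, q: str, strand: str = "+") -> List[Anchor]:
    """Every anchor ([x..y], (1, v, ||v||)) with ℓ(v) = Q[x..y], via
    Aho-Corasick over the node labels (overlapping occurrences all
    reported).  Serves as the exhaustive comparison seeder."""
    if not q:
        return []
    label_nodes: Dict[str, List[str]] = {}
    for v in g.nodes():
        label_nodes.setdefault(g.labels[v], []).append(v)
    ac = AhoCorasick(label_nodes.keys())
    anchors: List[Anchor] = []
    for end, pat in ac.finditer(q):
        x = end - len(pat) + 1
        for v in label_nodes[pat]:
            anchors.append(Anchor(x, end, SubPath(1, (v,), len(pat)), strand))
    anchors.sort(key=lambda a: (a.query_start, a.query_end, a.subpath.nodes))
    return anchors


def seed_read(
    g: EFGraph,
    idx: EdgeTextIndex,
    read_id: str,
    seq: str,
    top_x: Optional[int] = None,
    both_strands: bool = True,
    min_length: int = 1,
    keep_nonsrf: bool = True,
) -> List[Seed]:
    """Seed a read on the forward strand and (optionally) its reverse
    complement.  Minus-strand seeds keep query coordinates on the
    original read; the subpath stays on the forward graph."""
    out: List[Seed] = []
    strands = [("+", seq)] + ([("-", revcomp(seq))] if both_strands else [])
    n = len(seq)
    for strand, s in strands:
        if top_x is None:
            found = greedy_srf_seeds(g, idx, s, read_id, strand, min_length)
        else:
            found = top_x_expand(g, idx, s, top_x, read_id, strand, keep_nonsrf)
            found = [sd for sd in found if sd.length >= min_length]
        if strand == "-":
            conv = []
            for sd in found:
                a = sd.anchor
                conv.append(
                    Seed(read_id, Anchor(n - a.query_end + 1, n - a.query_start + 1,
                                         a.subpath, "-"))
                )
            found = conv
        out.extend(found)
    return out


# ---------------------------------------------------------------------
# GAF serialization
# ---------------------------------------------------------------------

def _subpath_gaf_fields(g: EFGraph, sp: SubPath, length: int) -> Tuple[str, int, int, int]:
    path = "".join(">" + v for v in sp.nodes)
    plen = sum(g.node_len(v) for v in sp.nodes)
    pstart = sp.start_offset - 1
    return path, plen, pstart, pstart + length


def seeds_to_gaf(seeds: Iterable[Seed], g: EFGraph, read_lengths: Dict[str, int]) -> List[str]:
    """One GAF line per seed (0-based half-open query coordinates,
    forward-path coordinates, MAPQ 255)."""
    lines = []
    for sd in seeds:
        a = sd.anchor
        length = a.length
        path, plen, pstart, pend = _subpath_gaf_fields(g, a.subpath, length)
        qlen = read_lengths[sd.read_id]
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    sd.read_id, qlen, a.query_start - 1, a.query_end,
                    a.strand, path, plen, pstart, pend, length, length, 255,
                )
            )
        )
    return lines


def parse_gaf(path: str, g: EFGraph) -> List[Tuple[str, int, Anchor]]:
    """Read a GAF file of seeds back into anchors (needs the graph to
    recover the end offset within the last node)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            read_id, qlen = f[0], int(f[1])
            qstart, qend, strand = int(f[2]), int(f[3]), f[4]
            nodes = tuple(p for p in f[5].replace(">", " ").split() if p)
            pstart, pend = int(f[7]), int(f[8])
            head = sum(g.node_len(v) for v in nodes[:-1])
            j = pend - head
            a = Anchor(qstart + 1, qend, SubPath(pstart + 1, nodes, j), strand)
            out.append((read_id, qlen, a))
    return out
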