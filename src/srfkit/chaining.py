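"""Co-linear chaining of node anchors on the EDS relaxation.

Multi-node seeds are split into node anchors; precedence and the
connect cost (gap plus overlap-difference) are O(1) after
precomputing each node's block index and the prefix sums of per-block
minimum label lengths.  Two solvers are provided: the provably
optimal O(n^2) dynamic program (the oracle), and the iterative
window-restricted algorithm with geometric ramp-up, modified to
window on the *gap* between anchors rather than their start-position
distance.  Global mode charges both query- and graph-side end gaps
through two virtual terminal anchors; semi-global mode frees the
graph side (the natural objective for long reads inside a larger
graph).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .graph import Anchor, EDS, EFGraph, SubPath
from .seeding import Seed


@dataclass
class BlockTables:
    """Constant-time lookups for EDS chaining: node block indices and
    prefix sums S[i] of per-block minimum label lengths."""

    block: Dict[str, int]
    lens: Dict[str, int]
    labels: Dict[str, str]
    blocks: List[List[str]]
    S: List[int]  # S[0] = 0, S[i] = sum of min label lengths of blocks 1..i

    @classmethod
    def from_graph(cls, g: Union[EFGraph, EDS]) -> "BlockTables":
        blocks = [list(b) for b in g.blocks]
        labels = dict(g.labels)
        block = {}
        for k, b in enumerate(blocks, start=1):
            for v in b:
                block[v] = k
        lens = {v: len(labels[v]) for v in labels}
        S = [0]
        for b in blocks:
            S.append(S[-1] + min(lens[v] for v in b))
        return cls(block, lens, labels, blocks, S)

    @property
    def b(self) -> int:
        return len(self.blocks)

    def min_node(self, k: int) -> str:
        """Deterministic minimum-length representative of block k."""
        return min(self.blocks[k - 1], key=lambda v: (self.lens[v], self.labels[v], v))


@dataclass
class ChainConfig:
    mode: str = "global"          # "global" | "semiglobal"
    b1: int = 128                 # initial window guess
    alpha: float = 4.0            # ramp-up factor, > 1
    beta: Optional[float] = None  # coverage-based guess: beta * (|Q| - c)

    def __post_init__(self) -> None:
        if self.mode not in ("global", "semiglobal"):
            raise ValueError("mode must be 'global' or 'semiglobal'")
        if self.alpha <= 1:
            raise ValueError("ramp-up factor must exceed 1")
        if self.b1 < 1:
            raise ValueError("initial window must be >= 1")
        if self.beta is not None and not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")


@dataclass
class ChainResult:
    chain: List[Anchor]
    cost: int
    iterations: int = 1
    final_window: Optional[int] = None


def split_to_node_anchors(g: Union[EFGraph, EDS, BlockTables], a: Anchor) -> List[Anchor]:
    """Split a multi-node anchor into per-node anchors whose query
    intervals partition [x..y] according to the label lengths."""
    lens = g.lens if isinstance(g, BlockTables) else {v: len(g.labels[v]) for v in a.subpath.nodes}
    sp = a.subpath
    k = len(sp.nodes)
    parts: List[Tuple[str, int, int]] = []  # (node, i, j)
    if k == 1:
        parts.append((sp.nodes[0], sp.start_offset, sp.end_offset))
    else:
        parts.append((sp.nodes[0], sp.start_offset, lens[sp.nodes[0]]))
        for v in sp.nodes[1:-1]:
            parts.append((v, 1, lens[v]))
        parts.append((sp.nodes[-1], 1, sp.end_offset))
    total = sum(j - i + 1 for _, i, j in parts)
    if total != a.length:
        raise ValueError("anchor query interval does not match subpath length")
    out = []
    x = a.query_start
    for v, i, j in parts:
        out.append(Anchor(x, x + (j - i), SubPath(i, (v,), j), a.strand))
        x += j - i + 1
    return out


def _node(a: Anchor) -> str:
    if len(a.subpath.nodes) != 1:
        raise ValueError("chaining operates on node anchors; split first")
    return a.subpath.nodes[0]


def precedes(ap: Anchor, aq: Anchor, t: BlockTables) -> bool:
    """Anchor precedence on the EDS: query intervals in order, and
    either the same node with offset intervals in order, or a strictly
    earlier block."""
    if not (ap.query_start <= aq.query_start and ap.query_end <= aq.query_end):
        return False
    up, uq = _node(ap), _node(aq)
    if up == uq:
        return (ap.subpath.start_offset <= aq.subpath.start_offset
                and ap.subpath.end_offset <= aq.subpath.end_offset)
    return t.block[up] < t.block[uq]


def _gap(ap: Anchor, aq: Anchor, t: BlockTables) -> int:
    """Maximum of query gap and graph gap (each floored at 0)."""
    qgap = aq.query_start - ap.query_end - 1
    up, uq = _node(ap), _node(aq)
    if up == uq:
        ggap = aq.subpath.start_offset - ap.subpath.end_offset - 1
    else:
        ggap = (
            t.lens[up] - ap.subpath.end_offset
            + (t.S[t.block[uq] - 1] - t.S[t.block[up]])
            + (aq.subpath.start_offset - 1)
        )
    return max(0, qgap, ggap)


def connect_cost(ap: Anchor, aq: Anchor, t: BlockTables) -> int:
    """Gap plus overlap-difference between consecutive chain anchors.
    The graph-side overlap is zero across distinct nodes."""
    if not precedes(ap, aq, t):
        raise ValueError("connect requires ap to precede aq")
    up, uq = _node(ap), _node(aq)
    q_over = max(0, ap.query_end - aq.query_start + 1)
    if up == uq:
        g_over = max(0, ap.subpath.end_offset - aq.subpath.start_offset + 1)
    else:
        g_over = 0
    return _gap(ap, aq, t) + abs(q_over - g_over)


def _start_connect(aq: Anchor, t: BlockTables, mode: str) -> int:
    qgap = aq.query_start - 1
    if mode == "semiglobal":
        return max(0, qgap)
    uq = _node(aq)
    ggap = t.S[t.block[uq] - 1] + (aq.subpath.start_offset - 1)
    return max(0, qgap, ggap)


def _end_connect(ap: Anchor, t: BlockTables, qlen: int, mode: str) -> int:
    qgap = qlen - ap.query_end
    if mode == "semiglobal":
        return max(0, qgap)
    up = _node(ap)
    ggap = (t.lens[up] - ap.subpath.end_offset) + (t.S[t.b] - t.S[t.block[up]])
    return max(0, qgap, ggap)


def _empty_chain_cost(t: BlockTables, qlen: int, mode: str) -> int:
    return qlen if mode == "semiglobal" else max(qlen, t.S[t.b])


def _sorted_anchors(anchors: Sequence[Anchor], t: BlockTables) -> List[Anchor]:
    return sorted(
        set(anchors),
        key=lambda a: (
            a.query_start, a.query_end, t.block[_node(a)],
            a.subpath.start_offset, a.subpath.end_offset, _node(a),
        ),
    )


def _dp(
    anchors: List[Anchor],
    t: BlockTables,
    qlen: int,
    mode: str,
    window: Optional[int],
) -> Tuple[int, List[Anchor]]:
    n = len(anchors)
    cost = [0] * n
    back: List[Optional[int]] = [None] * n
    for q in range(n):
        aq = anchors[q]
        best = _start_connect(aq, t, mode)
        bptr = None
        for p in range(q):
            ap = anchors[p]
            if not precedes(ap, aq, t):
                continue
            if window is not None and _gap(ap, aq, t) > window:
                continue
            c = cost[p] + connect_cost(ap, aq, t)
            if c < best:
                best, bptr = c, p
        cost[q] = best
        back[q] = bptr
    total = _empty_chain_cost(t, qlen, mode)
    last: Optional[int] = None
    for q in range(n):
        c = cost[q] + _end_connect(anchors[q], t, qlen, mode)
        if c < total:
            total, last = c, q
    chain: List[Anchor] = []
    while last is not None:
        chain.append(anchors[last])
        last = back[last]
    chain.reverse()
    return total, chain


def chain_dp(
    anchors: Sequence[Anchor],
    t: BlockTables,
    qlen: int,
    cfg: Optional[ChainConfig] = None,
) -> ChainResult:
    """Provably optimal O(n^2) chaining; the oracle for the iterative
    solver.  Accepts anchors overlapping in the query."""
    cfg = cfg or ChainConfig()
    ordered = _sorted_anchors(anchors, t)
    cost, chain = _dp(ordered, t, qlen, cfg.mode, None)
    return ChainResult(chain, cost)


def chain_chainx(
    anchors: Sequence[Anchor],
    t: BlockTables,
    qlen: int,
    cfg: Optional[ChainConfig] = None,
    coverage: Optional[int] = None,
) -> ChainResult:
    """Iterative window-restricted chaining with geometric ramp-up.

    Transitions are admitted when the *gap* between the anchors is at
    most the current window B; if the best cost found exceeds B, the
    window grows by the ramp-up factor and the DP repeats.  For
    anchors pairwise non-overlapping in the query this returns the
    optimal cost (every gap along an optimal chain is bounded by its
    total cost, so once B reaches OPT the restricted DP is exact).
    """
    cfg = cfg or ChainConfig()
    ordered = _sorted_anchors(anchors, t)
    if cfg.beta is not None:
        cov = coverage if coverage is not None else _query_coverage(ordered)
        window = max(1, int(cfg.beta * max(0, qlen - cov)))
    else:
        window = cfg.b1
    iterations = 0
    while True:
        iterations += 1
        cost, chain = _dp(ordered, t, qlen, cfg.mode, window)
        if cost <= window:
            return ChainResult(chain, cost, iterations, window)
        window = max(window + 1, int(window * cfg.alpha))


def _query_coverage(anchors: Sequence[Anchor]) -> int:
    """Number of query positions covered by at least one anchor."""
    ivs = sorted((a.query_start, a.query_end) for a in anchors)
    cov = 0
    cur_s, cur_e = None, -1
    for s, e in ivs:
        if cur_s is None or s > cur_e + 1:
            if cur_s is not None:
                cov += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_s is not None:
        cov += cur_e - cur_s + 1
    return cov


def chain_read(
    seeds: Sequence[Seed],
    t: BlockTables,
    qlen: int,
    cfg: Optional[ChainConfig] = None,
    solver: str = "chainx",
) -> Tuple[str, ChainResult]:
    """Chain a read's seeds per strand and report the lower-cost
    strand's chain (tie broken toward '+')."""
    cfg = cfg or ChainConfig()
    results: Dict[str, ChainResult] = {}
    for strand in "+-":
        node_anchors: List[Anchor] = []
        for sd in seeds:
            if sd.strand != strand:
                continue
            a = sd.anchor
            if strand == "-":
                # seeds carry original-read coordinates; chaining needs
                # the reverse-complement frame, where query order and
                # graph block order agree
                a = Anchor(qlen - a.query_end + 1, qlen - a.query_start + 1,
                           a.subpath, strand)
            node_anchors.extend(split_to_node_anchors(t, a))
        if not node_anchors and strand == "-":
            continue
        fn = chain_chainx if solver == "chainx" else chain_dp
        res = fn(node_anchors, t, qlen, cfg)
        if strand == "-":
            res = ChainResult(
                [Anchor(qlen - a.query_end + 1, qlen - a.query_start + 1,
                        a.subpath, strand) for a in res.chain],
                res.cost, res.iterations, res.final_window,
            )
        results[strand] = res
    best = min(results, key=lambda s: (results[s].cost, s))
    return best, results[best]


def _edit(a: str, b: str) -> int:
    # tiny Levenshtein for filler scoring (strings are node-label sized)
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _fwd_interval(a: Anchor, qlen: Optional[int]) -> Tuple[int, int]:
    """Query interval of an anchor in the graph-forward frame."""
    if a.strand == "-" and qlen is not None:
        return qlen - a.query_end + 1, qlen - a.query_start + 1
    return a.query_start, a.query_end


def _pick_filler(t: BlockTables, k: int, window: str, share: float) -> str:
    """Filler node for skipped block k: match the read window when one
    is available, otherwise the length share of the query gap."""
    if window:
        return min(
            t.blocks[k - 1],
            key=lambda w: (_edit(t.labels[w], window[: t.lens[w]]),
                           t.lens[w], t.labels[w], w),
        )
    return min(
        t.blocks[k - 1],
        key=lambda w: (abs(t.lens[w] - share), t.lens[w], t.labels[w], w),
    )


def chain_implied_subpath(
    chain: Sequence[Anchor],
    t: BlockTables,
    qlen: Optional[int] = None,
    read: Optional[str] = None,
) -> Optional[SubPath]:
    """EDS subpath implied by a chain: the chained nodes in graph
    order, with every skipped block bridged by a filler node.

    Fillers are chosen per block to match the read segment spanned by
    the gap when ``read`` (in graph-forward orientation) is supplied —
    a light-weight extension step — and to match the query-gap length
    otherwise.  When ``qlen`` is given the subpath is also extended
    through neighboring blocks to cover the query positions before
    the first and after the last anchor, entering mid-node so the
    graph-side length matches the uncovered flank.  None for an empty
    chain."""
    if not chain:
        return None
    if read is not None:
        qlen = len(read)
    nodes: List[str] = []
    prev: Optional[Anchor] = None
    for a in chain:
        u = _node(a)
        if prev is not None and u == _node(prev):
            prev = a
            continue
        if prev is not None:
            up = _node(prev)
            ks = range(t.block[up] + 1, t.block[u])
            if ks:
                p_s, p_e = _fwd_interval(prev, qlen)
                a_s, a_e = _fwd_interval(a, qlen)
                qgap = a_s - p_e - 1
                tail = t.lens[up] - prev.subpath.end_offset
                head = a.subpath.start_offset - 1
                rem = max(0, qgap - tail - head)
                window = ""
                if read is not None and qgap > 0:
                    window = read[p_e + tail : a_s - 1 - head]
                combos = 1
                for k in ks:
                    combos *= len(t.blocks[k - 1])
                if window and combos <= 128:
                    # joint choice over the skipped blocks: minimize the
                    # edit distance of the bridged spelling to the read
                    import itertools

                    best = min(
                        itertools.product(*(sorted(t.blocks[k - 1]) for k in ks)),
                        key=lambda vs: (
                            _edit("".join(t.labels[v] for v in vs), window),
                            sum(t.lens[v] for v in vs),
                            vs,
                        ),
                    )
                    nodes.extend(best)
                else:
                    left = len(ks)
                    for k in ks:
                        v = _pick_filler(t, k, window, rem / left)
                        nodes.append(v)
                        window = window[t.lens[v] :]
                        rem = max(0, rem - t.lens[v])
                        left -= 1
        nodes.append(u)
        prev = a
    i = chain[0].subpath.start_offset
    j = chain[-1].subpath.end_offset
    if qlen is not None:
        lo = min(_fwd_interval(a, qlen)[0] for a in chain)
        hi = max(_fwd_interval(a, qlen)[1] for a in chain)
        left_gap, right_gap = lo - 1, qlen - hi
        # absorb into the terminal nodes first, then whole filler nodes
        take = min(left_gap, i - 1)
        i -= take
        left_gap -= take
        k = t.block[nodes[0]]
        head_nodes: List[str] = []
        while left_gap > 0 and k > 1:
            k -= 1
            if read is not None:
                window = read[:left_gap]
                v = min(
                    t.blocks[k - 1],
                    key=lambda w: (_edit(t.labels[w], window[-t.lens[w]:]),
                                   t.lens[w], t.labels[w], w),
                )
            else:
                v = t.min_node(k)
            head_nodes.append(v)
            take = min(left_gap, t.lens[v])
            i = t.lens[v] - take + 1
            left_gap -= take
        nodes = head_nodes[::-1] + nodes
        take = min(right_gap, t.lens[nodes[-1]] - j)
        j += take
        right_gap -= take
        k = t.block[nodes[-1]]
        while right_gap > 0 and k < t.b:
            k += 1
            if read is not None:
                window = read[qlen - right_gap : qlen]
                v = min(
                    t.blocks[k - 1],
                    key=lambda w: (_edit(t.labels[w], window[: t.lens[w]]),
                                   t.lens[w], t.labels[w], w),
                )
            else:
                v = t.min_node(k)
            nodes.append(v)
            j = min(right_gap, t.lens[v])
            right_gap -= j
    return SubPath(i, tuple(nodes), j)


def eds_spell(t: BlockTables, sp: SubPath) -> str:
    """Spell a subpath on the EDS relaxation (consecutive-block moves
    are always legal there, so no edge checks)."""
    nodes = sp.nodes
    if len(nodes) == 1:
        return t.labels[nodes[0]][sp.start_offset - 1 : sp.end_offset]
    parts = [t.labels[nodes[0]][sp.start_offset - 1 :]]
    parts.extend(t.labels[v] for v in nodes[1:-1])
    parts.append(t.labels[nodes[-1]][: sp.end_offset])
    return "".join(parts)
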