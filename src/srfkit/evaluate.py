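"""Alignment-evaluation criteria and the anchored-edit-distance oracle.

Three parameterized correctness criteria for a reported alignment
against the simulated truth:

1. *path accuracy*: base-level overlap between reported and true
   subpaths (shared (node, offset) positions) is at least δ times the
   true subpath length;
2. *truth edit distance*: Levenshtein(reported sequence, true
   sequence) ≤ σ_truth · |truth|;
3. *read edit distance*: Levenshtein(read, reported sequence) ≤
   σ_read · |read|.

The anchored edit distance restricts zero-cost matches to position
pairs covered consistently by some anchor, while unit-cost
substitutions, insertions and deletions remain available everywhere.
With two virtual terminal anchors this quantity equals the minimum
co-linear chain cost under the gap/overlap connect function, which is
what the chaining test-suite exercises.
"""

from __future__ import annotations

from typing import List, Sequence, Set, Tuple, Union

import edlib

from .chaining import BlockTables, eds_spell
from .graph import EDS, EFGraph, SubPath


def levenshtein(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def subpath_positions(g: Union[EFGraph, EDS, BlockTables], sp: SubPath) -> Set[Tuple[str, int]]:
    """Per-base graph positions (node id, 1-based offset) of a subpath."""
    labels = g.labels if not isinstance(g, BlockTables) else g.labels
    out: Set[Tuple[str, int]] = set()
    nodes = sp.nodes
    for idx, v in enumerate(nodes):
        lo = sp.start_offset if idx == 0 else 1
        hi = sp.end_offset if idx == len(nodes) - 1 else len(labels[v])
        for off in range(lo, hi + 1):
            out.add((v, off))
    return out


def evaluate_alignment(
    t: BlockTables,
    reported: SubPath,
    truth: SubPath,
    read: str,
    delta: float = 0.1,
    sigma_truth: float = 0.1,
    sigma_read: float = 0.1,
) -> Tuple[bool, bool, bool]:
    """The three criteria for one alignment, in order
    (path, truth-edit-distance, read-edit-distance)."""
    true_pos = subpath_positions(t, truth)
    rep_pos = subpath_positions(t, reported)
    overlap = len(true_pos & rep_pos)
    path_ok = overlap >= delta * len(true_pos)

    rep_seq = eds_spell(t, reported)
    true_seq = eds_spell(t, truth)
    truth_ok = levenshtein(rep_seq, true_seq) <= sigma_truth * len(true_seq)
    read_ok = levenshtein(read, rep_seq) <= sigma_read * len(read)
    return path_ok, truth_ok, read_ok


StringAnchor = Tuple[Tuple[int, int], Tuple[int, int]]  # ([x..y], [a..b]), 1-based


def anchored_edit_distance(t1: str, t2: str, anchors: Sequence[StringAnchor]) -> int:
    """Edit distance where a zero-cost match of T1[i] with T2[j] is
    allowed only when some anchor covers the pair consistently
    (x<=i<=y, a<=j<=b, i-x = j-a); substitutions, insertions and
    deletions cost 1 everywhere.  Exhaustive DP, oracle scale."""
    n1, n2 = len(t1), len(t2)
    allowed: Set[Tuple[int, int]] = set()
    for (x, y), (a, b) in anchors:
        if y - x != b - a:
            raise ValueError("anchor intervals must have equal length")
        for k in range(y - x + 1):
            i, j = x + k, a + k
            if not (1 <= i <= n1 and 1 <= j <= n2):
                raise ValueError("anchor outside the strings")
            if t1[i - 1] != t2[j - 1]:
                raise ValueError("anchor covers a mismatching pair")
            allowed.add((i, j))
    dp = [[0] * (n2 + 1) for _ in range(n1 + 1)]
    for i in range(n1 + 1):
        dp[i][0] = i
    for j in range(n2 + 1):
        dp[0][j] = j
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            best = min(dp[i - 1][j] + 1, dp[i][j - 1] + 1, dp[i - 1][j - 1] + 1)
            if (i, j) in allowed:
                best = min(best, dp[i - 1][j - 1])
            dp[i][j] = best
    return dp[n1][n2]


def common_substring_anchors(t1: str, t2: str) -> List[StringAnchor]:
    """All maximal-by-position common substrings as anchors: one anchor
    per (i, j, length) triple with matching extensions; includes every
    single-character match, so the anchored edit distance with this set
    equals the plain edit distance."""
    out: List[StringAnchor] = []
    for i in range(1, len(t1) + 1):
        for j in range(1, len(t2) + 1):
            if t1[i - 1] != t2[j - 1]:
                continue
            if i > 1 and j > 1 and t1[i - 2] == t2[j - 2]:
                continue  # not left-maximal; covered by a longer anchor
            k = 0
            while i + k <= len(t1) and j + k <= len(t2) and t1[i + k - 1] == t2[j + k - 1]:
                k += 1
            out.append(((i, i + k - 1), (j, j + k - 1)))
    return out
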