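"""Synthetic fixtures: random gapped alignments and noisy reads
sampled from graph paths.

The alignment generator mutates a random ancestor per row
(substitutions plus geometric gap runs), giving the kind of closely
related haplotype rows a founder graph is built from.  The read
simulator samples a source-to-sink path uniformly (by path-count DP),
takes a window of its spelling, and applies a uniform iid error model
(substitution / insertion / deletion, each at rate/3) — a deliberate
simplification of long-read error spectra, adequate because nothing
downstream depends on the error profile's shape.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .alphabet import DNA, revcomp
from .graph import EFGraph, SubPath
from .msa import MSA


def random_msa(
    m: int,
    n: int,
    mutation_rate: float = 0.05,
    gap_rate: float = 0.1,
    seed: int = 0,
    mean_gap_len: float = 2.0,
) -> MSA:
    """Random m x n gapped alignment with a variant-locus structure.

    Rows are haplotypes of a random ancestor: substitution loci appear
    at ``mutation_rate`` per column and indel loci cover ``gap_rate``
    of the columns (geometric event length, mean ``mean_gap_len``);
    each row carries each variant with a per-locus allele frequency.
    Indels are therefore shared events at fixed loci rather than
    independent per-row gaps — the column structure of an alignment
    derived from a reference plus called variants.  Deterministic
    under ``seed``; every row spells a nonempty sequence."""
    if m < 1 or n < 1:
        raise ValueError("need m, n >= 1")
    if not (0 <= mutation_rate < 1 and 0 <= gap_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = random.Random(seed)
    ancestor = [rng.choice(DNA) for _ in range(n)]

    # Alignment boundaries fall in conserved reference context (the
    # first/last variant of a reference-anchored alignment sits well
    # inside it), so the flanking columns carry no variant loci.
    flank = min(5, n // 4)
    lo, hi = flank, n - flank

    # substitution loci: (column, alt base, allele frequency)
    subs = []
    for j in range(lo, hi):
        if rng.random() < mutation_rate:
            alt = rng.choice([c for c in DNA if c != ancestor[j]])
            subs.append((j, alt, rng.uniform(0.2, 0.8)))
    # indel loci: (start, length, allele frequency); carriers are gapped
    indels = []
    j = lo
    open_rate = gap_rate / mean_gap_len
    while j < hi:
        if rng.random() < open_rate:
            run = 1
            while rng.random() < 1 - 1 / mean_gap_len:
                run += 1
            run = min(run, n - j)
            indels.append((j, run, rng.uniform(0.2, 0.8)))
            j += run
        else:
            j += 1

    rows: List[str] = []
    for _ in range(m):
        row = list(ancestor)
        for j, alt, freq in subs:
            if rng.random() < freq:
                row[j] = alt
        for j, run, freq in indels:
            if rng.random() < freq:
                for jj in range(j, j + run):
                    row[jj] = "-"
        if all(c == "-" for c in row):
            row[rng.randrange(n)] = rng.choice(DNA)
        rows.append("".join(row))
    return MSA(rows)


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    source_path: Tuple[str, ...]
    start_offset: int   # 1-based offset in first node of the truth subpath
    end_offset: int     # 1-based offset in last node
    strand: str
    error_rate: float
    truth_spelling: str

    @property
    def truth_subpath(self) -> SubPath:
        return SubPath(self.start_offset, self.source_path, self.end_offset)


def _sample_path(g: EFGraph, rng: random.Random) -> List[str]:
    """Uniform source-to-sink path via the path-count DP."""
    counts: Dict[str, int] = {v: 1 for v in g.blocks[0]}
    for block in g.blocks[1:]:
        for v in block:
            counts[v] = sum(counts.get(u, 0) for u in g.predecessors(v))
    sinks = [(v, counts.get(v, 0)) for v in g.blocks[-1]]
    total = sum(c for _, c in sinks)
    if total == 0:
        raise ValueError("graph has no source-to-sink path")
    r = rng.randrange(total)
    for v, c in sinks:
        if r < c:
            node = v
            break
        r -= c
    path = [node]
    while g.block_of(node) > 1:
        preds = [(u, counts.get(u, 0)) for u in g.predecessors(node) if counts.get(u, 0)]
        tot = sum(c for _, c in preds)
        r = rng.randrange(tot)
        for u, c in preds:
            if r < c:
                node = u
                break
            r -= c
        path.append(node)
    path.reverse()
    return path


def _apply_errors(seq: str, rate: float, rng: random.Random) -> str:
    out: List[str] = []
    for c in seq:
        if rng.random() < rate:
            kind = rng.randrange(3)
            if kind == 0:  # substitution
                out.append(rng.choice([x for x in DNA if x != c]))
            elif kind == 1:  # insertion before the base
                out.append(rng.choice(DNA))
                out.append(c)
            # kind == 2: deletion, emit nothing
        else:
            out.append(c)
    return "".join(out)


def simulate_read(
    g: EFGraph,
    length: int,
    error_rate: float = 0.05,
    seed: int = 0,
    read_id: str = "read",
) -> ReadRecord:
    """Sample one read: uniform path, window of its spelling (clipped
    at the path end), iid errors, strand flipped with probability 1/2.
    """
    if length < 1:
        raise ValueError("read length must be >= 1")
    rng = random.Random(seed)
    path = _sample_path(g, rng)
    spelling = "".join(g.labels[v] for v in path)
    plen = len(spelling)
    start = rng.randrange(max(1, plen - length + 1)) + 1  # 1-based
    end = min(plen, start + length - 1)
    truth = spelling[start - 1 : end]

    # trim the path to the nodes the window actually touches
    node_start = []
    off = 0
    for v in path:
        node_start.append(off)
        off += g.node_len(v)
    first = max(i for i in range(len(path)) if node_start[i] < start)
    last = max(i for i in range(len(path)) if node_start[i] < end)
    sub_nodes = tuple(path[first : last + 1])
    i = start - node_start[first]
    j = end - node_start[last]

    seq = _apply_errors(truth, error_rate, rng)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        seq = revcomp(seq)
    return ReadRecord(read_id, seq, sub_nodes, i, j, strand, error_rate, truth)


def simulate_reads(
    g: EFGraph, count: int, length: int, error_rate: float = 0.05, seed: int = 0
) -> List[ReadRecord]:
    """Batch wrapper with per-read derived seeds (deterministic)."""
    rng = random.Random(seed)
    return [
        simulate_read(g, length, error_rate, rng.randrange(2**31), f"read{i+1}")
        for i in range(count)
    ]
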