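"""Alphabet conventions shared across the package.

The DNA alphabet is A, C, G, T plus the ambiguity symbol N.  N is an
ordinary symbol for indexing purposes but never participates in exact
matching: a read position holding N can anchor nothing, so seeds are
real sequence only.  The separator '#' delimits edge labels in the
indexed text and '$' terminates it; their collation order is fixed so
suffix-array construction is reproducible: $ < # < A < C < G < N < T.
"""

from __future__ import annotations

DNA = "ACGT"
SIGMA = "ACGTN"

#: fixed collation order for the edge-label text
CHAR_ORDER = {c: r for r, c in enumerate("$#ACGN T".replace(" ", ""))}

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return s.translate(_COMP)[::-1]


def is_dna(s: str) -> bool:
    """True if every symbol of ``s`` is in {A,C,G,T} (matchable sequence)."""
    return all(c in DNA for c in s)
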