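"""Primitive nucleotide-sequence operations.

Sequences are plain Python strings over the uppercase alphabet ``{A, C, G, T, N}``.
``N`` marks unknown/masked bases; it never base-pairs and is excluded from
GC-content denominators.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"

_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")

# integer codes used by the vectorised scanner: A=0 C=1 G=2 T=3 N=4
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

# complement codes; N maps to 5 so that no base code ever equals comp(N)
COMP_CODE = np.array([3, 2, 1, 0, 5], dtype=np.uint8)


def normalize(seq: str) -> str:
    """Uppercase ``seq`` and reject characters outside ``{A,C,G,T,N}``.

    Raises
    ------
    ValueError
        Naming the 0-based position of the first offending character.
    """
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in ALPHABET:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, N<->N).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    s = normalize(seq)
    return s.translate(_COMP_TABLE)[::-1]


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); N excluded from the denominator.

    Returns ``nan`` when the sequence has no non-N base.
    """
    s = seq.upper()
    g = s.count("G")
    c = s.count("C")
    denom = g + c + s.count("A") + s.count("T")
    if denom == 0:
        return float("nan")
    return (g + c) / denom


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    if codes.size and codes.max() == 255:
        pos = int(np.argmax(codes == 255))
        raise ValueError(f"invalid nucleotide {seq[pos]!r} at position {pos}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def is_pure_at(seq: str) -> bool:
    """True when the sequence contains no C or G (only A/T/N)."""
    s = seq.upper()
    return s.count("C") + s.count("G") == 0


def find_occurrences(haystack: str, query: str, *, both_strands: bool = True) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of every occurrence of ``query``.

    With ``both_strands`` the reverse complement of the query is searched too
    (a double-stranded sequence and its reverse complement are the same
    molecule); overlapping occurrences are reported, duplicates merged.
    """
    queries = {normalize(query)}
    if both_strands:
        queries.add(reverse_complement(query))
    k = len(query)
    hits: set[int] = set()
    hs = haystack.upper()
    for q in queries:
        start = hs.find(q)
        while start != -1:
            hits.add(start)
            start = hs.find(q, start + 1)
    return [(s, s + k) for s in sorted(hits)]
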