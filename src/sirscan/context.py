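"""Genomic landscape of SIRs: binned densities, GC models, trinucleotide
spectra and annotation against interval tracks.

SIR density tracks local base composition: inverted repeats are enriched in
AT-rich sequence, and the relationship between per-bin density and GC content
is summarised by a quadratic least-squares fit.  Sequence composition of the
spacer/arm/control domains is compared through 32 pyrimidine-centred
trinucleotide frequencies and their cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import SIRRecord
from .sequence import encode, gc_content, reverse_complement

# 32 pyrimidine-centred trinucleotides: centre C then centre T, flanks in
# lexicographic order (ACA, ACC, ..., TCT, ATA, ..., TTT).
CONTEXTS_32: list[str] = [
    f"{five}{centre}{three}"
    for centre in "CT"
    for five in "ACGT"
    for three in "ACGT"
]
_CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(CONTEXTS_32)}
for _ctx in list(_CONTEXT_INDEX):
    _CONTEXT_INDEX[reverse_complement(_ctx)] = _CONTEXT_INDEX[_ctx]

DEFAULT_BIN_WIDTH = 2_000_000  # 2-Mb density bins


@dataclass(frozen=True)
class GenomicBin:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    sir_count: int
    sir_density: float  # SIRs per Mb of non-N sequence


@dataclass(frozen=True)
class AnnotationTrack:
    """A named set of merged, sorted, half-open genomic intervals."""

    name: str
    intervals: Mapping[str, np.ndarray]  # chrom -> (n, 2) array

    @classmethod
    def from_intervals(cls, name: str, intervals: Iterable[tuple[str, int, int]]) -> "AnnotationTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        merged = {c: merge_intervals(iv) for c, iv in by_chrom.items()}
        return cls(name=name, intervals=merged)

    def contains(self, chrom: str, pos: int) -> bool:
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return False
        i = int(np.searchsorted(iv[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < iv[i, 1]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def bin_sir_density(
    sirs: Sequence[SIRRecord],
    genome: Mapping[str, str],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> list[GenomicBin]:
    """Per-bin SIR counts and densities (per Mb of non-N sequence).

    Each SIR is assigned to the bin containing its spacer midpoint; the last
    bin of a chromosome may be shorter than ``bin_width``.
    """
    counts: dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        n_bins = max(1, -(-len(seq) // bin_width))
        counts[chrom] = np.zeros(n_bins, dtype=np.int64)
    for r in sirs:
        if r.chrom not in counts:
            raise ValueError(f"SIR on chromosome {r.chrom!r} absent from the genome")
        counts[r.chrom][r.center // bin_width] += 1

    bins: list[GenomicBin] = []
    for chrom, seq in genome.items():
        for b, count in enumerate(counts[chrom]):
            start = b * bin_width
            end = min(len(seq), start + bin_width)
            sub = seq[start:end].upper()
            non_n = len(sub) - sub.count("N")
            density = float("nan") if non_n == 0 else count / (non_n / 1e6)
            bins.append(
                GenomicBin(
                    chrom=chrom,
                    start=start,
                    end=end,
                    gc_fraction=gc_content(sub),
                    sir_count=int(count),
                    sir_density=density,
                )
            )
    return bins


def fit_density_gc_quadratic(bins: Sequence[GenomicBin]) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of SIR density on (1, gc, gc^2).

    Returns (coefficients [c0, c1, c2], fitted values).  Bins with undefined
    density or GC are ignored; a rank-deficient design (fewer than 3 distinct
    GC values) is rejected.
    """
    gc = np.array([b.gc_fraction for b in bins], dtype=float)
    y = np.array([b.sir_density for b in bins], dtype=float)
    ok = np.isfinite(gc) & np.isfinite(y)
    gc, y = gc[ok], y[ok]
    X = np.column_stack([np.ones_like(gc), gc, gc**2])
    if len(gc) < 3 or np.linalg.matrix_rank(X) < 3:
        raise ValueError("degenerate design: need >=3 bins with distinct GC fractions")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef, X @ coef


def trinucleotide_spectrum(
    intervals: Iterable[tuple[str, int, int]],
    genome: Mapping[str, str],
) -> np.ndarray:
    """Relative frequencies of the 32 pyrimidine-centred trinucleotides.

    Every overlapping 3-mer window lying fully inside an interval is counted;
    purine-centred 3-mers are reverse-complemented before counting; windows
    containing N are skipped.  Normalised to sum to 1 (all-zero when nothing
    was counted).
    """
    counts = np.zeros(32, dtype=float)
    for chrom, start, end in intervals:
        seq = genome[chrom][max(0, start) : end].upper()
        for i in range(len(seq) - 2):
            idx = _CONTEXT_INDEX.get(seq[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def spectrum_frame(freqs: np.ndarray) -> pd.Series:
    return pd.Series(freqs, index=CONTEXTS_32, name="frequency")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonnegative spectra; in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def annotate_sirs(
    sirs: Sequence[SIRRecord],
    tracks: Sequence[AnnotationTrack],
) -> list[set[str]]:
    """Track labels per SIR, by spacer-midpoint containment.

    An SIR whose spacer midpoint falls in no track is labelled ``{"others"}``.
    """
    labels: list[set[str]] = []
    for r in sirs:
        hit = {t.name for t in tracks if t.contains(r.chrom, r.center)}
        labels.append(hit or {"others"})
    return labels


def timing_deciles(
    intervals: Iterable[tuple[str, int, int, float]],
) -> list[AnnotationTrack]:
    """Split a continuous replication-timing track into 10 decile tracks.

    Intervals are ranked genome-wide by their timing value; decile boundaries
    weight each interval by its length, so each decile covers ~10% of the
    covered bases.  Decile 1 holds the lowest values.
    """
    ivs = sorted(intervals, key=lambda t: t[3])
    lengths = np.array([e - s for _, s, e, _ in ivs], dtype=float)
    total = lengths.sum()
    if total == 0:
        raise ValueError("no covered bases in timing track")
    cum_mid = (np.cumsum(lengths) - lengths / 2) / total
    decile = np.minimum(9, (cum_mid * 10).astype(int)) + 1
    out = []
    for d in range(1, 11):
        members = [(c, s, e) for (c, s, e, _), dd in zip(ivs, decile) if dd == d]
        out.append(AnnotationTrack.from_intervals(f"timing_decile_{d}", members))
    return out


def read_bed_tracks(path) -> list[AnnotationTrack]:
    """Read a BED4 file into one AnnotationTrack per distinct name.

    Malformed lines are rejected with their line number.
    """
    by_name: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed BED line {lineno}: expected >=4 columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {exc}") from None
            if end <= start:
                raise ValueError(f"malformed BED line {lineno}: empty interval")
            by_name.setdefault(parts[3], []).append((chrom, start, end))
    return [AnnotationTrack.from_intervals(name, ivs) for name, ivs in by_name.items()]
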