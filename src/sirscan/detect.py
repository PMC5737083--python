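"""Detection of short inverted repeats (SIRs).

A short inverted repeat is ``left_arm + spacer + reverse_complement(left_arm)``:
on single-stranded DNA the two arms can hybridise into a hairpin stem while the
spacer forms the loop.  The scanner enumerates every perfect-arm inverted
repeat with spacer length 4-8 bp and arm length 6-25 bp (both configurable),
collapses candidates that span the same locus to the most stable hairpin
category (shortest admissible loop, hence longest stem), drops pure-A/T
spacers, and resolves overlapping loci by keeping the longest repeat.

Coordinates are 0-based half-open internally; serialised tables are 1-based
inclusive, BED output 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence import (
    COMP_CODE,
    encode,
    gc_content,
    is_pure_at,
    normalize,
    reverse_complement,
)


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the SIR search and of downstream control windows.

    The spacer minimum of 4 bp reflects the steric limit on hairpin-loop
    length; arms beyond ~25 bp add no hairpin stability.  Substitution/indel
    analyses use 100-bp flanking controls, rearrangement breakpoints 1000 bp.
    """

    spacer_min: int = 4
    spacer_max: int = 8
    arm_min: int = 6
    arm_max: int = 25
    control_width_sub_indel: int = 100
    control_width_rearrangement: int = 1000
    drop_pure_at: bool = True

    def __post_init__(self) -> None:
        if self.spacer_min < 4:
            raise ValueError("spacer_min must be >= 4 (hairpin-loop steric constraint)")
        if self.spacer_max < self.spacer_min or self.arm_max < self.arm_min or self.arm_min < 1:
            raise ValueError("inconsistent spacer/arm ranges")
        if self.control_width_sub_indel <= 0 or self.control_width_rearrangement <= 0:
            raise ValueError("control widths must be positive")

    def control_width(self, var_class: str) -> int:
        if var_class == "rearrangement_breakpoint":
            return self.control_width_rearrangement
        return self.control_width_sub_indel

    @property
    def min_total_length(self) -> int:
        return 2 * self.arm_min + self.spacer_min


@dataclass(frozen=True)
class SIRRecord:
    """One canonical short inverted repeat.

    ``start``/``end`` are 0-based half-open; ``end - start == 2*arm_len +
    spacer_len``.  The right arm (not stored) is the reverse complement of
    ``left_arm``.
    """

    chrom: str
    start: int
    end: int
    arm_len: int
    spacer_len: int
    left_arm: str
    spacer: str

    def __post_init__(self) -> None:
        if self.end - self.start != 2 * self.arm_len + self.spacer_len:
            raise ValueError("end - start must equal 2*arm_len + spacer_len")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_pure_at_spacer(self) -> bool:
        return is_pure_at(self.spacer)

    @property
    def right_arm(self) -> str:
        return reverse_complement(self.left_arm)

    @property
    def spacer_start(self) -> int:
        return self.start + self.arm_len

    @property
    def spacer_end(self) -> int:
        return self.start + self.arm_len + self.spacer_len

    @property
    def center(self) -> int:
        """Spacer midpoint, rounded down (left-of-middle for even loops)."""
        return (self.spacer_start + self.spacer_end - 1) // 2


@dataclass(frozen=True)
class DomainIntervals:
    """Spacer / arm / flanking-control intervals derived from one SIR."""

    spacer: tuple[int, int]
    arms: tuple[tuple[int, int], tuple[int, int]]
    controls: tuple[tuple[int, int], ...]


def enumerate_ir_decompositions(
    seq: str,
    config: SearchConfig | None = None,
    arm_floor: int | None = None,
) -> list[tuple[int, int]]:
    """All (arm_len, spacer_len) splits of ``seq`` into a perfect inverted repeat.

    Returns every ``(a, s)`` with ``2a + s == len(seq)``, ``spacer_min <= s <=
    spacer_max``, ``a >= arm_floor`` and ``seq[:a]`` reverse-complementary to
    ``seq[-a:]``, sorted by ascending spacer length.  ``arm_floor`` defaults
    to the configured minimum arm length; categorisation of one locus may pass
    a lower floor to see every hairpin category of the sequence.
    """
    config = config or SearchConfig()
    if arm_floor is None:
        arm_floor = config.arm_min
    s = normalize(seq)
    if "N" in s:
        raise ValueError("sequence must not contain N")
    out: list[tuple[int, int]] = []
    n = len(s)
    for spacer_len in range(config.spacer_min, config.spacer_max + 1):
        if (n - spacer_len) % 2 != 0:
            continue
        a = (n - spacer_len) // 2
        if a < arm_floor:
            continue
        if s[:a] == reverse_complement(s[n - a:]):
            out.append((a, spacer_len))
    return out


def scan_inverted_repeats(seq: str, chrom: str, config: SearchConfig | None = None) -> list[SIRRecord]:
    """Scan one chromosome for inverted repeats and canonicalise per locus.

    Raw hits are all windows ``arm + spacer + revcomp(arm)`` with perfect arm
    complementarity and lengths within the configured ranges.  Candidates that
    span the identical ``[start, end)`` extent are collapsed to the most
    stable hairpin category: the smallest spacer >= ``spacer_min`` (hence the
    longest arm).  Windows containing N are never emitted.  Output is sorted
    by (start, end); pure-AT filtering and overlap resolution are separate
    steps.
    """
    config = config or SearchConfig()
    s = normalize(seq)
    L = len(s)
    if L < config.min_total_length:
        return []
    code = encode(s)
    compc = COMP_CODE[code]
    n_prefix = np.concatenate([[0], np.cumsum(code == 4)])

    # best (longest) matching arm per extent [i, i+total)
    best: dict[tuple[int, int], int] = {}
    for spacer_len in range(config.spacer_min, config.spacer_max + 1):
        prev: np.ndarray | None = None
        for a in range(1, config.arm_max + 1):
            d = 2 * a + spacer_len - 1  # outermost pair distance
            n = L - d
            if n <= 0:
                break
            pair = code[:n] == compc[d:]
            f = pair if prev is None else (pair & prev[1 : n + 1])
            prev = f
            if a < config.arm_min:
                continue
            total = 2 * a + spacer_len
            for i in np.flatnonzero(f):
                i = int(i)
                if n_prefix[i + total] - n_prefix[i] > 0:
                    continue  # N inside the window (spacer; arms auto-fail)
                key = (i, i + total)
                if best.get(key, 0) < a:
                    best[key] = a

    records = [
        SIRRecord(
            chrom=chrom,
            start=start,
            end=end,
            arm_len=a,
            spacer_len=end - start - 2 * a,
            left_arm=s[start : start + a],
            spacer=s[start + a : end - a],
        )
        for (start, end), a in best.items()
    ]
    records.sort(key=lambda r: (r.start, r.end))
    return records


def filter_pure_at(sirs: Iterable[SIRRecord]) -> list[SIRRecord]:
    """Drop records whose spacer contains no C or G; order preserved."""
    return [r for r in sirs if not r.is_pure_at_spacer]


def resolve_overlaps(sirs: Sequence[SIRRecord]) -> list[SIRRecord]:
    """Greedily keep the longest SIR among overlapping ones.

    Candidates are visited by descending total length (ties: smaller start,
    then smaller spacer length) and kept when disjoint from everything already
    kept.  The result is pairwise non-overlapping, sorted by coordinate.
    """
    import bisect

    ordered = sorted(sirs, key=lambda r: (-(r.length), r.start, r.spacer_len))
    kept: list[SIRRecord] = []
    # per-chromosome sorted, pairwise-disjoint kept intervals
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for r in ordered:
        ss = starts.setdefault(r.chrom, [])
        ee = ends.setdefault(r.chrom, [])
        i = bisect.bisect_right(ss, r.start) - 1
        if i >= 0 and ee[i] > r.start:
            continue  # overlaps a kept interval starting at or before r.start
        if i + 1 < len(ss) and ss[i + 1] < r.end:
            continue  # overlaps the next kept interval
        ss.insert(i + 1, r.start)
        ee.insert(i + 1, r.end)
        kept.append(r)
    kept.sort(key=lambda r: (r.chrom, r.start, r.end))
    return kept


def find_sirs(seq: str, chrom: str, config: SearchConfig | None = None) -> list[SIRRecord]:
    """Full per-chromosome pipeline: scan -> canonicalise -> pure-AT filter ->
    overlap resolution."""
    config = config or SearchConfig()
    records = scan_inverted_repeats(seq, chrom, config)
    if config.drop_pure_at:
        records = filter_pure_at(records)
    return resolve_overlaps(records)


def find_sirs_genome(genome: dict[str, str], config: SearchConfig | None = None) -> list[SIRRecord]:
    out: list[SIRRecord] = []
    for chrom in genome:  # FASTA order preserved
        out.extend(find_sirs(genome[chrom], chrom, config))
    return out


def domain_intervals(sir: SIRRecord, control_width: int, chrom_length: int) -> DomainIntervals:
    """Spacer, arm and flanking-control intervals of one SIR.

    Controls are ``control_width`` bp immediately up- and downstream,
    truncated at the chromosome boundaries.
    """
    if control_width <= 0:
        raise ValueError("control_width must be positive")
    spacer = (sir.spacer_start, sir.spacer_end)
    arms = ((sir.start, sir.spacer_start), (sir.spacer_end, sir.end))
    up = (max(0, sir.start - control_width), sir.start)
    down = (sir.end, min(chrom_length, sir.end + control_width))
    controls = tuple(iv for iv in (up, down) if iv[1] > iv[0])
    return DomainIntervals(spacer=spacer, arms=arms, controls=controls)


# ---------------------------------------------------------------------------
# serialisation

SIR_COLUMNS = [
    "chrom",
    "start_1based",
    "end_1based",
    "arm_len",
    "spacer_len",
    "left_arm",
    "spacer",
    "gc_spacer",
    "gc_arm",
]


def sirs_to_frame(sirs: Sequence[SIRRecord]) -> pd.DataFrame:
    """SIR table with 1-based inclusive coordinates (the reporting convention)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in sirs],
            "start_1based": [r.start + 1 for r in sirs],
            "end_1based": [r.end for r in sirs],
            "arm_len": [r.arm_len for r in sirs],
            "spacer_len": [r.spacer_len for r in sirs],
            "left_arm": [r.left_arm for r in sirs],
            "spacer": [r.spacer for r in sirs],
            "gc_spacer": [gc_content(r.spacer) for r in sirs],
            "gc_arm": [gc_content(r.left_arm) for r in sirs],
        },
        columns=SIR_COLUMNS,
    )


def frame_to_sirs(frame: pd.DataFrame) -> list[SIRRecord]:
    return [
        SIRRecord(
            chrom=str(row.chrom),
            start=int(row.start_1based) - 1,
            end=int(row.end_1based),
            arm_len=int(row.arm_len),
            spacer_len=int(row.spacer_len),
            left_arm=str(row.left_arm),
            spacer=str(row.spacer),
        )
        for row in frame.itertuples(index=False)
    ]


def write_sirs_tsv(sirs: Sequence[SIRRecord], path) -> None:
    sirs_to_frame(sirs).to_csv(path, sep="\t", index=False)


def read_sirs_tsv(path) -> list[SIRRecord]:
    return frame_to_sirs(pd.read_csv(path, sep="\t"))


def write_sirs_bed(sirs: Sequence[SIRRecord], path) -> None:
    """BED6: 0-based half-open, name = spacer sequence, score = arm length."""
    with open(path, "w") as fh:
        for r in sirs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.spacer}\t{r.arm_len}\t+\n")
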