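"""Mapping somatic variants onto SIR domains and density summaries.

Every variant is reduced to a single genomic point (substitution: the mutated
base; indel: the first affected base after the VCF-style anchor; rearrangement:
the breakpoint position) and labelled ``spacer`` / ``arm`` / ``control`` /
``outside`` by containment.  Control windows flank each SIR by 100 bp for
substitutions and indels, 1000 bp for rearrangement breakpoints; control bases
falling inside another SIR keep that SIR's domain label.

Densities are cohort densities: mutations per bp per sample, reported per Mb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import SearchConfig, SIRRecord
from .sequence import reverse_complement

VAR_CLASSES = ("substitution", "indel", "rearrangement_breakpoint")

MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "var_class", "signature"]

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_PY_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class SubstitutionClass:
    """Pyrimidine-strand substitution class.

    ``six`` is one of C>A/C>G/C>T/T>A/T>C/T>G; ``context`` the pyrimidine-
    strand trinucleotide (None when a flank is N); ``label96`` the 96-class
    label such as ``T[C>T]A``.
    """

    six: str
    context: str | None

    @property
    def label96(self) -> str | None:
        if self.context is None:
            return None
        return f"{self.context[0]}[{self.six}]{self.context[2]}"


def classify_substitution(ref: str, alt: str, fivep: str = "N", threep: str = "N") -> SubstitutionClass:
    """Classify a single-base substitution on the pyrimidine strand.

    Purine reference bases are complemented (and the flanks swapped) so the
    mutated base is reported as C or T.
    """
    ref, alt, fivep, threep = ref.upper(), alt.upper(), fivep.upper(), threep.upper()
    if ref == alt or len(ref) != 1 or len(alt) != 1:
        raise ValueError("substitution requires single, distinct ref and alt bases")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError("N is not a valid ref/alt base")
    if ref in "GA":
        ref, alt = _PY_COMP[ref], _PY_COMP[alt]
        fivep, threep = _PY_COMP.get(threep, "N"), _PY_COMP.get(fivep, "N")
    context = None if "N" in (fivep, threep) else f"{fivep}{ref}{threep}"
    return SubstitutionClass(six=f"{ref}>{alt}", context=context)


def mutations_frame(records: Sequence[Mapping]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=MUTATION_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    return df


def read_variants_tsv(path) -> pd.DataFrame:
    """Read a variant table: sample, chrom, pos (1-based), ref, alt[, var_class[, signature]].

    ``var_class`` defaults to substitution/indel inferred from allele lengths.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if "var_class" not in df.columns:
        df["var_class"] = np.where(
            (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1), "substitution", "indel"
        )
    if "signature" not in df.columns:
        df["signature"] = pd.NA
    bad = ~df["var_class"].isin(VAR_CLASSES)
    if bad.any():
        raise ValueError(f"unknown var_class values: {sorted(df.loc[bad, 'var_class'].unique())}")
    return df[MUTATION_COLUMNS]


def read_variants_vcf(path) -> pd.DataFrame:
    """Read a minimal single-cohort VCF-like file.

    Requires CHROM/POS/REF/ALT columns plus a mandatory SAMPLE column (the
    spec of this dialect carries the sample in-band rather than in genotypes).
    """
    rows = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise ValueError("VCF column header line (#CHROM...) missing")
            rows.append(dict(zip(header, line.split("\t"))))
    df = pd.DataFrame(rows)
    upper = {c.upper(): c for c in df.columns}
    for col in ("CHROM", "POS", "REF", "ALT", "SAMPLE"):
        if col not in upper:
            raise ValueError(f"VCF input missing {col} column")
    out = pd.DataFrame(
        {
            "sample": df[upper["SAMPLE"]],
            "chrom": df[upper["CHROM"]],
            "pos": df[upper["POS"]].astype(int),
            "ref": df[upper["REF"]],
            "alt": df[upper["ALT"]],
        }
    )
    out["var_class"] = np.where(
        (out["ref"].str.len() == 1) & (out["alt"].str.len() == 1), "substitution", "indel"
    )
    out["signature"] = pd.NA
    return out[MUTATION_COLUMNS]


def read_breakpoints_bedpe(path) -> pd.DataFrame:
    """Read rearrangement breakpoints from BEDPE (two records per line).

    Columns: chrom1 start1 end1 chrom2 start2 end2 sample; each breakpoint end
    contributes one rearrangement_breakpoint record at the interval start
    (0-based BEDPE start -> 1-based position start+1).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"malformed BEDPE line {lineno}: expected >=7 columns")
            sample = parts[6]
            for chrom, start in ((parts[0], parts[1]), (parts[3], parts[4])):
                rows.append(
                    (sample, chrom, int(start) + 1, "N", ".", "rearrangement_breakpoint", pd.NA)
                )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def mutation_points(muts: pd.DataFrame) -> np.ndarray:
    """0-based genomic point of each variant.

    Substitutions and breakpoints: ``pos - 1``; indels: the base immediately
    after the anchor, i.e. 0-based ``pos``.
    """
    pos0 = muts["pos"].to_numpy(dtype=np.int64) - 1
    return np.where(muts["var_class"].to_numpy() == "indel", pos0 + 1, pos0)


# ---------------------------------------------------------------------------
# domain assignment


class DomainAssigner:
    """Precomputed per-chromosome SIR interval index for point assignment."""

    def __init__(self, sirs: Sequence[SIRRecord], config: SearchConfig | None = None):
        self.config = config or SearchConfig()
        self.sirs = list(sirs)
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        order: dict[str, list[int]] = {}
        for i, r in enumerate(self.sirs):
            order.setdefault(r.chrom, []).append(i)
        for chrom, idx in order.items():
            idx.sort(key=lambda i: self.sirs[i].start)
            starts = np.array([self.sirs[i].start for i in idx], dtype=np.int64)
            ends = np.array([self.sirs[i].end for i in idx], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError("SIRs must be non-overlapping (run resolve_overlaps first)")
            self._by_chrom[chrom] = {
                "idx": np.array(idx, dtype=np.int64),
                "starts": starts,
                "ends": ends,
                "sp_starts": np.array([self.sirs[i].spacer_start for i in idx], dtype=np.int64),
                "sp_ends": np.array([self.sirs[i].spacer_end for i in idx], dtype=np.int64),
            }

    def assign_points(self, chrom: str, points: np.ndarray, control_width: int) -> tuple[np.ndarray, np.ndarray]:
        """(domain labels, owner SIR indices) for 0-based points on one chromosome.

        Owner is -1 for ``outside``; a point inside two SIRs' control windows
        goes to the nearer SIR (ties: the upstream one).
        """
        labels = np.full(len(points), "outside", dtype=object)
        owner = np.full(len(points), -1, dtype=np.int64)
        tab = self._by_chrom.get(chrom)
        if tab is None or len(points) == 0:
            return labels, owner
        starts, ends = tab["starts"], tab["ends"]
        j = np.searchsorted(starts, points, side="right") - 1
        inside = (j >= 0) & (points < ends[np.maximum(j, 0)])
        ji = j[inside]
        pin = points[inside]
        in_spacer = (pin >= tab["sp_starts"][ji]) & (pin < tab["sp_ends"][ji])
        labels[inside] = np.where(in_spacer, "spacer", "arm")
        owner[inside] = tab["idx"][ji]

        out = ~inside
        if out.any():
            p = points[out]
            jo = j[out]
            prev_ok = jo >= 0
            dist_prev = np.where(prev_ok, p - np.where(prev_ok, ends[np.maximum(jo, 0)], 0) + 1, np.iinfo(np.int64).max)
            nxt = jo + 1
            next_ok = nxt < len(starts)
            dist_next = np.where(next_ok, np.where(next_ok, starts[np.minimum(nxt, len(starts) - 1)], 0) - p, np.iinfo(np.int64).max)
            in_prev = prev_ok & (dist_prev <= control_width)
            in_next = next_ok & (dist_next <= control_width)
            use_prev = in_prev & (~in_next | (dist_prev <= dist_next))
            use_next = in_next & ~use_prev
            lab = np.where(in_prev | in_next, "control", "outside")
            own = np.full(len(p), -1, dtype=np.int64)
            own[use_prev] = tab["idx"][jo[use_prev]]
            own[use_next] = tab["idx"][nxt[use_next]]
            labels[out] = lab
            owner[out] = own
        return labels, owner

    # -- per-SIR interval bookkeeping ------------------------------------

    def control_subintervals(self, sir_index: int, control_width: int, chrom_length: int | None) -> list[tuple[int, int]]:
        """Control windows of one SIR, clipped at chromosome bounds and with
        every other SIR's body removed."""
        r = self.sirs[sir_index]
        L = chrom_length if chrom_length is not None else np.iinfo(np.int64).max
        windows = [
            (max(0, r.start - control_width), r.start),
            (r.end, min(L, r.end + control_width)),
        ]
        tab = self._by_chrom[r.chrom]
        starts, ends = tab["starts"], tab["ends"]
        out: list[tuple[int, int]] = []
        for ws, we in windows:
            if we <= ws:
                continue
            cur = ws
            k = int(np.searchsorted(ends, ws, side="right"))
            while cur < we:
                if k < len(starts) and starts[k] < we:
                    if starts[k] > cur:
                        out.append((cur, int(starts[k])))
                    cur = int(ends[k])
                    k += 1
                else:
                    out.append((cur, we))
                    break
        return [(s, e) for s, e in out if e > s]


def assign_to_domains(
    muts: pd.DataFrame,
    sirs: Sequence[SIRRecord],
    config: SearchConfig | None = None,
) -> pd.DataFrame:
    """Per-mutation domain labels and owning SIR index.

    Returns a frame aligned with ``muts`` with columns ``point`` (0-based),
    ``domain`` and ``sir_index``.  Mutations on chromosomes without any SIR
    are labelled ``outside``; unknown chromosomes additionally warn.
    """
    config = config or SearchConfig()
    assigner = DomainAssigner(sirs, config)
    points = mutation_points(muts)
    domain = np.full(len(muts), "outside", dtype=object)
    owner = np.full(len(muts), -1, dtype=np.int64)
    known = set(assigner._by_chrom)
    chroms = muts["chrom"].to_numpy()
    var_class = muts["var_class"].to_numpy()
    for chrom in pd.unique(chroms):
        if chrom not in known:
            warnings.warn(f"mutations on chromosome {chrom!r} match no SIR chromosome; labelled outside")
            continue
        for vc in VAR_CLASSES:
            mask = (chroms == chrom) & (var_class == vc)
            if not mask.any():
                continue
            lab, own = assigner.assign_points(chrom, points[mask], config.control_width(vc))
            domain[mask] = lab
            owner[mask] = own
    return pd.DataFrame({"point": points, "domain": domain, "sir_index": owner}, index=muts.index)


# ---------------------------------------------------------------------------
# effective lengths and densities


def _non_n_length(genome: Mapping[str, str] | None, chrom: str, start: int, end: int) -> int:
    if end <= start:
        return 0
    if genome is None:
        return end - start
    seg = genome[chrom][start:end].upper()
    return len(seg) - seg.count("N")


def effective_domain_lengths(
    sirs: Sequence[SIRRecord],
    config: SearchConfig | None = None,
    genome: Mapping[str, str] | None = None,
    var_class: str = "substitution",
) -> dict[str, int]:
    """Total non-N bp per domain; overlapping control windows counted once."""
    config = config or SearchConfig()
    cw = config.control_width(var_class)
    chrom_lengths = {c: len(s) for c, s in genome.items()} if genome is not None else {}
    spacer = sum(_non_n_length(genome, r.chrom, r.spacer_start, r.spacer_end) for r in sirs)
    arm = sum(
        _non_n_length(genome, r.chrom, r.start, r.spacer_start)
        + _non_n_length(genome, r.chrom, r.spacer_end, r.end)
        for r in sirs
    )
    from .context import merge_intervals

    control = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    bodies: dict[str, list[tuple[int, int]]] = {}
    for r in sirs:
        L = chrom_lengths.get(r.chrom)
        hi = L if L is not None else None
        up = (max(0, r.start - cw), r.start)
        down = (r.end, r.end + cw if hi is None else min(hi, r.end + cw))
        by_chrom.setdefault(r.chrom, []).extend([up, down])
        bodies.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, windows in by_chrom.items():
        merged = merge_intervals([w for w in windows if w[1] > w[0]])
        body = merge_intervals(bodies[chrom])
        for ws, we in merged:
            cur = ws
            for bs, be in body:
                if be <= cur or bs >= we:
                    continue
                if bs > cur:
                    control += _non_n_length(genome, chrom, cur, min(bs, we))
                cur = max(cur, be)
            if cur < we:
                control += _non_n_length(genome, chrom, cur, we)
    return {"spacer": spacer, "arm": arm, "control": control}


def domain_density(
    assignment: pd.DataFrame,
    muts: pd.DataFrame,
    sirs: Sequence[SIRRecord],
    n_samples: int,
    config: SearchConfig | None = None,
    genome: Mapping[str, str] | None = None,
    var_classes: Sequence[str] = ("substitution",),
    by: pd.Series | None = None,
) -> pd.DataFrame:
    """Cohort mutation density per domain (mutations per Mb per sample).

    ``by`` optionally stratifies counts (e.g. six-class labels or signature
    labels); effective lengths are shared across strata.  Densities are
    ``count / (effective_length * n_samples) * 1e6``; NaN when the effective
    length is zero.
    """
    config = config or SearchConfig()
    in_scope = muts["var_class"].isin(var_classes).to_numpy()
    lengths = effective_domain_lengths(sirs, config, genome, var_class=var_classes[0])
    rows = []
    strata = [None] if by is None else list(pd.unique(by[in_scope].dropna()))
    for stratum in strata:
        sel = in_scope if stratum is None else (in_scope & (by == stratum).to_numpy())
        dom = assignment.loc[sel, "domain"]
        for domain in ("spacer", "arm", "control"):
            n = int((dom == domain).sum())
            eff = lengths[domain]
            density = np.nan if eff == 0 else n / (eff * n_samples) * 1e6
            rows.append(
                {
                    "stratum": stratum,
                    "domain": domain,
                    "n_mutations": n,
                    "effective_length": eff,
                    "n_samples": n_samples,
                    "density_per_mb": density,
                }
            )
    out = pd.DataFrame(rows)
    return out.drop(columns="stratum") if by is None else out


def per_sir_counts(
    muts: pd.DataFrame,
    sirs: Sequence[SIRRecord],
    config: SearchConfig | None = None,
    genome: Mapping[str, str] | None = None,
    var_classes: Sequence[str] = ("substitution",),
) -> pd.DataFrame:
    """Per-SIR spacer/arm/control mutation counts and effective lengths.

    Control windows are clipped at chromosome boundaries and exclude every
    SIR body; mutations in the overlap of two SIRs' control windows count for
    both SIRs here (per-SIR testing convention).
    """
    config = config or SearchConfig()
    cw = config.control_width(var_classes[0])
    assigner = DomainAssigner(sirs, config)
    chrom_lengths = {c: len(s) for c, s in genome.items()} if genome is not None else {}
    sel = muts["var_class"].isin(var_classes).to_numpy()
    points_by_chrom: dict[str, np.ndarray] = {}
    pts = mutation_points(muts)
    for chrom in pd.unique(muts["chrom"].to_numpy()):
        mask = sel & (muts["chrom"].to_numpy() == chrom)
        points_by_chrom[chrom] = np.sort(pts[mask])

    def count_in(chrom: str, start: int, end: int) -> int:
        p = points_by_chrom.get(chrom)
        if p is None:
            return 0
        return int(np.searchsorted(p, end, side="left") - np.searchsorted(p, start, side="left"))

    rows = []
    for i, r in enumerate(sirs):
        ctrl = assigner.control_subintervals(i, cw, chrom_lengths.get(r.chrom))
        rows.append(
            {
                "sir_index": i,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "spacer_len": r.spacer_len,
                "arm_len": r.arm_len,
                "spacer": r.spacer,
                "n_spacer": count_in(r.chrom, r.spacer_start, r.spacer_end),
                "n_arm": count_in(r.chrom, r.start, r.spacer_start)
                + count_in(r.chrom, r.spacer_end, r.end),
                "n_control": sum(count_in(r.chrom, s, e) for s, e in ctrl),
                "len_spacer": _non_n_length(genome, r.chrom, r.spacer_start, r.spacer_end),
                "len_arm": _non_n_length(genome, r.chrom, r.start, r.spacer_start)
                + _non_n_length(genome, r.chrom, r.spacer_end, r.end),
                "len_control": sum(_non_n_length(genome, r.chrom, s, e) for s, e in ctrl),
            }
        )
    return pd.DataFrame(rows)


def density_by_geometry(per_sir: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    """Mean and SD of per-SIR densities per (spacer_len, arm_len) group.

    SIRs are partitioned into the spacer-length x arm-length categories; for
    each group and each domain the mean of per-SIR densities (per Mb per
    sample) and the standard deviation across SIRs are reported.
    """
    df = per_sir.copy()
    for dom in ("spacer", "arm", "control"):
        lens = df[f"len_{dom}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            df[f"density_{dom}"] = np.where(
                lens > 0, df[f"n_{dom}"] / (lens * n_samples) * 1e6, np.nan
            )
    agg = df.groupby(["spacer_len", "arm_len"]).agg(
        n_sirs=("sir_index", "size"),
        **{
            f"{stat}_{dom}": (f"density_{dom}", stat)
            for dom in ("spacer", "arm", "control")
            for stat in ("mean", "std")
        },
    )
    return agg.reset_index()


def distance_profile(
    muts: pd.DataFrame,
    sirs: Sequence[SIRRecord],
    half_window: int,
    chrom_lengths: Mapping[str, int] | None = None,
    var_classes: Sequence[str] = ("substitution",),
) -> pd.DataFrame:
    """Mutation likelihood vs signed distance to the SIR centre.

    The centre is the spacer midpoint (left-of-middle for even loops).  For
    each offset in [-half_window, half_window] the mutation count at that
    offset, pooled over SIRs, is divided by the number of SIRs whose offset
    position lies within the chromosome.
    """
    offsets = np.arange(-half_window, half_window + 1)
    counts = np.zeros(len(offsets), dtype=np.int64)
    avail = np.zeros(len(offsets), dtype=np.int64)
    pts = mutation_points(muts)
    sel = muts["var_class"].isin(var_classes).to_numpy()
    by_chrom = {
        chrom: np.sort(pts[sel & (muts["chrom"].to_numpy() == chrom)])
        for chrom in pd.unique(muts["chrom"].to_numpy())
    }
    for r in sirs:
        c = r.center
        L = chrom_lengths.get(r.chrom) if chrom_lengths is not None else None
        lo = c - half_window
        hi = c + half_window
        valid_lo = max(lo, 0)
        valid_hi = hi if L is None else min(hi, L - 1)
        avail[valid_lo - lo : valid_hi - lo + 1] += 1
        p = by_chrom.get(r.chrom)
        if p is None:
            continue
        for q in p[np.searchsorted(p, lo) : np.searchsorted(p, hi, side="right")]:
            counts[q - lo] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        likelihood = np.where(avail > 0, counts / avail, np.nan)
    return pd.DataFrame({"offset": offsets, "count": counts, "n_sirs": avail, "likelihood": likelihood})
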