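"""Synthetic genomes and mutation catalogs with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
random-base chromosome at a target GC content with planted SIRs at well
separated loci; a cohort of samples placing mutations independently per
position-sample unit at a uniform background density; a multiplicative
mutability fold on hairpin-loop (spacer) positions; optional hotspot spacers
with their own folds; and per-sample mutational phenotypes (APOBEC-like
TCN-context C>T/C>G bias, MSI-like 1-bp indels at A/T runs, or flat).

Everything is driven by one seed: per-sample substreams are derived by
counter, so adding samples never perturbs earlier ones, and identical
config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import SearchConfig, SIRRecord, find_sirs
from .mutations import MUTATION_COLUMNS
from .sequence import decode, is_pure_at, reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the published cohort's regime at desk scale: the spacer
    fold matches the reported ~1.35x loop mutability, and the per-sample
    background density is inflated so that cohort position-sample coverage of
    each SIR (spacer bp x samples x density) is comparable to a 560-genome
    cohort despite the much smaller genome.
    """

    seed: int = 0
    chrom_length: int = 200_000
    gc_target: float = 0.41
    n_planted_sirs: int = 200
    planted_spacer_lens: tuple[int, ...] = (4, 5, 6, 7, 8)
    planted_arm_lens: tuple[int, ...] = (6, 8, 10, 12, 15, 20, 25)
    n_samples: int = 100
    background_density: float = 2e-3  # mutations per bp per sample
    spacer_fold: float = 1.35
    hotspot_spec: tuple[tuple[str, float, int], ...] = ()
    signature_mix: Mapping[str, float] = field(
        default_factory=lambda: {"flat": 1.0, "APOBEC": 0.0, "MSI": 0.0}
    )
    msi_indel_density: float = 2e-3  # per candidate bp per MSI sample
    rearrangement_density: float = 0.0
    chrom_name: str = "chrSim"
    allow_pure_at_spacers: bool = False

    def sample_classes(self) -> list[str]:
        """Deterministic per-sample generator classes honouring the mix."""
        keys = [k for k in ("APOBEC", "MSI", "flat") if self.signature_mix.get(k, 0.0) > 0]
        total = sum(self.signature_mix[k] for k in keys)
        counts = {k: int(round(self.signature_mix[k] / total * self.n_samples)) for k in keys}
        while sum(counts.values()) > self.n_samples:
            counts[max(counts, key=counts.get)] -= 1
        while sum(counts.values()) < self.n_samples:
            counts[keys[0]] += 1
        out: list[str] = []
        for k in keys:
            out.extend([k] * counts[k])
        return out[: self.n_samples]


@dataclass
class TruthManifest:
    """Ground truth of one simulation, JSON round-trippable."""

    planted: list[dict]
    sample_classes: dict[str, str]
    spacer_intervals: list[list] = field(default_factory=list)  # [chrom, start, end, fold]
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def planted_records(self) -> list[SIRRecord]:
        return [
            SIRRecord(
                chrom=p["chrom"],
                start=p["start"],
                end=p["end"],
                arm_len=p["arm_len"],
                spacer_len=p["spacer_len"],
                left_arm=p["left_arm"],
                spacer=p["spacer"],
            )
            for p in self.planted
        ]


def _sample_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _draw_spacer(rng: np.random.Generator, s: int, require_cg: bool, spacer_min: int) -> str:
    """Random planted spacer.

    When ``require_cg`` the spacer gets at least one C/G (the pure-AT filter
    would otherwise drop the planted SIR).  When the loop is long enough that
    the scanner could re-canonicalise it (s >= spacer_min + 2), spacers whose
    outer bases base-pair are redrawn — such a loop would fold two bases into
    the stem and the planted category would not be recovered as planted.
    """
    while True:
        sp = "".join(rng.choice(list(_BASES), size=s))
        if require_cg and is_pure_at(sp):
            pos = int(rng.integers(1, s - 1)) if s >= 3 else int(rng.integers(0, s))
            sp = sp[:pos] + str(rng.choice(["C", "G"])) + sp[pos + 1 :]
        if s >= spacer_min + 2 and sp[0] == _PAIR[sp[-1]]:
            continue
        return sp


def generate_genome(
    config: SimulationConfig,
    search_config: SearchConfig | None = None,
) -> tuple[dict[str, str], TruthManifest]:
    """Random chromosome with planted SIRs and unambiguous ground truth.

    Planted loci are evenly spaced with jitter, pairwise separated by more
    than twice the control width.  After planting, the chromosome is screened:
    any scanner-detected SIR that lies within one control width of a planted
    locus but is not exactly the planted record has one of its non-planted
    bases redrawn, until the neighbourhood of every planted SIR is clean.
    """
    sc = search_config or SearchConfig()
    rng = _sample_rng(config.seed, 0)
    cw = sc.control_width_sub_indel
    gc = config.gc_target
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    plants: list[tuple[int, int, str | None, float]] = []  # (arm_len, spacer_len, spacer_seq, fold)
    for _ in range(config.n_planted_sirs):
        a = int(rng.choice(config.planted_arm_lens))
        s = int(rng.choice(config.planted_spacer_lens))
        plants.append((a, s, None, config.spacer_fold))
    for spacer_seq, fold, n_loc in config.hotspot_spec:
        for _ in range(n_loc):
            a = int(rng.choice(config.planted_arm_lens))
            plants.append((a, len(spacer_seq), spacer_seq, float(fold)))

    n_plants = len(plants)
    max_len = 2 * max(config.planted_arm_lens) + max(
        [max(config.planted_spacer_lens)] + [len(h[0]) for h in config.hotspot_spec]
    )
    slot = config.chrom_length // (n_plants + 1) if n_plants else config.chrom_length
    need = max_len + 2 * cw + 10
    if n_plants and slot < need:
        raise ValueError(
            f"chrom_length too small for {n_plants} planted SIRs: need >= {(n_plants + 1) * need}"
        )

    codes = rng.choice(4, size=config.chrom_length, p=probs).astype(np.uint8)
    seq = list(decode(codes))

    planted_records: list[SIRRecord] = []
    for k, (a, s, spacer_seq, fold) in enumerate(plants):
        base = (k + 1) * slot
        jitter = int(rng.integers(-slot // 8, slot // 8 + 1)) if slot >= 16 else 0
        start = base + jitter
        if spacer_seq is None:
            require_cg = sc.drop_pure_at and not config.allow_pure_at_spacers
            spacer = _draw_spacer(rng, s, require_cg, sc.spacer_min)
        else:
            spacer = spacer_seq.upper()
            if len(spacer) >= sc.spacer_min + 2 and spacer[0] == _PAIR.get(spacer[-1]):
                raise ValueError(
                    f"hotspot spacer {spacer!r} would re-canonicalise (outer bases pair)"
                )
        arm = "".join(rng.choice(list(_BASES), size=a))
        ir = arm + spacer + reverse_complement(arm)
        seq[start : start + len(ir)] = list(ir)
        planted_records.append(
            SIRRecord(
                chrom=config.chrom_name,
                start=start,
                end=start + len(ir),
                arm_len=a,
                spacer_len=len(spacer),
                left_arm=arm,
                spacer=spacer,
            )
        )

    # screen: planted neighbourhoods must contain exactly the planted SIRs
    planted_set = {
        (r.start, r.end, r.arm_len): r for r in planted_records
    }
    zones = [(r.start - cw, r.end + cw) for r in planted_records]
    zones.sort()
    planted_spans = sorted((r.start, r.end) for r in planted_records)

    def in_zone(start: int, end: int) -> bool:
        import bisect

        i = bisect.bisect_right([z[0] for z in zones], end) - 1
        return i >= 0 and zones[i][1] > start

    def in_planted(pos: int) -> bool:
        import bisect

        i = bisect.bisect_right([z[0] for z in planted_spans], pos) - 1
        return i >= 0 and planted_spans[i][1] > pos

    for _ in range(200):
        chrom_seq = "".join(seq)
        detected = find_sirs(chrom_seq, config.chrom_name, sc)
        offenders = [
            d
            for d in detected
            if in_zone(d.start, d.end) and (d.start, d.end, d.arm_len) not in planted_set
        ]
        # planted records removed by the scan's own pure-AT filter cannot be required
        required = {
            k
            for k, r in planted_set.items()
            if not (sc.drop_pure_at and is_pure_at(r.spacer))
        }
        missing = required - {(d.start, d.end, d.arm_len) for d in detected}
        if not offenders and not missing:
            break
        if not offenders:
            raise RuntimeError("planted SIR lost without an offending overlap; seed unusable")
        for d in offenders:
            candidates = [p for p in range(d.start, d.end) if not in_planted(p)]
            if not candidates:
                continue
            pos = candidates[int(rng.integers(0, len(candidates)))]
            old = seq[pos]
            choices = [b for b in _BASES if b != old]
            seq[pos] = str(rng.choice(choices))
    else:
        raise RuntimeError("could not screen background IRs near planted loci in 200 rounds")

    genome = {config.chrom_name: "".join(seq)}
    manifest = TruthManifest(
        planted=[
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "arm_len": r.arm_len,
                "spacer_len": r.spacer_len,
                "left_arm": r.left_arm,
                "spacer": r.spacer,
                "fold": plants[i][3],
                "is_hotspot": plants[i][2] is not None,
            }
            for i, r in enumerate(planted_records)
        ],
        sample_classes={f"S{i:04d}": c for i, c in enumerate(config.sample_classes())},
        config=dataclasses.asdict(config) | {"signature_mix": dict(config.signature_mix)},
    )
    return genome, manifest


def _homopolymer_at_runs(seq: str, min_run: int = 4) -> np.ndarray:
    """Boolean mask of positions inside A or T homopolymer runs of >= min_run."""
    mask = np.zeros(len(seq), dtype=bool)
    i = 0
    while i < len(seq):
        b = seq[i]
        j = i
        while j < len(seq) and seq[j] == b:
            j += 1
        if b in "AT" and j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def generate_mutations(
    config: SimulationConfig,
    genome: Mapping[str, str],
    truth: TruthManifest,
    search_config: SearchConfig | None = None,
) -> pd.DataFrame:
    """Mutation catalog for the synthetic cohort.

    The spacer fold applies to the spacer positions of every SIR detectable in
    the genome (hairpin-loop hypermutability is a property of the structure,
    not of how the locus arose); hotspot folds override on their planted
    spacers.  APOBEC-like samples place 80% of their substitution budget on
    TpC (and complementary GpA) context positions as C>T (2/3) or C>G (1/3);
    MSI-like samples add 1-bp slippage indels at A/T homopolymer runs and at
    AT-rich spacers; flat samples are uniform.
    """
    sc = search_config or SearchConfig()
    chrom = config.chrom_name
    seq = genome[chrom]
    L = len(seq)
    d = config.background_density

    detected = find_sirs(seq, chrom, sc)
    fold = np.ones(L, dtype=float)
    for r in detected:
        fold[r.spacer_start : r.spacer_end] = config.spacer_fold
    hotspot_folds = {
        (p["start"], p["end"]): p["fold"] for p in truth.planted if p["is_hotspot"]
    }
    for p in truth.planted:
        if p["is_hotspot"]:
            a = p["arm_len"]
            fold[p["start"] + a : p["end"] - a] = p["fold"]
    truth.spacer_intervals = [
        [chrom, r.spacer_start, r.spacer_end, float(fold[r.spacer_start])] for r in detected
    ]

    if float(np.max(fold)) * d >= 1.0:
        raise ValueError("fold * background_density >= 1: expected mutations exceed positions")

    base = np.array(list(seq))
    acgt = base != "N"
    is_c, is_g = base == "C", base == "G"
    tcn = np.zeros(L, dtype=bool)
    tcn[1:] = is_c[1:] & (base[:-1] == "T")
    nga = np.zeros(L, dtype=bool)
    nga[:-1] = is_g[:-1] & (base[1:] == "A")
    apobec_ctx = (tcn | nga) & acgt
    n_ctx = int(apobec_ctx.sum())
    at_runs = _homopolymer_at_runs(seq)
    at_spacer = np.zeros(L, dtype=bool)
    for r in detected:
        sp = r.spacer
        gc = (sp.count("G") + sp.count("C")) / max(1, len(sp))
        if gc <= 0.25:
            at_spacer[r.spacer_start : r.spacer_end] = True
    indel_candidates = (at_runs | at_spacer) & acgt

    classes = config.sample_classes()
    rows: list[tuple] = []
    code_of = {b: i for i, b in enumerate(_BASES)}
    base_code = np.array([code_of.get(b, 0) for b in base], dtype=np.int8)
    for si, cls in enumerate(classes):
        sample = f"S{si:04d}"
        rng = _sample_rng(config.seed, 1000 + si)
        rate = d * fold
        if cls == "APOBEC":
            # keep total budget ~ L*d; 80% concentrated on TpC/GpA context
            bg = 0.2 * L * d / max(1, L - n_ctx)
            ctx = 0.8 * L * d / max(1, n_ctx)
            rate = np.where(apobec_ctx, ctx, bg) * fold
        u = rng.random(L)
        hit_pos = np.flatnonzero((u < rate) & acgt)
        # vectorised alt draw: one of the three non-ref bases
        alt_code = (base_code[hit_pos] + 1 + rng.integers(0, 3, size=len(hit_pos))) % 4
        transitions = rng.random(len(hit_pos)) < 2 / 3
        ap_sigs = np.where(rng.random(len(hit_pos)) < 0.5, "2", "13")
        for k, p in enumerate(hit_pos):
            p = int(p)
            ref = base[p]
            if cls == "APOBEC" and apobec_ctx[p]:
                if ref == "C":
                    alt = "T" if transitions[k] else "G"
                else:
                    alt = "A" if transitions[k] else "C"
                sig = str(ap_sigs[k])
            else:
                alt = _BASES[alt_code[k]]
                sig = {"flat": "5", "MSI": "6", "APOBEC": "5"}[cls]
            rows.append((sample, chrom, p + 1, ref, alt, "substitution", sig))
        if cls == "MSI":
            ui = rng.random(L)
            ipos = np.flatnonzero((ui < config.msi_indel_density) & indel_candidates)
            deletions = rng.random(len(ipos)) < 0.5
            msi_sigs = np.asarray(["6", "20", "26"])[rng.integers(0, 3, size=len(ipos))]
            for k, p in enumerate(ipos):
                p = int(p)
                if p < 1:
                    continue
                anchor = base[p - 1]
                if deletions[k]:
                    ref, alt = anchor + base[p], anchor  # 1-bp deletion
                else:
                    ref, alt = anchor, anchor + base[p]  # 1-bp slippage insertion
                rows.append((sample, chrom, p, ref, alt, "indel", str(msi_sigs[k])))
        if config.rearrangement_density > 0:
            ur = rng.random(L)
            for p in np.flatnonzero((ur < config.rearrangement_density) & acgt):
                p = int(p)
                rows.append((sample, chrom, p + 1, base[p], ".", "rearrangement_breakpoint", pd.NA))

    muts = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    return muts.sort_values(["sample", "chrom", "pos"], kind="stable").reset_index(drop=True)


def generate_exposures(
    sample_classes: Mapping[str, str],
    seed: int = 0,
    noise: float = 0.02,
) -> pd.DataFrame:
    """Per-sample exposure proportions over the 12 signatures.

    Archetypes: APOBEC mass on signatures 2/13, MSI on 6/20/26, BRCA on 3,
    flat on 1/5, APOBEC+MSI split between both groups; small Dirichlet-style
    noise on the remaining signatures.
    """
    from .classify import SIGNATURES_12

    rng = np.random.default_rng([seed, 7])
    arche = {
        "APOBEC": {"2": 0.45, "13": 0.35},
        "MSI": {"6": 0.35, "20": 0.25, "26": 0.2},
        "APOBEC+MSI": {"2": 0.25, "13": 0.2, "6": 0.2, "20": 0.15},
        "BRCA": {"3": 0.7},
        "flat": {"1": 0.4, "5": 0.4},
        "Others": {"1": 0.4, "5": 0.4},
    }
    rows = {}
    for sample, cls in sample_classes.items():
        vec = np.full(len(SIGNATURES_12), 0.0)
        for sig, w in arche[cls].items():
            vec[SIGNATURES_12.index(sig)] = w
        vec += rng.random(len(vec)) * noise
        rows[sample] = vec / vec.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=SIGNATURES_12)


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
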