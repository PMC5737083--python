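"""Binomial enrichment statistics for SIR spacers.

The null model: spacer positions mutate at the local background rate estimated
from the SIR's own flanking control windows.  For an SIR with ``n`` spacer
mutations over ``L_spacer * n_samples`` position-sample trials and control
density ``d`` (mutations per bp per sample), the one-sided p-value is
``P[X >= n]`` for ``X ~ Binomial(L_spacer * n_samples, d)``.  Benjamini-
Hochberg correction is applied within each tested family; SIRs at adjusted
p <= 0.01 are called highly mutated, overlapping calls are collapsed into
genomic sites, and spacer sequences are additionally tested against identical
sequences not flanked by palindromic arms (SIR hotspots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .detect import SearchConfig, SIRRecord
from .mutations import mutation_points, per_sir_counts
from .sequence import find_occurrences, reverse_complement

logger = logging.getLogger(__name__)

Q_THRESHOLD_DEFAULT = 0.01


@dataclass(frozen=True)
class HotspotSite:
    """One genomic location of highly mutated, overlapping SIRs.

    The longest member SIR (ties: leftmost) represents the site; its spacer
    interval is the site's hotspot interval.
    """

    chrom: str
    start: int
    end: int
    representative: SIRRecord
    members: tuple[SIRRecord, ...]
    fold_vs_non_sir: float = float("nan")

    @property
    def spacer_seq(self) -> str:
        return self.representative.spacer


_SUMMATION_TRIALS_MAX = 100_000


def binomial_spacer_test(
    n_muts_spacer: int,
    spacer_len: int,
    n_samples: int,
    background_density: float,
) -> float:
    """Exact upper-tail binomial p-value ``P[X >= n]``, X ~ Bin(L*n_samples, d).

    For moderate trial counts the tail is summed term by term in log space
    (exact and free of the deep-tail underflow of incomplete-beta routines);
    for larger trials the scipy survival function is used.  Convention:
    ``d == 0`` with observed mutations gives p = 0 (an impossible event under
    the null).
    """
    trials = spacer_len * n_samples
    if not (0.0 <= background_density <= 1.0):
        raise ValueError("background_density must be a probability")
    if n_muts_spacer < 0 or n_muts_spacer > trials:
        raise ValueError("n_muts_spacer must lie in [0, spacer_len * n_samples]")
    if n_muts_spacer == 0:
        return 1.0
    p = background_density
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    if trials > _SUMMATION_TRIALS_MAX:
        return float(binom.sf(n_muts_spacer - 1, trials, p))
    from scipy.special import gammaln

    j = np.arange(n_muts_spacer, trials + 1, dtype=float)
    logpmf = (
        gammaln(trials + 1)
        - gammaln(j + 1)
        - gammaln(trials - j + 1)
        + j * np.log(p)
        + (trials - j) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logpmf).sum()))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_highly_mutated(
    muts: pd.DataFrame,
    sirs: Sequence[SIRRecord],
    n_samples: int,
    config: SearchConfig | None = None,
    genome: Mapping[str, str] | None = None,
    q_threshold: float = Q_THRESHOLD_DEFAULT,
    var_classes: Sequence[str] = ("substitution",),
) -> pd.DataFrame:
    """Per-SIR binomial enrichment over the SIR's own control density.

    Only SIRs with at least one spacer mutation form the tested family; SIRs
    without usable control bases are excluded (logged).  Returns one row per
    tested SIR with counts, background density, p, BH q, fold and the
    highly-mutated flag (q <= ``q_threshold``).
    """
    config = config or SearchConfig()
    counts = per_sir_counts(muts, sirs, config, genome, var_classes=var_classes)
    tested = counts[counts["n_spacer"] >= 1].copy()
    unusable = tested["len_control"] <= 0
    if unusable.any():
        for _, row in tested[unusable].iterrows():
            logger.warning(
                "SIR %s:%d-%d excluded: no usable control bases", row.chrom, row.start, row.end
            )
        tested = tested[~unusable]
    if tested.empty:
        return tested.assign(
            background_density=[], trials=[], fold=[], p_value=[], q_value=[], is_highly_mutated=[]
        )
    tested["background_density"] = tested["n_control"] / (tested["len_control"] * n_samples)
    tested["trials"] = tested["len_spacer"] * n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        spacer_density = tested["n_spacer"] / tested["trials"]
        tested["fold"] = spacer_density / tested["background_density"]
    tested["p_value"] = [
        binomial_spacer_test(int(n), 1, int(t), float(d))
        for n, t, d in zip(tested["n_spacer"], tested["trials"], tested["background_density"])
    ]
    tested["q_value"] = bh_adjust(tested["p_value"].to_numpy())
    tested["is_highly_mutated"] = tested["q_value"] <= q_threshold
    return tested.reset_index(drop=True)


def collapse_to_sites(
    highly_mutated: pd.DataFrame,
    sirs: Sequence[SIRRecord],
) -> list[HotspotSite]:
    """Merge overlapping highly mutated SIRs into genomic sites.

    Sites are the connected components of the interval-overlap graph; the
    longest member (ties: leftmost) is the representative.  Sorted by
    coordinate.
    """
    flagged = highly_mutated[highly_mutated["is_highly_mutated"]]
    members = sorted(
        (sirs[int(i)] for i in flagged["sir_index"]), key=lambda r: (r.chrom, r.start, r.end)
    )
    sites: list[HotspotSite] = []
    group: list[SIRRecord] = []

    def flush() -> None:
        if not group:
            return
        rep = max(group, key=lambda r: (r.length, -r.start))
        sites.append(
            HotspotSite(
                chrom=group[0].chrom,
                start=min(r.start for r in group),
                end=max(r.end for r in group),
                representative=rep,
                members=tuple(group),
            )
        )

    for r in members:
        if group and r.chrom == group[0].chrom and r.start < max(g.end for g in group):
            group.append(r)
        else:
            flush()
            group = [r]
    flush()
    return sites


def _interval_mut_count(points: np.ndarray, intervals: Sequence[tuple[int, int]]) -> int:
    return int(
        sum(
            np.searchsorted(points, e, side="left") - np.searchsorted(points, s, side="left")
            for s, e in intervals
        )
    )


def hotspot_spacer_tests(
    muts: pd.DataFrame,
    sirs: Sequence[SIRRecord],
    genome: Mapping[str, str],
    n_samples: int,
    q_threshold: float = Q_THRESHOLD_DEFAULT,
    var_classes: Sequence[str] = ("substitution",),
    min_spacer_mutations: int = 1,
) -> pd.DataFrame:
    """Test each spacer sequence against identical sequences outside SIRs.

    For every unique spacer sequence (a spacer and its reverse complement are
    the same double-stranded sequence) with at least ``min_spacer_mutations``
    mutations pooled over its in-SIR spacer occurrences, the background is the
    mutation density over all genomic occurrences of the sequence lying wholly
    outside every SIR, and the binomial test compares the pooled in-SIR spacer
    counts against it.  BH correction runs across all tested sequences.
    Sequences without any out-of-SIR occurrence are reported untestable.
    """
    sel = muts["var_class"].isin(var_classes).to_numpy()
    pts = mutation_points(muts)
    points_by_chrom = {
        chrom: np.sort(pts[sel & (muts["chrom"].to_numpy() == chrom)])
        for chrom in pd.unique(muts["chrom"].to_numpy())
    }
    bodies: dict[str, list[tuple[int, int]]] = {}
    for r in sirs:
        bodies.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom in bodies:
        bodies[chrom].sort()

    def outside_sirs(chrom: str, s: int, e: int) -> bool:
        ivs = bodies.get(chrom, [])
        import bisect

        i = bisect.bisect_right([x[0] for x in ivs], s) - 1
        if i >= 0 and ivs[i][1] > s:
            return False
        return not (i + 1 < len(ivs) and ivs[i + 1][0] < e)

    # canonical key: lexicographic min of sequence and its reverse complement
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(sirs):
        key = min(r.spacer, reverse_complement(r.spacer))
        groups.setdefault(key, []).append(i)

    rows = []
    for key, idxs in sorted(groups.items()):
        in_intervals: dict[str, list[tuple[int, int]]] = {}
        for i in idxs:
            r = sirs[i]
            in_intervals.setdefault(r.chrom, []).append((r.spacer_start, r.spacer_end))
        n_in = sum(
            _interval_mut_count(points_by_chrom.get(c, np.array([], dtype=np.int64)), ivs)
            for c, ivs in in_intervals.items()
        )
        if n_in < min_spacer_mutations:
            continue
        len_in = sum(e - s for ivs in in_intervals.values() for s, e in ivs)
        n_out = 0
        len_out = 0
        for chrom, seq in genome.items():
            occ = [
                (s, e)
                for s, e in find_occurrences(seq, key)
                if outside_sirs(chrom, s, e)
            ]
            len_out += sum(e - s for s, e in occ)
            n_out += _interval_mut_count(points_by_chrom.get(chrom, np.array([], dtype=np.int64)), occ)
        testable = len_out > 0
        d_out = n_out / (len_out * n_samples) if testable else np.nan
        d_in = n_in / (len_in * n_samples)
        p = binomial_spacer_test(n_in, 1, len_in * n_samples, min(d_out, 1.0)) if testable else np.nan
        rows.append(
            {
                "spacer_seq": key,
                "n_in_sir": n_in,
                "len_in_sir": len_in,
                "n_out_sir": n_out,
                "len_out_sir": len_out,
                "density_in": d_in,
                "density_out": d_out,
                "fold": d_in / d_out if testable and d_out > 0 else np.inf if testable else np.nan,
                "testable": testable,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    q = np.full(len(out), np.nan)
    mask = out["testable"].to_numpy()
    if mask.any():
        q[mask] = bh_adjust(out.loc[mask, "p_value"].to_numpy())
    out["q_value"] = q
    out["is_hotspot"] = (out["q_value"] <= q_threshold).fillna(False)
    return out


def attach_site_folds(sites: list[HotspotSite], spacer_tests: pd.DataFrame) -> list[HotspotSite]:
    """Copy per-spacer-sequence folds onto sites via the representative spacer."""
    folds = {}
    for row in spacer_tests.itertuples(index=False):
        folds[row.spacer_seq] = row.fold
    out = []
    for s in sites:
        key = min(s.spacer_seq, reverse_complement(s.spacer_seq))
        out.append(
            HotspotSite(
                chrom=s.chrom,
                start=s.start,
                end=s.end,
                representative=s.representative,
                members=s.members,
                fold_vs_non_sir=float(folds.get(key, np.nan)),
            )
        )
    return out


def odds_ratio_spacer_control(
    spacer_muts: float,
    spacer_units: float,
    control_muts: float,
    control_units: float,
) -> tuple[float, tuple[float, float]]:
    """Odds ratio of mutation in spacer vs control position-sample units.

    2x2 table of mutated vs non-mutated units; Haldane-Anscombe 0.5 added to
    every cell when any cell is zero; Wald 95% CI on the log odds ratio.
    """
    if spacer_units <= 0 or control_units <= 0:
        raise ValueError("unit totals must be positive")
    a = float(spacer_muts)
    b = float(spacer_units - spacer_muts)
    c = float(control_muts)
    d = float(control_units - control_muts)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(or_) - 1.96 * se))
    hi = float(np.exp(np.log(or_) + 1.96 * se))
    return float(or_), (lo, hi)


def signature_odds_ratios(
    muts: pd.DataFrame,
    assignment: pd.DataFrame,
    sirs: Sequence[SIRRecord],
    n_samples: int,
    config: SearchConfig | None = None,
    genome: Mapping[str, str] | None = None,
    exposures: pd.DataFrame | None = None,
    var_classes: Sequence[str] = ("substitution",),
) -> pd.DataFrame:
    """Spacer:control odds ratio per mutational signature.

    When per-mutation ``signature`` labels are present they are used directly;
    otherwise each mutation contributes fractionally to every signature in
    proportion to its sample's exposures (rows of ``exposures`` indexed by
    sample, columns = signatures).
    """
    from .mutations import effective_domain_lengths

    config = config or SearchConfig()
    lengths = effective_domain_lengths(sirs, config, genome, var_class=var_classes[0])
    spacer_units = lengths["spacer"] * n_samples
    control_units = lengths["control"] * n_samples
    sel = muts["var_class"].isin(var_classes).to_numpy()
    dom = assignment["domain"].to_numpy()
    have_labels = muts["signature"].notna() & sel

    weights: dict[str, np.ndarray] = {}
    if have_labels.any():
        for sig in sorted(muts.loc[have_labels, "signature"].unique()):
            weights[str(sig)] = (sel & (muts["signature"] == sig).to_numpy()).astype(float)
    elif exposures is not None:
        props = exposures.div(exposures.sum(axis=1), axis=0)
        for sig in props.columns:
            w = muts["sample"].map(props[sig]).fillna(0.0).to_numpy()
            weights[str(sig)] = np.where(sel, w, 0.0)
    else:
        raise ValueError("need per-mutation signature labels or a sample exposure matrix")

    rows = []
    for sig, w in weights.items():
        a = float(w[dom == "spacer"].sum())
        c = float(w[dom == "control"].sum())
        or_, (lo, hi) = odds_ratio_spacer_control(a, spacer_units, c, control_units)
        rows.append(
            {"signature": sig, "n_spacer": a, "n_control": c, "odds_ratio": or_, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def sites_to_frame(sites: Sequence[HotspotSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "start_1based": [s.start + 1 for s in sites],
            "end_1based": [s.end for s in sites],
            "n_members": [len(s.members) for s in sites],
            "rep_start_1based": [s.representative.start + 1 for s in sites],
            "rep_end_1based": [s.representative.end for s in sites],
            "rep_arm_len": [s.representative.arm_len for s in sites],
            "rep_spacer": [s.spacer_seq for s in sites],
            "fold_vs_non_sir": [s.fold_vs_non_sir for s in sites],
        }
    )
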