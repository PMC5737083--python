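"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (cubic-time
enumeration, literal step-up BH, log-space tail summation) so that the package
implementations are checked against an independent route.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy.special import gammaln

from sirscan.detect import SearchConfig, SIRRecord
from sirscan.model import SIRMutabilityModel
from sirscan.simulate import SimulationConfig, generate_genome, generate_mutations


# ---------------------------------------------------------------------------
# oracles


def oracle_revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def brute_force_scan(seq: str, chrom: str, cfg: SearchConfig) -> list[SIRRecord]:
    """Cubic-time enumeration of all IR windows + per-extent canonicalisation."""
    n = len(seq)
    best: dict[tuple[int, int], int] = {}
    for i in range(n):
        for s in range(cfg.spacer_min, cfg.spacer_max + 1):
            for a in range(cfg.arm_min, cfg.arm_max + 1):
                end = i + 2 * a + s
                if end > n:
                    break
                window = seq[i:end]
                if "N" in window:
                    continue
                if window[:a] == oracle_revcomp(window[-a:]):
                    key = (i, end)
                    if best.get(key, 0) < a:
                        best[key] = a
    recs = [
        SIRRecord(
            chrom=chrom,
            start=i,
            end=end,
            arm_len=a,
            spacer_len=end - i - 2 * a,
            left_arm=seq[i : i + a],
            spacer=seq[i + a : end - a],
        )
        for (i, end), a in best.items()
    ]
    recs.sort(key=lambda r: (r.start, r.end))
    return recs


def greedy_resolve_oracle(records: list[SIRRecord]) -> list[SIRRecord]:
    """Literal 'sort by length descending, greedily keep if disjoint' rule."""
    ordered = sorted(records, key=lambda r: (-(r.end - r.start), r.start, r.spacer_len))
    kept: list[SIRRecord] = []
    for r in ordered:
        if all(r.chrom != k.chrom or r.end <= k.start or r.start >= k.end for k in kept):
            kept.append(r)
    return sorted(kept, key=lambda r: (r.chrom, r.start, r.end))


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Literal BH step-up: sort, scale by m/i, cumulative minimum, clip."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def binom_sf_summation_oracle(k: int, n: int, p: float) -> float:
    """P[X >= k] by direct log-space summation of binomial pmf terms."""
    if k <= 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    j = np.arange(k, n + 1, dtype=float)
    logpmf = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(n - j + 1)
        + j * np.log(p)
        + (n - j) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logpmf).sum()))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_sim():
    """One cohort simulation at the default study conditions (shared)."""
    cfg = SimulationConfig(
        seed=11,
        chrom_length=120_000,
        n_planted_sirs=120,
        n_samples=60,
        background_density=2e-3,
        spacer_fold=1.35,
    )
    genome, truth = generate_genome(cfg)
    muts = generate_mutations(cfg, genome, truth)
    return cfg, genome, truth, muts


@pytest.fixture(scope="session")
def fitted_results(default_sim):
    cfg, genome, truth, muts = default_sim
    model = SIRMutabilityModel(genome, muts, n_samples=cfg.n_samples)
    return model.fit()


def make_sir(start: int, arm: int, spacer: str, chrom: str = "chr1", left_arm: str | None = None) -> SIRRecord:
    arm_seq = left_arm if left_arm is not None else "G" * arm
    return SIRRecord(
        chrom=chrom,
        start=start,
        end=start + 2 * arm + len(spacer),
        arm_len=arm,
        spacer_len=len(spacer),
        left_arm=arm_seq,
        spacer=spacer,
    )


def muts_frame(rows) -> pd.DataFrame:
    """rows: (sample, chrom, pos1, ref, alt, var_class[, signature])"""
    out = []
    for r in rows:
        r = list(r)
        if len(r) == 6:
            r.append(pd.NA)
        out.append(tuple(r))
    return pd.DataFrame(
        out, columns=["sample", "chrom", "pos", "ref", "alt", "var_class", "signature"]
    )
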