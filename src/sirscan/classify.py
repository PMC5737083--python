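"""Tumor-sample classification from signature exposures and hotspot mutations.

Two independent classifiers:

* hierarchical clustering (Ward, Euclidean) of per-sample mutational-signature
  exposure proportions into phenotype classes named by their dominant
  signatures (2/13 -> APOBEC, 6/20/26 -> MSI, both -> APOBEC+MSI, 3 -> BRCA,
  else Others);
* a hotspot-count rule: a sample mutated at >= 16 distinct AT-only hotspot
  sites is flagged MSI (mismatch-repair deficient), and at >= 7 distinct
  GC-containing sites is flagged APOBEC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .enrichment import HotspotSite
from .mutations import mutation_points
from .sequence import is_pure_at

SIGNATURES_12 = ["1", "2", "3", "5", "6", "8", "13", "17", "18", "20", "26", "30"]

APOBEC_SIGNATURES = ("2", "13")
MSI_SIGNATURES = ("6", "20", "26")
BRCA_SIGNATURE = "3"

MSI_THRESHOLD_DEFAULT = 16
APOBEC_THRESHOLD_DEFAULT = 7
NAMING_FLOOR = 0.20  # minimum mean proportion for a signature group to name a cluster


@dataclass(frozen=True)
class SampleCall:
    sample_id: str
    n_at_only_sites_mutated: int
    n_gc_sites_mutated: int
    msi_flag: bool
    apobec_flag: bool
    cluster_class: str | None = None


def _name_cluster(mean_props: pd.Series) -> str:
    apobec = sum(mean_props.get(s, 0.0) for s in APOBEC_SIGNATURES)
    msi = sum(mean_props.get(s, 0.0) for s in MSI_SIGNATURES)
    brca = mean_props.get(BRCA_SIGNATURE, 0.0)
    if apobec >= NAMING_FLOOR and msi >= NAMING_FLOOR:
        return "APOBEC+MSI"
    if apobec >= NAMING_FLOOR:
        return "APOBEC"
    if msi >= NAMING_FLOOR:
        return "MSI"
    if brca >= NAMING_FLOOR:
        return "BRCA"
    return "Others"


def cluster_signature_classes(exposures: pd.DataFrame, k: int = 5) -> pd.Series:
    """Agglomerative (Ward/Euclidean) clustering of exposure proportions.

    ``exposures``: samples x signatures (columns named by signature number).
    Returns a sample-indexed Series of class labels; clusters are named by
    their dominant mean signature content with a 20% floor.  The partition is
    invariant to sample order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(exposures) < k:
        raise ValueError(f"need at least k={k} samples, got {len(exposures)}")
    props = exposures.div(exposures.sum(axis=1), axis=0).fillna(0.0)
    ordered = props.sort_index()
    if k == 1:
        assign = np.ones(len(ordered), dtype=int)
    else:
        Z = linkage(ordered.to_numpy(), method="ward", metric="euclidean")
        assign = fcluster(Z, t=k, criterion="maxclust")
    labels = {}
    for cl in np.unique(assign):
        members = ordered.index[assign == cl]
        labels[cl] = _name_cluster(ordered.loc[members].mean())
    out = pd.Series([labels[c] for c in assign], index=ordered.index, name="cluster_class")
    return out.reindex(exposures.index)


def hotspot_site_partition(sites: Sequence[HotspotSite]) -> tuple[list[HotspotSite], list[HotspotSite]]:
    """Split sites into (AT-only spacer, GC-containing spacer); exhaustive and disjoint."""
    at_only = [s for s in sites if is_pure_at(s.spacer_seq)]
    gc_positive = [s for s in sites if not is_pure_at(s.spacer_seq)]
    return at_only, gc_positive


def classify_samples(
    muts: pd.DataFrame,
    sites: Sequence[HotspotSite],
    msi_threshold: int = MSI_THRESHOLD_DEFAULT,
    apobec_threshold: int = APOBEC_THRESHOLD_DEFAULT,
    cluster_classes: pd.Series | None = None,
) -> list[SampleCall]:
    """Per-sample hotspot-site mutation counts and MMRd/APOBEC flags.

    A site counts as mutated for a sample when at least one of the sample's
    variants (any class) falls inside the representative spacer interval;
    multiple mutations in one site count once.
    """
    at_only, gc_positive = hotspot_site_partition(sites)
    pts = mutation_points(muts)
    chroms = muts["chrom"].to_numpy()
    samples = muts["sample"].to_numpy()

    def mutated_sites(site_list: Sequence[HotspotSite]) -> pd.Series:
        per_sample: dict[str, set[int]] = {}
        for si, site in enumerate(site_list):
            rep = site.representative
            hit = (
                (chroms == site.chrom)
                & (pts >= rep.spacer_start)
                & (pts < rep.spacer_end)
            )
            for s in samples[hit]:
                per_sample.setdefault(s, set()).add(si)
        return pd.Series({s: len(v) for s, v in per_sample.items()}, dtype=int)

    n_at = mutated_sites(at_only)
    n_gc = mutated_sites(gc_positive)
    all_samples = sorted(set(samples))
    calls = []
    for s in all_samples:
        na = int(n_at.get(s, 0))
        ng = int(n_gc.get(s, 0))
        calls.append(
            SampleCall(
                sample_id=s,
                n_at_only_sites_mutated=na,
                n_gc_sites_mutated=ng,
                msi_flag=na >= msi_threshold,
                apobec_flag=ng >= apobec_threshold,
                cluster_class=None if cluster_classes is None else cluster_classes.get(s),
            )
        )
    return calls


def calls_to_frame(calls: Sequence[SampleCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [c.sample_id for c in calls],
            "n_at_only_sites_mutated": [c.n_at_only_sites_mutated for c in calls],
            "n_gc_sites_mutated": [c.n_gc_sites_mutated for c in calls],
            "msi_flag": [c.msi_flag for c in calls],
            "apobec_flag": [c.apobec_flag for c in calls],
            "cluster_class": [c.cluster_class for c in calls],
        }
    )


def read_exposures_tsv(path) -> pd.DataFrame:
    """Exposure matrix TSV: first column = sample id, remaining = signatures."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    if (df.to_numpy() < 0).any():
        raise ValueError("exposures must be nonnegative")
    return df
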