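"""Cohort-level SIR mutability model.

``SIRMutabilityModel`` binds a genome and a somatic mutation catalog;
``fit()`` runs the full analysis — SIR detection, domain assignment, density
estimation, per-SIR binomial enrichment with BH correction, hotspot-spacer
testing, site collapsing and sample classification — and returns a
``SIRMutabilityResults`` object carrying the estimates, their uncertainties
and a text summary.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    APOBEC_THRESHOLD_DEFAULT,
    MSI_THRESHOLD_DEFAULT,
    calls_to_frame,
    classify_samples,
    cluster_signature_classes,
)
from .detect import SearchConfig, SIRRecord, find_sirs_genome, sirs_to_frame
from .enrichment import (
    Q_THRESHOLD_DEFAULT,
    attach_site_folds,
    call_highly_mutated,
    collapse_to_sites,
    hotspot_spacer_tests,
    sites_to_frame,
)
from .mutations import assign_to_domains, domain_density, read_variants_tsv
from .simulate import read_genome_fasta

logger = logging.getLogger(__name__)


class SIRMutabilityModel:
    """Domain-dependent mutability of short inverted repeats in a cohort.

    Parameters
    ----------
    genome : mapping chromosome -> sequence
    mutations : DataFrame with columns sample, chrom, pos (1-based), ref, alt,
        var_class, signature
    n_samples : cohort size (defaults to the number of distinct samples in
        the catalog)
    search_config : SIR search and control-window parameters
    sirs : optional pre-computed SIR set (skips scanning)
    """

    def __init__(
        self,
        genome: Mapping[str, str],
        mutations: pd.DataFrame,
        n_samples: int | None = None,
        search_config: SearchConfig | None = None,
        sirs: Sequence[SIRRecord] | None = None,
        exposures: pd.DataFrame | None = None,
    ) -> None:
        self.genome = dict(genome)
        self.mutations = mutations.reset_index(drop=True)
        self.n_samples = int(n_samples or self.mutations["sample"].nunique())
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        self.search_config = search_config or SearchConfig()
        self.sirs = list(sirs) if sirs is not None else None
        self.exposures = exposures

    @classmethod
    def from_files(
        cls,
        fasta_path,
        variants_path,
        n_samples: int | None = None,
        search_config: SearchConfig | None = None,
        exposures_path=None,
    ) -> "SIRMutabilityModel":
        from .classify import read_exposures_tsv

        genome = read_genome_fasta(fasta_path)
        muts = read_variants_tsv(variants_path)
        exposures = read_exposures_tsv(exposures_path) if exposures_path else None
        return cls(genome, muts, n_samples=n_samples, search_config=search_config, exposures=exposures)

    def fit(
        self,
        q_threshold: float = Q_THRESHOLD_DEFAULT,
        msi_threshold: int = MSI_THRESHOLD_DEFAULT,
        apobec_threshold: int = APOBEC_THRESHOLD_DEFAULT,
        test_hotspot_spacers: bool = True,
    ) -> "SIRMutabilityResults":
        cfg = self.search_config
        sirs = self.sirs if self.sirs is not None else find_sirs_genome(self.genome, cfg)
        logger.info("detected %d SIRs", len(sirs))
        assignment = assign_to_domains(self.mutations, sirs, cfg)
        densities = domain_density(
            assignment, self.mutations, sirs, self.n_samples, cfg, genome=self.genome
        )
        enrichment = call_highly_mutated(
            self.mutations, sirs, self.n_samples, cfg, genome=self.genome, q_threshold=q_threshold
        )
        sites = collapse_to_sites(enrichment, sirs) if len(enrichment) else []
        spacer_tests = pd.DataFrame()
        if test_hotspot_spacers:
            spacer_tests = hotspot_spacer_tests(
                self.mutations, sirs, self.genome, self.n_samples, q_threshold=q_threshold
            )
            sites = attach_site_folds(sites, spacer_tests) if sites else sites
        cluster = (
            cluster_signature_classes(self.exposures) if self.exposures is not None else None
        )
        calls = classify_samples(
            self.mutations,
            sites,
            msi_threshold=msi_threshold,
            apobec_threshold=apobec_threshold,
            cluster_classes=cluster,
        )
        return SIRMutabilityResults(
            model=self,
            sirs=sirs,
            assignment=assignment,
            densities=densities,
            enrichment=enrichment,
            spacer_tests=spacer_tests,
            sites=sites,
            sample_calls=calls,
            q_threshold=q_threshold,
        )


@dataclass
class SIRMutabilityResults:
    """Fitted quantities of a :class:`SIRMutabilityModel`."""

    model: SIRMutabilityModel
    sirs: list[SIRRecord]
    assignment: pd.DataFrame
    densities: pd.DataFrame
    enrichment: pd.DataFrame
    spacer_tests: pd.DataFrame
    sites: list
    sample_calls: list
    q_threshold: float

    def _density(self, domain: str) -> float:
        row = self.densities[self.densities["domain"] == domain]
        return float(row["density_per_mb"].iloc[0])

    def _count(self, domain: str) -> int:
        row = self.densities[self.densities["domain"] == domain]
        return int(row["n_mutations"].iloc[0])

    @property
    def fold_spacer_control(self) -> float:
        """Spacer:control substitution density ratio (the headline fold)."""
        return self._density("spacer") / self._density("control")

    @property
    def fold_spacer_control_ci(self) -> tuple[float, float]:
        """~95% CI on the fold from the Poisson ratio (log-normal approx)."""
        ns, nc = self._count("spacer"), self._count("control")
        if ns == 0 or nc == 0:
            return (float("nan"), float("nan"))
        se = np.sqrt(1 / ns + 1 / nc)
        f = self.fold_spacer_control
        return (float(f * np.exp(-1.96 * se)), float(f * np.exp(1.96 * se)))

    @property
    def n_highly_mutated(self) -> int:
        if self.enrichment.empty:
            return 0
        return int(self.enrichment["is_highly_mutated"].sum())

    @property
    def n_hotspot_spacers(self) -> int:
        if self.spacer_tests.empty:
            return 0
        return int(self.spacer_tests["is_hotspot"].sum())

    def summary(self) -> str:
        ci = self.fold_spacer_control_ci
        lines = [
            "SIR mutability results",
            "=" * 58,
            f"{'chromosomes':38s}{len(self.model.genome):>12d}",
            f"{'cohort size (samples)':38s}{self.model.n_samples:>12d}",
            f"{'SIRs detected':38s}{len(self.sirs):>12d}",
            f"{'mutations in catalog':38s}{len(self.model.mutations):>12d}",
        ]
        for domain in ("spacer", "arm", "control"):
            lines.append(
                f"{'density ' + domain + ' (per Mb per sample)':38s}{self._density(domain):>12.2f}"
            )
        lines += [
            f"{'fold spacer:control':38s}{self.fold_spacer_control:>12.3f}",
            f"{'  95% CI':38s}{'[%.3f, %.3f]' % ci:>12s}",
            f"{'SIRs tested (>=1 spacer mutation)':38s}{len(self.enrichment):>12d}",
            f"{'highly mutated SIRs (q<=%.2g)' % self.q_threshold:38s}{self.n_highly_mutated:>12d}",
            f"{'hotspot sites':38s}{len(self.sites):>12d}",
            f"{'hotspot spacer sequences':38s}{self.n_hotspot_spacers:>12d}",
            f"{'samples flagged MSI':38s}{sum(c.msi_flag for c in self.sample_calls):>12d}",
            f"{'samples flagged APOBEC':38s}{sum(c.apobec_flag for c in self.sample_calls):>12d}",
            "=" * 58,
        ]
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        ci = self.fold_spacer_control_ci
        return {
            "version": __version__,
            "n_samples": self.model.n_samples,
            "n_sirs": len(self.sirs),
            "n_mutations": len(self.model.mutations),
            "density_per_mb": {
                d: self._density(d) for d in ("spacer", "arm", "control")
            },
            "fold_spacer_control": self.fold_spacer_control,
            "fold_spacer_control_ci": list(ci),
            "n_tested_sirs": len(self.enrichment),
            "n_highly_mutated_sirs": self.n_highly_mutated,
            "n_hotspot_sites": len(self.sites),
            "n_hotspot_spacers": self.n_hotspot_spacers,
            "n_msi_flagged": int(sum(c.msi_flag for c in self.sample_calls)),
            "n_apobec_flagged": int(sum(c.apobec_flag for c in self.sample_calls)),
            "search_config": {
                "spacer_min": self.model.search_config.spacer_min,
                "spacer_max": self.model.search_config.spacer_max,
                "arm_min": self.model.search_config.arm_min,
                "arm_max": self.model.search_config.arm_max,
                "control_width_sub_indel": self.model.search_config.control_width_sub_indel,
                "control_width_rearrangement": self.model.search_config.control_width_rearrangement,
                "drop_pure_at": self.model.search_config.drop_pure_at,
            },
            "q_threshold": self.q_threshold,
        }

    def save(self, outdir) -> None:
        """Write all intermediate tables and a machine-readable JSON summary."""
        os.makedirs(outdir, exist_ok=True)
        sirs_to_frame(self.sirs).to_csv(os.path.join(outdir, "sirs.tsv"), sep="\t", index=False)
        self.densities.to_csv(os.path.join(outdir, "densities.tsv"), sep="\t", index=False)
        self.enrichment.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
        if not self.spacer_tests.empty:
            self.spacer_tests.to_csv(
                os.path.join(outdir, "hotspot_spacers.tsv"), sep="\t", index=False
            )
        sites_to_frame(self.sites).to_csv(os.path.join(outdir, "sites.tsv"), sep="\t", index=False)
        calls_to_frame(self.sample_calls).to_csv(
            os.path.join(outdir, "sample_calls.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(self.summary_dict(), fh, indent=1, sort_keys=True)


def run_all(
    fasta_path,
    variants_path,
    outdir,
    n_samples: int | None = None,
    search_config: SearchConfig | None = None,
    q_threshold: float = Q_THRESHOLD_DEFAULT,
    msi_threshold: int = MSI_THRESHOLD_DEFAULT,
    apobec_threshold: int = APOBEC_THRESHOLD_DEFAULT,
    exposures_path=None,
) -> SIRMutabilityResults:
    """File-to-file orchestration: scan -> mutability -> hotspots -> classify.

    A stage failure raises with the stage name; outputs of completed stages
    are retained under ``outdir``.
    """
    stage = "inputs"
    try:
        model = SIRMutabilityModel.from_files(
            fasta_path, variants_path, n_samples=n_samples,
            search_config=search_config, exposures_path=exposures_path,
        )
        stage = "fit"
        results = model.fit(
            q_threshold=q_threshold,
            msi_threshold=msi_threshold,
            apobec_threshold=apobec_threshold,
        )
        stage = "save"
        results.save(outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
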