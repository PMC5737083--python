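# sirscan

Short inverted repeats (SIRs) are palindromic DNA sequences — two
reverse-complementary *arms* of 6–25 bp flanking a short *spacer* of 4–8 bp —
that can fold into hairpins on single-stranded DNA, with the arms forming the
stem and the spacer the loop. In somatic cells the loop is locally
hypermutable: spacer sequences accumulate substitutions at roughly 1.35× the
rate of their flanking sequence, some spacers act as recurrent mutation
hotspots, and the pattern of mutated hotspot sites carries information about
a tumor's mutational processes (mismatch-repair deficiency, APOBEC activity).

`sirscan` is a toolkit for this analysis on any genome FASTA and somatic
variant catalog:

* **Detection** — exhaustive scan for perfect inverted repeats, collapsed per
  locus to the most stable hairpin category (loop as short as possible but
  ≥4 bp, stem as long as possible), pure-A/T spacers removed, overlapping
  loci resolved to the longest repeat.
* **Genomic context** — binned SIR densities with a quadratic density-vs-GC
  model, 32-trinucleotide spectra with cosine similarity, annotation against
  regulatory-element and replication-timing tracks.
* **Mutability** — somatic variants mapped onto spacer / arm / flanking
  control domains (100 bp controls for substitutions and indels, 1000 bp for
  rearrangement breakpoints), with six- and 96-class substitution spectra,
  distance-to-center profiles and geometry-stratified densities.
* **Inference** — for each SIR with spacer mutations, the one-sided binomial
  test `P[X ≥ N]` with `X ~ Binomial(L_spacer · n_samples, d_control)`,
  Benjamini–Hochberg correction across the tested family, *highly mutated
  SIRs* at q ≤ 0.01, overlapping calls collapsed to genomic sites, and spacer
  sequences tested against identical sequences not flanked by palindromes
  (*SIR hotspots*), plus spacer:control odds ratios per mutational signature.
* **Classification** — hierarchical clustering of signature exposures into
  phenotype classes, and per-sample hotspot counts: ≥16 mutated AT-only sites
  flags MSI, ≥7 mutated GC-containing sites flags APOBEC.
* **Simulation** — a generator for genomes with planted SIRs and cohorts with
  configurable background density, spacer fold, hotspot folds and
  APOBEC-/MSI-like samples, with a ground-truth manifest, so the entire
  pipeline is testable without any external download.

## Worked example

The whole analysis is exposed statsmodels-style: a model object built from
data whose `fit()` returns a results object.

```python
from sirscan import (SIRMutabilityModel, SimulationConfig,
                     generate_genome, generate_mutations)

cfg = SimulationConfig(seed=7)            # 200 kb, 100 samples, spacer fold 1.35
genome, truth = generate_genome(cfg)
muts = generate_mutations(cfg, genome, truth)

res = SIRMutabilityModel(genome, muts, n_samples=cfg.n_samples).fit()
print(res.summary())
```

```
SIR mutability results
==========================================================
chromosomes                                      1
cohort size (samples)                          100
SIRs detected                                  383
mutations in catalog                         40212
density spacer (per Mb per sample)         2732.46
density arm (per Mb per sample)            2047.29
density control (per Mb per sample)        1998.62
fold spacer:control                          1.367
  95% CI                              [1.262, 1.481]
SIRs tested (>=1 spacer mutation)              300
highly mutated SIRs (q<=0.01)                    1
hotspot sites                                    1
hotspot spacer sequences                         1
samples flagged MSI                              0
samples flagged APOBEC                           0
==========================================================
```

The generator planted a 1.35-fold loop hypermutability on a uniform
2000-per-Mb-per-sample background; the fitted spacer:control fold of 1.367
(CI [1.26, 1.48]) recovers it, while arm and control densities sit at the
background. Under this near-null cohort the enrichment machinery calls
almost nothing highly mutated, as it should.

The same stages are available from the shell:

```sh
sirscan simulate --seed 7 --out sim/
sirscan scan --fasta sim/genome.fa --out sirs.tsv
sirscan run --fasta sim/genome.fa --variants sim/mutations.tsv \
            --n-samples 100 --out results/
```

`results/` then holds `sirs.tsv`, `densities.tsv`, `enrichment.tsv`,
`hotspot_spacers.tsv`, `sites.tsv`, `sample_calls.tsv` and a machine-readable
`summary.json`.

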