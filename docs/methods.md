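# Methods

## The object of study

A short inverted repeat (SIR) is `arm + spacer + reverse_complement(arm)`.
On single-stranded DNA the arms can hybridise into a hairpin stem while the
spacer forms the loop. Loop lengths of ~4–5 bp and stems of ≥7 bp favour
stable hairpins, and stability plateaus near 25 bp of stem, which motivates
the default search space: spacer 4–8 bp, arm 6–25 bp (both configurable).
The spacer minimum of 4 bp is a steric constraint on loop formation and is
enforced as a hard lower bound in `SearchConfig`.

## Detection

The scanner finds every window with perfectly reverse-complementary arms in
the configured ranges. Matching is exact: the analysis is about the loci
that can actually base-pair into a stem, and mismatch-tolerant matching is
out of scope. The scan is single-strand by construction — an inverted repeat
on the forward strand is the same double-stranded object on the reverse
strand — and the suite checks the mirror-coordinate symmetry explicitly.

Per locus (identical `[start, end)` extent) candidates are collapsed to the
most stable hairpin category: the smallest spacer ≥ the minimum, hence the
longest arm. Because pairing within a fixed extent is the same map
(`j ↔ L−1−j`), an arm of length `a` matching implies all shorter arms match,
so the canonical category is simply the longest admissible matching arm. The
implementation exploits this with an incremental AND over pair-match arrays
(one vectorised operation per arm length and spacer length), giving an
O(ranges · L) scan; the test suite proves it equal to a cubic-time
brute-force enumeration on 200 random 500-bp sequences.

Filters are applied in the order: raw scan → per-extent canonicalisation →
removal of pure-A/T spacers → overlap resolution. Overlap resolution visits
candidates by descending total length (ties: smaller start, then smaller
spacer) and keeps each candidate that is disjoint from everything already
kept; this greedy rule is deterministic and is checked against a literal
oracle. Windows containing N are never emitted; N never base-pairs and is
excluded from every length denominator.

Coordinates are 0-based half-open internally; serialised tables are 1-based
inclusive and BED output is 0-based half-open.

## Domains and densities

Each SIR defines three domain classes: the spacer, the two arms, and control
windows of 100 bp immediately up- and downstream (1000 bp for rearrangement
breakpoints, whose genomic density is far lower). Controls are truncated at
chromosome ends, and control bases falling inside another SIR keep that
SIR's own domain label. When the control windows of adjacent SIRs overlap,
the overlap is counted once in cohort-level densities but contributes to
each SIR in per-SIR tests; both conventions are exercised in the tests.

Variants are reduced to points: substitutions at the mutated base, indels at
the first affected base after the VCF-style anchor (left-aligned), and
breakpoints at the breakpoint position. Cohort density is
`count / (effective_length · n_samples)`, reported per Mb, where effective
length counts non-N bases. Substitutions are classified on the pyrimidine
strand (purine references complemented, flanks swapped) into the 6 and 96
standard classes; trinucleotide composition uses 32 pyrimidine-centred
contexts counted over overlapping windows, the standard convention in
mutational-context work. Distance-to-center profiles use the spacer
midpoint, rounded down for even loops, and normalise each offset by the
number of SIRs contributing a valid position there.

For bin and track assignment an SIR is represented by its spacer midpoint —
a single unambiguous point. Binned densities (default 2 Mb) divide counts by
the bin's non-N length, and the density-vs-GC relationship is summarised by
an ordinary least-squares quadratic; replication-timing tracks are split
into deciles by length-weighted genome-wide ranking of interval values.

## Enrichment inference

For an SIR with `N` spacer substitutions, `P[X ≥ N]` is computed for
`X ~ Binomial(L_spacer · n_samples, d)`, where `d` is the per-bp-per-sample
mutation density of that SIR's own control windows — the parameterisation
must be a probability, which fixes the units of `d`. Only SIRs with at least
one spacer mutation form the tested family; Benjamini–Hochberg correction is
applied within the family and calls use q ≤ 0.01 (configurable). SIRs with
no usable control bases are excluded with a logged reason. `d = 0` with
observed mutations yields p = 0 by documented convention.

The binomial tail is summed term-by-term in log space for up to 1e5 trials —
exact, and free of the deep-tail underflow of incomplete-beta routines —
and delegates to the scipy survival function beyond that; the two routes are
checked against each other at the boundary. BH delegates to statsmodels and
is verified against the literal step-up definition on 1000 random vectors.

Overlapping highly mutated SIRs merge into sites (connected components of
the interval-overlap graph); the longest member, ties to the left, is the
representative. Separately, each spacer *sequence* is tested against
identical sequences not flanked by palindromes: occurrences of the sequence
or its reverse complement (one double-stranded object) lying wholly outside
every SIR supply the background density, pooled in-SIR spacer occurrences
supply the observation, and BH runs across this second, separate family.
Untestable sequences (no outside occurrence) are reported as such.
Per-location results are available alongside the pooled test via the
per-SIR enrichment table. Signature-stratified spacer:control odds ratios
come from the 2×2 table of mutated vs non-mutated position-sample units,
with the Haldane–Anscombe 0.5 correction for empty cells and a Wald 95% CI
on the log odds ratio; when per-mutation signature labels are absent, each
mutation contributes fractionally to every signature in proportion to its
sample's exposures.

## Sample classification

Two complementary classifiers. First, agglomerative hierarchical clustering
(Ward linkage, Euclidean distance — unstated in the source analyses, chosen
as the standard default and configurable) of per-sample exposure proportions
over the 12 breast-cancer substitution signatures, cut at k = 5; clusters
are named by dominant mean content with a 20% floor (2/13 → APOBEC,
6/20/26 → MSI, both → APOBEC+MSI, 3 → BRCA, else Others). Second, the
hotspot-count rule: sites are partitioned by representative spacer into
AT-only and GC-containing; a sample mutated (any variant class, counted once
per site, spacer interval only) at ≥16 AT-only sites is flagged MSI and at
≥7 GC-containing sites is flagged APOBEC. Both thresholds are exact
boundaries and configurable.

## The synthetic cohort

The generator defines the study conditions under which the pipeline is
validated. Defaults: one 200-kb chromosome at GC 0.41 (human-like), 200
planted SIRs at well-separated loci (> 2 control widths apart), 100 samples,
a uniform background of 2×10⁻³ mutations per bp per sample, and a spacer
fold of 1.35 — the headline loop-hypermutability effect. The per-sample
density is far above a real tumor's (~1–10 per Mb) by design: what powers
the statistics is position-sample coverage per SIR (spacer bp × samples ×
density), and these defaults give each planted SIR a coverage comparable to
what a 560-genome cohort provides over a full genome, at desk scale. The
fold applies to the spacers of *every* SIR detectable in the generated
genome, not only the planted ones — hairpin-loop hypermutability is a
property of the structure, not of how the locus arose — which keeps the
downstream cohort-level fold estimator unbiased in the presence of
background repeats arising by chance.

Planted loci are screened so the truth is unambiguous: any detected SIR
within one control width of a planted locus that is not exactly the planted
record has a non-planted base redrawn until the neighbourhood is clean, and
planted spacers are drawn so their outer bases cannot base-pair (which would
fold two loop bases into the stem and change the canonical category).
APOBEC-like samples put 80% of their substitution budget on TpC-context
cytosines (C>T 2:1 over C>G); MSI-like samples add 1-bp slippage indels at
A/T homopolymer runs (≥4 bp) and AT-rich spacers; flat samples are uniform.
All randomness derives from one seed with per-sample substreams indexed by
counter, so outputs are byte-identical across runs and adding samples never
perturbs earlier ones.

What the generator does not emulate — and hence what passing tests do not
show about real data: chromatin- and replication-timing covariation of the
background rate, mutational-signature interactions beyond the three
archetypes, rearrangement mechanisms (breakpoints are placed uniformly),
assembly gaps and low-complexity structure of real genomes, and selection.
The type-I and recovery results certify the statistical machinery under the
stated model, not the biology of any particular cohort.

## Problem sizes and numerical choices

Validation runs use 100-kb genomes, 60–100 samples and 20 seeds per
condition, sized so each condition yields several hundred spacer mutations
(fold standard error ≈ 0.05–0.07 per seed, ≈ 0.015 for a 20-seed mean).
Type-I control is asserted as pooled flagged fraction ≤ 0.01 + 3·SE across
seeds; fold recovery as |mean − truth| ≤ 0.1 for folds 1.35 and 2.0; planted
fold-10 hotspot spacers must reach q ≤ 0.01 in ≥ 90% of seeds. Degenerate
inputs are defined, not guessed: zero effective length yields NaN densities
rather than an error, empty test families return empty tables, a zero
spectrum vector is rejected in cosine similarity, and rank-deficient designs
are rejected in the quadratic fit.

## Known limitations

Perfect-arm matching only (no mismatched or gapped stems, no cruciform
two-strand modelling, no thermodynamic ΔG); hotspot testing pools
occurrences per spacer sequence rather than testing each location against
its own sequence-matched background; per-signature attribution without
labels is probabilistic via exposures; the classifier thresholds (16/7) are
taken as fixed operating points, not re-derived.
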