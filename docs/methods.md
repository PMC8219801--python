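# Methods

## The analysis model

Bru-seq measures ongoing transcription by sequencing RNA labelled with
bromouridine over a 30-minute pulse. Recovery times of 0, 2, 6 and 24 h
plus the pulse give effective labelled timepoints of 0.5, 2.5, 6.5 and
24.5 h post irradiation (label-midpoint convention); the package accepts
either naming ("2h30" or 2.5) through an alias map.

Abundance is RPKM over the **full annotated gene body**, not exonic or
mature-transcript length, because nascent transcripts are intron-containing
and the downstream length partitions are transcription-unit lengths.
RPKM(g, s) = counts(g, s) / (length_kb(g) · library_size_millions(s)).

Because RPKM is normalised to total reads it cannot see genome-wide shifts
in transcriptional output — the dominant signal after UVC. Biological
scaling normalisation multiplies every RPKM value by a per-(condition,
timepoint) correction factor measured independently of sequencing (mean
nascent-RNA signal per nucleus relative to the same condition's
unirradiated sample). Factors are therefore anchored at 1 for every
condition's timepoint 0, and this is enforced as a hard invariant. Whether
replicates share one factor table is not constrained by the data model; the
default assumes per-(condition, timepoint) factors shared across
replicates.

All downstream statistics operate on ratios to the same condition's
baseline. Genes with zero baseline signal are excluded outright
("baseline_zero") rather than stabilised with pseudo-counts: the analysis
is threshold-based, and a pseudo-count would silently move genes across
fold-change boundaries.

## Classifiers and boundary conventions

* UV-repressed: control ratio at 2.5 h ≤ 1/2 (threshold fold 2,
  configurable). UV-induced: control ratio at 0.5 h ≥ 2. A gene meeting
  both is excluded as "conflict" rather than double-counted.
* Kinetics (repressed genes only): *fast* if the 2-fold drop is already
  present at 0.5 h, else *slow*. Fast ∪ slow = repressed exactly.
* Dependency: relative recovery r = (24.5 h ratio, knockdown)/(24.5 h
  ratio, control). r ≤ 0.90 → stimulated (the gene requires the factor);
  r ≥ 1.10 → inhibited; the open interval between → independent.
  "Transcription recovery" is the 24.5 h level relative to the same
  condition's baseline, not the rebound from the 2.5 h trough.

All "at least/at most" thresholds are inclusive on the
repressed/induced/stimulated/inhibited side, so the three dependency bands
tile (0, ∞) with no gaps and every positive ratio receives exactly one
class. Classification is invariant under any positive rescaling of a
gene's raw values, since only ratios enter.

Partitions (short/long, low/high expression, quartiles) recompute medians
and quartile breaks on the analysed set itself; reference values from any
particular dataset are never hard-coded. Ties at a median go to the lower
class; quartile ranks break length ties by gene identifier so the
shortest 25 % is quartile 1 deterministically.

With multiple replicates, terminal per-gene calls are made on
replicate-mean ratios; in `per_replicate` mode the report additionally
carries each replicate's repressed set and their intersection as a
consistency (Venn-style) view. Classifying per replicate and intersecting
is available to users who prefer per-experiment calls.

## Poisson lesion model

UV photoproducts are distributed essentially uniformly, so the expected
lesion count of a gene is λ = L · (dose/10 J/m²) · (1/6000 bp) · s, with
s = ½ for the transcribed strand (only template-strand lesions stall
RNAPII) and s = 1 for double-stranded DNA. Dose scaling is assumed linear
on both sides of the 10 J/m² reference. P(≥ 1 lesion) = 1 − e^(−λ),
computed with `expm1` for accuracy at small λ. "Damaged" means ≥ 1 lesion
within the annotated gene body; regulatory elements outside it are not
modelled. The predicted damaged fraction of a gene set is the mean of the
per-gene probabilities (per-gene averaging, not a single probability at
the mean length — the two differ because P is concave in L; the choice is
deliberate and tested against Monte-Carlo lesion placement).

## Overlap statistics

Coordinates are 0-based half-open throughout; 1-based inclusive input is
converted at the reader. Upstream (promoter) extension is strand-aware
(5 kb default), clipped at the chromosome origin; peaks are treated as
unstranded and a 1 bp overlap suffices to call a gene a peak target. Peak
filters follow the stated strict inequalities (FDR < 1, fold enrichment
> 10). Gene-list overlaps use the two-sided Fisher's exact test with the
minimum-likelihood summation convention (scipy's implementation; the test
suite checks it against an exact-rational hypergeometric enumeration).
The default universe is the analysed (baseline-detectable) gene set, not
the whole annotation, since compared lists are drawn from analysed genes.

## Synthetic cohorts

The generator plants a complete truth so that recovery of every label is a
measurable quantity, under these default study conditions:

| parameter | default | rationale |
|---|---|---|
| gene length | lognormal, median 48,667 bp, σ_log 1.3, ≥ 200 bp | median matches the analysed human nascent transcriptome; σ_log gives a realistically heavy tail |
| baseline expression | lognormal, median 0.2798 RPKM, σ_log 1.5 | median of detectable nascent genes |
| dose | 10 J/m² | the irradiation used for sequencing |
| damaged genes | Bernoulli(1 − e^(−λ(L))) | the lesion model itself |
| trans-repressed fraction | 0.35 of undamaged genes | slow repression of mostly short, undamaged genes |
| cis ratios | 0.30 (0.5 h), 0.25 (2.5 h) | fast, deep repression at damaged genes |
| trans ratios | 0.85 (0.5 h), 0.35 (2.5 h) | repression appearing only by 2.5 h |
| induced fraction / ratio | 0.02 of non-repressed genes, ×3 at 0.5 h | small immediate-early response |
| control recovery | 0.90 at 24.5 h | near-complete recovery in control |
| dependency plan | 88 % stimulated / 4.3 % independent / 7.7 % inhibited | the planted recovery-dependency structure |
| dependency effects | U(0.40, 0.75) / 1.0 / U(1.20, 1.50) | multiplicative caps on 24.5 h recovery mapping one-to-one onto the classifier bands |
| depth | 5 × 10⁷ reads/sample | typical per-sample depth for this assay |
| count noise | Poisson + 2 % lognormal overdispersion | tight technical replication at this depth |

Truth invariants: damaged ⇒ repressed with fast kinetics; trans-repressed
⇒ slow; dependency classes exist only for repressed genes.

Sequencing is emulated by distributing the fixed depth over genes
proportionally to signal × length (multinomial expectation), which
deliberately reproduces RPKM's blindness to the global level; the true
correction factor is the cohort-total nascent output at t relative to
t = 0 — the quantity an imaging measurement tracks — so that scaling
normalisation recovers planted ratios exactly in the noiseless limit.
Planted baseline "RPKM" values act as relative abundances: realised RPKM
differs from them by a single depth- and cohort-dependent constant, which
cancels in every ratio-based statistic (partition medians are recomputed
from realised values, as in real data).

What the generator does **not** emulate: read-position structure within
genes (promoter-proximal pausing profiles), sequence-dependent lesion
hotspots, lesion repair kinetics, mappability, or biological
between-replicate variability beyond count overdispersion. Passing
round-trip tests therefore validate the analysis logic and its estimators,
not robustness to those real-data features.

Peak generation places one passing peak inside each planted target gene's
extended interval, passing decoys on a gene-free chromosome, and
failing-attribute peaks (FDR = 1 or FE ≤ 10) on random genes, so the
stated filters retain exactly the intended set.

`tune_length_median_for_damage` solves E[1 − e^(−λ(L))] = p for the
lognormal median (truncated support, Gauss-like quadrature + Brent
bisection), used to build short-gene cohorts with a chosen predicted
damaged fraction.

## Numerical and design choices

* No pseudo-counts anywhere; zeros propagate to explicit exclusion
  reasons ("baseline_zero", "control_recovery_zero", "missing_ratio",
  "conflict"), and the report's gene accounting is checked to cover the
  annotation exactly.
* Unit scaling factors are a bit-wise identity (unit-factor columns are
  not touched), so an all-ones factor table cannot perturb values by
  float rounding.
* Sample standard deviations use ddof = 1, defined as 0 for a single
  gene.
* The pipeline is a pure function of (config, seed): reports are
  byte-identical across reruns, and every random draw descends from the
  config seed via independent `SeedSequence` streams per stage.
* Problem sizes in the test suite (cohorts of 400–5,000 genes, 20
  replicates for the stochastic recovery check, 10⁵ draws for
  Monte-Carlo agreement) were chosen as the smallest sizes at which the
  binomial/3σ arguments in the tests have the stated power.

## Known limitations

* The imaging-derived correction factors are consumed as a table; their
  estimation from images is out of scope, and factor error propagates
  multiplicatively into every ratio.
* Threshold classification near a boundary is intrinsically unstable
  under noise; the parameter-recovery guarantees hold for effect sizes
  away from the band edges (as planted), not for genes sitting on them.
* The lesion model ignores damage to regulatory elements outside gene
  bodies, so "predicted damaged" is a lower bound on lesion-affected
  genes.
* With a single replicate the per-replicate/replicate-mean distinction
  collapses; consistency reporting needs ≥ 2 replicates.
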