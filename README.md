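# uvrecover

Downstream analysis of nascent-RNA sequencing (Bru-seq) time courses after
UVC irradiation, for researchers studying how transcription shuts down and
restarts around DNA damage.

After UVC, photolesions (mainly cyclobutane pyrimidine dimers) stall
elongating RNA polymerase II in *cis*, and a global *trans* programme
represses transcription initiation genome-wide, including at undamaged
genes. Bru-seq time courses (labelled at 0, 0.5, 2.5, optionally 6.5, and
24.5 h post UV, in control and knockdown conditions) measure this
repression and the subsequent recovery — but only if the analysis corrects
for the fact that read-count normalisation erases genome-wide shifts.
`uvrecover` implements that full downstream analysis:

- **Quantification** — gene-body RPKM over the full transcription unit
  (nascent RNA contains introns), then *biological scaling normalisation*:
  every RPKM value is multiplied by an externally measured per-(condition,
  timepoint) correction factor (e.g. mean EU incorporation per nucleus
  relative to the unirradiated sample), restoring the global transcription
  scale. Post-UV levels are expressed relative to each condition's own
  baseline; genes undetectable before UV (RPKM = 0) are excluded.
- **Classification** — UV-repressed genes (level at 2.5 h ≤ ½ baseline in
  control) and UV-induced genes (≥ 2× at 0.5 h); *fast* (cis) versus *slow*
  (trans) repression kinetics; and recovery dependency per knockdown from
  the relative recovery ratio r = recovery(knockdown)/recovery(control) at
  24.5 h: the gene *requires* the factor if r ≤ 0.90 ("stimulated"),
  recovers better without it if r ≥ 1.10 ("inhibited"), and is independent
  in between. Gene sets are partitioned by length, expression and coding
  potential with medians recomputed on the analysed set.
- **Poisson lesion-load model** — at 10 J/m² the lesion rate is 1/6 kb on
  double-stranded DNA, hence λ = L/12 kb on the transcribed strand for a
  gene of length L, scaling linearly with dose; P(damaged) = 1 − e^(−λ).
  Comparing the predicted damaged fraction with the observed
  factor-dependent fraction on short genes separates lesion-driven from
  trans-acting recovery requirements.
- **Interval and overlap statistics** — strand-aware 5 kb upstream
  (promoter) extension, ChIP-peak filtering (FDR < 1, fold enrichment
  > 10), peak-to-gene intersection, and two-sided Fisher's exact tests for
  gene-list overlaps.
- **Synthetic cohorts with planted truth** — a generator that emulates the
  cohort structure (lognormal lengths and expression, Poisson-placed
  lesions, cis-fast/trans-slow repression, planted dependency classes,
  true scaling factors, planted peak targets) so that every stage is
  validated by parameter recovery.

## Worked example

```python
from uvrecover import GeneratorConfig, RunConfig, run_pipeline

cfg = RunConfig(simulate=GeneratorConfig(n_genes=5_000, seed=7), seed=7)
report = run_pipeline(cfg).report
print(report["dependency"]["knockdown_A"]["fractions"])
print(report["damage_vs_dependency"]["knockdown_A"])
```

prints (seed 7, 50 M reads/sample, 2 % overdispersion):

```
{'stimulated': 0.8764..., 'independent': 0.0413..., 'inhibited': 0.0821...}
{'predicted_damaged_fraction': 0.5848..., 'observed_dependent_fraction': 0.8600...,
 'excess': 0.2751..., 'n': 893}
```

The recovered dependency fractions match the planted plan (88 % of
UV-repressed genes require the knocked-down factor for recovery, 4.3 % are
independent, 7.7 % recover better without it). On the shortest quartile of
repressed genes the observed dependent fraction far exceeds the fraction
the Poisson model predicts can carry even one lesion — the signature of a
trans-acting, lesion-independent recovery requirement.

The `examples/` directory holds one short script per capability
(normalisation, classification, lesion model, peak overlap, full pipeline);
each prints its numbers with a line on what they mean. A thin CLI is also
installed:

```bash
uvrecover simulate --n-genes 2000 --seed 1 --out sim/
uvrecover run --config run.yaml --out results/
uvrecover figures --config run.yaml --out figs/
```

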