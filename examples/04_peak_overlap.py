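"""ChIP-peak filtering, promoter-extended intersection, and overlap testing.

Generates a synthetic cohort plus a peak set planted on 40% of genes,
filters peaks (FDR < 1, fold enrichment > 10), extends genes 5 kb upstream,
intersects, and tests whether targets are enriched among repressed genes.
"""

from uvrecover import (GeneratorConfig, extend_upstream_frame, filter_peaks,
                       generate_cohort, generate_peaks, intersect_targets,
                       overlap_fisher)

cfg = GeneratorConfig(n_genes=800, seed=3)
annotation, truth = generate_cohort(cfg)
# plant peaks preferentially on repressed genes
repressed = annotation.index[truth["repressed_truth"]]
peaks, planted = generate_peaks(annotation, cfg, target_fraction=0.4,
                                target_genes=repressed)

kept = filter_peaks(peaks, fdr_max=1.0, fold_enrichment_min=10.0)
print(f"peaks: {len(peaks)} total, {len(kept)} pass FDR < 1 and FE > 10")

extended = extend_upstream_frame(annotation[["chrom", "start", "end", "strand"]],
                                 distance_bp=5_000)
flags = intersect_targets(extended, kept)
print(f"target genes after intersection: {int(flags.sum())} "
      f"(planted: {len(planted)})")

res = overlap_fisher(set(repressed), set(flags.index[flags]),
                     set(annotation.index))
print(f"repressed vs targets: overlap {res.overlap_size}, "
      f"odds ratio {res.odds_ratio:.2f}, two-sided Fisher p = {res.p_value:.3g}")
print("\nA tiny p-value with a large odds ratio says the peak targets are "
      "enriched among UV-repressed genes far beyond chance.")
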