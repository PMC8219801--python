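"""End-to-end run under realistic noise, with figure export.

Simulates a 5,000-gene cohort at 50M-read depth with 2% overdispersion,
runs every stage, prints the report highlights and writes the figure panels
plus all tables to ./example_run/.
"""

import json

from uvrecover import GeneratorConfig, RunConfig, export_figures, run_pipeline

cfg = RunConfig(simulate=GeneratorConfig(n_genes=5_000, seed=7),
                output_dir="example_run", seed=7)
res = run_pipeline(cfg)
rep = res.report

print("analysed genes:", rep["n_analysed"], "of", rep["n_genes"])
print("computed medians:", {k: round(v, 4)
                            for k, v in rep["partition_medians"].items()})
print("mean expected lesions per length quartile of repressed genes:",
      {q: round(v, 2) for q, v in rep["quartile_mean_lesions"].items()})
pair = rep["damage_vs_dependency"]["knockdown_A"]
print(f"shortest-quartile repressed genes (<= {rep['short_gene_cutoff_bp']:.0f} bp): "
      f"predicted damaged {pair['predicted_damaged_fraction']:.2f} vs "
      f"observed dependent {pair['observed_dependent_fraction']:.2f}")
print("recovered dependency fractions:",
      {k: round(v, 3)
       for k, v in rep["dependency"]["knockdown_A"]["fractions"].items()})

paths = export_figures(res, "example_run/figures")
print("\nfigures written:", *[p.name for p in paths])
print("full report: example_run/report.json "
      f"({len(json.dumps(rep))} bytes of JSON)")
print("\nThe observed dependent fraction exceeding the predicted damaged "
      "fraction on the shortest genes is the signature of a trans-acting, "
      "lesion-independent requirement for transcription recovery.")
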