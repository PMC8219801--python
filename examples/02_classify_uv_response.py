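"""Classify a synthetic cohort: UV response, repression kinetics, dependency.

Simulates a 1,000-gene noiseless cohort, runs the classifiers via the
pipeline, and compares the calls with the planted truth.
"""

from uvrecover import GeneratorConfig, RunConfig, run_pipeline

cfg = GeneratorConfig(n_genes=1_000, seed=42, count_noise_sd=0.0)
res = run_pipeline(RunConfig(simulate=cfg, seed=42))

rep = res.report
print("gene accounting:", rep["accounting"])
print("kinetics among repressed genes:",
      {k: round(v, 3) for k, v in rep["kinetics_fractions"].items()})
dep = rep["dependency"]["knockdown_A"]
print("dependency fractions:", {k: round(v, 3) for k, v in dep["fractions"].items()})
print("agreement with planted truth:",
      {k: v for k, v in rep["truth_comparison"].items() if "agreement" in k})
print("\nWith zero noise every planted label is recovered exactly; the "
      "dependency fractions are the planted plan (88% of repressed genes "
      "require the knocked-down factor for recovery).")
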