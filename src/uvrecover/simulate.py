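"""Synthetic Bru-seq cohorts with planted truth.

Generates gene cohorts, UV-response time courses, true scaling factors and
ChIP-peak sets whose statistical structure matches what the downstream
analysis assumes, so every pipeline stage can be exercised against known
ground truth without any data download.

The kinetic model is multiplicative per gene g, condition c, timepoint t:

    signal(g, c, t) = baseline_rpkm(g) * cis(g, t) * trans(g, t)
                      * dependency_effect(g, c, t)

* cis: genes carrying >=1 transcribed-strand lesion (drawn per gene from
  the Poisson lesion model) are repressed already at 0.5 h and stay down at
  2.5 h, recovering by 24.5 h in the control — fast repression.
* trans: a configurable fraction of undamaged genes is repressed only from
  2.5 h — slow, lesion-independent repression.
* dependency_effect: under a knockdown, the 24.5 h recovery of a repressed
  gene is capped at <=0.9x (stimulated), left at 1.0x (independent) or
  lifted to >=1.1x (inhibited) of the control recovery, per the planted
  dependency class.

Sequencing is emulated by distributing a fixed read depth over genes
proportionally to signal x length (RPKM-style normalisation then cancels
the global transcription level, exactly the blind spot that biological
scaling normalisation corrects).  True correction factors are the
cohort-total nascent output at t relative to t = 0 per condition — the
quantity an EU-incorporation measurement tracks.

Counts are Poisson around a lognormally perturbed mean (overdispersion);
with ``count_noise_sd = 0`` exact expected counts are emitted, making
noiseless runs an identity round-trip for the classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .damage import LesionModelParams, prob_damaged, fraction_damaged
from .errors import ConfigError
from .intervals import extend_upstream_frame
from .quantify import ExpressionMatrix, ScalingFactorTable

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "simulate_timecourse",
    "generate_peaks",
    "tune_length_median_for_damage",
]

DEPENDENCY_CLASSES = ("stimulated", "independent", "inhibited")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the real experiment: lognormal gene lengths targeting
    a median of 48,667 bp, lognormal baseline expression targeting a median
    of 0.279766 RPKM, 10 J/m2 UVC, 50 million reads per sample, one control
    plus one knockdown condition at 0/0.5/2.5/24.5 h, and a dependency plan
    of 88% stimulated / 4.3% independent / 7.7% inhibited among repressed
    genes.
    """

    n_genes: int = 5000
    seed: int = 0
    # cohort structure
    length_median_bp: float = 48667.0
    length_sigma_log: float = 1.3
    min_length_bp: int = 200
    max_length_bp: float | None = None       # optional truncation (short-gene cohorts)
    expr_median_rpkm: float = 0.279766
    expr_sigma_log: float = 1.5
    coding_fraction: float = 0.85
    # damage / response structure
    dose: float = 10.0                        # J/m2
    trans_repressed_fraction: float = 0.35    # of undamaged genes, repressed in trans
    induced_fraction: float = 0.02            # of non-repressed genes
    cis_early_ratio: float = 0.30             # damaged genes at 0.5 h
    cis_late_ratio: float = 0.25              # damaged genes at 2.5 h
    trans_early_ratio: float = 0.85           # trans-repressed at 0.5 h (> 0.5: slow)
    trans_late_ratio: float = 0.35            # trans-repressed at 2.5 h
    induction_ratio: float = 3.0              # induced genes at 0.5 h
    recovery_control: float = 0.90            # mean 24.5 h ratio, control
    # knockdown dependency plan
    knockdowns: tuple[str, ...] = ("knockdown_A",)
    dependency_plan: dict = field(default_factory=lambda: {
        "stimulated": 0.88, "independent": 0.043, "inhibited": 0.077})
    stimulated_effect: tuple[float, float] = (0.40, 0.75)
    inhibited_effect: tuple[float, float] = (1.20, 1.50)
    # sequencing emulation
    timepoints: tuple[float, ...] = (0.0, 0.5, 2.5, 24.5)
    n_replicates: int = 1
    count_depth: float = 5e7                  # reads per sample
    count_noise_sd: float = 0.02              # lognormal overdispersion of the mean
    factor_noise_sd: float = 0.0              # lognormal noise on emitted factors
    # chromosome layout
    chrom_size_bp: int = 100_000_000
    intergenic_gap_bp: int = 20_000

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for name in ("trans_repressed_fraction", "induced_fraction", "coding_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        plan = self.dependency_plan
        if set(plan) - set(DEPENDENCY_CLASSES):
            raise ConfigError(f"unknown dependency classes in plan: {sorted(set(plan) - set(DEPENDENCY_CLASSES))}")
        if any(not 0 <= p <= 1 for p in plan.values()):
            raise ConfigError("dependency fractions must be in [0, 1]")
        if abs(sum(plan.values()) - 1.0) > 1e-9:
            raise ConfigError(f"dependency fractions must sum to 1, got {sum(plan.values())}")
        for name in ("length_median_bp", "expr_median_rpkm", "count_depth",
                     "recovery_control", "induction_ratio"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.dose < 0:
            raise ConfigError("dose must be non-negative")
        if self.count_noise_sd < 0 or self.factor_noise_sd < 0:
            raise ConfigError("noise parameters must be non-negative")

    def lesion_params(self) -> LesionModelParams | None:
        if self.dose == 0:
            return None
        return LesionModelParams(dose=self.dose)


def _sample_truncated_lognormal(rng, median, sigma, n, lo, hi):
    mu = math.log(median)
    out = rng.lognormal(mu, sigma, size=n)
    bad = (out < lo) | (hi is not None and (out > hi))
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = (out < lo) | (hi is not None and (out > hi))
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (annotation, truth) for a synthetic cohort.

    Annotation: gene_id-indexed chrom/start/end/strand/biotype/length_bp,
    genes laid out without overlap on synthetic chromosomes.  Truth holds
    the planted per-gene labels: damaged, repressed, induced, kinetics,
    dependency class and effect per knockdown, and the lesion-model
    probability used for the damage draw.  Fully deterministic under the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    lengths = np.round(_sample_truncated_lognormal(
        rng, config.length_median_bp, config.length_sigma_log, n,
        config.min_length_bp, config.max_length_bp)).astype(int)
    baseline = _sample_truncated_lognormal(
        rng, config.expr_median_rpkm, config.expr_sigma_log, n, 1e-6, None)
    coding = rng.random(n) < config.coding_fraction
    strand = np.where(rng.random(n) < 0.5, "+", "-")

    params = config.lesion_params()
    if params is None:
        p_dam = np.zeros(n)
    else:
        p_dam = prob_damaged(lengths, params)
    damaged = rng.random(n) < p_dam
    trans = ~damaged & (rng.random(n) < config.trans_repressed_fraction)
    repressed = damaged | trans
    induced = ~repressed & (rng.random(n) < config.induced_fraction)
    kinetics = np.where(damaged, "fast", np.where(trans, "slow", "not_applicable"))

    gene_ids = [f"G{i:06d}" for i in range(n)]
    truth = pd.DataFrame({
        "length_bp": lengths,
        "baseline_rpkm": baseline,
        "prob_damaged": p_dam,
        "damaged": damaged,
        "trans_repressed": trans,
        "repressed_truth": repressed,
        "induced_truth": induced,
        "kinetics_truth": kinetics,
    }, index=pd.Index(gene_ids, name="gene_id"))

    classes = np.array(DEPENDENCY_CLASSES)
    probs = np.array([config.dependency_plan.get(c, 0.0) for c in DEPENDENCY_CLASSES])
    for kd in config.knockdowns:
        cls = np.full(n, "not_applicable", dtype=object)
        eff = np.ones(n)
        idx = np.flatnonzero(repressed)
        draw = classes[rng.choice(len(classes), size=len(idx), p=probs)]
        cls[idx] = draw
        lo_s, hi_s = config.stimulated_effect
        lo_i, hi_i = config.inhibited_effect
        eff[idx] = np.where(
            draw == "stimulated", rng.uniform(lo_s, hi_s, size=len(idx)),
            np.where(draw == "inhibited", rng.uniform(lo_i, hi_i, size=len(idx)), 1.0))
        truth[f"dependency_truth_{kd}"] = cls
        truth[f"dependency_effect_{kd}"] = eff

    # non-overlapping layout on synthetic chromosomes
    chroms, starts, ends = [], [], []
    chrom_i, cursor = 1, config.intergenic_gap_bp
    for L in lengths:
        if cursor + L > config.chrom_size_bp:
            chrom_i += 1
            cursor = config.intergenic_gap_bp
        chroms.append(f"chrS{chrom_i}")
        starts.append(cursor)
        ends.append(cursor + int(L))
        cursor += int(L) + config.intergenic_gap_bp
    annotation = pd.DataFrame({
        "chrom": chroms, "start": starts, "end": ends, "strand": strand,
        "biotype": np.where(coding, "protein_coding", "noncoding"),
        "length_bp": lengths,
    }, index=truth.index)
    return annotation, truth


def _true_ratio(truth: pd.DataFrame, config: GeneratorConfig,
                condition: str, timepoint: float) -> np.ndarray:
    """Planted signal(g, c, t) / signal(g, c, 0) for every gene."""
    n = len(truth)
    r = np.ones(n)
    damaged = truth["damaged"].to_numpy()
    trans = truth["trans_repressed"].to_numpy()
    induced = truth["induced_truth"].to_numpy()
    repressed = truth["repressed_truth"].to_numpy()
    if timepoint == 0.0:
        return r
    if timepoint == 0.5:
        r[damaged] = config.cis_early_ratio
        r[trans] = config.trans_early_ratio
        r[induced] = config.induction_ratio
    elif timepoint == 24.5:
        rec = np.where(repressed, config.recovery_control, 1.0)
        if condition != "control":
            rec = rec * truth[f"dependency_effect_{condition}"].to_numpy()
        r = rec
    else:  # intermediate repression timepoints (2.5 h, optionally 6.5 h)
        r[damaged] = config.cis_late_ratio
        r[trans] = config.trans_late_ratio
    return r


def simulate_timecourse(annotation: pd.DataFrame, truth: pd.DataFrame,
                        config: GeneratorConfig
                        ) -> tuple[ExpressionMatrix, ScalingFactorTable]:
    """Simulate the sequencing time course and the true factor table.

    Returns a counts-state :class:`ExpressionMatrix` covering control +
    knockdown conditions at the configured timepoints and replicates, and
    the true :class:`ScalingFactorTable` (cohort-total nascent output at t
    relative to t = 0, per condition; optionally lognormally perturbed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    conditions = ["control", *config.knockdowns]
    len_kb = truth["length_bp"].to_numpy() / 1e3
    base = truth["baseline_rpkm"].to_numpy()

    values = {}
    meta_rows = []
    factors = {}
    for cond in conditions:
        w0 = float(np.sum(base * len_kb))
        for tp in config.timepoints:
            ratio = _true_ratio(truth, config, cond, tp)
            signal = base * ratio
            w = signal * len_kb
            f = float(np.sum(w)) / w0  # global nascent output relative to t = 0
            if tp != 0.0 and config.factor_noise_sd > 0:
                f *= rng.lognormal(0.0, config.factor_noise_sd)
            factors[(cond, tp)] = 1.0 if tp == 0.0 else f
            expected = w / w.sum() * config.count_depth
            for rep in range(1, config.n_replicates + 1):
                sid = f"{cond}_t{tp:g}_r{rep}"
                if config.count_noise_sd == 0:
                    counts = expected
                else:
                    mean = expected * rng.lognormal(0.0, config.count_noise_sd,
                                                    size=len(expected))
                    counts = rng.poisson(mean).astype(float)
                values[sid] = counts
                meta_rows.append({
                    "sample_id": sid, "condition": cond, "timepoint_h": tp,
                    "replicate": rep, "library_size": float(counts.sum()),
                })
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=truth.index),
        pd.DataFrame(meta_rows),
        state="counts",
    )
    return matrix, ScalingFactorTable(factors)


def generate_peaks(annotation: pd.DataFrame, config: GeneratorConfig,
                   target_fraction: float = 0.3,
                   target_genes=None,
                   peak_width: tuple[int, int] = (200, 1000),
                   decoy_fraction: float = 0.5,
                   failing_fraction: float = 0.3,
                   upstream_bp: int = 5000) -> tuple[pd.DataFrame, set]:
    """Generate a ChIP-peak table with a planted target-gene set.

    Target genes (a Bernoulli(target_fraction) draw over ``target_genes``,
    default the whole annotation) each receive one passing peak (fdr < 1,
    fold enrichment > 10) inside their 5 kb-upstream-extended interval.
    Decoys are passing peaks on a gene-free synthetic chromosome, plus
    peaks with failing attributes placed on random genes, so that the
    stated filters retain exactly the intended set.  Returns (peaks, set
    of planted target gene_ids).
    """
    if not 0 <= target_fraction <= 1:
        raise ConfigError("target_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pool = pd.Index(target_genes) if target_genes is not None else annotation.index
    picked = pool[rng.random(len(pool)) < target_fraction]
    extended = extend_upstream_frame(annotation.loc[:, ["chrom", "start", "end", "strand"]],
                                     upstream_bp)
    rows = []
    for i, gid in enumerate(picked):
        g = extended.loc[gid]
        width = int(rng.integers(peak_width[0], peak_width[1] + 1))
        lo = int(g["start"])
        hi = max(lo, int(g["end"]) - width)
        start = int(rng.integers(lo, hi + 1))
        rows.append({
            "chrom": g["chrom"], "start": start, "end": start + width,
            "name": f"peak_target_{i}", "score": 0, "strand": ".",
            "fdr": float(rng.uniform(0.0, 0.9)),
            "fold_enrichment": float(rng.uniform(12.0, 60.0)),
        })
    n_decoy = int(round(decoy_fraction * max(len(picked), 1)))
    for i in range(n_decoy):
        width = int(rng.integers(peak_width[0], peak_width[1] + 1))
        start = int(rng.integers(0, config.chrom_size_bp - width))
        rows.append({
            "chrom": "chrDecoy", "start": start, "end": start + width,
            "name": f"peak_decoy_{i}", "score": 0, "strand": ".",
            "fdr": float(rng.uniform(0.0, 0.9)),
            "fold_enrichment": float(rng.uniform(12.0, 60.0)),
        })
    n_fail = int(round(failing_fraction * max(len(picked), 1)))
    fail_genes = annotation.index[rng.integers(0, len(annotation), size=n_fail)]
    for i, gid in enumerate(fail_genes):
        g = extended.loc[gid]
        width = int(rng.integers(peak_width[0], peak_width[1] + 1))
        lo = int(g["start"])
        hi = max(lo, int(g["end"]) - width)
        start = int(rng.integers(lo, hi + 1))
        # failing attributes: boundary or sub-threshold values the filter drops
        if rng.random() < 0.5:
            fdr, fe = 1.0, float(rng.uniform(12.0, 60.0))
        else:
            fdr, fe = float(rng.uniform(0.0, 0.9)), float(rng.uniform(1.0, 10.0))
        rows.append({
            "chrom": g["chrom"], "start": start, "end": start + width,
            "name": f"peak_fail_{i}", "score": 0, "strand": ".",
            "fdr": fdr, "fold_enrichment": fe,
        })
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand",
                       "fdr", "fold_enrichment"])
    return peaks, set(picked)


def tune_length_median_for_damage(target_prob: float,
                                  sigma_log: float,
                                  max_length_bp: float,
                                  params: LesionModelParams = LesionModelParams(),
                                  min_length_bp: float = 200.0,
                                  n_quad: int = 20001) -> float:
    """Median of a truncated lognormal length law hitting a target mean
    damage probability.

    Solves E[1 - exp(-lambda(L))] = target_prob for the lognormal median,
    with L truncated to [min_length_bp, max_length_bp], by quadrature over
    the truncated law and bisection on the median.  Used to build cohorts
    whose Poisson-predicted damaged fraction equals a chosen value.
    """
    if not 0 < target_prob < 1:
        raise ConfigError("target_prob must be in (0, 1)")

    def mean_prob(median):
        mu = math.log(median)
        a = (math.log(min_length_bp) - mu) / sigma_log
        b = (math.log(max_length_bp) - mu) / sigma_log
        z = np.linspace(a, b, n_quad)
        dens = np.exp(-0.5 * z * z)
        lengths = np.exp(mu + sigma_log * z)
        probs = prob_damaged(lengths, params)
        return float(np.trapezoid(dens * probs, z) / np.trapezoid(dens, z))

    lo, hi = min_length_bp * 1.01, max_length_bp * 10
    return float(optimize.brentq(lambda m: mean_prob(m) - target_prob, lo, hi,
                                 xtol=1e-6, rtol=1e-12))
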