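"""End-to-end orchestration: quantify -> scale -> ratios -> classify ->
partitions -> damage model -> peak intersection -> overlap tests -> report.

A single :class:`RunConfig` drives both simulation mode (a
:class:`~uvrecover.simulate.GeneratorConfig` inline) and real-data mode
(paths to count/annotation/factor/peak tables), so synthetic validation and
reprocessing of deposited count tables share one code path.

With multiple replicates, terminal per-gene calls are made on the
replicate-mean ratio matrices; in ``per_replicate`` mode the report
additionally carries per-replicate UV-repressed sets and their
intersection (the Venn-style consistency view).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as uvio
from .classify import (EARLY_TIMEPOINT, LATE_TIMEPOINT, RECOVERY_TIMEPOINT,
                       call_dependency, call_kinetics, call_uv_response,
                       mean_response_curve, partition_genes,
                       summarize_dependency)
from .damage import LesionModelParams, damage_vs_dependency, expected_lesions, prob_damaged
from .errors import ConfigError, DataError
from .intervals import extend_upstream_frame, filter_peaks, intersect_targets, overlap_fisher
from .quantify import (ExpressionMatrix, RatioTable, ScalingFactorTable,
                       apply_scaling, compute_rpkm, filter_complete_cases,
                       relative_to_baseline)
from .simulate import GeneratorConfig, generate_cohort, generate_peaks, simulate_timecourse

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "export_figures"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``simulate`` is set (synthetic mode) or the input paths are.
    Thresholds default to the study's printed values: 2-fold response
    threshold, +/-10% dependency band, 5 kb upstream extension, FDR < 1 and
    fold enrichment > 10 peak filters, 10 J/m2 dose.
    """

    simulate: GeneratorConfig | None = None
    # real-data inputs
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    factors_path: str | None = None
    peaks_path: str | None = None
    # thresholds
    fold_threshold: float = 2.0
    dependency_band: float = 0.10
    upstream_bp: int = 5000
    fdr_max: float = 1.0
    fold_enrichment_min: float = 10.0
    dose: float = 10.0
    peak_target_fraction: float = 0.3
    # mode
    ratio_mode: str = "per_replicate"
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.simulate is None:
            need = [self.counts_path, self.sample_sheet_path,
                    self.annotation_path, self.factors_path]
            if any(p is None for p in need):
                raise ConfigError(
                    "either simulate or counts/sample_sheet/annotation/factors "
                    "paths must be provided")
        if self.fold_threshold <= 1:
            raise ConfigError("fold_threshold must exceed 1")
        if not 0 < self.dependency_band < 1:
            raise ConfigError("dependency_band must be in (0, 1)")
        if self.dose <= 0:
            raise ConfigError("dose must be positive")
        if self.ratio_mode not in ("per_replicate", "replicate_mean"):
            raise ConfigError(f"unknown ratio_mode {self.ratio_mode!r}")

    def config_hash(self) -> str:
        payload = asdict(self)
        if self.simulate is not None:
            payload["simulate"] = asdict(self.simulate)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: dict
    classification: pd.DataFrame
    ratios: RatioTable
    scaled: ExpressionMatrix
    annotation: pd.DataFrame
    curves: dict
    heatmap: pd.DataFrame
    truth: pd.DataFrame | None = None


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, (DataError, ConfigError)):
                exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",)
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and assemble the machine-readable report."""
    truth = None
    with _stage("load"):
        if config.simulate is not None:
            gen = config.simulate
            annotation, truth = generate_cohort(gen)
            counts, factors = simulate_timecourse(annotation, truth, gen)
            peaks, planted_targets = generate_peaks(
                annotation, gen, target_fraction=config.peak_target_fraction,
                upstream_bp=config.upstream_bp)
        else:
            annotation = uvio.read_annotation(config.annotation_path)
            counts = uvio.read_expression(config.counts_path, config.sample_sheet_path)
            factors = uvio.read_factor_table(config.factors_path)
            peaks = (uvio.read_peaks_bed(config.peaks_path)
                     if config.peaks_path else None)
            planted_targets = None

    with _stage("quantify"):
        rpkm = compute_rpkm(counts, annotation["length_bp"])
        scaled = apply_scaling(rpkm, factors)

    with _stage("ratios"):
        ratios = relative_to_baseline(scaled, mode=config.ratio_mode)
        control_wide = ratios.wide("control")
        analysed = control_wide.index
        knockdowns = [c for c in scaled.conditions if c != "control"]

    with _stage("classify"):
        responses = call_uv_response(control_wide, config.fold_threshold)
        repressed = responses.index[responses["response"] == "repressed"]
        kinetics = call_kinetics(responses, control_wide, config.fold_threshold)
        dependency = {}
        for kd in knockdowns:
            kd_wide = ratios.wide(kd)
            dependency[kd] = call_dependency(
                control_wide, kd_wide, repressed,
                recovery_timepoint=RECOVERY_TIMEPOINT, band=config.dependency_band)
        if config.ratio_mode == "per_replicate" and "replicate" in ratios.ratios.columns:
            reps = sorted(ratios.ratios["replicate"].unique())
            per_rep_repressed = {
                int(r): set(call_uv_response(ratios.wide("control", replicate=r),
                                             config.fold_threshold)
                            .query("response == 'repressed'").index)
                for r in reps
            }
        else:
            per_rep_repressed = None

    with _stage("partitions"):
        baseline_ids = scaled.sample_ids("control", 0.0)
        baseline_rpkm = rpkm.values[baseline_ids].mean(axis=1).loc[analysed]
        partitions = partition_genes(
            annotation.loc[analysed, "length_bp"].astype(float),
            baseline_rpkm,
            annotation["biotype"] if "biotype" in annotation.columns else None)

    with _stage("damage"):
        params = LesionModelParams(dose=config.dose)
        lam = expected_lesions(annotation.loc[analysed, "length_bp"].to_numpy(),
                               params, strand="transcribed")
        damage_table = pd.DataFrame({
            "length_bp": annotation.loc[analysed, "length_bp"],
            "expected_lesions": lam,
            "prob_damaged": prob_damaged(
                annotation.loc[analysed, "length_bp"].to_numpy(), params),
        }, index=analysed)
        rep_part = partitions.loc[repressed]
        quartile_lambda = {
            int(q): float(damage_table.loc[
                rep_part.index[rep_part["length_quartile"] == q],
                "expected_lesions"].mean())
            for q in (1, 2, 3, 4) if (rep_part["length_quartile"] == q).any()
        }
        short_cutoff = (float(rep_part.loc[rep_part["length_quartile"] == 1,
                                           "length_bp"].max())
                        if len(rep_part) else float("nan"))
        short_repressed = rep_part.index[rep_part["length_quartile"] == 1]
        fig5e = {}
        for kd in knockdowns:
            if len(short_repressed):
                fig5e[kd] = damage_vs_dependency(
                    annotation.loc[short_repressed, "length_bp"].astype(float),
                    dependency[kd]["dependency"].loc[short_repressed], params)

    with _stage("intersect"):
        overlaps = {}
        target_flags = None
        if peaks is not None and len(peaks):
            kept = filter_peaks(peaks, config.fdr_max, config.fold_enrichment_min)
            extended = extend_upstream_frame(
                annotation.loc[analysed, ["chrom", "start", "end", "strand"]],
                config.upstream_bp)
            target_flags = intersect_targets(extended, kept)
            targets = set(target_flags.index[target_flags])
            universe = set(analysed)
            overlaps["repressed_vs_targets"] = overlap_fisher(
                set(repressed), targets, universe).to_dict()
            for kd in knockdowns:
                dep = dependency[kd]
                stim = set(dep.index[dep["dependency"] == "stimulated"])
                overlaps[f"stimulated_{kd}_vs_targets"] = overlap_fisher(
                    stim, targets, universe).to_dict()

    with _stage("report"):
        classification = responses.copy()
        classification["kinetics"] = kinetics.reindex(classification.index) \
            .fillna("not_applicable")
        for kd in knockdowns:
            dep = dependency[kd]
            classification[f"dependency_{kd}"] = dep["dependency"] \
                .reindex(classification.index).fillna("not_applicable")
            classification[f"relative_recovery_{kd}"] = dep["relative_recovery"] \
                .reindex(classification.index)
        classification = classification.join(
            partitions.drop(columns=["length_bp"]), how="left")
        classification = classification.join(damage_table, how="left")
        if target_flags is not None:
            classification["peak_target"] = target_flags.reindex(classification.index)

        n_total = len(annotation)
        excluded_baseline = ratios.excluded_genes("control")
        resp_counts = responses["response"].value_counts().to_dict()
        accounting = {
            "baseline_zero": len(excluded_baseline),
            "repressed": int(resp_counts.get("repressed", 0)),
            "induced": int(resp_counts.get("induced", 0)),
            "unchanged": int(resp_counts.get("unchanged", 0)),
            "conflict": int(resp_counts.get("excluded", 0)),
        }
        if sum(accounting.values()) != n_total:
            raise DataError("gene accounting does not cover the annotation")

        curves = {}
        if len(repressed):
            for cond in scaled.conditions:
                if cond == "control":
                    curves[cond] = mean_response_curve(control_wide, repressed)
                else:
                    wide = ratios.wide(cond)
                    common = repressed.intersection(wide.index)
                    if len(common):
                        curves[cond] = mean_response_curve(wide, common)

        cc_conditions = list(scaled.conditions)
        complete = filter_complete_cases(scaled, cc_conditions)
        heat_genes = pd.Index(repressed).intersection(complete)
        heat_cols = {}
        for cond in cc_conditions:
            wide = ratios.wide(cond)
            for tp in sorted(c for c in wide.columns):
                heat_cols[f"{cond}@{tp:g}h"] = wide.reindex(heat_genes)[tp]
        heatmap = pd.DataFrame(heat_cols, index=heat_genes)
        heatmap.insert(0, "length_bp", annotation.loc[heat_genes, "length_bp"])
        heatmap = heatmap.sort_values("length_bp")

        n_rep = max(len(repressed), 1)
        report = {
            "provenance": {
                "package": "uvrecover",
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.seed,
            },
            "n_genes": n_total,
            "n_analysed": int(len(analysed)),
            "accounting": accounting,
            "response_fractions": {
                k: accounting[k] / n_total for k in accounting},
            "kinetics_fractions": {
                "fast": float((kinetics == "fast").sum()) / n_rep,
                "slow": float((kinetics == "slow").sum()) / n_rep,
            },
            "dependency": {kd: summarize_dependency(dependency[kd])
                           for kd in knockdowns if len(repressed)},
            "partition_medians": {
                "length_median_bp": partitions.attrs["length_median_bp"],
                "rpkm_median": partitions.attrs["rpkm_median"],
            },
            "quartile_mean_lesions": quartile_lambda,
            "short_gene_cutoff_bp": short_cutoff,
            "damage_vs_dependency": fig5e,
            "overlaps": overlaps,
            "curves": {c: curves[c].reset_index().to_dict(orient="list")
                       for c in curves},
            "heatmap_n_genes": int(len(heat_genes)),
        }
        if per_rep_repressed is not None and len(per_rep_repressed) > 1:
            inter = set.intersection(*per_rep_repressed.values())
            report["replicate_consistency"] = {
                "per_replicate_repressed": {str(r): len(s)
                                            for r, s in per_rep_repressed.items()},
                "intersection": len(inter),
            }
        if truth is not None:
            planted = truth.loc[analysed]
            report["truth_comparison"] = _truth_comparison(
                planted, responses, kinetics, dependency, knockdowns)
            if planted_targets is not None and target_flags is not None:
                tgt = set(target_flags.index[target_flags])
                report["truth_comparison"]["peak_target_agreement"] = (
                    len(tgt & (planted_targets & set(analysed)))
                    / max(len(planted_targets & set(analysed)), 1))

    result = PipelineResult(report=report, classification=classification,
                            ratios=ratios, scaled=scaled, annotation=annotation,
                            curves=curves, heatmap=heatmap, truth=truth)
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _truth_comparison(planted, responses, kinetics, dependency, knockdowns) -> dict:
    called_rep = responses["response"] == "repressed"
    out = {
        "repressed_agreement": float(
            (called_rep == planted["repressed_truth"]).mean()),
        "induced_agreement": float(
            ((responses["response"] == "induced")
             == (planted["induced_truth"] & ~planted["repressed_truth"])).mean()),
    }
    rep_both = planted.index[planted["repressed_truth"] & called_rep]
    if len(rep_both):
        out["kinetics_agreement"] = float(
            (kinetics.loc[rep_both] == planted.loc[rep_both, "kinetics_truth"]).mean())
    for kd in knockdowns:
        col = f"dependency_truth_{kd}"
        if col in planted.columns and len(rep_both):
            dep = dependency[kd]["dependency"].loc[rep_both]
            out[f"dependency_agreement_{kd}"] = float(
                (dep == planted.loc[rep_both, col]).mean())
            out[f"recovered_fractions_{kd}"] = {
                c: float((dep == c).mean())
                for c in ("stimulated", "independent", "inhibited")}
            out[f"planted_fractions_{kd}"] = {
                c: float((planted.loc[rep_both, col] == c).mean())
                for c in ("stimulated", "independent", "inhibited")}
    return out


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.classification.to_csv(outdir / "classification.tsv", sep="\t")
    result.ratios.ratios.to_csv(outdir / "ratios.tsv", sep="\t", index=False)
    result.ratios.excluded.to_csv(outdir / "excluded.tsv", sep="\t", index=False)
    result.heatmap.to_csv(outdir / "heatmap.tsv", sep="\t")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)


def export_figures(result: PipelineResult, outdir) -> list:
    """Write the standard panels as PNGs; returns the written paths.

    Panels: recovery curves (mean +/- sd per condition over UV-repressed
    genes), dependency pie per knockdown, ratio heatmap (genes ranked by
    length) and the predicted-damaged vs observed-dependent bar pair.
    Empty panels are skipped with a warning.
    """
    import warnings

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if result.curves:
        fig, ax = plt.subplots(figsize=(5, 4))
        for cond, curve in result.curves.items():
            ax.errorbar(curve.index, curve["mean"], yerr=curve["sd"],
                        marker="o", capsize=3, label=cond)
        ax.set_xlabel("time post UVC (h)")
        ax.set_ylabel("nascent level relative to t=0")
        ax.legend()
        ax.set_title("UV-repressed genes: repression and recovery")
        fig.tight_layout()
        path = outdir / "recovery_curves.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    else:
        warnings.warn("no UV-repressed genes: recovery-curve panel omitted")

    for kd, summary in result.report.get("dependency", {}).items():
        fracs = summary["fractions"]
        labels = [c for c in fracs if fracs[c] > 0]
        if not labels:
            warnings.warn(f"empty dependency classes for {kd}: pie omitted")
            continue
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.pie([fracs[c] for c in labels], labels=labels, autopct="%.1f%%")
        ax.set_title(f"recovery dependency on {kd}")
        path = outdir / f"dependency_pie_{kd}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    heat = result.heatmap.drop(columns=["length_bp"], errors="ignore")
    if len(heat):
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(np.clip(heat.to_numpy(dtype=float), 0, 2),
                       aspect="auto", cmap="RdBu_r", vmin=0, vmax=2)
        ax.set_xticks(range(len(heat.columns)))
        ax.set_xticklabels(heat.columns, rotation=90, fontsize=6)
        ax.set_ylabel(f"{len(heat)} genes (ranked by length)")
        fig.colorbar(im, ax=ax, label="ratio to t=0")
        fig.tight_layout()
        path = outdir / "heatmap.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    else:
        warnings.warn("no complete-case repressed genes: heatmap omitted")

    for kd, pair in result.report.get("damage_vs_dependency", {}).items():
        fig, ax = plt.subplots(figsize=(3.5, 4))
        ax.bar(["predicted\ndamaged", f"observed\n{kd}-dependent"],
               [pair["predicted_damaged_fraction"],
                pair["observed_dependent_fraction"]],
               color=["grey", "firebrick"])
        ax.set_ylabel("fraction of short UV-repressed genes")
        ax.set_ylim(0, 1)
        fig.tight_layout()
        path = outdir / f"damage_vs_dependency_{kd}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
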