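"""UV-response, repression-kinetics and recovery-dependency classification.

All classifiers operate on baseline-normalised ratio matrices (genes x
timepoints, see :meth:`uvrecover.quantify.RatioTable.wide`) and use simple
fold-change thresholds:

* UV-repressed: nascent level at 2.5 h post UVC at or below 1/2 of the
  pre-irradiation level (control condition).
* UV-induced: level at 0.5 h at or above 2x baseline.
* Fast vs slow repression: a repressed gene is *fast* if the 2-fold drop is
  already visible at 0.5 h (cis inhibition by lesions blocking elongating
  RNAPII), *slow* if it only appears by 2.5 h (trans repression of mostly
  undamaged genes).
* Recovery dependency: for each UV-repressed gene, the 24.5 h recovery
  ratio under a knockdown divided by the control recovery ratio.  At most
  0.90 -> the gene *requires* the factor ("stimulated" by it); at least
  1.10 -> the gene recovers better without it ("inhibited"); strictly in
  between -> independent.  The three bands tile (0, inf).

Boundaries follow the literal "at least / at most" reading and are
inclusive on the repressed/induced/stimulated/inhibited side.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "call_uv_response",
    "call_kinetics",
    "call_dependency",
    "classify_recovery_ratio",
    "partition_genes",
    "summarize_dependency",
    "mean_response_curve",
    "EARLY_TIMEPOINT",
    "LATE_TIMEPOINT",
    "RECOVERY_TIMEPOINT",
]

EARLY_TIMEPOINT = 0.5   # 30 min post UVC (label midpoint)
LATE_TIMEPOINT = 2.5    # 2 h 30 min
RECOVERY_TIMEPOINT = 24.5

#: dependency band half-width: +/-10% around the control recovery
DEPENDENCY_BAND = 0.10


def _require_timepoint(wide: pd.DataFrame, tp: float) -> pd.Series:
    if tp not in wide.columns:
        raise DataError(f"ratio matrix is missing timepoint {tp} h "
                        f"(has {sorted(wide.columns)})")
    return wide[tp]


def call_uv_response(control_wide: pd.DataFrame,
                     threshold_fold: float = 2.0,
                     early: float = EARLY_TIMEPOINT,
                     late: float = LATE_TIMEPOINT) -> pd.DataFrame:
    """Classify genes as repressed / induced / unchanged in the control.

    Returns a frame indexed by gene_id with columns ``response``,
    ``early_ratio`` (0.5 h), ``late_ratio`` (2.5 h) and ``reason``.  A gene
    meeting both the repression and the induction criterion is excluded
    with reason ``conflict``.
    """
    if threshold_fold <= 1:
        raise DataError(f"threshold_fold must exceed 1, got {threshold_fold}")
    r_early = _require_timepoint(control_wide, early)
    r_late = _require_timepoint(control_wide, late)
    repressed = r_late <= 1.0 / threshold_fold
    induced = r_early >= threshold_fold
    response = np.select(
        [repressed & induced, repressed, induced],
        ["excluded", "repressed", "induced"],
        default="unchanged",
    )
    out = pd.DataFrame({
        "response": response,
        "early_ratio": r_early,
        "late_ratio": r_late,
        "reason": np.where(repressed & induced, "conflict", ""),
    }, index=control_wide.index)
    out.index.name = "gene_id"
    return out


def call_kinetics(responses: pd.DataFrame,
                  control_wide: pd.DataFrame,
                  threshold_fold: float = 2.0,
                  early: float = EARLY_TIMEPOINT,
                  genes: Iterable[str] | None = None) -> pd.Series:
    """Fast/slow repression calls for the UV-repressed genes.

    Fast: the >=2-fold inhibition is already detectable at 0.5 h
    (early ratio <= 1/threshold); slow otherwise.  Requesting kinetics for
    a gene that is not repressed raises.
    """
    if genes is None:
        genes = responses.index[responses["response"] == "repressed"]
    else:
        genes = pd.Index(genes)
        bad = genes[responses.loc[genes, "response"] != "repressed"]
        if len(bad):
            raise DataError(f"kinetics undefined for non-repressed gene(s): {list(bad)[:5]}")
    r_early = _require_timepoint(control_wide, early).loc[genes]
    kin = pd.Series(np.where(r_early <= 1.0 / threshold_fold, "fast", "slow"),
                    index=genes, name="kinetics")
    kin.index.name = "gene_id"
    return kin


def classify_recovery_ratio(relative_recovery, band: float = DEPENDENCY_BAND):
    """Map relative recovery ratio(s) to dependency class(es).

    stimulated: r <= 1 - band; inhibited: r >= 1 + band; independent in the
    open band between.  Vectorised; every positive ratio maps to exactly
    one class.
    """
    r = np.asarray(relative_recovery, dtype=float)
    out = np.select([r <= 1.0 - band, r >= 1.0 + band],
                    ["stimulated", "inhibited"], default="independent")
    if out.ndim == 0:
        return out.item()
    return out


def call_dependency(control_wide: pd.DataFrame,
                    knockdown_wide: pd.DataFrame,
                    genes: Iterable[str],
                    recovery_timepoint: float = RECOVERY_TIMEPOINT,
                    band: float = DEPENDENCY_BAND) -> pd.DataFrame:
    """Dependency of transcription recovery on the knocked-down factor.

    ``genes`` is the UV-repressed set to classify.  Transcription recovery
    is the 24.5 h level normalised to the same condition's baseline;
    relative recovery = knockdown / control.  Genes absent from the
    knockdown table (no baseline there) or with zero control recovery are
    excluded with an explicit reason.
    """
    genes = pd.Index(genes)
    rec_ctrl = _require_timepoint(control_wide, recovery_timepoint)
    rec_kd = _require_timepoint(knockdown_wide, recovery_timepoint)
    out = pd.DataFrame(index=genes, columns=[
        "recovery_control", "recovery_knockdown", "relative_recovery",
        "dependency", "reason"])
    out.index.name = "gene_id"
    out["recovery_control"] = rec_ctrl.reindex(genes)
    out["recovery_knockdown"] = rec_kd.reindex(genes)
    missing = out["recovery_control"].isna() | out["recovery_knockdown"].isna()
    zero_ctrl = ~missing & (out["recovery_control"] == 0)
    ok = ~missing & ~zero_ctrl
    rel = out.loc[ok, "recovery_knockdown"] / out.loc[ok, "recovery_control"]
    out.loc[ok, "relative_recovery"] = rel
    out["dependency"] = "excluded"
    out.loc[ok, "dependency"] = classify_recovery_ratio(rel.to_numpy(), band=band)
    out["reason"] = ""
    out.loc[missing, "reason"] = "missing_ratio"
    out.loc[zero_ctrl, "reason"] = "control_recovery_zero"
    return out


def partition_genes(lengths: pd.Series,
                    baseline_rpkm: pd.Series,
                    biotypes: pd.Series | None = None) -> pd.DataFrame:
    """Partition the analysed gene set by length, expression and biotype.

    Medians and quartile breaks are recomputed on the analysed set itself.
    Ties at the median go to the lower class (short / low); quartile ranks
    break ties by (length, gene_id) so the shortest 25% is quartile 1
    deterministically.  The computed medians are attached as
    ``result.attrs['length_median_bp']`` / ``['rpkm_median']``.
    """
    genes = pd.Index(lengths.index)
    if len(genes) == 0:
        raise DataError("partition_genes: empty gene set")
    if not genes.equals(pd.Index(baseline_rpkm.index)):
        baseline_rpkm = baseline_rpkm.reindex(genes)
        if baseline_rpkm.isna().any():
            raise DataError("baseline RPKM missing for some genes")
    length_median = float(lengths.median())
    rpkm_median = float(baseline_rpkm.median())
    out = pd.DataFrame(index=genes)
    out.index.name = "gene_id"
    out["length_bp"] = lengths
    out["length_class"] = np.where(lengths <= length_median, "short", "long")
    order = sorted(genes, key=lambda g: (lengths[g], g))
    rank = pd.Series({g: i for i, g in enumerate(order)})
    out["length_quartile"] = (rank.loc[genes] * 4 // len(genes) + 1).astype(int)
    out["expression_class"] = np.where(baseline_rpkm <= rpkm_median, "low", "high")
    if biotypes is not None:
        bt = biotypes.reindex(genes)
        out["biotype_class"] = np.where(
            bt.astype(str).str.contains("coding", case=False) & ~bt.isna(),
            "coding", "noncoding")
    out.attrs["length_median_bp"] = length_median
    out.attrs["rpkm_median"] = rpkm_median
    return out


def summarize_dependency(dependency: pd.DataFrame) -> dict:
    """Class fractions over non-excluded UV-repressed genes + gene lists."""
    kept = dependency[dependency["dependency"] != "excluded"]
    if len(kept) == 0:
        raise DataError("summarize_dependency: no non-excluded calls")
    classes = ("stimulated", "independent", "inhibited")
    n = len(kept)
    fractions = {c: float((kept["dependency"] == c).sum()) / n for c in classes}
    gene_lists = {c: sorted(kept.index[kept["dependency"] == c]) for c in classes}
    return {
        "n": n,
        "n_excluded": int((dependency["dependency"] == "excluded").sum()),
        "fractions": fractions,
        "genes": gene_lists,
    }


def mean_response_curve(wide: pd.DataFrame, genes: Iterable[str]) -> pd.DataFrame:
    """Mean +/- sample sd of ratios over a gene set at each timepoint.

    The summary-curve statistic behind recovery plots.  sd is the ddof=1
    sample standard deviation (0 for a single gene); n is reported.
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise DataError("mean_response_curve: empty gene set")
    sub = wide.loc[genes]
    out = pd.DataFrame({
        "mean": sub.mean(axis=0),
        "sd": sub.std(axis=0, ddof=1).fillna(0.0) if len(genes) > 1
              else pd.Series(0.0, index=sub.columns),
        "n": sub.notna().sum(axis=0).astype(int),
    })
    out.index.name = "timepoint_h"
    return out
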