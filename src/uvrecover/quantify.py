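"""Gene-body quantification and biological scaling normalisation.

Bru-seq measures nascent transcription by sequencing bromouridine-labelled
RNA over a short pulse.  Abundances are expressed as RPKM over the *full*
annotated gene body (nascent transcripts contain introns), and because RPKM
is normalised to total reads it is blind to genome-wide shifts in
transcriptional output — precisely the signal of interest after UVC
irradiation.  Biological scaling normalisation restores the global scale by
multiplying every RPKM value by an externally measured per-(condition,
timepoint) correction factor (e.g. mean EU-incorporation per nucleus
relative to the unirradiated sample of the same condition).

The module is organised around :class:`ExpressionMatrix` (genes x samples
with a state flag tracking the counts -> rpkm -> scaled_rpkm progression),
:class:`ScalingFactorTable`, and :class:`RatioTable` (post-UV levels
relative to each condition's own unirradiated baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "ExpressionMatrix",
    "ScalingFactorTable",
    "RatioTable",
    "compute_rpkm",
    "apply_scaling",
    "relative_to_baseline",
    "filter_complete_cases",
    "parse_timepoint",
]

#: canonical recovery timepoints (hours post UVC, BrU-label midpoint
#: convention: 0/2/6/24 h recovery + 30 min labelling pulse)
CANONICAL_TIMEPOINTS = (0.0, 0.5, 2.5, 6.5, 24.5)

_TIMEPOINT_ALIASES = {
    "0": 0.0, "0h": 0.0, "0h00": 0.0, "t0": 0.0, "nouv": 0.0, "no_uv": 0.0,
    "30min": 0.5, "0h30": 0.5, "0.5": 0.5, "0.5h": 0.5,
    "2h30": 2.5, "2.5": 2.5, "2.5h": 2.5,
    "6h30": 6.5, "6.5": 6.5, "6.5h": 6.5,
    "24h30": 24.5, "24.5": 24.5, "24.5h": 24.5,
}

SAMPLE_COLUMNS = ["condition", "timepoint_h", "replicate", "library_size"]


def parse_timepoint(label) -> float:
    """Resolve a timepoint label (``"2h30"``, ``"24.5"``, 2.5, ...) to hours.

    User tables may name timepoints either by recovery time + label midpoint
    ("2h30") or numerically; both resolve to the same float.
    """
    if isinstance(label, (int, float, np.integer, np.floating)):
        return float(label)
    key = str(label).strip().lower()
    if key in _TIMEPOINT_ALIASES:
        return _TIMEPOINT_ALIASES[key]
    try:
        return float(key)
    except ValueError:
        raise DataError(f"unrecognised timepoint label: {label!r}") from None


def _normalise_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    samples = samples.copy()
    if "sample_id" in samples.columns:
        samples = samples.set_index("sample_id")
    missing = [c for c in ("condition", "timepoint_h") if c not in samples.columns]
    if missing:
        raise DataError(f"sample sheet missing columns: {missing}")
    if not samples.index.is_unique:
        dupes = samples.index[samples.index.duplicated()].tolist()
        raise DataError(f"duplicate sample_id(s): {dupes}")
    samples["timepoint_h"] = [parse_timepoint(t) for t in samples["timepoint_h"]]
    if "replicate" not in samples.columns:
        samples["replicate"] = 1
    samples["replicate"] = samples["replicate"].astype(int)
    if "library_size" not in samples.columns:
        samples["library_size"] = np.nan
    return samples


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with sample metadata.

    ``state`` tracks the allowed normalisation progression
    counts -> rpkm -> scaled_rpkm.  Values are non-negative reals
    (fractional "counts" are permitted so that noiseless expected counts can
    flow through the same code path).
    """

    values: pd.DataFrame  # index: gene_id, columns: sample_id
    samples: pd.DataFrame  # index: sample_id; condition/timepoint_h/replicate/library_size
    state: str = "counts"

    _STATES = ("counts", "rpkm", "scaled_rpkm")

    def __post_init__(self) -> None:
        if self.state not in self._STATES:
            raise DataError(f"unknown matrix state {self.state!r}")
        self.samples = _normalise_sample_sheet(self.samples)
        extra = set(self.values.columns) - set(self.samples.index)
        if extra:
            raise DataError(f"samples missing from sample sheet: {sorted(extra)}")
        # keep metadata aligned with (and ordered like) the value columns
        self.samples = self.samples.loc[list(self.values.columns)]
        if (self.values.to_numpy() < 0).any():
            raise DataError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.samples["condition"]))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(self.values.loc[genes], self.samples.copy(), self.state)

    def sample_ids(self, condition=None, timepoint=None, replicate=None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if timepoint is not None:
            mask &= self.samples["timepoint_h"] == parse_timepoint(timepoint)
        if replicate is not None:
            mask &= self.samples["replicate"] == replicate
        return list(self.samples.index[mask])


class ScalingFactorTable:
    """Per-(condition, timepoint) global-transcription correction factors.

    Factors are defined relative to each condition's own unirradiated
    sample, so the factor at timepoint 0 is identically 1 for every
    condition (an absent timepoint-0 entry is treated as the implied 1).
    """

    def __init__(self, entries: Mapping[tuple[str, float], float]):
        self._entries: dict[tuple[str, float], float] = {}
        for (cond, tp), factor in entries.items():
            tp = parse_timepoint(tp)
            factor = float(factor)
            if not factor > 0:
                raise DataError(f"non-positive scaling factor for ({cond}, {tp}): {factor}")
            if tp == 0.0 and factor != 1.0:
                raise DataError(
                    f"baseline factor for condition {cond!r} must be exactly 1, got {factor}"
                )
            self._entries[(str(cond), tp)] = factor

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScalingFactorTable":
        """Build from a table with columns condition, timepoint_h, factor."""
        need = {"condition", "timepoint_h", "factor"}
        if not need.issubset(frame.columns):
            raise DataError(f"factor table needs columns {sorted(need)}")
        return cls({
            (row.condition, row.timepoint_h): row.factor
            for row in frame.itertuples(index=False)
        })

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": c, "timepoint_h": t, "factor": f}
            for (c, t), f in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows, columns=["condition", "timepoint_h", "factor"])

    def factor(self, condition: str, timepoint) -> float:
        tp = parse_timepoint(timepoint)
        if tp == 0.0:
            return self._entries.get((condition, 0.0), 1.0)
        try:
            return self._entries[(condition, tp)]
        except KeyError:
            raise DataError(
                f"no scaling factor for (condition={condition!r}, timepoint={tp})"
            ) from None

    def __eq__(self, other) -> bool:
        return isinstance(other, ScalingFactorTable) and self._entries == other._entries


@dataclass
class RatioTable:
    """Post-UV nascent levels relative to the same condition's baseline.

    ``ratios`` is long-form with columns gene_id, condition, timepoint_h,
    ratio (plus replicate in per_replicate mode).  Genes whose baseline is
    zero in a condition are moved to ``excluded`` with reason
    ``baseline_zero`` — the RPKM > 0 detectability filter.
    """

    ratios: pd.DataFrame
    excluded: pd.DataFrame  # gene_id, condition, reason
    mode: str = "per_replicate"

    def wide(self, condition: str, replicate: int | None = None) -> pd.DataFrame:
        """Genes x timepoints ratio matrix for one condition.

        In per_replicate mode with ``replicate=None`` the replicates are
        averaged (summary-curve view); pass a replicate for per-experiment
        classification.
        """
        sub = self.ratios[self.ratios["condition"] == condition]
        if replicate is not None:
            if "replicate" not in sub.columns:
                raise DataError("ratio table has no replicate column")
            sub = sub[sub["replicate"] == replicate]
        return sub.pivot_table(index="gene_id", columns="timepoint_h",
                               values="ratio", aggfunc="mean")

    def excluded_genes(self, condition: str | None = None) -> set[str]:
        ex = self.excluded
        if condition is not None:
            ex = ex[ex["condition"] == condition]
        return set(ex["gene_id"])


def compute_rpkm(matrix: ExpressionMatrix, gene_lengths) -> ExpressionMatrix:
    """Counts -> RPKM over the full gene body.

    RPKM(g, s) = counts(g, s) / (length_kb(g) * library_size_millions(s)).
    Lengths are the full annotated transcription-unit lengths in bp, which
    is the relevant denominator for intron-containing nascent transcripts.
    """
    if matrix.state != "counts":
        raise DataError(f"compute_rpkm expects counts, got state {matrix.state!r}")
    lengths = pd.Series(gene_lengths, dtype=float)
    missing = matrix.genes.difference(lengths.index)
    if len(missing):
        raise DataError(f"missing gene length for: {sorted(missing)[:10]}")
    lengths = lengths.loc[matrix.genes]
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise DataError(f"non-positive gene length for: {bad[:10]}")
    lib = matrix.samples["library_size"].astype(float)
    if lib.isna().any() or (lib <= 0).any():
        bad = lib.index[lib.isna() | (lib <= 0)].tolist()
        raise DataError(f"missing or non-positive library_size for samples: {bad}")
    denom = np.outer(lengths.to_numpy() / 1e3, lib.to_numpy() / 1e6)
    rpkm = matrix.values / denom
    return ExpressionMatrix(rpkm, matrix.samples.copy(), state="rpkm")


def apply_scaling(matrix: ExpressionMatrix, factors: ScalingFactorTable) -> ExpressionMatrix:
    """Multiply RPKM by the per-(condition, timepoint) correction factor.

    Baseline samples carry factor 1 and are returned unchanged (bit-wise).
    """
    if matrix.state != "rpkm":
        raise DataError(f"apply_scaling expects rpkm, got state {matrix.state!r}")
    col_factors = np.array([
        factors.factor(row.condition, row.timepoint_h)
        for row in matrix.samples.itertuples()
    ])
    scaled = matrix.values.copy()
    hot = col_factors != 1.0  # leave unit-factor columns untouched bit-wise
    if hot.any():
        cols = matrix.values.columns[hot]
        scaled.loc[:, cols] = matrix.values.loc[:, cols] * col_factors[hot]
    return ExpressionMatrix(scaled, matrix.samples.copy(), state="scaled_rpkm")


def relative_to_baseline(matrix: ExpressionMatrix, mode: str = "per_replicate") -> RatioTable:
    """Express each post-UV sample relative to its condition's baseline.

    ratio(g, c, t) = scaled(g, c, t) / scaled(g, c, 0), computed within
    each replicate.  In ``replicate_mean`` mode per-replicate ratios are
    then averaged.  Genes with a zero baseline in a condition are excluded
    with reason ``baseline_zero`` (the RPKM > 0 filter).
    """
    if mode not in ("per_replicate", "replicate_mean"):
        raise DataError(f"unknown mode {mode!r}")
    if matrix.state != "scaled_rpkm":
        raise DataError(f"relative_to_baseline expects scaled_rpkm, got {matrix.state!r}")
    rows = []
    excluded: dict[tuple[str, str], str] = {}
    meta = matrix.samples
    for condition in matrix.conditions:
        reps = sorted(meta.loc[meta["condition"] == condition, "replicate"].unique())
        for rep in reps:
            base_ids = matrix.sample_ids(condition, 0.0, rep)
            if len(base_ids) != 1:
                raise DataError(
                    f"condition {condition!r} replicate {rep} needs exactly one "
                    f"timepoint-0 baseline, found {len(base_ids)}"
                )
            baseline = matrix.values[base_ids[0]]
            zero = baseline == 0
            for gid in matrix.genes[zero]:
                excluded[(gid, condition)] = "baseline_zero"
            post_ids = [
                s for s in matrix.sample_ids(condition, replicate=rep)
                if meta.loc[s, "timepoint_h"] != 0.0
            ]
            for sid in post_ids:
                tp = meta.loc[sid, "timepoint_h"]
                ratio = matrix.values[sid][~zero] / baseline[~zero]
                rows.append(pd.DataFrame({
                    "gene_id": ratio.index,
                    "condition": condition,
                    "timepoint_h": tp,
                    "replicate": rep,
                    "ratio": ratio.to_numpy(),
                }))
    long = (pd.concat(rows, ignore_index=True) if rows else
            pd.DataFrame(columns=["gene_id", "condition", "timepoint_h", "replicate", "ratio"]))
    # a gene excluded in any replicate of a condition is excluded for that
    # condition outright: classification needs a baseline in every experiment
    ex_keys = set(excluded)
    if ex_keys:
        drop = pd.MultiIndex.from_frame(long[["gene_id", "condition"]]).isin(ex_keys)
        long = long[~drop]
    if mode == "replicate_mean":
        long = (long.groupby(["gene_id", "condition", "timepoint_h"], as_index=False)
                ["ratio"].mean())
    excluded_df = pd.DataFrame(
        [{"gene_id": g, "condition": c, "reason": r} for (g, c), r in sorted(excluded.items())],
        columns=["gene_id", "condition", "reason"],
    )
    return RatioTable(long, excluded_df, mode=mode)


def filter_complete_cases(matrix: ExpressionMatrix,
                          conditions: Iterable[str] = ()) -> pd.Index:
    """Genes with a strictly positive value in every sample of the listed
    conditions (heatmap-export filter).  An empty condition list is vacuous:
    all genes are retained.
    """
    if matrix.state not in ("rpkm", "scaled_rpkm"):
        raise DataError("filter_complete_cases expects rpkm or scaled_rpkm")
    conditions = list(conditions)
    if not conditions:
        return matrix.genes
    sids: list[str] = []
    for cond in conditions:
        ids = matrix.sample_ids(cond)
        if not ids:
            raise DataError(f"no samples for condition {cond!r}")
        sids.extend(ids)
    keep = (matrix.values[sids] > 0).all(axis=1)
    return matrix.genes[keep]
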