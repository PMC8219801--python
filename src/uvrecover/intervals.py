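"""Genomic-interval operations and gene-list overlap statistics.

Strand-aware promoter extension of transcription units, ChIP-peak filtering
and peak-to-gene intersection, and Fisher's exact test for the overlap of
two gene lists within an analysed universe.

Coordinates are 0-based half-open (BED dialect) throughout; convert 1-based
inclusive input at the reader.  Peak strand is ignored during intersection
(ChIP peaks are unstranded); gene strand matters only for deciding which
side is upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import DataError

__all__ = [
    "GenomicInterval",
    "OverlapResult",
    "extend_upstream",
    "extend_upstream_frame",
    "filter_peaks",
    "intersect_targets",
    "overlap_fisher",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.chrom:
            raise DataError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise DataError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise DataError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def extend_upstream(interval: GenomicInterval, distance_bp: int = 5000) -> GenomicInterval:
    """Extend an interval upstream (promoter side) by ``distance_bp``.

    + strand: start moves left (clipped at 0); - strand: end moves right.
    Unstranded intervals have no defined upstream side and raise.
    """
    if distance_bp < 0:
        raise DataError("extension distance must be non-negative")
    if interval.strand == "+":
        return replace(interval, start=max(0, interval.start - distance_bp))
    if interval.strand == "-":
        return replace(interval, end=interval.end + distance_bp)
    raise DataError("upstream is undefined for unstranded interval")


def extend_upstream_frame(genes: pd.DataFrame, distance_bp: int = 5000) -> pd.DataFrame:
    """Vectorised upstream extension of a gene table (chrom/start/end/strand)."""
    need = {"chrom", "start", "end", "strand"}
    if not need.issubset(genes.columns):
        raise DataError(f"gene table needs columns {sorted(need)}")
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise DataError(f"unstranded gene(s): {genes.index[bad].tolist()[:5]}")
    out = genes.copy()
    plus = genes["strand"] == "+"
    out.loc[plus, "start"] = np.maximum(0, genes.loc[plus, "start"] - distance_bp)
    out.loc[~plus, "end"] = genes.loc[~plus, "end"] + distance_bp
    return out


def filter_peaks(peaks: pd.DataFrame,
                 fdr_max: float = 1.0,
                 fold_enrichment_min: float = 10.0) -> pd.DataFrame:
    """Keep peaks with fdr < fdr_max and fold_enrichment > fold_enrichment_min.

    Both inequalities are strict.  Missing attribute values raise, naming
    the offending peak.
    """
    for col in ("fdr", "fold_enrichment"):
        if col not in peaks.columns:
            raise DataError(f"peak table missing column {col!r}")
        bad = peaks[col].isna()
        if bad.any():
            raise DataError(f"peak(s) missing {col}: {peaks.index[bad].tolist()[:5]}")
    keep = (peaks["fdr"] < fdr_max) & (peaks["fold_enrichment"] > fold_enrichment_min)
    return peaks[keep]


def intersect_targets(extended_genes: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Per-gene boolean: does >=1 peak overlap the (already extended) gene?

    Half-open overlap semantics, >=1 bp; strand-agnostic for peaks.
    Indexed like ``extended_genes``.
    """
    need = {"chrom", "start", "end"}
    for name, df in (("gene", extended_genes), ("peak", peaks)):
        if not need.issubset(df.columns):
            raise DataError(f"{name} table needs columns {sorted(need)}")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int)))
    hits = []
    for row in extended_genes.itertuples():
        tree = trees.get(row.chrom)
        hits.append(bool(tree.overlap(int(row.start), int(row.end))) if tree else False)
    out = pd.Series(hits, index=extended_genes.index, name="peak_target")
    out.index.name = extended_genes.index.name
    return out


@dataclass(frozen=True)
class OverlapResult:
    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap_size: int
    odds_ratio: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "set_a_size": self.set_a_size,
            "set_b_size": self.set_b_size,
            "universe_size": self.universe_size,
            "overlap_size": self.overlap_size,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
        }


def overlap_fisher(set_a, set_b, universe) -> OverlapResult:
    """Two-sided Fisher's exact test for the overlap of two gene lists.

    The 2x2 table counts genes in both lists, in A only, in B only, and in
    neither, within the analysed universe.  Two-sided p sums hypergeometric
    probabilities of all tables (with the observed margins) whose
    probability does not exceed the observed table's (minimum-likelihood
    convention).  Odds ratio is the sample odds ratio a*d / (b*c).
    """
    universe = set(universe)
    if not universe:
        raise DataError("overlap_fisher: empty universe")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise DataError("overlap_fisher: sets must be subsets of the universe")
    both = len(set_a & set_b)
    a_only = len(set_a) - both
    b_only = len(set_b) - both
    neither = len(universe) - both - a_only - b_only
    odds, p = stats.fisher_exact([[both, a_only], [b_only, neither]],
                                 alternative="two-sided")
    return OverlapResult(
        set_a_size=len(set_a), set_b_size=len(set_b),
        universe_size=len(universe), overlap_size=both,
        odds_ratio=float(odds), p_value=float(p),
    )
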