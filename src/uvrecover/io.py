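"""Readers and writers for the plain-text interchange formats.

Matrices are TSV with gene_id as the first column and one column per
sample; sample metadata, factor tables and annotations are TSV with
headers; peaks are BED6+2 (fdr, fold_enrichment) without a header, with a
configurable column mapping for other dialects.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError
from .quantify import ExpressionMatrix, ScalingFactorTable

__all__ = [
    "read_matrix", "write_matrix",
    "read_sample_sheet", "write_sample_sheet",
    "read_factor_table", "write_factor_table",
    "read_annotation", "write_annotation", "write_annotation_bed",
    "read_peaks_bed", "write_peaks_bed",
    "read_expression", "write_expression",
]

_BED_PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                     "fdr", "fold_enrichment"]


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise DataError(f"{path}: first column must be gene_id, got {df.columns[0]!r}")
    return df.set_index("gene_id")


def write_matrix(values: pd.DataFrame, path) -> None:
    out = values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    out = samples.reset_index() if samples.index.name == "sample_id" else samples
    out.to_csv(path, sep="\t", index=False)


def read_expression(matrix_path, sample_sheet_path, state: str = "counts") -> ExpressionMatrix:
    return ExpressionMatrix(read_matrix(matrix_path),
                            read_sample_sheet(sample_sheet_path), state=state)


def write_expression(matrix: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    write_matrix(matrix.values, matrix_path)
    write_sample_sheet(matrix.samples, sample_sheet_path)


def read_factor_table(path) -> ScalingFactorTable:
    return ScalingFactorTable.from_frame(pd.read_csv(path, sep="\t"))


def write_factor_table(factors: ScalingFactorTable, path) -> None:
    factors.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation(path, one_based: bool = False) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, chrom, start, end, strand[, biotype].

    ``one_based=True`` converts 1-based inclusive starts to the internal
    0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "chrom", "start", "end", "strand"}
    if not need.issubset(df.columns):
        raise DataError(f"{path}: annotation needs columns {sorted(need)}")
    df = df.set_index("gene_id")
    if one_based:
        df["start"] = df["start"] - 1
    if "length_bp" not in df.columns:
        df["length_bp"] = df["end"] - df["start"]
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": annotation["chrom"],
        "start": annotation["start"],
        "end": annotation["end"],
        "name": annotation.index,
        "score": 0,
        "strand": annotation["strand"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_peaks_bed(path, columns: list[str] | None = None) -> pd.DataFrame:
    """BED6+ peak table; default column mapping BED6 + fdr + fold_enrichment."""
    columns = columns or _BED_PEAK_COLUMNS
    df = pd.read_csv(path, sep="\t", header=None, names=columns)
    need = {"chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise DataError(f"{path}: peak table needs columns {sorted(need)}")
    return df


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_PEAK_COLUMNS if c in peaks.columns]
    peaks[cols].to_csv(path, sep="\t", index=False, header=False)
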