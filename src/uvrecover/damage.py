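"""Poisson model of the UV lesion load per transcription unit.

UVC photoproducts (mainly cyclobutane pyrimidine dimers) are deposited
nearly uniformly along the genome, so the expected lesion count in a gene
scales linearly with its length and with the UV dose.  At the reference
dose of 10 J/m2 the double-stranded rate is 1 lesion per 6 kb; only lesions
on the transcribed (template) strand block elongating RNAPII, giving an
effective rate of 1 lesion per 12 kb.  Lesion counts per gene are modelled
as Poisson(lambda), so the probability that a gene carries at least one
transcription-blocking lesion is 1 - exp(-lambda).

Comparing this predicted damaged fraction with the observed fraction of
genes whose recovery depends on a trans-acting factor separates cis
(lesion-driven) from trans (genome-wide) effects: an observed dependent
fraction far above the predicted damaged fraction cannot be explained by
direct damage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "LesionModelParams",
    "expected_lesions",
    "prob_damaged",
    "fraction_damaged",
    "damage_vs_dependency",
]


@dataclass(frozen=True)
class LesionModelParams:
    """Lesion-rate parameters.

    ds_rate_per_bp: lesions per bp of double-stranded DNA at the reference
    dose (1/6000 at 10 J/m2).  strand_factor halves the rate for the
    transcribed strand.  Dose response is linear.
    """

    reference_dose: float = 10.0       # J/m2
    ds_rate_per_bp: float = 1.0 / 6000.0
    strand_factor: float = 0.5
    dose: float = 10.0                 # J/m2

    def __post_init__(self):
        if self.reference_dose <= 0 or self.ds_rate_per_bp <= 0:
            raise DataError("lesion rates and reference dose must be positive")
        if self.dose <= 0:
            raise DataError("dose must be positive")
        if not 0 < self.strand_factor <= 1:
            raise DataError("strand_factor must be in (0, 1]")


def expected_lesions(length_bp, params: LesionModelParams = LesionModelParams(),
                     strand: str = "transcribed"):
    """Expected lesion count lambda for a gene of the given length.

    lambda = length_bp * (dose / reference_dose) * ds_rate_per_bp
             * (strand_factor if transcribed else 1).
    Accepts scalars or arrays; negative lengths raise.
    """
    if strand not in ("transcribed", "double_stranded"):
        raise DataError(f"unknown strand {strand!r}")
    length = np.asarray(length_bp, dtype=float)
    if (length < 0).any():
        raise DataError("negative gene length")
    lam = length * (params.dose / params.reference_dose) * params.ds_rate_per_bp
    if strand == "transcribed":
        lam = lam * params.strand_factor
    if lam.ndim == 0:
        return float(lam)
    return lam


def prob_damaged(length_bp, params: LesionModelParams = LesionModelParams()):
    """P(>=1 transcription-blocking lesion) = 1 - exp(-lambda), transcribed strand."""
    lam = expected_lesions(length_bp, params, strand="transcribed")
    p = -np.expm1(-np.asarray(lam, dtype=float))
    if p.ndim == 0:
        return float(p)
    return p


def fraction_damaged(lengths, params: LesionModelParams = LesionModelParams()) -> float:
    """Expected fraction of a gene set carrying >=1 transcribed-strand lesion.

    Per-gene probability averaging: mean over genes of prob_damaged.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise DataError("fraction_damaged: empty gene set")
    return float(np.mean(prob_damaged(lengths, params)))


def damage_vs_dependency(lengths: pd.Series,
                         dependency: pd.Series,
                         params: LesionModelParams = LesionModelParams(),
                         dependent_class: str = "stimulated") -> dict:
    """Predicted-damaged vs observed factor-dependent fractions for a gene set.

    ``dependency`` holds the per-gene dependency class for the same genes
    as ``lengths``; observed is the fraction classified ``dependent_class``
    (genes requiring the factor) among non-excluded calls.  Also reports
    the excess = observed - predicted, the trans-acting component the
    lesion model cannot account for.
    """
    genes = pd.Index(lengths.index)
    dep = dependency.reindex(genes)
    if dep.isna().any():
        missing = genes[dep.isna()].tolist()
        raise DataError(f"dependency call missing for: {missing[:5]}")
    kept = dep[dep != "excluded"]
    if len(kept) == 0:
        raise DataError("damage_vs_dependency: no non-excluded dependency calls")
    predicted = fraction_damaged(lengths.to_numpy(), params)
    observed = float((kept == dependent_class).sum()) / len(kept)
    return {
        "predicted_damaged_fraction": predicted,
        "observed_dependent_fraction": observed,
        "excess": observed - predicted,
        "n": int(len(kept)),
    }
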