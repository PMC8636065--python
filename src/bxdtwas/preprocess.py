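"""Normalization, trait aggregation and strain alignment.

Modified Z normalization
    Each strain column (one array) is standardized to z-scores, multiplied by
    2 and shifted by 8, so every array has mean 8 and SD 2.  This removes
    array-level location/scale effects while keeping values on a familiar
    log2-like scale.  The sample (n-1) standard deviation is used; with
    thousands of genes per array the choice is numerically irrelevant but is
    fixed here so results reproduce bit-for-bit.

Hearing-acuity aggregation
    The ABR threshold (dB SPL) is measured per mouse at 8, 16 and 32 kHz.
    The strain trait is a two-step mean: individuals are first averaged
    within each frequency, then the per-frequency strain means are averaged.
    With unbalanced individual counts this differs from the pooled grand
    mean — the two-step order is the contract.  Ceiling-censored thresholds
    (no response at the maximum tested level) enter at face value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    AbrRecordTable,
    ExpressionMatrix,
    Scale,
    StrainTraitVector,
    VALID_FREQUENCIES_KHZ,
)

__all__ = [
    "AlignedPair",
    "modified_z_normalize",
    "aggregate_abr",
    "align",
    "age_confound_check",
]


def modified_z_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-array modified Z: z-score each strain column, then 2z + 8.

    Requires raw log2 input; a zero-variance column is an error naming the
    strain (its z-scores would be undefined).
    """
    if matrix.scale is not Scale.RAW_LOG2:
        raise ValueError(f"input must be on the raw_log2 scale, got {matrix.scale.value}")
    values = matrix.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance array column for strain {matrix.strain_ids[zero[0]]!r}"
        )
    z = (values - mean) / sd
    out = pd.DataFrame(2.0 * z + 8.0, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(out, Scale.MODIFIED_Z)


def aggregate_abr(
    records: AbrRecordTable,
    frequencies: Sequence[float] = VALID_FREQUENCIES_KHZ,
) -> StrainTraitVector:
    """Collapse ABR records to one hearing-acuity value per strain.

    Two-step mean per strain: (1) average thresholds over individuals within
    each requested frequency (repeated measurements on one mouse at one
    frequency are first averaged within that mouse); (2) average the
    per-frequency means.  Every requested frequency must be present for every
    strain.
    """
    freqs = sorted(float(f) for f in frequencies)
    if not freqs:
        raise ValueError("need at least one frequency")
    bad = [f for f in freqs if f not in VALID_FREQUENCIES_KHZ]
    if bad:
        raise ValueError(f"frequencies {bad} not in tested set {VALID_FREQUENCIES_KHZ}")

    df = records.records[records.records["frequency_khz"].isin(freqs)]
    rows = {}
    for strain, grp in df.groupby("strain", sort=True):
        present = set(grp["frequency_khz"])
        missing = [f for f in freqs if f not in present]
        if missing:
            raise ValueError(f"strain {strain!r} missing frequencies {missing}")
        per_mouse = grp.groupby(["frequency_khz", "individual"])["threshold_db"].mean()
        per_freq = per_mouse.groupby(level="frequency_khz").mean()
        rows[strain] = {
            "trait_value": per_freq.mean(),
            "n_individuals": grp["individual"].nunique(),
        }
    return StrainTraitVector(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class AlignedPair:
    """Expression matrix and trait vector restricted to their shared strains,
    in identical (sorted) strain order."""

    expression: ExpressionMatrix
    trait: StrainTraitVector
    dropped_expression_strains: tuple[str, ...] = ()
    dropped_trait_strains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.expression.strain_ids != self.trait.strains:
            raise ValueError("expression and trait strain orders differ")

    @property
    def n_shared(self) -> int:
        return len(self.trait)

    @property
    def strains(self) -> list[str]:
        return self.trait.strains


def align(
    expression: ExpressionMatrix,
    trait: StrainTraitVector,
    min_shared: int = 6,
) -> AlignedPair:
    """Intersect the strain sets of an expression matrix and a trait vector.

    The shared strains are taken in sorted order on both sides; strains
    dropped from either side are reported on the returned pair.  Fewer than
    ``min_shared`` shared strains is an error — a correlation over a handful
    of strains is meaningless.
    """
    expr_strains = set(expression.strain_ids)
    trait_strains = set(trait.strains)
    shared = sorted(expr_strains & trait_strains)
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} strains shared between expression "
            f"({len(expr_strains)}) and trait ({len(trait_strains)}); "
            f"need at least {min_shared}"
        )
    return AlignedPair(
        expression=expression.restrict(strains=shared),
        trait=trait.restrict(shared),
        dropped_expression_strains=tuple(sorted(expr_strains - trait_strains)),
        dropped_trait_strains=tuple(sorted(trait_strains - expr_strains)),
    )


def age_confound_check(
    gene_values: Sequence[float], ages: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of expression on strain age: (slope, two-sided slope p, R²).

    Used to check whether an apparent trait association is an age artifact.
    The p-value is from the t distribution with n - 2 df.
    """
    y = np.asarray(gene_values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("gene_values and ages must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 strains for the regression")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise ValueError("zero variance in age")
    yc = y - y.mean()
    slope = (xc @ yc) / sxx
    resid = yc - slope * xc
    sse = resid @ resid
    sst = yc @ yc
    r_squared = 1.0 if sst == 0 else 1.0 - sse / sst
    df = n - 2
    sigma2 = sse / df
    if sigma2 == 0:
        slope_p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / np.sqrt(sigma2 / sxx)
        slope_p = float(2.0 * stats.t.sf(abs(t), df))
    return float(slope), slope_p, float(r_squared)
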