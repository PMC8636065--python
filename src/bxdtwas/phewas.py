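"""Phenome-wide scan: one gene's expression against many published phenotypes.

Published strain phenotypes are measured on overlapping but unequal strain
panels, so each phenotype is correlated with the focal gene over the
pairwise-complete strain overlap.  Phenotypes whose overlap falls below
``min_n`` (default 6) are reported as skipped, never silently dropped.  The
(r, p, n) triple per phenotype comes from the same Pearson code path as the
transcriptome screen.  No multiple-testing correction is applied by default
— published-phenotype scans of this kind conventionally report unadjusted
correlations — but BH can be requested.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import pearson_r_p
from .io import ExpressionMatrix, PhenotypeTable, normalize_strain_name

__all__ = ["phenotype_scan", "count_significant"]


def phenotype_scan(
    gene_values: pd.Series,
    phenotypes: PhenotypeTable,
    min_n: int = 6,
    adjust_bh: bool = False,
) -> pd.DataFrame:
    """Correlate one gene's per-strain expression with every phenotype.

    ``gene_values`` is a Series indexed by strain (e.g. one row of an
    :class:`~bxdtwas.io.ExpressionMatrix`).  Returns a table with columns
    ``phenotype_id, description, r, p_raw, n_overlap`` sorted by p; skipped
    phenotypes (overlap < min_n, or zero variance on the overlap) are listed
    in ``table.attrs["skipped"]`` as (phenotype_id, reason) pairs.
    """
    gene_values = pd.Series(
        gene_values.to_numpy(dtype=float),
        index=[normalize_strain_name(s) for s in gene_values.index],
    )
    rows = []
    skipped: list[tuple[str, str]] = []
    for pheno_id in phenotypes.phenotype_ids:
        pheno = phenotypes.data.loc[pheno_id].dropna()
        shared = sorted(set(pheno.index) & set(gene_values.index))
        if len(shared) < min_n:
            skipped.append((pheno_id, f"only {len(shared)} shared strains (< {min_n})"))
            continue
        x = gene_values.loc[shared].to_numpy()
        y = pheno.loc[shared].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            skipped.append((pheno_id, "zero variance on the strain overlap"))
            continue
        r, p, n = pearson_r_p(x, y)
        rows.append(
            {
                "phenotype_id": pheno_id,
                "description": phenotypes.descriptions.get(pheno_id, ""),
                "r": r,
                "p_raw": p,
                "n_overlap": n,
            }
        )
    if not rows:
        raise ValueError(
            f"no phenotype reaches the minimum strain overlap of {min_n}"
        )
    table = pd.DataFrame(rows).sort_values(
        ["p_raw", "phenotype_id"], kind="stable"
    ).reset_index(drop=True)
    if adjust_bh:
        warnings.warn(
            "BH correction requested for a phenome-wide scan; reported "
            "counts conventionally use unadjusted p-values",
            stacklevel=2,
        )
        table["fdr_bh"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    table.attrs["skipped"] = skipped
    return table


def count_significant(result: pd.DataFrame, p_threshold: float = 0.05) -> int:
    """Number of phenotypes with unadjusted p below the threshold."""
    if len(result) == 0:
        return 0
    return int((result["p_raw"].to_numpy() < p_threshold).sum())


def gene_row(expression: ExpressionMatrix, gene: str) -> pd.Series:
    """Extract one gene's per-strain expression as a Series indexed by strain."""
    if gene not in expression.data.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    return expression.data.loc[gene]
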