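"""Hypergeometric over-representation analysis of a query gene list.

For each annotated set, with N background genes, K of them in the set and a
query of n genes of which k fall in the set:

* p = P(X >= k), X ~ Hypergeometric(N, K, n) — the upper tail, i.e. the
  over-representation (ORA) direction only;
* expected overlap = n * K / N;
* enrichment ratio = k / expected (observed over expected).

Benjamini–Hochberg FDR is computed across the sets of one collection (GO and
pathway collections are expected to be corrected separately).  The default
background is the set of genes actually measured on the platform, since only
measured genes can become correlation candidates; a genome-wide background
can be supplied explicitly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = ["hypergeometric_overrep", "enrichment_ratio", "enrich_collection"]


def hypergeometric_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` observed overlap, ``K`` set size within the background, ``n`` query
    size, ``N`` background size.
    """
    _validate_counts(k, K, n, N)
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes the tail stably
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrichment_ratio(k: int, K: int, n: int, N: int) -> float:
    """Observed over expected overlap: k / (n * K / N)."""
    _validate_counts(k, K, n, N)
    if K == 0 or n == 0:
        raise ValueError("enrichment ratio undefined for empty set or empty query")
    expected = n * K / N
    return k / expected


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N:
        raise ValueError(f"set (K={K}) and query (n={n}) must fit in background N={N}")
    if N <= 0:
        raise ValueError("background must be nonempty")


def enrich_collection(
    query_genes: set[str],
    background_genes: set[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Over-representation of a query against every set in a collection.

    Query genes outside the background are dropped (count recorded in
    ``table.attrs["n_query_outside_background"]``); set members are likewise
    intersected with the background.  Returns one row per set with columns
    ``set_name, k_observed, set_size, expected, enrichment_ratio,
    p_hypergeometric, fdr_bh``, sorted by p ascending.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    background = {str(g) for g in background_genes}
    query_raw = {str(g) for g in query_genes}
    query = query_raw & background
    n_outside = len(query_raw) - len(query)

    N, n = len(background), len(query)
    rows = []
    for gene_set in collection:
        members = gene_set.members & background
        K = len(members)
        k = len(query & members)
        expected = n * K / N if N else 0.0
        rows.append(
            {
                "set_name": gene_set.name,
                "k_observed": k,
                "set_size": K,
                "expected": expected,
                "enrichment_ratio": (k / expected) if expected > 0 else np.nan,
                "p_hypergeometric": hypergeometric_overrep(k, K, n, N) if K else 1.0,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr_bh"] = multipletests(table["p_hypergeometric"], method="fdr_bh")[1]
    table = table.sort_values(
        ["p_hypergeometric", "set_name"], kind="stable"
    ).reset_index(drop=True)
    table.attrs["n_query_outside_background"] = n_outside
    return table
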