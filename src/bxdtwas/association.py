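"""Trait–transcriptome Pearson association screen with permutation adjustment.

The screen correlates every gene's expression across strains with one
strain-level trait value (here: the hearing-acuity ABR threshold).  Raw
p-values come from the exact t transform of the Pearson coefficient,

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   two-sided on t with n - 2 df,

and family-wise error is controlled by the Westfall–Young single-step maxT
permutation procedure on |r|: the trait vector is permuted over strain labels
B times, the maximum |r| over all genes is recorded per permutation, and

    p_adjusted(g) = (1 + #{b : M_b >= |r_obs(g)|}) / (B + 1).

Permuting the trait only (expression fixed) preserves the gene–gene
correlation structure, which is exactly what makes maxT valid under
dependence.  A step-down refinement is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AlignedPair

__all__ = [
    "PermutationConfig",
    "pearson_r_p",
    "pearson_screen",
    "critical_r",
    "maxt_adjusted_p",
    "westfall_young_adjust",
    "filter_significant",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the Westfall–Young permutation adjustment.

    ``n_permutations`` is B in the (count+1)/(B+1) estimator; the statistic is
    fixed to |r|.
    """

    n_permutations: int = 1000
    seed: int = 0
    step_down: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t transform with n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # |r| == 1 gives t = inf -> p = 0; keep p in (0, 1] by the smallest float
    p = np.where(np.isclose(np.abs(r), 1.0), np.nextafter(0.0, 1.0), p)
    return np.minimum(p, 1.0)


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r, two-sided t-based p and n for two paired vectors.

    This is the single correlation code path shared by the transcriptome
    screen and the phenome-wide scan.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    return r, float(_t_pvalue(np.array([r]), n)[0]), n


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each row and scale to unit L2 norm; return (matrix, row norms)."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = centered / norms[:, None]
    return unit, norms


def pearson_screen(pair: AlignedPair) -> pd.DataFrame:
    """Correlate every gene with the trait over the shared strains.

    Returns an association table with columns ``gene, r, p_raw, n`` sorted by
    |r| descending.  Genes with zero variance across the shared strains are
    excluded; their ids are recorded in ``table.attrs["excluded_genes"]``.
    """
    n = pair.n_shared
    if n < 6:
        raise ValueError(f"need at least 6 shared strains, got {n}")
    values = pair.expression.values
    unit, norms = _standardize_rows(values)
    genes = np.asarray(pair.expression.gene_ids)
    ok = norms > 0
    excluded = [str(g) for g in genes[~ok]]

    y = pair.trait.values.to_numpy(dtype=float)
    yc = y - y.mean()
    ynorm = np.sqrt(yc @ yc)
    if ynorm == 0:
        raise ValueError("trait has zero variance across shared strains")
    r = np.clip(unit[ok] @ (yc / ynorm), -1.0, 1.0)

    table = pd.DataFrame(
        {
            "gene": genes[ok],
            "r": r,
            "p_raw": _t_pvalue(r, n),
            "n": n,
        }
    )
    order = np.argsort(-np.abs(table["r"].to_numpy()), kind="stable")
    table = table.iloc[order].reset_index(drop=True)
    table.attrs["excluded_genes"] = excluded
    return table


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| reaching two-sided significance ``alpha`` at sample size n.

    Inverts the t transform: r* = t* / sqrt(t*^2 + n - 2) with t* the upper
    alpha/2 quantile of t with n-2 df.  For n = 26 strains at alpha = 0.05
    this is 0.388, the screen's significance boundary.
    """
    if n < 3:
        raise ValueError("critical_r requires n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_star / np.sqrt(t_star**2 + n - 2))


def maxt_adjusted_p(r_obs_abs: np.ndarray, maxima: np.ndarray) -> np.ndarray:
    """Single-step maxT adjusted p from observed |r| and permutation maxima.

    p(g) = (1 + #{b : M_b >= |r_obs(g)|}) / (B + 1); the >= comparison makes
    ties conservative and the +1 (the identity permutation) keeps p > 0.
    """
    r_obs_abs = np.atleast_1d(np.asarray(r_obs_abs, dtype=float))
    maxima = np.sort(np.asarray(maxima, dtype=float))
    B = maxima.size
    counts = B - np.searchsorted(maxima, r_obs_abs, side="left")
    return (1.0 + counts) / (B + 1.0)


def westfall_young_adjust(
    pair: AlignedPair,
    config: PermutationConfig,
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fill ``p_adjusted`` by the Westfall–Young maxT permutation procedure.

    Single-step by default: p_adjusted(g) = (1 + #{b : M_b >= |r_obs(g)|}) /
    (B + 1) where M_b is the max |r| over genes in permutation b.  With
    ``config.step_down`` the Westfall–Young step-down refinement is used
    (successive maxima over the genes ranked at or below each gene, with
    monotonicity enforcement).  Either way p_adjusted is monotone
    nonincreasing in |r_obs| and never below p_raw or 1/(B+1).
    """
    if table is None:
        table = pearson_screen(pair)
    table = table.copy()

    values = pair.expression.restrict(genes=list(table["gene"])).values
    unit, norms = _standardize_rows(values)
    if (norms == 0).any():
        raise ValueError("zero-variance gene reached the adjustment stage")
    y = pair.trait.values.to_numpy(dtype=float)
    yc = y - y.mean()
    yunit = yc / np.sqrt(yc @ yc)

    B = config.n_permutations
    rng = np.random.default_rng(config.seed)
    n = y.size
    # |r| for every gene under every permutation of the trait's strain labels
    perms = np.stack([rng.permutation(n) for _ in range(B)])
    r_perm = np.abs(unit @ yunit[perms].T)  # genes x B

    r_obs = np.abs(table["r"].to_numpy())
    if config.step_down:
        # table rows are sorted by |r| descending already
        order = np.argsort(-r_obs, kind="stable")
        suffix_max = np.maximum.accumulate(r_perm[order][::-1], axis=0)[::-1]
        counts = (suffix_max >= r_obs[order][:, None]).sum(axis=1)
        p = (1.0 + counts) / (B + 1.0)
        p = np.maximum.accumulate(p)  # enforce step-down monotonicity
        p_adj = np.empty_like(p)
        p_adj[order] = p
    else:
        p_adj = maxt_adjusted_p(r_obs, r_perm.max(axis=0))

    # the finite-B estimator can dip below the analytic raw p; repair
    table["p_adjusted"] = np.maximum(p_adj, table["p_raw"].to_numpy())
    return table


def filter_significant(
    table: pd.DataFrame,
    p_threshold: float | None = 0.05,
    r_threshold: float | None = 0.3,
) -> list[str]:
    """Genes passing the significance screen.

    Keeps genes with p_raw < ``p_threshold`` and |r| > ``r_threshold``; either
    threshold may be ``None`` to disable that rule.  The 0.3 default encodes
    the moderate-correlation convention (|r| > 0.3).
    """
    keep = np.ones(len(table), dtype=bool)
    if p_threshold is not None:
        keep &= table["p_raw"].to_numpy() < p_threshold
    if r_threshold is not None:
        keep &= np.abs(table["r"].to_numpy()) > r_threshold
    return [str(g) for g in table.loc[keep, "gene"]]
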