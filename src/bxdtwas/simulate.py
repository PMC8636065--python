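"""Synthetic BXD-like panel generator with planted ground truth.

The generator emulates the statistical structure of a recombinant-inbred
strain study joining two cohorts at the strain level:

* a latent per-strain hearing trait T ~ Normal(71, 18²) dB SPL, observed
  through individual mice as T + frequency offset + within-strain noise,
  censored at the ceiling of the tested stimulus range (100 dB SPL);
* a block of trait-associated transcripts planted at a chosen strain-level
  Pearson magnitude, with alternating signs (real screens find both
  directions);
* a co-expression module driven by one shared latent factor, the hub gene
  carrying the largest loading, with the factor itself moderately coupled to
  the trait (module genes in real screens are trait-correlated);
* the remaining transcripts as independent Gaussian noise;
* published-phenotype tables with strain-level missingness, a few phenotypes
  coupled to the module factor (emulating learning traits) and the rest null.

Expression is finally rescaled per strain column to mean 8, SD 2 — the
modified-Z array scale — exactly as the real arrays are normalized.  All
randomness flows through one ``numpy.random.default_rng`` (PCG64) seeded
from the config, so identical configs give bit-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AbrRecordTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PhenotypeTable,
    Scale,
    SyntheticTruth,
    write_abr_records,
    write_expression,
    write_gmt,
    write_phenotypes,
)

__all__ = ["SimulationConfig", "simulate_panel", "simulate_null_panel", "write_panel"]


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of the simulated strain panel.

    Defaults mirror the real study: 26 strains shared between the hearing and
    expression cohorts, ~2000 transcripts, strain ABR mean 71 / SD 18 dB SPL
    censored at the 100 dB SPL ceiling, a 9-gene co-expression module with a
    single hub, and 50 transcripts planted at |r| = 0.6 with the trait.
    """

    n_strains: int = 26
    n_genes: int = 2000
    n_associated: int = 50
    target_r: float = 0.6
    module_size: int = 9
    hub_edge_r: float = 0.6       # latent loading of non-hub module genes
    hub_loading: float = 0.95     # hub's loading; must exceed hub_edge_r
    module_trait_r: float = 0.5   # module factor <-> trait coupling
    abr_mean_db: float = 71.0
    abr_sd_db: float = 18.0
    ceiling_db: float = 100.0
    individuals_per_strain: int = 4
    within_strain_sd_db: float = 8.0
    frequencies_khz: tuple[float, ...] = (8.0, 16.0, 32.0)
    # worse hearing at high frequency: +5/+10 dB at 16/32 kHz
    frequency_offsets_db: tuple[float, ...] = (0.0, 5.0, 10.0)
    n_phenotypes: int = 20
    n_coupled_phenotypes: int = 5
    phenotype_r: float = 0.6
    phenotype_missing_rate: float = 0.25
    n_decoy_sets: int = 9
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 6:
            raise ValueError("n_strains must be >= 6")
        if self.module_size and self.module_size < 3:
            raise ValueError("module_size must be 0 or >= 3")
        if self.n_associated + self.module_size > self.n_genes:
            raise ValueError("n_associated + module_size must not exceed n_genes")
        if not 0 < self.target_r < 1:
            raise ValueError("target_r must be in (0, 1)")
        if not 0 < self.hub_edge_r < self.hub_loading < 1:
            raise ValueError("need 0 < hub_edge_r < hub_loading < 1")
        if not 0 <= abs(self.module_trait_r) < 1:
            raise ValueError("module_trait_r must be in (-1, 1)")
        if self.ceiling_db < self.abr_mean_db:
            raise ValueError("ceiling_db must be >= abr_mean_db")
        if len(self.frequencies_khz) != len(self.frequency_offsets_db):
            raise ValueError("one frequency offset per frequency")
        if self.individuals_per_strain < 1:
            raise ValueError("individuals_per_strain must be >= 1")
        if self.n_coupled_phenotypes > self.n_phenotypes:
            raise ValueError("n_coupled_phenotypes must not exceed n_phenotypes")


def _standardized(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_panel(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, AbrRecordTable, PhenotypeTable, GeneSetCollection, SyntheticTruth]:
    """Generate one synthetic panel with planted associations and a hub module.

    Returns the expression matrix (modified-Z scale), the per-individual ABR
    records, a phenotype table with missingness, a gene-set collection whose
    first set is the planted pathway (the associated genes) plus size-matched
    decoys, and the :class:`~bxdtwas.io.SyntheticTruth` record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    strains = [f"BXD{i:03d}" for i in range(1, config.n_strains + 1)]
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    # latent strain trait and its standardized form used for effect planting
    T = rng.normal(config.abr_mean_db, config.abr_sd_db, config.n_strains)
    zT = _standardized(T)

    # disjoint associated and module gene positions
    special = rng.choice(
        config.n_genes, size=config.n_associated + config.module_size, replace=False
    )
    assoc_idx = np.sort(special[: config.n_associated])
    module_idx = np.sort(special[config.n_associated :])

    expr = rng.standard_normal((config.n_genes, config.n_strains))

    r = config.target_r
    signs = np.array([1 if i % 2 == 0 else -1 for i in range(config.n_associated)])
    for sign, gi in zip(signs, assoc_idx):
        expr[gi] = sign * (r * zT + np.sqrt(1 - r**2) * rng.standard_normal(config.n_strains))

    hub_gene: str | None = None
    if config.module_size:
        rho = config.module_trait_r
        factor = rho * zT + np.sqrt(1 - rho**2) * rng.standard_normal(config.n_strains)
        loadings = np.full(config.module_size, config.hub_edge_r)
        hub_pos = 0
        loadings[hub_pos] = config.hub_loading
        for lam, gi in zip(loadings, module_idx):
            expr[gi] = lam * factor + np.sqrt(1 - lam**2) * rng.standard_normal(
                config.n_strains
            )
        hub_gene = genes[module_idx[hub_pos]]

    # per-array (per-strain-column) modified-Z scale: mean 8, SD 2 exactly
    expr = 8.0 + 2.0 * (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=1)
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=strains), Scale.MODIFIED_Z
    )

    abr = _simulate_abr(config, rng, strains, T)
    phenotypes = _simulate_phenotypes(
        config, rng, strains,
        factor if config.module_size else rng.standard_normal(config.n_strains),
    )
    collection = _build_gene_sets(config, rng, genes, assoc_idx)

    truth = SyntheticTruth(
        associated_gene_ids=tuple(genes[i] for i in assoc_idx),
        target_r=config.target_r,
        hub_gene_id=hub_gene,
        module_gene_ids=tuple(genes[i] for i in module_idx),
        seed=config.seed,
        censoring_db=config.ceiling_db,
    )
    return expression, abr, phenotypes, collection, truth


def simulate_null_panel(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, AbrRecordTable, PhenotypeTable, GeneSetCollection, SyntheticTruth]:
    """Global-null panel: no planted associations, no module–trait coupling.

    The module's gene–gene correlation structure is still generated (real
    transcriptomes are not independent), but nothing is coupled to the trait
    and the truth lists are empty.
    """
    null_config = replace(
        config, n_associated=0, module_trait_r=0.0, n_coupled_phenotypes=0
    )
    expression, abr, phenotypes, collection, _ = simulate_panel(null_config)
    truth = SyntheticTruth(
        associated_gene_ids=(),
        target_r=config.target_r,
        hub_gene_id=None,
        module_gene_ids=(),
        seed=config.seed,
        censoring_db=config.ceiling_db,
    )
    return expression, abr, phenotypes, collection, truth


def _simulate_abr(
    config: SimulationConfig,
    rng: np.random.Generator,
    strains: list[str],
    T: np.ndarray,
) -> AbrRecordTable:
    rows = []
    for s, strain in enumerate(strains):
        for m in range(config.individuals_per_strain):
            individual = f"{strain}_m{m + 1}"
            sex = "M" if (s + m) % 2 == 0 else "F"
            age = round(float(rng.uniform(19.0, 25.0)), 1)
            for freq, offset in zip(config.frequencies_khz, config.frequency_offsets_db):
                raw = T[s] + offset + rng.normal(0.0, config.within_strain_sd_db)
                rows.append(
                    {
                        "strain": strain,
                        "individual": individual,
                        "sex": sex,
                        "age_months": age,
                        "frequency_khz": freq,
                        # ceiling censoring at the loudest tested level
                        "threshold_db": float(np.clip(raw, 0.0, config.ceiling_db)),
                    }
                )
    return AbrRecordTable(pd.DataFrame(rows))


def _simulate_phenotypes(
    config: SimulationConfig,
    rng: np.random.Generator,
    strains: list[str],
    factor: np.ndarray,
) -> PhenotypeTable:
    n_s = len(strains)
    z_factor = _standardized(factor)
    values = np.empty((config.n_phenotypes, n_s))
    descriptions = {}
    r = config.phenotype_r
    for p in range(config.n_phenotypes):
        pid = f"PH{p + 1:04d}"
        if p < config.n_coupled_phenotypes:
            base = r * z_factor + np.sqrt(1 - r**2) * rng.standard_normal(n_s)
            descriptions[pid] = f"synthetic learning-related phenotype {p + 1}"
        else:
            base = rng.standard_normal(n_s)
            descriptions[pid] = f"synthetic unrelated phenotype {p + 1}"
        values[p] = 50.0 + 10.0 * base
    table = pd.DataFrame(values, index=list(descriptions), columns=strains)

    # strain-level missingness: each phenotype observed on a random subset,
    # keeping enough strains for a meaningful correlation
    min_keep = max(8, int(np.ceil(n_s * (1 - 2 * config.phenotype_missing_rate))))
    for pid in table.index:
        n_missing = rng.binomial(n_s, config.phenotype_missing_rate)
        n_missing = min(n_missing, n_s - min_keep)
        if n_missing > 0:
            drop = rng.choice(n_s, size=n_missing, replace=False)
            table.loc[pid, table.columns[drop]] = np.nan
    return PhenotypeTable(table, descriptions)


def _build_gene_sets(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: list[str],
    assoc_idx: np.ndarray,
) -> GeneSetCollection:
    sets: list[GeneSet] = []
    assoc = {genes[i] for i in assoc_idx}
    size = len(assoc) if assoc else max(
        3, min(config.n_associated or 20, config.n_genes // 4)
    )
    if assoc:
        sets.append(GeneSet("planted_pathway", "planted trait-associated genes", frozenset(assoc)))
    pool = np.array([i for i in range(len(genes)) if genes[i] not in assoc])
    for d in range(config.n_decoy_sets):
        picks = rng.choice(pool, size=min(size, pool.size), replace=False)
        sets.append(
            GeneSet(
                f"decoy_{d + 1:02d}",
                "size-matched random gene set",
                frozenset(genes[i] for i in picks),
            )
        )
    return GeneSetCollection(sets)


def write_panel(
    outdir: str | Path,
    expression: ExpressionMatrix,
    abr: AbrRecordTable,
    phenotypes: PhenotypeTable,
    collection: GeneSetCollection,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the five panel artifacts into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "abr_records": outdir / "abr_records.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    write_expression(expression, paths["expression"])
    write_abr_records(abr, paths["abr_records"])
    write_phenotypes(phenotypes, paths["phenotypes"])
    write_gmt(collection, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths
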