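"""End-to-end pipeline: normalize -> aggregate -> align -> associate -> filter
-> enrich -> network -> phewas, driven by one YAML config.

Every stage writes its table under the output directory, and a JSON run
report collects the headline numbers (strain counts, trait summary,
significant-gene counts, hub statistics, top enrichment rows, phewas count).
Identical config + seed give a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import association, enrichment, network, phewas, preprocess
from .io import (
    Scale,
    StrainTraitVector,
    read_abr_records,
    read_expression,
    read_gmt,
    read_phenotypes,
    write_expression,
    write_trait,
)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_trait"]

log = logging.getLogger("bxdtwas")


@dataclass
class PipelineConfig:
    """File paths and analysis settings for one pipeline run."""

    expression: Path
    abr_records: Path
    gene_sets: Path
    outdir: Path
    phenotypes: Path | None = None
    expression_scale: str = "modified_z"
    frequencies_khz: tuple[float, ...] = (8.0, 16.0, 32.0)
    p_threshold: float = 0.05
    r_threshold: float | None = None
    n_permutations: int = 1000
    seed: int = 0
    network_genes: tuple[str, ...] | None = None
    network_threshold: float = 0.3
    background_genes: Path | None = None  # None -> genes measured on the platform
    focal_gene: str | None = None  # None -> the network hub
    min_n: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"pipeline config {path} is not a YAML mapping")
        kwargs: dict[str, Any] = {}
        for key in (
            "expression", "abr_records", "gene_sets", "outdir",
            "phenotypes", "background_genes",
        ):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for key in (
            "expression_scale", "p_threshold", "r_threshold", "n_permutations",
            "seed", "network_threshold", "focal_gene", "min_n",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if raw.get("frequencies_khz"):
            kwargs["frequencies_khz"] = tuple(float(f) for f in raw["frequencies_khz"])
        if raw.get("network_genes"):
            kwargs["network_genes"] = tuple(str(g) for g in raw["network_genes"])
        return cls(**kwargs)

    def validate(self) -> None:
        for key in ("expression", "abr_records", "gene_sets", "phenotypes", "background_genes"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config.{key}: no such file: {path}")
        Scale(self.expression_scale)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def summarize_trait(trait: StrainTraitVector) -> dict[str, Any]:
    """Mean, median, extrema (with strain labels) and n of a trait vector.

    The median uses the midpoint convention for even n.
    """
    values = trait.values
    if len(values) == 0:
        raise ValueError("empty trait vector")
    return {
        "mean": float(values.mean()),
        "median": float(values.median()),
        "min": float(values.min()),
        "min_strain": str(values.idxmin()),
        "max": float(values.max()),
        "max_strain": str(values.idxmax()),
        "n": int(len(values)),
    }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and return (and write) the JSON run report.

    Partial outputs are retained on failure; the raised
    :class:`PipelineStageError` names the failing stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")

    report: dict[str, Any] = {"seed": config.seed}

    # --- load & normalize -------------------------------------------------
    expr = _stage("load_expression")(read_expression)(
        config.expression, Scale(config.expression_scale)
    )
    if expr.scale is Scale.RAW_LOG2:
        expr = _stage("normalize")(preprocess.modified_z_normalize)(expr)
        write_expression(expr, outdir / "expression.modified_z.tsv")
    report["n_strains_expression"] = expr.n_strains
    report["n_genes"] = expr.n_genes

    # --- trait aggregation -------------------------------------------------
    abr = _stage("load_abr")(read_abr_records)(config.abr_records)
    trait = _stage("aggregate_abr")(preprocess.aggregate_abr)(
        abr, config.frequencies_khz
    )
    write_trait(trait, outdir / "trait.tsv")
    report["n_strains_trait"] = len(trait)

    # --- alignment ---------------------------------------------------------
    pair = _stage("align")(preprocess.align)(expr, trait)
    report["n_shared"] = pair.n_shared
    report["dropped_expression_strains"] = list(pair.dropped_expression_strains)
    report["dropped_trait_strains"] = list(pair.dropped_trait_strains)
    report["trait_summary"] = summarize_trait(pair.trait)
    (outdir / "join_report.json").write_text(
        json.dumps(
            {
                "n_shared": pair.n_shared,
                "shared_strains": pair.strains,
                "dropped_expression_strains": list(pair.dropped_expression_strains),
                "dropped_trait_strains": list(pair.dropped_trait_strains),
            },
            indent=2, sort_keys=True,
        ) + "\n"
    )

    # --- association screen ------------------------------------------------
    perm = association.PermutationConfig(
        n_permutations=config.n_permutations, seed=config.seed
    )
    table = _stage("associate")(association.westfall_young_adjust)(pair, perm)
    table.to_csv(outdir / "association.tsv", sep="\t", index=False)
    report["critical_r"] = association.critical_r(pair.n_shared, config.p_threshold)
    report["n_significant_p"] = len(
        association.filter_significant(table, config.p_threshold, None)
    )
    report["n_significant_p_and_r"] = len(
        association.filter_significant(table, config.p_threshold, 0.3)
    )
    report["n_significant_adjusted"] = int(
        (table["p_adjusted"] < config.p_threshold).sum()
    )
    significant = association.filter_significant(
        table, config.p_threshold, config.r_threshold
    )
    (outdir / "significant_genes.txt").write_text("\n".join(significant) + "\n")
    report["n_significant_selected"] = len(significant)

    # --- enrichment ----------------------------------------------------
    collection = _stage("load_gene_sets")(read_gmt)(config.gene_sets)
    if config.background_genes is not None:
        background = set(
            Path(config.background_genes).read_text().split()
        )
    else:
        background = set(expr.gene_ids)
    enrich_table = _stage("enrich")(enrichment.enrich_collection)(
        set(significant), background, collection
    )
    enrich_table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    report["top_enrichment"] = [
        {
            "set_name": str(row.set_name),
            "k_observed": int(row.k_observed),
            "enrichment_ratio": None
            if not np.isfinite(row.enrichment_ratio)
            else float(row.enrichment_ratio),
            "p_hypergeometric": float(row.p_hypergeometric),
            "fdr_bh": float(row.fdr_bh),
        }
        for row in enrich_table.head(5).itertuples()
    ]

    # --- co-expression network ------------------------------------------
    if config.network_genes is not None:
        net_genes = list(config.network_genes)
    else:
        # default: the strongest screened genes, capped for an all-pairs graph
        net_genes = significant[: min(50, len(significant))]
    if len(net_genes) >= 3:
        graph = _stage("network")(network.build_network)(
            pair.expression, net_genes, config.network_threshold
        )
        stats = network.node_stats(graph)
        stats.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
        edges = [
            {"gene_a": a, "gene_b": b, "r": round(float(d["r"]), 10)}
            for a, b, d in sorted(graph.edges(data=True))
        ]
        (outdir / "network_edges.tsv").write_text(
            "gene_a\tgene_b\tr\n"
            + "".join(f"{e['gene_a']}\t{e['gene_b']}\t{e['r']:.10g}\n" for e in edges)
        )
        hub, _ = network.identify_hub(stats)
        hub_row = stats.loc[stats["gene"] == hub].iloc[0]
        report["hub"] = {
            "gene": hub,
            "degree": int(hub_row["degree"]),
            "weight_abs": float(hub_row["weight_abs"]),
            "weight_avg": float(hub_row["weight_avg"]),
            "n_network_genes": len(net_genes),
        }
    else:
        report["hub"] = None

    # --- phenome-wide scan ------------------------------------------------
    if config.phenotypes is not None:
        focal = config.focal_gene
        if focal is None and report["hub"] is not None:
            focal = report["hub"]["gene"]
        if focal is not None:
            phenotypes = _stage("load_phenotypes")(read_phenotypes)(config.phenotypes)
            scan = _stage("phewas")(phewas.phenotype_scan)(
                phewas.gene_row(pair.expression, focal), phenotypes, config.min_n
            )
            scan.to_csv(outdir / "phewas.tsv", sep="\t", index=False)
            report["phewas"] = {
                "focal_gene": focal,
                "n_phenotypes_tested": int(len(scan)),
                "n_skipped": len(scan.attrs["skipped"]),
                "n_significant": phewas.count_significant(scan, config.p_threshold),
            }
        else:
            report["phewas"] = None
    else:
        report["phewas"] = None

    report_json = json.dumps(report, indent=2, sort_keys=True) + "\n"
    (outdir / "report.json").write_text(report_json)
    log.info("pipeline complete; report at %s", outdir / "report.json")
    return report


def _setup_logging(logfile: Path) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_bxdtwas_tag", None) for h in log.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._bxdtwas_tag = "stderr"  # type: ignore[attr-defined]
        log.addHandler(h)
    fh = logging.FileHandler(logfile)
    fh._bxdtwas_tag = "file"  # type: ignore[attr-defined]
    for h in [h for h in log.handlers if getattr(h, "_bxdtwas_tag", None) == "file"]:
        log.removeHandler(h)
        h.close()
    log.addHandler(fh)
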