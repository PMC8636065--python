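"""Generate the synthetic BXD-like panel all downstream steps analyze.

Writes expression (2000 genes x 26 strains, modified-Z scale), per-mouse ABR
records, a published-phenotype table with strain missingness, the gene-set
collection (planted pathway + decoys) and the ground-truth record to
results/panel/.
"""

from pathlib import Path

from bxdtwas.simulate import SimulationConfig, simulate_panel, write_panel

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "panel"
SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    expression, abr, phenotypes, collection, truth = simulate_panel(cfg)
    paths = write_panel(OUTDIR, expression, abr, phenotypes, collection, truth)
    print(
        f"panel: {expression.n_genes} genes x {expression.n_strains} strains, "
        f"{len(abr)} ABR records, {phenotypes.data.shape[0]} phenotypes, "
        f"{len(collection)} gene sets"
    )
    print(
        f"planted: {len(truth.associated_gene_ids)} trait-associated genes at "
        f"|r| = {truth.target_r}, hub {truth.hub_gene_id} in a "
        f"{len(truth.module_gene_ids)}-gene module"
    )
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
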