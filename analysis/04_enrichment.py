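"""Gene-set over-representation of the hearing-associated genes.

Tests the screened gene list against the panel's gene-set collection
(planted pathway + size-matched decoys) by the hypergeometric upper tail,
with the measured transcriptome as background.  Writes results/enrichment.tsv.
"""

from pathlib import Path

from bxdtwas.enrichment import enrich_collection
from bxdtwas.io import Scale, read_expression, read_gmt

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    expression = read_expression(RESULTS / "panel" / "expression.tsv", Scale.MODIFIED_Z)
    collection = read_gmt(RESULTS / "panel" / "gene_sets.gmt")
    query = set((RESULTS / "significant_genes.txt").read_text().split())

    table = enrich_collection(query, set(expression.gene_ids), collection)
    table.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)

    top = table.iloc[0]
    print(f"query: {len(query)} genes against {len(collection)} sets")
    print(
        f"top set: {top['set_name']} — observed {int(top['k_observed'])}, "
        f"expected {top['expected']:.1f}, enrichment ratio "
        f"{top['enrichment_ratio']:.2f}, p = {top['p_hypergeometric']:.2e} "
        f"(BH FDR {top['fdr_bh']:.2e})"
    )


if __name__ == "__main__":
    main()
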