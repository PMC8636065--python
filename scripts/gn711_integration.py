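"""Optional integration check against the real GeneNetwork accession.

The real study's expression data are the GeneNetwork dataset "UTHSC BXD Aged
Hippocampus Affy MoGene1.0 ST (May 15) RMA Gene Level" (accession GN711,
http://gn1.genenetwork.org/webqtl/main.py?FormID=sharinginfo&GN_AccessionId=711)
joined with BXD ABR hearing thresholds.  Those files must be downloaded and
converted by hand; this package never fetches them itself, and this script is
NOT part of the test suite.

Given a directory containing

    expression.tsv   genes x strains, modified-Z scale, gene symbols as ids
    trait.tsv        strain / trait_value / n_individuals (3-frequency ABR mean)

it recomputes the published headline numbers: 26 shared strains; trait mean
71 / median 76 / min 33 (BXD74) / max 100 (BXD101) dB SPL; 1,435 transcripts
at p < 0.05; and, over the nine glutamatergic-pathway genes, the Gls hub with
degree 8 and average connection weight 0.49.

Usage:
    python scripts/gn711_integration.py --data-dir path/to/gn711
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from bxdtwas import association
from bxdtwas.io import Scale, read_expression, read_trait
from bxdtwas.network import build_network, identify_hub, node_stats
from bxdtwas.pipeline import summarize_trait
from bxdtwas.preprocess import align

# the nine hearing-loss-associated glutamatergic-pathway genes
PATHWAY_GENES = [
    "Adcy4", "Mapk3", "Shank3", "Dlg4", "Adrbk2", "Slc38a1", "Slc38a2",
    "Gria3", "Gls",
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    expression = read_expression(args.data_dir / "expression.tsv", Scale.MODIFIED_Z)
    trait = read_trait(args.data_dir / "trait.tsv")
    pair = align(expression, trait)

    table = association.pearson_screen(pair)
    n_significant = len(association.filter_significant(table, 0.05, None))

    present = [g for g in PATHWAY_GENES if g in expression.data.index]
    hub_report = None
    if len(present) >= 3:
        stats = node_stats(build_network(pair.expression, present, threshold=0.3))
        hub, ranking = identify_hub(stats)
        top = ranking.iloc[0]
        hub_report = {
            "hub_gene": hub,
            "degree": int(top["degree"]),
            "avg_connection_weight": round(float(top["weight_avg"]), 3),
            "genes_found": present,
        }

    report = {
        "n_shared_strains": pair.n_shared,
        "trait_summary": summarize_trait(pair.trait),
        "n_significant_p05": n_significant,
        "critical_r": round(association.critical_r(pair.n_shared, 0.05), 3),
        "pathway_network": hub_report,
    }
    text = json.dumps(report, indent=2, sort_keys=True)
    print(text)
    if args.out:
        args.out.write_text(text + "\n")


if __name__ == "__main__":
    main()
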