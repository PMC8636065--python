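"""Collapse per-mouse ABR thresholds to one hearing-acuity value per strain.

Individuals are averaged within each stimulus frequency (8/16/32 kHz), then
the three per-frequency strain means are averaged.  Writes results/trait.tsv
and prints the trait summary (in the real study: mean 71, median 76, range
33-100 dB SPL over 26 strains).
"""

from pathlib import Path

from bxdtwas.io import read_abr_records, write_trait
from bxdtwas.pipeline import summarize_trait
from bxdtwas.preprocess import aggregate_abr

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    abr = read_abr_records(RESULTS / "panel" / "abr_records.tsv")
    trait = aggregate_abr(abr)
    write_trait(trait, RESULTS / "trait.tsv")
    s = summarize_trait(trait)
    print(
        f"{s['n']} strains: mean {s['mean']:.1f} dB SPL, median {s['median']:.1f}, "
        f"range {s['min']:.1f} ({s['min_strain']}) to {s['max']:.1f} ({s['max_strain']})"
    )


if __name__ == "__main__":
    main()
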