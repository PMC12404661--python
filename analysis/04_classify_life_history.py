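#!/usr/bin/env python
"""Classify the community's life-history strategies from genome traits.

Converts codon-usage-predicted maximal growth rates to doubling times
(fast/slow dichotomy at 5 h) and scores each species against Grime's CSR
framework by extreme-quartile trait membership.  Writes results/csr.tsv.
"""

import argparse
from pathlib import Path

from biphasix import io
from biphasix.life_history import classify_community


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--traits", type=Path, default=Path("results/data/traits.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/csr.tsv"))
    args = parser.parse_args()

    table = io.read_trait_table(args.traits)
    result = classify_community(table)
    result.to_csv(args.out, sep="\t", index=False)

    print(f"classified {len(result)} species -> {args.out}")
    for _, row in result.iterrows():
        dt = table.frame.loc[row.species_id, "doubling_time_h"]
        print(
            f"  {row.species_id:8s} C={row.score_C} S={row.score_S} R={row.score_R}"
            f"  -> {row.assignment:16s} ({row.growth_class}, doubling {dt:.1f} h)"
        )


if __name__ == "__main__":
    main()
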