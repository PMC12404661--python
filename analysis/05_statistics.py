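#!/usr/bin/env python
"""Exact nonparametric comparisons of the assay tables.

Mirrors the study's comparison families on the synthetic data: species A vs
species B abundances per assay (paired across replicates, exact signed-rank)
and mono- vs co-culture abundances per species and habitat (exact
Mann-Whitney U), all BH-FDR corrected within their family.  Writes
results/tests.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from biphasix import io
from biphasix.datamodel import Assay, Culture
from biphasix.stats import bh_fdr, mann_whitney_exact, wilcoxon_signed_rank_exact


def _cfu(table, species, assay, culture, time_h=None):
    sel = table.select(species_id=species, assay=assay, culture=culture, time_h=time_h)
    return [o.cfu for o in sorted(sel.observations, key=lambda o: o.replicate)]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/tests.tsv"))
    args = parser.parse_args()

    co = io.read_cfu_table(args.datadir / "co.tsv")
    mono = io.read_cfu_table(args.datadir / "mono.tsv")
    species = sorted({o.species_id for o in co.observations})
    sp_a, sp_b = species[0], species[1]

    results = []
    # family 1: A vs B within the co-culture, paired by replicate
    for assay, time_h in [
        (Assay.growth, 72.0),
        (Assay.early_colonization, None),
        (Assay.established_colonization, None),
        (Assay.persistence, None),
        (Assay.release, None),
    ]:
        x = _cfu(co, sp_a, assay, Culture.co, time_h)
        y = _cfu(co, sp_b, assay, Culture.co, time_h)
        results.append(
            wilcoxon_signed_rank_exact(x, y, comparison_id=f"{assay.value}:A_vs_B")
        )
    # family 2: mono vs co per species (plate 72 h and worm persistence)
    for sp in (sp_a, sp_b):
        for assay, time_h in [(Assay.growth, 72.0), (Assay.persistence, None)]:
            x = _cfu(mono, sp, assay, Culture.mono, time_h)
            y = _cfu(co, sp, assay, Culture.co, time_h)
            results.append(
                mann_whitney_exact(x, y, comparison_id=f"{sp}:{assay.value}:mono_vs_co")
            )

    frame = pd.DataFrame([r.__dict__ for r in results])
    frame["p_adjusted"] = bh_fdr(frame["p_value"].tolist())
    frame.to_csv(args.out, sep="\t", index=False)
    print(f"wrote {len(frame)} comparisons to {args.out}")
    sig = frame[frame.p_adjusted <= 0.05]
    print(f"{len(sig)} significant after FDR (q <= 0.05):")
    for _, row in sig.iterrows():
        print(
            f"  {row.comparison_id:40s} {row.statistic_name}={row.statistic:.1f} "
            f"p={row.p_value:.4f} q={row.p_adjusted:.4f}"
        )


if __name__ == "__main__":
    main()
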