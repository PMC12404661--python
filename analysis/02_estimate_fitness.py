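#!/usr/bin/env python
"""Estimate the life-cycle model parameters from the generated CFU tables.

Within-host relative fitness comes from co-culture proportions during
short-term persistence; free-living relative fitness from co-culture
proportions on agar at 72 h; carrying capacities from the observed maximum
population sizes.  Prints the estimates next to the planted truth and writes
results/params.json.
"""

import argparse
import json
from pathlib import Path

from biphasix import io
from biphasix.fitness import estimate_parameters
from biphasix.synthetic import GeneratorConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/params.json"))
    args = parser.parse_args()

    truth = GeneratorConfig(seed=args.seed)  # generator defaults = planted truth
    co = io.read_cfu_table(args.datadir / "co.tsv")
    params = estimate_parameters(co, truth.species_a, truth.species_b)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(params.model_dump(), indent=2, sort_keys=True) + "\n")

    print(f"estimated parameters written to {args.out}:")
    print(f"  w_W_A = {params.w_W_A:.4f}  (planted {truth.true_w_W_A})")
    print(f"  w_P_A = {params.w_P_A:.4f}  (planted {truth.true_w_P_A})")
    print(f"  K_W   = {params.K_W:.3g}   (planted {truth.K_W:g})")
    print(f"  K_P   = {params.K_P:.3g}   (planted {truth.K_P:g})")


if __name__ == "__main__":
    main()
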