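#!/usr/bin/env python
"""Generate the synthetic three-phase small-RNA experiment.

Writes three ~200k-read FASTQ libraries (uninucleate microspore UM,
binucleate BCP and trinucleate TCP pollen), reference FASTAs, the EST
set with planted hairpins and target sites, the GO annotation, and the
truth tables under scratch/sim/.  Large raw data stays in scratch/;
downstream scripts read from there.
"""

import argparse
from pathlib import Path

from pollenmir.simdata import SimulationConfig, simulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "sim")
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed)
    world = simulate(config, args.outdir)
    print(f"simulation written to {args.outdir}")
    print(f"  libraries: {[lib for lib, _ in config.libraries]}")
    print(f"  planted known miRNAs: {len(world.known_catalog)}")
    print(f"  planted novel hairpins: {len(world.novel_truth)}")
    print(f"  planted target sites: {len(world.target_truth)}")
    print(f"  planted enriched GO terms: {list(world.go_truth['term'])}")


if __name__ == "__main__":
    main()
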