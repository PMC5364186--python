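#!/usr/bin/env python
"""Clean-read statistics: length distributions and pairwise overlaps.

From the collapsed libraries produced by the pipeline, tabulates the
per-library clean/unique read counts, the clean-read length histogram
(expected modes at 24 nt and 21 nt), and the pairwise shared/specific
unique-read fractions between developmental phases.
"""

import argparse
from itertools import combinations
from pathlib import Path

import pandas as pd

from pollenmir.io import read_collapsed_fasta
from pollenmir.preprocess import length_histogram, merge_libraries, pairwise_overlap

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--rundir", type=Path, default=ROOT / "scratch" / "pipeline")
    args = parser.parse_args()

    pre = args.rundir / "preprocess"
    libs = sorted(p.name.replace(".collapsed.fa", "") for p in pre.glob("*.collapsed.fa"))
    per_lib = {lib: read_collapsed_fasta(pre / f"{lib}.collapsed.fa") for lib in libs}
    unique = merge_libraries(per_lib)

    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)

    hist = pd.DataFrame(
        {lib: pd.Series(length_histogram(unique, lib)) for lib in libs}
    ).fillna(0).astype(int).sort_index()
    hist.rename_axis("length_nt").to_csv(outdir / "length_histogram.tsv", sep="\t")
    modes = hist.sum(axis=1).sort_values(ascending=False)
    print(f"clean-read length modes: {list(modes.index[:3])} (counts {list(modes[:3])})")

    rows = []
    for a, b in combinations(libs, 2):
        frac = pairwise_overlap(per_lib[a], per_lib[b])
        rows.append({"library_a": a, "library_b": b, **frac})
        print(
            f"{a} vs {b}: {100 * frac['shared_fraction']:.1f}% unique reads shared, "
            f"{100 * frac['a_specific_fraction']:.1f}% / "
            f"{100 * frac['b_specific_fraction']:.1f}% phase-specific"
        )
    pd.DataFrame(rows).to_csv(outdir / "pairwise_overlap.tsv", sep="\t", index=False)
    print(f"tables written to {outdir}")


if __name__ == "__main__":
    main()
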