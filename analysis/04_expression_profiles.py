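#!/usr/bin/env python
"""Expression tiers, developmental trends and profile clustering.

Summarises the differential-expression report: abundance tiers (high
> 10,000 reads, moderate > 1,000, low otherwise), trend classes across
the three phases (increasing, decreasing, V, reversed V, flat), the
significant pairwise calls, and hierarchical groups of the pairwise
log2 fold-change profiles.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--rundir", type=Path, default=ROOT / "scratch" / "pipeline")
    args = parser.parse_args()

    de = pd.read_csv(args.rundir / "de" / "de_report.tsv", sep="\t")
    groups = pd.read_csv(args.rundir / "de" / "groups.tsv", sep="\t")
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)

    per_mirna = de.drop_duplicates("mirna")[["mirna", "tier", "trend"]]
    tier_counts = per_mirna["tier"].value_counts()
    trend_counts = per_mirna["trend"].value_counts()
    print("abundance tiers:", dict(tier_counts))
    print("trend classes:", dict(trend_counts))

    sig = de[de["significant"]]
    print(f"significant DE calls: {len(sig)} across "
          f"{sig['mirna'].nunique()} miRNAs")
    for (a, b), sub in sig.groupby(["library_a", "library_b"]):
        up = (sub["log2fc"] >= 1).sum()
        down = (sub["log2fc"] <= -1).sum()
        print(f"  {a} vs {b}: {up} up, {down} down")

    summary = per_mirna.merge(
        de.groupby("mirna")["significant"].any().rename("any_significant"),
        on="mirna",
    ).merge(groups, on="mirna", how="left")
    summary.to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
    print(f"profile groups: {groups['group'].nunique()}; "
          f"summary written to {outdir / 'expression_summary.tsv'}")


if __name__ == "__main__":
    main()
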