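#!/usr/bin/env python
"""Summary statistics of the published novel miRNA candidate set.

Parses the packaged table of 55 broccoli-pollen novel miRNA candidates
and reports the mean and extreme precursor folding free energies and
the mature-length range.
"""

from pathlib import Path

import pandas as pd

from pollenmir.catalog import catalog_summary, load_novel_mirna_catalog

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    df = load_novel_mirna_catalog()
    s = catalog_summary(df)
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    pd.DataFrame([s]).to_csv(outdir / "catalog_summary.tsv", sep="\t", index=False)
    print(f"candidates: {s['n_candidates']}")
    print(f"mean precursor MFE: {s['mean_mfe']:.2f} kcal/mol")
    print(f"MFE range: {s['min_mfe']} .. {s['max_mfe']} kcal/mol")
    print(f"mature lengths: {s['min_mature_length']} .. {s['max_mature_length']} nt")
    dominant = df["mature_length"].mode().iloc[0]
    print(f"dominant mature length: {dominant} nt")


if __name__ == "__main__":
    main()
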