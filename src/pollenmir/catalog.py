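"""The published broccoli-pollen novel miRNA candidate set.

The 55 novel miRNA candidates reported for broccoli uninucleate
microspores, binucleate and trinucleate pollen grains ship with the
package as a small TSV (name, mature sequence, precursor minimum folding
free energy in kcal/mol) and back the summary-statistics checks.
"""

from __future__ import annotations

from importlib.resources import files
from typing import Dict

import pandas as pd

_DATA = "data/broccoli_novel_mirnas.tsv"


def load_novel_mirna_catalog() -> pd.DataFrame:
    """The published candidate table: name, mature_sequence, precursor MFE."""
    with files("pollenmir").joinpath(_DATA).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["mature_length"] = df["mature_sequence"].str.len()
    return df


def catalog_summary(df: pd.DataFrame | None = None) -> Dict[str, float]:
    """Summary statistics of the published candidate set.

    Mean and extreme precursor MFEs (kcal/mol) and mature-length extremes.
    """
    if df is None:
        df = load_novel_mirna_catalog()
    mfe = df["precursor_mfe_kcal_mol"]
    length = df["mature_length"]
    return {
        "n_candidates": int(len(df)),
        "mean_mfe": float(mfe.mean()),
        "min_mfe": float(mfe.min()),
        "max_mfe": float(mfe.max()),
        "min_mature_length": int(length.min()),
        "max_mature_length": int(length.max()),
    }
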