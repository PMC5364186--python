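#!/usr/bin/env python
"""Score the blind pipeline run against the planted truth.

Compares the pipeline reports (scratch/pipeline) with the generator's
truth tables (scratch/sim/truth): novel-miRNA recall/precision, planted
fold-change recovery and false significant calls, planted target-site
recall and decoy exclusion, and planted GO-term recovery.
"""

import argparse
from pathlib import Path

import pandas as pd

from pollenmir import evaluate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=ROOT / "scratch" / "sim")
    parser.add_argument("--rundir", type=Path, default=ROOT / "scratch" / "pipeline")
    args = parser.parse_args()

    truth = {p.stem: pd.read_csv(p, sep="\t") for p in (args.simdir / "truth").glob("*.tsv")}
    novel = pd.read_csv(args.rundir / "discover" / "novel_mirnas.tsv", sep="\t")
    de = pd.read_csv(args.rundir / "de" / "de_report.tsv", sep="\t")
    targets = pd.read_csv(args.rundir / "targets" / "targets.tsv", sep="\t")
    go = pd.read_csv(args.rundir / "go" / "go_enrichment.tsv", sep="\t")

    rows = {}
    rows.update(evaluate.novel_recovery(novel["mature"], truth["novel_mirnas"]["mature"]))
    rows.update(evaluate.de_recovery(de, truth["de"]))
    name_map = evaluate.match_novel_names(novel, truth["novel_mirnas"])
    tt = truth["targets"].copy()
    tt["mirna"] = tt["mirna"].map(lambda n: name_map.get(n, n))
    rows.update(evaluate.target_recovery(targets, tt))
    rows.update(evaluate.go_recovery(go, truth["go_terms"]))

    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    table = pd.DataFrame([{"metric": k, "value": v} for k, v in rows.items()])
    table.to_csv(outdir / "recovery.tsv", sep="\t", index=False)
    for k, v in rows.items():
        print(f"{k}: {v}")


if __name__ == "__main__":
    main()
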