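"""Truth-recovery metrics for pipeline runs on synthetic data."""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd


def novel_recovery(
    predicted_matures: Iterable[str], truth_matures: Iterable[str]
) -> Dict[str, float]:
    """Recall/precision of predicted novel mature sequences vs truth.

    A prediction matches a planted mature when one is a substring of the
    other (1-nt end jitter tolerated by construction of the reads).
    """
    pred = set(predicted_matures)
    truth = set(truth_matures)

    def hits(query: str, pool: Set[str]) -> bool:
        return any(query in t or t in query for t in pool)

    tp_truth = sum(1 for t in truth if hits(t, pred))
    tp_pred = sum(1 for p in pred if hits(p, truth))
    recall = tp_truth / len(truth) if truth else float("nan")
    precision = tp_pred / len(pred) if pred else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_truth": len(truth),
        "n_predicted": len(pred),
    }


def match_novel_names(
    novel_report: pd.DataFrame, novel_truth: pd.DataFrame
) -> Dict[str, str]:
    """Map planted novel-miRNA names to the pipeline's candidate names.

    Predictions are renamed during discovery, so correspondence goes
    through the mature sequence (substring match tolerates end jitter).
    """
    mapping: Dict[str, str] = {}
    for _, t in novel_truth.iterrows():
        for _, p in novel_report.iterrows():
            if t["mature"] in p["mature"] or p["mature"] in t["mature"]:
                mapping[t["name"]] = p["name"]
                break
    return mapping


def de_recovery(
    de_report: pd.DataFrame, de_truth: pd.DataFrame
) -> Dict[str, float]:
    """Recovery of planted fold changes and false-call rate on nulls.

    Both frames carry (mirna, library_a, library_b); the report carries a
    ``significant`` call and the truth an ``is_de`` flag.  Pair orientation
    is canonicalised before joining (significance is symmetric).
    """

    def canon(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        pair = df[["library_a", "library_b"]].apply(
            lambda r: "|".join(sorted(r.astype(str))), axis=1
        )
        df["pair_key"] = df["mirna"].astype(str) + ":" + pair
        return df

    key = ["pair_key"]
    merged = canon(de_truth).merge(
        canon(de_report)[key + ["significant"]], on=key, how="inner"
    )
    de = merged[merged["is_de"]]
    null = merged[~merged["is_de"]]
    return {
        "de_recall": float(de["significant"].mean()) if len(de) else float("nan"),
        "false_call_rate": float(null["significant"].mean()) if len(null) else 0.0,
        "n_de_truth": int(len(de)),
        "n_null_truth": int(len(null)),
    }


def target_recovery(
    sites: pd.DataFrame, target_truth: pd.DataFrame, max_score: float = 4.0
) -> Dict[str, float]:
    """Fraction of sub-threshold planted sites recovered at their EST, and
    whether any above-threshold decoy leaked through."""
    planted = target_truth[target_truth["intended_score"] <= max_score]
    decoys = target_truth[target_truth["intended_score"] > max_score]
    found = 0
    for _, row in planted.iterrows():
        sub = sites[(sites["mirna"] == row["mirna"]) & (sites["est_id"] == row["est_id"])]
        if any((sub["start"] < row["end"]) & (sub["end"] > row["start"])):
            found += 1
    leaked = 0
    for _, row in decoys.iterrows():
        sub = sites[(sites["mirna"] == row["mirna"]) & (sites["est_id"] == row["est_id"])]
        if any((sub["start"] < row["end"]) & (sub["end"] > row["start"])):
            leaked += 1
    return {
        "target_recall": found / len(planted) if len(planted) else float("nan"),
        "n_planted": int(len(planted)),
        "decoys_leaked": leaked,
        "n_decoys": int(len(decoys)),
    }


def go_recovery(enrichment: pd.DataFrame, go_truth: pd.DataFrame) -> Dict[str, float]:
    """Fraction of planted GO terms called significant."""
    planted = set(go_truth["term"]) if len(go_truth) else set()
    if not planted:
        return {"go_recall": float("nan"), "n_planted_terms": 0}
    sig = set(enrichment.loc[enrichment["significant"], "term"])
    return {
        "go_recall": len(planted & sig) / len(planted),
        "n_planted_terms": len(planted),
        "n_significant_terms": int(len(sig)),
    }
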