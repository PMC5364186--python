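"""Hypergeometric GO-term enrichment of predicted target genes.

For each term the tail probability of drawing at least m term-annotated
genes among the n target candidates, out of N annotated background genes
of which M carry the term:

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)

P-values are Bonferroni-corrected over the tested terms.  The enrichment
ratio is reported in both orientations: the printed form (n/N)/(m/M) and
the conventional fold enrichment (m/n)/(M/N), which are reciprocals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Set

import pandas as pd
from scipy.stats import hypergeom

from .quantify import bonferroni


@dataclass(frozen=True)
class ContingencyCounts:
    """(N, n, M, m): background, targets, term-annotated, term targets."""

    N: int
    n: int
    M: int
    m: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.m <= min(self.n, self.M)
            and self.M <= self.N
            and self.n <= self.N
            and self.n - self.m <= self.N - self.M
        )
        if not ok:
            raise ValueError(f"inconsistent contingency counts {self}")


def hypergeom_upper_tail(c: ContingencyCounts) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n); 1.0 when m = 0."""
    if c.m == 0:
        return 1.0
    p = float(hypergeom.sf(c.m - 1, c.N, c.M, c.n))
    return min(max(p, 0.0), 1.0)


def enrichment_ratio(c: ContingencyCounts, orientation: str = "as_printed") -> Optional[float]:
    """(n/N)/(m/M) as printed, or the conventional (m/n)/(M/N).

    The printed orientation is undefined when m = 0 (returns None).
    """
    if orientation == "as_printed":
        if c.m == 0:
            return None
        return (c.n / c.N) / (c.m / c.M)
    if orientation == "conventional":
        if c.n == 0 or c.M == 0:
            return None
        return (c.m / c.n) / (c.M / c.N)
    raise ValueError(f"unknown orientation {orientation!r}")


def enrich_terms(
    target_genes: Set[str],
    annotation: Dict[str, Set[str]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term-by-term enrichment of a target gene set.

    ``annotation`` maps gene -> set of GO terms; genes are the counting
    unit (a gene hit by several miRNAs counts once).  N counts background
    genes with at least one annotation; only terms with M >= 1 are
    tested; Bonferroni runs over the tested terms.  Sorted by corrected
    then raw P.
    """
    if not target_genes:
        raise ValueError("empty target gene set")
    background = set(background)
    if not target_genes <= background:
        raise ValueError("target genes must be a subset of the background")
    annotated = {g for g in background if annotation.get(g)}
    N = len(annotated)
    targets = target_genes & annotated
    n = len(targets)
    term_genes: Dict[str, Set[str]] = {}
    for gene in annotated:
        for term in annotation[gene]:
            term_genes.setdefault(term, set()).add(gene)

    rows = []
    for term, genes in sorted(term_genes.items()):
        M = len(genes)
        m = len(genes & targets)
        counts = ContingencyCounts(N=N, n=n, M=M, m=m)
        rows.append(
            {
                "term": term,
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "p_raw": hypergeom_upper_tail(counts),
                "enrichment_as_printed": enrichment_ratio(counts, "as_printed"),
                "enrichment_conventional": enrichment_ratio(counts, "conventional"),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_bonf"] = bonferroni(df["p_raw"].tolist())
    df["significant"] = df["p_bonf"] < alpha
    return df.sort_values(["p_bonf", "p_raw", "term"]).reset_index(drop=True)
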