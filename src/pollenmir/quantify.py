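"""Expression normalisation and exact differential-expression testing.

Counts are normalised to reads per million (RPM); zero counts receive the
pseudo-value 0.01 so that log2 fold changes are always defined.  The
pairwise test is the exact conditional construction for two Poisson
libraries: conditional on the summed count, the count in library A is
binomial with success probability total_A / (total_A + total_B); the
two-sided P-value sums all outcome probabilities no larger than the
observed outcome's (minimum-likelihood two-siding).  P-values are
Bonferroni-corrected; a miRNA is called significant when |log2FC| >= 1
and corrected P < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import binom

PSEUDO_RPM = 0.01


def normalize_rpm(raw_count: int, total_clean: int) -> float:
    """RPM = count / total x 1e6; zero counts give the 0.01 pseudo-value."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    if raw_count == 0:
        return PSEUDO_RPM
    return raw_count / total_clean * 1_000_000


def log2_fold_change(rpm_a: float, rpm_b: float) -> float:
    if rpm_a <= 0 or rpm_b <= 0:
        raise ValueError("RPM values must be positive (pseudo-value handles zeros)")
    return float(np.log2(rpm_a / rpm_b))


def poisson_pair_test(x_a: int, total_a: int, x_b: int, total_b: int) -> float:
    """Exact two-sided conditional test of equal per-read rates.

    Under the null, x_a | (x_a + x_b) ~ Binomial(n, total_a/(total_a+total_b)).
    P is the sum of all outcome probabilities <= the observed outcome's.
    Returns 1.0 when both counts are zero (no evidence).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if x_a < 0 or x_b < 0:
        raise ValueError("counts must be non-negative")
    n = x_a + x_b
    if n == 0:
        return 1.0
    p = total_a / (total_a + total_b)
    pmf = binom.pmf(np.arange(n + 1), n, p)
    observed = pmf[x_a]
    # tolerance guards against float noise when many outcomes tie
    pval = float(pmf[pmf <= observed * (1 + 1e-12)].sum())
    return min(max(pval, np.nextafter(0, 1)), 1.0)


def bonferroni(p_values: Sequence[float], n_tests: Optional[int] = None) -> List[float]:
    """p' = min(1, p * n_tests); n_tests defaults to len(p_values)."""
    ps = list(p_values)
    n = len(ps) if n_tests is None else n_tests
    if n < len(ps):
        raise ValueError("n_tests must be >= number of p-values")
    out = []
    for p in ps:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * n))
    return out


def call_significant(log2fc: float, p_bonf: float, lfc: float = 1.0, alpha: float = 0.05) -> bool:
    return abs(log2fc) >= lfc and p_bonf < alpha


def classify_abundance(clean_read_count: int) -> str:
    """high (> 10,000 reads), moderate (> 1,000) or low (<= 1,000)."""
    if clean_read_count < 0:
        raise ValueError("count must be non-negative")
    if clean_read_count > 10_000:
        return "high"
    if clean_read_count > 1_000:
        return "moderate"
    return "low"


def classify_trend(
    rpm_phase1: float,
    rpm_phase2: float,
    rpm_phase3: float,
    step_threshold: float = 1.0,
) -> str:
    """Trend over the ordered phases from the two log2 step ratios.

    A step counts as up/down only when |log2 ratio| >= ``step_threshold``:
    (+,+) increasing, (-,-) decreasing, (-,+) V, (+,-) reversed_V,
    otherwise flat.
    """
    s1 = log2_fold_change(rpm_phase2, rpm_phase1)
    s2 = log2_fold_change(rpm_phase3, rpm_phase2)

    def sign(step: float) -> int:
        if step >= step_threshold:
            return 1
        if step <= -step_threshold:
            return -1
        return 0

    key = (sign(s1), sign(s2))
    return {
        (1, 1): "increasing",
        (-1, -1): "decreasing",
        (-1, 1): "V",
        (1, -1): "reversed_V",
    }.get(key, "flat")


@dataclass(frozen=True)
class DEResult:
    mirna: str
    pair: Tuple[str, str]
    count_a: int
    count_b: int
    rpm_a: float
    rpm_b: float
    log2fc: float
    p_raw: float
    p_bonf: float
    significant: bool


def differential_expression(
    counts: pd.DataFrame,
    totals: Dict[str, int],
    pairs: Sequence[Tuple[str, str]],
    lfc: float = 1.0,
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Pairwise exact-test DE over a miRNA x library count matrix.

    Bonferroni is applied per pairwise comparison over ``n_tests``
    (default: the number of miRNAs in the matrix).
    """
    rows = []
    for lib_a, lib_b in pairs:
        raws = []
        for mirna in counts.index:
            xa = int(counts.loc[mirna, lib_a])
            xb = int(counts.loc[mirna, lib_b])
            raws.append(poisson_pair_test(xa, totals[lib_a], xb, totals[lib_b]))
        corrected = bonferroni(raws, n_tests if n_tests is not None else len(counts))
        for mirna, p_raw, p_bonf in zip(counts.index, raws, corrected):
            xa = int(counts.loc[mirna, lib_a])
            xb = int(counts.loc[mirna, lib_b])
            rpm_a = normalize_rpm(xa, totals[lib_a])
            rpm_b = normalize_rpm(xb, totals[lib_b])
            fc = log2_fold_change(rpm_a, rpm_b)
            rows.append(
                {
                    "mirna": mirna,
                    "library_a": lib_a,
                    "library_b": lib_b,
                    "count_a": xa,
                    "count_b": xb,
                    "rpm_a": rpm_a,
                    "rpm_b": rpm_b,
                    "log2fc": fc,
                    "p_raw": p_raw,
                    "p_bonf": p_bonf,
                    "significant": call_significant(fc, p_bonf, lfc, alpha),
                }
            )
    return pd.DataFrame(rows)


def expression_profile_matrix(
    counts: pd.DataFrame, totals: Dict[str, int], pairs: Sequence[Tuple[str, str]]
) -> pd.DataFrame:
    """miRNA x pairwise-log2FC matrix of RPM ratios (clustering input)."""
    data = {}
    for lib_a, lib_b in pairs:
        col = f"log2({lib_a}/{lib_b})"
        data[col] = [
            log2_fold_change(
                normalize_rpm(int(counts.loc[m, lib_a]), totals[lib_a]),
                normalize_rpm(int(counts.loc[m, lib_b]), totals[lib_b]),
            )
            for m in counts.index
        ]
    return pd.DataFrame(data, index=counts.index)


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 2,
    method: str = "complete",
    metric: str = "euclidean",
) -> Tuple[np.ndarray, pd.Series]:
    """Agglomerative clustering of expression profiles.

    Returns the scipy linkage matrix and a miRNA -> group label series for
    the cut at ``k`` groups.  A constant matrix collapses to one group
    with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing values")
    values = profiles.to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        warnings.warn("constant profile matrix: single-group result")
        labels = pd.Series(1, index=profiles.index, name="group")
        Z = linkage(values, method=method, metric=metric)
        return Z, labels
    Z = linkage(values, method=method, metric=metric)
    labels = pd.Series(
        fcluster(Z, t=k, criterion="maxclust"), index=profiles.index, name="group"
    )
    return Z, labels
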