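import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenmir.quantify import (
    bonferroni,
    call_significant,
    classify_abundance,
    classify_trend,
    cluster_profiles,
    differential_expression,
    log2_fold_change,
    normalize_rpm,
    poisson_pair_test,
)


class TestNormalizeRpm:
    def test_direct_formula(self):
        assert normalize_rpm(100, 20_000_000) == 5.0

    def test_zero_count_gets_pseudo_value(self):
        assert normalize_rpm(0, 20_000_000) == 0.01

    def test_full_library_is_one_million(self):
        assert normalize_rpm(12345, 12345) == 1_000_000

    def test_invalid_total_errors(self):
        with pytest.raises(ValueError):
            normalize_rpm(1, 0)

    @given(count=st.integers(1, 10**6), total=st.integers(1, 10**7))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, count, total):
        assert math.isclose(normalize_rpm(count, total), normalize_rpm(2 * count, 2 * total))


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(5.0, 5.0, 0.0), (4.0, 1.0, 2.0), (0.01, 10.24, -10.0)]
    )
    def test_examples(self, a, b, expected):
        assert math.isclose(log2_fold_change(a, b), expected)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            log2_fold_change(0.0, 1.0)

    @given(
        a=st.floats(1e-2, 1e6, allow_nan=False), b=st.floats(1e-2, 1e6, allow_nan=False)
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert math.isclose(log2_fold_change(a, b), -log2_fold_change(b, a), abs_tol=1e-12)


def exact_min_likelihood_p(x_a, n, p_num, p_den):
    """Brute-force oracle with exact rational binomial probabilities."""
    from fractions import Fraction

    p = Fraction(p_num, p_den)
    pmf = [
        math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)
    ]
    obs = pmf[x_a]
    return float(sum(q for q in pmf if q <= obs))


class TestPoissonPairTest:
    def test_symmetric_modal_outcome_is_one(self):
        assert poisson_pair_test(12, 10**6, 12, 10**6) == 1.0

    def test_both_zero_is_one_by_convention(self):
        assert poisson_pair_test(0, 10**6, 0, 10**6) == 1.0

    def test_thirty_vs_ten_matches_enumeration_oracle(self):
        # exhaustive enumeration over the 41 outcomes of Binomial(40, 1/2)
        expected = exact_min_likelihood_p(30, 40, 1, 2)
        assert math.isclose(poisson_pair_test(30, 10**6, 10, 10**6), expected, rel_tol=1e-9)

    def test_unequal_totals_matches_oracle(self):
        expected = exact_min_likelihood_p(8, 20, 1, 3)  # totalA : totalB = 1 : 2
        assert math.isclose(
            poisson_pair_test(8, 10**6, 12, 2 * 10**6), expected, rel_tol=1e-9
        )

    @given(xa=st.integers(0, 40), xb=st.integers(0, 40))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_under_library_swap(self, xa, xb):
        p1 = poisson_pair_test(xa, 10**6, xb, 10**6)
        p2 = poisson_pair_test(xb, 10**6, xa, 10**6)
        assert math.isclose(p1, p2, rel_tol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_pair_test(1, 0, 1, 10)
        with pytest.raises(ValueError):
            poisson_pair_test(-1, 10, 1, 10)


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni([0.001], n_tests=60) == [0.06]
        assert bonferroni([0.5], n_tests=3) == [1.0]

    def test_order_preserved(self):
        out = bonferroni([0.01, 0.02, 0.2], n_tests=10)
        assert out == sorted(out)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], n_tests=1)


class TestSignificanceCall:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [(1.5, 0.01, True), (0.9, 1e-5, False), (2.0, 0.05, False), (-1.0, 0.049, True)],
    )
    def test_joint_criteria(self, lfc, p, expected):
        assert call_significant(lfc, p) is expected


class TestAbundanceAndTrend:
    @pytest.mark.parametrize(
        "count,tier",
        [(15_000, "high"), (2_000, "moderate"), (500, "low"), (10_000, "moderate"), (1_000, "low")],
    )
    def test_tiers(self, count, tier):
        assert classify_abundance(count) == tier

    @pytest.mark.parametrize(
        "p1,p2,p3,cls",
        [
            (1, 4, 16, "increasing"),
            (16, 4, 1, "decreasing"),
            (16, 4, 16, "V"),
            (4, 16, 4, "reversed_V"),
            (4, 4.1, 4, "flat"),
        ],
    )
    def test_trend_classes(self, p1, p2, p3, cls):
        assert classify_trend(p1, p2, p3) == cls


class TestClusterProfiles:
    def test_identical_rows_share_a_group(self):
        prof = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"])
        _, groups = cluster_profiles(prof, k=2)
        assert groups["a"] == groups["b"] != groups["c"]

    def test_two_tight_blobs_recovered_at_k2(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0, 0.05, size=(3, 3))
        blob2 = rng.normal(10, 0.05, size=(3, 3))
        prof = pd.DataFrame(
            np.vstack([blob1, blob2]), index=[f"m{i}" for i in range(6)]
        )
        _, groups = cluster_profiles(prof, k=2)
        # brute-force nearest-pair verification: each blob is one group
        assert len(set(groups[:3])) == 1 and len(set(groups[3:])) == 1
        assert groups.iloc[0] != groups.iloc[5]

    def test_constant_matrix_warns_single_group(self):
        prof = pd.DataFrame([[1.0, 1.0]] * 3, index=list("abc"))
        with pytest.warns(UserWarning):
            _, groups = cluster_profiles(prof, k=2)
        assert set(groups) == {1}

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame([[1.0]]), k=1)


class TestDifferentialExpression:
    def test_report_calls_planted_change(self):
        counts = pd.DataFrame(
            {"A": [400, 2000], "B": [100, 2000]}, index=["up", "flat"]
        ).T.rename_axis("mirna")
        counts = pd.DataFrame({"A": [400, 2000], "B": [100, 2000]}, index=["up", "flat"])
        de = differential_expression(counts, {"A": 10**6, "B": 10**6}, [("A", "B")])
        up = de[de.mirna == "up"].iloc[0]
        flat = de[de.mirna == "flat"].iloc[0]
        assert up.significant and math.isclose(up.log2fc, 2.0)
        assert not flat.significant and flat.p_bonf == 1.0

    def test_type_i_error_on_null_pairs(self):
        # simulated equal-rate pairs: raw rejection at 0.05 stays near level
        rng = np.random.default_rng(5)
        n = 2000
        xa = rng.poisson(100, size=n)
        xb = rng.poisson(100, size=n)
        rej = sum(
            poisson_pair_test(int(a), 10**6, int(b), 10**6) < 0.05 for a, b in zip(xa, xb)
        )
        assert rej / n <= 0.06

    def test_power_on_fourfold_changes(self):
        rng = np.random.default_rng(6)
        n = 300
        xa = rng.poisson(200, size=n)
        xb = rng.poisson(50, size=n)
        called = 0
        for a, b in zip(xa, xb):
            p = poisson_pair_test(int(a), 10**6, int(b), 10**6)
            fc = log2_fold_change(
                normalize_rpm(int(a), 10**6), normalize_rpm(int(b), 10**6)
            )
            if call_significant(fc, min(1.0, p * 300)):
                called += 1
        assert called / n >= 0.9
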