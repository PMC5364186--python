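import itertools
import math

import numpy as np
import pytest

from pollenmir.io import revcomp
from pollenmir.simdata import plant_target_sites
from pollenmir.targets import (
    ScoringScheme,
    TargetSite,
    cleavage_position,
    scan_targets,
    score_site,
)

SCHEME = ScoringScheme()
MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _pair_penalty(m, t, scheme):
    if (m, t) in _WC:
        return 0.0
    if (m, t) in _WOBBLE:
        return scheme.gu_wobble_penalty
    return scheme.mismatch_penalty


def oracle_score(mirna, window, scheme):
    """Exhaustive alignment oracle: enumerate every gap placement
    directly over index tuples (independent of the implementation)."""
    tgt = window[::-1]
    m, w = len(mirna), len(tgt)
    best = math.inf
    if m == w:
        layouts = [list(zip(range(m), range(m)))]
    elif w == m - 1:
        layouts = []
        for g in range(m):
            mi = list(range(m))
            ti = list(range(g)) + [None] + list(range(g, w))
            layouts.append(list(zip(mi, ti)))
    elif w == m + 1:
        layouts = []
        for g in range(w):
            ti = list(range(w))
            mi = list(range(g)) + [None] + list(range(g, m))
            layouts.append(list(zip(mi, ti)))
    else:
        return math.inf
    for layout in layouts:
        s = 0.0
        seen = 0
        for mi, ti in layout:
            if mi is not None and ti is not None:
                weight = 2.0 if scheme.core_start <= mi + 1 <= scheme.core_end else 1.0
                s += _pair_penalty(mirna[mi], tgt[ti], scheme) * weight
                seen = mi + 1
            elif ti is None:
                weight = 2.0 if scheme.core_start <= mi + 1 <= scheme.core_end else 1.0
                s += scheme.gap_penalty * weight
                seen = mi + 1
            else:
                pos = min(max(seen, 1), m)
                weight = 2.0 if scheme.core_start <= pos <= scheme.core_end else 1.0
                s += scheme.gap_penalty * weight
        best = min(best, s)
    return best


def _mutate(window, mirna_pos, base):
    """Set the window base opposite 1-based miRNA position."""
    idx = len(window) - mirna_pos
    return window[:idx] + base + window[idx + 1 :]


class TestScoreSite:
    def test_perfect_complement_scores_zero(self):
        score, aln = score_site(MIRNA, revcomp(MIRNA), SCHEME)
        assert score == 0.0
        assert set(aln.lines()[1]) == {"|"}

    def test_core_mismatch_costs_double(self):
        w = revcomp(MIRNA)
        # a mismatch opposite position 15 (outside the 2-13 core) costs 1
        w15 = _mutate(w, 15, "C" if w[len(w) - 15] != "C" else "A")
        s15, _ = score_site(MIRNA, w15, SCHEME)
        # the same substitution opposite position 5 (core) costs 2
        w5 = _mutate(w, 5, "C" if w[len(w) - 5] != "C" else "A")
        s5, _ = score_site(MIRNA, w5, SCHEME)
        assert (s15, s5) == (1.0, 2.0)

    def test_wobble_plus_mismatch(self):
        w = revcomp(MIRNA)
        # G:U wobble opposite core position 5 (x2) plus a mismatch at 20
        assert MIRNA[4] == "A"  # need a G or T for a wobble: use position 6
        assert MIRNA[5] == "G"
        w6 = _mutate(w, 6, "T")
        w6_20 = _mutate(w6, 20, "C" if w6[len(w6) - 20] != "C" else "A")
        score, _ = score_site(MIRNA, w6_20, SCHEME)
        assert score == 0.5 * 2 + 1.0

    def test_window_length_outside_gap_budget_errors(self):
        with pytest.raises(ValueError):
            score_site(MIRNA, revcomp(MIRNA)[:-3], SCHEME)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            score_site("", "ACGT")

    def test_matches_exhaustive_oracle_on_short_pairs(self):
        rng = np.random.default_rng(42)
        bases = list("ACGT")
        for _ in range(250):
            m = int(rng.integers(8, 13))
            w = m + int(rng.integers(-1, 2))
            mirna = "".join(rng.choice(bases, size=m))
            window = "".join(rng.choice(bases, size=w))
            got, _ = score_site(mirna, window, SCHEME)
            assert got == oracle_score(mirna, window, SCHEME), (mirna, window)

    def test_additional_mismatch_never_decreases_score(self):
        rng = np.random.default_rng(9)
        w = revcomp(MIRNA)
        base_score, _ = score_site(MIRNA, w, SCHEME)
        for pos in range(1, 22):
            i = len(w) - pos
            for b in "ACGT":
                if b == w[i]:
                    continue
                s, _ = score_site(MIRNA, w[:i] + b + w[i + 1 :], SCHEME)
                assert s >= base_score


class TestScanTargets:
    def test_exact_complement_found_once_with_score_zero(self):
        est = "G" * 60 + revcomp(MIRNA) + "C" * 60
        sites = scan_targets(MIRNA, est, SCHEME)
        assert len(sites) == 1
        assert sites[0].score == 0.0 and sites[0].start == 60

    def test_random_est_has_no_sub_threshold_windows(self):
        # exhaustive check (no prescreen) on a seeded random sequence
        rng = np.random.default_rng(100)
        est = "".join(rng.choice(list("ACGT"), size=400))
        sites = scan_targets(MIRNA, est, SCHEME, prescreen=False)
        assert sites == []

    def test_prescreen_equals_exhaustive_scan_on_planted_sites(self, rng):
        est = list("".join(rng.choice(list("ACGT"), size=300)))
        w = revcomp(MIRNA)
        est[40 : 40 + len(w)] = w
        est = "".join(est)
        fast = scan_targets(MIRNA, est, SCHEME, prescreen=True)
        slow = scan_targets(MIRNA, est, SCHEME, prescreen=False)
        assert [(s.start, s.end, s.score) for s in fast] == [
            (s.start, s.end, s.score) for s in slow
        ]

    def test_overlapping_windows_deduplicated_to_best(self):
        est = "A" * 30 + revcomp(MIRNA) + "A" * 30
        sites = scan_targets(MIRNA, est, SCHEME)
        spans = [(s.start, s.end) for s in sites]
        assert len(spans) == len(set(spans))
        for a, b in itertools.combinations(sites, 2):
            assert a.end <= b.start or b.end <= a.start


class TestCleavagePosition:
    def test_ungapped_site_positions_oppose_mirna_10_and_11(self):
        est = "T" * 100 + revcomp(MIRNA) + "T" * 100
        site = scan_targets(MIRNA, est, SCHEME)[0]
        # alignment-walking oracle: target base opposite miRNA position p
        # of an ungapped site starting at EST position s is s + (21 - p)
        assert site.cleavage_positions == (100 + 21 - 10, 100 + 21 - 11)

    def test_cleavage_always_inside_site(self):
        est = "G" * 40 + revcomp(MIRNA) + "G" * 40
        site = scan_targets(MIRNA, est, SCHEME)[0]
        lo, hi = site.cleavage_positions[1], site.cleavage_positions[0]
        assert site.start <= lo <= hi < site.end

    def test_short_mirna_errors(self):
        score, aln = score_site("ACGTACGTAC", revcomp("ACGTACGTAC"), SCHEME)
        site = TargetSite("m", "e", 0, 10, score, aln)
        with pytest.raises(ValueError):
            cleavage_position(site)


class TestPlantedScores:
    def test_planted_sites_recovered_at_intended_scores(self, rng):
        ests = {"e1": "".join(rng.choice(list("ACGT"), size=500)),
                "e2": "".join(rng.choice(list("ACGT"), size=500))}
        mirnas = {"m1": MIRNA}
        design = [("m1", "e1", 0.0), ("m1", "e2", 2.0)]
        planted, truth = plant_target_sites(ests, mirnas, design, rng)
        for _, row in truth.iterrows():
            sites = scan_targets(MIRNA, planted[row["est_id"]], SCHEME)
            match = [s for s in sites if s.start == row["start"]]
            assert match and match[0].score == row["intended_score"]

    def test_decoy_above_threshold_not_reported(self, rng):
        ests = {"e1": "".join(rng.choice(list("ACGT"), size=500))}
        planted, truth = plant_target_sites(
            ests, {"m1": MIRNA}, [("m1", "e1", 4.5)], rng
        )
        sites = scan_targets(MIRNA, planted["e1"], SCHEME)
        start = truth.iloc[0]["start"]
        assert not any(s.start < truth.iloc[0]["end"] and s.end > start for s in sites)
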