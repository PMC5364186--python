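import numpy as np
import pytest

from pollenmir.discover import (
    HairpinParams,
    Locus,
    PrecursorCandidate,
    detect_star,
    discover_novel,
    duplex_features,
    evaluate_candidate,
    extract_windows,
    map_reads_to_ests,
    sirna_filter,
)
from pollenmir.fold import fold_builtin, pair_table
from pollenmir.io import revcomp
from pollenmir.simdata import make_hairpin_precursor

MATURE = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


class TestMapReads:
    EST = {"e1": "G" * 50 + MATURE + "C" * 50}

    def test_single_locus(self):
        loci = map_reads_to_ests([MATURE], self.EST)
        assert loci == [Locus(MATURE, "e1", 50, "+")]

    def test_reverse_complement_match_gets_minus_strand(self):
        loci = map_reads_to_ests([revcomp(MATURE)], self.EST)
        assert loci == [Locus(revcomp(MATURE), "e1", 50, "-")]

    def test_repetitive_read_above_copy_cap_dropped(self):
        read = ("AACCG" * 5)[:21]  # not reverse-complement symmetric
        est = {"e1": ("TT" + read) * 21}
        assert map_reads_to_ests([read], est, max_copies=20) == []
        assert len(map_reads_to_ests([read], est, max_copies=25)) == 21

    def test_empty_est_set_errors(self):
        with pytest.raises(ValueError):
            map_reads_to_ests([MATURE], {})


class TestExtractWindows:
    def test_windows_around_interior_locus(self):
        # 21-nt read at position 150 of a 400-nt EST, flank 100
        est = "A" * 400
        locus = Locus("N" * 21, "e", 150, "+")
        spans = [(lo, hi) for lo, hi, _ in extract_windows(est, locus, 100)]
        assert spans == [(50, 171), (150, 271)]

    def test_truncation_at_est_start(self):
        est = "A" * 400
        locus = Locus("N" * 21, "e", 0, "+")
        spans = [(lo, hi) for lo, hi, _ in extract_windows(est, locus, 100)]
        assert spans == [(0, 21), (0, 121)]

    def test_minus_strand_window_is_reverse_complemented(self):
        est = "G" * 30 + revcomp(MATURE) + "C" * 30
        locus = Locus(MATURE, "e", 30, "-")
        for _lo, _hi, seq in extract_windows(est, locus, 10):
            assert MATURE in seq

    def test_window_bounds_always_inside_est(self):
        rng = np.random.default_rng(0)
        est = "".join(rng.choice(list("ACGT"), size=200))
        for start in (0, 5, 90, 179):
            locus = Locus(est[start : start + 21], "e", start, "+")
            for lo, hi, seq in extract_windows(est, locus, 100):
                assert 0 <= lo < hi <= len(est)
                assert locus.read in seq or revcomp(locus.read) in seq


def _stem_structure(mature_len=21, loop=10):
    return "(" * mature_len + "." * loop + ")" * mature_len


class TestDuplexFeatures:
    def test_perfect_duplex(self):
        s = _stem_structure()
        f = duplex_features(s, (0, 21), (31, 52))
        assert (f.pair_count, f.max_bulge, f.asymmetry, f.duplex_space) == (21, 0, 0, 10)

    def test_three_nt_bulge_on_mature_arm(self):
        # 9 pairs, a 3-nt bulge on the 5' arm, 9 more pairs, 4-nt loop
        s = "(" * 9 + "..." + "(" * 9 + "...." + ")" * 18
        # position-by-position oracle: mature span 0..20, bulge at 9..11
        f = duplex_features(s, (0, 21), (25, 43))
        assert f.max_bulge == 3 and f.asymmetry == 3
        assert f.pair_count == 18

    def test_duplex_space_is_interval_gap(self):
        s = _stem_structure(21, 310)
        f = duplex_features(s, (0, 21), (331, 352))
        assert f.duplex_space == 310

    def test_overlapping_intervals_error(self):
        with pytest.raises(ValueError):
            duplex_features(_stem_structure(), (0, 21), (15, 36))


def _candidate(structure, mfe=-40.0, seq=None):
    seq = seq or "A" * len(structure)
    return PrecursorCandidate("e", 0, len(structure), "+", seq, structure, mfe)


class TestEvaluateCandidate:
    PARAMS = HairpinParams()

    def test_qualifying_hairpin_passes(self):
        ok, reasons = evaluate_candidate(_candidate(_stem_structure()), (0, 21), self.PARAMS)
        assert ok and reasons == []

    def test_mfe_above_threshold_fails_with_reason(self):
        ok, reasons = evaluate_candidate(
            _candidate(_stem_structure(), mfe=-17.5), (0, 21), self.PARAMS
        )
        assert not ok and reasons == ["mfe"]

    def test_too_few_duplex_pairs(self):
        # 15-pair stem: below the 16-pair duplex minimum
        s = "(" * 15 + "......" + "." * 10 + ")" * 15
        ok, reasons = evaluate_candidate(_candidate(s), (0, 21), self.PARAMS)
        assert not ok and "duplex_pairs" in reasons

    def test_excessive_bulge(self):
        s = "(" * 8 + "." * 5 + "(" * 13 + "...." + ")" * 21
        ok, reasons = evaluate_candidate(_candidate(s), (0, 26), self.PARAMS)
        assert not ok and "duplex_bulge" in reasons and "duplex_asymmetry" in reasons

    def test_excessive_duplex_space(self):
        s = _stem_structure(21, 310)
        ok, reasons = evaluate_candidate(
            _candidate(s), (0, 21), self.PARAMS, star_interval=(331, 352)
        )
        assert not ok and reasons == ["duplex_space"]

    def test_mature_spanning_both_arms_fails_arm_rule(self):
        s = _stem_structure(21, 10)
        ok, reasons = evaluate_candidate(_candidate(s), (10, 32), self.PARAMS)
        assert not ok and "arm" in reasons

    def test_mature_length_bounds(self):
        s = _stem_structure(30, 10)
        ok, reasons = evaluate_candidate(_candidate(s), (0, 30), self.PARAMS)
        assert not ok and "mature_length" in reasons

    def test_relaxing_any_single_bound_never_turns_pass_into_fail(self):
        import dataclasses

        cand = _candidate(_stem_structure())
        base = HairpinParams()
        assert evaluate_candidate(cand, (0, 21), base)[0]
        relaxed = [
            dataclasses.replace(base, max_precursor_free_energy=-10.0),
            dataclasses.replace(base, min_duplex_pairs=10),
            dataclasses.replace(base, max_duplex_bulge=8),
            dataclasses.replace(base, max_duplex_asymmetry=8),
            dataclasses.replace(base, max_duplex_space=500),
            dataclasses.replace(base, max_mature_len=28),
        ]
        for params in relaxed:
            assert evaluate_candidate(cand, (0, 21), params)[0]


class TestDetectStar:
    def test_star_of_perfect_stem_is_shifted_reverse_complement(self):
        # independent structure-walking oracle: with every mature base i
        # paired to n-1-i, the 2-nt-overhang star spans pt[me-3]..pt[ms]+2
        seq = MATURE + "ACAACAACAA" + revcomp(MATURE)
        structure, _ = fold_builtin(seq)
        cand = PrecursorCandidate("e", 0, len(seq), "+", seq, structure, -40)
        star = detect_star(cand, (0, 21))
        pt = pair_table(structure)
        assert star is not None
        expected_start = pt[21 - 3]
        assert star.interval[0] == expected_start
        assert star.interval[1] == min(len(seq), pt[0] + 3)

    def test_star_support_requires_exact_read(self):
        seq = MATURE + "ACAACAACAA" + revcomp(MATURE)
        structure, _ = fold_builtin(seq)
        cand = PrecursorCandidate("e", 0, len(seq), "+", seq, structure, -40)
        bare = detect_star(cand, (0, 21), reads={})
        assert bare is not None and not bare.observed
        star_seq = bare.sequence
        seen = detect_star(cand, (0, 21), reads={star_seq: {"UM": 3}})
        assert seen.observed and seen.support == {"UM": 3}

    def test_unpaired_mature_has_no_star(self):
        cand = PrecursorCandidate("e", 0, 40, "+", "A" * 40, "." * 40, 0.0)
        assert detect_star(cand, (5, 26)) is None


class TestSirnaFilter:
    def _profile(self, n=100):
        plus = np.zeros(n)
        minus = np.zeros(n)
        return plus, minus

    def test_balanced_strands_excluded(self):
        plus, minus = self._profile()
        plus[10] = 50
        minus[40] = 50
        keep, reasons = sirna_filter(plus, minus, [(0, 100)])
        assert not keep and reasons == ["both_strands"]

    def test_concentrated_single_strand_kept(self):
        plus, minus = self._profile()
        plus[10] = 95
        plus[60] = 5
        keep, _ = sirna_filter(plus, minus, [(5, 30), (55, 80)])
        assert keep

    def test_wide_distribution_excluded(self):
        # 10% minus reads, 60% of reads scattered outside mature+star:
        # counting oracle: inside = 40, outside = 60 -> fraction 0.6 > 0.5
        plus, minus = self._profile()
        plus[5] = 36
        minus[6] = 4
        for p in range(40, 100, 2):
            plus[p] = 2
        keep, reasons = sirna_filter(plus, minus, [(0, 30)])
        assert not keep and reasons == ["wide_distribution"]

    def test_empty_profile_kept(self):
        plus, minus = self._profile()
        keep, reasons = sirna_filter(plus, minus, [(0, 10)])
        assert keep and reasons == []


class TestDiscoveryEndToEnd:
    def test_planted_hairpin_recovered_from_est(self, rng):
        hp, (ms, me), _ = make_hairpin_precursor(rng)
        mature = hp[ms:me]
        flank5 = "".join(rng.choice(list("ACGT"), size=150))
        flank3 = "".join(rng.choice(list("ACGT"), size=150))
        ests = {"e1": flank5 + hp + flank3}
        reads = {mature: {"UM": 30}}
        novels = discover_novel(reads, ests, min_seed_count=5)
        assert len(novels) == 1
        assert novels[0].passed and novels[0].mature == mature
        assert novels[0].precursor.sequence.count(mature) >= 1

    def test_minus_strand_hairpin_recovered(self, rng):
        hp, (ms, me), _ = make_hairpin_precursor(rng)
        mature = hp[ms:me]
        flank5 = "".join(rng.choice(list("ACGT"), size=150))
        flank3 = "".join(rng.choice(list("ACGT"), size=150))
        ests = {"e1": revcomp(flank5 + hp + flank3)}
        novels = discover_novel({mature: {"UM": 30}}, ests, min_seed_count=5)
        assert len(novels) == 1 and novels[0].passed
        assert novels[0].precursor.strand == "-"
        assert mature in novels[0].precursor.sequence

    def test_low_support_seed_not_evaluated(self, rng):
        hp, (ms, me), _ = make_hairpin_precursor(rng)
        ests = {"e1": "ACGT" * 40 + hp + "TGCA" * 40}
        novels = discover_novel({hp[ms:me]: {"UM": 2}}, ests, min_seed_count=5)
        assert novels == []
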