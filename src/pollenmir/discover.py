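"""Novel miRNA discovery from unannotated reads.

Candidate reads are mapped to an EST/transcript set; windows around each
locus are excised and folded; the resulting hairpins are judged against
Mireap-style structural criteria (precursor free energy, miRNA/miRNA*
duplex pairing, bulge, asymmetry, spacing); star support is sought under
the Dicer 2-nt 3' overhang convention; and siRNA-like loci (balanced
plus/minus mapping or widely scattered reads) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .fold import Engine, fold, pair_table
from .io import revcomp


@dataclass(frozen=True)
class HairpinParams:
    """Structural criteria for a candidate miRNA hairpin."""

    min_mature_len: int = 18
    max_mature_len: int = 25
    min_ref_len: int = 20
    max_ref_len: int = 23
    max_copies_on_reference: int = 20
    max_precursor_free_energy: float = -18.0  # kcal/mol
    max_duplex_space: int = 300  # nt between miRNA and miRNA*
    min_duplex_pairs: int = 16
    max_duplex_bulge: int = 4
    max_duplex_asymmetry: int = 4
    precursor_flank: int = 20
    window_flank: int = 100

    def __post_init__(self) -> None:
        if self.min_mature_len > self.max_mature_len or self.min_ref_len > self.max_ref_len:
            raise ValueError("min bound exceeds max bound")
        if self.max_precursor_free_energy > 0:
            raise ValueError("free-energy threshold must be <= 0")


class Locus(NamedTuple):
    """A full-length exact match of a read on a reference sequence."""

    read: str
    est_id: str
    start: int  # 0-based on the reference plus strand
    strand: str  # '+' or '-'

    @property
    def end(self) -> int:
        return self.start + len(self.read)


@dataclass
class PrecursorCandidate:
    source_id: str
    start: int  # 0-based half-open, reference plus strand
    end: int
    strand: str
    sequence: str  # strand-oriented (contains the mature verbatim)
    structure: str
    mfe: float


@dataclass(frozen=True)
class DuplexFeatures:
    pair_count: int
    max_bulge: int
    asymmetry: int
    duplex_space: int


@dataclass(frozen=True)
class StarResult:
    sequence: str
    interval: Tuple[int, int]
    support: Dict[str, int]
    observed: bool


@dataclass
class NovelMiRNA:
    mature: str
    star: Optional[StarResult]
    precursor: PrecursorCandidate
    mature_interval: Tuple[int, int]
    read_support: Dict[str, int]
    passed: bool
    reasons: List[str] = field(default_factory=list)

    @property
    def star_support(self) -> Dict[str, int]:
        return self.star.support if self.star else {}


def map_reads_to_ests(
    reads: Iterable[str],
    ests: Dict[str, str],
    max_copies: int = 20,
) -> List[Locus]:
    """Exact full-length matches of reads on either strand of the ESTs.

    Reads matching more than ``max_copies`` loci in total are dropped.
    """
    if not ests:
        raise ValueError("empty EST set")
    reads = list(reads)
    if not reads:
        return []
    # exact prefix-seed index: a full-length match must extend its prefix
    seed_len = min(18, min(len(r) for r in reads))
    index: Dict[str, List[Tuple[str, int]]] = {}
    for est_id, seq in ests.items():
        for p in range(len(seq) - seed_len + 1):
            index.setdefault(seq[p : p + seed_len], []).append((est_id, p))

    def occurrences(query: str, strand: str, read: str) -> List[Locus]:
        found: List[Locus] = []
        for est_id, p in index.get(query[:seed_len], ()):
            if ests[est_id][p : p + len(query)] == query:
                found.append(Locus(read, est_id, p, strand))
        return found

    out: List[Locus] = []
    for read in reads:
        rc = revcomp(read)
        loci = occurrences(read, "+", read)
        if rc != read:
            loci += occurrences(rc, "-", read)
        if 0 < len(loci) <= max_copies:
            out.extend(loci)
    return out


def extract_windows(
    est: str, locus: Locus, window_flank: int = 100
) -> List[Tuple[int, int, str]]:
    """Excise up to two candidate windows around a locus.

    One window extends ``window_flank`` nt upstream of the read (read near
    the window 3' end), the other downstream (read near the 5' end); both
    contain the read and are truncated at the EST boundaries.  Coordinates
    are on the plus strand; minus-strand sequences are returned
    reverse-complemented.
    """
    if not (0 <= locus.start and locus.end <= len(est)):
        raise ValueError("locus outside EST")
    windows = []
    spans = [
        (max(0, locus.start - window_flank), locus.end),
        (locus.start, min(len(est), locus.end + window_flank)),
    ]
    seen = set()
    for lo, hi in spans:
        if (lo, hi) in seen:
            continue
        seen.add((lo, hi))
        seq = est[lo:hi]
        if locus.strand == "-":
            seq = revcomp(seq)
        windows.append((lo, hi, seq))
    return windows


def _oriented_interval(
    w_lo: int, w_hi: int, strand: str, start: int, end: int
) -> Tuple[int, int]:
    """Map a plus-strand sub-interval into window-oriented coordinates."""
    if strand == "+":
        return start - w_lo, end - w_lo
    return w_hi - end, w_hi - start


def duplex_features(
    structure: str, mature_interval: Tuple[int, int], star_interval: Tuple[int, int]
) -> DuplexFeatures:
    """Pairing statistics of the miRNA/miRNA* duplex within a structure.

    ``pair_count`` counts mature bases paired into the star interval;
    ``max_bulge`` is the longest unpaired run inside the duplex span on
    either strand; ``asymmetry`` is the difference in unpaired counts
    between the two strands; ``duplex_space`` is the gap separating the
    intervals.
    """
    ms, me = mature_interval
    ss, se = star_interval
    if max(ms, ss) < min(me, se):
        raise ValueError("mature and star intervals overlap")
    pt = pair_table(structure)

    def paired_flags(lo: int, hi: int, other_lo: int, other_hi: int) -> np.ndarray:
        part = pt[lo:hi]
        return (part >= other_lo) & (part < other_hi)

    m_flags = paired_flags(ms, me, ss, se)
    s_flags = paired_flags(ss, se, ms, me)
    pair_count = int(m_flags.sum())

    def span_unpaired(flags: np.ndarray) -> Tuple[int, int]:
        idx = np.flatnonzero(flags)
        if idx.size == 0:
            return 0, 0
        inner = flags[idx[0] : idx[-1] + 1]
        unpaired = int((~inner).sum())
        longest = run = 0
        for f in inner:
            run = 0 if f else run + 1
            longest = max(longest, run)
        return unpaired, longest

    um, bm = span_unpaired(m_flags)
    us, bs = span_unpaired(s_flags)
    space = ss - me if me <= ss else ms - se
    return DuplexFeatures(
        pair_count=pair_count,
        max_bulge=max(bm, bs),
        asymmetry=abs(um - us),
        duplex_space=int(space),
    )


def detect_star(
    precursor: PrecursorCandidate,
    mature_interval: Tuple[int, int],
    reads: Optional[Dict[str, Dict[str, int]]] = None,
) -> Optional[StarResult]:
    """Predict the miRNA* segment (2-nt 3' overhang on each strand).

    The star interval is anchored on the partners of the mature 5' end and
    of the base three from its 3' end, stepping to the nearest paired base
    when an anchor is unpaired.  The star is flagged ``observed`` only
    when at least one read equals it exactly.
    """
    ms, me = mature_interval
    pt = pair_table(precursor.structure)
    n = len(precursor.sequence)

    def anchor(pos: int, step: int, lo: int, hi: int) -> Optional[int]:
        p = pos
        while lo <= p < hi:
            if pt[p] >= 0:
                return p
            p += step
        return None

    a = anchor(me - 3, -1, ms, me)  # star 5' anchor
    b = anchor(ms, +1, ms, me)  # star 3' anchor
    if a is None or b is None:
        return None
    star_start = int(pt[a]) - ((me - 3) - a)
    star_end = int(pt[b]) + (b - ms) + 3
    star_start = max(0, star_start)
    star_end = min(n, star_end)
    if star_end - star_start < 2 or (max(ms, star_start) < min(me, star_end)):
        return None
    star_seq = precursor.sequence[star_start:star_end]
    support: Dict[str, int] = {}
    if reads and star_seq in reads:
        support = dict(reads[star_seq])
    return StarResult(star_seq, (star_start, star_end), support, bool(support))


def evaluate_candidate(
    cand: PrecursorCandidate,
    mature_interval: Tuple[int, int],
    params: HairpinParams = HairpinParams(),
    star_interval: Optional[Tuple[int, int]] = None,
) -> Tuple[bool, List[str]]:
    """Judge a folded precursor against the hairpin criteria.

    Returns (passed, reasons); the reason list enumerates every violated
    rule: mature_length, mfe, duplex_pairs, duplex_bulge,
    duplex_asymmetry, duplex_space, arm.
    """
    reasons: List[str] = []
    ms, me = mature_interval
    if not params.min_mature_len <= me - ms <= params.max_mature_len:
        reasons.append("mature_length")
    if cand.mfe > params.max_precursor_free_energy:
        reasons.append("mfe")

    pt = pair_table(cand.structure)
    partners = [int(pt[p]) for p in range(ms, me) if pt[p] >= 0]
    on_one_arm = bool(partners) and (
        all(q >= me for q in partners) or all(q < ms for q in partners)
    )
    if not on_one_arm:
        reasons.append("arm")

    if star_interval is None:
        star = detect_star(cand, mature_interval)
        star_interval = star.interval if star else None
    if star_interval is None:
        reasons.extend(["duplex_pairs"])
        return False, reasons

    feats = duplex_features(cand.structure, mature_interval, star_interval)
    if feats.pair_count < params.min_duplex_pairs:
        reasons.append("duplex_pairs")
    if feats.max_bulge > params.max_duplex_bulge:
        reasons.append("duplex_bulge")
    if feats.asymmetry > params.max_duplex_asymmetry:
        reasons.append("duplex_asymmetry")
    if feats.duplex_space > params.max_duplex_space:
        reasons.append("duplex_space")
    return not reasons, reasons


def sirna_filter(
    plus_starts: np.ndarray,
    minus_starts: np.ndarray,
    windows: Sequence[Tuple[int, int]],
    minus_band: Tuple[float, float] = (0.4, 0.6),
    outside_threshold: float = 0.5,
) -> Tuple[bool, List[str]]:
    """Exclude siRNA-like loci.

    ``plus_starts``/``minus_starts`` hold per-position read-start counts on
    the precursor.  A locus is excluded when the minus-strand read
    fraction falls within ``minus_band`` (reads map almost equally to both
    strands) or when more than ``outside_threshold`` of the reads start
    outside the mature/star windows (wide distribution).
    Returns (keep, reasons).
    """
    plus_starts = np.asarray(plus_starts, dtype=float)
    minus_starts = np.asarray(minus_starts, dtype=float)
    total = plus_starts.sum() + minus_starts.sum()
    reasons: List[str] = []
    if total == 0:
        return True, reasons
    minus_frac = minus_starts.sum() / total
    if minus_band[0] <= minus_frac <= minus_band[1]:
        reasons.append("both_strands")
    mask = np.zeros(len(plus_starts), dtype=bool)
    for lo, hi in windows:
        mask[max(0, lo) : max(0, hi)] = True
    inside = plus_starts[mask].sum() + minus_starts[mask].sum()
    if total > 0 and (total - inside) / total > outside_threshold:
        reasons.append("wide_distribution")
    return not reasons, reasons


# ---------------------------------------------------------------------------
# orchestration


def _cluster_loci(loci: List[Locus]) -> List[List[Locus]]:
    """Group loci into chains of overlapping intervals per EST."""
    clusters: List[List[Locus]] = []
    cur_end = -1
    for locus in sorted(loci, key=lambda l: (l.est_id, l.start, l.end)):
        if clusters and clusters[-1][0].est_id == locus.est_id and locus.start < cur_end:
            clusters[-1].append(locus)
            cur_end = max(cur_end, locus.end)
        else:
            clusters.append([locus])
            cur_end = locus.end
    return clusters


def _read_profile(
    precursor_seq: str, reads: Dict[str, Dict[str, int]]
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position read-start counts on a precursor, both strands."""
    n = len(precursor_seq)
    plus = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=np.int64)
    for read, per_lib in reads.items():
        total = sum(per_lib.values())
        rc = revcomp(read)
        pos = precursor_seq.find(read)
        while pos >= 0:
            plus[pos] += total
            pos = precursor_seq.find(read, pos + 1)
        if rc != read:
            pos = precursor_seq.find(rc)
            while pos >= 0:
                minus[pos] += total
                pos = precursor_seq.find(rc, pos + 1)
    return plus, minus


def discover_novel(
    candidate_reads: Dict[str, Dict[str, int]],
    ests: Dict[str, str],
    all_reads: Optional[Dict[str, Dict[str, int]]] = None,
    params: HairpinParams = HairpinParams(),
    engine: Engine = "builtin",
    min_seed_count: int = 5,
    include_failed: bool = False,
) -> List[NovelMiRNA]:
    """Run the full discovery chain on unannotated/intronic reads.

    ``candidate_reads`` seed loci; ``all_reads`` (default: the candidates)
    provide the read-distribution profile for the siRNA exclusion and the
    star support.  Each overlapping-locus cluster is seeded by its most
    abundant read (requiring ``min_seed_count`` total reads); both
    directional windows are folded and the lower-energy qualifying hairpin
    is kept.  Candidates sharing a mature sequence keep the
    highest-support precursor.
    """
    if all_reads is None:
        all_reads = candidate_reads
    totals = {r: sum(c.values()) for r, c in candidate_reads.items()}
    loci = map_reads_to_ests(candidate_reads, ests, params.max_copies_on_reference)
    if all_reads is candidate_reads:
        profile_loci = loci
    else:
        profile_loci = map_reads_to_ests(all_reads, ests, params.max_copies_on_reference)
    all_totals = {r: sum(c.values()) for r, c in all_reads.items()}
    loci_index: Dict[str, List[Locus]] = {}
    for locus in profile_loci:
        loci_index.setdefault(locus.est_id, []).append(locus)
    for lst in loci_index.values():
        lst.sort(key=lambda l: l.start)

    results: List[NovelMiRNA] = []
    for cluster in _cluster_loci(loci):
        best_read = max(cluster, key=lambda l: (totals[l.read], l.read)).read
        if totals[best_read] < min_seed_count:
            continue
        seed = next(l for l in cluster if l.read == best_read)
        novel = _evaluate_locus(
            seed, ests, all_reads, params, engine, loci_index, all_totals
        )
        if novel is not None and (novel.passed or include_failed):
            novel.read_support = dict(candidate_reads[best_read])
            results.append(novel)
    # dedupe: one candidate per mature sequence and per overlapping locus
    by_mature: Dict[str, NovelMiRNA] = {}
    for novel in results:
        prev = by_mature.get(novel.mature)
        if (
            prev is None
            or (novel.passed, sum(novel.read_support.values()))
            > (prev.passed, sum(prev.read_support.values()))
        ):
            by_mature[novel.mature] = novel
    ranked = sorted(
        by_mature.values(),
        key=lambda n: (not n.passed, -sum(n.read_support.values()), n.mature),
    )
    accepted: List[NovelMiRNA] = []
    for novel in ranked:
        p = novel.precursor
        clash = any(
            a.precursor.source_id == p.source_id
            and max(a.precursor.start, p.start) < min(a.precursor.end, p.end)
            for a in accepted
        )
        if not clash:
            accepted.append(novel)
    return accepted


def _evaluate_locus(
    locus: Locus,
    ests: Dict[str, str],
    all_reads: Dict[str, Dict[str, int]],
    params: HairpinParams,
    engine: Engine,
    loci_index: Optional[Dict[str, List[Locus]]] = None,
    all_totals: Optional[Dict[str, int]] = None,
) -> Optional[NovelMiRNA]:
    est_seq = ests[locus.est_id]
    best: Optional[Tuple[bool, float, NovelMiRNA]] = None
    seen: set = set()
    # several excision extents per side: a long window can fold the read
    # into flank-involving structures, a short one isolates the hairpin
    flanks = sorted(
        {params.window_flank, max(40, int(0.6 * params.window_flank)), 40}, reverse=True
    )
    for flank in flanks:
        for w_lo, w_hi, w_seq in extract_windows(est_seq, locus, flank):
            if (w_lo, w_hi) in seen:
                continue
            seen.add((w_lo, w_hi))
            structure, mfe = fold(w_seq, engine)
            ms, me = _oriented_interval(w_lo, w_hi, locus.strand, locus.start, locus.end)
            window = PrecursorCandidate(
                locus.est_id, w_lo, w_hi, locus.strand, w_seq, structure, mfe
            )
            novel = _finalize_candidate(
                window, (ms, me), all_reads, params, engine, loci_index, all_totals
            )
            if novel is None:
                continue
            key = (novel.passed, -novel.precursor.mfe)
            if best is None or key > best[:2]:
                best = (novel.passed, -novel.precursor.mfe, novel)
    return best[2] if best else None


def _profile_from_index(
    precursor: PrecursorCandidate,
    loci_index: Dict[str, List[Locus]],
    all_totals: Dict[str, int],
) -> Tuple[np.ndarray, np.ndarray]:
    """Read-start profile on a precursor from a precomputed locus index."""
    n = len(precursor.sequence)
    plus = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=np.int64)
    for locus in loci_index.get(precursor.source_id, ()):  # sorted by start
        if locus.end <= precursor.start:
            continue
        if locus.start >= precursor.end:
            break
        if precursor.strand == "+":
            rel = locus.start - precursor.start
            same = locus.strand == "+"
        else:
            rel = precursor.end - locus.end
            same = locus.strand == "-"
        rel = min(max(rel, 0), n - 1)
        if same:
            plus[rel] += all_totals.get(locus.read, 0)
        else:
            minus[rel] += all_totals.get(locus.read, 0)
    return plus, minus


def _finalize_candidate(
    window: PrecursorCandidate,
    mature_interval: Tuple[int, int],
    all_reads: Dict[str, Dict[str, int]],
    params: HairpinParams,
    engine: Engine,
    loci_index: Optional[Dict[str, List[Locus]]] = None,
    all_totals: Optional[Dict[str, int]] = None,
) -> Optional[NovelMiRNA]:
    """Trim the window to the hairpin, refold and judge the candidate."""
    star = detect_star(window, mature_interval)
    ms, me = mature_interval
    if star is None:
        passed, reasons = evaluate_candidate(window, mature_interval, params)
        return NovelMiRNA(
            window.sequence[ms:me], None, window, mature_interval, {}, False,
            reasons or ["duplex_pairs"],
        )
    lo = max(0, min(ms, star.interval[0]) - params.precursor_flank)
    hi = min(len(window.sequence), max(me, star.interval[1]) + params.precursor_flank)
    prec_seq = window.sequence[lo:hi]
    structure, mfe = fold(prec_seq, engine)
    if window.strand == "+":
        p_start, p_end = window.start + lo, window.start + hi
    else:
        p_start, p_end = window.end - hi, window.end - lo
    precursor = PrecursorCandidate(
        window.source_id, p_start, p_end, window.strand, prec_seq, structure, mfe
    )
    m_iv = (ms - lo, me - lo)
    star2 = detect_star(precursor, m_iv, all_reads)
    passed, reasons = evaluate_candidate(
        precursor, m_iv, params, star2.interval if star2 else None
    )
    windows = [m_iv] + ([star2.interval] if star2 else [])
    if loci_index is not None and all_totals is not None:
        plus, minus = _profile_from_index(precursor, loci_index, all_totals)
    else:
        plus, minus = _read_profile(prec_seq, all_reads)
    keep, sirna_reasons = sirna_filter(plus, minus, windows)
    if not keep:
        passed = False
        reasons = reasons + sirna_reasons
    return NovelMiRNA(
        prec_seq[m_iv[0] : m_iv[1]], star2, precursor, m_iv, {}, passed, reasons
    )
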