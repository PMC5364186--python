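"""Plant miRNA target prediction by complementarity scoring.

A target window is scored by the standard plant penalty scheme: 0 for a
Watson-Crick pair, 0.5 for a G:U wobble, 1 for a mismatch, 2 for a gap,
with penalties doubled in the 5' core (miRNA positions 2-13).  Windows
scoring at most ``max_score`` (default 4.0) are reported, and the
expected cleavage site is the target position opposite miRNA positions
10 and 11.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import normalize_seq

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class ScoringScheme:
    mismatch_penalty: float = 1.0
    gu_wobble_penalty: float = 0.5
    gap_penalty: float = 2.0
    core_start: int = 2  # 1-based from the miRNA 5' end, inclusive
    core_end: int = 13
    max_score: float = 4.0
    max_gaps: int = 1
    strict: bool = False  # no mismatch at 10-11, <=1 mismatch in 2-12

    def weight(self, mirna_pos_1based: int) -> float:
        return 2.0 if self.core_start <= mirna_pos_1based <= self.core_end else 1.0


@dataclass
class Alignment:
    """Anti-parallel miRNA/target alignment.

    ``ops`` pairs a 0-based miRNA index (5'->3') with a 0-based index into
    the reversed target window (3'->5'); ``None`` marks a gap.
    """

    mirna: str
    window: str
    ops: List[Tuple[Optional[int], Optional[int]]]

    def lines(self) -> Tuple[str, str, str]:
        """(miRNA 3'->5', match line, target 5'->3') display strings."""
        tgt_rev = self.window[::-1]
        top, mid, bot = [], [], []
        for mi, ti in reversed(self.ops):
            a = self.mirna[mi] if mi is not None else "-"
            b = tgt_rev[ti] if ti is not None else "-"
            top.append(a)
            bot.append(b)
            if mi is None or ti is None:
                mid.append(" ")
            elif (a, b) in _WC:
                mid.append("|")
            elif (a, b) in _WOBBLE:
                mid.append("o")
            else:
                mid.append(" ")
        return "".join(top), "".join(mid), "".join(bot)


@dataclass
class TargetSite:
    mirna: str  # miRNA name (or sequence when unnamed)
    est_id: str
    start: int  # 0-based half-open on the EST plus strand
    end: int
    score: float
    alignment: Alignment
    cleavage_positions: Optional[Tuple[int, int]] = None


def _base_penalty(m: str, t: str, scheme: ScoringScheme) -> float:
    if (m, t) in _WC:
        return 0.0
    if (m, t) in _WOBBLE:
        return scheme.gu_wobble_penalty
    return scheme.mismatch_penalty


def _score_ops(
    mirna: str,
    tgt_rev: str,
    ops: Sequence[Tuple[Optional[int], Optional[int]]],
    scheme: ScoringScheme,
) -> float:
    score = 0.0
    mirna_seen = 0
    for mi, ti in ops:
        if mi is not None and ti is not None:
            score += _base_penalty(mirna[mi], tgt_rev[ti], scheme) * scheme.weight(mi + 1)
            mirna_seen = mi + 1
        elif ti is None:  # gap in target opposite miRNA base mi
            score += scheme.gap_penalty * scheme.weight(mi + 1)
            mirna_seen = mi + 1
        else:  # target insertion; weighted by the adjacent 5' miRNA position
            wpos = min(max(mirna_seen, 1), len(mirna))
            score += scheme.gap_penalty * scheme.weight(wpos)
    return score


def _strict_ok(
    mirna: str, tgt_rev: str, ops: Sequence[Tuple[Optional[int], Optional[int]]]
) -> bool:
    """Schwab-style constraints: no mismatch opposite miRNA positions
    10-11 and at most one mismatch within positions 2-12."""
    core_mm = 0
    for mi, ti in ops:
        if mi is None:
            continue
        pos = mi + 1
        mismatch = ti is None or (
            (mirna[mi], tgt_rev[ti]) not in _WC and (mirna[mi], tgt_rev[ti]) not in _WOBBLE
        )
        if mismatch and pos in (10, 11):
            return False
        if mismatch and 2 <= pos <= 12:
            core_mm += 1
    return core_mm <= 1


def _enumerate_ops(
    mlen: int, wlen: int, max_gaps: int
) -> List[List[Tuple[Optional[int], Optional[int]]]]:
    if wlen == mlen:
        return [[(i, i) for i in range(mlen)]]
    if wlen == mlen - 1 and max_gaps >= 1:
        all_ops = []
        for g in range(mlen):
            ops: List[Tuple[Optional[int], Optional[int]]] = []
            for i in range(mlen):
                if i < g:
                    ops.append((i, i))
                elif i == g:
                    ops.append((i, None))
                else:
                    ops.append((i, i - 1))
            all_ops.append(ops)
        return all_ops
    if wlen == mlen + 1 and max_gaps >= 1:
        all_ops = []
        for g in range(wlen):
            ops = []
            for t in range(wlen):
                if t < g:
                    ops.append((t, t))
                elif t == g:
                    ops.append((None, t))
                else:
                    ops.append((t - 1, t))
            all_ops.append(ops)
        return all_ops
    return []


def score_site(
    mirna: str, target_window: str, scheme: ScoringScheme = ScoringScheme()
) -> Tuple[float, Alignment]:
    """Optimal anti-parallel pairing score of a miRNA against one window.

    The window length must be within ``max_gaps`` of the miRNA length.
    Returns the minimal penalty total and the achieving alignment.
    """
    if not mirna or not target_window:
        raise ValueError("empty miRNA or target window")
    mirna = normalize_seq(mirna)
    window = normalize_seq(target_window)
    if abs(len(window) - len(mirna)) > scheme.max_gaps:
        raise ValueError("window length outside the gap budget")
    tgt_rev = window[::-1]
    best: Optional[Tuple[float, List[Tuple[Optional[int], Optional[int]]]]] = None
    for ops in _enumerate_ops(len(mirna), len(window), scheme.max_gaps):
        s = _score_ops(mirna, tgt_rev, ops, scheme)
        if scheme.strict and not _strict_ok(mirna, tgt_rev, ops):
            continue
        if best is None or s < best[0]:
            best = (s, ops)
    if best is None:
        return float("inf"), Alignment(mirna, window, [])
    return best[0], Alignment(mirna, window, best[1])


def cleavage_position(site: TargetSite) -> Tuple[int, int]:
    """EST coordinates opposite miRNA positions 10 and 11.

    Walks the alignment; a target gap opposite position 10/11 is skipped
    to the next aligned target base.  Requires a miRNA of >= 11 nt.
    """
    mirna = site.alignment.mirna
    if len(mirna) < 11:
        raise ValueError("miRNA shorter than 11 nt has no cleavage positions")
    wlen = len(site.alignment.window)
    out = []
    for want in (9, 10):  # 0-based miRNA indices of positions 10 and 11
        ti = None
        seen = False
        for mi, t in site.alignment.ops:
            if mi is not None and mi >= want and t is not None:
                ti = t
                seen = True
                break
        if not seen:
            raise ValueError("alignment does not cover the cleavage region")
        est_pos = site.start + (wlen - 1 - ti)
        out.append(est_pos)
    return (out[0], out[1])


_COMP_BYTES = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_BYTES[_a] = _b


def _ungapped_scores(mirna: str, est: str, scheme: ScoringScheme) -> np.ndarray:
    """Vectorised ungapped score for every window start on the EST."""
    mlen = len(mirna)
    est_arr = np.frombuffer(est.encode(), dtype=np.uint8)
    if len(est_arr) < mlen:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(est_arr, mlen)
    pattern = np.frombuffer(mirna[::-1].encode(), dtype=np.uint8)
    wc = win == _COMP_BYTES[pattern]
    wobble = ((pattern == ord("G")) & (win == ord("T"))) | (
        (pattern == ord("T")) & (win == ord("G"))
    )
    pen = np.where(wc, 0.0, np.where(wobble, scheme.gu_wobble_penalty, scheme.mismatch_penalty))
    mirna_pos = mlen - np.arange(mlen)  # 1-based miRNA position per window column
    weights = np.where(
        (mirna_pos >= scheme.core_start) & (mirna_pos <= scheme.core_end), 2.0, 1.0
    )
    return (pen * weights).sum(axis=1)


def scan_targets(
    mirna: str,
    est: str,
    scheme: ScoringScheme = ScoringScheme(),
    mirna_name: Optional[str] = None,
    est_id: str = "est",
    prescreen: bool = True,
    prescreen_margin: float = 8.0,
) -> List[TargetSite]:
    """All non-overlapping target sites with score <= ``scheme.max_score``.

    A vectorised ungapped screen selects anchor offsets (ungapped score at
    most ``max_score + prescreen_margin``); each anchor is then rescored
    exactly at window lengths within the gap budget, and overlapping sites
    are deduplicated to the best-scoring one.  Set ``prescreen=False`` to
    rescore every offset exactly.
    """
    mirna = normalize_seq(mirna)
    est = normalize_seq(est)
    mlen = len(mirna)
    if len(est) < mlen:
        raise ValueError("EST shorter than the miRNA")
    if prescreen:
        scores = _ungapped_scores(mirna, est, scheme)
        anchors = np.flatnonzero(scores <= scheme.max_score + prescreen_margin)
    else:
        anchors = np.arange(len(est) - mlen + 1)
    candidates: List[TargetSite] = []
    seen: set = set()
    for o in anchors:
        for start in (o - 1, o, o + 1):
            for wlen in range(mlen - scheme.max_gaps, mlen + scheme.max_gaps + 1):
                end = start + wlen
                if start < 0 or end > len(est) or (start, end) in seen:
                    continue
                seen.add((start, end))
                score, aln = score_site(mirna, est[start:end], scheme)
                if score <= scheme.max_score:
                    site = TargetSite(
                        mirna_name or mirna, est_id, int(start), int(end), score, aln
                    )
                    if mlen >= 11:
                        site.cleavage_positions = cleavage_position(site)
                    candidates.append(site)
    # deduplicate overlapping windows: best score, then leftmost
    candidates.sort(key=lambda s: (s.score, s.start))
    accepted: List[TargetSite] = []
    for site in candidates:
        if all(site.end <= a.start or site.start >= a.end for a in accepted):
            accepted.append(site)
    accepted.sort(key=lambda s: s.start)
    return accepted


def scan_many(
    mirnas: Dict[str, str],
    ests: Dict[str, str],
    scheme: ScoringScheme = ScoringScheme(),
    **kwargs,
) -> List[TargetSite]:
    """Scan every miRNA against every EST."""
    sites: List[TargetSite] = []
    for name, seq in mirnas.items():
        for est_id, est_seq in ests.items():
            if len(est_seq) < len(seq):
                continue
            sites.extend(
                scan_targets(seq, est_seq, scheme, mirna_name=name, est_id=est_id, **kwargs)
            )
    return sites
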