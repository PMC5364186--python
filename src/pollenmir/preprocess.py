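"""Raw-read cleaning: adapter trimming, filtering and read collapsing.

Clean reads are adapter-trimmed, quality-filtered sequences of 18-30 nt.
Identical clean reads collapse into unique reads carrying per-library
counts.  Every input read is accounted for exactly once, either inside a
unique read or in the per-reason discard ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple, Union

ADAPTER_ONLY = ""
"""Sentinel returned by :func:`trim_adapter` for an empty insert."""

MIN_CLEAN_LEN = 18
MAX_CLEAN_LEN = 30


@dataclass(frozen=True)
class SmallRNARead:
    """A raw sequencing read (phred+33 quality optional)."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length must equal sequence length")


@dataclass
class LibraryStats:
    """Per-library accounting of the cleaning step."""

    raw_count: int = 0
    clean_count: int = 0
    unique_count: int = 0
    length_histogram: Dict[int, int] = field(default_factory=dict)
    discarded: Dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if sum(self.length_histogram.values()) != self.clean_count:
            raise AssertionError("length histogram does not sum to clean_count")
        if self.clean_count + sum(self.discarded.values()) != self.raw_count:
            raise AssertionError("read conservation violated")


def _mismatches_ok(read: str, adapter: str, start: int, max_rate: float) -> bool:
    overlap = min(len(read) - start, len(adapter))
    budget = int(max_rate * overlap)
    mm = 0
    for k in range(overlap):
        a = read[start + k]
        if a != adapter[k] or a == "N":
            mm += 1
            if mm > budget:
                return False
    return True


def trim_adapter(
    sequence: str,
    adapter3: str,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
) -> str:
    """Return the insert preceding the leftmost 3' adapter match.

    Semi-global match: the adapter may sit fully inside the read or hang
    off its 3' end, as long as the overlap is >= ``min_overlap`` with a
    mismatch fraction <= ``max_mismatch_rate``.  Returns ``ADAPTER_ONLY``
    (the empty string) when the adapter starts at position 0, and the full
    sequence when no acceptable match exists.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    if not adapter3 or min_overlap < 1:
        raise ValueError("adapter3 must be non-empty and min_overlap >= 1")
    n = len(sequence)
    # Fast path: an exact hit of the adapter prefix bounds the fuzzy scan.
    probe_len = max(min(10, len(adapter3)), min(min_overlap, len(adapter3)))
    exact = sequence.find(adapter3[:probe_len])
    scan_end = exact if exact >= 0 else n - min_overlap + 1
    for i in range(0, max(scan_end, 0)):
        if min(n - i, len(adapter3)) < min_overlap:
            break
        if _mismatches_ok(sequence, adapter3, i, max_mismatch_rate):
            return sequence[:i]
    if exact >= 0 and min(n - exact, len(adapter3)) >= min_overlap:
        return sequence[:exact]
    return sequence


TrimmedRead = Union[SmallRNARead, Tuple[str, Optional[str]]]
"""Either a read object or a bare (sequence, quality) pair; the pair form
may carry an empty sequence (adapter-only insert)."""


def _as_pair(read: TrimmedRead) -> Tuple[str, Optional[str]]:
    if isinstance(read, SmallRNARead):
        return read.sequence, read.quality
    return read


def filter_and_collapse(
    reads: Iterable[TrimmedRead],
    min_len: int = MIN_CLEAN_LEN,
    max_len: int = MAX_CLEAN_LEN,
    polya_fraction_threshold: float = 0.8,
    min_quality: float = 20.0,
) -> Tuple[Dict[str, int], LibraryStats]:
    """Filter adapter-trimmed reads and collapse identical sequences.

    Discard reasons, applied in order: ``adapter_only`` (empty insert),
    ``low_quality`` (mean phred below ``min_quality`` or any N),
    ``too_short``, ``too_long``, ``polyA`` (A fraction >= threshold).
    Returns (seq -> count, stats); the stats ledger accounts for every
    input read exactly once.
    """
    counts: Dict[str, int] = {}
    stats = LibraryStats()
    discard = stats.discarded
    hist = stats.length_histogram

    def drop(reason: str) -> None:
        discard[reason] = discard.get(reason, 0) + 1

    for read in reads:
        seq, qual = _as_pair(read)
        stats.raw_count += 1
        if not seq:
            drop("adapter_only")
        elif "N" in seq:
            drop("low_quality")
        elif qual is not None and _mean_phred(qual[: len(seq)]) < min_quality:
            drop("low_quality")
        elif len(seq) < min_len:
            drop("too_short")
        elif len(seq) > max_len:
            drop("too_long")
        elif seq.count("A") / len(seq) >= polya_fraction_threshold:
            drop("polyA")
        else:
            counts[seq] = counts.get(seq, 0) + 1
            hist[len(seq)] = hist.get(len(seq), 0) + 1
            stats.clean_count += 1
    stats.unique_count = len(counts)
    stats.check()
    return counts, stats


def _mean_phred(quality: str) -> float:
    return sum(quality.encode()) / len(quality) - 33.0


def preprocess_library(
    raw_reads: Iterable[Tuple[str, str, Optional[str]]],
    adapter3: str,
    adapter5: Optional[str] = None,
    min_overlap: int = 8,
    max_mismatch_rate: float = 0.1,
    **filter_kwargs,
) -> Tuple[Dict[str, int], LibraryStats]:
    """Trim the 3' adapter, then filter and collapse one library.

    ``raw_reads`` yields (read_id, sequence, quality-or-None).  Reads whose
    trimmed insert still contains the 5' adapter are discarded as
    ``contaminant_5p`` (library-chemistry carry-over).
    """
    n_5p = 0

    def trimmed() -> Iterable[Tuple[str, Optional[str]]]:
        nonlocal n_5p
        for _read_id, seq, qual in raw_reads:
            insert = trim_adapter(seq, adapter3, min_overlap, max_mismatch_rate)
            if adapter5 is not None and insert and adapter5 in insert:
                n_5p += 1
                continue
            yield insert, (qual[: len(insert)] if qual and insert else None)

    counts, stats = filter_and_collapse(trimmed(), **filter_kwargs)
    if n_5p:
        stats.raw_count += n_5p
        stats.discarded["contaminant_5p"] = n_5p
        stats.check()
    return counts, stats


def length_histogram(
    unique_reads: Dict[str, Dict[str, int]], library: str
) -> Dict[int, int]:
    """Clean-read length histogram for one library (counts, not uniques)."""
    libs: Set[str] = set()
    for per_lib in unique_reads.values():
        libs.update(per_lib)
    if library not in libs:
        raise KeyError(f"unknown library id {library!r}")
    hist: Dict[int, int] = {}
    for seq, per_lib in unique_reads.items():
        c = per_lib.get(library, 0)
        if c:
            hist[len(seq)] = hist.get(len(seq), 0) + c
    return hist


def pairwise_overlap(
    a: Union[Set[str], Dict[str, int]], b: Union[Set[str], Dict[str, int]]
) -> Dict[str, float]:
    """Shared/specific unique-sequence fractions over the union of two sets."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise ValueError("both unique-read sets are empty")
    shared = len(sa & sb)
    return {
        "shared_fraction": shared / len(union),
        "a_specific_fraction": len(sa - sb) / len(union),
        "b_specific_fraction": len(sb - sa) / len(union),
    }


def merge_libraries(
    per_library: Dict[str, Dict[str, int]]
) -> Dict[str, Dict[str, int]]:
    """Merge per-library seq->count maps into seq -> {library: count}."""
    merged: Dict[str, Dict[str, int]] = {}
    for lib, counts in per_library.items():
        for seq, c in counts.items():
            merged.setdefault(seq, {})[lib] = c
    return merged
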