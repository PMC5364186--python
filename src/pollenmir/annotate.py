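"""Hierarchical read annotation and known-miRNA count matrices.

Unique reads are annotated against reference categories with a fixed
priority: structural RNAs (rRNA = tRNA = snRNA = snoRNA) > known miRNA >
repeat > exon > intron.  A read is assigned the highest-priority category
in which it has a hit; reads hitting nothing are "unannotated".

Structural/repeat/exon/intron hits are exact substring matches of the
read in a reference sequence on either strand.  Known-miRNA hits use an
ungapped overlap alignment: >= 16 nt of overlap with at most 2 mismatches
by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

import pandas as pd

from .io import revcomp

STRUCTURAL_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA")
CATEGORIES = STRUCTURAL_CATEGORIES + ("known_miRNA", "repeat", "exon", "intron")
UNANNOTATED = "unannotated"

#: annotation priority rank (lower = higher priority); structural RNAs tie.
_PRIORITY = {
    **{c: 0 for c in STRUCTURAL_CATEGORIES},
    "known_miRNA": 1,
    "repeat": 2,
    "exon": 3,
    "intron": 4,
}


@dataclass
class ReferenceSet:
    """A category of reference sequences (id -> DNA)."""

    category: str
    records: Dict[str, str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown reference category {self.category!r}")
        for rid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty reference sequence {rid!r}")
        self._text: Optional[str] = None
        self._bounds: Optional[List[int]] = None
        self._ids: Optional[List[str]] = None

    def _index(self) -> Tuple[str, List[int], List[str]]:
        if self._text is None:
            parts, bounds, ids = [], [], []
            pos = 1
            for rid, seq in self.records.items():
                bounds.append(pos)
                ids.append(rid)
                parts.append(seq)
                pos += len(seq) + 1
            self._text = "#" + "#".join(parts) + "#"
            self._bounds, self._ids = bounds, ids
        return self._text, self._bounds, self._ids

    def substring_hit(self, read: str, rc: str) -> Optional[str]:
        """Id of a record containing the read on either strand, or None."""
        from bisect import bisect_right

        text, bounds, ids = self._index()
        for query in (read, rc):
            p = text.find(query)
            if p >= 0:
                return ids[bisect_right(bounds, p) - 1]
        return None

    @classmethod
    def from_records(cls, category: str, pairs: Iterable[Tuple[str, str]]) -> "ReferenceSet":
        records: Dict[str, str] = {}
        for rid, seq in pairs:
            if rid in records:
                raise ValueError(f"duplicate reference id {rid!r}")
            records[rid] = seq
        return cls(category, records)


@dataclass(frozen=True)
class AnnotationRecord:
    sequence: str
    category: str
    hit_id: Optional[str]

    def __post_init__(self) -> None:
        if (self.category == UNANNOTATED) != (self.hit_id is None):
            raise ValueError("category 'unannotated' iff hit_id is None")


class MiRNAHit(NamedTuple):
    """Best ungapped overlap alignment of a read against a mature miRNA."""

    offset: int  # read start relative to mature start (may be negative)
    overlap: int
    mismatches: int


def match_known_mirna(
    read: str,
    mature: str,
    min_overlap: int = 16,
    max_mismatches: int = 2,
) -> Optional[MiRNAHit]:
    """Exact rule for assigning a read to a mature miRNA.

    Enumerates every ungapped offset of the read against the mature
    sequence; a hit requires overlap >= ``min_overlap`` with at most
    ``max_mismatches`` mismatches inside the overlap.  Returns the best
    hit (largest overlap, then fewest mismatches) or None.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    lr, lm = len(read), len(mature)
    best: Optional[MiRNAHit] = None
    for offset in range(-(lr - min_overlap), lm - min_overlap + 1):
        r0 = max(0, -offset)
        m0 = max(0, offset)
        overlap = min(lr - r0, lm - m0)
        if overlap < min_overlap:
            continue
        mm = sum(
            1 for k in range(overlap) if read[r0 + k] != mature[m0 + k]
        )
        if mm <= max_mismatches:
            hit = MiRNAHit(offset, overlap, mm)
            if best is None or (hit.overlap, -hit.mismatches) > (best.overlap, -best.mismatches):
                best = hit
    return best


class SeedIndex:
    """Exact word-seed screen over a mature-miRNA catalog.

    Mirrors how a Blastn-style search seeds alignments: a read is only
    aligned against matures with which it shares an exact ``word``-mer.
    The screen is a performance filter; :func:`match_known_mirna` still
    decides every hit.  Reads whose mismatches fragment every shared word
    below ``word`` nt are not seeded (as for a word-seeded aligner).
    """

    def __init__(self, entries: Dict[str, str], word: int = 8) -> None:
        self.word = word
        self.index: Dict[str, Set[str]] = {}
        for name, mature in entries.items():
            for i in range(len(mature) - word + 1):
                self.index.setdefault(mature[i : i + word], set()).add(name)

    def candidates(self, read: str) -> Set[str]:
        out: Set[str] = set()
        idx = self.index
        w = self.word
        for i in range(len(read) - w + 1):
            hit = idx.get(read[i : i + w])
            if hit:
                out |= hit
        return out


@dataclass
class KnownMiRNACatalog:
    """Named mature miRNA sequences with family assignments."""

    entries: Dict[str, str]
    family_of: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.entries.items():
            if not 18 <= len(seq) <= 30:
                raise ValueError(f"mature {name!r} length {len(seq)} outside 18-30 nt")
        for name in self.entries:
            try:
                self.family_of.setdefault(name, assign_family(name))
            except ValueError:  # no numeric family token: family = own name
                self.family_of.setdefault(name, name)

    @classmethod
    def from_records(
        cls,
        pairs: Iterable[Tuple[str, str]],
        merge_map: Optional[Dict[str, str]] = None,
    ) -> "KnownMiRNACatalog":
        entries = dict(pairs)
        fams = {name: assign_family(name, merge_map) for name in entries}
        return cls(entries, fams)


_FAMILY_RE = re.compile(r"miR[\s-]?(\d+)", re.IGNORECASE)


def assign_family(
    mirna_name: str, merge_map: Optional[Dict[str, str]] = None
) -> str:
    """Collapse a miRNA name to its family: numeric token, variant letters
    stripped, optionally merged (e.g. miR157 -> miR156/157)."""
    m = _FAMILY_RE.search(mirna_name)
    if not m:
        raise ValueError(f"cannot parse miRNA family from {mirna_name!r}")
    family = f"miR{m.group(1)}"
    if merge_map:
        family = merge_map.get(family, merge_map.get(m.group(1), family))
    return family


def annotate_reads(
    unique_reads: Iterable[str],
    refsets: Sequence[ReferenceSet],
    min_overlap: int = 16,
    max_mismatches: int = 2,
    screen: bool = True,
) -> List[AnnotationRecord]:
    """Assign each read its highest-priority reference category."""
    by_rank = sorted(refsets, key=lambda rs: _PRIORITY[rs.category])
    seeds = {
        id(rs): SeedIndex(rs.records)
        for rs in by_rank
        if rs.category == "known_miRNA"
    }
    records: List[AnnotationRecord] = []
    for read in unique_reads:
        rc = revcomp(read)
        category, hit_id = UNANNOTATED, None
        for rs in by_rank:
            if rs.category == "known_miRNA":
                hid = None
                names = seeds[id(rs)].candidates(read) if screen else rs.records
                for name in sorted(names):
                    if match_known_mirna(read, rs.records[name], min_overlap, max_mismatches):
                        hid = name
                        break
            else:
                hid = rs.substring_hit(read, rc)
            if hid is not None:
                category, hit_id = rs.category, hid
                break
        records.append(AnnotationRecord(read, category, hit_id))
    return records


def build_count_matrix(
    unique_reads: Dict[str, Dict[str, int]],
    catalog: KnownMiRNACatalog,
    libraries: Sequence[str],
    min_overlap: int = 16,
    max_mismatches: int = 2,
    screen: bool = True,
) -> pd.DataFrame:
    """Per-miRNA x per-library clean-read count matrix.

    Each unique read contributes its full count to every miRNA it hits
    under :func:`match_known_mirna` (multi-mapping reads count toward each
    matched miRNA; no fractional allocation).
    """
    acc: Dict[str, Dict[str, int]] = {name: {lib: 0 for lib in libraries} for name in catalog.entries}
    seed = SeedIndex(catalog.entries)
    for read, per_lib in unique_reads.items():
        names = seed.candidates(read) if screen else catalog.entries
        for name in names:
            if match_known_mirna(read, catalog.entries[name], min_overlap, max_mismatches):
                row = acc[name]
                for lib, c in per_lib.items():
                    if lib in row:
                        row[lib] += c
    mat = pd.DataFrame.from_dict(acc, orient="index")[list(libraries)].astype(int)
    mat.index.name = "mirna"
    return mat
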