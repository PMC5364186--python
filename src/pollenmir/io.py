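"""FASTA/FASTQ reading and the collapsed-FASTA dialect.

All sequences are normalised to the DNA alphabet (uppercase, U -> T) on
input.  Collapsed FASTA uses headers of the form ``seq<k>_x<count>``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterator, Tuple

from Bio import SeqIO

_COLLAPSED_RE = re.compile(r"^(?:\S*?)_x(\d+)$")

_COMP = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA to DNA alphabet."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a FASTA file into an id -> sequence dict.

    Raises ``ValueError`` on duplicate record ids.
    """
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        records[rec.id] = normalize_seq(str(rec.seq))
    return records


def iter_fastq(path: str | Path) -> Iterator[Tuple[str, str, str]]:
    """Yield (read_id, sequence, phred+33 quality string) from FASTQ."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # separator
            qual = fh.readline().rstrip("\n")
            yield header[1:].split()[0], normalize_seq(seq), qual


def read_collapsed_fasta(path: str | Path) -> Dict[str, int]:
    """Read collapsed FASTA (``seq<k>_x<count>`` headers) to seq -> count.

    Headers without an ``_x<count>`` suffix count as 1; repeated sequences
    are summed.
    """
    counts: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED_RE.match(rec.id)
        c = int(m.group(1)) if m else 1
        seq = normalize_seq(str(rec.seq))
        counts[seq] = counts.get(seq, 0) + c
    return counts


def write_collapsed_fasta(counts: Dict[str, int], path: str | Path) -> None:
    """Write seq -> count as collapsed FASTA, most abundant first."""
    with open(path, "w") as fh:
        order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        for k, (seq, c) in enumerate(order, start=1):
            fh.write(f">seq{k}_x{c}\n{seq}\n")


def write_fasta(records: Dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
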