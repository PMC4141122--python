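"""FASTA and BED input, and the genome-wide CpG index.

Coordinates are 0-based, half-open everywhere.  CpGs are indexed on the plus
strand only: a CG dinucleotide is its own reverse complement, so each CpG dyad
is counted once.  Soft-masked (lower-case) input is upper-cased on read, and
any site or CpG spanning an ``N`` never matches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "CpGIndex",
    "Interval",
    "IntervalSet",
    "read_fasta",
    "build_cpg_index",
    "read_intervals",
]

logger = logging.getLogger("rrbsdesign")

_VALID_CHARS = set("ACGTN")
_ILLEGAL_RE = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}, upper-case."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        m = _ILLEGAL_RE.search(self.sequence)
        if m:
            raise ValueError(
                f"record {self.id!r}: illegal character {m.group()!r} "
                f"at position {m.start()}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CpGIndex:
    """Sorted plus-strand positions of CG dinucleotides, per sequence.

    ``positions[seq_id][i]`` is the 0-based coordinate of the C of the i-th
    CpG.  ``total_cpgs`` counts each dyad once.
    """

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_cpgs(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def __getitem__(self, seq_id: str) -> np.ndarray:
        return self.positions[seq_id]

    def get(self, seq_id: str) -> np.ndarray:
        return self.positions.get(seq_id, np.empty(0, dtype=np.int64))


@dataclass(frozen=True)
class Interval:
    """Half-open interval [start, end), optionally stranded ('+'/'-')."""

    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")


@dataclass
class IntervalSet:
    """Category-labeled intervals per sequence, sorted by start."""

    category: str
    by_seq: dict[str, list[Interval]] = field(default_factory=dict)

    def add(self, seq_id: str, interval: Interval) -> None:
        self.by_seq.setdefault(seq_id, []).append(interval)

    def sort(self) -> None:
        for ivs in self.by_seq.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_seq.values())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into normalized records.

    Lower-case soft-masking is upper-cased; characters outside
    {A, C, G, T, N} raise ``ValueError`` naming the offending position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def build_cpg_index(records) -> CpGIndex:
    """Index every CG dinucleotide position across the given records.

    A ``CG`` spanning an N never matches (N is not C or G).  Equivalent to a
    per-position scan; vectorized over the byte representation.
    """
    index = CpGIndex()
    for rec in records:
        arr = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        if len(arr) < 2:
            index.positions[rec.id] = np.empty(0, dtype=np.int64)
            continue
        hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        index.positions[rec.id] = np.flatnonzero(hits).astype(np.int64)
    return index


def read_intervals(
    path: str | Path,
    category: str,
    valid_ids: set[str] | None = None,
) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet`.

    BED coordinates are consumed natively (0-based, half-open).  The strand
    column, when present, is retained for TSS derivation.  Lines whose
    sequence id is not in ``valid_ids`` (when given) are skipped with a
    logged warning; a line with ``end <= start`` raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out = IntervalSet(category=category)
    skipped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            seq_id = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end ({end}) <= start ({start})"
                )
            if valid_ids is not None and seq_id not in valid_ids:
                skipped += 1
                continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
            out.add(seq_id, Interval(start, end, strand))
    if skipped:
        logger.warning(
            "%s: skipped %d line(s) with unknown sequence ids", path, skipped
        )
    out.sort()
    return out
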