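"""Per-combination coverage metrics at a fixed sequencing depth.

A sequencer reads ``depth_nt`` bases in from each fragment end, so the
observable part of a size-selected fragment is the union of its two terminal
windows.  A CpG counts as covered when its C lies inside such a window (the
methylation call reads the C; strict mode requires the G as well).  From the
covered-CpG set and the fragment count the screening metrics follow:

* genomic CpG coverage % = 100 x covered / total CpGs (computed from the
  genome, or a preset assumed total),
* CpG/fragment ratio = covered CpGs per size-selected fragment,
* read coverage (fold) = instrument throughput / fragments,
* CpG-free fragments = fragments whose depth windows contain no CpG
  (pure sequencing cost in RRBS).

Values are kept at full precision; Table-style formatting rounds only at
output (percentages and folds to one decimal, ratios to two, half-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal

import numpy as np

from .catalog import RestrictionEnzyme
from .digestion import (
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    Fragment,
    cut_positions,
    fragments_from_cuts,
    size_select,
)
from .genome_io import CpGIndex, SequenceRecord, build_cpg_index

__all__ = [
    "CoverageParams",
    "CoverageReport",
    "CoveredSet",
    "covered_intervals",
    "covered_cpgs",
    "coverage_report",
    "fragment_size_profile",
    "DEFAULT_DEPTH_NT",
    "DEFAULT_THROUGHPUT_READS",
]

#: Read length from each fragment end (nt).
DEFAULT_DEPTH_NT = 50
#: Typical high-output flow-cell throughput (reads).
DEFAULT_THROUGHPUT_READS = 150_000_000


@dataclass(frozen=True)
class CoverageParams:
    """Screening parameters: depth, throughput, size window, denominator.

    ``total_cpgs_denominator`` is either ``"computed"`` (count CpG dyads in
    the input genome) or an integer preset such as the assumed genome totals
    27 M (human), 23.9 M (rat) and 21.9 M (mouse).
    """

    depth_nt: int = DEFAULT_DEPTH_NT
    throughput_reads: int = DEFAULT_THROUGHPUT_READS
    total_cpgs_denominator: int | Literal["computed"] = "computed"
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    include_terminal: bool = False
    strict_cpg: bool = False

    def __post_init__(self) -> None:
        if self.depth_nt <= 0:
            raise ValueError("depth_nt must be positive")
        if self.throughput_reads <= 0:
            raise ValueError("throughput_reads must be positive")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.total_cpgs_denominator != "computed":
            if int(self.total_cpgs_denominator) <= 0:
                raise ValueError("denominator must be positive")


@dataclass
class CoveredSet:
    """Covered CpG positions per sequence (sorted, unique int64 arrays).

    Set operations are exact and memory is linear in the number of CpGs.
    """

    by_seq: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return int(sum(len(v) for v in self.by_seq.values()))

    def seq_ids(self) -> set[str]:
        return set(self.by_seq)

    def intersection_size(self, other: "CoveredSet") -> int:
        total = 0
        for seq_id, pos in self.by_seq.items():
            opos = other.by_seq.get(seq_id)
            if opos is not None:
                total += len(np.intersect1d(pos, opos, assume_unique=True))
        return total

    def contains_all(self, other: "CoveredSet") -> bool:
        return other.size == other.intersection_size(self)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal("1." + "0" * decimals) if decimals else Decimal("1")
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageReport:
    """The six screening metrics for one enzyme combination.

    ``coverage_pct``, ``cpg_per_fragment`` and ``read_coverage`` are NaN when
    the digestion yields zero fragments (undefined, not a division failure).
    """

    enzymes: tuple[str, ...]
    cpgs_covered: int
    fragments_generated: int
    coverage_pct: float
    cpg_per_fragment: float
    cpg_free_fragments: int
    read_coverage: float

    @classmethod
    def from_counts(
        cls,
        enzymes: Iterable[str],
        cpgs_covered: int,
        fragments_generated: int,
        total_cpgs: int,
        throughput_reads: int = DEFAULT_THROUGHPUT_READS,
        cpg_free_fragments: int = 0,
    ) -> "CoverageReport":
        """Derive the ratio columns from raw counts and constants."""
        if fragments_generated > 0:
            ratio = cpgs_covered / fragments_generated
            fold = throughput_reads / fragments_generated
        else:
            ratio = math.nan
            fold = math.nan
        pct = 100.0 * cpgs_covered / total_cpgs if total_cpgs else math.nan
        return cls(
            enzymes=tuple(enzymes),
            cpgs_covered=int(cpgs_covered),
            fragments_generated=int(fragments_generated),
            coverage_pct=pct,
            cpg_per_fragment=ratio,
            cpg_free_fragments=int(cpg_free_fragments),
            read_coverage=fold,
        )

    @property
    def label(self) -> str:
        return " ".join(self.enzymes)

    def formatted(self) -> dict[str, object]:
        """Rounded, table-ready values (percent/fold to 1 dp, ratio to 2 dp)."""
        def fmt(x: float, nd: int):
            return None if math.isnan(x) else _round_half_up(x, nd)

        return {
            "enzymes": self.label,
            "cpgs_covered": self.cpgs_covered,
            "fragments_generated": self.fragments_generated,
            "coverage_pct": fmt(self.coverage_pct, 1),
            "cpg_per_fragment": fmt(self.cpg_per_fragment, 2),
            "cpg_free_fragments": self.cpg_free_fragments,
            "read_coverage": fmt(self.read_coverage, 1),
        }


def covered_intervals(
    fragment: Fragment, depth_nt: int = DEFAULT_DEPTH_NT
) -> list[tuple[int, int]]:
    """Observable windows of a fragment: depth_nt from the 5' and 3' ends.

    Returns one merged interval when the windows touch or overlap
    (length <= 2 x depth), otherwise two disjoint half-open intervals.
    """
    if depth_nt <= 0:
        raise ValueError("depth_nt must be positive")
    start, end = fragment.start, fragment.end
    if end - start <= 2 * depth_nt:
        return [(start, end)]
    return [(start, start + depth_nt), (end - depth_nt, end)]


def covered_cpgs(
    fragments: Iterable[Fragment],
    cpg_index: CpGIndex,
    depth_nt: int = DEFAULT_DEPTH_NT,
    strict: bool = False,
) -> tuple[CoveredSet, int]:
    """Covered CpG positions (union across fragments) and CpG-free count.

    A CpG at p is covered when p falls in a window; in strict mode p+1 must
    fall inside the same window as well.  A fragment whose windows contain no
    CpG is CpG-free.
    """
    per_seq: dict[str, list[np.ndarray]] = {}
    cpg_free = 0
    for frag in fragments:
        pos = cpg_index.get(frag.seq_id)
        hit_any = False
        for a, b in covered_intervals(frag, depth_nt):
            hi = b - 1 if strict else b
            lo_i, hi_i = np.searchsorted(pos, [a, hi])
            if hi_i > lo_i:
                per_seq.setdefault(frag.seq_id, []).append(pos[lo_i:hi_i])
                hit_any = True
        if not hit_any:
            cpg_free += 1
    covered = CoveredSet(
        {sid: np.unique(np.concatenate(chunks)) for sid, chunks in per_seq.items()}
    )
    return covered, cpg_free


def coverage_report(
    records: Iterable[SequenceRecord],
    enzymes: Iterable[RestrictionEnzyme],
    params: CoverageParams = CoverageParams(),
    cpg_index: CpGIndex | None = None,
    return_covered: bool = False,
):
    """Digest, size-select and measure coverage for one enzyme combination.

    Returns a :class:`CoverageReport`, or ``(report, CoveredSet)`` when
    ``return_covered`` is set (the screen needs the sets for baseline
    comparison).
    """
    records = list(records)
    enzymes = list(enzymes)
    if cpg_index is None:
        cpg_index = build_cpg_index(records)
    fragments: list[Fragment] = []
    for rec in records:
        cuts = cut_positions(rec, enzymes)
        fragments.extend(fragments_from_cuts(rec, cuts, params.include_terminal))
    fragments = size_select(fragments, params.min_len, params.max_len)
    covered, cpg_free = covered_cpgs(
        fragments, cpg_index, params.depth_nt, params.strict_cpg
    )
    denom = (
        cpg_index.total_cpgs
        if params.total_cpgs_denominator == "computed"
        else int(params.total_cpgs_denominator)
    )
    report = CoverageReport.from_counts(
        enzymes=[e.name for e in enzymes],
        cpgs_covered=covered.size,
        fragments_generated=len(fragments),
        total_cpgs=denom,
        throughput_reads=params.throughput_reads,
        cpg_free_fragments=cpg_free,
    )
    return (report, covered) if return_covered else report


def fragment_size_profile(
    fragments: Iterable[Fragment],
    bin_width: int = 10,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of fragment lengths over [min_len, max_len].

    Returns ``(bin_edges, counts)`` with ``len(edges) == len(counts) + 1``;
    the last bin is closed so a length equal to ``max_len`` is counted and
    the counts sum to the number of in-range fragments.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = np.array([f.length for f in fragments], dtype=np.int64)
    nbins = max(1, math.ceil((max_len - min_len + 1) / bin_width))
    edges = min_len + bin_width * np.arange(nbins + 1)
    if len(lengths):
        lengths = lengths[(lengths >= min_len) & (lengths <= max_len)]
    counts, _ = np.histogram(lengths, bins=np.append(edges[:-1], max_len + 1))
    return edges, counts
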