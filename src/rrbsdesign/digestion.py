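"""In silico restriction digestion: site finding, cuts, fragments, size selection.

Digestion is modeled as complete (no partials).  Every catalog site is
palindromic, so the plus strand is scanned; overlapping occurrences are all
reported.  Cut coordinates from different enzymes that coincide collapse to a
single fragment boundary.

Terminal chromosome pieces (before the first cut / after the last) are
excluded by default: an RRBS library fragment needs two enzyme-cut ends for
adapter ligation.  ``include_terminal=True`` restores them, in which case
fragments partition the sequence.
"""

from __future__ import annotations

import re
from typing import Iterable, NamedTuple

import numpy as np

from .catalog import IUPAC_CODES, RestrictionEnzyme
from .genome_io import SequenceRecord

__all__ = [
    "Fragment",
    "find_sites",
    "cut_positions",
    "fragments_from_cuts",
    "size_select",
    "digest",
    "DEFAULT_MIN_LEN",
    "DEFAULT_MAX_LEN",
]

#: Fragment size-selection window (bp, inclusive) used for screening.
DEFAULT_MIN_LEN = 40
DEFAULT_MAX_LEN = 400


class Fragment(NamedTuple):
    """Half-open genomic interval [start, end) produced by digestion."""

    seq_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _site_regex(site: str) -> re.Pattern:
    # Lookahead so overlapping occurrences are all reported; explicit
    # character classes so N in the genome never matches.
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]" for c in site
    )
    return re.compile(f"(?=({body}))")


_REGEX_CACHE: dict[str, re.Pattern] = {}


def find_sites(record: SequenceRecord, enzyme: RestrictionEnzyme) -> np.ndarray:
    """Start positions of every occurrence of the enzyme's recognition site."""
    pat = _REGEX_CACHE.get(enzyme.site)
    if pat is None:
        pat = _REGEX_CACHE[enzyme.site] = _site_regex(enzyme.site)
    return np.fromiter(
        (m.start() for m in pat.finditer(record.sequence)), dtype=np.int64
    )


def cut_positions(
    record: SequenceRecord, enzymes: Iterable[RestrictionEnzyme]
) -> np.ndarray:
    """Sorted, deduplicated top-strand cut coordinates for an enzyme set."""
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("enzyme set must be non-empty")
    cuts = [find_sites(record, enz) + enz.cut_offset for enz in enzymes]
    return np.unique(np.concatenate(cuts)) if cuts else np.empty(0, dtype=np.int64)


def fragments_from_cuts(
    record: SequenceRecord,
    cuts: np.ndarray,
    include_terminal: bool = False,
) -> list[Fragment]:
    """Fragments between consecutive cuts.

    With ``include_terminal`` the leading [0, first_cut) and trailing
    [last_cut, length) pieces are added, so the fragments partition
    [0, length) whenever at least one cut exists.
    """
    cuts = np.asarray(cuts, dtype=np.int64)
    if include_terminal:
        bounds = np.unique(np.concatenate([[0], cuts, [record.length]]))
    else:
        bounds = cuts
    return [
        Fragment(record.id, int(s), int(e))
        for s, e in zip(bounds[:-1], bounds[1:])
        if e > s
    ]


def size_select(
    fragments: Iterable[Fragment],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[Fragment]:
    """Keep fragments with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [f for f in fragments if min_len <= f.length <= max_len]


def digest(
    records: Iterable[SequenceRecord],
    enzymes: Iterable[RestrictionEnzyme],
    min_len: int | None = DEFAULT_MIN_LEN,
    max_len: int | None = DEFAULT_MAX_LEN,
    include_terminal: bool = False,
) -> list[Fragment]:
    """Digest records with an enzyme combination and size-select.

    Pass ``min_len=None`` (or ``max_len=None``) to skip size selection.
    """
    enzymes = list(enzymes)
    fragments: list[Fragment] = []
    for rec in records:
        cuts = cut_positions(rec, enzymes)
        fragments.extend(fragments_from_cuts(rec, cuts, include_terminal))
    if min_len is not None and max_len is not None:
        fragments = size_select(fragments, min_len, max_len)
    return fragments
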