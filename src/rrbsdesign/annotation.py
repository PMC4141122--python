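"""Genomic-context classification of CpG positions.

Categories follow the standard CpG-island neighborhood nomenclature: shores
are the 2 kb flanking a CGI, shelves the next 2-4 kb band, promoters the 2 kb
strictly upstream of a TSS (strand-aware), and open sea is the residual —
CpGs in none of genes, promoters, CGIs, shores or shelves.

A position can fall in several annotations at once (a promoter inside a
shore, a gene under a CGI); classification resolves this with a fixed
precedence CGI > shore > shelf > promoter > gene > open sea, so every
position receives exactly one category and category counts over any CpG set
sum to the set's size.  When exon intervals are supplied the gene category
splits into exon and intron (exon taking precedence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .coverage import CoveredSet
from .genome_io import IntervalSet

__all__ = [
    "RegionMap",
    "derive_regions",
    "classify_cpg",
    "distribution",
    "SHORE_BP",
    "SHELF_BP",
    "PROMOTER_BP",
]

SHORE_BP = 2_000
SHELF_BP = 4_000  # outer edge of the shelf band, measured from the CGI
PROMOTER_BP = 2_000


def _merge(intervals: list[tuple[int, int]]) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) pairs into a sorted (n, 2) array."""
    if not intervals:
        return np.empty((0, 2), dtype=np.int64)
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def _subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b for merged interval arrays."""
    if len(a) == 0 or len(b) == 0:
        return a.copy()
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def _expand(a: np.ndarray, pad: int, length: int) -> list[tuple[int, int]]:
    return [
        (max(0, int(s) - pad), min(length, int(e) + pad)) for s, e in a
    ]


@dataclass
class RegionMap:
    """Merged category intervals per sequence, in classification precedence.

    ``categories[seq_id]`` maps category name -> merged (n, 2) interval
    array.  ``precedence`` lists category names highest-priority first;
    ``"open_sea"`` is implicit.
    """

    categories: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    precedence: tuple[str, ...] = ()
    seq_lengths: dict[str, int] = field(default_factory=dict)

    def intervals(self, seq_id: str, category: str) -> np.ndarray:
        return self.categories.get(seq_id, {}).get(
            category, np.empty((0, 2), dtype=np.int64)
        )


def derive_regions(
    cgi: IntervalSet | None,
    genes: IntervalSet | None,
    seq_lengths: dict[str, int],
    exons: IntervalSet | None = None,
    shore_bp: int = SHORE_BP,
    shelf_bp: int = SHELF_BP,
    promoter_bp: int = PROMOTER_BP,
) -> RegionMap:
    """Build the category partition from CGI and gene annotations.

    shore = CGIs expanded by ``shore_bp`` minus the CGIs themselves;
    shelf = the ``shore_bp``..``shelf_bp`` band (expansion difference), which
    excludes CGIs and shores by construction; promoter = ``promoter_bp``
    strictly upstream of each TSS (gene start on '+', gene end on '-'),
    clipped to the sequence.  With no CGI input the shore/shelf bands are
    empty.  Promoters require stranded gene intervals.
    """
    gene_split = exons is not None and len(exons) > 0
    precedence = (
        ("cgi", "shore", "shelf", "promoter", "exon", "intron")
        if gene_split
        else ("cgi", "shore", "shelf", "promoter", "gene")
    )
    rmap = RegionMap(precedence=precedence, seq_lengths=dict(seq_lengths))
    for seq_id, length in seq_lengths.items():
        cats: dict[str, np.ndarray] = {}
        cgi_ivs = _merge(
            [(iv.start, iv.end) for iv in (cgi.by_seq.get(seq_id, []) if cgi else [])]
        )
        cats["cgi"] = cgi_ivs
        near = _merge(_expand(cgi_ivs, shore_bp, length))
        far = _merge(_expand(cgi_ivs, shelf_bp, length))
        cats["shore"] = _subtract(near, cgi_ivs)
        cats["shelf"] = _subtract(far, near)

        gene_list = genes.by_seq.get(seq_id, []) if genes else []
        promoters: list[tuple[int, int]] = []
        for iv in gene_list:
            if iv.strand is None:
                raise ValueError(
                    f"gene interval {seq_id}:{iv.start}-{iv.end} lacks a strand; "
                    "promoters require stranded genes"
                )
            if iv.strand == "+":
                s, e = iv.start - promoter_bp, iv.start
            else:
                s, e = iv.end, iv.end + promoter_bp
            s, e = max(0, s), min(length, e)
            if e > s:
                promoters.append((s, e))
        cats["promoter"] = _merge(promoters)

        gene_ivs = _merge([(iv.start, iv.end) for iv in gene_list])
        if gene_split:
            exon_ivs = _merge(
                [(iv.start, iv.end) for iv in exons.by_seq.get(seq_id, [])]
            )
            cats["exon"] = exon_ivs
            cats["intron"] = _subtract(gene_ivs, exon_ivs)
        else:
            cats["gene"] = gene_ivs
        rmap.categories[seq_id] = cats
    return rmap


def _position_in(ivs: np.ndarray, pos: int) -> bool:
    if len(ivs) == 0:
        return False
    i = int(np.searchsorted(ivs[:, 0], pos, side="right")) - 1
    return i >= 0 and pos < ivs[i, 1]


def classify_cpg(seq_id: str, position: int, region_map: RegionMap) -> str:
    """Category of a single position: first match in precedence order."""
    for cat in region_map.precedence:
        if _position_in(region_map.intervals(seq_id, cat), position):
            return cat
    return "open_sea"


def distribution(
    covered: CoveredSet | dict[str, Iterable[int]],
    region_map: RegionMap,
) -> dict[str, int]:
    """Per-category counts of a covered-CpG set (they sum to the set size)."""
    by_seq = covered.by_seq if isinstance(covered, CoveredSet) else covered
    counts = {cat: 0 for cat in region_map.precedence}
    counts["open_sea"] = 0
    for seq_id, positions in by_seq.items():
        pos = np.asarray(list(positions) if not isinstance(positions, np.ndarray) else positions)
        if len(pos) == 0:
            continue
        assigned = np.zeros(len(pos), dtype=bool)
        for cat in region_map.precedence:
            ivs = region_map.intervals(seq_id, cat)
            if len(ivs) == 0:
                continue
            idx = np.searchsorted(ivs[:, 0], pos, side="right") - 1
            inside = (idx >= 0) & (pos < ivs[np.clip(idx, 0, None), 1])
            hit = inside & ~assigned
            counts[cat] += int(hit.sum())
            assigned |= hit
        counts["open_sea"] += int((~assigned).sum())
    return counts
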