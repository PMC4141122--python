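"""Near-neighbor analysis: k-mers most frequently found flanking genomic CpGs.

For every CpG dyad [p, p+2) a window of ``window_nt`` bases on each side is
examined and each distinct k-mer lying fully inside the padded window
contributes one count for that CpG (per-CpG presence, not an occurrence
tally: the question is how many CpGs an enzyme cutting at that k-mer could
reach, and multiple occurrences near one CpG would double-count it).
Restricting the resulting table to catalog recognition sites ranks the
enzymes by the number of CpGs they can reach at a given sequencing depth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .catalog import EnzymeCatalog, default_catalog
from .genome_io import SequenceRecord

__all__ = ["NeighborTable", "near_neighbor_counts", "rank_enzyme_sites"]

_ACGT = frozenset("ACGT")


@dataclass
class NeighborTable:
    """k-mer -> number of CpGs with that k-mer within the flanking window."""

    counts: Counter = field(default_factory=Counter)
    window_nt: int = 50
    k: int = 4
    total_cpgs_scanned: int = 0

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def fraction(self, kmer: str) -> float:
        if self.total_cpgs_scanned == 0:
            return 0.0
        return self.counts.get(kmer, 0) / self.total_cpgs_scanned


def near_neighbor_counts(
    records: Iterable[SequenceRecord],
    window_nt: int = 50,
    k: int = 4,
) -> NeighborTable:
    """Count, per k-mer, the CpGs having it within ``window_nt`` of the dyad.

    A k-mer must lie fully within [p - window_nt, p + 2 + window_nt) to count
    for the CpG at p; k-mers containing N are skipped.  Each k-mer counts at
    most once per CpG.
    """
    if window_nt < k:
        raise ValueError("window_nt must be >= k")
    table = NeighborTable(window_nt=window_nt, k=k)
    for rec in records:
        seq = rec.sequence
        n = len(seq)
        p = seq.find("CG")
        while p != -1:
            table.total_cpgs_scanned += 1
            lo = max(0, p - window_nt)
            hi = min(n, p + 2 + window_nt)
            seen = {
                kmer
                for i in range(lo, hi - k + 1)
                if _ACGT.issuperset(kmer := seq[i : i + k])
            }
            table.counts.update(seen)
            p = seq.find("CG", p + 1)
    return table


def rank_enzyme_sites(
    table: NeighborTable, catalog: EnzymeCatalog | None = None
) -> list[tuple[str, str, int]]:
    """Restrict a neighbor table to catalog recognition sites and rank them.

    Only enzymes whose site length equals the table's k are reported.  A
    degenerate site scores the maximum over its concrete expansions (the
    enzyme reaches at least that many CpGs).  Rows are ``(enzyme, site,
    cpg_count)`` sorted by count descending, ties broken by enzyme name.
    """
    if catalog is None:
        catalog = default_catalog()
    rows = []
    for enz in catalog:
        if len(enz.site) != table.k:
            continue
        count = max(table[exp] for exp in sorted(enz.expansions))
        rows.append((enz.name, enz.site, count))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return rows
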