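"""Independent brute-force reference implementations used only by tests.

Each function is a direct transcription of the operation's definition —
per-position scans and double loops — deliberately sharing no code with the
package, so agreement is evidence and not tautology.
"""

from __future__ import annotations

from collections import Counter

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_find_sites(sequence: str, site: str) -> list[int]:
    """Every start where each base is in the IUPAC class (N never matches)."""
    hits = []
    k = len(site)
    for i in range(len(sequence) - k + 1):
        if all(sequence[i + j] in _IUPAC[site[j]] for j in range(k)):
            hits.append(i)
    return hits


def naive_cpg_index(sequence: str) -> list[int]:
    return [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]


def naive_covered_cpgs(
    fragments: list[tuple[int, int]], cpg_positions: list[int], depth: int
) -> tuple[set[int], int]:
    """Per-base window membership; returns (covered set, CpG-free count)."""
    covered: set[int] = set()
    cpg_free = 0
    cpgs = set(cpg_positions)
    for start, end in fragments:
        window = set()
        for b in range(start, min(start + depth, end)):
            window.add(b)
        for b in range(max(start, end - depth), end):
            window.add(b)
        frag_hits = {p for p in window if p in cpgs}
        if frag_hits:
            covered |= frag_hits
        else:
            cpg_free += 1
    return covered, cpg_free


def naive_neighbor_counts(sequence: str, window: int, k: int) -> Counter:
    """Double loop: every CpG x every fully-contained k-mer start."""
    counts: Counter = Counter()
    for p in range(len(sequence) - 1):
        if sequence[p : p + 2] != "CG":
            continue
        lo = max(0, p - window)
        hi = min(len(sequence), p + 2 + window)
        seen = set()
        for i in range(lo, hi - k + 1):
            kmer = sequence[i : i + k]
            if set(kmer) <= set("ACGT"):
                seen.add(kmer)
        counts.update(seen)
    return counts
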