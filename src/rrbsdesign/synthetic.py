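"""Deterministic synthetic genomes, annotations and the seven-site insert.

Real mammalian assemblies are multi-gigabase; the generator builds small
genomes with the features the digestion pipeline cares about — controllable
GC background, CpG-dense island regions, restriction sites planted at known
coordinates (an exact truth table), and matching CGI/gene annotations — so
every other module is testable end to end without downloads.

Background bases are drawn i.i.d. at the requested GC fraction.  Island
regions use an insertion model: at each step a CG dyad is written with
probability d/(1-d) (else one background base), giving an expected CpG
density of d per base.  Planted sites are written last and any accidental
occurrence of a planted enzyme's site elsewhere is mutated away, so the truth
table is exact.  The same seed always yields the same genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from .catalog import EnzymeCatalog, RRBS_COMPATIBLE_NAMES, default_catalog
from .genome_io import SequenceRecord

__all__ = [
    "SynthSpec",
    "InsertDesign",
    "synth_genome",
    "synth_insert",
    "synth_annotations",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic sequence.

    islands: (start, length, cpg_density) regions; planted_sites:
    (enzyme name, position) pairs whose recognition sites are written
    verbatim; genes: (start, end, strand) used only by annotations.
    """

    length: int
    gc_fraction: float = 0.41  # mammalian-like background
    islands: tuple[tuple[int, int, float], ...] = ()
    planted_sites: tuple[tuple[str, int], ...] = ()
    genes: tuple[tuple[int, int, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        for start, ln, dens in self.islands:
            if not (0 <= start and start + ln <= self.length and ln > 0):
                raise ValueError("island outside sequence")
            if not 0.0 <= dens < 1.0:
                raise ValueError("cpg_density must be in [0, 1)")


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _BASES[rng.choice(4, size=n, p=probs)]


def _island(rng: np.random.Generator, n: int, density: float, gc: float) -> np.ndarray:
    # Insertion model: expected CpGs per base = rho/(1+rho) with
    # rho = density/(1-density), i.e. exactly `density`.
    rho = density / (1.0 - density) if density > 0 else 0.0
    out = np.empty(n, dtype=np.uint8)
    i = 0
    while i < n:
        if rho > 0 and i + 1 < n and rng.random() < rho:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            base = _background(rng, 1, gc)[0]
            # suppress accidental background CG dyads so the island's CpG
            # density is exactly the insertion model's
            while i > 0 and out[i - 1] == ord("C") and base == ord("G"):
                base = _background(rng, 1, gc)[0]
            out[i] = base
            i += 1
    return out


def _planted_spans(
    spec: SynthSpec, catalog: EnzymeCatalog, rng: np.random.Generator
) -> list[tuple[str, int, str]]:
    """Resolve planted sites to (enzyme, position, concrete sequence)."""
    spans = []
    for name, pos in spec.planted_sites:
        enz = catalog.get(name)
        expansions = sorted(enz.expansions)
        concrete = expansions[int(rng.integers(len(expansions)))]
        if not 0 <= pos <= spec.length - len(concrete):
            raise ValueError(f"planted site {name} at {pos} outside sequence")
        spans.append((enz.name, pos, concrete))
    spans.sort(key=lambda t: t[1])
    for (_, p1, s1), (_, p2, _) in zip(spans, spans[1:]):
        if p1 + len(s1) > p2:
            raise ValueError("planted sites overlap after expansion")
    return spans


def _find_all(seq: bytes, patterns: Iterable[bytes]) -> list[int]:
    hits = []
    for pat in patterns:
        start = seq.find(pat)
        while start != -1:
            hits.append(start)
            start = seq.find(pat, start + 1)
    return sorted(set(hits))


def synth_genome(
    spec: SynthSpec, catalog: EnzymeCatalog | None = None
) -> tuple[SequenceRecord, dict[str, np.ndarray]]:
    """Generate the sequence plus an exact truth table of planted cuts.

    Returns ``(record, truth)`` where ``truth[enzyme] `` is the sorted array
    of cut coordinates implied by that enzyme's planted sites.  After
    planting, accidental occurrences of any planted enzyme's site are
    destroyed by point mutation, so digesting with the planted enzymes
    recovers exactly the truth cuts.
    """
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(spec.seed)
    arr = _background(rng, spec.length, spec.gc_fraction)
    for start, ln, dens in spec.islands:
        arr[start : start + ln] = _island(rng, ln, dens, spec.gc_fraction)
    spans = _planted_spans(spec, catalog, rng)
    for _, pos, concrete in spans:
        arr[pos : pos + len(concrete)] = np.frombuffer(
            concrete.encode("ascii"), dtype=np.uint8
        )

    protected = np.zeros(spec.length, dtype=bool)
    for _, pos, concrete in spans:
        protected[pos : pos + len(concrete)] = True

    planted_enzymes = {name for name, _, _ in spans}
    allowed_starts = {
        name: {pos for n2, pos, _ in spans if n2 == name} for name in planted_enzymes
    }
    for _ in range(200):
        dirty = False
        seq_bytes = arr.tobytes()
        for name in sorted(planted_enzymes):
            enz = catalog.get(name)
            pats = [e.encode("ascii") for e in sorted(enz.expansions)]
            for hit in _find_all(seq_bytes, pats):
                if hit in allowed_starts[name]:
                    continue
                free = [
                    i for i in range(hit, hit + len(enz.site)) if not protected[i]
                ]
                if not free:
                    raise ValueError(
                        f"planted sites induce an unremovable {name} site at {hit}"
                    )
                i = free[int(rng.integers(len(free)))]
                choices = [b for b in b"ACGT" if b != arr[i]]
                arr[i] = choices[int(rng.integers(len(choices)))]
                dirty = True
        if not dirty:
            break
    else:
        raise RuntimeError("site scrubbing did not converge")

    record = SequenceRecord(
        id=f"synth_seed{spec.seed}", sequence=arr.tobytes().decode("ascii")
    )
    truth: dict[str, np.ndarray] = {}
    for name in sorted(planted_enzymes):
        enz = catalog.get(name)
        cuts = sorted(pos + enz.cut_offset for n2, pos, _ in spans if n2 == name)
        truth[name] = np.array(cuts, dtype=np.int64)
    return record, truth


class InsertDesign(NamedTuple):
    """The synthetic insert and the start position of each planted site."""

    record: SequenceRecord
    site_positions: dict[str, int]


def synth_insert(
    enzyme_names: Iterable[str] = RRBS_COMPATIBLE_NAMES,
    spacing_nt: int = 50,
    catalog: EnzymeCatalog | None = None,
) -> InsertDesign:
    """A linear insert bearing one site per enzyme, ~``spacing_nt`` apart.

    Sites appear in catalog order separated by AC-repeat spacers; generation
    verifies that each requested enzyme matches exactly once and that no
    other catalog enzyme matches at all, so single-enzyme digestion yields
    exactly one cut.
    """
    if catalog is None:
        catalog = default_catalog()
    enzymes = catalog.resolve(enzyme_names)
    longest = max(len(e.site) for e in enzymes)
    if spacing_nt < longest:
        raise ValueError("spacing_nt must be at least the longest site")
    spacer = ("AC" * spacing_nt)[:spacing_nt]
    parts = [spacer]
    positions: dict[str, int] = {}
    offset = len(spacer)
    for enz in enzymes:
        concrete = sorted(enz.expansions)[0]
        positions[enz.name] = offset
        parts.append(concrete)
        offset += len(concrete)
        parts.append(spacer)
        offset += len(spacer)
    record = SequenceRecord(id="synthetic_insert", sequence="".join(parts))

    seq_bytes = record.sequence.encode("ascii")
    planted = set(positions)
    for enz in catalog:
        hits = _find_all(seq_bytes, [e.encode("ascii") for e in sorted(enz.expansions)])
        if enz.name in planted:
            if hits != [positions[enz.name]]:
                raise RuntimeError(f"insert construction: {enz.name} hits {hits}")
        elif hits:
            raise RuntimeError(
                f"insert construction: unplanted {enz.name} site at {hits}"
            )
    return InsertDesign(record, positions)


def synth_annotations(
    spec: SynthSpec, cgi_path: str | Path, genes_path: str | Path, seq_id: str | None = None
) -> None:
    """Write CGI and gene BED files matching the spec's placements.

    CGI intervals equal the island regions; gene intervals carry strands
    (BED6 with placeholder name/score).  Files round-trip exactly through
    ``read_intervals``.
    """
    if seq_id is None:
        seq_id = f"synth_seed{spec.seed}"
    with Path(cgi_path).open("w") as fh:
        for start, ln, _ in spec.islands:
            fh.write(f"{seq_id}\t{start}\t{start + ln}\n")
    with Path(genes_path).open("w") as fh:
        for i, (start, end, strand) in enumerate(spec.genes):
            fh.write(f"{seq_id}\t{start}\t{end}\tgene{i}\t0\t{strand}\n")


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 70
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
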