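"""Restriction enzyme catalog for RRBS library design.

The built-in catalog lists eleven 4- and 5-nt cutters whose recognition sites
are enriched near genomic CpGs and whose cutting is (with two flagged
exceptions) unaffected by CpG methylation.  Seven of them — AluI, BfaI,
HaeIII, HpyCH4V, MluCI, MseI and MspI — share a single reaction condition
(37 °C, CutSmart buffer) and form the default screening set.

Recognition sites are stored as IUPAC strings with a top-strand cut offset:
``C|CGG`` is ``site="CCGG", cut_offset=1``.  All catalog sites are palindromic
(every concrete expansion equals its own reverse complement), so scanning the
plus strand finds every cut.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path

__all__ = [
    "RestrictionEnzyme",
    "EnzymeCatalog",
    "IUPAC_CODES",
    "expand_iupac",
    "reverse_complement",
    "load_catalog",
    "get_enzyme",
    "rrbs_compatible_set",
    "RRBS_COMPATIBLE_NAMES",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: The seven enzymes sharing 37 °C / CutSmart reaction conditions.
RRBS_COMPATIBLE_NAMES: tuple[str, ...] = (
    "AluI", "BfaI", "HaeIII", "HpyCH4V", "MluCI", "MseI", "MspI",
)

#: Alternate spellings accepted by name lookup (case-insensitive).
_ALIASES: dict[str, str] = {
    "taqαi": "TaqI",  # TaqαI
    "taqai": "TaqI",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def expand_iupac(site: str) -> set[str]:
    """Expand an IUPAC pattern into the set of concrete A/C/G/T strings.

    The result size is the product of per-position degeneracies, e.g.
    ``GCWGC -> {GCAGC, GCTGC}``.

    Raises
    ------
    ValueError
        If ``site`` contains a character that is not an IUPAC nucleotide code.
    """
    site = site.upper()
    for i, ch in enumerate(site):
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC code {ch!r} at position {i} in site {site!r}"
            )
    return {"".join(combo) for combo in product(*(IUPAC_CODES[c] for c in site))}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """One catalog row: recognition site, cut geometry and reaction metadata.

    ``cut_offset`` is the number of bases preceding the top-strand cut within
    the site; the bottom-strand cut (overhang geometry) is not modeled because
    fragment coordinates depend on a single cut coordinate per site.
    """

    name: str
    site: str
    cut_offset: int
    incubation_temp_c: int
    buffer: str
    heat_inactivation_temp_c: int | None
    methylation_sensitive: str
    catalog_number: str

    def __post_init__(self) -> None:
        if not 4 <= len(self.site) <= 5:
            raise ValueError(f"{self.name}: site length must be 4 or 5")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"{self.name}: cut_offset outside site")
        expand_iupac(self.site)  # validates characters

    @property
    def consensus(self) -> str:
        """Supplier-style notation with ``|`` at the cut: ``C|CGG``."""
        return self.site[: self.cut_offset] + "|" + self.site[self.cut_offset:]

    @property
    def expansions(self) -> set[str]:
        """Concrete A/C/G/T sequences matching the recognition site."""
        return expand_iupac(self.site)

    def is_palindromic(self) -> bool:
        """True when the expansion set is closed under reverse complement."""
        exp = self.expansions
        return {reverse_complement(s) for s in exp} == exp


class EnzymeCatalog:
    """Ordered, case-insensitive collection of :class:`RestrictionEnzyme`."""

    def __init__(self, enzymes: list[RestrictionEnzyme]):
        self._enzymes = list(enzymes)
        self._by_key: dict[str, RestrictionEnzyme] = {}
        for enz in self._enzymes:
            key = enz.name.lower()
            if key in self._by_key:
                raise ValueError(f"duplicate enzyme name {enz.name!r}")
            self._by_key[key] = enz

    def __iter__(self):
        return iter(self._enzymes)

    def __len__(self) -> int:
        return len(self._enzymes)

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
            return True
        except KeyError:
            return False

    @property
    def names(self) -> list[str]:
        return [e.name for e in self._enzymes]

    def get(self, name: str) -> RestrictionEnzyme:
        """Look up an enzyme by name (case-insensitive, aliases honored)."""
        key = name.lower()
        key = _ALIASES.get(key, key).lower()
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(
                f"unknown enzyme {name!r}; catalog contains: "
                + ", ".join(self.names)
            ) from None

    def resolve(self, names) -> list[RestrictionEnzyme]:
        """Resolve an iterable of names to enzymes, preserving order."""
        return [self.get(n) for n in names]


def _parse_row(row: dict[str, str]) -> RestrictionEnzyme:
    heat = row.get("heat_inactivation_temp_c", "").strip()
    return RestrictionEnzyme(
        name=row["name"].strip(),
        site=row["site"].strip().upper(),
        cut_offset=int(row["cut_offset"]),
        incubation_temp_c=int(row["incubation_temp_c"]),
        buffer=row["buffer"].strip(),
        heat_inactivation_temp_c=int(heat) if heat else None,
        methylation_sensitive=row["methylation_sensitive"].strip(),
        catalog_number=row.get("catalog_number", "").strip(),
    )


def load_catalog(path: str | Path | None = None) -> EnzymeCatalog:
    """Load the built-in catalog TSV, or a user-supplied one in the same schema.

    The TSV columns are: name, site, cut_offset, incubation_temp_c, buffer,
    heat_inactivation_temp_c (may be empty), methylation_sensitive,
    catalog_number.  ``#`` lines are comments.
    """
    if path is None:
        text = (
            resources.files("rrbsdesign") / "data" / "enzymes.tsv"
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return EnzymeCatalog([_parse_row(row) for row in reader])


_DEFAULT_CATALOG: EnzymeCatalog | None = None


def default_catalog() -> EnzymeCatalog:
    """The built-in eleven-enzyme catalog (loaded once, cached)."""
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = load_catalog()
    return _DEFAULT_CATALOG


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Fetch a single enzyme from the built-in catalog by name."""
    return default_catalog().get(name)


def rrbs_compatible_set() -> list[RestrictionEnzyme]:
    """The seven enzymes sharing 37 °C/CutSmart conditions, sorted by name."""
    cat = default_catalog()
    return sorted(
        (cat.get(n) for n in RRBS_COMPATIBLE_NAMES), key=lambda e: e.name
    )
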