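"""Combinatorial enzyme screen: enumerate, measure, filter, rank, compare.

Every combination of up to ``max_size`` enzymes is digested with identical
parameters; combinations are ranked by genomic CpG coverage (ties by read
coverage, then label), filtered by a minimum predicted read coverage (the
throughput spread over fewer fragments means each is read more often), and
compared against reference digests — conventionally MspI and MspI + ApeKI —
by exact covered-CpG set overlap.  Per-enzyme cut positions are computed once
per sequence and unioned per combination, so the screen scales with genome
size, not with the number of combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations as _combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import RestrictionEnzyme
from .coverage import (
    CoverageParams,
    CoverageReport,
    CoveredSet,
    covered_cpgs,
)
from .digestion import Fragment, find_sites, fragments_from_cuts, size_select
from .genome_io import CpGIndex, SequenceRecord, build_cpg_index

__all__ = [
    "OverlapSummary",
    "ComboResult",
    "enumerate_combinations",
    "screen",
    "apply_read_coverage_cutoff",
    "compare_to_baseline",
    "results_table",
    "DEFAULT_READ_COVERAGE_CUTOFF",
]

logger = logging.getLogger("rrbsdesign")

DEFAULT_READ_COVERAGE_CUTOFF = 10.0


@dataclass(frozen=True)
class OverlapSummary:
    """Exact covered-CpG overlap between a combination and a baseline."""

    shared: int
    new: int
    baseline_only: int


@dataclass
class ComboResult:
    """One screened combination: its report, covered set and baseline overlaps."""

    enzymes: tuple[str, ...]
    report: CoverageReport
    covered: CoveredSet
    baseline_overlaps: dict[str, OverlapSummary] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return " ".join(self.enzymes)


def enumerate_combinations(
    enzymes: Sequence[RestrictionEnzyme], max_size: int = 3
) -> list[tuple[RestrictionEnzyme, ...]]:
    """All subsets of size 1..max_size, ordered by size then names."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    pool = sorted(enzymes, key=lambda e: e.name)
    out: list[tuple[RestrictionEnzyme, ...]] = []
    for size in range(1, min(max_size, len(pool)) + 1):
        out.extend(_combinations(pool, size))
    return out


def compare_to_baseline(
    combo_covered: CoveredSet, baseline_covered: CoveredSet
) -> OverlapSummary:
    """Exact set intersection/differences between two covered-CpG sets."""
    shared = combo_covered.intersection_size(baseline_covered)
    return OverlapSummary(
        shared=shared,
        new=combo_covered.size - shared,
        baseline_only=baseline_covered.size - shared,
    )


def _combo_result(
    records: list[SequenceRecord],
    combo: tuple[RestrictionEnzyme, ...],
    site_cuts: dict[str, dict[str, np.ndarray]],
    cpg_index: CpGIndex,
    params: CoverageParams,
) -> ComboResult:
    fragments: list[Fragment] = []
    for rec in records:
        cuts = np.unique(
            np.concatenate([site_cuts[rec.id][enz.name] for enz in combo])
        )
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
        enzymes=[e.name for e in combo],
        cpgs_covered=covered.size,
        fragments_generated=len(fragments),
        total_cpgs=denom,
        throughput_reads=params.throughput_reads,
        cpg_free_fragments=cpg_free,
    )
    return ComboResult(tuple(e.name for e in combo), report, covered)


def screen(
    records: Iterable[SequenceRecord],
    combinations: Iterable[tuple[RestrictionEnzyme, ...]],
    params: CoverageParams = CoverageParams(),
    baselines: dict[str, tuple[RestrictionEnzyme, ...]] | None = None,
) -> list[ComboResult]:
    """Measure every combination under identical parameters and rank them.

    ``baselines`` maps a label (e.g. ``"MspI ApeKI"``) to an enzyme tuple;
    each result carries an :class:`OverlapSummary` against every baseline.
    Sorting: coverage % descending, then read coverage descending, then
    label; deterministic for identical inputs.
    """
    records = list(records)
    combinations = [tuple(c) for c in combinations]
    baselines = baselines or {}
    cpg_index = build_cpg_index(records)

    all_enzymes: dict[str, RestrictionEnzyme] = {}
    for combo in list(combinations) + list(baselines.values()):
        for enz in combo:
            all_enzymes[enz.name] = enz
    site_cuts: dict[str, dict[str, np.ndarray]] = {}
    for rec in records:
        site_cuts[rec.id] = {
            name: find_sites(rec, enz) + enz.cut_offset
            for name, enz in all_enzymes.items()
        }

    baseline_sets = {
        label: _combo_result(records, combo, site_cuts, cpg_index, params).covered
        for label, combo in baselines.items()
    }

    results = [
        _combo_result(records, combo, site_cuts, cpg_index, params)
        for combo in combinations
    ]
    for res in results:
        for label, bset in baseline_sets.items():
            res.baseline_overlaps[label] = compare_to_baseline(res.covered, bset)

    def sort_key(res: ComboResult):
        pct = res.report.coverage_pct
        fold = res.report.read_coverage
        return (
            -(pct if pct == pct else float("-inf")),  # NaN sorts last
            -(fold if fold == fold else float("-inf")),
            res.label,
        )

    results.sort(key=sort_key)
    return results


def apply_read_coverage_cutoff(
    results: Iterable[ComboResult],
    min_fold: float = DEFAULT_READ_COVERAGE_CUTOFF,
) -> list[ComboResult]:
    """Keep results with predicted read coverage >= min_fold, order preserved."""
    results = list(results)
    kept = [
        r
        for r in results
        if r.report.read_coverage == r.report.read_coverage
        and r.report.read_coverage >= min_fold
    ]
    if results and not kept:
        logger.warning(
            "no combination reaches the %gx read-coverage cutoff", min_fold
        )
    return kept


def results_table(results: Iterable[ComboResult]) -> pd.DataFrame:
    """Tabulate ranked results in the screening column order.

    Columns: enzymes, cpgs_covered, fragments_generated, coverage_pct,
    cpg_per_fragment, cpg_free_fragments, read_coverage, then
    ``shared_with_<baseline>`` / ``new_vs_<baseline>`` per baseline.
    """
    rows = []
    for res in results:
        row = res.report.formatted()
        for label, ov in res.baseline_overlaps.items():
            key = label.replace(" ", "+")
            row[f"shared_with_{key}"] = ov.shared
            row[f"new_vs_{key}"] = ov.new
        rows.append(row)
    return pd.DataFrame(rows)
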