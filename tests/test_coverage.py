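import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import naive_covered_cpgs, naive_cpg_index
from rrbsdesign import (
    CoverageParams,
    CoverageReport,
    SequenceRecord,
    build_cpg_index,
    coverage_report,
    covered_cpgs,
    covered_intervals,
    fragment_size_profile,
    get_enzyme,
)
from rrbsdesign.digestion import Fragment

dna = st.text(alphabet="ACGT", min_size=1, max_size=500)


@pytest.mark.parametrize(
    "frag, depth, expected",
    [
        (Fragment("s", 100, 220), 50, [(100, 150), (170, 220)]),
        (Fragment("s", 100, 180), 50, [(100, 180)]),  # windows merge
        (Fragment("s", 0, 30), 50, [(0, 30)]),  # short fragment fully read
        (Fragment("s", 0, 100), 50, [(0, 100)]),  # touching windows merge
    ],
)
def test_covered_intervals(frag, depth, expected):
    assert covered_intervals(frag, depth) == expected


def test_covered_cpgs_middle_of_long_fragment_is_invisible():
    # CpGs at 10, 60, 100 in a 120 bp fragment at depth 50: only the ones
    # within [0,50) and [70,120) are observable
    seq = ["A"] * 121
    for p in (10, 60, 100):
        seq[p], seq[p + 1] = "C", "G"
    rec = SequenceRecord("s", "".join(seq))
    idx = build_cpg_index([rec])
    covered, cpg_free = covered_cpgs([Fragment("s", 0, 120)], idx, 50)
    assert covered.by_seq["s"].tolist() == [10, 100]
    assert cpg_free == 0


def test_covered_cpgs_counts_each_cpg_once_and_free_fragments():
    rec = SequenceRecord("s", "ATATATATAT" * 10)
    idx = build_cpg_index([rec])
    frags = [Fragment("s", 0, 50), Fragment("s", 50, 100)]
    covered, cpg_free = covered_cpgs(frags, idx, 50)
    assert covered.size == 0
    assert cpg_free == 2


@given(
    dna,
    st.integers(min_value=1, max_value=120),
    st.integers(min_value=0, max_value=7),
)
def test_covered_cpgs_matches_per_base_oracle(seq, depth, seed):
    rec = SequenceRecord("s", seq)
    idx = build_cpg_index([rec])
    rng = np.random.default_rng(seed)
    bounds = sorted(set(rng.integers(0, len(seq) + 1, size=6).tolist()))
    frag_pairs = [(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]
    frags = [Fragment("s", a, b) for a, b in frag_pairs]
    covered, cpg_free = covered_cpgs(frags, idx, depth)
    exp_covered, exp_free = naive_covered_cpgs(
        frag_pairs, naive_cpg_index(seq), depth
    )
    got = set(covered.by_seq.get("s", np.empty(0)).tolist())
    assert got == exp_covered
    assert cpg_free == exp_free


def test_strict_mode_requires_the_g_inside_the_window():
    seq = "A" * 49 + "CG" + "A" * 69  # CpG C at 49, G at 50; fragment 120bp
    rec = SequenceRecord("s", seq)
    idx = build_cpg_index([rec])
    frag = [Fragment("s", 0, 120)]
    lenient, _ = covered_cpgs(frag, idx, 50, strict=False)
    strict, _ = covered_cpgs(frag, idx, 50, strict=True)
    assert lenient.by_seq["s"].tolist() == [49]
    assert strict.size == 0


@pytest.mark.parametrize(
    "cpgs, frags, pct, ratio, fold",
    [
        (6_755_710, 4_521_945, 25.0, 1.49, 33.2),  # single-enzyme GGCC digest
        (8_703_801, 5_613_529, 32.2, 1.55, 26.7),  # two-enzyme digest
    ],
)
def test_report_formatting_reproduces_published_style_rounding(
    cpgs, frags, pct, ratio, fold
):
    rep = CoverageReport.from_counts(
        ["X"], cpgs, frags, total_cpgs=27_000_000, throughput_reads=150_000_000
    )
    fmt = rep.formatted()
    assert fmt["coverage_pct"] == pct
    assert fmt["cpg_per_fragment"] == ratio
    assert fmt["read_coverage"] == fold


def test_zero_fragments_yield_undefined_markers_not_errors():
    rep = CoverageReport.from_counts(["X"], 0, 0, total_cpgs=1000)
    assert math.isnan(rep.read_coverage) and math.isnan(rep.cpg_per_fragment)
    fmt = rep.formatted()
    assert fmt["read_coverage"] is None and fmt["cpg_per_fragment"] is None


def test_coverage_report_end_to_end_small_genome():
    # two MspI sites 100 bp apart -> one internal fragment of length 100
    seq = "A" * 30 + "CCGG" + "A" * 20 + "CG" + "A" * 74 + "CCGG" + "A" * 30
    rec = SequenceRecord("s", seq)
    params = CoverageParams(depth_nt=50, min_len=40, max_len=400)
    rep = coverage_report([rec], [get_enzyme("MspI")], params)
    assert rep.fragments_generated == 1
    # fragment [31, 131) is fully observable (100 <= 2*50); it holds the
    # CpGs at 31 and 54, while the CpG at 131 starts the next fragment
    assert rep.cpgs_covered == 2
    assert rep.cpg_free_fragments == 0


def test_mspi_only_digests_have_no_cpg_free_fragments(random_record_factory):
    # every internal fragment starts CGG..., i.e. with a CpG at its 5' end,
    # so a CG-containing consensus cannot yield CpG-free internal fragments;
    # with terminal pieces kept, only the leading [0, first_cut) fragment
    # (which ends just before its CG) can ever be CpG-free
    mspi = get_enzyme("MspI")
    for seed in range(5):
        rec = random_record_factory(seed, 4000)
        rep = coverage_report([rec], [mspi], CoverageParams())
        if rep.fragments_generated:
            assert rep.cpg_free_fragments == 0
        rep_t = coverage_report(
            [rec], [mspi], CoverageParams(include_terminal=True)
        )
        assert rep_t.cpg_free_fragments <= 1


def test_coverage_monotone_in_enzymes_without_size_selection(
    random_record_factory,
):
    # splitting a fragment only adds observable windows when terminal
    # fragments are kept and no size selection discards pieces
    params = CoverageParams(
        include_terminal=True, min_len=1, max_len=10**9
    )
    for seed in range(5):
        rec = random_record_factory(seed + 100, 3000)
        _, cov1 = coverage_report(
            [rec], [get_enzyme("MspI")], params, return_covered=True
        )
        _, cov2 = coverage_report(
            [rec], [get_enzyme("MspI"), get_enzyme("AluI")], params,
            return_covered=True,
        )
        assert cov2.contains_all(cov1)


def test_fragment_size_profile_bins_and_totals():
    frags = [Fragment("s", 0, ln) for ln in (40, 45, 399, 400)]
    edges, counts = fragment_size_profile(frags, bin_width=10)
    assert counts.sum() == 4
    assert counts[0] == 2  # [40, 50)
    assert counts[(399 - 40) // 10] == 1
    assert counts[-1] == 1  # max_len falls in the closed last bin
    _, empty = fragment_size_profile([], bin_width=10)
    assert empty.sum() == 0


@given(st.lists(st.integers(min_value=40, max_value=400), max_size=50))
def test_fragment_size_profile_conserves_counts(lengths):
    frags = [Fragment("s", 0, ln) for ln in lengths]
    _, counts = fragment_size_profile(frags, bin_width=7)
    assert counts.sum() == len(lengths)
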