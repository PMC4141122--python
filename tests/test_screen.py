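import numpy as np
import pytest

from rrbsdesign import (
    CoverageParams,
    CoveredSet,
    SequenceRecord,
    apply_read_coverage_cutoff,
    compare_to_baseline,
    coverage_report,
    enumerate_combinations,
    get_enzyme,
    results_table,
    rrbs_compatible_set,
    screen,
)


def _covered(*positions):
    return CoveredSet({"s": np.array(sorted(positions), dtype=np.int64)})


def test_enumerate_combinations_counts():
    seven = rrbs_compatible_set()
    combos = enumerate_combinations(seven, max_size=3)
    assert len(combos) == 63  # 7 + 21 + 35
    assert len(enumerate_combinations(seven[:1], max_size=3)) == 1
    assert len(enumerate_combinations(seven, max_size=1)) == 7
    # deterministic order: by size, then names
    assert [len(c) for c in combos] == sorted(len(c) for c in combos)
    with pytest.raises(ValueError):
        enumerate_combinations(seven, max_size=0)


def test_overlap_summary_identities():
    ov = compare_to_baseline(_covered(1, 2, 3), _covered(2, 3, 4))
    assert (ov.shared, ov.new, ov.baseline_only) == (2, 1, 1)
    same = compare_to_baseline(_covered(1, 2), _covered(1, 2))
    assert (same.new, same.baseline_only) == (0, 0)
    disjoint = compare_to_baseline(_covered(1), _covered(2))
    assert disjoint.shared == 0


def test_read_coverage_cutoff_boundary(monkeypatch):
    class R:
        def __init__(self, fold):
            class Rep:
                read_coverage = fold
            self.report = Rep()

    results = [R(33.2), R(10.3), R(10.0), R(9.9)]
    kept = apply_read_coverage_cutoff(results, 10)
    assert [r.report.read_coverage for r in kept] == [33.2, 10.3, 10.0]
    assert apply_read_coverage_cutoff(results, 0) == results


@pytest.fixture
def mspi_only_genome():
    # only CCGG sites: every MspI-containing combination ties at the top
    seq = ("A" * 60 + "CCGG") * 30 + "A" * 60
    return SequenceRecord("g", seq)


def test_screen_ranks_and_overlaps(mspi_only_genome):
    seven = rrbs_compatible_set()
    params = CoverageParams(total_cpgs_denominator="computed")
    combos = enumerate_combinations(seven, max_size=2)
    baselines = {"MspI": (get_enzyme("MspI"),)}
    results = screen([mspi_only_genome], combos, params, baselines=baselines)
    assert len(results) == 28
    pcts = [r.report.coverage_pct for r in results]
    assert pcts == sorted(pcts, reverse=True)
    top = results[0]
    assert "MspI" in top.enzymes
    # vs the MspI baseline, MspI-containing combos share everything
    for res in results:
        ov = res.baseline_overlaps["MspI"]
        assert ov.shared + ov.new == res.report.cpgs_covered
        if "MspI" in res.enzymes:
            assert ov.new == 0 and ov.baseline_only == 0


def test_single_enzyme_screen_agrees_with_direct_report(mspi_only_genome):
    mspi = get_enzyme("MspI")
    params = CoverageParams()
    [res] = screen([mspi_only_genome], [(mspi,)], params)
    direct = coverage_report([mspi_only_genome], [mspi], params)
    assert res.report == direct


def test_screen_of_empty_genome_is_all_zero():
    rec = SequenceRecord("empty", "AT" * 50)
    results = screen([rec], enumerate_combinations(rrbs_compatible_set(), 1))
    assert all(r.report.cpgs_covered == 0 for r in results)
    assert all(r.report.fragments_generated == 0 for r in results)


def test_screen_is_byte_deterministic(mspi_only_genome, random_record_factory):
    rec = random_record_factory(42, 6000)
    seven = rrbs_compatible_set()
    combos = enumerate_combinations(seven, max_size=3)
    baselines = {
        "MspI": (get_enzyme("MspI"),),
        "MspI ApeKI": (get_enzyme("MspI"), get_enzyme("ApeKI")),
    }
    tsvs = [
        results_table(
            screen([rec], combos, CoverageParams(), baselines=baselines)
        ).to_csv(sep="\t", index=False)
        for _ in range(2)
    ]
    assert tsvs[0] == tsvs[1]
    assert len(tsvs[0].splitlines()) == 64  # header + 63 combinations


def test_additivity_for_disjoint_planted_regions():
    # MspI sites only in the left half, AluI sites only in the right half,
    # separated by a spacer longer than any fragment: covered sets do not
    # interact, so the pair's coverage is the sum of the singles
    left = ("T" * 50 + "CCGG") * 10
    right = ("T" * 50 + "AGCT") * 10
    rec = SequenceRecord("s", left + "T" * 1000 + right)
    params = CoverageParams()
    mspi, alui = get_enzyme("MspI"), get_enzyme("AluI")
    [pair] = screen([rec], [(alui, mspi)], params)
    [single_m] = screen([rec], [(mspi,)], params)
    [single_a] = screen([rec], [(alui,)], params)
    assert (
        pair.report.cpgs_covered
        == single_m.report.cpgs_covered + single_a.report.cpgs_covered
    )
    assert (
        pair.report.fragments_generated
        == single_m.report.fragments_generated
        + single_a.report.fragments_generated
    )
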