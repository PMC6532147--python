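import pytest
from hypothesis import given
from hypothesis import strategies as st

from neoepitope.heterogeneity import (
    classify_clonality,
    clonal_fraction,
    summarize_burden,
)
from neoepitope.models import (
    BurdenSummary,
    EpitopeCandidate,
    EpitopePair,
    ProteinChange,
    TranscriptModel,
    VariantRecord,
)


@pytest.mark.parametrize(
    "presence,expected",
    [
        ([True, True, True], "clonal"),
        ([True, True, False], "shared"),
        ([False, True, False], "subclonal"),
        ([True], "clonal"),          # single-region input
        ([True, False], "subclonal"),
        ([True] * 8, "clonal"),
    ],
)
def test_clonality_definitions(presence, expected):
    assert classify_clonality(presence) == expected


def test_all_absent_vector_is_an_error():
    with pytest.raises(ValueError):
        classify_clonality([False, False])


presence_vectors = st.lists(st.booleans(), min_size=1, max_size=8).filter(any)


@given(presence_vectors)
def test_classification_partitions_and_is_permutation_invariant(vec):
    cls = classify_clonality(vec)
    assert cls in ("clonal", "shared", "subclonal")
    assert classify_clonality(list(reversed(vec))) == cls
    assert classify_clonality(sorted(vec)) == cls


@given(presence_vectors)
def test_adding_an_absent_region_demotes_clonal_only(vec):
    before = classify_clonality(vec)
    after = classify_clonality(vec + [False])
    if before == "clonal" and sum(vec) >= 2:
        assert after == "shared"
    elif before == "subclonal" or sum(vec) == 1:
        assert after == "subclonal"
    else:
        assert after == before


# ---------------------------------------------------------------------------
# burden summaries


def _candidate(presence, binder, peptide="ARNDCQEGH", allele="HLA-A01:01",
               pos=100):
    regions = tuple(f"R{i+1}" for i in range(len(presence)))
    v = VariantRecord("chr1", pos, "A", "T", "P1", regions,
                      tuple(presence), pos)
    tx = TranscriptModel("G", "T", "chr1", "+", ((0, 1000),), 0, 999)
    change = ProteinChange(v, tx, "missense")
    pair = EpitopePair(peptide, None, len(peptide), 1, change)
    return EpitopeCandidate(pair, allele, 0.3, 50.0, binder_class=binder)


def test_summary_matrix_counts_and_totals():
    cands = (
        [_candidate([1, 1, 1], "SB", peptide=f"PEP{i}", pos=i)
         for i in range(3)]
        + [_candidate([0, 1, 0], "WB", pos=50)]
        + [_candidate([1, 0, 0], "NB", pos=60)]  # excluded
    )
    s = summarize_burden(cands, "P1")
    assert s.counts == {("SB", "clonal"): 3, ("WB", "subclonal"): 1}
    assert s.total == 4
    assert s.class_total("clonal") == 3 and s.binder_total("SB") == 3
    assert clonal_fraction(s) == 0.75


def test_summary_per_region_totals_and_shared_contributions():
    s = summarize_burden(
        [_candidate([1, 1, 0, 0, 0], "WB")], "P1"
    )
    assert s.counts == {("WB", "shared"): 1}
    assert s.per_region == {"R1": 1, "R2": 1, "R3": 0, "R4": 0, "R5": 0}


def test_summary_empty_candidates():
    s = summarize_burden([], "P1")
    assert s.total == 0
    assert clonal_fraction(s) is None


def test_variant_level_counting_takes_strongest_class():
    cands = [
        _candidate([1, 1], "WB", peptide="AAAAAAAAK", allele="HLA-A01:01"),
        _candidate([1, 1], "SB", peptide="AAAAAAAAR", allele="HLA-A02:01"),
    ]
    s = summarize_burden(cands, "P1", unit="variant")
    assert s.counts == {("SB", "clonal"): 1}
    with pytest.raises(ValueError):
        summarize_burden([], "P1", unit="bogus")


def test_clonal_fraction_arithmetic():
    s = BurdenSummary("P", 5, ("R1",) * 5,
                      {("SB", "clonal"): 72, ("WB", "shared"): 378},
                      {})
    assert clonal_fraction(s) == pytest.approx(0.16)
    s2 = BurdenSummary("P", 2, ("R1", "R2"), {("WB", "clonal"): 4}, {})
    assert clonal_fraction(s2) == 1.0
    s3 = BurdenSummary("P", 2, ("R1", "R2"), {("WB", "shared"): 4}, {})
    assert clonal_fraction(s3) == 0.0
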