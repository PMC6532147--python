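import math
import random
from dataclasses import replace
from itertools import product

import pytest

from neoepitope import recognition as rp
from neoepitope.fixtures import naive_sw, truth_R
from neoepitope.models import BindingScore, EpitopeDatabase

PARAMS = rp.RecognitionParams()


# ---------------------------------------------------------------------------
# novelty


def test_is_novel_substring_semantics():
    assert rp.is_novel("MVK", ["AMVKL"]) is False
    assert rp.is_novel("MWK", ["AMVKL"]) is True
    assert rp.is_novel("MWK", []) is True  # empty proteome: all novel


# ---------------------------------------------------------------------------
# Smith-Waterman


def test_sw_blosum62_self_alignments():
    assert rp.sw_align("AAA", "AAA", PARAMS) == 12.0  # 3 x diagonal A (4)
    assert rp.sw_align("W", "W", PARAMS) == 11.0      # W diagonal entry


def test_sw_matches_naive_dp_on_similar_peptides():
    for a, b in [
        ("SIINFEKL", "SIINYEKL"),
        ("SIINFEKL", "SIINFEKL"),
        ("KLGGALQAK", "KLGGAAK"),      # internal deletion: gap needed
        ("AAAWAAA", "AAAA"),
        ("MNPQRSTV", "VTSRQPNM"),
    ]:
        assert rp.sw_align(a, b, PARAMS) == naive_sw(a, b)


def test_sw_random_pairs_match_naive_dp():
    rng = random.Random(3)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(150):
        a = "".join(rng.choice(aas) for _ in range(rng.randint(1, 11)))
        b = "".join(rng.choice(aas) for _ in range(rng.randint(1, 11)))
        assert rp.sw_align(a, b, PARAMS) == naive_sw(a, b), (a, b)


def test_sw_rejects_unknown_residue():
    with pytest.raises(ValueError, match="X"):
        rp.sw_align("AXA", "AAA", PARAMS)


def test_params_validation():
    with pytest.raises(ValueError):
        rp.RecognitionParams(k=0)
    with pytest.raises(ValueError):
        rp.RecognitionParams(gap_open=1, gap_extend=2)


# ---------------------------------------------------------------------------
# R (similarity to known epitopes)


def test_r_empty_database_is_zero():
    assert rp.compute_R("SIINFEKL", EpitopeDatabase(()), PARAMS) == (0.0, None)


def test_r_is_half_when_best_score_sits_at_midpoint():
    # one epitope whose alignment score equals the displacement a -> w = 1
    pep = "SIINFEKL"
    s_self = rp.sw_align(pep, pep, PARAMS)
    params = replace(PARAMS, a=s_self)
    r, best = rp.compute_R(pep, EpitopeDatabase((("E1", pep),)), params)
    assert r == pytest.approx(0.5, abs=1e-12)
    assert best == "E1"


def test_r_two_epitopes_matches_direct_formula():
    pep = "SIINFEKL"
    db = EpitopeDatabase((("E1", "SIINYEKL"), ("E2", "SIINFEKL")))
    k, a = 1.0, 10.0
    params = replace(PARAMS, k=k, a=a)
    s = [rp.sw_align(pep, e, params) for _, e in db.entries]
    z = sum(math.exp(-k * (a - si)) for si in s)
    r, best = rp.compute_R(pep, db, params)
    assert r == pytest.approx(z / (1 + z), rel=1e-12)
    assert best == "E2"  # exact match scores highest


def test_r_never_decreases_when_database_grows():
    pep = "SIINFEKL"
    entries = [("E1", "MNPQRSTV"), ("E2", "SIINYEKL"), ("E3", "SIINFEKL")]
    prev = 0.0
    for i in range(len(entries) + 1):
        r, _ = rp.compute_R(pep, EpitopeDatabase(tuple(entries[:i])), PARAMS)
        assert r >= prev
        prev = r


def test_r_increasing_in_alignment_scores():
    # raising the midpoint `a` lowers every weight, so R must drop; this is
    # the scalar monotonicity of R in (s_e - a)
    pep = "SIINFEKL"
    db = EpitopeDatabase((("E1", "SIINYEKL"),))
    rs = [
        rp.compute_R(pep, db, replace(PARAMS, k=0.5, a=a))[0]
        for a in (20.0, 26.0, 32.0, 40.0)
    ]
    assert rs == sorted(rs, reverse=True)
    assert len(set(rs)) == len(rs)  # strictly decreasing, no saturation
    assert all(0.0 <= r < 1.0 for r in rs)


def test_r_logsumexp_agrees_with_naive_summation():
    rng = random.Random(5)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    pep = "SIINFEKL"
    entries = tuple(
        (f"E{i}", "".join(rng.choice(aas) for _ in range(9)))
        for i in range(12)
    )
    db = EpitopeDatabase(entries)
    r, _ = rp.compute_R(pep, db, PARAMS)
    scores = [rp.sw_align(pep, e, PARAMS) for _, e in entries]
    z = math.fsum(math.exp(-PARAMS.k * (PARAMS.a - s)) for s in scores)
    assert r == pytest.approx(z / (1 + z), rel=1e-9)
    # and against the independently coded truth-oracle evaluation
    assert r == pytest.approx(
        truth_R(pep, [e for _, e in entries], PARAMS.k, PARAMS.a), rel=1e-9
    )


def test_r_ties_keep_first_epitope_in_file_order():
    db = EpitopeDatabase((("FIRST", "SIINFEKL"), ("SECOND", "SIINFEKL")))
    _, best = rp.compute_R("SIINFEKL", db, PARAMS)
    assert best == "FIRST"


# ---------------------------------------------------------------------------
# A and the product


def _score(aff):
    return BindingScore("SIINFEKL", "HLA-A02:01", 1.0, aff)


@pytest.mark.parametrize(
    "wt,mt,expected", [(500.0, 50.0, 10.0), (50.0, 50.0, 1.0),
                       (50.0, 500.0, 0.1)]
)
def test_amplitude_is_dissociation_ratio(wt, mt, expected):
    assert rp.compute_A(_score(wt), _score(mt)) == pytest.approx(expected)


def test_amplitude_requires_affinities():
    with pytest.raises(ValueError):
        rp.compute_A(_score(None), _score(50.0))


def test_recognition_potential_product_identities():
    assert rp.recognition_potential(10.0, 0.5) == 5.0
    assert rp.recognition_potential(123.0, 0.0) == 0.0
    for r in (0.0, 0.25, 0.99):
        assert rp.recognition_potential(1.0, r) == r
    # self-paired amplitude is exactly 1, so the product equals R
    a = rp.compute_A(_score(77.0), _score(77.0))
    assert rp.recognition_potential(a, 0.37) == 0.37
    with pytest.raises(ValueError):
        rp.recognition_potential(-1.0, 0.5)
    with pytest.raises(ValueError):
        rp.recognition_potential(1.0, 1.5)
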