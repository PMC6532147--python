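import random

import pytest

from neoepitope import coding_change as cc
from neoepitope.errors import EmptyTailError, ReferenceMismatchError
from neoepitope.fixtures import (
    VARIANT_CLASSES,
    expected_class,
    plant_variant,
    synthesize_locus,
)
from neoepitope.models import (
    GenomeSequence,
    ProteinChange,
    TranscriptModel,
    VariantRecord,
    revcomp,
)

from _oracles import rebuild_proteins, classify_oracle


def _tx(exons, strand="+", cds=None, contig="c"):
    cds = cds or (exons[0][0], exons[-1][1])
    return TranscriptModel("G", "T", contig, strand, tuple(exons), *cds)


def _genome(seq, contig="c"):
    return {contig: GenomeSequence(contig, seq)}


def _variant(pos, ref, alt, contig="c"):
    return VariantRecord(contig, pos, ref, alt, "P", ("R1",), (True,), 1)


# ---------------------------------------------------------------------------
# build_cds


def test_build_cds_single_exon_plus():
    assert cc.build_cds(_tx([(0, 12)]), _genome("ATGGCTAAATGA")) == (
        "ATGGCTAAATGA"
    )


def test_build_cds_minus_strand_reverse_complements():
    seq = "ATGGCTAAATGA"
    assert cc.build_cds(_tx([(0, 12)], strand="-"), _genome(seq)) == (
        revcomp(seq)
    )


def test_build_cds_splice_join():
    tx = _tx([(0, 3), (6, 9)], cds=(0, 9))
    assert cc.build_cds(tx, _genome("ATGCCCGCTCCC")) == "ATGGCT"


def test_build_cds_missing_contig_and_out_of_bounds():
    with pytest.raises(cc.AnnotationError):
        cc.build_cds(_tx([(0, 12)], contig="nope"), _genome("ATG" * 4))
    with pytest.raises(cc.AnnotationError):
        cc.build_cds(_tx([(0, 12)]), _genome("ATG"))


# ---------------------------------------------------------------------------
# apply_variant


def test_apply_variant_snv():
    tx = _tx([(0, 12)])
    cds = "ATGGCTAAATGA"
    # c.5 C>T (1-based CDS position 5 == genomic pos 5 here)
    out = cc.apply_variant(cds, tx, _variant(5, "C", "T"))
    assert out == "ATGGTTAAATGA"


def test_apply_variant_one_bp_deletion_shifts_downstream():
    tx = _tx([(0, 12)])
    cds = "ATGGCTAAATGA"
    # delete c.4 G (VCF anchors at previous base)
    out = cc.apply_variant(cds, tx, _variant(3, "GG", "G"))
    assert out == "ATGCTAAATGA"


def test_apply_variant_ref_mismatch_reports_both_strings():
    tx = _tx([(0, 12)])
    with pytest.raises(ReferenceMismatchError) as exc:
        cc.apply_variant("ATGGCTAAATGA", tx, _variant(5, "A", "T"))
    assert exc.value.expected == "A"
    assert exc.value.found == "C"


def test_apply_variant_minus_strand_uses_reverse_complement():
    plus = "ATGGCTAAATGA"
    genome_seq = revcomp(plus)  # transcript reads as `plus` on '-'
    tx = _tx([(0, 12)], strand="-")
    cds = cc.build_cds(tx, _genome(genome_seq))
    assert cds == plus
    # genomic SNV at pos 8 (0-based 7) = complement of CDS position 5 (1-based)
    g_pos = 12 - 4  # CDS offset 4 (0-based) -> genomic 0-based 7
    ref = genome_seq[g_pos - 1]
    alt = "A" if ref != "A" else "T"
    out = cc.apply_variant(cds, tx, _variant(g_pos, ref, alt))
    assert out[4] == revcomp(alt)
    assert out[:4] == cds[:4] and out[5:] == cds[5:]


# ---------------------------------------------------------------------------
# classify_change


@pytest.mark.parametrize(
    "wt,mt,kind,expected",
    [
        ("MAK", "MVK", "snv", ("missense", 2)),
        ("MAK", "MAK", "snv", ("synonymous", None)),
        ("MAK", "MAKLQR", "snv", ("stop_loss", 4)),
        ("MAKL", "MA", "snv", ("stop_gain", 3)),
        ("MAKL", "MAL", "inframe_indel", ("inframe_indel", 3)),
        ("MAKL", "MAKQRS", "frameshift", ("frameshift", 4)),
    ],
)
def test_classify_change(wt, mt, kind, expected):
    assert cc.classify_change(wt, mt, kind) == expected


# ---------------------------------------------------------------------------
# extract_context


def _change(cls, wt, mt, first):
    return ProteinChange(
        _variant(1, "A", "T"), _tx([(0, 12)]), cls,
        wt_protein=wt, mt_protein=mt, first_changed_aa=first,
    )


def test_missense_context_truncated_at_protein_ends():
    ctx, wt_ctx, core = cc.extract_context(
        _change("missense", "MAK", "MVK", 2), max_len=3
    )
    assert (ctx, wt_ctx, core) == ("MVK", "MAK", (1, 2))


def test_missense_context_full_window_is_2l_minus_1():
    wt = "M" + "A" * 99
    mt = wt[:49] + "V" + wt[50:]
    ctx, wt_ctx, core = cc.extract_context(
        _change("missense", wt, mt, 50), max_len=9
    )
    assert len(ctx) == 17
    assert ctx[8] == "V" and core == (8, 9)
    assert wt_ctx == wt[41:58]


def test_frameshift_context_upstream_flank_plus_novel_tail():
    # first changed residue 4, novel tail LQRS, max_len 3 -> 2 upstream + tail
    ctx, wt_ctx, core = cc.extract_context(
        _change("frameshift", "MAKDEF", "MAKLQRS", 4), max_len=3
    )
    assert ctx == "AKLQRS"
    assert wt_ctx is None
    assert core == (2, 6)


def test_frameshift_immediate_stop_rejected():
    with pytest.raises(EmptyTailError):
        cc.extract_context(_change("frameshift", "MAKDEF", "MAK", 4), 3)


def test_inframe_deletion_has_empty_core_at_junction():
    # wt MAKDEF -> mt MADEF (K deleted): junction after 'A'
    ctx, wt_ctx, core = cc.extract_context(
        _change("inframe_indel", "MAKDEF", "MADEF", 3), max_len=3
    )
    assert core[0] == core[1]
    assert ctx[core[0] - 1] + ctx[core[0]] == "AD"


# ---------------------------------------------------------------------------
# Oracle equivalence (small fast version; the full-depth sweep lives in the
# acceptance suite)


@pytest.mark.parametrize("vclass", VARIANT_CLASSES)
def test_annotation_agrees_with_rebuild_oracle(vclass):
    rng = random.Random(hash(vclass) % 2**31)
    for i in range(40):
        locus = synthesize_locus(rng, i, 0)
        pv = plant_variant(locus, vclass, rng)
        variant = VariantRecord(
            "chr1", pv.pos, pv.ref, pv.alt, "P", ("R1",), (True,), 1
        )
        genome = {"chr1": GenomeSequence("chr1", locus.genomic_piece)}
        changes = cc.annotate_variant(variant, [locus.tx], genome, 10)
        assert len(changes) == 1
        got = changes[0]
        wt_o, mt_o = rebuild_proteins(locus.genomic_piece, locus.tx, variant)
        assert got.wt_protein == wt_o
        assert got.mt_protein == mt_o
        assert got.change_class == classify_oracle(
            wt_o, mt_o, variant.ref, variant.alt
        )


def test_missense_context_differs_at_exactly_one_core_position():
    rng = random.Random(7)
    for i in range(30):
        locus = synthesize_locus(rng, i, 0)
        pv = plant_variant(locus, "missense", rng)
        variant = VariantRecord(
            "chr1", pv.pos, pv.ref, pv.alt, "P", ("R1",), (True,), 1
        )
        genome = {"chr1": GenomeSequence("chr1", locus.genomic_piece)}
        (change,) = cc.annotate_variant(variant, [locus.tx], genome, 10)
        diffs = [
            k for k, (a, b) in enumerate(zip(change.wt_context,
                                             change.mt_context))
            if a != b
        ]
        assert len(diffs) == 1
        assert change.core_start <= diffs[0] < change.core_end
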