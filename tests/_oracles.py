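"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths they check: translation
goes through a plain codon dictionary, splicing/CDS extraction is recomputed
from scratch, and the mutant transcript is obtained by rebuilding the whole
mutated contig and shifting every genomic coordinate downstream of the edit.
"""

from __future__ import annotations

from neoepitope.fixtures import _CODON_TABLE
from neoepitope.models import TranscriptModel, VariantRecord, revcomp


def translate_oracle(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def _coding_plus_utr(contig_seq, exons, strand, cds_start, cds_end):
    spliced = "".join(contig_seq[s:e] for s, e in exons)
    if strand == "-":
        spliced = revcomp(spliced)
        offset = sum(max(0, e - max(s, cds_end)) for s, e in exons)
    else:
        offset = sum(max(0, min(e, cds_start) - s) for s, e in exons)
    return spliced[offset:]


def rebuild_proteins(
    contig_seq: str, tx: TranscriptModel, variant: VariantRecord
) -> tuple[str, str]:
    """(wt_protein, mt_protein) by mutating the whole contig, shifting every
    transcript coordinate downstream of the edit, re-splicing, and
    re-translating CDS + 3'UTR read-through."""
    pos0 = variant.pos - 1
    ref_end = pos0 + len(variant.ref)
    assert contig_seq[pos0:ref_end] == variant.ref
    delta = len(variant.alt) - len(variant.ref)
    mutated = contig_seq[:pos0] + variant.alt + contig_seq[ref_end:]

    def shift(coord):
        return coord + delta if coord >= ref_end else coord

    exons_mt = tuple((shift(s), shift(e)) for s, e in tx.exons)
    wt = translate_oracle(
        _coding_plus_utr(contig_seq, tx.exons, tx.strand,
                         tx.cds_start, tx.cds_end)
    )
    mt = translate_oracle(
        _coding_plus_utr(mutated, exons_mt, tx.strand,
                         shift(tx.cds_start), shift(tx.cds_end))
    )
    return wt, mt


def classify_oracle(wt: str, mt: str, ref: str, alt: str):
    """Consequence class from the protein diff, written independently of
    the production classifier."""
    if wt == mt:
        return "synonymous"
    delta = len(alt) - len(ref)
    if delta != 0:
        return "frameshift" if delta % 3 else "inframe_indel"
    if len(mt) < len(wt):
        return "stop_gain"
    if len(mt) > len(wt):
        return "stop_loss"
    ndiff = sum(a != b for a, b in zip(wt, mt))
    return "missense" if ndiff == 1 else "inframe_indel"
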