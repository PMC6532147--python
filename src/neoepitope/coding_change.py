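"""Variant -> protein consequence: splice, mutate, translate, classify.

This is a native re-implementation of the coding-change step usually
delegated to genome annotators: the transcript's coding sequence is built
from the genome, the variant is projected into spliced coordinates
(strand-aware), applied, and both proteins are translated and diffed.

Stop-loss and frameshift variants read through the normal stop, so the
annotation driver translates the CDS *plus* the transcript's 3'UTR for both
alleles — the wild-type stops at its stop codon regardless, while the mutant
acquires its novel tail up to the next downstream in-frame stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .errors import AnnotationError, EmptyTailError, ReferenceMismatchError
from .models import (
    GenomeSequence,
    ProteinChange,
    TranscriptModel,
    VariantRecord,
    revcomp,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Spliced-coordinate arithmetic (pure functions of the transcript structure)


def _plus_offset(tx: TranscriptModel, gpos: int) -> Optional[int]:
    """Offset of genomic position in the concatenated exon sequence
    (genomic orientation), or None if intronic/outside."""
    cum = 0
    for s, e in tx.exons:
        if s <= gpos < e:
            return cum + (gpos - s)
        cum += e - s
    return None


def _exonic_length(tx: TranscriptModel) -> int:
    return sum(e - s for s, e in tx.exons)


def tx_index(tx: TranscriptModel, gpos: int) -> Optional[int]:
    """Index of a genomic position in the spliced transcript, counted in
    translation orientation (5'->3' of the mRNA)."""
    off = _plus_offset(tx, gpos)
    if off is None:
        return None
    if tx.strand == "+":
        return off
    return _exonic_length(tx) - 1 - off


def cds_tx_start(tx: TranscriptModel) -> int:
    """Spliced-transcript index of the first coding base."""
    g = tx.cds_start if tx.strand == "+" else tx.cds_end - 1
    idx = tx_index(tx, g)
    if idx is None:
        raise AnnotationError(
            f"{tx.tx_name}: CDS boundary {g} not inside any exon"
        )
    return idx


def spliced_cds_length(tx: TranscriptModel) -> int:
    return sum(
        max(0, min(e, tx.cds_end) - max(s, tx.cds_start)) for s, e in tx.exons
    )


def spliced_transcript(
    tx: TranscriptModel, genome: Mapping[str, GenomeSequence]
) -> str:
    """Full spliced transcript sequence in translation orientation."""
    if tx.contig not in genome:
        raise AnnotationError(
            f"{tx.tx_name}: contig {tx.contig!r} not in genome"
        )
    contig = genome[tx.contig].sequence
    if tx.tx_end > len(contig):
        raise AnnotationError(
            f"{tx.tx_name}: transcript extends past end of {tx.contig} "
            f"({tx.tx_end} > {len(contig)})"
        )
    plus = "".join(contig[s:e] for s, e in tx.exons)
    return revcomp(plus) if tx.strand == "-" else plus


def build_cds(
    tx: TranscriptModel, genome: Mapping[str, GenomeSequence]
) -> str:
    """Spliced CDS (stop codon included) in translation orientation."""
    full = spliced_transcript(tx, genome)
    start = cds_tx_start(tx)
    return full[start : start + spliced_cds_length(tx)]


def coding_with_utr3(
    tx: TranscriptModel, genome: Mapping[str, GenomeSequence]
) -> str:
    """CDS plus everything downstream of it on the spliced transcript."""
    full = spliced_transcript(tx, genome)
    return full[cds_tx_start(tx):]


# ---------------------------------------------------------------------------
# Variant projection and application


@dataclass(frozen=True)
class ProjectedVariant:
    """A variant re-expressed in CDS coordinates (translation orientation)."""

    offset: int  # 0-based offset of the first replaced base within the CDS
    ref: str     # transcript-strand REF
    alt: str     # transcript-strand ALT


def project_variant(
    tx: TranscriptModel, variant: VariantRecord
) -> Optional[ProjectedVariant]:
    """Project a genomic variant into CDS coordinates.

    Returns None when the variant does not fall cleanly inside the coding
    exons (intronic, UTR, junction-spanning, or off-transcript): such
    variants are classified noncoding and skipped.
    """
    g0 = variant.pos - 1
    n = len(variant.ref)
    idx = [tx_index(tx, g0 + i) for i in range(n)]
    if any(i is None for i in idx):
        return None
    if tx.strand == "+":
        if idx != list(range(idx[0], idx[0] + n)):
            return None  # REF spans a splice junction
        start = idx[0]
        ref_t, alt_t = variant.ref, variant.alt
    else:
        if idx != list(range(idx[0], idx[0] - n, -1)):
            return None
        start = idx[-1]
        ref_t, alt_t = revcomp(variant.ref), revcomp(variant.alt)
    offset = start - cds_tx_start(tx)
    if offset < 0 or offset + n > spliced_cds_length(tx):
        return None
    return ProjectedVariant(offset, ref_t, alt_t)


def apply_variant(
    seq: str, tx: TranscriptModel, variant: VariantRecord
) -> str:
    """Apply a variant to a spliced coding sequence (CDS or CDS+3'UTR).

    ``seq`` must start at the first coding base. Raises
    ReferenceMismatchError when the projected REF disagrees with ``seq`` and
    AnnotationError when the variant is not cleanly coding.
    """
    pv = project_variant(tx, variant)
    if pv is None:
        raise AnnotationError(
            f"{variant.key} does not project into the CDS of {tx.tx_name}"
        )
    found = seq[pv.offset : pv.offset + len(pv.ref)]
    if found != pv.ref:
        raise ReferenceMismatchError(pv.ref, found, pv.offset)
    return seq[: pv.offset] + pv.alt + seq[pv.offset + len(pv.ref):]


# ---------------------------------------------------------------------------
# Translation and classification


def translate(cds: str) -> tuple[str, bool]:
    """Standard-code translation up to (and excluding) the first stop.

    Returns (protein, stop_found). Trailing partial codons are ignored;
    codons containing N translate to 'X'.
    """
    if len(cds) < 3:
        raise ValueError("sequence shorter than one codon")
    trimmed = cds[: len(cds) - len(cds) % 3]
    protein = str(Seq(trimmed).translate())
    stop = protein.find("*")
    if stop >= 0:
        return protein[:stop], True
    return protein, False


def variant_kind(ref: str, alt: str) -> str:
    """Coarse variant kind driving consequence classification."""
    delta = len(alt) - len(ref)
    if delta == 0:
        return "snv" if len(ref) == 1 else "mnv"
    return "frameshift" if delta % 3 else "inframe_indel"


def classify_change(
    wt_protein: str, mt_protein: str, kind: str
) -> tuple[str, Optional[int]]:
    """Classify a protein-level consequence and locate the first change.

    Substitutions: identical -> synonymous; shorter mutant -> stop_gain;
    longer mutant -> stop_loss (read-through); equal length with one diff ->
    missense (several diffs from an MNV are treated as a segment change).
    Indels keep their frame-derived class. ``first_changed_aa`` is 1-based.
    """
    if wt_protein == mt_protein:
        return "synonymous", None
    first = next(
        (
            i + 1
            for i, (a, b) in enumerate(zip(wt_protein, mt_protein))
            if a != b
        ),
        min(len(wt_protein), len(mt_protein)) + 1,
    )
    if kind in ("snv", "mnv"):
        if len(mt_protein) < len(wt_protein):
            return "stop_gain", first
        if len(mt_protein) > len(wt_protein):
            return "stop_loss", first
        diffs = sum(a != b for a, b in zip(wt_protein, mt_protein))
        return ("missense" if diffs == 1 else "inframe_indel"), first
    return kind, first


def extract_context(
    change: ProteinChange, max_len: int
) -> tuple[str, Optional[str], tuple[int, int]]:
    """Extract the peptide window around the change for epitope enumeration.

    Missense: up to 2*max_len-1 residues centered on the changed residue,
    with the matching wild-type window. Frameshift/stop-loss: max_len-1
    wild-type residues followed by the whole novel tail. In-frame indels:
    max_len-1 flanks around the altered segment (an empty core interval
    marks a pure deletion junction). Returns (mt_context, wt_context|None,
    core_span) with core_span half-open and 0-based within the context.
    Raises EmptyTailError when a frameshift/stop-loss stops immediately.
    """
    cls = change.change_class
    wt, mt = change.wt_protein, change.mt_protein
    i = change.first_changed_aa
    L = max_len
    if cls == "missense":
        lo = max(0, i - 1 - (L - 1))
        hi = min(len(mt), i - 1 + L)
        return mt[lo:hi], wt[lo:hi], (i - 1 - lo, i - lo)
    if cls in ("frameshift", "stop_loss"):
        tail = mt[i - 1:]
        if not tail:
            raise EmptyTailError(
                f"{change.variant.key}/{change.transcript.tx_name}: novel "
                "tail empty (immediate stop)"
            )
        lo = max(0, i - 1 - (L - 1))
        return mt[lo:], None, (i - 1 - lo, len(mt) - lo)
    if cls == "inframe_indel":
        p = 0
        while p < min(len(wt), len(mt)) and wt[p] == mt[p]:
            p += 1
        s = 0
        while (
            s < min(len(wt), len(mt)) - p
            and wt[len(wt) - 1 - s] == mt[len(mt) - 1 - s]
        ):
            s += 1
        seg_end = len(mt) - s
        lo = max(0, p - (L - 1))
        hi = min(len(mt), seg_end + (L - 1))
        return mt[lo:hi], None, (p - lo, seg_end - lo)
    raise ValueError(f"no peptide context defined for class {cls!r}")


# ---------------------------------------------------------------------------
# Driver


def annotate_variant(
    variant: VariantRecord,
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, GenomeSequence],
    max_len: int,
) -> list[ProteinChange]:
    """Annotate one variant against all overlapping transcripts.

    Transcripts are visited in ``tx_name`` order so that downstream
    deduplication keeps the first transcript by name. Flagged/noncoding
    transcripts and junction-spanning hits yield ``noncoding`` records.
    """
    changes = []
    v_lo, v_hi = variant.pos - 1, variant.pos - 1 + len(variant.ref)
    for tx in sorted(transcripts, key=lambda t: t.tx_name):
        if tx.contig != variant.contig:
            continue
        if v_hi <= tx.cds_start or v_lo >= tx.cds_end:
            continue
        if tx.flags:
            log.warning(
                "%s: transcript %s flagged %s; variant skipped",
                variant.key, tx.tx_name, ",".join(tx.flags),
            )
            continue
        pv = project_variant(tx, variant)
        if pv is None:
            changes.append(ProteinChange(variant, tx, "noncoding"))
            continue
        extended = coding_with_utr3(tx, genome)
        wt_protein, _ = translate(extended)
        mt_extended = apply_variant(extended, tx, variant)
        mt_protein, mt_stop = translate(mt_extended)
        kind = variant_kind(variant.ref, variant.alt)
        cls, first = classify_change(wt_protein, mt_protein, kind)
        change = ProteinChange(
            variant, tx, cls,
            wt_protein=wt_protein,
            mt_protein=mt_protein,
            first_changed_aa=first,
        )
        if cls in ("missense", "frameshift", "stop_loss", "inframe_indel"):
            try:
                mt_ctx, wt_ctx, core = extract_context(change, max_len)
            except EmptyTailError as e:
                change.reject_reason = str(e)
            else:
                change.mt_context = mt_ctx
                change.wt_context = wt_ctx
                change.core_start, change.core_end = core
                if not mt_stop and cls in ("frameshift", "stop_loss"):
                    log.warning(
                        "%s/%s: read-through reached end of transcript "
                        "without a stop codon; tail may be truncated",
                        variant.key, tx.tx_name,
                    )
        changes.append(change)
    return changes
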