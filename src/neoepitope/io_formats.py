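"""Readers/writers for every external format the pipeline touches.

Genome and proteome FASTA go through Bio.SeqIO; VCF through pysam; the flat
tab-separated dialects (refFlat transcripts, HLA files, expression tables,
epitope lists, output tables) are parsed here since their grammars are
trivial and need exact control of errors and round-tripping.
"""

from __future__ import annotations

import gzip
import logging
import math
import re
from pathlib import Path
from typing import Optional, Sequence, Union

import pysam
from Bio import SeqIO

from .errors import FormatError, HlaParseError
from .models import (
    AA20,
    BurdenSummary,
    EpitopeCandidate,
    EpitopeDatabase,
    ExpressionTable,
    GenomeSequence,
    HlaGenotype,
    TranscriptModel,
    VariantRecord,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

NUCLEOTIDES = frozenset("ACGTN")

#: Fallback MHC-I alleles used when no haplotype file is supplied: common
#: European-ancestry alleles, two per HLA gene. Override via ``default_hla``.
DEFAULT_HLA_ALLELES = (
    "HLA-A01:01",
    "HLA-A02:01",
    "HLA-B07:02",
    "HLA-B08:01",
    "HLA-C07:01",
    "HLA-C07:02",
)

_HLA_CANONICAL = re.compile(r"^HLA-[ABC]\d{2}:\d{2}$")
_HLA_STARRED = re.compile(r"^HLA-([ABC])\*?(\d{1,3}):(\d{1,3})$")
_POLYSOLVER_TOKEN = re.compile(r"^hla_([abc])_(\d+)_(\d+)(?:_\d+)*$", re.I)


def _open_text(path: PathLike):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> list[GenomeSequence]:
    """Read a nucleotide FASTA; headers truncated at first whitespace."""
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-IUPAC "
                    f"nucleotide characters {sorted(bad)}"
                )
            records.append(GenomeSequence(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_protein_fasta(path: PathLike) -> list[GenomeSequence]:
    """Read a proteome FASTA (20 standard residues; X tolerated, trailing
    '*' stripped)."""
    allowed = AA20 | {"X"}
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper().rstrip("*")
            if not seq:
                raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
            bad = set(seq) - allowed
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-amino-acid "
                    f"characters {sorted(bad)}"
                )
            records.append(GenomeSequence(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# refFlat transcript table


def read_transcripts(path: PathLike) -> list[TranscriptModel]:
    """Parse an 11-column refFlat-style table into TranscriptModels.

    Rows with a structurally invalid CDS are returned flagged (``flags``),
    never silently dropped; malformed rows (wrong column/exon counts) raise.
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 11:
                raise FormatError(
                    f"{path}:{lineno}: expected 11 tab-separated columns, "
                    f"got {len(cols)}"
                )
            gene, tx, contig, strand, *rest = cols
            try:
                tx_start, tx_end, cds_start, cds_end, n_exons = (
                    int(rest[i]) for i in range(5)
                )
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate: {e}")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            starts = [int(x) for x in rest[5].rstrip(",").split(",") if x != ""]
            ends = [int(x) for x in rest[6].rstrip(",").split(",") if x != ""]
            if len(starts) != n_exons or len(ends) != n_exons:
                raise FormatError(
                    f"{path}:{lineno}: exonCount={n_exons} inconsistent with "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            exons = tuple(zip(starts, ends))
            flags = []
            if any(e <= s for s, e in exons) or any(
                exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)
            ):
                raise FormatError(
                    f"{path}:{lineno}: exon intervals not sorted/non-overlapping"
                )
            if cds_start >= cds_end:
                flags.append("noncoding")
            else:
                spliced = sum(
                    max(0, min(e, cds_end) - max(s, cds_start)) for s, e in exons
                )
                if not _cds_within_exons(exons, cds_start, cds_end):
                    flags.append("cds_outside_exons")
                if spliced % 3 != 0:
                    flags.append("cds_length_not_multiple_of_3")
            out.append(
                TranscriptModel(
                    gene, tx, contig, strand, exons, cds_start, cds_end,
                    tuple(flags),
                )
            )
    return out


def _cds_within_exons(exons, cds_start, cds_end):
    if cds_start < exons[0][0] or cds_end > exons[-1][1]:
        return False
    # both CDS boundaries must fall inside (or at the edge of) an exon
    def inside(p):
        return any(s <= p <= e for s, e in exons)

    return inside(cds_start) and inside(cds_end)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: PathLike, patient_id: str) -> list[VariantRecord]:
    """Read a single- or multi-region VCF into VariantRecords.

    One record per (site, ALT allele). Presence in region *i* means sample
    *i*'s GT contains that ALT's allele index; ``./.`` is absent. A VCF with
    no sample columns yields a single region ``R1`` with presence ``[True]``.
    Records present in no region are dropped with a warning.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as e:
        raise FormatError(f"{path}: not a parseable VCF ({e})")
    with vf:
        samples = list(vf.header.samples)
        region_names = tuple(samples) if samples else ("R1",)
        records: list[VariantRecord] = []
        for line_id, rec in enumerate(vf, start=1):
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                if alt is None or not set(alt.upper()) <= NUCLEOTIDES:
                    log.warning(
                        "%s site %d: skipping symbolic/non-sequence ALT %r",
                        path, line_id, alt,
                    )
                    continue
                ref = rec.ref.upper()
                alt = alt.upper()
                if ref == alt:
                    log.warning("%s site %d: REF==ALT, skipped", path, line_id)
                    continue
                if samples:
                    presence = []
                    for s in samples:
                        sample = rec.samples[s]
                        if "GT" not in sample:
                            log.warning(
                                "%s site %d sample %s: no GT field; assuming "
                                "present", path, line_id, s,
                            )
                            presence.append(True)
                            continue
                        gt = sample["GT"]
                        presence.append(
                            any(g == alt_index for g in gt if g is not None)
                        )
                else:
                    presence = [True]
                if not any(presence):
                    log.warning(
                        "%s site %d ALT %s: absent from every region, dropped",
                        path, line_id, alt,
                    )
                    continue
                records.append(
                    VariantRecord(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        patient_id=patient_id,
                        region_names=region_names,
                        presence=tuple(presence),
                        line_id=line_id,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# HLA


def normalize_hla(token: str) -> str:
    """Normalize one HLA allele token to the canonical ``HLA-A01:01`` form.

    Accepts canonical names, starred names (``HLA-A*01:01``) and POLYSOLVER
    winners tokens (``hla_a_01_01_01_01`` -> gene + first two numeric fields).
    """
    token = token.strip()
    m = _POLYSOLVER_TOKEN.match(token)
    if m:
        gene = m.group(1).upper()
        f1, f2 = int(m.group(2)), int(m.group(3))
        return f"HLA-{gene}{f1:02d}:{f2:02d}"
    m = _HLA_STARRED.match(token.upper())
    if m:
        return f"HLA-{m.group(1)}{int(m.group(2)):02d}:{int(m.group(3)):02d}"
    raise HlaParseError(f"unparseable HLA allele token: {token!r}")


def read_hla(
    path: PathLike,
    dialect: str,
    patient_id: Optional[str] = None,
) -> HlaGenotype:
    """Read an HLA haplotype file in either supported dialect.

    ``simple_tsv``: lines ``patient<TAB>allele1<TAB>...``; when the file holds
    several patients, ``patient_id`` selects the row (default: first line).
    ``polysolver_winners``: one patient per file, lines like
    ``HLA-A<TAB>hla_a_01_01_01_01<TAB>hla_a_02_01_01``. Homozygous duplicates
    collapse to a single allele.
    """
    if dialect not in ("simple_tsv", "polysolver_winners"):
        raise ValueError(f"unknown HLA dialect: {dialect!r}")
    alleles: list[str] = []
    found_patient = patient_id
    with _open_text(path) as fh:
        lines = [
            ln.rstrip("\n") for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if dialect == "simple_tsv":
        row = None
        for ln in lines:
            cols = ln.split("\t")
            if patient_id is None or cols[0] == patient_id:
                row = cols
                break
        if row is None:
            raise HlaParseError(
                f"{path}: no HLA row for patient {patient_id!r}"
            )
        found_patient = row[0]
        for tok in row[1:]:
            if tok:
                alleles.append(normalize_hla(tok))
    else:
        for ln in lines:
            for tok in ln.split("\t")[1:]:
                tok = tok.strip()
                if not tok or tok.upper() in ("NA", "NONE", "-"):
                    continue
                alleles.append(normalize_hla(tok))
        if found_patient is None:
            found_patient = Path(str(path)).stem
    deduped = tuple(dict.fromkeys(alleles))
    if not deduped:
        raise HlaParseError(f"{path}: no HLA alleles parsed")
    return HlaGenotype(found_patient, deduped, dialect)


def default_hla(
    alleles: Optional[Sequence[str]] = None,
    patient_id: str = "default",
) -> HlaGenotype:
    """The fallback genotype used when no haplotype file is given."""
    chosen = tuple(
        normalize_hla(a) for a in (alleles or DEFAULT_HLA_ALLELES)
    )
    return HlaGenotype(patient_id, tuple(dict.fromkeys(chosen)), "defaults")


# ---------------------------------------------------------------------------
# Expression & epitope DB


def read_expression(path: PathLike) -> ExpressionTable:
    """Read a gene expression TSV: col 1 gene, cols 2..n region values.

    A header row is detected when every value column is non-numeric; '#'
    comment lines are ignored; non-numeric values become NaN with a warning.
    """
    values: dict[str, tuple[float, ...]] = {}
    region_names: tuple[str, ...] = ()
    first_data = True
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected gene + >=1 value column"
                )
            if first_data:
                first_data = False
                if all(not _is_number(c) for c in cols[1:]):
                    region_names = tuple(cols[1:])
                    continue
            row = []
            for c in cols[1:]:
                if _is_number(c):
                    row.append(float(c))
                else:
                    log.warning(
                        "%s:%d: non-numeric expression value %r -> missing",
                        path, lineno, c,
                    )
                    row.append(math.nan)
            values[cols[0]] = tuple(row)
    if not region_names and values:
        width = len(next(iter(values.values())))
        region_names = tuple(f"R{i+1}" for i in range(width))
    return ExpressionTable(values, region_names)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_epitope_db(path: PathLike) -> EpitopeDatabase:
    """Read an epitope list TSV: ``epitope_id<TAB>peptide`` per line."""
    entries = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected id<TAB>peptide")
            if not entries and cols[1].strip().lower() == "peptide":
                continue  # header row
            pep = cols[1].strip().upper()
            if not pep or set(pep) - AA20:
                raise FormatError(
                    f"{path}:{lineno}: invalid peptide {cols[1]!r}"
                )
            entries.append((cols[0], pep))
    return EpitopeDatabase(tuple(entries))


# ---------------------------------------------------------------------------
# Output tables

CANDIDATE_COLUMNS = [
    "patient", "line_id", "regions", "chrom", "pos", "ref", "alt", "gene",
    "tx", "change_class", "hla_allele", "peptide_mt", "peptide_wt",
    "core_position", "rank_mt", "affinity_mt", "rank_wt", "affinity_wt",
    "binder_class", "novel", "expression", "A", "R", "recognition_potential",
]

SUMMARY_COLUMNS = ["patient", "n_regions", "category", "binder", "count"]


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def candidate_row(c: EpitopeCandidate) -> list[str]:
    v = c.variant
    ch = c.pair.change
    return [
        v.patient_id,
        str(v.line_id),
        " ".join("1" if p else "0" for p in v.presence),
        v.contig,
        str(v.pos),
        v.ref,
        v.alt,
        ch.transcript.gene_name,
        ch.transcript.tx_name,
        ch.change_class,
        c.allele,
        c.pair.mt_peptide,
        c.pair.wt_peptide if c.pair.wt_peptide else "-",
        str(c.pair.core_position),
        _fmt(float(c.rank_mt)),
        _fmt(None if c.affinity_mt is None else float(c.affinity_mt)),
        _fmt(None if c.rank_wt is None else float(c.rank_wt)),
        _fmt(None if c.affinity_wt is None else float(c.affinity_wt)),
        c.binder_class,
        _fmt(c.novel),
        _fmt(None if c.expression is None else float(c.expression)),
        _fmt(None if c.amplitude is None else float(c.amplitude)),
        _fmt(None if c.similarity is None else float(c.similarity)),
        _fmt(None if c.potential is None else float(c.potential)),
    ]


def write_output_tables(
    candidates: Sequence[EpitopeCandidate],
    summaries: Sequence[BurdenSummary],
    out_dir: PathLike,
) -> dict[str, dict[str, Path]]:
    """Write per-patient SNV, indel-type, and summary tables.

    Returns ``{patient: {"snv": path, "indel": path, "summary": path}}``.
    Rows are ordered by (patient, line_id, peptide, allele); candidates from
    single-residue changes go to the SNV table, larger-segment changes
    (in-frame indels, frameshifts, stop-losses) to the indel table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_patient: dict[str, list[EpitopeCandidate]] = {}
    for c in candidates:
        by_patient.setdefault(c.variant.patient_id, []).append(c)
    patients = list(dict.fromkeys(
        [s.patient_id for s in summaries] + list(by_patient)
    ))
    paths: dict[str, dict[str, Path]] = {}
    summaries_by_patient = {s.patient_id: s for s in summaries}
    for patient in patients:
        cands = sorted(
            by_patient.get(patient, []),
            key=lambda c: (c.variant.line_id, c.pair.mt_peptide, c.allele),
        )
        snv_path = out_dir / f"{patient}.neoantigens.snv.tsv"
        indel_path = out_dir / f"{patient}.neoantigens.indel.tsv"
        summary_path = out_dir / f"{patient}.summary.tsv"
        for path, subset in (
            (snv_path, [c for c in cands if c.pair.change.is_snv_type]),
            (indel_path, [c for c in cands if not c.pair.change.is_snv_type]),
        ):
            with open(path, "w") as fh:
                fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
                for c in subset:
                    fh.write("\t".join(candidate_row(c)) + "\n")
        with open(summary_path, "w") as fh:
            fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
            s = summaries_by_patient.get(patient)
            if s is not None:
                for binder in BurdenSummary.BINDERS:
                    for clon in BurdenSummary.CLONALITY:
                        fh.write(
                            f"{patient}\t{s.n_regions}\t{clon}\t{binder}\t"
                            f"{s.counts.get((binder, clon), 0)}\n"
                        )
                for rname in s.region_names:
                    fh.write(
                        f"{patient}\t{s.n_regions}\tregion:{rname}\ttotal\t"
                        f"{s.per_region.get(rname, 0)}\n"
                    )
        paths[patient] = {
            "snv": snv_path, "indel": indel_path, "summary": summary_path,
        }
    return paths


def read_candidate_table(path: PathLike) -> list[dict]:
    """Re-parse an output candidate table into typed row dicts (round-trip
    companion of :func:`write_output_tables`)."""
    rows = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CANDIDATE_COLUMNS:
            raise FormatError(f"{path}: unexpected candidate table header")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            row = dict(zip(header, cols))
            row["line_id"] = int(row["line_id"])
            row["pos"] = int(row["pos"])
            row["core_position"] = int(row["core_position"])
            row["presence"] = tuple(x == "1" for x in row["regions"].split(" "))
            for k in ("rank_mt", "affinity_mt", "rank_wt", "affinity_wt",
                      "expression", "A", "R", "recognition_potential"):
                row[k] = None if row[k] == "NA" else float(row[k])
            row["peptide_wt"] = (
                None if row["peptide_wt"] == "-" else row["peptide_wt"]
            )
            row["novel"] = (
                None if row["novel"] == "NA" else row["novel"] == "1"
            )
            rows.append(row)
    return rows


def read_summary_table(path: PathLike) -> list[dict]:
    rows = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SUMMARY_COLUMNS:
            raise FormatError(f"{path}: unexpected summary table header")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            row = dict(zip(header, cols))
            row["n_regions"] = int(row["n_regions"])
            row["count"] = int(row["count"])
            rows.append(row)
    return rows
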