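"""Deterministic synthetic cohort generator with a machine-readable truth file.

``make_cohort`` fabricates a complete miniature study — genome, transcript
table, per-patient multi-region VCFs with planted coding changes of every
consequence class, HLA files in both dialects, a predictor score table, a
reference proteome, an epitope database and an expression table — plus a
truth TSV recording the expected downstream value of every planted variant.

Truth values are computed here by straight-line arithmetic that is coded
independently of the production modules (separate naive Smith-Waterman DP,
separate codon table, separate window logic) so a bug shared between the
generator and the pipeline cannot silently cancel out.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio.Align import substitution_matrices

from .io_formats import DEFAULT_HLA_ALLELES
from .models import TranscriptModel, revcomp

PathLike = Union[str, Path]

VARIANT_CLASSES = (
    "missense",
    "synonymous",
    "stop_gain",
    "stop_loss",
    "inframe_indel",
    "frameshift",
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_AA = "ACDEFGHIKLMNPQRSTVWY"

# Standard genetic code, written out here so truth translation never touches
# the production translation path.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _translate_until_stop(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# Locus synthesis


@dataclass
class Locus:
    """One synthetic transcript locus and its mapping to the genome."""

    tx: TranscriptModel
    tx_seq: str  # spliced transcript in translation orientation
    utr5: int
    cds_len: int
    intron_at: Optional[int]  # tx coordinate of the intron insertion point
    intron_len: int
    g0: int
    piece_len: int
    genomic_piece: str

    @property
    def strand(self) -> str:
        return self.tx.strand

    def tx2g(self, u: int) -> int:
        """Genomic position of spliced-transcript coordinate ``u``."""
        v = u
        if self.intron_at is not None and u >= self.intron_at:
            v += self.intron_len
        if self.strand == "+":
            return self.g0 + v
        return self.g0 + self.piece_len - 1 - v


def _random_codon(rng: random.Random) -> str:
    while True:
        c = "".join(rng.choice(_BASES) for _ in range(3))
        if c not in _STOPS:
            return c


def synthesize_locus(
    rng: random.Random,
    index: int,
    g0: int,
    contig: str = "chr1",
    n_codons: int = 40,
    strand: Optional[str] = None,
    with_intron: Optional[bool] = None,
) -> Locus:
    """Build one random coding locus (strand and intron cycle with index).

    Layout in transcript orientation: 9 nt 5'UTR, ATG + random non-stop
    codons + TAA, then a 3'UTR of 15 non-stop codons followed by a pattern
    carrying stop codons in all three frames, so frameshift and stop-loss
    read-through always terminates.
    """
    if strand is None:
        strand = "+-"[index % 2]
    if with_intron is None:
        with_intron = index % 4 >= 2
    utr5 = "".join(rng.choice(_BASES) for _ in range(9))
    cds = "ATG" + "".join(
        _random_codon(rng) for _ in range(n_codons - 2)
    ) + "TAA"
    utr3 = "".join(
        _random_codon(rng) for _ in range(15)
    ) + "TAACTAACTAAC"
    tx_seq = utr5 + cds + utr3
    intron_at = None
    intron_seq = ""
    if with_intron:
        intron_at = len(utr5) + 3 * (n_codons // 2)
        intron_seq = "GT" + "".join(
            rng.choice(_BASES) for _ in range(20)
        ) + "AG"
    piece_plus = (
        tx_seq[:intron_at] + intron_seq + tx_seq[intron_at:]
        if with_intron
        else tx_seq
    )
    piece_len = len(piece_plus)
    genomic_piece = revcomp(piece_plus) if strand == "-" else piece_plus
    if with_intron:
        exons_piece = [(0, intron_at), (intron_at + len(intron_seq), piece_len)]
    else:
        exons_piece = [(0, piece_len)]
    if strand == "+":
        exons = tuple((g0 + s, g0 + e) for s, e in exons_piece)
    else:
        exons = tuple(
            sorted((g0 + piece_len - e, g0 + piece_len - s)
                   for s, e in exons_piece)
        )
    locus = Locus(
        tx=TranscriptModel(
            gene_name=f"GENE{index:03d}",
            tx_name=f"TX{index:03d}",
            contig=contig,
            strand=strand,
            exons=exons,
            cds_start=0,  # placeholder, fixed below
            cds_end=0,
        ),
        tx_seq=tx_seq,
        utr5=len(utr5),
        cds_len=len(cds),
        intron_at=intron_at,
        intron_len=len(intron_seq),
        g0=g0,
        piece_len=piece_len,
        genomic_piece=genomic_piece,
    )
    a = locus.tx2g(len(utr5))
    b = locus.tx2g(len(utr5) + len(cds) - 1)
    locus.tx = TranscriptModel(
        gene_name=locus.tx.gene_name,
        tx_name=locus.tx.tx_name,
        contig=contig,
        strand=strand,
        exons=exons,
        cds_start=min(a, b),
        cds_end=max(a, b) + 1,
    )
    return locus


# ---------------------------------------------------------------------------
# Variant planting (transcript-level edit -> genomic VCF fields)


@dataclass
class PlantedVariant:
    """A planted coding change: transcript-level edit plus VCF-level fields."""

    locus: Locus
    vclass: str  # requested consequence class
    u0: int      # tx coordinate of first replaced base
    ref_tx: str
    alt_tx: str
    pos: int     # 1-based genomic position (VCF)
    ref: str
    alt: str


def _tx_edit_ok(locus: Locus, u0: int, u1: int) -> bool:
    """Edit interval must sit inside the CDS and inside a single exon."""
    lo, hi = locus.utr5, locus.utr5 + locus.cds_len
    if u0 < lo or u1 > hi:
        return False
    if locus.intron_at is not None:
        if not (u1 <= locus.intron_at or u0 >= locus.intron_at):
            return False
    return True


def _to_genomic(locus: Locus, u0: int, ref_tx: str, alt_tx: str):
    n = len(ref_tx)
    if locus.strand == "+":
        return locus.tx2g(u0) + 1, ref_tx, alt_tx
    return locus.tx2g(u0 + n - 1) + 1, revcomp(ref_tx), revcomp(alt_tx)


def plant_variant(
    locus: Locus, vclass: str, rng: random.Random
) -> PlantedVariant:
    """Plant one variant of the requested consequence class into a locus."""
    n_codons = locus.cds_len // 3
    utr5 = locus.utr5

    def codon_at(j):
        u = utr5 + 3 * j
        return u, locus.tx_seq[u : u + 3]

    body = list(range(2, n_codons - 3))
    for _ in range(200):
        if vclass == "stop_loss":
            j = n_codons - 1
        else:
            j = rng.choice(body)
        u, codon = codon_at(j)
        if vclass in ("missense", "synonymous", "stop_gain", "stop_loss"):
            offsets = [0, 1, 2]
            rng.shuffle(offsets)
            edit = None
            for off in offsets:
                for base in rng.sample(_BASES, 4):
                    if base == codon[off]:
                        continue
                    new = codon[:off] + base + codon[off + 1:]
                    wt_aa, mt_aa = _CODON_TABLE[codon], _CODON_TABLE[new]
                    ok = (
                        (vclass == "missense" and mt_aa not in ("*", wt_aa))
                        or (vclass == "synonymous" and mt_aa == wt_aa)
                        or (vclass == "stop_gain" and wt_aa != "*"
                            and mt_aa == "*")
                        or (vclass == "stop_loss" and wt_aa == "*"
                            and mt_aa != "*")
                    )
                    if ok:
                        edit = (u + off, codon[off], base)
                        break
                if edit:
                    break
            if edit is None:
                continue
            u0, ref_tx, alt_tx = edit
            u1 = u0 + 1
        elif vclass == "inframe_indel":
            if rng.random() < 0.5:  # delete codon j, anchored one base left
                u0 = u - 1
                ref_tx = locus.tx_seq[u0 : u0 + 4]
                alt_tx = ref_tx[0]
                u1 = u0 + 4
            else:  # insert one non-stop codon after the anchor base
                u0 = u - 1
                ref_tx = locus.tx_seq[u0]
                alt_tx = ref_tx + _random_codon(rng)
                u1 = u0 + 1
        elif vclass == "frameshift":
            width = rng.choice((1, 2))
            if rng.random() < 0.5:  # deletion of 1-2 bases
                u0 = u - 1
                ref_tx = locus.tx_seq[u0 : u0 + 1 + width]
                alt_tx = ref_tx[0]
                u1 = u0 + 1 + width
            else:  # insertion of 1-2 bases
                u0 = u
                ref_tx = locus.tx_seq[u0]
                alt_tx = ref_tx + "".join(
                    rng.choice(_BASES) for _ in range(width)
                )
                u1 = u0 + 1
        else:
            raise ValueError(f"unknown variant class {vclass!r}")
        if not _tx_edit_ok(locus, u0, u1):
            continue
        pos, ref, alt = _to_genomic(locus, u0, ref_tx, alt_tx)
        return PlantedVariant(locus, vclass, u0, ref_tx, alt_tx, pos, ref, alt)
    raise RuntimeError(f"could not plant a {vclass} variant (locus too small?)")


# ---------------------------------------------------------------------------
# Independent straight-line truth arithmetic


def mutant_proteins(pv: PlantedVariant) -> tuple[str, str]:
    """(wt_protein, mt_protein) by direct re-translation of the edited
    transcript (CDS + 3'UTR read-through)."""
    locus = pv.locus
    wt_ext = locus.tx_seq[locus.utr5:]
    mt_tx = (
        locus.tx_seq[: pv.u0] + pv.alt_tx
        + locus.tx_seq[pv.u0 + len(pv.ref_tx):]
    )
    mt_ext = mt_tx[locus.utr5:]
    return _translate_until_stop(wt_ext), _translate_until_stop(mt_ext)


def expected_class(pv: PlantedVariant, wt: str, mt: str):
    """(consequence class, first changed residue) from the protein diff."""
    if wt == mt:
        return "synonymous", None
    first = min(len(wt), len(mt)) + 1
    for i, (x, y) in enumerate(zip(wt, mt)):
        if x != y:
            first = i + 1
            break
    delta = len(pv.alt_tx) - len(pv.ref_tx)
    if delta == 0:
        if len(mt) < len(wt):
            return "stop_gain", first
        if len(mt) > len(wt):
            return "stop_loss", first
        ndiff = sum(x != y for x, y in zip(wt, mt))
        return ("missense" if ndiff == 1 else "inframe_indel"), first
    return ("frameshift" if delta % 3 else "inframe_indel"), first


def expected_context(cls, wt, mt, first, max_len):
    """(mt_context, wt_context|None, core_span) or None when no peptide
    context exists for the class / the novel tail is empty."""
    L = max_len
    if cls == "missense":
        lo = max(0, first - 1 - (L - 1))
        hi = min(len(mt), first - 1 + L)
        return mt[lo:hi], wt[lo:hi], (first - 1 - lo, first - lo)
    if cls in ("frameshift", "stop_loss"):
        if first > len(mt):
            return None  # immediate stop: empty novel tail
        lo = max(0, first - 1 - (L - 1))
        return mt[lo:], None, (first - 1 - lo, len(mt) - lo)
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
    return None


def expected_windows(ctx: str, core, lengths) -> list[tuple[int, int]]:
    """All (L, start) windows overlapping the core, in (L, start) order."""
    cs, ce = core
    out = []
    for L in sorted(set(lengths)):
        if L > len(ctx):
            continue
        for s in range(len(ctx) - L + 1):
            if s < ce and s + L > cs:
                out.append((L, s))
    return out


def expected_clonality(presence: Sequence[bool]) -> str:
    n = sum(presence)
    if n == len(presence):
        return "clonal"
    if n == 1:
        return "subclonal"
    return "shared"


_TRUTH_MATRIX = None


def _blosum62():
    global _TRUTH_MATRIX
    if _TRUTH_MATRIX is None:
        m = substitution_matrices.load("BLOSUM62")
        _TRUTH_MATRIX = {
            (x, y): float(m[x, y]) for x in m.alphabet for y in m.alphabet
        }
    return _TRUTH_MATRIX


def naive_sw(a: str, b: str, gap_open: float = 11.0,
             gap_extend: float = 1.0) -> float:
    """Naive local-alignment DP (explicit gap-length enumeration); the truth
    oracle counterpart of the production Gotoh implementation. A gap of
    length g costs gap_open + g*gap_extend."""
    S = _blosum62()
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            v = H[i - 1][j - 1] + S[(a[i - 1], b[j - 1])]
            for g in range(1, i + 1):
                v = max(v, H[i - g][j] - (gap_open + gap_extend * g))
            for g in range(1, j + 1):
                v = max(v, H[i][j - g] - (gap_open + gap_extend * g))
            H[i][j] = max(0.0, v)
            if H[i][j] > best:
                best = H[i][j]
    return best


def truth_R(peptide: str, db_peptides: Sequence[str],
            k: float = 4.86936, a: float = 26.0) -> float:
    """Direct formula evaluation of R = Z/(1+Z), Z = sum exp(-k(a-s_e)),
    in hand-rolled log space (independent of scipy's logsumexp)."""
    if not db_peptides:
        return 0.0
    logs = [-k * (a - naive_sw(peptide, e)) for e in db_peptides]
    mx = max(logs)
    log_z = mx + math.log(math.fsum(math.exp(x - mx) for x in logs))
    if log_z > 0:
        return 1.0 / (1.0 + math.exp(-log_z))
    z = math.exp(log_z)
    return z / (1.0 + z)


# ---------------------------------------------------------------------------
# Cohort assembly


@dataclass
class CohortPaths:
    root: Path
    genome: Path
    transcripts: Path
    vcf_dir: Path
    hla_simple: Path
    hla_polysolver_dir: Path
    predictor_table: Path
    proteome: Path
    epitope_db: Path
    expression: Path
    truth: Path


TRUTH_COLUMNS = [
    "patient", "chrom", "pos", "ref", "alt", "gene", "tx", "change_class",
    "clonality", "has_candidates", "focus_peptide", "focus_wt", "allele",
    "rank_mt", "binder_class", "novel", "expression", "A", "R", "product",
    "mt_context",
]

_FOCUS_RANKS = (0.3, 1.5, 5.0)       # SB / WB / NB cycle
_FOCUS_MT_AFFINITY = 50.0
_FOCUS_WT_AFFINITIES = (500.0, 50.0, 5.0)  # A = 10 / 1 / 0.1 cycle
_FOCUS_WT_RANK = 10.0


def _presence_pattern(ordinal: int, n_regions: int) -> tuple[bool, ...]:
    kind = ordinal % 3
    if n_regions == 1 or kind == 0:
        return tuple([True] * n_regions)
    if kind == 1 and n_regions >= 3:
        return tuple([True, True] + [False] * (n_regions - 2))
    return tuple(
        [i == min(1, n_regions - 1) for i in range(n_regions)]
    )


def _polysolver_token(allele: str) -> str:
    gene = allele[4].lower()
    f1, f2 = allele[5:].split(":")
    return f"hla_{gene}_{f1}_{f2}_01_01"


def make_cohort(
    out_dir: PathLike,
    seed: int = 1,
    n_patients: int = 2,
    n_regions: int = 3,
    n_variants_per_class: int = 1,
    lengths: tuple[int, ...] = (8, 9, 10),
) -> CohortPaths:
    """Generate the full fixture directory; byte-identical for a fixed seed."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_patients < 1 or n_variants_per_class < 1:
        raise ValueError("need at least one patient and one variant per class")
    rng = random.Random(seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    vcf_dir = root / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    poly_dir = root / "hla_polysolver"
    poly_dir.mkdir(exist_ok=True)

    patients = [f"P{i+1}" for i in range(n_patients)]
    region_names = tuple(f"R{i+1}" for i in range(n_regions))
    alleles = DEFAULT_HLA_ALLELES
    max_len = max(lengths)

    # --- loci and planted variants -------------------------------------
    contig = "chr1"
    genome_parts = ["".join(rng.choice(_BASES) for _ in range(30))]
    g_cursor = 30
    planted: dict[str, list[PlantedVariant]] = {p: [] for p in patients}
    index = 0
    for patient in patients:
        for vclass in VARIANT_CLASSES:
            for _ in range(n_variants_per_class):
                locus = synthesize_locus(rng, index, g_cursor, contig)
                genome_parts.append(locus.genomic_piece)
                g_cursor += locus.piece_len
                spacer = "".join(rng.choice(_BASES) for _ in range(20))
                genome_parts.append(spacer)
                g_cursor += 20
                planted[patient].append(plant_variant(locus, vclass, rng))
                index += 1
    genome_seq = "".join(genome_parts)

    # --- per-variant truth ----------------------------------------------
    records = []
    for patient in patients:
        for ordinal, pv in enumerate(planted[patient]):
            wt, mt = mutant_proteins(pv)
            cls, first = expected_class(pv, wt, mt)
            ctx = (
                expected_context(cls, wt, mt, first, max_len)
                if cls in ("missense", "frameshift", "stop_loss",
                           "inframe_indel")
                else None
            )
            windows = (
                expected_windows(ctx[0], ctx[2], lengths) if ctx else []
            )
            focus = None
            if windows:
                nine = [w for w in windows if w[0] == 9] or windows
                L, s = nine[0]
                focus = (ctx[0][s : s + L],
                         ctx[1][s : s + L] if ctx[1] else None)
            presence = _presence_pattern(ordinal, n_regions)
            records.append({
                "patient": patient,
                "ordinal": ordinal,
                "pv": pv,
                "wt": wt,
                "mt": mt,
                "cls": cls,
                "ctx": ctx,
                "windows": windows,
                "focus": focus,
                "presence": presence,
            })

    # --- predictor table -------------------------------------------------
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for rec in records:
        if not rec["ctx"]:
            continue
        mt_ctx, wt_ctx, _core = rec["ctx"]
        for L, s in rec["windows"]:
            peps = [mt_ctx[s : s + L]]
            if wt_ctx:
                peps.append(wt_ctx[s : s + L])
            for pep in peps:
                for al in alleles:
                    if (pep, al) not in table:
                        table[(pep, al)] = (
                            round(rng.uniform(0.05, 30.0), 4),
                            round(rng.uniform(10.0, 5000.0), 2),
                        )
    for rec in records:
        if not rec["focus"]:
            continue
        focus_mt, focus_wt = rec["focus"]
        wt_aff = _FOCUS_WT_AFFINITIES[rec["ordinal"] % 3]
        for k, al in enumerate(alleles):
            rank = _FOCUS_RANKS[(rec["ordinal"] + k) % 3]
            table[(focus_mt, al)] = (rank, _FOCUS_MT_AFFINITY)
            if focus_wt:
                table[(focus_wt, al)] = (_FOCUS_WT_RANK, wt_aff)
        rec["wt_aff"] = wt_aff

    # --- proteome, epitope DB, expression --------------------------------
    proteome_records = []
    for rec in records:
        proteome_records.append(
            (f"PROT_{rec['pv'].locus.tx.tx_name}_{rec['patient']}", rec["wt"])
        )
    for rec in records:
        if rec["focus"] and rec["ordinal"] % 3 == 0:
            flank_l = "".join(rng.choice(_AA) for _ in range(5))
            flank_r = "".join(rng.choice(_AA) for _ in range(5))
            proteome_records.append(
                (
                    f"PLANT_{rec['patient']}_{rec['ordinal']}",
                    flank_l + rec["focus"][0] + flank_r,
                )
            )
    proteome_seqs = [s for _, s in proteome_records]

    db_entries = []
    for rec in records:
        if rec["focus"] and rec["ordinal"] % 2 == 0:
            db_entries.append(
                (f"DB_{rec['patient']}_{rec['ordinal']}", rec["focus"][0])
            )
    for i in range(4):
        db_entries.append(
            (f"DB_RAND_{i}", "".join(rng.choice(_AA) for _ in range(9)))
        )
    db_peptides = [p for _, p in db_entries]

    expression_values = {}
    for rec in records:
        gene = rec["pv"].locus.tx.gene_name
        expression_values[gene] = round(rng.uniform(0.5, 100.0), 2)

    # --- truth rows -------------------------------------------------------
    truth_rows = []
    for rec in records:
        pv = rec["pv"]
        clonality = expected_clonality(rec["presence"])
        base = [
            rec["patient"], contig, str(pv.pos), pv.ref, pv.alt,
            pv.locus.tx.gene_name, pv.locus.tx.tx_name, rec["cls"], clonality,
        ]
        if not rec["focus"]:
            truth_rows.append(
                base + ["0", "-", "-", "-", "-", "-", "-", "-", "-", "-",
                        "-", "-"]
            )
            continue
        focus_mt, focus_wt = rec["focus"]
        novel = not any(focus_mt in s for s in proteome_seqs)
        expr = expression_values[pv.locus.tx.gene_name]
        r_val = truth_R(focus_mt, db_peptides)
        for k, al in enumerate(alleles):
            rank = _FOCUS_RANKS[(rec["ordinal"] + k) % 3]
            binder = "SB" if rank <= 0.5 else ("WB" if rank <= 2.0 else "NB")
            if focus_wt is not None:
                a_val = rec["wt_aff"] / _FOCUS_MT_AFFINITY
            else:
                a_val = 1.0
            truth_rows.append(
                base
                + [
                    "1", focus_mt, focus_wt or "-", al, repr(rank), binder,
                    "1" if novel else "0", repr(expr), repr(a_val),
                    repr(r_val), repr(a_val * r_val), rec["ctx"][0],
                ]
            )

    # --- write files ------------------------------------------------------
    paths = CohortPaths(
        root=root,
        genome=root / "genome.fa",
        transcripts=root / "transcripts.refflat",
        vcf_dir=vcf_dir,
        hla_simple=root / "hla.simple.tsv",
        hla_polysolver_dir=poly_dir,
        predictor_table=root / "predictor_table.tsv",
        proteome=root / "proteome.fa",
        epitope_db=root / "epitope_db.tsv",
        expression=root / "expression.tsv",
        truth=root / "truth.tsv",
    )

    with open(paths.genome, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(genome_seq), 60):
            fh.write(genome_seq[i : i + 60] + "\n")

    with open(paths.transcripts, "w") as fh:
        loci = [pv.locus for p in patients for pv in planted[p]]
        for locus in loci:
            tx = locus.tx
            starts = ",".join(str(s) for s, _ in tx.exons) + ","
            ends = ",".join(str(e) for _, e in tx.exons) + ","
            fh.write(
                "\t".join([
                    tx.gene_name, tx.tx_name, tx.contig, tx.strand,
                    str(tx.tx_start), str(tx.tx_end),
                    str(tx.cds_start), str(tx.cds_end),
                    str(len(tx.exons)), starts, ends,
                ]) + "\n"
            )

    for patient in patients:
        recs = [r for r in records if r["patient"] == patient]
        recs.sort(key=lambda r: r["pv"].pos)
        with open(vcf_dir / f"{patient}.vcf", "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig},length={len(genome_seq)}>\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description='
                '"Genotype">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(region_names) + "\n"
            )
            for rec in recs:
                pv = rec["pv"]
                gts = "\t".join(
                    "0/1" if p else "0/0" for p in rec["presence"]
                )
                fh.write(
                    f"{contig}\t{pv.pos}\t.\t{pv.ref}\t{pv.alt}\t.\tPASS\t"
                    f".\tGT\t{gts}\n"
                )

    with open(paths.hla_simple, "w") as fh:
        for patient in patients:
            fh.write(patient + "\t" + "\t".join(alleles) + "\n")

    for patient in patients:
        with open(poly_dir / f"{patient}.winners.txt", "w") as fh:
            for gene in "ABC":
                toks = [
                    _polysolver_token(a) for a in alleles
                    if a.startswith(f"HLA-{gene}")
                ]
                fh.write(f"HLA-{gene}\t" + "\t".join(toks) + "\n")

    with open(paths.predictor_table, "w") as fh:
        fh.write("peptide\tallele\trank\taffinity_nM\n")
        for (pep, al), (rank, aff) in sorted(table.items()):
            fh.write(f"{pep}\t{al}\t{rank!r}\t{aff!r}\n")

    with open(paths.proteome, "w") as fh:
        for name, seq in proteome_records:
            fh.write(f">{name}\n{seq}\n")

    with open(paths.epitope_db, "w") as fh:
        fh.write("epitope_id\tpeptide\n")
        for eid, pep in db_entries:
            fh.write(f"{eid}\t{pep}\n")

    with open(paths.expression, "w") as fh:
        for gene in sorted(expression_values):
            fh.write(f"{gene}\t{expression_values[gene]!r}\n")

    with open(paths.truth, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for row in truth_rows:
            fh.write("\t".join(row) + "\n")

    return paths


def read_truth(path: PathLike) -> list[dict]:
    """Parse a truth TSV back into row dicts (str fields; '-' = absent)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows
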