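"""Core domain types shared by every pipeline stage.

The toolkit models a neoantigen workflow: somatic variants (with per-region
presence vectors from multi-region VCFs) are projected onto transcript models,
translated into protein changes, windowed into candidate epitopes, scored
against the patient's MHC-I (HLA) alleles, and summarized by clonality class.
All genomic coordinates are stored 0-based half-open; VCF positions are
converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

#: Standard 20 amino acids (one-letter).
AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig of a reference genome (uppercase A/C/G/T/N)."""

    name: str
    sequence: str


@dataclass(frozen=True)
class TranscriptModel:
    """A coding transcript: exon structure plus CDS bounds on a genome.

    ``exons`` are 0-based half-open genomic intervals sorted ascending and
    non-overlapping regardless of strand; ``cds_start``/``cds_end`` bound the
    coding region (stop codon included) in genomic coordinates.  Structural
    problems found at parse time (e.g. CDS length not divisible by 3) are
    recorded in ``flags`` rather than raised, mirroring how gene-model tables
    ship imperfect rows.
    """

    gene_name: str
    tx_name: str
    contig: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    flags: tuple[str, ...] = ()

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class VariantRecord:
    """A normalized somatic variant with its multi-region presence vector.

    ``pos`` is the 1-based genomic position of the first REF base (VCF
    convention). ``presence[i]`` says whether region ``region_names[i]``
    carries the ALT allele; ``line_id`` is the ordinal of the source VCF site
    so multi-allelic splits of one site share it.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    patient_id: str
    region_names: tuple[str, ...]
    presence: tuple[bool, ...]
    line_id: int

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("REF and ALT must differ")
        if len(self.presence) != len(self.region_names):
            raise ValueError("presence vector length != number of regions")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class HlaGenotype:
    """A patient's MHC-I alleles, normalized to e.g. ``HLA-A01:01``."""

    patient_id: str
    alleles: tuple[str, ...]
    source_dialect: str  # simple_tsv | polysolver_winners | defaults


@dataclass
class ExpressionTable:
    """Gene-level expression, one value per region (or one shared value)."""

    values: dict[str, tuple[float, ...]]
    region_names: tuple[str, ...] = ()

    def value(self, gene: str) -> Optional[float]:
        """Mean of the finite region values for ``gene`` (None if unknown)."""
        row = self.values.get(gene)
        if row is None:
            return None
        finite = [v for v in row if math.isfinite(v)]
        if not finite:
            return None
        return sum(finite) / len(finite)


@dataclass(frozen=True)
class EpitopeDatabase:
    """A curated list of known (e.g. IEDB) epitopes: (id, peptide) pairs."""

    entries: tuple[tuple[str, str], ...]


@dataclass
class ProteinChange:
    """A classified protein consequence of one variant on one transcript.

    ``mt_context`` is the peptide window handed to epitope enumeration;
    ``core_start``/``core_end`` delimit (half-open, 0-based within the
    context) the novel residues. For a pure in-frame deletion the core is an
    empty interval marking the junction, so only peptides spanning the
    junction are considered novel. ``wt_context`` is present for missense
    changes only (aligned window for wild-type predictions).
    """

    variant: VariantRecord
    transcript: TranscriptModel
    change_class: str  # missense | synonymous | stop_gain | stop_loss |
    #                    inframe_indel | frameshift | noncoding
    wt_protein: str = ""
    mt_protein: str = ""
    first_changed_aa: Optional[int] = None  # 1-based
    mt_context: Optional[str] = None
    wt_context: Optional[str] = None
    core_start: Optional[int] = None
    core_end: Optional[int] = None
    reject_reason: Optional[str] = None

    @property
    def core_span(self) -> Optional[tuple[int, int]]:
        if self.core_start is None:
            return None
        return (self.core_start, self.core_end)

    @property
    def is_snv_type(self) -> bool:
        """True for single-residue changes (reported in the SNV table)."""
        return self.change_class == "missense"


@dataclass(frozen=True)
class EpitopePair:
    """One candidate mutant epitope, paired with its wild-type counterpart
    for missense changes (indel-type candidates have no aligned WT)."""

    mt_peptide: str
    wt_peptide: Optional[str]
    length: int
    offset: int  # 1-based start within the context
    change: ProteinChange = field(compare=False, hash=False)

    @property
    def core_position(self) -> int:
        """1-based position within the peptide of the first novel residue
        (for a pure deletion junction: the first residue after it)."""
        cs = self.change.core_start
        ce = self.change.core_end
        start0 = self.offset - 1
        if cs == ce:  # junction
            return cs - start0 + 1
        return max(cs, start0) - start0 + 1


@dataclass(frozen=True)
class BindingScore:
    """A predicted (peptide, allele) MHC-I binding score.

    ``rank`` is the percentile rank (0–100, lower = stronger binder);
    ``affinity`` the predicted dissociation constant in nM when available.
    """

    peptide: str
    allele: str
    rank: float
    affinity: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.rank <= 100.0):
            raise ValueError(f"percentile rank outside [0,100]: {self.rank}")
        if self.affinity is not None and not self.affinity > 0:
            raise ValueError(f"affinity must be positive: {self.affinity}")


@dataclass
class EpitopeCandidate:
    """One fully scored (peptide, HLA allele) output unit."""

    pair: EpitopePair
    allele: str
    rank_mt: float
    affinity_mt: Optional[float]
    rank_wt: Optional[float] = None
    affinity_wt: Optional[float] = None
    binder_class: str = "NB"
    novel: Optional[bool] = None
    expression: Optional[float] = None
    amplitude: Optional[float] = None
    similarity: Optional[float] = None
    potential: Optional[float] = None
    best_epitope_id: Optional[str] = None
    amplitude_undefined: bool = False

    @property
    def variant(self) -> VariantRecord:
        return self.pair.change.variant

    @property
    def presence(self) -> tuple[bool, ...]:
        return self.variant.presence


@dataclass
class BurdenSummary:
    """Per-patient neoantigen burden over binder class x clonality class."""

    patient_id: str
    n_regions: int
    region_names: tuple[str, ...]
    counts: dict[tuple[str, str], int]  # (binder, clonality) -> n
    per_region: dict[str, int]

    CLONALITY = ("clonal", "shared", "subclonal")
    BINDERS = ("SB", "WB")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def class_total(self, clonality: str) -> int:
        return sum(self.counts.get((b, clonality), 0) for b in self.BINDERS)

    def binder_total(self, binder: str) -> int:
        return sum(self.counts.get((binder, c), 0) for c in self.CLONALITY)
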