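"""Pluggable MHC-I binding prediction and binder-class assignment.

The neural-network predictor the field uses (netMHCpan) stays external: this
module defines the predictor contract, two built-in deterministic predictors
(a table lookup for golden tests, a seeded hash predictor for property tests
at scale), an adapter that parses netMHCpan 4.x plain-text output, and the
percentile-rank thresholds for strong/weak binder classes.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, Union

from .errors import FormatError, PredictionError
from .io_formats import _open_text, normalize_hla
from .models import BindingScore

log = logging.getLogger(__name__)

#: Percentile-rank thresholds recommended with netMHCpan: rank <= 0.5 ->
#: strong binder (SB), <= 2 -> weak binder (WB), else non-binder (NB).
SB_RANK_THRESHOLD = 0.5
WB_RANK_THRESHOLD = 2.0


class Predictor(Protocol):
    """Anything that can score a (peptide, allele) pair deterministically."""

    def score(self, peptide: str, allele: str) -> BindingScore: ...


@dataclass(frozen=True)
class PredictionFailure:
    peptide: str
    allele: str
    reason: str


class TablePredictor:
    """Deterministic lookup predictor backed by a (peptide, allele) table."""

    def __init__(self, scores: dict[tuple[str, str], BindingScore]):
        self._scores = dict(scores)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "TablePredictor":
        """Load a predictor table: peptide, allele, rank, affinity_nM."""
        scores: dict[tuple[str, str], BindingScore] = {}
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if cols[0].lower() == "peptide":
                    continue
                if len(cols) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected peptide, allele, rank"
                        "[, affinity_nM]"
                    )
                try:
                    rank = float(cols[2])
                    affinity = float(cols[3]) if len(cols) > 3 else None
                except ValueError as e:
                    raise FormatError(f"{path}:{lineno}: {e}")
                allele = normalize_hla(cols[1])
                scores[(cols[0], allele)] = BindingScore(
                    cols[0], allele, rank, affinity
                )
        return cls(scores)

    @classmethod
    def from_scores(cls, scores: Iterable[BindingScore]) -> "TablePredictor":
        return cls({(s.peptide, s.allele): s for s in scores})

    def score(self, peptide: str, allele: str) -> BindingScore:
        try:
            return self._scores[(peptide, allele)]
        except KeyError:
            raise PredictionError(
                f"no table entry for ({peptide}, {allele})"
            )


class HashPredictor:
    """Seeded stable-hash predictor for large-scale property tests.

    Maps (peptide, allele) deterministically into a percentile rank in
    (0, 100] and an affinity in (1, 50000] nM. No fixed values are promised —
    only determinism and range.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def _unit(self, tag: str, peptide: str, allele: str) -> float:
        digest = hashlib.sha256(
            f"{self.seed}|{tag}|{peptide}|{allele}".encode()
        ).digest()
        return int.from_bytes(digest[:8], "big") / 2**64  # [0, 1)

    def score(self, peptide: str, allele: str) -> BindingScore:
        rank = 100.0 * (1.0 - self._unit("rank", peptide, allele))
        affinity = 1.0 + 49999.0 * (1.0 - self._unit("aff", peptide, allele))
        return BindingScore(peptide, allele, rank, affinity)


def predict(
    peptides: Sequence[str],
    alleles: Sequence[str],
    predictor: Predictor,
) -> tuple[list[BindingScore], list[PredictionFailure]]:
    """Score the cartesian product peptides x alleles.

    Unscorable pairs become explicit failure records; the batch continues.
    """
    scores, failures = [], []
    for pep in peptides:
        for allele in alleles:
            try:
                scores.append(predictor.score(pep, allele))
            except PredictionError as e:
                failures.append(PredictionFailure(pep, allele, str(e)))
    return scores, failures


def classify_binder(
    rank: float,
    sb_threshold: float = SB_RANK_THRESHOLD,
    wb_threshold: float = WB_RANK_THRESHOLD,
) -> str:
    """SB / WB / NB from a percentile rank (boundaries inclusive)."""
    if not (0.0 <= rank <= 100.0):
        raise ValueError(f"percentile rank outside [0,100]: {rank}")
    if rank <= sb_threshold:
        return "SB"
    if rank <= wb_threshold:
        return "WB"
    return "NB"


# ---------------------------------------------------------------------------
# netMHCpan 4.x plain-text output adapter

_SEPARATOR = re.compile(r"^[-=\s]+$")


def parse_netmhcpan(path: Union[str, Path]) -> list[BindingScore]:
    """Parse netMHCpan 4.0/4.1 long-format output into BindingScores.

    The eluted-ligand percentile rank (``%Rank_EL``) is preferred when both
    EL and BA columns exist; 4.0 files expose a single ``%Rank`` column.
    Allele names are normalized (``HLA-A*01:01`` -> ``HLA-A01:01``).
    """
    scores: list[BindingScore] = []
    header: Optional[list[str]] = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if _SEPARATOR.match(line):
                continue
            tokens = line.split()
            if tokens[0] in ("Pos", "pos"):
                header = tokens
                continue
            if not tokens[0].lstrip("-").isdigit():
                continue  # prose lines (e.g. per-protein footers)
            if header is None:
                raise FormatError(
                    f"{path}:{lineno}: data row before any header line"
                )
            idx = {name: i for i, name in enumerate(header)}
            allele_col = idx.get("MHC", idx.get("HLA"))
            pep_col = idx.get("Peptide")
            rank_col = idx.get("%Rank_EL", idx.get("%Rank"))
            aff_col = idx.get("Aff(nM)")
            if allele_col is None or pep_col is None or rank_col is None:
                raise FormatError(
                    f"{path}: header lacks MHC/Peptide/%Rank columns"
                )
            try:
                rank = float(tokens[rank_col])
                affinity = (
                    float(tokens[aff_col])
                    if aff_col is not None and aff_col < len(tokens)
                    else None
                )
                allele = normalize_hla(tokens[allele_col])
            except (ValueError, IndexError) as e:
                raise FormatError(f"{path}:{lineno}: malformed row ({e})")
            scores.append(
                BindingScore(tokens[pep_col], allele, rank, affinity)
            )
    if not scores:
        raise FormatError(f"{path}: no netMHCpan data rows found")
    return scores


def load_netmhcpan_dir(directory: Union[str, Path]) -> TablePredictor:
    """Build a lookup predictor from a directory of netMHCpan output files."""
    directory = Path(directory)
    scores: dict[tuple[str, str], BindingScore] = {}
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix in (".txt", ".out", ".pan") and p.is_file()
    )
    if not files:
        raise FormatError(f"{directory}: no netMHCpan output files found")
    for f in files:
        for s in parse_netmhcpan(f):
            scores[(s.peptide, s.allele)] = s
    return TablePredictor(scores)
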