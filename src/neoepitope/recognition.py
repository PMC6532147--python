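"""Proteome novelty and TCR recognition-potential scoring.

The recognition potential of a neoantigen is the product A*R:

* A (amplitude) compares wild-type and mutant MHC-I binding as the ratio of
  predicted dissociation constants, K_d(WT)/K_d(MT) — a mutant that binds
  more strongly than its wild-type counterpart has A > 1.
* R weights the neoantigen's similarity to known immunogenic epitopes via a
  multistate thermodynamic (partition-function) model: each database epitope
  e contributes a Boltzmann factor w_e = exp(-k*(a - s_e)) built from its
  Smith-Waterman alignment score s_e, and R = Z/(1+Z) with Z the sum of the
  factors — a logistic function of the log-partition sum, bounded in [0,1).

The local alignment is a native affine-gap Smith-Waterman (Gotoh recursion)
over a standard substitution matrix, with the BLAST gap convention: a gap of
length g costs gap_open + g*gap_extend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Align import substitution_matrices
from scipy.special import expit, logsumexp

from .models import AA20, BindingScore, EpitopeDatabase

log = logging.getLogger(__name__)

#: Defaults of the thermodynamic similarity model (steepness k and score
#: midpoint a) as distributed with the companion recognition-potential
#: method, alongside blastp-style BLOSUM62 affine-gap alignment parameters.
DEFAULT_K = 4.86936
DEFAULT_A = 26.0


@dataclass(frozen=True)
class RecognitionParams:
    """Tunable parameters of the recognition-potential model."""

    k: float = DEFAULT_K
    a: float = DEFAULT_A
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError("k must be > 0")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


_MATRIX_CACHE: dict[str, dict[tuple[str, str], float]] = {}


def _matrix(name: str) -> dict[tuple[str, str], float]:
    if name not in _MATRIX_CACHE:
        m = substitution_matrices.load(name)
        table = {}
        for x in m.alphabet:
            for y in m.alphabet:
                table[(x, y)] = float(m[x, y])
        _MATRIX_CACHE[name] = table
    return _MATRIX_CACHE[name]


def is_novel(peptide: str, proteome: Sequence[str]) -> bool:
    """False iff the peptide occurs verbatim in any proteome sequence."""
    if not peptide:
        raise ValueError("empty peptide")
    if not proteome:
        log.warning("empty proteome: every peptide considered novel")
        return True
    return not any(peptide in seq for seq in proteome)


def sw_align(
    pep_a: str, pep_b: str, params: RecognitionParams = RecognitionParams()
) -> float:
    """Smith-Waterman local alignment score with affine gaps (Gotoh).

    Gap of length g costs gap_open + g*gap_extend. Score is >= 0.
    """
    if not pep_a or not pep_b:
        raise ValueError("peptides must be non-empty")
    for pep in (pep_a, pep_b):
        bad = set(pep) - AA20
        if bad:
            raise ValueError(f"unknown residue(s) {sorted(bad)} in {pep!r}")
    S = _matrix(params.substitution_matrix)
    open_cost = params.gap_open + params.gap_extend  # first gapped residue
    ext = params.gap_extend
    n, m = len(pep_a), len(pep_b)
    neg = float("-inf")
    H_prev = [0.0] * (m + 1)
    F_prev = [neg] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        H_cur = [0.0] * (m + 1)
        F_cur = [neg] * (m + 1)
        E = neg
        ai = pep_a[i - 1]
        for j in range(1, m + 1):
            E = max(H_cur[j - 1] - open_cost, E - ext)
            F_cur[j] = max(H_prev[j] - open_cost, F_prev[j] - ext)
            h = max(
                0.0,
                H_prev[j - 1] + S[(ai, pep_b[j - 1])],
                E,
                F_cur[j],
            )
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, F_prev = H_cur, F_cur
    return best


def compute_R(
    peptide: str,
    db: EpitopeDatabase,
    params: RecognitionParams = RecognitionParams(),
) -> tuple[float, Optional[str]]:
    """Similarity-to-known-epitopes probability R and the best-matching id.

    R = Z / (1 + Z) with Z = sum_e exp(-k*(a - s_e)); evaluated through
    log-sum-exp so large alignment scores cannot overflow. An empty database
    gives R = 0 (the model's no-evidence limit). Ties on the best score keep
    the first epitope in file order.
    """
    if not db.entries:
        return 0.0, None
    best_id, best_score = None, float("-inf")
    log_weights = []
    for epitope_id, ep in db.entries:
        s = sw_align(peptide, ep, params)
        log_weights.append(-params.k * (params.a - s))
        if s > best_score:
            best_id, best_score = epitope_id, s
    log_z = float(logsumexp(log_weights))
    return float(expit(log_z)), best_id


def compute_A(wt_score: BindingScore, mt_score: BindingScore) -> float:
    """Amplitude: dissociation-constant ratio K_d(WT)/K_d(MT) in nM.

    Lower mutant nM means stronger mutant binding and larger A.
    """
    if wt_score.affinity is None or mt_score.affinity is None:
        raise ValueError("amplitude requires affinities for both alleles")
    return wt_score.affinity / mt_score.affinity


def recognition_potential(A: float, R: float) -> float:
    """The recognition potential: the exact product A*R.

    Mathematically R < 1 strictly, but the logistic saturates to 1.0 in
    double precision for very strong matches, so the closed bound is
    accepted here.
    """
    if A < 0:
        raise ValueError("A must be >= 0")
    if not (0.0 <= R <= 1.0):
        raise ValueError("R must lie in [0, 1]")
    return A * R
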