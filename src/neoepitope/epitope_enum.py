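"""Sliding-window enumeration of candidate epitopes from mutant contexts."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .models import EpitopePair, ProteinChange

log = logging.getLogger(__name__)


def enumerate_epitopes(
    change: ProteinChange,
    lengths: Iterable[int],
) -> list[EpitopePair]:
    """All L-mers of the mutant context overlapping the novel core.

    For each requested length L, every window of the context that overlaps
    ``core_span`` is emitted; an empty core interval (pure in-frame deletion
    junction) requires the window to span the junction. Missense windows
    carry the aligned wild-type L-mer. Output is sorted by (L, offset);
    duplicate mutant peptides within the change are collapsed; peptides
    containing 'X' (from N bases) are dropped with a warning since binding
    predictors cannot score them.
    """
    ctx = change.mt_context
    if ctx is None:
        return []
    cs, ce = change.core_start, change.core_end
    out: list[EpitopePair] = []
    seen: set[str] = set()
    for L in sorted(set(lengths)):
        if L < 1 or L > len(ctx):
            continue
        for s in range(len(ctx) - L + 1):
            if not (s < ce and s + L > cs):
                continue
            mt = ctx[s : s + L]
            if "X" in mt:
                log.warning(
                    "%s: dropping peptide %r containing X",
                    change.variant.key, mt,
                )
                continue
            if mt in seen:
                continue
            seen.add(mt)
            wt = None
            if change.wt_context is not None:
                wt = change.wt_context[s : s + L]
            out.append(EpitopePair(mt, wt, L, s + 1, change))
    return out


def dedupe_candidates(pairs: Sequence[EpitopePair]) -> list[EpitopePair]:
    """Collapse pairs with identical (mt_peptide, variant) across transcripts.

    Stable: the first occurrence wins, so callers that enumerate transcripts
    in name order keep the first transcript by name.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs:
        key = (p.mt_peptide, p.change.variant.key)
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out
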