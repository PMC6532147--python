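"""Multi-region clonality classification and neoantigen burden summaries.

A variant's presence vector over the sequenced regions determines its
clonality class: present in all regions -> clonal; in at least two but not
all -> shared; in exactly one -> subclonal. Single-region inputs are clonal
by convention. Burden summaries count strong/weak binders (non-binders are
excluded) per clonality class and per region.
"""

from __future__ import annotations

from typing import Sequence

from .models import BurdenSummary, EpitopeCandidate


def classify_clonality(presence: Sequence[bool]) -> str:
    """clonal / shared / subclonal from a region presence vector."""
    if len(presence) < 1:
        raise ValueError("presence vector must have at least one region")
    n_present = sum(bool(p) for p in presence)
    if n_present == 0:
        raise ValueError("variant absent from every region (upstream bug)")
    if n_present == len(presence):
        return "clonal"
    if n_present == 1:
        return "subclonal"
    return "shared"


def summarize_burden(
    candidates: Sequence[EpitopeCandidate],
    patient_id: str,
    unit: str = "peptide_allele",
) -> BurdenSummary:
    """Count SB/WB candidates by clonality class and by region.

    ``unit='peptide_allele'`` counts each scored (peptide, allele) row;
    ``unit='variant'`` counts each variant once, taking its strongest binder
    class. Non-binders never enter the summary.
    """
    if unit not in ("peptide_allele", "variant"):
        raise ValueError(f"unknown counting unit {unit!r}")
    region_names: tuple[str, ...] = ()
    counts: dict[tuple[str, str], int] = {}
    per_region: dict[str, int] = {}
    binders = [c for c in candidates if c.binder_class in ("SB", "WB")]
    if unit == "variant":
        best: dict[str, EpitopeCandidate] = {}
        for c in binders:
            cur = best.get(c.variant.key)
            if cur is None or (c.binder_class == "SB" and
                               cur.binder_class == "WB"):
                best[c.variant.key] = c
        binders = list(best.values())
    for c in binders:
        if not region_names:
            region_names = c.variant.region_names
            per_region = {r: 0 for r in region_names}
        clon = classify_clonality(c.presence)
        key = (c.binder_class, clon)
        counts[key] = counts.get(key, 0) + 1
        for name, present in zip(c.variant.region_names, c.presence):
            if present:
                per_region[name] = per_region.get(name, 0) + 1
    return BurdenSummary(
        patient_id=patient_id,
        n_regions=len(region_names),
        region_names=region_names,
        counts=counts,
        per_region=per_region,
    )


def clonal_fraction(summary: BurdenSummary):
    """Fraction of counted neoantigens that are clonal (None when empty)."""
    total = summary.total
    if total == 0:
        return None
    return summary.class_total("clonal") / total
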