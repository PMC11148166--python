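"""Proximity-proteomics (TurboID) interactor filtering and set logic.

Consumes a moderated-statistics enrichment table (protein, bait,
condition, log2FC vs the nuclear-localized ligase control, adjusted p)
and applies bait-specific enrichment thresholds, removes proteins seen
only at steady state, and partitions interactor sets for Venn summaries.
"""

from __future__ import annotations

import pandas as pd

BAIT_LFC_MIN = {"STAT1": 1.0, "IRF1": 0.5}
ACTIVE_CONDITIONS = ("IFNb_3h", "IFNg_3h")


def filter_interactors(
    records: pd.DataFrame,
    bait: str,
    lfc_min: float | None = None,
    padj_max: float = 0.05,
    padj_strict: bool = True,
) -> dict:
    """Per-condition interactor sets for one bait.

    Thresholds default to the bait-specific enrichment cutoffs
    (STAT1: log2FC >= 1, IRF1: log2FC >= 0.5) with padj < 0.05 (strict by
    default, configurable). ``records`` columns: protein_id, bait,
    condition, log2fc, padj.
    """
    if lfc_min is None:
        if bait not in BAIT_LFC_MIN:
            raise ValueError(f"no default threshold for bait {bait!r}; pass lfc_min")
        lfc_min = BAIT_LFC_MIN[bait]
    sub = records[records["bait"] == bait]
    pass_p = sub["padj"] < padj_max if padj_strict else sub["padj"] <= padj_max
    kept = sub[(sub["log2fc"] >= lfc_min) & pass_p]
    return {cond: set(grp["protein_id"]) for cond, grp in kept.groupby("condition")}


def exclude_steady_only(
    per_condition: dict, active_conditions=ACTIVE_CONDITIONS
) -> set:
    """Interactors present in at least one stimulated condition.

    Proteins found exclusively at steady state are removed; a protein in
    both steady and a stimulated condition is kept.
    """
    active: set = set()
    for cond in active_conditions:
        active |= per_condition.get(cond, set())
    return active


def all_interactors(per_condition: dict) -> set:
    out: set = set()
    for members in per_condition.values():
        out |= members
    return out


def venn_partition(set_a: set, set_b: set) -> dict:
    """Disjoint partition of two sets: a_only, common, b_only with counts."""
    a_only = set_a - set_b
    common = set_a & set_b
    b_only = set_b - set_a
    return {
        "a_only": a_only,
        "common": common,
        "b_only": b_only,
        "counts": (len(a_only), len(common), len(b_only)),
    }
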