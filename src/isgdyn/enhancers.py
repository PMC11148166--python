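"""Enhancer (eRNA) linkage: from transcribed regulatory elements to genes.

Transcribed regulatory element (TRE) interval sets discovered per
condition are unioned, genic regions excluded, survivors linked to genes
whose TSS lies within 50 kb, and links filtered for trend concordance:
the TRE's eRNA signal must be significantly induced in a contrast in
which the linked gene's cluster is itself induced. ChIP peak sets then
give per-cluster bound fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import significant
from .genomic import (
    GeneAnnotation,
    IntervalSet,
    merge_intervals,
    overlap_any,
    subtract_intervals,
)


def combine_tres(tre_sets: list[IntervalSet]) -> IntervalSet:
    """Union of per-condition TRE sets, merged (bookended intervals join).

    Ids ``tre_0001`` ... are assigned in coordinate order.
    """
    frames = [t.df[["chrom", "start", "end"]] for t in tre_sets if len(t)]
    if not frames:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name"]))
    merged = merge_intervals(IntervalSet(pd.concat(frames, ignore_index=True)))
    df = merged.df.copy()
    df["name"] = [f"tre_{i + 1:05d}" for i in range(len(df))]
    return IntervalSet(df)


def exclude_genic(tres: IntervalSet, ann: GeneAnnotation, min_fragment: int = 50) -> IntervalSet:
    """Subtract gene spans (strand-ignorant) from TREs.

    Fragments shorter than ``min_fragment`` bp after subtraction are
    discarded. Fragment names inherit the source TRE id (with a suffix
    when a TRE splits into several pieces).
    """
    spans = ann.gene_spans()
    if len(tres) == 0:
        return tres
    pieces = subtract_intervals(tres, spans)
    if len(pieces) == 0:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name"]))
    df = pieces.df[(pieces.df["end"] - pieces.df["start"]) >= min_fragment].reset_index(drop=True)
    # map each fragment back to the TRE that contains it
    names = []
    src = tres.df
    if "name" not in src.columns:
        src = src.assign(name=[f"tre_{i + 1:05d}" for i in range(len(src))])
    counts: dict = {}
    for _, row in df.iterrows():
        hit = src[
            (src["chrom"] == row["chrom"]) & (src["start"] <= row["start"]) & (src["end"] >= row["end"])
        ]
        base = hit["name"].iloc[0] if len(hit) else "tre_orphan"
        counts[base] = counts.get(base, 0) + 1
        names.append(base if counts[base] == 1 else f"{base}.{counts[base]}")
    df = df.assign(name=names)
    return IntervalSet(df)


def link_to_genes(tres: IntervalSet, ann: GeneAnnotation, window: int = 50_000) -> pd.DataFrame:
    """Candidate TRE-gene links: every gene whose TSS is within ``window`` bp.

    Distance is 0 when the TRE covers the TSS, else the distance from the
    TSS to the nearest TRE boundary base. Multiple links per TRE are kept.
    """
    genes = ann.df
    rows = []
    for chrom, sub in tres.df.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if len(g) == 0:
            continue
        tss = g["tss"].to_numpy(np.int64)
        gid = g["gene_id"].to_numpy()
        for _, tre in sub.iterrows():
            s, e = int(tre["start"]), int(tre["end"])
            inside = (tss >= s) & (tss < e)
            dist = np.minimum(np.abs(s - tss), np.abs((e - 1) - tss))
            dist = np.where(inside, 0, dist)
            near = dist <= window
            for j in np.flatnonzero(near):
                rows.append((tre.get("name", f"{chrom}:{s}-{e}"), chrom, s, e, gid[j], int(dist[j])))
    return pd.DataFrame(
        rows, columns=["tre_id", "chrom", "start", "end", "gene_id", "distance_to_tss"]
    )


def induced_contrasts_per_cluster(
    de_per_condition: dict,
    assignment,
    lfc_min: float = 1.0,
    padj_max: float = 0.01,
    min_fraction: float = 0.5,
) -> dict:
    """Contrasts in which each cluster counts as induced.

    A cluster is induced in a contrast when at least ``min_fraction`` of
    its genes are significantly up there.
    """
    out: dict = {}
    for cid in assignment.cluster_ids:
        genes = assignment.genes_in(cid)
        induced = []
        for cond, de in de_per_condition.items():
            sig_up = significant(de, lfc_min=lfc_min, padj_max=padj_max, direction="up")
            frac = len(genes.intersection(sig_up)) / max(len(genes), 1)
            if frac >= min_fraction:
                induced.append(cond)
        out[cid] = induced
    return out


def concordance_filter(
    links: pd.DataFrame,
    tre_de_per_condition: dict,
    assignment,
    lfc_min: float = 1.0,
    padj_max: float = 0.01,
    cluster_induced: dict | None = None,
    de_per_condition: dict | None = None,
) -> pd.DataFrame:
    """Keep links whose TRE tracks its gene's induction.

    A link is concordant when the TRE is significantly induced
    (log2fc >= lfc_min, padj < padj_max in the both-strand eRNA counts) in
    at least one contrast in which the linked gene's cluster is induced.
    ``cluster_induced`` maps cluster_id -> contrast names; if absent it is
    derived from ``de_per_condition``.
    """
    if cluster_induced is None:
        if de_per_condition is None:
            raise ValueError("need cluster_induced or de_per_condition")
        cluster_induced = induced_contrasts_per_cluster(
            de_per_condition, assignment, lfc_min=lfc_min, padj_max=padj_max
        )
    sig_by_cond = {
        cond: set(significant(de, lfc_min=lfc_min, padj_max=padj_max, direction="up"))
        for cond, de in tre_de_per_condition.items()
    }
    out = links.copy()
    out["cluster_id"] = out["gene_id"].map(assignment.labels)
    concordant = []
    for _, row in out.iterrows():
        cid = row["cluster_id"]
        conds = cluster_induced.get(cid, []) if pd.notna(cid) else []
        concordant.append(any(row["tre_id"] in sig_by_cond.get(c, set()) for c in conds))
    out["concordant"] = concordant
    return out[out["concordant"]].reset_index(drop=True)


def bound_fraction(
    enhancers: pd.DataFrame, peak_sets: dict, assignment=None
) -> pd.DataFrame:
    """Per-cluster fraction of enhancers overlapping each factor's peaks.

    ``enhancers`` is a (filtered) link table with tre_id/chrom/start/end
    and either a cluster_id column or a gene_id column resolvable through
    ``assignment``; ``peak_sets`` maps factor name -> IntervalSet (the
    union of that factor's peaks across timepoints). Bound means >= 1 bp
    overlap. One row per (factor, cluster).
    """
    enh = enhancers.drop_duplicates(subset=["tre_id"]).reset_index(drop=True)
    if "cluster_id" not in enh.columns:
        if assignment is None:
            raise ValueError("need a cluster_id column or an assignment")
        enh = enh.assign(cluster_id=enh["gene_id"].map(assignment.labels))
    ivs = IntervalSet(enh[["chrom", "start", "end"]].assign(name=enh["tre_id"].values))
    rows = []
    for factor, peaks in peak_sets.items():
        flags = overlap_any(ivs, peaks)
        bound_map = dict(zip(ivs.df["name"], flags))
        enh_flagged = enh.assign(bound=enh["tre_id"].map(bound_map))
        for cid, grp in enh_flagged.groupby("cluster_id", sort=True):
            n, nb = len(grp), int(grp["bound"].sum())
            rows.append((factor, cid, n, nb, nb / n if n else np.nan))
    return pd.DataFrame(rows, columns=["factor", "cluster_id", "n_enhancers", "n_bound", "fraction"])
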