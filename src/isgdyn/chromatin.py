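"""ATAC–PRO integration: accessibility peaks, dependence calls, trends.

Accessibility peaks are annotated to their nearest TSS (within 2 kb);
genes are then classified by whether their induction depends on a
transcription factor (knockout reduces transcription) and whether that
dependence extends to chromatin accessibility. Category names follow the
volcano-plot color scheme: 'induced' (dark blue), 'tf_dependent'
(violet), 'tf_and_accessibility' (yellow); yellow is a subset of violet
by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import significant
from .genomic import GeneAnnotation, IntervalSet


def annotate_atac_to_genes(
    atac_peaks: IntervalSet, ann: GeneAnnotation, max_distance: int = 2000
) -> pd.DataFrame:
    """Assign each accessibility peak to its nearest TSS.

    Peaks farther than ``max_distance`` bp from every TSS are dropped.
    Distance is 0 when the peak covers the TSS, else from the nearest peak
    boundary. Returns peak_id/gene_id/distance; a gene may receive several
    peaks.
    """
    rows = []
    genes = ann.df
    peaks = atac_peaks.df
    if "name" not in peaks.columns:
        peaks = peaks.assign(name=[f"peak_{i + 1:05d}" for i in range(len(peaks))])
    for chrom, sub in peaks.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if len(g) == 0:
            continue
        tss = g["tss"].to_numpy(np.int64)
        gid = g["gene_id"].to_numpy()
        for _, pk in sub.iterrows():
            s, e = int(pk["start"]), int(pk["end"])
            inside = (tss >= s) & (tss < e)
            dist = np.where(inside, 0, np.minimum(np.abs(s - tss), np.abs((e - 1) - tss)))
            j = int(np.argmin(dist))
            if dist[j] <= max_distance:
                rows.append((pk["name"], chrom, s, e, gid[j], int(dist[j])))
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "gene_id", "distance"])


def gene_level_atac_de(atac_de: pd.DataFrame, peak_to_gene: pd.DataFrame) -> pd.DataFrame:
    """Collapse peak-level accessibility DE to genes.

    Each gene takes its most significant assigned peak (smallest padj; NA
    padj last). ``atac_de`` is indexed by peak_id with log2fc/padj.
    """
    joined = peak_to_gene.merge(
        atac_de[["log2fc", "padj"]], left_on="peak_id", right_index=True, how="left"
    )
    joined = joined.sort_values(["padj"], na_position="last", kind="mergesort")
    best = joined.drop_duplicates(subset=["gene_id"]).set_index("gene_id")
    return best[["peak_id", "log2fc", "padj"]]


def classify_dependence(
    gene_de_wt: dict,
    gene_de_ko_vs_wt: dict,
    atac_de_gene: dict,
    tf: str,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Dual-criterion dependence classification (per gene, one TF).

    * induced: up in WT (log2fc >= lfc_min, padj <= padj_max) under either
      IFN at the matched timepoint (``gene_de_wt``: treatment -> DE frame).
    * tf_dependent (violet): induced AND down in the knockout vs WT
      (log2fc <= -lfc_min, padj <= padj_max) in transcription, under any
      provided condition (``gene_de_ko_vs_wt``: condition -> DE frame).
    * tf_and_accessibility (yellow): violet AND accessibility down in the
      knockout (same thresholds) in at least one provided accessibility
      contrast (``atac_de_gene``: condition -> gene-level DE frame, the OR
      over IFN treatment and homeostasis). Genes with no assigned
      accessibility peak cannot be yellow and are flagged ``no_peak``.
    """
    induced_by: dict = {}
    for treatment, de in gene_de_wt.items():
        up = significant(
            de, lfc_min=lfc_min, padj_max=padj_max, direction="up", padj_inclusive=True
        )
        for gene in up:
            induced_by.setdefault(gene, set()).add(treatment)
    tf_dep = set()
    for _, de in gene_de_ko_vs_wt.items():
        tf_dep |= set(
            significant(de, lfc_min=lfc_min, padj_max=padj_max, direction="down", padj_inclusive=True)
        )
    acc_dep = set()
    genes_with_peak = set()
    for _, de in atac_de_gene.items():
        genes_with_peak |= set(de.index[de["padj"].notna()])
        acc_dep |= set(
            significant(de, lfc_min=lfc_min, padj_max=padj_max, direction="down", padj_inclusive=True)
        )
    rows = []
    for gene, treatments in sorted(induced_by.items()):
        transcription_dependent = gene in tf_dep
        accessibility_dependent = transcription_dependent and gene in acc_dep
        if accessibility_dependent:
            category = "tf_and_accessibility"
        elif transcription_dependent:
            category = "tf_dependent"
        else:
            category = "induced_only"
        rows.append(
            {
                "gene_id": gene,
                "induced_by": ",".join(sorted(treatments)),
                "tf": tf,
                "transcription_dependent": transcription_dependent,
                "accessibility_dependent": accessibility_dependent,
                "category": category,
                "no_peak": gene not in genes_with_peak,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "induced_by",
            "tf",
            "transcription_dependent",
            "accessibility_dependent",
            "category",
            "no_peak",
        ],
    )


def trend_concordance(
    pro_z: pd.DataFrame, atac_z: pd.DataFrame, assignment=None
) -> tuple[pd.Series, pd.DataFrame]:
    """Correlate transcription and accessibility z-profiles per gene.

    Both inputs are gene x matched-condition z-score matrices with
    identical column meaning (e.g. untreated/early/late per treatment on
    each assay's own timepoint grid). Returns per-gene Pearson r (NaN for
    constant rows, excluded from medians) and, when an assignment is
    given, per-cluster median trend lines of both assays.
    """
    common = pro_z.index.intersection(atac_z.index)
    a = pro_z.loc[common].to_numpy(float)
    b = atac_z.loc[common].to_numpy(float)
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum(axis=1) * (b_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a_c * b_c).sum(axis=1) / denom, np.nan)
    r = pd.Series(r, index=common, name="pearson_r")
    medians = pd.DataFrame()
    if assignment is not None:
        rows = []
        labels = assignment.labels.reindex(common)
        for cid in assignment.cluster_ids:
            genes = common[labels == cid]
            if len(genes) == 0:
                continue
            for cond in pro_z.columns:
                rows.append(
                    (
                        cid,
                        cond,
                        float(pro_z.loc[genes, cond].median()),
                        float(atac_z.loc[genes, cond].median()),
                        float(r.loc[genes].median(skipna=True)),
                        len(genes),
                    )
                )
        medians = pd.DataFrame(
            rows,
            columns=["cluster_id", "condition", "pro_median_z", "atac_median_z", "median_r", "n_genes"],
        )
    return r, medians
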