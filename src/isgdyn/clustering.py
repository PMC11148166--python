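"""Temporal clustering of differentially transcribed genes.

Pools the top differentially transcribed genes per condition, z-scores
condition-averaged VST profiles separately per IFN type, clusters with the
Ward.D2 criterion (squared Euclidean distances inside the merge
criterion), and summarizes per-cluster trends. Also PCA on the most
variable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .diffexpr import significant
from .genomic import SampleDesign

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """gene_id -> cluster_id in 1..k, with the linkage record."""

    labels: pd.Series  # index gene_id, values int
    linkage: np.ndarray
    k: int

    def genes_in(self, cluster_id: int) -> pd.Index:
        return self.labels.index[self.labels == cluster_id]

    @property
    def cluster_ids(self) -> list:
        return sorted(self.labels.unique())


def pool_top_genes(
    de_per_condition: dict,
    n: int = 1000,
    lfc_min: float = 1.0,
    padj_max: float = 0.01,
) -> pd.Index:
    """Union over conditions of the top-n significant genes per condition.

    Per condition, genes passing |log2fc| >= lfc_min and padj < padj_max
    are ordered by padj (ties: larger |log2fc|, then gene id) and the first
    n retained. Conditions with fewer than n significant genes contribute
    all of them.
    """
    pooled: set = set()
    for cond, de in de_per_condition.items():
        sig = significant(de, lfc_min=lfc_min, padj_max=padj_max, direction="both")
        sub = de.loc[sig, ["padj", "log2fc"]].copy()
        sub["abs_lfc"] = sub["log2fc"].abs()
        sub["gene"] = sub.index
        sub = sub.sort_values(
            ["padj", "abs_lfc", "gene"], ascending=[True, False, True], kind="mergesort"
        )
        top = sub.index[:n]
        if len(sig) < n:
            logger.info("condition %s: only %d significant genes (< %d)", cond, len(sig), n)
        pooled.update(top)
    return pd.Index(sorted(pooled))


def condition_means(
    vst_matrix: pd.DataFrame, design: SampleDesign, genotypes=("WT",)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average replicates into condition columns.

    Returns (means, meta) where means columns are condition labels and meta
    maps each label to (genotype, treatment, timepoint_h).
    """
    df = design.df[design.df["genotype"].isin(genotypes)]
    cols, meta = {}, []
    for (gt, tr, tp), grp in df.groupby(["genotype", "treatment", "timepoint_h"], sort=True):
        label = f"{gt}_untreated" if tr == "untreated" else f"{gt}_{tr}_{tp:g}h"
        cols[label] = vst_matrix[grp["sample_id"].tolist()].mean(axis=1)
        meta.append((label, gt, tr, tp))
    means = pd.DataFrame(cols)
    meta = pd.DataFrame(meta, columns=["condition", "genotype", "treatment", "timepoint_h"]).set_index(
        "condition"
    )
    return means, meta


def zscore_profiles(
    vst_matrix: pd.DataFrame,
    genes: pd.Index,
    design: SampleDesign,
    scope: str = "wt_only",
) -> pd.DataFrame:
    """Per-gene z-scores of condition-averaged VST, separately per IFN type.

    Each IFN-type block contains that treatment's conditions plus the
    untreated baseline(s) for the in-scope genotypes; within a block each
    gene is scaled to mean 0, sd 1 across conditions (constant rows map to
    zeros). ``scope`` is 'wt_only' or 'all_genotypes'.
    """
    genotypes = ("WT",) if scope == "wt_only" else ("WT", "Irf9KO", "Irf1KO")
    means, meta = condition_means(vst_matrix.loc[genes], SampleDesign(design.df), genotypes)
    blocks = []
    for ifn in ("IFNb", "IFNg"):
        cols = meta.index[(meta["treatment"] == ifn) | (meta["treatment"] == "untreated")]
        block = means[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        z = block.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
        z.columns = [f"{ifn}|{c}" for c in cols]
        blocks.append(z)
    return pd.concat(blocks, axis=1)


def ward_cluster(z: pd.DataFrame, k: int = 11) -> ClusterAssignment:
    """Ward.D2 hierarchical clustering of gene profiles, cut into k clusters.

    Uses the Ward criterion on Euclidean distances (scipy's 'ward', the
    Ward.D2 convention) and renumbers clusters by decreasing size
    (ties: smaller original label first).
    """
    if k > len(z):
        raise ValueError(f"k={k} exceeds number of genes ({len(z)})")
    Z = linkage(z.to_numpy(float), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series([remap[c] for c in raw], index=z.index, name="cluster_id")
    return ClusterAssignment(labels=labels, linkage=Z, k=int(labels.max()))


def trend_summary(z: pd.DataFrame, assignment: ClusterAssignment) -> pd.DataFrame:
    """Mean and median z per cluster x condition (long form)."""
    rows = []
    for cid in assignment.cluster_ids:
        sub = z.loc[assignment.genes_in(cid)]
        for cond in z.columns:
            rows.append(
                (cid, cond, float(sub[cond].mean()), float(sub[cond].median()), len(sub))
            )
    return pd.DataFrame(rows, columns=["cluster_id", "condition", "mean_z", "median_z", "n_genes"])


def pca_top_variable(vst_matrix: pd.DataFrame, n: int = 500) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples using the n most variable genes.

    Returns (sample coordinates with PC columns, fraction of variance
    explained per PC). Genes are ranked by variance across samples; the
    data are centered per gene but not scaled.
    """
    variances = vst_matrix.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[: min(n, len(variances))]
    X = vst_matrix.loc[top].to_numpy(float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U * S
    var_explained = (S**2) / np.sum(S**2) if np.sum(S**2) > 0 else np.zeros_like(S)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=vst_matrix.columns, columns=cols), var_explained
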