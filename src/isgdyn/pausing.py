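"""Pol II pausing-index analysis.

The pausing index (PI) of a gene is the ratio of promoter-proximal signal
density (cpm/bp in the first 500 bp downstream of the TSS) to gene-body
density (cpm/bp over the body, excluding the last 500 bp). Treatment
effects are expressed as natural-log ratios of treated to untreated PI,
and compared per cluster with a two-sided Mann–Whitney U test.

PI is undefined (and the gene dropped pairwise, not globally) whenever
either density is zero. Because PI is a ratio of densities from the same
library, it is invariant to library size.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def pausing_index(tss_density, body_density):
    """PI = tss_density / body_density; NaN when either density is zero."""
    tss = np.asarray(tss_density, dtype=float)
    body = np.asarray(body_density, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where((body > 0) & (tss > 0), tss / body, np.nan)
    return pi if pi.ndim else float(pi)


def pausing_table(
    tss_counts, body_counts, library_sizes: pd.Series
) -> pd.DataFrame:
    """Per-gene, per-sample PI from TSS-region and body-region count matrices.

    Both inputs are CountMatrix objects over the same samples;
    ``library_sizes`` are whole-sample totals. Genes present in only one
    matrix are dropped.
    """
    common = tss_counts.feature_ids.intersection(body_counts.feature_ids)
    rows = []
    for sample_id in tss_counts.sample_ids:
        lib = library_sizes[sample_id]
        tss_d = (tss_counts.values.loc[common, sample_id] / lib * 1e6) / tss_counts.lengths.loc[common]
        body_d = (body_counts.values.loc[common, sample_id] / lib * 1e6) / body_counts.lengths.loc[common]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": common,
                    "sample_id": sample_id,
                    "tss_density": tss_d.values,
                    "body_density": body_d.values,
                    "pi": pausing_index(tss_d.values, body_d.values),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def condition_pausing(
    tss_counts, body_counts, design, library_sizes: pd.Series, genotype: str = "WT"
) -> pd.DataFrame:
    """Condition-level PI from replicate-pooled counts.

    Replicate counts (and library sizes) are summed within each
    (treatment, timepoint) condition of one genotype before densities are
    formed, so each gene gets one PI per condition.
    """
    sub = design.df[design.df["genotype"] == genotype]
    common = tss_counts.feature_ids.intersection(body_counts.feature_ids)
    out = []
    for (tr, tp), grp in sub.groupby(["treatment", "timepoint_h"], sort=True):
        samples = grp["sample_id"].tolist()
        lib = float(sum(library_sizes[s] for s in samples))
        tss_sum = tss_counts.values.loc[common, samples].sum(axis=1)
        body_sum = body_counts.values.loc[common, samples].sum(axis=1)
        tss_d = (tss_sum / lib * 1e6) / tss_counts.lengths.loc[common]
        body_d = (body_sum / lib * 1e6) / body_counts.lengths.loc[common]
        out.append(
            pd.DataFrame(
                {
                    "gene_id": common,
                    "treatment": tr,
                    "timepoint_h": tp,
                    "tss_density": tss_d.values,
                    "body_density": body_d.values,
                    "pi": pausing_index(tss_d.values, body_d.values),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def pausing_log_ratio(pi_treated, pi_untreated):
    """Natural-log ratio ln(PI_treated / PI_untreated); NaN propagates."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(np.asarray(pi_treated, dtype=float) / np.asarray(pi_untreated, dtype=float))


def pausing_contrasts(cond_pi: pd.DataFrame, assignment=None) -> pd.DataFrame:
    """Per-gene ln PI ratios of each treated condition vs untreated.

    Genes lacking a defined PI in either member of a pair are excluded for
    that pair only (pairwise deletion).
    """
    untreated = cond_pi[cond_pi["treatment"] == "untreated"].set_index("gene_id")["pi"]
    rows = []
    for (tr, tp), grp in cond_pi[cond_pi["treatment"] != "untreated"].groupby(
        ["treatment", "timepoint_h"], sort=True
    ):
        g = grp.set_index("gene_id")
        base = untreated.reindex(g.index)
        lr = pausing_log_ratio(g["pi"].to_numpy(), base.to_numpy())
        sub = pd.DataFrame(
            {
                "gene_id": g.index,
                "treatment": tr,
                "timepoint_h": tp,
                "pi_treated": g["pi"].to_numpy(),
                "pi_untreated": base.to_numpy(),
                "log_ratio": lr,
            }
        ).dropna(subset=["log_ratio"])
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    if assignment is not None:
        out["cluster_id"] = out["gene_id"].map(assignment.labels)
    return out


def mannwhitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact enumeration when both n <= 8.

    The exact branch enumerates all label assignments of the pooled sample
    (handling ties through midranks); otherwise the normal approximation
    with tie correction (and continuity correction) is used. Returns
    (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if min(n1, n2) == 0:
        raise ValueError("empty group")
    if n1 <= 8 and n2 <= 8:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        total = 0
        as_extreme = 0
        mu = n1 * n2 / 2.0
        d_obs = abs(u_obs - mu) - 1e-9
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= d_obs:
                as_extreme += 1
        return float(u_obs), as_extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def cluster_pausing_test(
    pi_table: pd.DataFrame,
    assignment,
    treatment: str,
    timepoint_h: float,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per-cluster Mann–Whitney U of gene-level PI, untreated vs treated.

    ``pi_table`` is the condition-level table from :func:`condition_pausing`.
    Clusters with fewer than ``min_genes`` genes with defined PI in both
    conditions get NA with a logged reason.
    """
    untreated = pi_table[pi_table["treatment"] == "untreated"].set_index("gene_id")["pi"]
    treated = pi_table[
        (pi_table["treatment"] == treatment) & (pi_table["timepoint_h"] == timepoint_h)
    ].set_index("gene_id")["pi"]
    rows = []
    for cid in assignment.cluster_ids:
        genes = assignment.genes_in(cid)
        u = untreated.reindex(genes).dropna()
        t = treated.reindex(genes).dropna()
        both = u.index.intersection(t.index)
        if len(both) < min_genes:
            logger.info("cluster %s: only %d genes with defined PI; test skipped", cid, len(both))
            rows.append((cid, treatment, timepoint_h, len(both), np.nan, np.nan, np.nan))
            continue
        u_stat, p = mannwhitney_u(u.loc[both].to_numpy(), t.loc[both].to_numpy())
        med_lr = float(np.median(np.log(t.loc[both] / u.loc[both])))
        rows.append((cid, treatment, timepoint_h, len(both), u_stat, p, med_lr))
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "treatment", "timepoint_h", "n_genes", "u_stat", "p", "median_log_ratio"],
    )
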