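"""Strand-aware windowed counting from base-resolution coverage.

Gene-level windows are defined in transcription direction: the first
``tss_offset`` bases downstream of the TSS are the promoter-proximal (TSS)
region, the remainder the gene body. Gene counting is same-strand only;
regulatory-element counting sums both strands. Counts are rounded half-up
to integers so downstream negative-binomial machinery sees integer counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genomic import CountMatrix, GeneAnnotation, IntervalSet, StrandedCoverage

logger = logging.getLogger(__name__)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5).astype(np.int64)


def _gene_windows(ann: GeneAnnotation, offset5: int, trim3: int) -> pd.DataFrame:
    """Half-open windows [start+offset5, end-trim3) in transcription direction.

    Returns a frame with genomic window_start/window_end and length; genes
    whose window is empty get length <= 0 and are filtered by callers.
    """
    df = ann.df
    plus = (df["strand"] == "+").to_numpy()
    w_start = np.where(plus, df["start"] + offset5, df["start"] + trim3)
    w_end = np.where(plus, df["end"] - trim3, df["end"] - offset5)
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "strand": df["strand"],
            "window_start": w_start,
            "window_end": w_end,
            "length_bp": w_end - w_start,
        }
    )


def _count_windows(
    coverages: dict, windows: pd.DataFrame, same_strand: bool = True
) -> CountMatrix:
    counts = {}
    for sample_id, cov in coverages.items():
        vals = np.zeros(len(windows))
        for (chrom, strand), idx in windows.groupby(["chrom", "strand"], sort=False).groups.items():
            sub = windows.loc[idx]
            if same_strand:
                if not any(c == chrom for c, _ in cov.keys()):
                    logger.warning("chromosome %s absent from coverage of %s", chrom, sample_id)
                w = cov.window_sums(chrom, strand, sub["window_start"], sub["window_end"])
            else:
                w = cov.window_sum_bothstrands(chrom, sub["window_start"], sub["window_end"])
            vals[windows.index.get_indexer(idx)] = w
        counts[sample_id] = _round_half_up(vals)
    values = pd.DataFrame(counts, index=windows["gene_id"].values)
    lengths = pd.Series(windows["length_bp"].values, index=windows["gene_id"].values, name="length_bp")
    return CountMatrix(values, lengths)


def count_gene_bodies(
    coverages: dict,
    ann: GeneAnnotation,
    tss_offset: int = 500,
    min_body: int = 1000,
) -> CountMatrix:
    """Gene-body counts: window [tss + tss_offset, gene 3' end), same strand.

    The first ``tss_offset`` bases downstream of the TSS are omitted to
    avoid promoter-proximal pausing bias; genes whose remaining body is
    shorter than ``min_body`` are excluded from the output.

    ``coverages`` maps sample_id -> StrandedCoverage.
    """
    windows = _gene_windows(ann, offset5=tss_offset, trim3=0)
    keep = windows["length_bp"] >= min_body
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d genes with gene body < %d bp", n_dropped, min_body)
    return _count_windows({k: v for k, v in coverages.items()}, windows[keep].reset_index(drop=True))


def count_tss_regions(coverages: dict, ann: GeneAnnotation, width: int = 500) -> CountMatrix:
    """Promoter-proximal counts: window [tss, tss + width), same strand."""
    windows = _gene_windows(ann, offset5=0, trim3=0)
    plus = (windows["strand"] == "+").to_numpy()
    gene_len = windows["length_bp"].to_numpy()
    w = np.minimum(width, gene_len)  # clip to gene span for very short genes
    windows["window_end"] = np.where(plus, windows["window_start"] + w, windows["window_end"])
    windows["window_start"] = np.where(plus, windows["window_start"], windows["window_end"] - w)
    windows["length_bp"] = w
    return _count_windows(coverages, windows)


def count_body_for_pausing(
    coverages: dict, ann: GeneAnnotation, tss_offset: int = 500, tail_trim: int = 500
) -> CountMatrix:
    """Pausing-analysis body counts: [tss + tss_offset, 3' end - tail_trim).

    Genes whose trimmed body is empty are excluded.
    """
    windows = _gene_windows(ann, offset5=tss_offset, trim3=tail_trim)
    keep = windows["length_bp"] > 0
    return _count_windows(coverages, windows[keep].reset_index(drop=True))


def count_regions_bothstrands(coverages: dict, regions: IntervalSet) -> CountMatrix:
    """Per-region counts summing both strands (regulatory-element counting)."""
    df = regions.df.copy()
    if "name" not in df.columns:
        df["name"] = [f"region_{i}" for i in range(len(df))]
    windows = pd.DataFrame(
        {
            "gene_id": df["name"].values,
            "chrom": df["chrom"].values,
            "strand": ".",
            "window_start": df["start"].values,
            "window_end": df["end"].values,
            "length_bp": (df["end"] - df["start"]).values,
        }
    )
    return _count_windows(coverages, windows, same_strand=False)


def densities(counts: CountMatrix, library_sizes: pd.Series) -> pd.DataFrame:
    """Long-form cpm/bp densities: (count / library_size * 1e6) / length_bp.

    ``library_sizes`` must be whole-sample library sizes (total coverage
    signal), not sums over the counted subset.
    """
    lib = pd.Series(library_sizes)
    missing = [s for s in counts.sample_ids if s not in lib.index]
    if missing:
        raise ValueError(f"library sizes missing for samples: {missing}")
    rows = []
    for sample_id in counts.sample_ids:
        cpm_bp = (counts.values[sample_id] / lib[sample_id] * 1e6) / counts.lengths
        rows.append(
            pd.DataFrame(
                {
                    "feature_id": counts.feature_ids,
                    "sample_id": sample_id,
                    "count": counts.values[sample_id].values,
                    "length_bp": counts.lengths.values,
                    "cpm_per_bp": cpm_bp.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
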