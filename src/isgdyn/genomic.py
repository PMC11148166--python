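"""Core genomic domain types and exact interval algebra.

All coordinates are 0-based half-open ``[start, end)`` (BED/bedGraph
convention); 1-based inclusive inputs (GTF) are converted at the boundary.
Interval operations follow bedtools semantics: bookended intervals merge,
overlap requires at least one shared base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss", "tes"]
INTERVAL_COLUMNS = ["chrom", "start", "end"]


# ---------------------------------------------------------------------------
# GeneAnnotation
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    """Gene models: one record per gene, with strand-aware TSS/TES.

    ``df`` columns: gene_id, chrom, strand (+/-), start, end, tss, tes.
    On the plus strand tss == start and tes == end - 1; on the minus strand
    tss == end - 1 and tes == start (positions of the 5' and 3' terminal
    bases in transcription direction).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        missing = [c for c in ("gene_id", "chrom", "strand", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_id in annotation: {dupes[:5]}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
            raise ValueError(f"start >= end for genes: {bad[:5]}")
        plus = df["strand"] == "+"
        df["tss"] = np.where(plus, df["start"], df["end"] - 1)
        df["tes"] = np.where(plus, df["end"] - 1, df["start"])
        self.df = df[ANNOTATION_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.df["gene_id"])

    def gene_spans(self) -> "IntervalSet":
        """Gene spans as an unstranded interval set (name = gene_id)."""
        return IntervalSet(
            self.df[["chrom", "start", "end"]].assign(name=self.df["gene_id"].values)
        )

    def subset(self, gene_ids) -> "GeneAnnotation":
        keep = self.df["gene_id"].isin(set(gene_ids))
        return GeneAnnotation(self.df.loc[keep])


# ---------------------------------------------------------------------------
# IntervalSet
# ---------------------------------------------------------------------------


@dataclass
class IntervalSet:
    """A set of genomic intervals, optionally named/scored/stranded.

    Records are kept sorted by (chrom, start, end). Intervals are 0-based
    half-open and must satisfy start < end.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in INTERVAL_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"interval set missing column {col!r}")
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end[, name[, score[, strand]]])."""
        cols = ["chrom", "start", "end", "name", "score", "strand"]
        rows = [tuple(r) for r in records]
        width = max((len(r) for r in rows), default=3)
        return cls(pd.DataFrame(rows, columns=cols[:width]))

    def chroms(self):
        return self.df["chrom"].unique()

    def _by_chrom(self, chrom: str):
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)


def merge_intervals(a: IntervalSet) -> IntervalSet:
    """Union of intervals as a minimal disjoint set (bookended merged)."""
    out = []
    for chrom in a.chroms():
        starts, ends = a._by_chrom(chrom)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or bookend
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return IntervalSet(pd.DataFrame(out, columns=INTERVAL_COLUMNS))


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b`` (bedtools subtract semantics)."""
    if len(b) == 0:
        return IntervalSet(a.df[INTERVAL_COLUMNS])
    b_merged = merge_intervals(b)
    out = []
    for chrom in a.chroms():
        a_starts, a_ends = a._by_chrom(chrom)
        b_starts, b_ends = b_merged._by_chrom(chrom)
        if len(b_starts) == 0:
            out.extend((chrom, s, e) for s, e in zip(a_starts, a_ends))
            continue
        for s, e in zip(a_starts, a_ends):
            # b intervals possibly overlapping [s, e)
            lo = int(np.searchsorted(b_ends, s, side="right"))
            cursor = s
            for bs, be in zip(b_starts[lo:], b_ends[lo:]):
                if bs >= e:
                    break
                if bs > cursor:
                    out.append((chrom, cursor, bs))
                cursor = max(cursor, be)
                if cursor >= e:
                    break
            if cursor < e:
                out.append((chrom, cursor, e))
    return IntervalSet(pd.DataFrame(out, columns=INTERVAL_COLUMNS))


def overlap_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Per record of ``a``: True iff >= 1 bp overlap with any record of ``b``.

    Flags are returned in the (sorted) record order of ``a.df``.
    """
    flags = np.zeros(len(a), dtype=bool)
    if len(b) == 0 or len(a) == 0:
        return flags
    b_merged = merge_intervals(b)
    for chrom in a.chroms():
        mask = (a.df["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = a.df.loc[mask, "start"].to_numpy(np.int64)
        ends = a.df.loc[mask, "end"].to_numpy(np.int64)
        b_starts, b_ends = b_merged._by_chrom(chrom)
        if len(b_starts) == 0:
            continue
        # candidate b interval: the first whose end is > a.start
        idx = np.searchsorted(b_ends, starts, side="right")
        hit = (idx < len(b_starts)) & (b_starts[np.minimum(idx, len(b_starts) - 1)] < ends)
        flags[np.flatnonzero(mask)] = hit
    return flags


def distance_to_tss(interval: tuple, ann: GeneAnnotation) -> pd.Series:
    """Distance (bp) from one interval to each gene's TSS.

    ``interval`` is (chrom, start, end). Distance is 0 when the TSS lies
    within [start, end), else the distance from the TSS to the nearest
    covered base, min(|start - tss|, |end - 1 - tss|). Genes on other
    chromosomes get NaN.
    """
    chrom, start, end = interval
    tss = ann.df["tss"].to_numpy(np.int64)
    inside = (tss >= start) & (tss < end)
    dist = np.minimum(np.abs(start - tss), np.abs((end - 1) - tss)).astype(float)
    dist[inside] = 0.0
    dist[(ann.df["chrom"] != chrom).to_numpy()] = np.nan
    return pd.Series(dist, index=ann.df["gene_id"].values, name="distance")


# ---------------------------------------------------------------------------
# StrandedCoverage
# ---------------------------------------------------------------------------


class StrandedCoverage:
    """Base-resolution stranded signal: (chrom, strand) -> position counts.

    Stores, per (chrom, strand), a sorted position array and matching
    non-negative count array (sparse representation of a PRO-seq style
    3'-end coverage track). ``library_size`` is the total signal over both
    strands.
    """

    def __init__(self, tracks: dict | None = None):
        # tracks: {(chrom, strand): (positions int64 sorted, counts float64)}
        self._tracks: dict = {}
        if tracks:
            for key, (pos, cnt) in tracks.items():
                self._set_track(key, np.asarray(pos), np.asarray(cnt))

    def _set_track(self, key, pos, cnt) -> None:
        pos = np.asarray(pos, dtype=np.int64)
        cnt = np.asarray(cnt, dtype=np.float64)
        if np.any(cnt < 0):
            raise ValueError("coverage counts must be non-negative")
        order = np.argsort(pos, kind="mergesort")
        pos, cnt = pos[order], cnt[order]
        if np.any(np.diff(pos) == 0):
            # collapse duplicate positions
            upos, inv = np.unique(pos, return_inverse=True)
            ucnt = np.bincount(inv, weights=cnt)
            pos, cnt = upos, ucnt
        keep = cnt > 0
        self._tracks[key] = (pos[keep], cnt[keep], np.concatenate([[0.0], np.cumsum(cnt[keep])]))

    @classmethod
    def from_positions(cls, events: dict) -> "StrandedCoverage":
        """Build from {(chrom, strand): array of read positions} (one count per entry)."""
        cov = cls()
        for key, positions in events.items():
            positions = np.asarray(positions, dtype=np.int64)
            if positions.size == 0:
                continue
            upos, cnts = np.unique(positions, return_counts=True)
            cov._set_track(key, upos, cnts.astype(float))
        return cov

    @property
    def library_size(self) -> float:
        return float(sum(cs[-1] for _, _, cs in self._tracks.values()))

    def keys(self):
        return self._tracks.keys()

    def track(self, chrom: str, strand: str):
        pos, cnt, _ = self._tracks.get((chrom, strand), (np.empty(0, np.int64), np.empty(0), np.zeros(1)))
        return pos, cnt

    def window_sums(self, chrom: str, strand: str, starts, ends) -> np.ndarray:
        """Total signal in each half-open window [start, end) on one strand."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        entry = self._tracks.get((chrom, strand))
        if entry is None:
            return np.zeros(len(starts))
        pos, _, csum = entry
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="left")
        return csum[i1] - csum[i0]

    def window_sum_bothstrands(self, chrom: str, starts, ends) -> np.ndarray:
        return self.window_sums(chrom, "+", starts, ends) + self.window_sums(chrom, "-", starts, ends)


# ---------------------------------------------------------------------------
# SampleDesign
# ---------------------------------------------------------------------------

GENOTYPES = ("WT", "Irf9KO", "Irf1KO")
TREATMENTS = ("untreated", "IFNb", "IFNg")
TIMEPOINTS_H = (0.0, 1.5, 4.0, 24.0, 48.0)


@dataclass
class SampleDesign:
    """Sample sheet: sample_id -> (genotype, treatment, timepoint_h, replicate)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        required = ["sample_id", "genotype", "treatment", "timepoint_h", "replicate"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        key = df[["genotype", "treatment", "timepoint_h", "replicate"]]
        if key.duplicated().any():
            raise ValueError("duplicate (genotype, treatment, timepoint, replicate)")
        untr = df["treatment"] == "untreated"
        if not ((df.loc[untr, "timepoint_h"] == 0).all() and (df.loc[~untr, "timepoint_h"] > 0).all()):
            raise ValueError("untreated samples must (and only they may) have timepoint 0")
        self.df = df[required]

    def __len__(self) -> int:
        return len(self.df)

    def samples_for(self, genotype=None, treatment=None, timepoint_h=None) -> list:
        df = self.df
        if genotype is not None:
            df = df[df["genotype"] == genotype]
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        if timepoint_h is not None:
            df = df[df["timepoint_h"] == timepoint_h]
        return df["sample_id"].tolist()

    def condition_label(self, sample_id: str) -> str:
        row = self.df.set_index("sample_id").loc[sample_id]
        if row["treatment"] == "untreated":
            return f"{row['genotype']}_untreated"
        return f"{row['genotype']}_{row['treatment']}_{row['timepoint_h']:g}h"


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts with region lengths."""

    values: pd.DataFrame  # index: feature_id, columns: sample_id
    lengths: pd.Series = field(default=None)  # bp per feature

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lengths is None:
            self.lengths = pd.Series(1, index=self.values.index, name="length_bp")
        self.lengths = self.lengths.reindex(self.values.index)
        if self.lengths.isna().any():
            raise ValueError("region_lengths missing for some features")
        if (self.lengths <= 0).any():
            raise ValueError("region_lengths must be positive")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.values[list(sample_ids)], self.lengths)

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(feature_ids)], self.lengths)
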