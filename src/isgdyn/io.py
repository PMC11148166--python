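"""Readers and writers for the plain-text formats the pipeline consumes.

bedGraph and BED are 0-based half-open; GTF is 1-based inclusive and is
converted on ingestion. Minus-strand bedGraph values may be negative (a
common track dialect) and are stored as absolute signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .genomic import (
    ANNOTATION_COLUMNS,
    CountMatrix,
    GeneAnnotation,
    IntervalSet,
    SampleDesign,
    StrandedCoverage,
)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(path, format: str = "gtf") -> GeneAnnotation:
    """Read a gene annotation from GTF or a tabular TSV.

    GTF: gene/transcript/exon rows are accepted; the stored record per gene
    is the union span over all its rows (longest transcript extent), with
    1-based inclusive coordinates converted to 0-based half-open. TSV needs
    columns gene_id, chrom, strand, start, end (already 0-based half-open).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        return GeneAnnotation(df)
    if format != "gtf":
        raise ValueError(f"unknown annotation format {format!r}")

    spans: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
            if strand not in "+-":
                raise ValueError(f"malformed GTF line {lineno}: strand {strand!r}")
            gene_id = _gtf_attribute(attrs, "gene_id")
            if gene_id is None:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id attribute")
            start0 = start_i - 1  # to 0-based half-open
            key = gene_id
            if key in spans:
                c, st, s0, e0 = spans[key]
                if c != chrom or st != strand:
                    raise ValueError(
                        f"malformed GTF line {lineno}: gene {gene_id} spans chromosomes/strands"
                    )
                spans[key] = (c, st, min(s0, start0), max(e0, end_i))
            else:
                spans[key] = (chrom, strand, start0, end_i)
    df = pd.DataFrame(
        [(g, c, st, s, e) for g, (c, st, s, e) in spans.items()],
        columns=["gene_id", "chrom", "strand", "start", "end"],
    )
    return GeneAnnotation(df)


def _gtf_attribute(attrs: str, key: str):
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk[len(key):].strip().strip('"')
    return None


def write_gene_annotation_tsv(ann: GeneAnnotation, path) -> None:
    ann.df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def _read_bedgraph(path) -> dict:
    """Parse one bedGraph file into {chrom: (pos, count)} expanded arrays."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            comment="#",
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return {}
    out: dict = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        vals = np.abs(sub["value"].to_numpy(float))
        order = np.argsort(starts, kind="mergesort")
        starts, ends, vals = starts[order], ends[order], vals[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: overlapping intervals on {chrom}; signal must be a function of position")
        lens = ends - starts
        pos = np.repeat(starts, lens) + _ranges(lens)
        cnt = np.repeat(vals, lens)
        out[chrom] = (pos, cnt)
    return out


def _ranges(lens: np.ndarray) -> np.ndarray:
    """Concatenated [0..l) ranges for each length (vectorized)."""
    if lens.sum() == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.arange(lens.sum(), dtype=np.int64)
    offsets = np.repeat(np.cumsum(lens) - lens, lens)
    return idx - offsets


def read_bedgraph_pair(plus_path, minus_path) -> StrandedCoverage:
    """Read a plus/minus bedGraph pair into a StrandedCoverage.

    Minus-strand values may be negative by dialect; absolute values are
    stored. Empty files yield an empty track.
    """
    tracks = {}
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        for chrom, (pos, cnt) in _read_bedgraph(path).items():
            tracks[(chrom, strand)] = (pos, cnt)
    cov = StrandedCoverage()
    for key, (pos, cnt) in tracks.items():
        cov._set_track(key, pos, cnt)
    return cov


def write_bedgraph_pair(cov: StrandedCoverage, plus_path, minus_path, negate_minus: bool = True) -> None:
    """Write a coverage object back to a plus/minus bedGraph pair.

    Runs of equal adjacent counts are emitted as single intervals.
    """
    for path, strand, sign in ((plus_path, "+", 1.0), (minus_path, "-", -1.0 if negate_minus else 1.0)):
        rows = []
        for chrom, st in sorted(cov.keys()):
            if st != strand:
                continue
            pos, cnt = cov.track(chrom, st)
            if pos.size == 0:
                continue
            # split into runs of consecutive positions with equal counts
            brk = np.flatnonzero((np.diff(pos) != 1) | (np.diff(cnt) != 0)) + 1
            for seg_pos, seg_cnt in zip(np.split(pos, brk), np.split(cnt, brk)):
                rows.append((chrom, seg_pos[0], seg_pos[-1] + 1, sign * seg_cnt[0]))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
            path, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path) -> IntervalSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    return IntervalSet(df)


def write_bed(ivs: IntervalSet, path) -> None:
    ivs.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Count matrices, designs, config
# ---------------------------------------------------------------------------


def read_count_matrix(path, lengths_path=None) -> CountMatrix:
    """TSV with feature ids in the first column, sample ids in the header.

    An optional ``length_bp`` column (or separate two-column TSV) carries
    region lengths.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if "length_bp" in df.columns:
        lengths = df.pop("length_bp")
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(df, lengths)


def write_count_matrix(cm: CountMatrix, path, with_lengths: bool = True) -> None:
    df = cm.values.copy()
    if with_lengths:
        df.insert(0, "length_bp", cm.lengths)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_design(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t"))


def write_sample_design(design: SampleDesign, path) -> None:
    design.df.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
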