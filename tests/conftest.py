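import numpy as np
import pandas as pd
import pytest

from isgdyn.genomic import GeneAnnotation, IntervalSet, StrandedCoverage
from isgdyn.simulate import SimulationConfig, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_annotation():
    """Four genes on two chromosomes, both strands."""
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC", "gD"],
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "strand": ["+", "-", "+", "-"],
                "start": [0, 10_000, 30_000, 5_000],
                "end": [2_000, 13_000, 31_400, 9_000],
            }
        )
    )


def make_coverage(events):
    """events: {(chrom, strand): list of read positions}."""
    return StrandedCoverage.from_positions(
        {k: np.asarray(v, dtype=np.int64) for k, v in events.items()}
    )


@pytest.fixture
def coverage_factory():
    return make_coverage


def random_intervals(rng, n, max_coord=10_000, max_len=500, chroms=("c1",)):
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, max_coord - max_len, size=n)
    length = rng.integers(1, max_len + 1, size=n)
    return IntervalSet(
        pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
    )


def occupancy(ivs: IntervalSet, chrom: str, size: int = 11_000) -> np.ndarray:
    """Per-base bit-vector oracle of interval coverage."""
    bits = np.zeros(size, dtype=bool)
    sub = ivs.df[ivs.df["chrom"] == chrom]
    for _, row in sub.iterrows():
        bits[row["start"]: row["end"]] = True
    return bits


@pytest.fixture(scope="session")
def small_experiment():
    """A compact synthetic experiment shared by read-only tests."""
    cfg = SimulationConfig(n_genes=200, seed=7, n_decoy_flat=20, n_decoy_far=10)
    return generate_experiment(cfg)
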