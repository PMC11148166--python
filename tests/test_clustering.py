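"""Gene pooling, z-scoring, Ward clustering, trend summaries and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isgdyn.clustering import (
    ClusterAssignment,
    pool_top_genes,
    pca_top_variable,
    trend_summary,
    ward_cluster,
    zscore_profiles,
)
from isgdyn.genomic import SampleDesign


def de_frame(rng, n, sig_fraction=0.8):
    genes = [f"g{i:04d}" for i in range(n)]
    lfc = rng.normal(0, 2, size=n)
    padj = np.where(rng.random(n) < sig_fraction, 10.0 ** -rng.uniform(2.5, 9, n), rng.uniform(0.02, 1, n))
    return pd.DataFrame({"log2fc": lfc, "padj": padj}, index=genes)


class TestPoolTopGenes:
    def test_disjoint_and_identical_unions(self, rng):
        de1 = de_frame(rng, 1200)
        de2 = de1.copy()
        de2.index = [f"h{i:04d}" for i in range(1200)]
        disjoint = pool_top_genes({"a": de1, "b": de2}, n=1000)
        identical = pool_top_genes({"a": de1, "b": de1.copy()}, n=1000)
        n1 = len(pool_top_genes({"a": de1}, n=1000))
        assert len(disjoint) == 2 * n1
        assert len(identical) == n1

    def test_matches_bruteforce_reselection(self, rng):
        de_dict = {c: de_frame(rng, 1500) for c in ("c1", "c2")}
        pooled = pool_top_genes(de_dict, n=1000)
        expected = set()
        for de in de_dict.values():
            sig = de[(de["log2fc"].abs() >= 1) & (de["padj"] < 0.01)]
            ordered = sorted(
                sig.index, key=lambda g: (sig.loc[g, "padj"], -abs(sig.loc[g, "log2fc"]), g)
            )
            expected |= set(ordered[:1000])
        assert set(pooled) == expected

    def test_fewer_than_n_takes_all(self, rng):
        de = de_frame(rng, 50)
        pooled = pool_top_genes({"c": de}, n=1000)
        sig = de[(de["log2fc"].abs() >= 1) & (de["padj"] < 0.01)]
        assert set(pooled) == set(sig.index)


def wt_design():
    rows = []
    for rep in (1, 2):
        rows.append((f"u_r{rep}", "WT", "untreated", 0.0, rep))
        for tr in ("IFNb", "IFNg"):
            for tp in (1.5, 4.0):
                rows.append((f"{tr}_{tp}_r{rep}", "WT", tr, tp, rep))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment", "timepoint_h", "replicate"])
    )


class TestZscoreProfiles:
    def test_constant_row_zeros_and_normalization(self, rng):
        design = wt_design()
        samples = design.df["sample_id"].tolist()
        data = pd.DataFrame(
            rng.normal(8, 2, size=(5, len(samples))), columns=samples,
            index=[f"g{i}" for i in range(5)],
        )
        data.loc["g0"] = 3.0  # constant gene
        z = zscore_profiles(data, data.index, design, scope="wt_only")
        assert (z.loc["g0"] == 0).all()
        for block in ("IFNb", "IFNg"):
            cols = [c for c in z.columns if c.startswith(block + "|")]
            nonconst = z.loc["g1", cols]
            assert nonconst.mean() == pytest.approx(0, abs=1e-12)
            assert nonconst.std(ddof=0) == pytest.approx(1, abs=1e-12)

    def test_hand_computed_three_conditions(self):
        rows = []
        for rep in (1, 2):
            rows.append((f"u_r{rep}", "WT", "untreated", 0.0, rep))
            rows.append((f"b_r{rep}", "WT", "IFNb", 1.5, rep))
            rows.append((f"b4_r{rep}", "WT", "IFNb", 4.0, rep))
        design = SampleDesign(
            pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment", "timepoint_h", "replicate"])
        )
        # replicate means: untreated 2, 1.5h 4, 4h 6 -> z = (-1.2247, 0, 1.2247)
        data = pd.DataFrame(
            {"u_r1": [1.0], "u_r2": [3.0], "b_r1": [4.0], "b_r2": [4.0], "b4_r1": [5.0], "b4_r2": [7.0]},
            index=["g"],
        )
        z = zscore_profiles(data, pd.Index(["g"]), design, scope="wt_only")
        cols = [c for c in z.columns if c.startswith("IFNb|")]
        np.testing.assert_allclose(sorted(z.loc["g", cols]), [-1.22474487, 0.0, 1.22474487])

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_within_block(self, scale, shift):
        design = wt_design()
        rng = np.random.default_rng(5)
        samples = design.df["sample_id"].tolist()
        data = pd.DataFrame(
            rng.normal(10, 3, size=(3, len(samples))), columns=samples, index=list("abc")
        )
        z1 = zscore_profiles(data, data.index, design)
        z2 = zscore_profiles(data * scale + shift, data.index, design)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-8)


class TestWardCluster:
    def test_two_blobs_perfect_split(self, rng):
        a = rng.normal(0, 0.2, size=(30, 6))
        b = rng.normal(5, 0.2, size=(25, 6))
        z = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(55)])
        asgn = ward_cluster(z, k=2)
        labels_a = set(asgn.labels.iloc[:30])
        labels_b = set(asgn.labels.iloc[30:])
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b
        # renumbering by decreasing size: the 30-gene blob is cluster 1
        assert asgn.labels.iloc[0] == 1

    def test_k_one_and_k_too_large(self, rng):
        z = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        assert set(ward_cluster(z, k=1).labels) == {1}
        with pytest.raises(ValueError, match="exceeds"):
            ward_cluster(z, k=6)

    def test_duplicated_rows_cocluster(self, rng):
        base = rng.normal(size=(10, 4))
        z = pd.DataFrame(np.vstack([base, base[:1]]), index=[f"g{i}" for i in range(11)])
        asgn = ward_cluster(z, k=4)
        assert asgn.labels.loc["g0"] == asgn.labels.loc["g10"]


class TestTrendSummary:
    def test_matches_groupby_oracle(self, rng):
        z = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"g{i}" for i in range(20)], columns=list("xyz"))
        labels = pd.Series(rng.integers(1, 4, size=20), index=z.index)
        asgn = ClusterAssignment(labels=labels, linkage=None, k=3)
        out = trend_summary(z, asgn).set_index(["cluster_id", "condition"])
        for cid in sorted(labels.unique()):
            sub = z.loc[labels[labels == cid].index]
            for cond in z.columns:
                assert out.loc[(cid, cond), "mean_z"] == pytest.approx(sub[cond].mean())
                assert out.loc[(cid, cond), "median_z"] == pytest.approx(sub[cond].median())
                assert out.loc[(cid, cond), "n_genes"] == len(sub)

    def test_single_gene_cluster_mean_equals_median(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 2)), index=list("abc"), columns=["c1", "c2"])
        asgn = ClusterAssignment(labels=pd.Series([1, 2, 2], index=z.index), linkage=None, k=2)
        out = trend_summary(z, asgn)
        solo = out[out["cluster_id"] == 1]
        assert (solo["mean_z"] == solo["median_z"]).all()


class TestPca:
    def test_duplicated_samples_coincide(self, rng):
        data = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        data["d"] = data["c"]
        coords, var = pca_top_variable(data, n=50)
        np.testing.assert_allclose(coords.loc["c"], coords.loc["d"], atol=1e-8)
        assert var.sum() <= 1.0 + 1e-9

    def test_matches_eigendecomposition_oracle(self, rng):
        data = pd.DataFrame(rng.normal(size=(5, 4)), index=[f"g{i}" for i in range(5)], columns=list("wxyz"))
        coords, var = pca_top_variable(data, n=5)
        X = data.to_numpy().T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        evals = evals[::-1]
        expect_var = evals / evals.sum()
        np.testing.assert_allclose(var[: len(expect_var)], expect_var, atol=1e-9)
        # coordinate magnitudes match up to sign per component
        proj = np.abs(coords.to_numpy())
        oracle = np.abs((evecs[:, ::-1] * np.sqrt(np.maximum(evals, 0))))
        np.testing.assert_allclose(proj[:, :3], oracle[:, :3], atol=1e-8)
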