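"""NB differential-transcription machinery: size factors, dispersion,
Wald test (cross-checked against statsmodels GLM), BH, VST, screens."""

import numpy as np
import pandas as pd
import pytest

from isgdyn.diffexpr import (
    Contrast,
    bh_adjust,
    estimate_dispersion,
    nb_wald,
    significant,
    size_factors,
    vst,
)
from isgdyn.genomic import CountMatrix


def cm(values: dict, index=None) -> CountMatrix:
    return CountMatrix(pd.DataFrame(values, index=index))


def nb_counts(rng, mu, alpha, n):
    lam = rng.gamma(1.0 / alpha, np.multiply.outer(mu, np.ones(n)) * alpha)
    return rng.poisson(lam)


class TestSizeFactors:
    def test_twofold_sample_closed_form(self, rng):
        base = rng.integers(50, 500, size=200)
        counts = cm({"s1": base, "s2": 2 * base})
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-6)
        assert sf["s2"] == pytest.approx(np.sqrt(2), rel=1e-6)

    def test_identical_samples_unity(self, rng):
        base = rng.integers(1, 100, size=50)
        sf = size_factors(cm({"a": base, "b": base, "c": base}))
        assert np.allclose(sf, 1.0)

    def test_single_sample_unity(self):
        assert size_factors(cm({"only": [5, 10]}))["only"] == 1.0

    def test_invariant_to_global_scaling(self, rng):
        base = rng.integers(10, 300, size=100)
        counts1 = cm({"a": base, "b": base + 5, "c": 2 * base})
        counts3 = cm({k: 3 * v for k, v in counts1.values.items()})
        pd.testing.assert_series_equal(size_factors(counts1), size_factors(counts3))

    def test_all_zero_feature_fallback_warns(self):
        counts = cm({"a": [0, 10], "b": [5, 0]})
        with pytest.warns(UserWarning, match="total-count"):
            size_factors(counts)


class TestDispersion:
    def test_poisson_data_near_floor(self, rng):
        y = rng.poisson(np.full((2000, 12), 200.0))
        counts = CountMatrix(pd.DataFrame(y, columns=[f"s{i}" for i in range(12)]))
        sf = pd.Series(1.0, index=counts.sample_ids)
        disp = estimate_dispersion(counts, sf, [list(counts.sample_ids)])
        assert disp["alpha_mom"].median() <= 0.01

    def test_nb_dispersion_recovered(self, rng):
        mu = np.full(2000, 300.0)
        y = nb_counts(rng, mu, 0.2, 12)
        counts = CountMatrix(pd.DataFrame(y, columns=[f"s{i}" for i in range(12)]))
        sf = pd.Series(1.0, index=counts.sample_ids)
        disp = estimate_dispersion(counts, sf, [list(counts.sample_ids)])
        assert disp["alpha"].median() == pytest.approx(0.2, abs=0.1)

    def test_constant_feature_floored(self):
        counts = cm({"a": [7, 100], "b": [7, 110], "c": [7, 90]})
        sf = pd.Series(1.0, index=["a", "b", "c"])
        disp = estimate_dispersion(counts, sf, [["a", "b", "c"]])
        assert disp["alpha_mom"].iloc[0] == pytest.approx(1e-8)


class TestNbWald:
    def test_agrees_with_statsmodels_glm(self, rng):
        """Independent route: statsmodels NB GLM with log(size factor) offset."""
        import statsmodels.api as sm

        alpha = 0.08
        mu = rng.uniform(30, 400, size=40)
        y = np.concatenate(
            [nb_counts(rng, mu, alpha, 3), nb_counts(rng, mu * 3.0, alpha, 3)], axis=1
        )
        samples = [f"s{i}" for i in range(6)]
        counts = CountMatrix(pd.DataFrame(y, index=[f"g{i}" for i in range(40)], columns=samples))
        sf = pd.Series(rng.uniform(0.7, 1.4, size=6), index=samples)
        de = nb_wald(counts, sf, Contrast("c", samples[3:], samples[:3]), alpha)
        X = np.column_stack([np.ones(6), np.array([0, 0, 0, 1, 1, 1])])
        for i, g in enumerate(counts.feature_ids):
            model = sm.GLM(
                y[i],
                X,
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf.values),
            ).fit()
            assert de.loc[g, "log2fc"] == pytest.approx(model.params[1] / np.log(2), abs=1e-4)
            assert de.loc[g, "se"] == pytest.approx(model.bse[1] / np.log(2), rel=1e-3)

    def test_fold_change_recovery(self, rng):
        mu = rng.uniform(100, 500, size=500)
        y = np.concatenate([nb_counts(rng, mu, 0.01, 3), nb_counts(rng, mu * 4, 0.01, 3)], axis=1)
        samples = [f"s{i}" for i in range(6)]
        counts = CountMatrix(pd.DataFrame(y, columns=samples))
        sf = pd.Series(1.0, index=samples)
        de = nb_wald(counts, sf, Contrast("c", samples[3:], samples[:3]), 0.01)
        assert de["log2fc"].median() == pytest.approx(2.0, abs=0.3)

    def test_all_zero_feature_is_na_and_excluded_from_bh(self):
        counts = cm({"a": [0, 10, 20], "b": [0, 12, 18], "c": [0, 11, 30], "d": [0, 9, 25]})
        sf = pd.Series(1.0, index=["a", "b", "c", "d"])
        de = nb_wald(counts, sf, Contrast("c", ["c", "d"], ["a", "b"]), 0.05)
        assert de["p"].isna().iloc[0] and de["padj"].isna().iloc[0]
        assert de["p"].notna().iloc[1:].all()

    def test_requires_two_replicates(self):
        counts = cm({"a": [1], "b": [2], "c": [3]})
        sf = pd.Series(1.0, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="replicates"):
            nb_wald(counts, sf, Contrast("c", ["c"], ["a", "b"]), 0.05)


class TestBhAdjust:
    def test_textbook_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_matches_stepup_oracle_and_permutation_invariance(self, rng):
        def oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out

        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            assert np.allclose(bh_adjust(p), oracle(p))
            perm = rng.permutation(len(p))
            assert np.allclose(bh_adjust(p[perm]), oracle(p)[perm])

    def test_na_propagated_and_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)  # m = 2, rank 1
        assert np.all(out[~np.isnan(out)] >= np.array([0.01, 0.04])[[0, 1]])


class TestVst:
    def test_zero_count_maps_to_two(self):
        counts = cm({"a": [0], "b": [0]})
        out = vst(counts, pd.Series(1.0, index=["a", "b"]))
        assert np.allclose(out, 2.0)

    def test_asymptotic_log2_shift(self):
        counts = cm({"a": [10_000], "b": [20_000]})
        out = vst(counts, pd.Series(1.0, index=["a", "b"]))
        assert out.loc[0, "b"] - out.loc[0, "a"] == pytest.approx(1.0, abs=0.001)

    def test_flattens_variance_across_mean_grid(self, rng):
        """Across an NB mean grid at fixed dispersion, the transform leaves
        near-constant variance while raw variance spans orders of magnitude."""
        mus = [10, 100, 1000, 10_000]
        raw_var, vst_var = [], []
        for mu in mus:
            lam = rng.gamma(1 / 0.05, mu * 0.05, size=(400, 4))
            y = rng.poisson(lam)
            counts = CountMatrix(pd.DataFrame(y, columns=list("abcd")))
            out = vst(counts, pd.Series(1.0, index=list("abcd")))
            raw_var.append(np.var(y))
            vst_var.append(float(np.var(out.to_numpy())))
        assert max(raw_var) / min(raw_var) > 100
        assert max(vst_var) / min(vst_var) < 10


class TestSignificant:
    def make_de(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "padj"], index=[f"g{i}" for i in range(len(rows))])

    def test_clustering_screen_boundaries(self):
        de = self.make_de([(1.0, 0.009), (0.99, 1e-9), (1.5, 0.01)])
        kept = significant(de, lfc_min=1, padj_max=0.01, direction="both")
        assert list(kept) == ["g0"]  # inclusive lfc, strict padj

    def test_downregulation_screen(self):
        de = self.make_de([(-1.2, 0.01), (-0.9, 0.001), (1.2, 0.01)])
        kept = significant(de, lfc_min=1, padj_max=0.05, direction="down", padj_inclusive=True)
        assert list(kept) == ["g0"]

    def test_na_padj_never_significant(self):
        de = self.make_de([(3.0, np.nan)])
        assert len(significant(de, direction="both")) == 0
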