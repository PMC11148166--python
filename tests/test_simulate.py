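"""Generator contracts: determinism, NB moments, planted effects, truth."""

import numpy as np
import pandas as pd
import pytest

from isgdyn.genomic import IntervalSet, merge_intervals
from isgdyn.quantify import count_gene_bodies
from isgdyn.simulate import (
    Archetype,
    SimulationConfig,
    _nb_draw,
    default_archetypes,
    generate_experiment,
    truth_tables,
)
from isgdyn.pausing import condition_pausing
from isgdyn.quantify import count_body_for_pausing, count_tss_regions


def tiny_cfg(**kwargs):
    defaults = dict(n_genes=60, seed=11, n_decoy_flat=6, n_decoy_far=4)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = generate_experiment(tiny_cfg())
        b = generate_experiment(tiny_cfg())
        pd.testing.assert_frame_equal(a.truth.genes, b.truth.genes)
        pd.testing.assert_frame_equal(a.proteomics, b.proteomics)
        pd.testing.assert_frame_equal(a.atac_counts.values, b.atac_counts.values)
        sample = a.design.df["sample_id"].iloc[5]
        for key in a.coverages[sample].keys():
            pa, ca = a.coverages[sample].track(*key)
            pb, cb = b.coverages[sample].track(*key)
            assert np.array_equal(pa, pb) and np.array_equal(ca, cb)

    def test_different_seed_differs(self):
        a = generate_experiment(tiny_cfg(seed=1))
        b = generate_experiment(tiny_cfg(seed=2))
        assert not a.truth.genes["baseline_mean"].equals(b.truth.genes["baseline_mean"])


class TestPlantedMeans:
    def test_unit_knockout_effects_equalize_genotypes(self):
        archetypes = [
            Archetype(a.name, a.folds, irf9_attenuation=1.0, irf1_attenuation=1.0, pausing_shift=a.pausing_shift)
            for a in default_archetypes()
        ]
        exp = generate_experiment(tiny_cfg(archetypes=archetypes))
        em = exp.truth.expected_means
        for tr, tp in (("IFNb", 1.5), ("IFNg", 48.0)):
            wt = em[f"WT_{tr}_{tp:g}h"]
            for gt in ("Irf9KO", "Irf1KO"):
                pd.testing.assert_series_equal(wt, em[f"{gt}_{tr}_{tp:g}h"], check_names=False)

    def test_low_dispersion_fold_recovery(self):
        """Archetype fold 8 at low dispersion: sample log2FC within 0.1 of 3
        for >= 95% of that cluster's genes."""
        arch = [Archetype("x8", {"IFNb": [1, 8, 8, 8, 8], "IFNg": [1, 1, 1, 1, 1]})]
        cfg = tiny_cfg(
            n_genes=200, de_fraction=1.0, archetypes=arch, nb_dispersion=1e-6,
            baseline_log_mean=np.log(5000), baseline_log_sd=0.1,
        )
        exp = generate_experiment(cfg)
        counts = count_gene_bodies(exp.coverages, exp.annotation)
        treated = exp.design.samples_for("WT", "IFNb", 1.5)
        untreated = exp.design.samples_for("WT", "untreated")
        lfc = np.log2(
            counts.values[treated].mean(axis=1) / counts.values[untreated].mean(axis=1)
        )
        assert (np.abs(lfc - 3.0) <= 0.1).mean() >= 0.95


class TestNbMoments:
    def test_mean_and_variance_match(self, rng):
        mu, alpha, n = 80.0, 0.1, 500
        draws = _nb_draw(rng, np.full(n, mu), alpha)
        assert draws.mean() == pytest.approx(mu, rel=0.1)
        expected_var = mu + alpha * mu**2
        assert draws.var(ddof=1) == pytest.approx(expected_var, rel=0.35)

    def test_zero_dispersion_is_poisson(self, rng):
        draws = _nb_draw(rng, np.full(2000, 50.0), 0.0)
        assert draws.var(ddof=1) == pytest.approx(50.0, rel=0.15)


class TestConservationAndLayout:
    def test_library_size_equals_reads_in_planted_regions(self, small_experiment):
        """All signal lies in gene spans plus TRE intervals (conservation)."""
        exp = small_experiment
        regions = pd.concat(
            [
                exp.annotation.df[["chrom", "start", "end"]],
                exp.truth.enhancers[["chrom", "start", "end"]],
            ],
            ignore_index=True,
        )
        union = merge_intervals(IntervalSet(regions))
        sample = exp.design.df["sample_id"].iloc[0]
        cov = exp.coverages[sample]
        total = 0.0
        for chrom, strand in cov.keys():
            sub = union.df[union.df["chrom"] == chrom]
            total += cov.window_sums(chrom, strand, sub["start"], sub["end"]).sum()
        assert total == cov.library_size

    def test_layout_overflow_raises(self):
        with pytest.raises(ValueError, match="overflow"):
            generate_experiment(tiny_cfg(gene_spacing=40_000))

    def test_enhancers_are_intergenic_with_unique_host(self, small_experiment):
        exp = small_experiment
        enh = exp.truth.enhancers
        true_enh = enh[enh["kind"] == "enhancer"]
        spans = exp.annotation.gene_spans()
        from isgdyn.genomic import overlap_any

        ivs = IntervalSet(true_enh[["chrom", "start", "end"]])
        assert not overlap_any(ivs, spans).any()
        assert true_enh["gene_id"].isin(exp.annotation.df["gene_id"]).all()


class TestPlantedPausing:
    def test_pi_ratio_recovers_shift_at_low_dispersion(self):
        arch = [
            Archetype(
                "shifted", {"IFNb": [1, 2, 2, 2, 2], "IFNg": [1, 2, 2, 2, 2]},
                pausing_shift={"IFNb": 2.0, "IFNg": 1.0},
            )
        ]
        cfg = tiny_cfg(n_genes=150, de_fraction=1.0, archetypes=arch, nb_dispersion=1e-3,
                       baseline_log_mean=np.log(2000), baseline_log_sd=0.1)
        exp = generate_experiment(cfg)
        tss = count_tss_regions(exp.coverages, exp.annotation)
        body = count_body_for_pausing(exp.coverages, exp.annotation)
        cond_pi = condition_pausing(tss, body, exp.design, exp.library_sizes)
        piv = cond_pi.pivot_table(index="gene_id", columns=["treatment", "timepoint_h"], values="pi")
        ratio_b = piv[("IFNb", 1.5)] / piv[("untreated", 0.0)]
        ratio_g = piv[("IFNg", 1.5)] / piv[("untreated", 0.0)]
        assert np.median(ratio_b) == pytest.approx(2.0, rel=0.1)
        assert np.median(ratio_g) == pytest.approx(1.0, rel=0.1)


class TestTruthTables:
    def test_roundtrip_and_bound_counts(self, small_experiment, tmp_path):
        exp = small_experiment
        paths = truth_tables(exp.truth, tmp_path)
        genes = pd.read_csv(paths["genes"], sep="\t")
        pd.testing.assert_frame_equal(
            genes, exp.truth.genes.reset_index(drop=True), check_dtype=False
        )
        enh = pd.read_csv(paths["enhancers"], sep="\t")
        cfg = exp.config
        dep9 = {a.name for a in cfg.archetypes if a.irf9_attenuation < 0.5}
        arch_of = exp.truth.genes.set_index("gene_id")["archetype"]
        true_enh = enh[enh["kind"] == "enhancer"].copy()
        true_enh["arch"] = true_enh["gene_id"].map(arch_of)
        dep = true_enh[true_enh["arch"].isin(dep9)]
        frac = dep["bound_IRF9"].mean()
        assert frac == pytest.approx(cfg.peak_bound_fraction["IRF9"], abs=1.0 / max(len(dep), 1))

    def test_interactor_truth_matches_config(self, small_experiment):
        truth = small_experiment.truth.interactors
        cfg = small_experiment.config
        stat1 = truth[truth["bait"] == "STAT1"]
        irf1 = truth[truth["bait"] == "IRF1"]
        assert len(stat1) == cfg.n_stat1_unique + cfg.n_common + cfg.n_stat1_steady_only
        assert len(irf1) == cfg.n_irf1_unique + cfg.n_common
        assert (~stat1["active_state"]).sum() == cfg.n_stat1_steady_only
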