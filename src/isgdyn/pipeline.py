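"""End-to-end pipeline on the synthetic experiment, with truth-based checks.

Chains simulate -> quantify -> differential transcription -> temporal
clustering -> pausing -> enhancer linkage -> chromatin integration ->
interactor filtering, and evaluates every stage against the planted
ground truth, producing a machine-readable report.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import chromatin, clustering, diffexpr, enhancers, pausing, quantify
from .diffexpr import Contrast
from .genomic import CountMatrix, IntervalSet, SampleDesign
from .proximity import all_interactors, exclude_steady_only, filter_interactors, venn_partition
from .simulate import (
    ATAC_TO_PRO_TIMEPOINT,
    TIMEPOINTS,
    SimulatedExperiment,
    SimulationConfig,
    generate_experiment,
)


@dataclass
class PipelineResult:
    experiment: SimulatedExperiment
    body_counts: CountMatrix
    tss_counts: CountMatrix
    pausing_body_counts: CountMatrix
    size_factors: pd.Series
    de_wt: dict  # condition -> DE frame (gene level, vs untreated)
    de_ko: dict  # (genotype, treatment) -> DE frame (KO vs WT at 1.5 h)
    vst: pd.DataFrame
    pooled_genes: pd.Index
    zscores: pd.DataFrame
    assignment: clustering.ClusterAssignment
    trend: pd.DataFrame
    condition_pi: pd.DataFrame
    pausing_ratios: pd.DataFrame
    pausing_tests: pd.DataFrame  # both treatments at 1.5 h
    tres_merged: IntervalSet
    tres_intergenic: IntervalSet
    tre_de: dict
    enhancer_links: pd.DataFrame
    bound_fractions: pd.DataFrame
    atac_gene_de: dict  # (genotype, condition) -> gene-level accessibility DE
    dependence: dict  # tf -> classification frame
    trend_r: pd.Series
    interactors: dict
    timings: dict = field(default_factory=dict)


def _replicate_groups(design: SampleDesign) -> list:
    return [
        grp["sample_id"].tolist()
        for _, grp in design.df.groupby(["genotype", "treatment", "timepoint_h"], sort=True)
        if len(grp) > 1
    ]


def run_pipeline(cfg: SimulationConfig | None = None, k: int = 11) -> PipelineResult:
    cfg = cfg or SimulationConfig()
    t0 = time.time()
    timings = {}
    exp = generate_experiment(cfg)
    timings["simulate"] = time.time() - t0
    design, ann = exp.design, exp.annotation
    lib = exp.library_sizes

    # --- quantification -----------------------------------------------------
    t0 = time.time()
    body = quantify.count_gene_bodies(exp.coverages, ann)
    tss = quantify.count_tss_regions(exp.coverages, ann)
    pbody = quantify.count_body_for_pausing(exp.coverages, ann)
    timings["quantify"] = time.time() - t0

    # --- differential transcription ----------------------------------------
    t0 = time.time()
    sf = diffexpr.size_factors(body)
    disp = diffexpr.estimate_dispersion(body, sf, _replicate_groups(design))
    de_wt = {}
    wt_untreated = design.samples_for("WT", "untreated")
    for tr in cfg.treatments:
        for tp in TIMEPOINTS[1:]:
            name = f"WT_{tr}_{tp:g}h"
            contrast = Contrast(name, design.samples_for("WT", tr, tp), wt_untreated)
            de_wt[name] = diffexpr.nb_wald(body, sf, contrast, disp["alpha"])
    de_ko = {}
    for gt in ("Irf9KO", "Irf1KO"):
        if gt not in cfg.genotypes:
            continue
        for tr in cfg.treatments:
            name = f"{gt}_vs_WT_{tr}_1.5h"
            contrast = Contrast(
                name, design.samples_for(gt, tr, 1.5), design.samples_for("WT", tr, 1.5)
            )
            de_ko[(gt, tr)] = diffexpr.nb_wald(body, sf, contrast, disp["alpha"])
    vst = diffexpr.vst(body, sf)
    timings["diffexpr"] = time.time() - t0

    # --- clustering ---------------------------------------------------------
    t0 = time.time()
    pooled = clustering.pool_top_genes(de_wt)
    z = clustering.zscore_profiles(vst, pooled, design, scope="wt_only")
    assignment = clustering.ward_cluster(z, k=k)
    trend = clustering.trend_summary(z, assignment)
    timings["clustering"] = time.time() - t0

    # --- pausing ------------------------------------------------------------
    t0 = time.time()
    cond_pi = pausing.condition_pausing(tss, pbody, design, lib, genotype="WT")
    ratios = pausing.pausing_contrasts(cond_pi, assignment)
    tests = pd.concat(
        [
            pausing.cluster_pausing_test(cond_pi, assignment, tr, 1.5)
            for tr in cfg.treatments
        ],
        ignore_index=True,
    )
    timings["pausing"] = time.time() - t0

    # --- enhancers ----------------------------------------------------------
    t0 = time.time()
    tres = enhancers.combine_tres(list(exp.tre_sets.values()))
    tres_x = enhancers.exclude_genic(tres, ann)
    tre_counts = quantify.count_regions_bothstrands(exp.coverages, tres_x)
    tre_disp = diffexpr.estimate_dispersion(tre_counts, sf, _replicate_groups(design))
    tre_de = {}
    for tr in cfg.treatments:
        for tp in TIMEPOINTS[1:]:
            name = f"WT_{tr}_{tp:g}h"
            contrast = Contrast(name, design.samples_for("WT", tr, tp), wt_untreated)
            tre_de[name] = diffexpr.nb_wald(tre_counts, sf, contrast, tre_disp["alpha"])
    links = enhancers.link_to_genes(tres_x, ann)
    enh = enhancers.concordance_filter(links, tre_de, assignment, de_per_condition=de_wt)
    bound = enhancers.bound_fraction(enh, exp.peak_sets, assignment)
    timings["enhancers"] = time.time() - t0

    # --- chromatin integration ----------------------------------------------
    t0 = time.time()
    peak_to_gene = chromatin.annotate_atac_to_genes(exp.atac_peaks, ann)
    atac_sf = diffexpr.size_factors(exp.atac_counts)
    atac_disp = diffexpr.estimate_dispersion(
        exp.atac_counts, atac_sf, _replicate_groups(exp.atac_design)
    )
    atac_gene_de = {}
    for gt in ("Irf9KO", "Irf1KO"):
        if gt not in cfg.genotypes:
            continue
        conditions = [("untreated", 0.0)] + [(tr, 2.0) for tr in cfg.treatments]
        for tr, tp in conditions:
            name = f"atac_{gt}_vs_WT_{tr}" + ("" if tr == "untreated" else f"_{tp:g}h")
            contrast = Contrast(
                name,
                exp.atac_design.samples_for(gt, tr, tp),
                exp.atac_design.samples_for("WT", tr, tp),
            )
            de = diffexpr.nb_wald(exp.atac_counts, atac_sf, contrast, atac_disp["alpha"])
            atac_gene_de[(gt, tr)] = chromatin.gene_level_atac_de(de, peak_to_gene)
    dependence = {}
    for tf, gt in (("IRF9", "Irf9KO"), ("IRF1", "Irf1KO")):
        if gt not in cfg.genotypes:
            continue
        gene_de_wt = {tr: de_wt[f"WT_{tr}_1.5h"] for tr in cfg.treatments}
        gene_de_ko = {tr: de_ko[(gt, tr)] for tr in cfg.treatments}
        atac_de = {tr: atac_gene_de[(gt, tr)] for tr in list(cfg.treatments) + ["untreated"]}
        dependence[tf] = chromatin.classify_dependence(gene_de_wt, gene_de_ko, atac_de, tf)
    # transcription vs accessibility trends (WT, matched early/late grid)
    pro_z = _matched_z(vst, design, {0.0: "untreated", 1.5: "early", 48.0: "late"}, cfg)
    atac_vst = diffexpr.vst(exp.atac_counts, atac_sf)
    atac_vst.index = [n.replace("atac_", "") for n in atac_vst.index]
    atac_z = _matched_z(
        atac_vst, exp.atac_design, {0.0: "untreated", 2.0: "early", 48.0: "late"}, cfg
    )
    trend_r, _ = chromatin.trend_concordance(pro_z, atac_z, assignment)
    timings["chromatin"] = time.time() - t0

    # --- interactors --------------------------------------------------------
    stat1_sets = filter_interactors(exp.proteomics, "STAT1")
    irf1_sets = filter_interactors(exp.proteomics, "IRF1")
    stat1_active = exclude_steady_only(stat1_sets)
    irf1_active = exclude_steady_only(irf1_sets)
    interactors = {
        "STAT1": {"per_condition": stat1_sets, "all": all_interactors(stat1_sets), "active": stat1_active},
        "IRF1": {"per_condition": irf1_sets, "all": all_interactors(irf1_sets), "active": irf1_active},
        "venn": venn_partition(stat1_active, irf1_active),
    }

    return PipelineResult(
        experiment=exp,
        body_counts=body,
        tss_counts=tss,
        pausing_body_counts=pbody,
        size_factors=sf,
        de_wt=de_wt,
        de_ko=de_ko,
        vst=vst,
        pooled_genes=pooled,
        zscores=z,
        assignment=assignment,
        trend=trend,
        condition_pi=cond_pi,
        pausing_ratios=ratios,
        pausing_tests=tests,
        tres_merged=tres,
        tres_intergenic=tres_x,
        tre_de=tre_de,
        enhancer_links=enh,
        bound_fractions=bound,
        atac_gene_de=atac_gene_de,
        dependence=dependence,
        trend_r=trend_r,
        interactors=interactors,
        timings=timings,
    )


def _matched_z(vst: pd.DataFrame, design: SampleDesign, tp_labels: dict, cfg) -> pd.DataFrame:
    """Per-gene z of condition means on a matched untreated/early/late grid."""
    cols = {}
    wt = design.df[design.df["genotype"] == "WT"]
    for tr in cfg.treatments:
        for tp, label in tp_labels.items():
            if tp == 0.0:
                samples = wt[wt["treatment"] == "untreated"]["sample_id"].tolist()
            else:
                samples = wt[(wt["treatment"] == tr) & (wt["timepoint_h"] == tp)]["sample_id"].tolist()
            cols[f"{tr}_{label}"] = vst[samples].mean(axis=1)
    means = pd.DataFrame(cols)
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    return means.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------


def _truth_assignment(truth_genes: pd.DataFrame) -> clustering.ClusterAssignment:
    labels = truth_genes.set_index("gene_id")["archetype"]
    labels = labels[labels != "background"]
    return clustering.ClusterAssignment(
        labels=labels, linkage=np.empty((0, 4)), k=labels.nunique()
    )


def evaluate(result: PipelineResult) -> dict:
    """Score every pipeline stage against the planted ground truth."""
    exp = result.experiment
    cfg = exp.config
    truth = exp.truth
    report: dict = {}

    # clustering: ARI over pooled genes that carry a planted archetype
    truth_labels = truth.genes.set_index("gene_id")["archetype"]
    common = result.assignment.labels.index.intersection(
        truth_labels.index[truth_labels != "background"]
    )
    report["clustering_ari"] = float(
        adjusted_rand_score(truth_labels.loc[common], result.assignment.labels.loc[common])
    )
    report["n_pooled_genes"] = int(len(result.pooled_genes))
    report["n_clusters"] = int(result.assignment.k)

    # pausing: recovery of the planted IFNb shifts; IFNg left null
    arch_shift = {a.name: a.pausing_shift.get("IFNb", 1.0) for a in cfg.archetypes}
    gene_arch = truth.genes.set_index("gene_id")["archetype"]
    ratios = result.pausing_ratios
    ifnb = ratios[(ratios["treatment"] == "IFNb") & (ratios["timepoint_h"] == 1.5)].copy()
    ifnb["shift"] = ifnb["gene_id"].map(gene_arch).map(arch_shift)
    shifted = ifnb[np.abs(np.log(ifnb["shift"].fillna(1.0))) > 0.01]
    if len(shifted):
        med = shifted.groupby("shift")["log_ratio"].median()
        report["pausing_median_log_ratio_error"] = float((med - np.log(med.index)).abs().max())
    truth_asgn = _truth_assignment(truth.genes)
    ptests = pd.concat(
        [
            pausing.cluster_pausing_test(result.condition_pi, truth_asgn, tr, 1.5)
            for tr in cfg.treatments
        ],
        ignore_index=True,
    )
    shifted_arches = {n for n, s in arch_shift.items() if abs(np.log(s)) > 0.01}
    b = ptests[ptests["treatment"] == "IFNb"]
    g = ptests[ptests["treatment"] == "IFNg"]
    report["pausing_shifted_clusters_significant"] = bool(
        b[b["cluster_id"].isin(shifted_arches)]["p"].lt(1e-4).all()
    )
    report["pausing_null_treatment_max_abs_median_ratio"] = float(
        g["median_log_ratio"].abs().max()
    )
    report["pausing_tests"] = ptests

    # enhancers: precision/recall of reported enhancers vs planted truth
    truth_enh = truth.enhancers[truth.enhancers["kind"] == "enhancer"]
    reported = result.enhancer_links.drop_duplicates(subset=["tre_id"])
    rep_iv = IntervalSet(
        reported[["chrom", "start", "end"]].assign(name=reported["tre_id"].values)
    )
    truth_iv = IntervalSet(
        truth_enh[["chrom", "start", "end"]].assign(name=truth_enh["truth_id"].values)
    )
    from .genomic import overlap_any

    if len(reported):
        precision = float(np.mean(overlap_any(rep_iv, truth_iv)))
        recall = float(np.mean(overlap_any(truth_iv, rep_iv)))
    else:
        precision = recall = 0.0
    report["enhancer_precision"] = precision
    report["enhancer_recall"] = recall

    # genic exclusion: zero overlap of reported enhancers with gene spans
    spans = exp.annotation.gene_spans()
    report["enhancer_genic_overlap_bases"] = int(
        0 if not len(reported) else np.sum(overlap_any(rep_iv, spans))
    )

    # bound fractions over the full planted enhancer set (counting check) and
    # over the recovered enhancers (the pipeline's observed value)
    dep9 = {a.name for a in cfg.archetypes if a.irf9_attenuation < 0.5}
    dep1 = {a.name for a in cfg.archetypes if a.irf1_attenuation < 0.5}
    truth_links = truth_enh.rename(columns={"truth_id": "tre_id"})[
        ["tre_id", "chrom", "start", "end", "gene_id"]
    ].copy()
    truth_links["cluster_id"] = truth_links["gene_id"].map(gene_arch)
    bf_truth = enhancers.bound_fraction(truth_links, exp.peak_sets, _truth_assignment(truth.genes))
    links_rep = result.enhancer_links.copy()
    links_rep["cluster_id"] = links_rep["gene_id"].map(gene_arch)
    bf_rep = enhancers.bound_fraction(links_rep, exp.peak_sets, _truth_assignment(truth.genes))
    for factor, dep in (("IRF9", dep9), ("IRF1", dep1)):
        for tag, bf in (("", bf_truth), ("_recovered", bf_rep)):
            sub = bf[(bf["factor"] == factor) & (bf["cluster_id"].isin(dep))]
            n, nb = int(sub["n_enhancers"].sum()), int(sub["n_bound"].sum())
            report[f"{factor.lower()}_bound_fraction{tag}"] = nb / n if n else np.nan
            report[f"{factor.lower()}_bound_n{tag}"] = (nb, n)
        report[f"{factor.lower()}_bound_fraction_configured"] = cfg.peak_bound_fraction[factor]

    # dependence classification F1
    tg = truth.genes.set_index("gene_id")
    for tf, col in (("IRF9", "irf9_dependent"), ("IRF1", "irf1_dependent")):
        if tf not in result.dependence:
            continue
        calls = result.dependence[tf].set_index("gene_id")
        predicted = set(calls.index[calls["transcription_dependent"]])
        actual = set(tg.index[tg[col]])
        report[f"dependence_f1_{tf.lower()}"] = _f1(predicted, actual)
        pred_yellow = set(calls.index[calls["accessibility_dependent"]])
        actual_yellow = set(tg.index[tg[col] & tg["accessibility_dependent"]])
        report[f"accessibility_f1_{tf.lower()}"] = _f1(pred_yellow, actual_yellow)
        # category nesting and the accessibility-independent exclusion
        n_yellow = int(calls["accessibility_dependent"].sum())
        n_violet = int(calls["transcription_dependent"].sum())
        report[f"nesting_ok_{tf.lower()}"] = bool(
            n_yellow <= n_violet <= len(calls)
            and (calls["accessibility_dependent"] <= calls["transcription_dependent"]).all()
        )
        indep = set(tg.index[tg[col] & ~tg["accessibility_dependent"]])
        report[f"accessibility_independent_never_yellow_{tf.lower()}"] = bool(
            len(pred_yellow & indep) == 0
        )

    # interactors
    venn = result.interactors["venn"]["counts"]
    report["stat1_interactors_total"] = len(result.interactors["STAT1"]["all"])
    report["irf1_interactors_total"] = len(result.interactors["IRF1"]["all"])
    report["stat1_unique_active"] = venn[0]
    report["common_active"] = venn[1]
    report["irf1_unique_active"] = venn[2]

    report["timings_s"] = {k: round(v, 2) for k, v in result.timings.items()}
    return report


def _f1(predicted: set, actual: set) -> float:
    tp = len(predicted & actual)
    if tp == 0:
        return 0.0
    precision = tp / len(predicted)
    recall = tp / len(actual)
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Wald-test calibration simulations (stand-alone)
# ---------------------------------------------------------------------------


def wald_calibration(
    n_genes: int = 2000,
    alpha: float = 0.1,
    n_per_group: int = 3,
    log2fc: float = 0.0,
    mean_low: float = 50.0,
    mean_high: float = 1000.0,
    seed: int = 0,
) -> dict:
    """Empirical rejection rate of the NB Wald test at nominal p < 0.05.

    Simulates NB counts at the given dispersion, with all size factors 1
    and means log-uniform in [mean_low, mean_high]; with ``log2fc`` = 0
    this measures type-I error, otherwise power.
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_low), np.log(mean_high), size=n_genes))
    mu1 = mu * 2.0**log2fc
    shape = 1.0 / alpha if alpha > 0 else None

    def draw(m, n):
        m = np.repeat(m[:, None], n, axis=1)
        if shape is None:
            return rng.poisson(m)
        return rng.poisson(rng.gamma(shape, m * alpha))

    y = np.concatenate([draw(mu, n_per_group), draw(mu1, n_per_group)], axis=1)
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    cm = CountMatrix(
        pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)], columns=samples)
    )
    sf = pd.Series(1.0, index=samples)
    contrast = Contrast("sim", samples[n_per_group:], samples[:n_per_group])
    de = diffexpr.nb_wald(cm, sf, contrast, alpha)
    rejection = float(np.nanmean(de["p"] < 0.05))
    return {"rejection_rate": rejection, "n": n_genes, "median_log2fc": float(de["log2fc"].median())}
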