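"""Synthetic interferon time-course experiment with planted ground truth.

Emulates the full study design on one synthetic chromosome: negative-
binomial nascent-transcription counts following cluster-archetype temporal
profiles under two IFN treatments, three genotypes (wild type, Irf9
knockout, Irf1 knockout) with cluster-specific knockout attenuation,
TSS-versus-body read allocation with treatment-dependent Pol II pausing,
intergenic regulatory elements (TREs) whose eRNA tracks the host gene's
induction, transcription-factor peak sets covering configured fractions of
enhancers, accessibility (ATAC) counts coupled to transcription, and a
proximity-proteomics enrichment table with planted interactors.

Genes are laid out on alternating strands with >= 120 kb separation so
every enhancer within 50 kb has an unambiguous host gene. All outputs are
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import CountMatrix, GeneAnnotation, IntervalSet, SampleDesign, StrandedCoverage

TIMEPOINTS = (0.0, 1.5, 4.0, 24.0, 48.0)
ATAC_TIMEPOINTS = (0.0, 2.0, 48.0)
# accessibility timepoints sampled on the ATAC grid; each maps to the
# transcription timepoint whose induction it mirrors
ATAC_TO_PRO_TIMEPOINT = {0.0: 0.0, 2.0: 1.5, 48.0: 48.0}


@dataclass
class Archetype:
    """Temporal induction profile of one cluster, per treatment.

    ``folds`` maps treatment -> multiplicative induction mu(t)/mu(0) at the
    five timepoints; attenuation factors give the residual expression in
    each knockout; ``pausing_shift`` multiplies the pausing index under
    each treatment.
    """

    name: str
    folds: dict
    irf9_attenuation: float = 1.0
    irf1_attenuation: float = 1.0
    pausing_shift: dict = field(default_factory=lambda: {"IFNb": 1.0, "IFNg": 1.0})


def default_archetypes() -> list[Archetype]:
    """Eleven temporal archetypes mirroring the observed cluster phenomenology:

    early-transient, sustained, delayed, IFN-type-specific and repressed
    shapes; ISGF3 (IRF9)-dependent clusters are strongly attenuated in the
    Irf9 knockout, the IFNg-skewed second-wave clusters in the Irf1
    knockout. Pausing shifts are planted under IFNb only.
    """
    A = Archetype
    return [
        A("early_transient_both", {"IFNb": [1, 10, 5, 1.5, 1], "IFNg": [1, 10, 5, 1.5, 1]},
          irf9_attenuation=0.15, pausing_shift={"IFNb": 0.5, "IFNg": 1.0}),
        A("sustained_b_transient_g", {"IFNb": [1, 8, 8, 8, 6], "IFNg": [1, 8, 4, 1.5, 1]},
          irf9_attenuation=0.15, pausing_shift={"IFNb": 0.5, "IFNg": 1.0}),
        A("delayed_both", {"IFNb": [1, 1.2, 3, 8, 8], "IFNg": [1, 1.2, 3, 8, 8]},
          irf9_attenuation=0.3, pausing_shift={"IFNb": 2.0, "IFNg": 1.0}),
        A("sustained_both", {"IFNb": [1, 6, 8, 8, 8], "IFNg": [1, 6, 8, 8, 8]},
          irf9_attenuation=0.15, pausing_shift={"IFNb": 0.5, "IFNg": 1.0}),
        A("g_early_sustained", {"IFNb": [1, 1.5, 1.5, 1.2, 1], "IFNg": [1, 6, 8, 8, 8]},
          irf1_attenuation=0.2),
        A("b_specific_transient", {"IFNb": [1, 10, 6, 2, 1], "IFNg": [1, 1.2, 1.2, 1, 1]},
          irf9_attenuation=0.15, pausing_shift={"IFNb": 0.5, "IFNg": 1.0}),
        A("mid_peak_both", {"IFNb": [1, 2, 6, 3, 1], "IFNg": [1, 2, 6, 3, 1]},
          pausing_shift={"IFNb": 0.7, "IFNg": 1.0}),
        A("repressed_early_both", {"IFNb": [1, 0.4, 0.25, 0.5, 1], "IFNg": [1, 0.4, 0.25, 0.5, 1]},
          pausing_shift={"IFNb": 2.0, "IFNg": 1.0}),
        A("g_sustained_b_transient", {"IFNb": [1, 4, 2, 1, 1], "IFNg": [1, 4, 6, 8, 8]},
          irf1_attenuation=0.2),
        A("g_delayed", {"IFNb": [1, 1, 1.2, 1.5, 1.2], "IFNg": [1, 1.2, 4, 8, 8]},
          irf1_attenuation=0.2),
        A("repressed_progressive", {"IFNb": [1, 0.8, 0.5, 0.25, 0.2], "IFNg": [1, 0.8, 0.5, 0.25, 0.2]}),
    ]


@dataclass
class SimulationConfig:
    """Scale, effect sizes and noise levels of the synthetic experiment."""

    n_genes: int = 2000
    de_fraction: float = 0.6  # genes carrying an archetype; the rest stay flat
    archetypes: list = field(default_factory=default_archetypes)
    replicates: int = 3
    genotypes: tuple = ("WT", "Irf9KO", "Irf1KO")
    treatments: tuple = ("IFNb", "IFNg")
    baseline_log_mean: float = np.log(150.0)
    baseline_log_sd: float = 0.6
    nb_dispersion: float = 0.05
    base_pausing_index: float = 2.0
    gene_length_range: tuple = (2500, 5000)
    gene_spacing: int = 130_000
    chrom: str = "chrS"
    # enhancers
    enhancer_gene_fraction: float = 0.4  # of eligible (induced-cluster) genes
    enhancer_distance_range: tuple = (5_000, 48_000)
    enhancer_width: int = 300
    enhancer_base_mean: float = 30.0  # eRNA mean per strand at baseline
    n_decoy_flat: int = 120  # near a gene but not induction-concordant
    n_decoy_far: int = 80  # > 50 kb from every TSS
    genic_tre_fraction: float = 0.15  # genes given a promoter-overlapping TRE
    tre_jitter: int = 20
    peak_bound_fraction: dict = field(
        default_factory=lambda: {"IRF9": 0.56, "IRF1": 0.23}
    )  # of enhancers in the factor's dependent clusters
    peak_background_fraction: float = 0.05
    # accessibility
    atac_base_mean: float = 100.0
    atac_coupling: float = 0.7  # exponent linking accessibility to induction
    atac_dispersion: float = 0.01
    accessibility_dependent_fraction: float = 0.6  # of TF-dependent genes
    # proteomics (counts mirror the published interactome partition)
    n_proteins: int = 600
    n_stat1_unique: int = 127
    n_common: int = 7
    n_irf1_unique: int = 30
    n_stat1_steady_only: int = 50
    interactor_log2fc_mean: float = 2.5
    interactor_log2fc_sd: float = 0.4
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted truth: per-gene labels, enhancer table, interactor sets,
    and expected gene-body means per condition."""

    genes: pd.DataFrame
    enhancers: pd.DataFrame
    expected_means: pd.DataFrame  # genes x condition labels
    interactors: pd.DataFrame


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    annotation: GeneAnnotation
    design: SampleDesign
    coverages: dict  # sample_id -> StrandedCoverage
    tre_sets: dict  # condition label -> IntervalSet
    peak_sets: dict  # factor -> IntervalSet
    atac_peaks: IntervalSet
    atac_counts: CountMatrix
    atac_design: SampleDesign
    proteomics: pd.DataFrame
    truth: GroundTruth

    @property
    def library_sizes(self) -> pd.Series:
        return pd.Series({s: c.library_size for s, c in self.coverages.items()}, name="library_size")


# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha mu^2, via gamma-Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(np.maximum(mean, 0.0))
    lam = rng.gamma(shape=1.0 / alpha, scale=np.maximum(mean, 1e-12) * alpha)
    return rng.poisson(lam)


def _condition_label(genotype: str, treatment: str, tp: float) -> str:
    if treatment == "untreated":
        return f"{genotype}_untreated"
    return f"{genotype}_{treatment}_{tp:g}h"


def _build_design(cfg: SimulationConfig) -> SampleDesign:
    rows = []
    for gt in cfg.genotypes:
        for rep in range(1, cfg.replicates + 1):
            rows.append((f"{gt}_untreated_r{rep}", gt, "untreated", 0.0, rep))
            for tr in cfg.treatments:
                for tp in TIMEPOINTS[1:]:
                    rows.append((f"{gt}_{tr}_{tp:g}h_r{rep}", gt, tr, tp, rep))
    return SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment", "timepoint_h", "replicate"])
    )


def _gene_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n)
    margin = 60_000
    starts = margin + np.arange(n, dtype=np.int64) * cfg.gene_spacing
    if cfg.gene_spacing < cfg.gene_length_range[1] + 2 * (50_000 + cfg.enhancer_width):
        raise ValueError(
            "gene layout overflow: spacing too small for unambiguous 50-kb enhancer "
            "assignment; increase gene_spacing"
        )
    strands = np.where(np.arange(n) % 2 == 0, "+", "-")
    n_de = int(round(n * cfg.de_fraction))
    arch_idx = np.full(n, -1)
    de_genes = rng.choice(n, size=n_de, replace=False)
    arch_idx[de_genes] = np.arange(n_de) % len(cfg.archetypes)
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n))
    df = pd.DataFrame(
        {
            "gene_id": [f"gene_{i + 1:04d}" for i in range(n)],
            "chrom": cfg.chrom,
            "strand": strands,
            "start": starts,
            "end": starts + lengths,
            "archetype_idx": arch_idx,
            "baseline_mean": baseline,
        }
    )
    df["archetype"] = [
        cfg.archetypes[i].name if i >= 0 else "background" for i in df["archetype_idx"]
    ]
    return df


def _expected_mean(cfg: SimulationConfig, gene: pd.Series, genotype: str, treatment: str, tp: float) -> float:
    """Expected body-region NB mean for one gene in one condition."""
    base = gene["baseline_mean"]
    ai = gene["archetype_idx"]
    if ai < 0:
        return float(base)
    arch = cfg.archetypes[int(ai)]
    ti = TIMEPOINTS.index(tp)
    fold = 1.0 if treatment == "untreated" else arch.folds[treatment][ti]
    att = 1.0
    if genotype == "Irf9KO":
        att = arch.irf9_attenuation
    elif genotype == "Irf1KO":
        att = arch.irf1_attenuation
    return float(base * fold * att)


def generate_experiment(cfg: SimulationConfig | None = None) -> SimulatedExperiment:
    """Generate the full synthetic experiment. Deterministic given cfg.seed."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    design = _build_design(cfg)
    genes = _gene_table(cfg, rng)
    ann = GeneAnnotation(genes[["gene_id", "chrom", "strand", "start", "end"]])
    genes = genes.merge(ann.df[["gene_id", "tss", "tes"]], on="gene_id")

    # --- per-condition expected means (truth) -----------------------------
    cond_labels, cond_keys = [], []
    for gt in cfg.genotypes:
        cond_labels.append(_condition_label(gt, "untreated", 0.0))
        cond_keys.append((gt, "untreated", 0.0))
        for tr in cfg.treatments:
            for tp in TIMEPOINTS[1:]:
                cond_labels.append(_condition_label(gt, tr, tp))
                cond_keys.append((gt, tr, tp))
    mean_mat = np.empty((len(genes), len(cond_keys)))
    for j, (gt, tr, tp) in enumerate(cond_keys):
        mean_mat[:, j] = [
            _expected_mean(cfg, genes.iloc[i], gt, tr, tp) for i in range(len(genes))
        ]
    expected_means = pd.DataFrame(mean_mat, index=genes["gene_id"], columns=cond_labels)

    # --- enhancers, decoys, genic TREs -------------------------------------
    enh_table = _plant_tres(cfg, genes, rng)
    peak_sets, enh_table = _plant_peaks(cfg, enh_table, genes, rng)

    # --- coverage per sample -----------------------------------------------
    coverages = {}
    for _, sample in design.df.iterrows():
        coverages[sample["sample_id"]] = _sample_coverage(
            cfg, genes, enh_table, sample, expected_means, rng
        )

    # --- TRE discovery sets (one per treated condition, jittered) ----------
    tre_sets = {}
    for tr in cfg.treatments:
        for tp in TIMEPOINTS[1:]:
            label = f"WT_{tr}_{tp:g}h"
            jit = rng.integers(-cfg.tre_jitter, cfg.tre_jitter + 1, size=(len(enh_table), 2))
            df = pd.DataFrame(
                {
                    "chrom": cfg.chrom,
                    "start": enh_table["start"].to_numpy() + jit[:, 0],
                    "end": enh_table["end"].to_numpy() + jit[:, 1],
                }
            )
            tre_sets[label] = IntervalSet(df)

    # --- ATAC ---------------------------------------------------------------
    atac_peaks, atac_counts, atac_design, genes = _plant_atac(cfg, genes, rng)

    # --- proteomics ---------------------------------------------------------
    proteomics, interactor_truth = _plant_proteomics(cfg, rng)

    # --- truth labels -------------------------------------------------------
    early_fold = np.zeros(len(genes))
    for i, row in genes.iterrows():
        ai = int(row["archetype_idx"])
        if ai >= 0:
            arch = cfg.archetypes[ai]
            early_fold[i] = max(arch.folds["IFNb"][1], arch.folds["IFNg"][1])
    genes["early_induced"] = early_fold >= 2.0
    genes["irf9_attenuation"] = [
        cfg.archetypes[int(i)].irf9_attenuation if i >= 0 else 1.0 for i in genes["archetype_idx"]
    ]
    genes["irf1_attenuation"] = [
        cfg.archetypes[int(i)].irf1_attenuation if i >= 0 else 1.0 for i in genes["archetype_idx"]
    ]
    genes["irf9_dependent"] = genes["early_induced"] & (genes["irf9_attenuation"] < 0.5)
    genes["irf1_dependent"] = genes["early_induced"] & (genes["irf1_attenuation"] < 0.5)

    truth = GroundTruth(
        genes=genes,
        enhancers=enh_table,
        expected_means=expected_means,
        interactors=interactor_truth,
    )
    return SimulatedExperiment(
        config=cfg,
        annotation=ann,
        design=design,
        coverages=coverages,
        tre_sets=tre_sets,
        peak_sets=peak_sets,
        atac_peaks=atac_peaks,
        atac_counts=atac_counts,
        atac_design=atac_design,
        proteomics=proteomics,
        truth=truth,
    )


def _plant_tres(cfg: SimulationConfig, genes: pd.DataFrame, rng) -> pd.DataFrame:
    """Lay out true enhancers, non-concordant decoys, far decoys and genic TREs."""
    rows = []
    # true enhancers: on genes whose archetype is induced somewhere
    induced = genes[(genes["archetype_idx"] >= 0)].copy()
    is_induced_arch = [
        max(max(cfg.archetypes[int(i)].folds[t]) for t in cfg.treatments) >= 2.0
        for i in induced["archetype_idx"]
    ]
    induced = induced[np.asarray(is_induced_arch)]
    n_enh = int(round(len(induced) * cfg.enhancer_gene_fraction))
    hosts = induced.iloc[rng.choice(len(induced), size=n_enh, replace=False)]
    d_lo, d_hi = cfg.enhancer_distance_range
    for _, g in hosts.iterrows():
        d = int(rng.integers(d_lo, d_hi + 1))
        # place upstream of the TSS (outside the gene span by construction)
        if g["strand"] == "+":
            start = int(g["tss"]) - d - cfg.enhancer_width
            end = start + cfg.enhancer_width
        else:
            start = int(g["tss"]) + d
            end = start + cfg.enhancer_width
        rows.append((cfg.chrom, start, end, g["gene_id"], "enhancer"))
    # flat decoys: near a random gene but with constant eRNA
    all_genes = genes.reset_index(drop=True)
    for _ in range(cfg.n_decoy_flat):
        g = all_genes.iloc[int(rng.integers(len(all_genes)))]
        d = int(rng.integers(d_lo, d_hi + 1))
        if g["strand"] == "+":
            start = int(g["tss"]) - d - cfg.enhancer_width - 600  # offset: avoid true enhancer
        else:
            start = int(g["tss"]) + d + 600
        rows.append((cfg.chrom, start, start + cfg.enhancer_width, g["gene_id"], "decoy_flat"))
    # far decoys: midway between neighborhoods, > 50 kb from every TSS
    for _ in range(cfg.n_decoy_far):
        g = all_genes.iloc[int(rng.integers(len(all_genes) - 1))]
        start = int(g["end"]) + 55_000 + int(rng.integers(0, 5_000))
        rows.append((cfg.chrom, start, start + cfg.enhancer_width, "", "decoy_far"))
    # genic TREs: cover the TSS (inside the gene span)
    n_genic = int(round(len(genes) * cfg.genic_tre_fraction))
    for gi in rng.choice(len(all_genes), size=n_genic, replace=False):
        g = all_genes.iloc[int(gi)]
        mid = int(g["tss"])
        lo = max(int(g["start"]), mid - cfg.enhancer_width // 2)
        rows.append((cfg.chrom, lo, min(int(g["end"]), lo + cfg.enhancer_width), g["gene_id"], "genic"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "kind"])
    df = df.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "truth_id", [f"truth_tre_{i + 1:05d}" for i in range(len(df))])
    return df


def _plant_peaks(cfg: SimulationConfig, enh_table: pd.DataFrame, genes: pd.DataFrame, rng):
    """ChIP peak sets covering configured fractions of enhancers per factor."""
    arch_of_gene = genes.set_index("gene_id")["archetype_idx"]
    peak_sets = {}
    for factor, frac in cfg.peak_bound_fraction.items():
        bound = np.zeros(len(enh_table), dtype=bool)
        enh_mask = (enh_table["kind"] == "enhancer").to_numpy()
        att = np.ones(len(enh_table))
        hosts = enh_table["gene_id"].to_numpy()
        for i in np.flatnonzero(enh_mask):
            arch = cfg.archetypes[int(arch_of_gene.loc[hosts[i]])]
            att[i] = arch.irf9_attenuation if factor == "IRF9" else arch.irf1_attenuation
        dependent = enh_mask & (att < 0.5)
        others = enh_mask & ~dependent
        for mask, f in ((dependent, frac), (others, cfg.peak_background_fraction)):
            idx = np.flatnonzero(mask)
            k = int(round(len(idx) * f))
            if k:
                bound[rng.choice(idx, size=k, replace=False)] = True
        enh_table[f"bound_{factor}"] = bound
        sub = enh_table[bound]
        peaks = pd.DataFrame(
            {
                "chrom": sub["chrom"],
                "start": sub["start"] - 100,
                "end": sub["end"] + 100,
                "name": [f"{factor}_peak_{i + 1:04d}" for i in range(len(sub))],
            }
        )
        peak_sets[factor] = IntervalSet(peaks)
    return peak_sets, enh_table


def _sample_coverage(
    cfg: SimulationConfig,
    genes: pd.DataFrame,
    enh_table: pd.DataFrame,
    sample: pd.Series,
    expected_means: pd.DataFrame,
    rng,
) -> StrandedCoverage:
    label = _condition_label(sample["genotype"], sample["treatment"], sample["timepoint_h"])
    mean_body = expected_means[label].to_numpy()

    body_counts = _nb_draw(rng, mean_body, cfg.nb_dispersion)
    # target pausing index per gene in this condition
    pi = np.full(len(genes), cfg.base_pausing_index)
    if sample["treatment"] != "untreated":
        shifts = np.array(
            [
                cfg.archetypes[int(i)].pausing_shift.get(sample["treatment"], 1.0) if i >= 0 else 1.0
                for i in genes["archetype_idx"]
            ]
        )
        pi = pi * shifts
    lengths = (genes["end"] - genes["start"]).to_numpy()
    body_len = lengths - 1000  # gene minus TSS region and tail
    tss_mean = pi * 500.0 * body_counts / body_len
    tail_mean = 500.0 * body_counts / body_len
    tss_counts = rng.poisson(tss_mean)
    tail_counts = rng.poisson(tail_mean)

    plus = (genes["strand"] == "+").to_numpy()
    g_start = genes["start"].to_numpy(np.int64)
    g_end = genes["end"].to_numpy(np.int64)
    # region bounds in genomic coordinates per gene
    tss_lo = np.where(plus, g_start, g_end - 500)
    body_lo = g_start + 500
    tail_lo = np.where(plus, g_end - 500, g_start)

    events_plus, events_minus = [], []
    for counts, lo, span in (
        (tss_counts, tss_lo, np.full(len(genes), 500)),
        (body_counts, body_lo, body_len),
        (tail_counts, tail_lo, np.full(len(genes), 500)),
    ):
        total = int(counts.sum())
        if total == 0:
            continue
        lo_rep = np.repeat(lo, counts)
        span_rep = np.repeat(span, counts)
        pos = lo_rep + (rng.random(total) * span_rep).astype(np.int64)
        strand_rep = np.repeat(plus, counts)
        events_plus.append(pos[strand_rep])
        events_minus.append(pos[~strand_rep])

    # eRNA on TREs (both strands); enhancers track the host gene's induction
    tre_mean = np.zeros(len(enh_table))
    gene_idx = {g: i for i, g in enumerate(genes["gene_id"])}
    for i, row in enumerate(enh_table.itertuples(index=False)):
        if row.kind == "enhancer":
            gi = gene_idx[row.gene_id]
            fold = mean_body[gi] / genes["baseline_mean"].iloc[gi]
            tre_mean[i] = cfg.enhancer_base_mean * fold
        elif row.kind in ("decoy_flat", "decoy_far"):
            tre_mean[i] = cfg.enhancer_base_mean
        else:  # genic: promoter-proximal signal already present; add modest eRNA
            tre_mean[i] = cfg.enhancer_base_mean
    tre_lo = enh_table["start"].to_numpy(np.int64)
    tre_span = (enh_table["end"] - enh_table["start"]).to_numpy()
    for strand_events in (events_plus, events_minus):
        cnts = _nb_draw(rng, tre_mean, cfg.nb_dispersion)
        total = int(cnts.sum())
        if total:
            lo_rep = np.repeat(tre_lo, cnts)
            span_rep = np.repeat(tre_span, cnts)
            strand_events.append(lo_rep + (rng.random(total) * span_rep).astype(np.int64))

    return StrandedCoverage.from_positions(
        {
            (cfg.chrom, "+"): np.concatenate(events_plus) if events_plus else np.empty(0, np.int64),
            (cfg.chrom, "-"): np.concatenate(events_minus) if events_minus else np.empty(0, np.int64),
        }
    )


def _plant_atac(cfg: SimulationConfig, genes: pd.DataFrame, rng):
    """Accessibility peaks at every TSS and NB counts coupled to induction."""
    tss = genes["tss"].to_numpy(np.int64)
    peaks = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": tss - 200,
            "end": tss + 200,
            "name": [f"atac_{g}" for g in genes["gene_id"]],
        }
    )
    atac_peaks = IntervalSet(peaks)

    # which TF-dependent genes also depend on the TF for accessibility
    acc_dep = np.zeros(len(genes), dtype=bool)
    dep_mask = np.array(
        [
            (cfg.archetypes[int(i)].irf9_attenuation < 0.5 or cfg.archetypes[int(i)].irf1_attenuation < 0.5)
            if i >= 0
            else False
            for i in genes["archetype_idx"]
        ]
    )
    dep_idx = np.flatnonzero(dep_mask)
    k = int(round(len(dep_idx) * cfg.accessibility_dependent_fraction))
    if k:
        acc_dep[rng.choice(dep_idx, size=k, replace=False)] = True
    genes = genes.copy()
    genes["accessibility_dependent"] = acc_dep

    rows = []
    for gt in cfg.genotypes:
        for rep in range(1, cfg.replicates + 1):
            rows.append((f"atac_{gt}_untreated_r{rep}", gt, "untreated", 0.0, rep))
            for tr in cfg.treatments:
                for tp in ATAC_TIMEPOINTS[1:]:
                    rows.append((f"atac_{gt}_{tr}_{tp:g}h_r{rep}", gt, tr, tp, rep))
    atac_design = SampleDesign(
        pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment", "timepoint_h", "replicate"])
    )

    values = {}
    for _, s in atac_design.df.iterrows():
        pro_tp = ATAC_TO_PRO_TIMEPOINT[s["timepoint_h"]]
        means = np.empty(len(genes))
        for i, row in enumerate(genes.itertuples(index=False)):
            ai = int(row.archetype_idx)
            fold = 1.0
            att = 1.0
            if ai >= 0 and s["treatment"] != "untreated":
                arch = cfg.archetypes[ai]
                fold = arch.folds[s["treatment"]][TIMEPOINTS.index(pro_tp)]
            if ai >= 0 and row.accessibility_dependent:
                arch = cfg.archetypes[ai]
                if s["genotype"] == "Irf9KO":
                    att = arch.irf9_attenuation
                elif s["genotype"] == "Irf1KO":
                    att = arch.irf1_attenuation
            means[i] = cfg.atac_base_mean * (fold * att) ** cfg.atac_coupling
        values[s["sample_id"]] = _nb_draw(rng, means, cfg.atac_dispersion)
    counts = CountMatrix(
        pd.DataFrame(values, index=peaks["name"].values),
        pd.Series((peaks["end"] - peaks["start"]).values, index=peaks["name"].values),
    )
    return atac_peaks, counts, atac_design, genes


def _plant_proteomics(cfg: SimulationConfig, rng):
    """Enrichment table with planted interactor sets for two baits."""
    proteins = [f"prot_{i + 1:04d}" for i in range(cfg.n_proteins)]
    order = rng.permutation(cfg.n_proteins)
    i = iter(order)
    stat1_unique = [proteins[next(i)] for _ in range(cfg.n_stat1_unique)]
    common = [proteins[next(i)] for _ in range(cfg.n_common)]
    irf1_unique = [proteins[next(i)] for _ in range(cfg.n_irf1_unique)]
    stat1_steady = [proteins[next(i)] for _ in range(cfg.n_stat1_steady_only)]

    membership = {}  # (bait, protein) -> set of conditions present
    for prot in stat1_unique + common:
        conds = {"IFNb_3h", "IFNg_3h", "steady"} if rng.random() < 0.5 else {
            ("IFNb_3h" if rng.random() < 0.5 else "IFNg_3h")
        }
        membership[("STAT1", prot)] = conds
    for prot in stat1_steady:
        membership[("STAT1", prot)] = {"steady"}
    for prot in irf1_unique + common:
        conds = {"IFNb_3h", "IFNg_3h"} if rng.random() < 0.5 else {
            ("IFNb_3h" if rng.random() < 0.5 else "IFNg_3h")
        }
        membership[("IRF1", prot)] = conds

    rows = []
    for bait in ("STAT1", "IRF1"):
        for prot in proteins:
            for cond in ("steady", "IFNb_3h", "IFNg_3h"):
                present = cond in membership.get((bait, prot), set())
                if present:
                    lfc = rng.normal(cfg.interactor_log2fc_mean, cfg.interactor_log2fc_sd)
                    padj = 10.0 ** (-rng.uniform(2, 6))
                else:
                    lfc = rng.normal(0.0, 0.3)
                    padj = rng.uniform(0.1, 1.0)
                rows.append((prot, bait, cond, lfc, padj))
    table = pd.DataFrame(rows, columns=["protein_id", "bait", "condition", "log2fc", "padj"])

    truth_rows = []
    for (bait, prot), conds in membership.items():
        truth_rows.append((prot, bait, ",".join(sorted(conds)), "steady" not in conds or len(conds) > 1))
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "bait", "conditions", "active_state"])
    return table, truth


def truth_tables(truth: GroundTruth, outdir) -> dict:
    """Serialize each truth facet as a TSV; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "truth_genes.tsv",
        "enhancers": outdir / "truth_enhancers.tsv",
        "expected_means": outdir / "truth_expected_means.tsv",
        "interactors": outdir / "truth_interactors.tsv",
    }
    truth.genes.to_csv(paths["genes"], sep="\t", index=False)
    truth.enhancers.to_csv(paths["enhancers"], sep="\t", index=False)
    truth.expected_means.to_csv(paths["expected_means"], sep="\t", index_label="gene_id")
    truth.interactors.to_csv(paths["interactors"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
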