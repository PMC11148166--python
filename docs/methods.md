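# Methods

## Coordinate conventions and signal model

All internal coordinates are 0-based half-open `[start, end)`; GTF input
(1-based inclusive) is converted at the boundary, and BED/bedGraph pass
through unchanged. Nascent-transcription signal is modeled as single-base
read 3′-end counts on each strand (the standard PRO-seq convention);
minus-strand bedGraph values may be negative by dialect and are stored as
absolute signal. A gene has one TSS — the annotated gene-level 5′ end
(`start` on +, `end − 1` on −); alternative isoform TSSs are out of
scope. Interval algebra follows bedtools semantics: bookended intervals
merge, overlap requires ≥ 1 shared base, and subtraction is per-base set
difference.

## Quantification windows

With TSS offset *o* = 500 bp and tail trim *t* = 500 bp, in transcription
direction:

* **TSS region**: `[tss, tss + o)` — promoter-proximal, where paused
  polymerase accumulates.
* **Gene body (expression)**: `[tss + o, 3′ end)`; genes whose body is
  shorter than 1 kb are excluded. The 1-kb filter is interpreted as a
  *post-offset body-length* filter (the offset is described first, the
  exclusion second); both the offset and the threshold are arguments.
* **Gene body (pausing)**: `[tss + o, 3′ end − t)` — the tail is trimmed
  because termination-proximal signal is not informative for pausing.

Gene counting is same-strand only; regulatory-element (TRE) counting sums
both strands, since eRNA is bidirectional. Window sums are rounded
half-up to integers so the NB machinery sees counts. Densities are
cpm/bp: `(count / library_size × 10⁶) / length`, with the library size
taken from the whole sample, never from the counted subset.

## Differential transcription

The DE layer is a deliberately transparent NB Wald test, not a DESeq2
reimplementation. Differences from DESeq2 are documented here and matter
only beyond the (log2FC, padj) thresholds the downstream screens use: no
LFC shrinkage, no Cook's-distance filtering, no independent filtering.

* **Size factors**: median-of-ratios against the geometric-mean
  reference over features nonzero in every sample, normalized to
  geometric mean 1; total-count fallback (with a warning) if no such
  feature exists.
* **Dispersion** (`var = μ + αμ²`): per-feature method-of-moments on
  normalized counts within replicate groups, floored at 10⁻⁸, then
  shrunk 50/50 on the log scale toward a robustly fitted trend
  `α(μ) = a₀ + a₁/μ`.
* **Wald test**: per feature, the two-group log-linear model
  `μ_ij = s_j exp(β₀ + β₁ x_j)` is fitted by IRLS (vectorized across
  features, which all share the design), with fixed α and expected
  Fisher information for `se(β₁)`; z = β₁/se, two-sided normal p, BH
  adjustment per contrast with NA excluded from the denominator.
  Coefficients are clamped to ±30 (nats) so one-sided-zero features stay
  finite. Calibration on null simulations (n = 3 vs 3, α ∈ {0.01, 0.1})
  gives type-I error ≈ 0.05 and power ~1 at four-fold changes with
  μ ≥ 50; the acceptance script reproduces both numbers.
* **VST**: `log2(normalized + 4)`. The pseudocount 4 flattens variance
  at low counts (approximating the closed-form NB VST near zero) and
  converges to log2 at high abundance; it is configurable.

Screens are exact about comparison strictness: the clustering screen
uses |log2FC| ≥ 1 and padj < 0.01; the dependence screen uses
log2FC ≥ 1 (or ≤ −1) and padj ≤ 0.05. One printed accessibility
criterion reads "log2FC ≤ 1" in the source material's figure legend; it
is implemented as ≤ −1 (a *decrease* in accessibility), consistent with
the accompanying prose.

## Clustering

Per condition, significant genes are ordered by padj (ties broken by
larger |log2FC|, then gene id — the ordering is otherwise undefined) and
the top 1000 taken; the union over the eight treatment/timepoint
contrasts is the clustering input. Replicates are averaged per
condition, and each gene's profile is z-scored separately within each
IFN-type block (the block contains that treatment's conditions plus the
untreated baseline); constant rows map to zeros. Both IFN blocks are
concatenated for one joint Ward clustering — scipy's `ward` on Euclidean
distances, i.e. the Ward.D2 convention — cut at k = 11. k defaults to 11
because that is the observed number of distinct temporal patterns; no
automatic model selection is attempted. Clusters are renumbered by
decreasing size for determinism. The z-scoring scope (`wt_only` vs
`all_genotypes`) is an explicit argument because the wild-type-only
heatmap and the knockout trend panels use different scopes.

## Pausing

PI = TSS density / body density (both cpm/bp); PI is undefined — not 0,
not ∞ — when either density is zero, and such genes are dropped pairwise
per contrast, not globally. Condition-level PIs are computed from
replicate-pooled counts (replicate handling is otherwise unspecified; a
per-replicate table is also available). Because cpm cancels in the
ratio, PI is invariant to library size. Treatment effects are ln(PI_t /
PI_u); per cluster, untreated vs treated gene-level PI distributions are
compared with a two-sided Mann–Whitney U — exact enumeration over label
assignments (midranks, so ties are handled) when both groups have ≤ 8
genes, otherwise the normal approximation with tie and continuity
correction. The "most relevant timepoint" for the test is an explicit
argument, not guessed.

## Enhancer linkage

TRE discovery itself (a trained model over nascent signal) is an input,
not reimplemented. Per-condition TRE sets are unioned and merged; gene
spans are subtracted strand-ignorantly and fragments under 50 bp
discarded (avoids degenerate 1-bp "enhancers"). A surviving TRE links to
*every* gene whose TSS lies within 50 kb (distance 0 if the TRE covers
the TSS, else nearest-boundary distance); the synthetic layout spaces
genes ≥ 120 kb apart so linkage is unambiguous there. A link is
*concordant* when the TRE's both-strand eRNA counts are significantly
induced (log2FC ≥ 1, padj < 0.01) in at least one contrast in which the
linked gene's cluster is induced, where a cluster counts as induced in a
contrast when ≥ 50% of its genes are significantly up there. Bound
fraction per cluster = enhancers with ≥ 1 bp overlap with the factor's
peak union / all enhancers in the cluster.

## Chromatin and proteome integration

Accessibility peaks are assigned to their nearest TSS and dropped beyond
2 kb; a gene's accessibility DE is its most significant assigned peak.
The dependence classes are nested by construction: *induced* (up in WT
under either IFN at 1.5 h), *TF-dependent* (induced ∧ down in the
knockout vs WT in transcription), *TF-and-accessibility-dependent*
(TF-dependent ∧ accessibility down in the knockout, evaluated as an OR
over IFN treatment and homeostasis). Genes without an assigned peak are
flagged and can never be accessibility-dependent. Transcription and
accessibility trends are compared as per-gene Pearson correlations of
matched condition z-profiles on each assay's own timepoint grid (early =
1.5 h for transcription, 2 h for accessibility; late = 48 h); constant
rows give NaN and are excluded from medians.

Proteomics enrichment tables (moderated statistics computed upstream)
are filtered with bait-specific thresholds — log2FC ≥ 1 (STAT1-BirA*) or
≥ 0.5 (IRF1-BirA*) over the nuclear-localized ligase control, padj
< 0.05 (strict by default, configurable) — then proteins found only at
steady state are removed and the active-state sets Venn-partitioned.

## Synthetic experiment

The generator is the package's test bed: one synthetic chromosome, genes
on alternating strands spaced 130 kb apart, full design (3 genotypes × 2
treatments × 4 timepoints + untreated, 3 replicates = 81 coverage
tracks). Defaults: 2000 genes, 60% carrying one of 11 temporal
archetypes (early-transient, sustained, delayed, IFN-type-specific,
repressed shapes with induction folds up to 10 and attenuations of
0.15–0.3 in the dependent knockout), baseline body-count means lognormal
around 150, NB dispersion α = 0.05.

Per condition, a gene's body count is drawn NB(baseline × archetype fold
× knockout attenuation, α); the TSS-region count is Poisson with mean
`PI × 500 × body / body_length` where PI = 2 × planted shift (shifts are
planted under IFNb only), and a tail count continues the body density.
Reads are scattered uniformly within each window. True enhancers are
placed 5–48 kb upstream of 40% of induced-cluster genes with eRNA on
both strands tracking the host gene's induction; decoys are either
non-concordant (flat eRNA near a gene), > 50 kb from every TSS, or
promoter-overlapping (removed by genic exclusion). ChIP peaks cover 56%
(IRF9) / 23% (IRF1) of enhancers in the respective dependent clusters
and 5% elsewhere. Accessibility counts at each promoter follow
`base × (fold × attenuation)^0.7` with attenuation applied only to the
60% of dependent genes planted as accessibility-dependent; ATAC
dispersion is 0.01, reflecting that promoter accessibility varies far
less across replicates than bursty nascent transcription (and making the
planted accessibility labels identifiable at the screen thresholds). The
proteomics table plants 184 STAT1 interactors (50 steady-only) and 37
IRF1 interactors with 7 shared active-state proteins, so the set logic
yields a 127/7/30 partition; enrichment effect sizes (log2FC ~ N(2.5,
0.4), tiny padj) sit far from the thresholds, making the counts
deterministic in practice.

What the generator does **not** emulate: mappability artifacts, multi-
mapping, batch effects, chained or shared enhancers (each enhancer has
one unambiguous host), isoform structure, partial/graded knockout
effects near the decision thresholds, and missing-value structure in
proteomics. Passing tests therefore demonstrate the correctness of the
analysis logic under the planted model, not robustness to every artifact
of real sequencing data.

Knockout attenuation multiplies the expected count at *all* timepoints
(basal expression of an ISGF3-dependent gene is reduced in the knockout
too), which is the simplest model consistent with the knockout-vs-WT
contrasts used downstream. Dependence truth labels are derived from the
config as "attenuation < 0.5 ∧ early induction fold ≥ 2", because
knockout dependence is only observable at the early contrast the
classification uses.

## Numerical choices and degenerate inputs

* Counts are rounded half-up; IRLS runs ≤ 50 iterations to Δβ < 10⁻¹⁰
  with coefficients clamped at ±30 nats.
* All-zero features give NA p-values and leave the BH denominator.
* z-scoring maps constant profiles to zeros; PCA is centered, unscaled,
  via SVD, components ordered by eigenvalue.
* Top-N selection, cluster renumbering and TRE id assignment use stable
  sorts with documented tie-breaks, so outputs are deterministic given
  the seed.
* Problem sizes in the test suite and acceptance script (2000-gene
  default study, 2000-feature calibration simulations, 1000 randomized
  interval instances) were chosen to give stable metrics at minutes-scale
  runtimes on one CPU.

## Known limitations

The DE layer supports only two-group contrasts with size factors (no
interaction terms or continuous covariates). Multi-gene enhancer
neighborhoods are linked to all candidate genes but the synthetic layout
never exercises ambiguous linkage. The exact Mann–Whitney branch
enumerates up to C(16,8) assignments and is only used for small
clusters. bigWig binary IO is not included — coverage is read from
bedGraph pairs (convert externally if needed).
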