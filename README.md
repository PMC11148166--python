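# isgdyn

Temporal dynamics of interferon-stimulated nascent transcription: a
reusable analysis pipeline for stranded, base-resolution nascent-RNA
(PRO-seq style) coverage across an IFNβ/IFNγ time course in wild-type and
transcription-factor knockout (Irf9⁻/⁻, Irf1⁻/⁻) cells.

Interferon-stimulated genes (ISGs) are driven by two tiers of
transcription factors — the ISGF3 complex (STAT1–STAT2–IRF9) and the
second-tier factor IRF1 — whose differential use over time separates the
type I and type II IFN transcriptomes. `isgdyn` implements the
computational layers of that analysis for anyone working with nascent
transcription data:

* **Gene quantification** from stranded coverage: gene-body counts that
  skip the first 500 bp downstream of the TSS (promoter-proximal pausing
  bias), excluding genes with a body under 1 kb.
* **Differential transcription**: a transparent negative-binomial Wald
  test (median-of-ratios size factors, trend-shrunk method-of-moments
  dispersion, BH adjustment per contrast, `log2(normalized + 4)` VST).
* **Temporal clustering**: the top differentially transcribed genes per
  condition (ordered by adjusted p) are pooled, condition-averaged VST
  profiles z-scored separately per IFN type, and Ward.D2 hierarchical
  clustering is cut at k = 11.
* **Pol II pausing**: pausing index PI = (TSS-region cpm/bp) / (gene-body
  cpm/bp, last 500 bp trimmed); ln PI ratios of treated vs untreated and
  per-cluster two-sided Mann–Whitney U tests (exact for small clusters).
* **Enhancer (eRNA) linkage**: merge per-condition TRE sets, exclude
  genic regions, link TREs to genes with a TSS within 50 kb, keep
  induction-concordant links (TRE log2FC ≥ 1, padj < 0.01 in a contrast
  where the gene's cluster is induced), and compute ChIP-bound fractions
  per cluster.
* **Chromatin integration**: ATAC peaks annotated to the nearest TSS
  (≤ 2 kb); genes classified as induced / TF-dependent /
  TF-and-accessibility-dependent from matched PRO and ATAC knockout
  contrasts (log2FC ≥ 1 resp. ≤ −1, padj ≤ 0.05).
* **Proximity proteomics**: TurboID interactor filtering with
  bait-specific enrichment thresholds (STAT1 log2FC ≥ 1, IRF1 ≥ 0.5,
  padj < 0.05 over the nuclear ligase control), steady-state-only
  exclusion, and Venn partitioning.
* **Synthetic experiment generator** with planted ground truth (temporal
  archetypes, knockout attenuation, pausing shifts, enhancers, bound
  fractions, accessibility coupling, interactor sets) so every stage is
  testable end to end without any sequencing data.

## Worked example

Each script in `examples/` exercises one capability on a small synthetic
dataset. For instance:

```bash
python examples/02_differential_and_clustering.py
```

prints

```
IFNb 1.5 h vs untreated: 138 significant genes (|log2FC| >= 1, padj < 0.01) of 400 tested
pooled across all 8 contrasts: 271 genes
clusters: 11, ARI vs planted archetypes: 0.86
```

meaning the NB Wald screen finds the induced/repressed genes, pooling
the top genes of all eight treatment-vs-untreated contrasts yields the
clustering input, and Ward.D2 at k = 11 re-finds the planted temporal
archetypes with an adjusted Rand index of 0.86 (1.0 = identical
partitions). `examples/03_pausing.py` shows the planted pausing shifts
being recovered as median ln PI ratios (−0.69 for a 0.5× multiplier)
under IFNβ only, and `examples/04_enhancers.py` reports enhancer
precision/recall of 1.00 against the planted truth with bound fractions
matching the configured 56% (IRF9) and 23% (IRF1).

The same stages are available from the shell:

```bash
isgdyn simulate --seed 3 --n-genes 200 --out sim/
isgdyn quantify --mode body --coverage-manifest sim/coverage_manifest.tsv \
    --annotation sim/annotation.tsv --out body.tsv
isgdyn de --counts body.tsv --design sim/design.tsv \
    --contrast "WT:IFNb:1.5|WT:untreated:0" --out de.tsv
isgdyn run-all --seed 3 --out report.json
```

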