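"""Generate a small synthetic IFN time course and quantify gene windows.

The generator plants negative-binomial nascent-transcription counts with
cluster-specific temporal profiles on a single synthetic chromosome and
emits base-resolution stranded coverage. Quantification then recovers
gene-body counts (skipping the first 500 bp downstream of the TSS, where
paused polymerase accumulates) and promoter-proximal TSS-region counts.
"""

import numpy as np

from isgdyn import SimulationConfig, generate_experiment, quantify

cfg = SimulationConfig(n_genes=120, seed=42, n_decoy_flat=10, n_decoy_far=5)
exp = generate_experiment(cfg)

print(f"samples: {len(exp.design)}  genes: {len(exp.annotation)}")
print(f"library size of first sample: {exp.library_sizes.iloc[0]:.0f} reads")

body = quantify.count_gene_bodies(exp.coverages, exp.annotation)
tss = quantify.count_tss_regions(exp.coverages, exp.annotation)

sample = exp.design.samples_for("WT", "IFNb", 1.5)[0]
untreated = exp.design.samples_for("WT", "untreated")[0]
induced = exp.truth.genes.query("archetype == 'early_transient_both'")["gene_id"].head(3)
print("\ngene-body counts, early-transient cluster genes (untreated vs IFNb 1.5 h):")
for g in induced:
    print(f"  {g}: {body.values.loc[g, untreated]:5d} -> {body.values.loc[g, sample]:5d}")
ratio = (tss.values[sample] / 500) / (body.values[sample] / body.lengths)
print(f"\nmedian TSS/body density ratio (crude pausing proxy): {np.nanmedian(ratio):.2f}")
print("values near the configured base pausing index (2.0) indicate promoter-")
print("proximal read enrichment; induced genes jump roughly 10-fold at 1.5 h.")
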