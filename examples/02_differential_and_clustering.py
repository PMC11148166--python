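"""Differential transcription and temporal clustering of induced genes.

Each IFN treatment/timepoint is contrasted against the untreated baseline
with the NB Wald test; the top differentially transcribed genes are
pooled, their condition-averaged VST profiles z-scored per IFN type, and
Ward.D2 clustering cut at k = 11 recovers the planted temporal archetypes
(measured by the adjusted Rand index against the ground truth).
"""

from sklearn.metrics import adjusted_rand_score

from isgdyn import SimulationConfig
from isgdyn.pipeline import run_pipeline

result = run_pipeline(SimulationConfig(n_genes=400, seed=7, n_decoy_flat=20, n_decoy_far=10))

de = result.de_wt["WT_IFNb_1.5h"]
sig = de[(de["log2fc"].abs() >= 1) & (de["padj"] < 0.01)]
print(f"IFNb 1.5 h vs untreated: {len(sig)} significant genes "
      f"(|log2FC| >= 1, padj < 0.01) of {len(de)} tested")
print(f"pooled across all 8 contrasts: {len(result.pooled_genes)} genes")

truth = result.experiment.truth.genes.set_index("gene_id")["archetype"]
common = result.assignment.labels.index.intersection(truth.index[truth != "background"])
ari = adjusted_rand_score(truth.loc[common], result.assignment.labels.loc[common])
print(f"clusters: {result.assignment.k}, ARI vs planted archetypes: {ari:.2f}")
print("ARI of 1.0 would be perfect recovery; >= 0.8 means the temporal")
print("archetypes (transient/sustained/delayed/repressed) are essentially re-found.")
sizes = result.assignment.labels.value_counts().sort_index()
print(f"cluster sizes: {sizes.tolist()}")
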