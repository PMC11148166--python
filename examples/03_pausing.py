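"""Pol II pausing-index analysis on the synthetic time course.

The pausing index (PI) is the promoter-proximal read density (cpm/bp in
the first 500 bp downstream of the TSS) over the gene-body density
(cpm/bp, excluding the last 500 bp). The generator plants PI multipliers
under IFNb only, so the ln(PI treated / PI untreated) ratios and the
per-cluster Mann-Whitney tests should fire for IFNb and stay null for
IFNg — mirroring the observation that pausing changes track type I IFN
signaling.
"""

import numpy as np

from isgdyn import SimulationConfig
from isgdyn.pipeline import run_pipeline

result = run_pipeline(SimulationConfig(n_genes=400, seed=7, n_decoy_flat=20, n_decoy_far=10))

arch = result.experiment.truth.genes.set_index("gene_id")["archetype"]
ratios = result.pausing_ratios.assign(archetype=lambda df: df["gene_id"].map(arch))
sub = ratios[(ratios["timepoint_h"] == 1.5)]
print("median ln PI ratio (1.5 h vs untreated) by planted archetype:")
table = sub.pivot_table(index="archetype", columns="treatment", values="log_ratio", aggfunc="median")
print(table.round(2).to_string())
shifts = {a.name: a.pausing_shift["IFNb"] for a in result.experiment.config.archetypes}
print("\nplanted IFNb PI multipliers:", {k: v for k, v in shifts.items() if v != 1.0})
print("ln(0.5) = -0.69 and ln(2) = 0.69: the medians above recover the planted")
print("shifts under IFNb while IFNg columns hover near 0 (no shift planted).")

tests = result.pausing_tests
sig_b = (tests[tests["treatment"] == "IFNb"]["p"] < 0.01).sum()
sig_g = (tests[tests["treatment"] == "IFNg"]["p"] < 0.01).sum()
print(f"\nclusters with p < 0.01 (Mann-Whitney, 1.5 h): IFNb {sig_b}, IFNg {sig_g}")
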