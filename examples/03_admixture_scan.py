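"""Case-only admixture scan with a weighted prior-risk model.

Simulates 500 cases with a 1.5-fold risk per European allele at one locus,
scans with the default 27-model risk grid (0.4-3.0, gamma-weighted, mean
1.6, SD 0.3), localises the peak, estimates the risk multiplier on a fine
grid, and assigns empirical significance from null-replicate maxima.
"""

import numpy as np

from admixscan import (DiseaseModel, RiskModel, ascertain_cases,
                       build_aim_panel, empirical_peak_pvalue,
                       estimate_global_admixture, estimate_risk,
                       forward_backward, run_case_only_scan,
                       simulate_null_maxima)

panel = build_aim_panel(n_markers=240,
                        chrom_lengths={c: 1.0 for c in range(1, 7)}, seed=5)
causal = panel.table["marker_id"].iloc[int(np.argmax(panel.sigma))]
cohort = ascertain_cases(panel, DiseaseModel(causal, psi=1.5), 500, 0, seed=6)

m_hat = estimate_global_admixture(panel, cohort.genotypes)
result = run_case_only_scan(panel, cohort.genotypes, m_hat)
print(f"best marker: {result.best_marker} (causal locus: {causal})")
print(f"best weighted LOD = {result.best_lod:.2f} "
      "(>2 suggestive, >5 genome-wide significant)")
print(f"genome score = {result.genome:.2f}")

post = forward_backward(panel, cohort.genotypes, m_hat)
psi_hat, _ = estimate_risk(post, RiskModel.fine(1.0, 2.0, 0.01))
print(f"estimated risk per European allele: psi_hat = {psi_hat:.2f} "
      "(simulated 1.5)")

null_max = simulate_null_maxima(panel, n_cases=500, n_replicates=40, seed=7)
p = empirical_peak_pvalue(result.best_lod, null_max)
print(f"empirical peak p from 40 null replicates: {p:.2g}")
print("-> the scan localises the causal AIM, recovers the risk model, and "
      "the observed peak far exceeds the null maxima.")
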