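"""Ancestry-aware risk accounting from summary statistics.

From control risk-allele frequencies and odds ratios: per-SNP and joint
population attributable risk; from ancestral allele frequencies and ORs:
the locus-specific ancestry risk ratio lambda, Weir-Cockerham F_ST and
Rosenberg informativeness.
"""

import numpy as np

from admixscan import (fst_wc, informativeness, lambda_combined,
                       lambda_locus, par_joint, par_single,
                       reorient_to_risk, sigma_diff)

# three SNPs: control 'G' frequency and per-'G'-allele OR (African-American)
table = [("rs13023380", 0.911, 0.75),
         ("rs10930046", 0.428, 0.80),
         ("rs1990760", 0.829, 0.82)]

pars = []
for snp, freq_g, or_g in table:
    p, or_ = reorient_to_risk(freq_g, or_g)
    par = par_single(p, or_)
    pars.append(par)
    print(f"{snp}: risk-allele p = {p:.3f}, OR = {or_:.3f}, "
          f"PAR = {100 * par:.1f}%")
print(f"joint PAR = {100 * par_joint(pars):.1f}% "
      "(published 18.1% for these three SNPs)")

# ancestry risk ratio from per-SNP lambdas
prod, pct = lambda_combined([1.12, 1.12, 1.16])
print(f"combined ancestry risk ratio = {prod:.3f} (+{pct:.1f}%), vs ~1.5 "
      "from the admixture scan")

# differentiation metrics for a strongly ancestry-informative SNP
p_eur, q_afr = 0.05, 0.65
print(f"example ancestral frequencies {p_eur} vs {q_afr}: "
      f"F_ST = {fst_wc(p_eur, 100, q_afr, 150):.2f}, "
      f"In = {informativeness(p_eur, q_afr):.2f} nats, "
      f"sigma = {sigma_diff(p_eur, q_afr):.2f}")
print(f"lambda at that locus for a protective-allele OR of 0.8: "
      f"{lambda_locus(p_eur, q_afr, 0.8):.3f}")
print("-> most of the scan's European-ancestry risk at the locus is "
      "accounted for by the three fine-mapped variants.")
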