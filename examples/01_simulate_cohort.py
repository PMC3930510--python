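"""Simulate a small urine-NMR GWAS cohort and inspect what was generated.

A cohort is genotypes (LD-blocked diallelic SNPs), log-normal metabolite
concentrations with one planted SNP effect, and per-sample 1D spectra
rendered as sums of Lorentzian peak signatures.
"""

import numpy as np

from nmrgwas.simulate import SimConfig, beta_for_variance_explained, simulate_cohort

maf = 0.3
beta = beta_for_variance_explained(maf, explained=0.10)  # 10% of log-conc variance
cfg = SimConfig(
    n_individuals=200,
    n_snps=50,
    maf_range=(maf, maf),
    n_metabolites=30,
    effect_table=[(10, 5, beta)],  # SNP 10 -> metabolite 5
    noise_sd=np.sqrt(0.9),
    seed=7,
)

dosages, snp_meta, truth, features = simulate_cohort(cfg)

print(f"genotypes : {dosages.shape[0]} individuals x {dosages.shape[1]} SNPs")
print(f"mean MAF  : {snp_meta['maf'].mean():.3f} (target {maf})")
print(f"features  : {features.shape[1]} spectral bins of width 0.005 ppm")
print(f"planted   : SNP {truth.causal_map[0][0]} -> metabolite {truth.causal_map[0][1]}, "
      f"beta={truth.causal_map[0][2]:.3f} per dosage unit")
peaks = truth.library[5].positions
print(f"metabolite 5 peaks at {np.round(peaks, 3)} ppm — the bins to watch in a GWAS")
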