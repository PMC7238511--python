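"""SNP-heritability estimation three ways: Haseman-Elston, REML, no-LD LDSC.

All three estimators are applied to one simulated cohort with known
h^2 = 0.25 and no nurture, so they should agree with the truth and with
each other within their standard errors.
"""

import numpy as np

import adoptsim as a
from adoptsim import gwas, varcomp

cfg = a.SimulationConfig(
    n_families=3_000, m_snps=1_000, h2_direct=0.25, nurture_w=0.0,
    sigma_e2=0.75, maf_low=0.05, seed=3,
)
cohort = a.simulate_cohort(cfg)
y = cohort.table["edu_liability"].to_numpy()

grm = varcomp.compute_grm(cohort.genotypes, ids=cohort.ids)
cutoff = 4 / np.sqrt(grm.m_snps)  # above the GRM noise floor at this SNP count

he = varcomp.he_regression(grm, y, cutoff=cutoff)
reml = varcomp.reml_fit(grm, y)
ss = gwas.assoc_scan(cohort.genotypes, y, None, cohort.variants)
ldsc = varcomp.noLD_ldsc_h2(ss, n=cohort.n, m_snps=cohort.m)

print(f"simulated h2      = {cfg.h2_direct}")
print(f"Haseman-Elston    = {he.h2:.3f} (SE {he.se:.3f})")
print(f"REML (GREML)      = {reml.h2:.3f} (SE {reml.se:.3f})")
print(f"no-LD LDSC        = {ldsc.h2:.3f} (SE {ldsc.se:.3f})")
print()
print("HE regresses phenotype cross-products on genomic relatedness; REML")
print("fits the same random-effect model by maximum likelihood; the LDSC")
print("analogue needs only the per-SNP chi^2 (here all LD scores are 1).")
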