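"""Published UK Biobank adoption-cohort descriptives used to calibrate the simulator.

These constants are the printed descriptive statistics of the UK Biobank
adoption natural experiment for years of education: the four analysis
groups (a: adoptees, b: GWAS discovery, c: polygenic-score training,
d: non-adopted comparison), the external consortium GWAS sample size that
enters the meta-analysis, and the qualification (ISCED) distribution of
both groups.  The simulator's defaults are derived from them; they are
inputs to the package, not quantities it estimates.
"""

from __future__ import annotations

# Analysis group sizes (full scale).
GROUP_SIZES_FULL = {"a": 6_311, "b": 318_843, "c": 50_000, "d": 6_500}

#: Total quality-controlled sample: sum of the four groups.
TOTAL_N = sum(GROUP_SIZES_FULL.values())

#: Non-adopted individuals with full phenotype data (groups b + c + d).
NONADOPTED_N = 375_343

#: External (consortium) education GWAS sample size meta-analysed with group b.
EXTERNAL_GWAS_N = 324_160

#: Pooled sample for the decile analysis: adoptees plus group d.
POOLED_DECILE_N = GROUP_SIZES_FULL["a"] + GROUP_SIZES_FULL["d"]

#: Sample prevalence of adoption among the analysed cohort.
ADOPTION_PREVALENCE = GROUP_SIZES_FULL["a"] / TOTAL_N  # ~0.0165

# Years-of-education (ISCED-mapped) counts per group.
EDU_YEARS = (7, 10, 13, 15, 19, 20)
EDU_COUNTS_ADOPTED = {7: 1_209, 10: 1_780, 13: 749, 15: 350, 19: 433, 20: 1_790}
EDU_COUNTS_NONADOPTED = {
    7: 62_651,
    10: 100_210,
    13: 43_448,
    15: 19_428,
    19: 24_300,
    20: 125_306,
}

# Covariate descriptives (adopted / non-adopted).
AGE_MEAN_ADOPTED, AGE_SD_ADOPTED = 56.4, 8.53
AGE_MEAN_NONADOPTED, AGE_SD_NONADOPTED = 56.7, 8.01
MALE_FRACTION_ADOPTED = 0.48
MALE_FRACTION_NONADOPTED = 0.46


def edu_proportions(counts: dict[int, int]) -> dict[int, float]:
    """Normalise a years-of-education count table to proportions."""
    total = sum(counts.values())
    return {y: c / total for y, c in counts.items()}


def college_share(counts: dict[int, int]) -> float:
    """Fraction of a group with a college/university degree (20 years)."""
    return counts[20] / sum(counts.values())
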