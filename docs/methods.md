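# Methods

## The design in brief

Polygenic scores for educational attainment predict more than the direct
effect of a person's own DNA: because children inherit both genes and
rearing environments from their parents, the score is correlated with
the quality of the home (passive gene–environment correlation, passive
rGE). Adoption severs this link — adoptive parents are genetically
unrelated to the child — so comparing adoptees with people reared by
biological kin isolates the passive-rGE component. `adoptsim` implements
that natural experiment end to end on simulated cohorts in which the
truth is known, so every stage of the analysis can be validated.

## Generative model

Each of `m` independent biallelic SNPs has allele frequency
`p_i ~ U(maf_low, maf_high)` and a direct effect
`beta_i ~ N(0, h2_direct/m)` on the standardized-genotype scale
`z = (x - 2p)/sqrt(2p(1-p))`. Founders are in Hardy–Weinberg
equilibrium; mating is random and monogamous; each couple has one child
whose genotype follows Mendelian transmission. The direct genetic value
is `g = sum_i beta_i z_i`, with `Var(g) = h2_direct` by construction.

The phenotype (a continuous years-of-education liability) is the
proportional-nurture model used in nontransmitted-allele work:

    y = g_child + w * (g_rear_mother + g_rear_father) + e

Each rearing parent contributes `w` times their own genetic value
through the environment they provide. Because child and biological
parent genotypes correlate 0.5, rearing by biological parents yields

    Var(y | non-adopted) = sigma_g^2 (1 + 2w + 2w^2) + sigma_e^2
    Var(y | adopted)     = sigma_g^2 (1 + 2w^2)      + sigma_e^2

a surplus of exactly `2 w sigma_g^2` in non-adoptees, and multiplies
marginal per-SNP effects by `(1 + w)`. With a noiseless (true-effect)
score, the ratio of variance explained is

    R2_adopted / R2_nonadopted = [1/(1+w)^2] * [Var_NA / Var_A].

These closed forms are the oracles for most of the test suite. They
hold exactly only when adoption is assigned independently of genotype
(`adoption_theta = 0`) and the adoptive environment is neither shifted
nor shrunk (`adopt_env_shift = 0`, `adopt_env_scale = 1`); tests that
use them fix those switches.

### Adoption

Adoption has its own liability,

    L = -theta * (g_m + g_f)/sqrt(2 sigma_g^2) + sqrt(1 - theta^2) eps,

standard normal by construction; children above the `1-K` quantile are
adopted (counts therefore fluctuate binomially around `K n`). The
negative loading encodes that adoption associates with lower parental
education value. Because `Cov(g_child, g_m + g_f) = sigma_g^2`, the
child's own genotype captures a liability-scale heritability of
adoption of `theta^2 / 2`. The default `theta = 0.344` therefore puts
that heritability at ~0.059, the scale reported for real adoptees; it
is a preset, not an estimate.

Adoptive parents come from a disjoint founder pool drawn at the same
allele frequencies. Two optional knobs encode selective placement:
`adopt_env_shift` (mean residual shift, "educationally supportive
adoptive homes") and `adopt_env_scale` (residual variance multiplier,
"more homogeneous adoptive families"). Both default to off. The design
cannot itself distinguish these from reduced passive rGE as the source
of adoptee differences; the simulator exposes both rather than
resolving the ambiguity.

### Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| `h2_direct` | 0.25 | direct-effect variance (sigma_g^2) |
| `nurture_w` | 0.414 | nurture weight; (1+w)^2 = 2, i.e. the score predicts twice as well in non-adoptees |
| `sigma_e2` | 0.6 | residual variance |
| `adoption_prev` | 0.017 | adoption prevalence (1.7%) |
| `adoption_theta` | 0.344 | liability loading; theta^2/2 ~ 0.059 |
| `m_snps` | 2,000 | independent SNPs |
| `n_families` | 8,000 | one child each; group sizes b/c/d default to the full design scaled by `n_families/400,000` (8,000 gives the 1/50 preset 126/6,377/1,000/130) |
| thresholds | .001,.05,.1,.2,.3,.4,.5,1 | standard p-value threshold ladder |
| `maf_min` | 0.01 | variant QC floor |
| `relatedness_cutoff` | 0.025 | GRM pruning threshold |
| bootstrap B | 1,000 | replications for R^2 SEs |

The continuous liability is the default analysis phenotype; a
six-category ISCED discretization (quantile cut at configurable
marginal proportions, mapped to {7, 10, 13, 15, 19, 20} years) is also
produced for ordinal-regime analyses such as the variance test on
years. Covariates are sex ~ Bernoulli(0.48), age ~ N(56.5, 8) truncated
to the 40–70 recruitment window, and birth year = reference year − age;
their effects on y default to zero so the closed-form moments hold
exactly, and can be switched on.

## Estimators

**GRM.** `A_jk = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i)/(2p_i(1-p_i))`
with sample frequencies. With sample centering the mean off-diagonal is
−1/(n−1), and entries have null SD ~ `1/sqrt(M)`.

**Haseman–Elston.** Regression of `y_j y_k` (phenotype standardized) on
`A_jk` over pairs at or below the relatedness cutoff; the slope
estimates observed-scale h². SE is a delete-one-individual jackknife
computed from rolling sums (O(n^2) total).

**REML.** Single-component GREML, `Var(y) = sigma_g^2 A + sigma_e^2 I`,
fitted by average-information REML in the eigenbasis of A (one `eigh`,
then every iteration is O(n p)). AI steps are damped by step-halving and
clamped at a positivity floor; failed steps fall back to EM.
Convergence: restricted-log-likelihood change < 1e-6 (max 100
iterations) or a boundary-pinned parameter; boundary estimates are
flagged. The SE of h² comes from the inverse AI matrix by the delta
method. Estimates outside [0,1] are flagged, not clipped.

**No-LD LDSC.** With independent SNPs every LD score is 1 and LD-score
regression collapses to `h2 = M (mean chi^2 - 1)/n` with the intercept
fixed at 1 (the simulation has no stratification or sample overlap). SEs
are a block jackknife over SNPs (200 blocks). A free intercept requires
variation in user-supplied LD scores; with constant scores slope and
intercept are collinear and the option raises an error. The genetic
correlation analogue is `rg = M mean(z1 z2) / (sqrt(n1 n2) sqrt(h1^2
h2^2))` for disjoint samples, jackknifed the same way; |rg| > 1 is
reported with a clipped flag rather than truncated.

**Liability conversion.** `h2_liab = h2_obs K^2(1-K)^2 / (P(1-P) z^2)`
with `z` the normal density at the threshold; exact inverse provided.
Note the published sensitivity triplet (0.059 → 0.047 / 0.066) is
consistent with an unrounded estimate near 0.0586; starting from the
printed 0.059 lands at 0.0478/0.0667, within one unit of the last
printed digit.

## Comparison suite

The variance test is Brown–Forsythe (one-way ANOVA on absolute
deviations from group medians, via `scipy.stats.levene(center=
"median")`). The descriptive table follows the original, slightly odd,
test assignment — Wald for years, z for age, Wilcoxon rank-sum for
binary sex — kept as documented behaviour. The R² comparison
bootstraps individuals within group (point estimates from the
unresampled data; normal z on the difference with combined bootstrap
SEs). Interaction models carry the full covariate-interaction (Keller)
term set — score×covariate and adoption×covariate for every covariate —
so the focal score×adoption term is not confounded; the multiplicative
model is a logistic fit on degree attainment (>= 20 years by default,
configurable). Deciles are cut on the pooled score with stable-rank tie
breaks; per-decile tests are Welch, with a Bonferroni flag over the 10
tests. Phenotype standardization for decile and interaction outputs
uses the pooled two-group sample.

## Pipeline and reproducibility

`run_experiment` chains simulate → variant QC → split (all adoptees →
a; b/c/d random disjoint non-adoptees) → GWAS in b (optional
inverse-variance meta-analysis with a second simulated "external
consortium" cohort) → threshold training in c → comparison suite and
HE/REML heritability on a vs d. Every stream derives from one master
seed by hashing `(seed, stage name)`, so a rerun writes a byte-identical
report JSON; timings and versions go to a separate run log. Interchange
files are plain TSV with repr-faithful floats (PLINK-.raw-style
genotypes, METAL-style summary stats with an effect-scale header
comment, GCTA-layout GRM), and write→read round-trips are exact.

Two pipeline-level guards matter at desk scale. The relatedness cutoff
is taken as `max(0.025, 4/sqrt(M))`: with a few thousand SNPs the GRM
noise floor exceeds 0.025 and the literal threshold would prune
unrelated samples wholesale, while at biobank SNP counts the guard is
inactive. And the MAF floor is re-applied within each analysis group,
since rare SNPs can be monomorphic inside a small subsample.

## What the simulation does and does not emulate

Emulated: independent common variants; direct plus parental-nurture
effects; adoption severing the genotype–environment correlation;
heritable, low-prevalence adoption; ISCED-discretized education;
sex/age/birth-year covariates; the four-group analysis design.

Not emulated: linkage disequilibrium (so clumping is a no-op and LDSC
runs in its no-LD special case), assortative mating, population
stratification, genotyping batch effects, imputation error, missing
genotypes (the call-rate filter is a pass-through unless missingness is
enabled), X chromosome. Passing tests therefore validate the estimators
and the design logic, not robustness to those real-data complications;
in particular, absolute R² values at desk scale are much larger than in
a real biobank because the simulated discovery sample is large relative
to the number of independent SNPs.

## Problem sizes used by the test suite

Parameter-recovery runs use n = 4,000 / M = 2,000 (HE, REML) and
n = 20,000 / M = 2,000 (no-LD LDSC). The design-oracle runs use
20 replicates of balanced 20,000-per-group cohorts; calibration uses
200 small-cohort replicates per test and 50 replicates at the published
group sizes (6,311 / 6,500) for the power check; the decile-crossing
check uses 50 replicates of 5,000-family cohorts. These sizes keep every
Monte-Carlo band (4 SE) comfortably tight while remaining desk-scale.
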