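"""Forward simulator for genetic-nurture cohorts with adoption.

The generative model is the proportional-nurture model used throughout
the nontransmitted-allele literature.  Each of ``m`` independent SNPs
carries a direct effect ``beta_i ~ N(0, h2_direct/m)`` on the
standardized-genotype scale.  A child's phenotype is

    y = g_child + w * (g_rear_mother + g_rear_father) + e

where ``g`` denotes an individual's direct genetic value and the rearing
parents equal the biological parents unless the child was adopted.
Because child and biological parent genotypes correlate 0.5, rearing by
biological parents induces passive gene-environment correlation:
Cov(g_child, w*(g_m + g_f)) = w * sigma_g^2, adding 2*w*sigma_g^2 to the
phenotypic variance and multiplying the marginal SNP effects by (1+w).
Adoption by genetically unrelated parents removes exactly this term.

Adoption itself is heritable through the biological parents: its
liability loads negatively on the mid-parent genetic value for education
with weight ``adoption_theta``, so that the child-genotype liability
heritability of being adopted equals ``adoption_theta**2 / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .errors import ConfigurationError, DataError
from .utils import stage_rng

# Years of education attached to the six simulated qualification bins
# (the two 10-year qualification categories collapse into one bin).
ISCED_YEARS = np.array([7, 10, 13, 15, 19, 20])

#: Full 7-category qualification -> years-of-education map.
ISCED_CATEGORY_YEARS = {
    1: 7,  # no qualifications
    2: 10,  # CSE or equivalent
    3: 10,  # O level / GCSE or equivalent
    4: 13,  # A level / AS level or equivalent
    5: 15,  # other professional qualification
    6: 19,  # NVQ / HNC or equivalent
    7: 20,  # college or university degree
}

ISCED_CATEGORY_LABELS = {
    1: "none of the above",
    2: "CSE or equivalent",
    3: "O level/GCSE or equivalent",
    4: "A level/AS level or equivalent",
    5: "other professional qualification",
    6: "NVQ/HNC or equivalent",
    7: "college or university degree",
}
_LABEL_TO_CATEGORY = {v: k for k, v in ISCED_CATEGORY_LABELS.items()}


@dataclass
class Cohort:
    """One simulated generation of children plus their (rearing) parents.

    Attributes
    ----------
    genotypes
        children x SNPs allele-count matrix (0/1/2, int8).
    variants
        per-SNP table: snp, a1, a2, freq (generative allele-1 frequency),
        beta_std (true direct effect, standardized-genotype scale).
    pedigree
        per-child biological and rearing parent ids.
    table
        per-child phenotype/covariate frame: iid, adopted, group,
        years_edu, edu_liability, sex, age, birth_year, g_direct
        (simulation truth, for oracles).
    parent_g
        direct genetic values of every parent id (biological + adoptive
        pool), used to reconstruct nurture components.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    pedigree: pd.DataFrame
    table: pd.DataFrame
    parent_g: pd.Series
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    @property
    def ids(self) -> np.ndarray:
        return self.table["iid"].to_numpy()

    def validate(self) -> None:
        """Cheap structural invariants; raises DataError on violation."""
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise DataError("allele counts outside {0,1,2}")
        ped, tab = self.pedigree, self.table
        same_rearing = (ped["rear_mother"] == ped["bio_mother"]) & (
            ped["rear_father"] == ped["bio_father"]
        )
        if not (tab["adopted"].to_numpy() == ~same_rearing.to_numpy()).all():
            raise DataError("adopted flag inconsistent with pedigree")
        if not np.isin(tab["years_edu"].unique(), ISCED_YEARS).all():
            raise DataError("years_edu outside the ISCED map")


def simulate_parents(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_couples: int | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw founder genotypes in Hardy-Weinberg equilibrium.

    Returns a ``2*n_couples x m`` allele-count matrix and the per-SNP
    allele-1 frequencies (uniform on [maf_low, maf_high] unless supplied
    — e.g. when drawing a second founder pool from the same population).
    """
    if not (0 < config.maf_low <= config.maf_high <= 0.5):
        raise ConfigurationError(
            f"invalid MAF range ({config.maf_low}, {config.maf_high})"
        )
    n_couples = config.n_families if n_couples is None else n_couples
    if freqs is None:
        freqs = rng.uniform(config.maf_low, config.maf_high, size=config.m_snps)
    geno = rng.binomial(2, freqs, size=(2 * n_couples, config.m_snps)).astype(np.int8)
    return geno, freqs


def mate_and_transmit(
    parental_genotypes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random monogamous mating with Mendelian transmission.

    Parents are shuffled and paired consecutively; each pair has one
    child who receives one allele from each parent (drawn Binomial(1,
    x/2) per SNP given the parent's count x).  Returns the child
    allele-count matrix and an ``n_children x 2`` array of (mother,
    father) row indices into ``parental_genotypes``.
    """
    n_parents = parental_genotypes.shape[0]
    if n_parents % 2:
        raise DataError(f"odd number of parents ({n_parents}); cannot pair")
    order = rng.permutation(n_parents)
    mothers, fathers = order[0::2], order[1::2]
    child = _transmit(parental_genotypes[mothers], rng) + _transmit(
        parental_genotypes[fathers], rng
    )
    return child.astype(np.int8), np.column_stack([mothers, fathers])


def _transmit(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(parent_geno.shape) < parent_geno / 2.0).astype(np.int8)


def draw_effects(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP direct effects beta_i ~ N(0, h2_direct/m), standardized scale."""
    if config.h2_direct < 0:
        raise ConfigurationError("h2_direct must be >= 0")
    if config.m_snps < 1:
        raise ConfigurationError("m_snps must be >= 1")
    if config.h2_direct == 0:
        return np.zeros(config.m_snps)
    return rng.normal(0.0, np.sqrt(config.h2_direct / config.m_snps), size=config.m_snps)


def genetic_values(
    genotypes: np.ndarray, freqs: np.ndarray, beta_std: np.ndarray
) -> np.ndarray:
    """Direct genetic value g = sum_i beta_i * (x_i - 2 p_i)/sqrt(2 p_i (1-p_i))."""
    denom = np.sqrt(2 * freqs * (1 - freqs))
    return (genotypes - 2 * freqs) @ (beta_std / denom)


def assign_adoption(
    parent_pairs: np.ndarray,
    parent_g: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_adoptive_couples: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Decide who is adopted and allocate adoptive couples.

    Liability per child:
        L = -theta * (g_m + g_f)/sqrt(2 sigma_g^2) + sqrt(1-theta^2) * eps
    which is standard normal, so children with L above the population
    (1-K) quantile are adopted (adoptee counts fluctuate binomially).
    The negative sign makes adoption genetically associated with *lower*
    parental education value.

    Returns the boolean adoption flags and, per child, the index of the
    adoptive couple assigned (-1 for non-adoptees).  Raises DataError if
    the adoptive pool is too small.
    """
    if not 0 < config.adoption_prev < 1:
        raise ConfigurationError("adoption_prev must lie in (0, 1)")
    n_children = parent_pairs.shape[0]
    theta = config.adoption_theta
    if config.h2_direct > 0 and theta > 0:
        midparent = parent_g[parent_pairs[:, 0]] + parent_g[parent_pairs[:, 1]]
        genetic_part = -theta * midparent / np.sqrt(2 * config.h2_direct)
    else:
        theta = 0.0
        genetic_part = np.zeros(n_children)
    liability = genetic_part + np.sqrt(1 - theta**2) * rng.standard_normal(n_children)
    adopted = liability > stats.norm.ppf(1 - config.adoption_prev)

    n_adopted = int(adopted.sum())
    if n_adoptive_couples is None:
        n_adoptive_couples = n_adopted
    if n_adoptive_couples < n_adopted:
        raise DataError(
            f"{n_adopted} adoptees but only {n_adoptive_couples} adoptive couples"
        )
    couple_idx = np.full(n_children, -1, dtype=int)
    couple_idx[adopted] = rng.choice(n_adoptive_couples, size=n_adopted, replace=False)
    return adopted, couple_idx


def simulate_phenotype(
    g_child: np.ndarray,
    g_rear_mother: np.ndarray,
    g_rear_father: np.ndarray,
    adopted: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous education liability y = g + w(g_r1 + g_r2) + e.

    The residual for adoptees is shifted by ``adopt_env_shift`` and has
    variance ``sigma_e2 * adopt_env_scale``; non-adoptees get plain
    N(0, sigma_e2) noise.  With shift 0 and scale 1 the closed forms

        Var(y | non-adopted) = sigma_g^2 (1 + 2w + 2w^2) + sigma_e^2
        Var(y | adopted)     = sigma_g^2 (1 + 2w^2)      + sigma_e^2

    hold, the difference being the passive-rGE term 2 w sigma_g^2.
    """
    arrays = (g_child, g_rear_mother, g_rear_father, adopted)
    if len({len(a) for a in arrays}) != 1:
        raise DataError("phenotype inputs have mismatched lengths")
    adopted = np.asarray(adopted, dtype=bool)
    sd = np.sqrt(config.sigma_e2 * np.where(adopted, config.adopt_env_scale, 1.0))
    e = rng.standard_normal(len(g_child)) * sd + config.adopt_env_shift * adopted
    return g_child + config.nurture_w * (g_rear_mother + g_rear_father) + e


def discretize_isced(
    y: np.ndarray, proportions: np.ndarray | None = None
) -> np.ndarray:
    """Quantile-cut a continuous liability into the six ISCED bins.

    Returns years of education per individual.  Bin sizes follow the
    target marginal proportions via cumulative rounding (counts match
    the targets within 1); ties in y are broken by stable rank, so the
    cut is monotone: y_a < y_b implies years_a <= years_b.
    """
    y = np.asarray(y, dtype=float)
    if proportions is None:
        from .config import _default_isced_proportions

        proportions = np.array(_default_isced_proportions())
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"ISCED proportions sum to {proportions.sum()!r}, expected 1"
        )
    if len(proportions) != len(ISCED_YEARS):
        raise ConfigurationError(
            f"expected {len(ISCED_YEARS)} proportions, got {len(proportions)}"
        )
    n = len(y)
    boundaries = np.round(np.cumsum(proportions) * n).astype(int)
    ranks = np.argsort(np.argsort(y, kind="stable"), kind="stable")
    bins = np.searchsorted(boundaries, ranks, side="right")
    bins = np.clip(bins, 0, len(ISCED_YEARS) - 1)
    return ISCED_YEARS[bins]


def map_isced_years(category: int | str) -> int:
    """Map a qualification category (1-7 or its label) to years of education."""
    if isinstance(category, str):
        if category not in _LABEL_TO_CATEGORY:
            raise DataError(f"unknown qualification category {category!r}")
        category = _LABEL_TO_CATEGORY[category]
    if category not in ISCED_CATEGORY_YEARS:
        raise DataError(f"unknown qualification category {category!r}")
    return ISCED_CATEGORY_YEARS[category]


def years_to_category(years: int) -> str:
    """Inverse lookup: years of education -> qualification label.

    The two 10-year qualifications collapse; the CSE label is returned.
    """
    for cat, yrs in ISCED_CATEGORY_YEARS.items():
        if yrs == years:
            return ISCED_CATEGORY_LABELS[cat]
    raise DataError(f"no qualification category maps to {years} years")


def simulate_covariates(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Sex, age (truncated to the 40-70 recruitment window) and birth year."""
    sex = (rng.random(n) < config.male_fraction).astype(int)
    if config.age_sd == 0:
        age = np.full(n, float(config.age_mean))
    else:
        a = (40 - config.age_mean) / config.age_sd
        b = (70 - config.age_mean) / config.age_sd
        age = stats.truncnorm.rvs(
            a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
        )
    birth_year = config.reference_year - np.floor(age).astype(int)
    return pd.DataFrame({"sex": sex, "age": age, "birth_year": birth_year})


def birth_year_bins(birth_year: np.ndarray, width: int = 5, n_bins: int = 7) -> np.ndarray:
    """Assign mutually exclusive fixed-width birth-year bins (labels 0..n_bins-1).

    Bins are anchored at the maximum observed year and extend downward in
    blocks of ``width`` years; together they partition
    [max - n_bins*width + 1, max].
    """
    birth_year = np.asarray(birth_year)
    top = int(birth_year.max())
    idx = (top - birth_year) // width
    if (idx >= n_bins).any():
        raise DataError(
            f"birth-year range exceeds {n_bins} bins of {width} years"
        )
    return (n_bins - 1 - idx).astype(int)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the full generative sequence for one cohort.

    Stages draw from independent hash-derived streams of ``config.seed``,
    so the cohort is bit-identical for a fixed config.
    """
    rng_founders = stage_rng(config.seed, "founders")
    rng_mating = stage_rng(config.seed, "mating")
    rng_effects = stage_rng(config.seed, "effects")
    rng_adoption = stage_rng(config.seed, "adoption")
    rng_phenotype = stage_rng(config.seed, "phenotype")
    rng_covariates = stage_rng(config.seed, "covariates")

    parents, freqs = simulate_parents(config, rng_founders)
    children, pairs = mate_and_transmit(parents, rng_mating)
    beta = draw_effects(config, rng_effects)

    parent_gv = genetic_values(parents, freqs, beta)
    child_gv = genetic_values(children, freqs, beta)

    # adoptive pool: disjoint couples, never biological parents of anyone
    n_pool = max(
        1, int(np.ceil(config.adoptive_pool_factor * config.adoption_prev * config.n_families))
    )
    pool_geno, _ = simulate_parents(config, rng_adoption, n_couples=n_pool, freqs=freqs)
    pool_gv = genetic_values(pool_geno, freqs, beta)

    adopted, couple_idx = assign_adoption(
        pairs, parent_gv, config, rng_adoption, n_adoptive_couples=n_pool
    )

    bio_ids = np.array([f"P{i:06d}" for i in range(len(parent_gv))])
    pool_ids = np.array([f"A{i:06d}" for i in range(2 * n_pool)])
    child_ids = np.array([f"I{i:06d}" for i in range(len(child_gv))])

    rear_mother = bio_ids[pairs[:, 0]].copy()
    rear_father = bio_ids[pairs[:, 1]].copy()
    rear_mother[adopted] = pool_ids[2 * couple_idx[adopted]]
    rear_father[adopted] = pool_ids[2 * couple_idx[adopted] + 1]

    parent_g = pd.Series(
        np.concatenate([parent_gv, pool_gv]),
        index=np.concatenate([bio_ids, pool_ids]),
        name="g_direct",
    )
    g_r1 = parent_g.loc[rear_mother].to_numpy()
    g_r2 = parent_g.loc[rear_father].to_numpy()

    y = simulate_phenotype(child_gv, g_r1, g_r2, adopted, config, rng_phenotype)
    covs = simulate_covariates(len(y), config, rng_covariates)
    y = y + config.sex_effect * covs["sex"].to_numpy() + config.age_effect * (
        covs["age"].to_numpy() - config.age_mean
    )
    years = discretize_isced(y, np.array(config.isced_proportions))

    variants = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(config.m_snps)],
            "a1": "A",
            "a2": "G",
            "freq": freqs,
            "beta_std": beta,
        }
    )
    pedigree = pd.DataFrame(
        {
            "iid": child_ids,
            "bio_mother": bio_ids[pairs[:, 0]],
            "bio_father": bio_ids[pairs[:, 1]],
            "rear_mother": rear_mother,
            "rear_father": rear_father,
        }
    )
    table = pd.DataFrame(
        {
            "iid": child_ids,
            "adopted": adopted.astype(int),
            "group": "",
            "years_edu": years,
            "edu_liability": y,
            "sex": covs["sex"],
            "age": covs["age"],
            "birth_year": covs["birth_year"],
            "g_direct": child_gv,
        }
    )
    return Cohort(
        genotypes=children,
        variants=variants,
        pedigree=pedigree,
        table=table,
        parent_g=parent_g,
        config=config,
    )
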