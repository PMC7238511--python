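import numpy as np
import pytest

import adoptsim as a


@pytest.fixture(scope="session")
def nurture_cohort():
    """A mid-sized cohort under the default nurture model, shared read-only."""
    cfg = a.SimulationConfig(n_families=3000, m_snps=400, seed=42)
    return a.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def balanced_cohort():
    """Cohort with 50% adoption so both groups are large (for group contrasts)."""
    cfg = a.SimulationConfig(
        n_families=20_000,
        m_snps=400,
        adoption_prev=0.5,
        adoption_theta=0.0,  # random adoption: the closed-form variance
        # contracts assume adoption independent of genotype
        adoptive_pool_factor=1.2,
        seed=7,
    )
    return a.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def true_beta_stats(cohort):
    """Summary statistics carrying the true allele-count-scale effects."""
    import pandas as pd

    from adoptsim.gwas import SummaryStats

    v = cohort.variants
    denom = np.sqrt(2 * v["freq"] * (1 - v["freq"]))
    table = pd.DataFrame(
        {
            "SNP": v["snp"],
            "A1": v["a1"],
            "A2": v["a2"],
            "BETA": v["beta_std"] / denom,
            "SE": 1.0,
            "P": 1.0,
            "N": cohort.n,
        }
    )
    return SummaryStats(table, effect_scale="allele-count, true effects")
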