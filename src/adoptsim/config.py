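"""Configuration objects for the simulator, QC, comparison suite and pipeline.

All configs are plain dataclasses with eager validation (`__post_init__`
raises :class:`~adoptsim.errors.ConfigurationError`) and YAML round-trip
helpers.  The defaults encode the study conditions of the UK Biobank
adoption design at desk scale: a 1/50-sized cohort, 2,000 independent
SNPs, direct-effect heritability 0.25, nurture weight w = 0.414 (so that
(1+w)^2 = 2, i.e. polygenic prediction twice as strong when reared by
biological relatives), adoption prevalence 1.7%.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import calibration
from .errors import ConfigurationError

#: Candidate p-value inclusion thresholds for polygenic scoring
#: (the standard PRSice set).
DEFAULT_PGS_THRESHOLDS = (0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)

#: Default desk scale relative to the full biobank design.
DEFAULT_SCALE = 1 / 50


def scaled_group_sizes(scale: float) -> dict[str, int]:
    """Group sizes a/b/c/d scaled down from the full design (rounded)."""
    if scale <= 0:
        raise ConfigurationError(f"scale must be positive, got {scale}")
    return {g: max(1, round(n * scale)) for g, n in calibration.GROUP_SIZES_FULL.items()}


def _default_isced_proportions() -> tuple[float, ...]:
    props = calibration.edu_proportions(calibration.EDU_COUNTS_NONADOPTED)
    return tuple(props[y] for y in calibration.EDU_YEARS)


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic adoption cohort.

    Parameters
    ----------
    n_families
        Number of child-bearing couples (one child each).
    m_snps
        Number of independent biallelic SNPs.
    maf_low, maf_high
        Range of per-SNP allele frequencies, drawn uniformly.
    h2_direct
        Variance of the child's direct genetic value g (sigma_g^2) on the
        scale where effects act on standardized genotypes.
    nurture_w
        Genetic-nurture weight w: each rearing parent contributes
        w * (their own g) to the child's phenotype.
    sigma_e2
        Residual environmental variance.
    adoption_prev
        Population prevalence K of adoption.
    adoption_theta
        Loading of the (sign-flipped) mid-parent genetic value on the
        adoption liability; theta^2 / 2 is the child-genotype
        liability-scale heritability of adoption implied by the model.
    adopt_env_shift
        Mean shift delta_A of the adoptee residual environment
        (phenotype SD units); positive = educationally supportive
        adoptive homes.
    adopt_env_scale
        Multiplier lambda on the adoptee residual variance
        (< 1 encodes more homogeneous adoptive families).
    group_sizes
        Target sizes of analysis groups a/b/c/d (a is informative only:
        all simulated adoptees form group a).
    male_fraction, age_mean, age_sd, reference_year
        Covariate generators (age truncated to the 40-70 recruitment
        window; birth_year = reference_year - age).
    sex_effect, age_effect
        Optional additive covariate effects on the phenotype
        (defaults 0 so the closed-form variance contracts hold exactly).
    isced_proportions
        Marginal proportions of the six years-of-education categories
        used by the quantile discretizer.
    adoptive_pool_factor
        Adoptive couples simulated per expected adoptee (>1 leaves slack
        for binomial fluctuation of the adoptee count).
    seed
        Master seed; every stream is derived from it.
    """

    n_families: int = 8_000
    m_snps: int = 2_000
    maf_low: float = 0.01
    maf_high: float = 0.5
    h2_direct: float = 0.25
    nurture_w: float = 0.414
    sigma_e2: float = 0.6
    adoption_prev: float = 0.017
    adoption_theta: float = 0.344
    adopt_env_shift: float = 0.0
    adopt_env_scale: float = 1.0
    group_sizes: dict[str, int] | None = None
    male_fraction: float = 0.48
    age_mean: float = 56.5
    age_sd: float = 8.0
    reference_year: int = 2009
    sex_effect: float = 0.0
    age_effect: float = 0.0
    isced_proportions: tuple[float, ...] = field(default_factory=_default_isced_proportions)
    adoptive_pool_factor: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError(
                f"need 0 < maf_low <= maf_high <= 0.5, got ({self.maf_low}, {self.maf_high})"
            )
        for name in ("n_families", "m_snps"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if not 0 <= self.h2_direct <= 1:
            raise ConfigurationError(f"h2_direct must lie in [0, 1], got {self.h2_direct}")
        if self.sigma_e2 < 0:
            raise ConfigurationError("sigma_e2 must be >= 0")
        if self.nurture_w < 0:
            raise ConfigurationError("nurture_w must be >= 0")
        if not 0 < self.adoption_prev < 1:
            raise ConfigurationError("adoption_prev must lie in (0, 1)")
        if not 0 <= self.adoption_theta <= 1:
            raise ConfigurationError("adoption_theta must lie in [0, 1]")
        if self.adopt_env_scale <= 0:
            raise ConfigurationError("adopt_env_scale must be > 0")
        if self.total_variance_nonadopted() <= 0:
            raise ConfigurationError("total phenotypic variance must be positive")
        if self.group_sizes is None:
            # scale the full design so b+c+d fits inside the cohort with
            # headroom for the (random) adoptee count; n_families=8000
            # gives exactly the 1/50 preset (126/6377/1000/130)
            self.group_sizes = scaled_group_sizes(self.n_families / 400_000)
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ConfigurationError("all group sizes must be positive")
        bcd = sum(self.group_sizes.get(g, 0) for g in "bcd")
        if bcd > self.n_families:
            raise ConfigurationError(
                f"group sizes b+c+d ({bcd}) exceed n_families ({self.n_families})"
            )
        if abs(sum(self.isced_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("isced_proportions must sum to 1")

    # Closed-form phenotypic variances under delta_A=0, lambda=1.
    def total_variance_nonadopted(self) -> float:
        w, sg2 = self.nurture_w, self.h2_direct
        return sg2 * (1 + 2 * w + 2 * w * w) + self.sigma_e2

    def total_variance_adopted(self) -> float:
        w, sg2 = self.nurture_w, self.h2_direct
        return sg2 * (1 + 2 * w * w) + self.sigma_e2 * self.adopt_env_scale

    def expected_r2_ratio(self) -> float:
        """Expected (true-score R^2 adopted) / (true-score R^2 non-adopted).

        With noiseless scores the covariance of phenotype and score is
        sigma_g^2 (1+w) in non-adoptees and sigma_g^2 in adoptees, giving
        the ratio [1/(1+w)^2] * [Var_NA / Var_A].
        """
        w = self.nurture_w
        return (1 / (1 + w) ** 2) * (
            self.total_variance_nonadopted() / self.total_variance_adopted()
        )


@dataclass
class QCConfig:
    """Variant/sample filters: MAF floor and the relatedness cutoff."""

    maf_min: float = 0.01
    relatedness_cutoff: float = 0.025
    protected_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not 0 <= self.maf_min < 0.5:
            raise ConfigurationError(f"maf_min must lie in [0, 0.5), got {self.maf_min}")
        if self.relatedness_cutoff <= 0:
            raise ConfigurationError("relatedness_cutoff must be > 0")
        self.protected_ids = frozenset(self.protected_ids)


@dataclass
class CompareConfig:
    """Settings for the group-comparison suite."""

    bootstrap_reps: int = 1_000
    seed: int = 0
    n_deciles: int = 10
    #: years of education at/above which the binary outcome of the
    #: multiplicative interaction model is 1 (degree attainment).
    dichotomize_at: float = 20.0
    min_stratum_n: int = 100

    def __post_init__(self):
        if self.bootstrap_reps < 100:
            raise ConfigurationError("bootstrap_reps must be >= 100")
        if self.n_deciles < 2:
            raise ConfigurationError("n_deciles must be >= 2")


@dataclass
class ExperimentConfig:
    """Config-driven description of one full in-silico study."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    pgs_thresholds: tuple[float, ...] = DEFAULT_PGS_THRESHOLDS
    output_dir: str | None = None
    seed: int = 0
    scenario: str = "education"
    #: when True, a second simulated cohort plays the external consortium
    #: and its scan is meta-analysed with the discovery scan.
    external_meta: bool = False
    external_n_families: int = 8_000

    def __post_init__(self):
        if self.scenario not in ("education", "height-control", "custom"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "height-control":
            # no genetic nurture: the negative-control trait
            self.simulation = dataclasses.replace(self.simulation, nurture_w=0.0)
        if not self.pgs_thresholds:
            raise ConfigurationError("pgs_thresholds must be non-empty")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        if "seed" not in raw:
            raise ConfigurationError("experiment config requires an explicit seed")
        sim = SimulationConfig(**_tupled(raw.get("simulation", {}), "isced_proportions"))
        qc = QCConfig(**raw.get("qc", {}))
        comp = CompareConfig(**raw.get("compare", {}))
        kwargs = {
            k: v for k, v in raw.items() if k not in ("simulation", "qc", "compare")
        }
        if "pgs_thresholds" in kwargs:
            kwargs["pgs_thresholds"] = tuple(kwargs["pgs_thresholds"])
        return cls(simulation=sim, qc=qc, compare=comp, **kwargs)


def _tupled(d: dict, key: str) -> dict:
    d = dict(d)
    if key in d:
        d[key] = tuple(d[key])
    return d


def _as_plain(obj):
    """Dataclass tree -> YAML-safe plain python."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(_as_plain(v) for v in obj)
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
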