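"""Per-SNP association scan and fixed-effects meta-analysis.

The scan is ordinary least squares of the (standardized) phenotype on
each SNP's allele count plus covariates, computed for all SNPs at once
via Frisch-Waugh residualization: phenotype and genotypes are projected
off the covariate space once, after which each SNP reduces to a simple
regression with the correct residual degrees of freedom.  Effects are
therefore on the allele-count scale with the phenotype standardized
within the scan sample, and the scale is recorded on the object and in
the file header.

Meta-analysis is METAL-style fixed effects with inverse-variance
weights, including allele alignment (a study whose effect allele is the
other study's alternate allele has its beta negated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateFitError
from .utils import standardize

SUMSTATS_COLUMNS = ["SNP", "A1", "A2", "BETA", "SE", "P", "N"]


@dataclass
class SummaryStats:
    """Per-SNP association results (the interchange currency of the package)."""

    table: pd.DataFrame
    effect_scale: str = "allele-count, phenotype standardized in scan sample"
    #: sample ids the scan was run on, kept for overlap guards downstream.
    source_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"summary statistics missing columns {missing}")
        t = self.table
        if (t["SE"] <= 0).any():
            raise DataError("summary statistics contain SE <= 0")
        if ((t["P"] <= 0) | (t["P"] > 1)).any():
            raise DataError("summary statistics contain p outside (0, 1]")
        if t["SNP"].duplicated().any():
            raise DataError("duplicate SNP ids in summary statistics")
        self.source_ids = frozenset(self.source_ids)

    def __len__(self):
        return len(self.table)

    @property
    def chi2(self) -> np.ndarray:
        b, se = self.table["BETA"].to_numpy(), self.table["SE"].to_numpy()
        return (b / se) ** 2

    @property
    def z(self) -> np.ndarray:
        return (self.table["BETA"] / self.table["SE"]).to_numpy()


def assoc_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    variants: pd.DataFrame,
    sample_ids=(),
) -> SummaryStats:
    """OLS association scan of phenotype on each SNP, adjusting for covariates.

    Constant genotype columns cannot be tested; they are flagged in the
    output (BETA/SE/P set to NaN, ``note`` column says why) rather than
    silently dropped, so row alignment with the variant table survives.
    """
    geno = np.asarray(genotypes, dtype=float)
    n, m = geno.shape
    y = standardize(np.asarray(phenotype, dtype=float))
    if len(y) != n:
        raise DataError(f"phenotype length {len(y)} != {n} samples")
    X = _covariate_matrix(covariates, n)
    if n <= X.shape[1] + 2:
        raise DataError(f"n={n} too small for {X.shape[1] - 1} covariates")
    if np.isnan(geno).any() or np.isnan(y).any():
        raise DataError("missing values in genotypes or phenotype")

    # project off covariates (incl. intercept) once
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    g_r = geno - Q @ (Q.T @ geno)

    sxx = np.einsum("ij,ij->j", g_r, g_r)
    constant = sxx < 1e-12
    sxx_safe = np.where(constant, 1.0, sxx)
    beta = (g_r.T @ y_r) / sxx_safe
    dof = n - X.shape[1] - 1
    rss = y_r @ y_r - beta**2 * sxx_safe
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / sxx_safe)
    perfect = (~constant) & (se == 0)
    if perfect.any():
        raise DegenerateFitError(
            f"perfect fit (zero residual) at SNPs {list(np.flatnonzero(perfect)[:5])}"
        )
    tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "SNP": variants["snp"].to_numpy(),
            "A1": variants["a1"].to_numpy(),
            "A2": variants["a2"].to_numpy(),
            "BETA": np.where(constant, np.nan, beta),
            "SE": np.where(constant, np.nan, se),
            "P": np.where(constant, np.nan, p),
            "N": n,
            "note": np.where(constant, "skipped: constant genotype", ""),
        }
    )
    tested = out[out["note"] == ""].reset_index(drop=True)
    skipped = out[out["note"] != ""].reset_index(drop=True)
    ss = SummaryStats(tested.drop(columns="note"), source_ids=frozenset(sample_ids))
    ss.skipped = skipped[["SNP", "note"]]
    return ss


def _covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise DataError(f"covariate rows {C.shape[0]} != {n} samples")
    return np.column_stack([np.ones(n), C])


def meta_fixed(stats_1: SummaryStats, stats_2: SummaryStats) -> SummaryStats:
    """Inverse-variance fixed-effects meta-analysis of two scans.

    SNPs are matched by id; effect alleles are aligned (swap -> negate).
    Requires full overlap of SNP sets and consistent allele pairs.
    """
    t1 = stats_1.table.set_index("SNP")
    t2 = stats_2.table.set_index("SNP")
    missing = t1.index.symmetric_difference(t2.index)
    if len(missing):
        raise DataError(
            f"{len(missing)} SNPs absent from one input, e.g. {list(missing[:5])}"
        )
    t2 = t2.loc[t1.index]

    same = (t1["A1"].to_numpy() == t2["A1"].to_numpy()) & (
        t1["A2"].to_numpy() == t2["A2"].to_numpy()
    )
    flipped = (t1["A1"].to_numpy() == t2["A2"].to_numpy()) & (
        t1["A2"].to_numpy() == t2["A1"].to_numpy()
    )
    bad = ~(same | flipped)
    if bad.any():
        raise DataError(
            "allele pairs irreconcilable (strand-ambiguous?) at "
            f"{list(t1.index[bad][:5])}"
        )
    b1 = t1["BETA"].to_numpy()
    b2 = np.where(flipped, -t2["BETA"].to_numpy(), t2["BETA"].to_numpy())
    w1 = 1.0 / t1["SE"].to_numpy() ** 2
    w2 = 1.0 / t2["SE"].to_numpy() ** 2
    beta = (w1 * b1 + w2 * b2) / (w1 + w2)
    se = 1.0 / np.sqrt(w1 + w2)
    z = beta / se
    p = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "SNP": t1.index.to_numpy(),
            "A1": t1["A1"].to_numpy(),
            "A2": t1["A2"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": t1["N"].to_numpy() + t2["N"].to_numpy(),
        }
    )
    return SummaryStats(
        out,
        effect_scale=stats_1.effect_scale,
        source_ids=stats_1.source_ids | stats_2.source_ids,
    )
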