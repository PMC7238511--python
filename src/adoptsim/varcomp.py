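"""SNP-heritability and genetic-correlation estimators, written from scratch.

Four estimators live here, all operating on the same simulated currency:

* :func:`compute_grm` — the standard genomic relationship matrix
  A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
  with allele frequencies taken from the sample.
* :func:`he_regression` — Haseman-Elston: regress phenotype cross
  products y_j y_k on A_jk over "unrelated" pairs; the slope estimates
  h², with a delete-one-individual jackknife SE.
* :func:`reml_fit` — single-component GREML: y = Xb + g + e with
  Var(y) = sigma_g² A + sigma_e² I, fitted by average-information REML
  with an EM fallback, solved in the eigenbasis of A so each iteration
  is O(n·p).
* :func:`noLD_ldsc_h2` / :func:`noLD_rg` — the LD-score regression
  estimators specialized to independent SNPs, where every LD score is 1
  and the slope collapses to the closed form h² = M (mean chi² - 1) / n;
  SEs come from a block jackknife over SNPs.

Observed/liability-scale conversion for binary traits uses the standard
threshold-model transformation
h²_l = h²_o · K²(1-K)² / (P(1-P) · z²), z = phi(Phi^{-1}(1-K)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DataError
from .gwas import SummaryStats


@dataclass
class GRM:
    """Genomic relationship matrix with sample ids and the SNP count used."""

    matrix: np.ndarray
    ids: np.ndarray
    m_snps: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise DataError(f"GRM shape {self.matrix.shape} != ({n}, {n})")
        if not np.isfinite(self.matrix).all():
            raise DataError("GRM contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    method: str  # HE | REML | noLD-LDSC
    scale: str = "observed"
    n: int = 0
    m_snps: int = 0
    converged: bool = True
    boundary: bool = False
    out_of_range: bool = False

    def __post_init__(self):
        self.out_of_range = not (0.0 <= self.h2 <= 1.0)


def compute_grm(genotypes: np.ndarray, ids=None) -> GRM:
    """GCTA-style GRM from an allele-count matrix.

    Allele frequencies are estimated from the sample; monomorphic SNPs
    make the standardization undefined and must be filtered first
    (see :func:`adoptsim.qc.filter_maf`).
    """
    geno = np.asarray(genotypes, dtype=float)
    n, m = geno.shape
    if n < 2:
        raise DataError("GRM needs at least two individuals")
    p = geno.mean(axis=0) / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        raise DataError(
            f"{mono.sum()} monomorphic SNPs present; run qc.filter_maf first"
        )
    Z = (geno - 2 * p) / np.sqrt(2 * p * (1 - p))
    A = (Z @ Z.T) / m
    if ids is None:
        ids = np.arange(n)
    return GRM(matrix=A, ids=np.asarray(ids), m_snps=m)


def he_regression(
    grm: GRM, phenotype: np.ndarray, cutoff: float = 0.025
) -> HeritabilityEstimate:
    """Haseman-Elston regression of y_j y_k on A_jk over unrelated pairs.

    The phenotype is standardized internally.  Pairs with A_jk above
    ``cutoff`` are excluded so the regression runs on the "unrelated"
    design; the slope then estimates h² on the observed scale.  The SE
    is a delete-one-individual jackknife (pairs containing the deleted
    individual drop out), computed from rolling sums so the whole thing
    stays O(n²).
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != grm.n:
        raise DataError("phenotype length does not match GRM")
    y = (y - y.mean()) / y.std()
    A = grm.matrix
    n = grm.n

    iu = np.triu_indices(n, k=1)
    x = A[iu]
    keep = x <= cutoff
    if keep.sum() < 100:
        raise DataError(f"only {int(keep.sum())} unrelated pairs; need >= 100")
    cp = y[iu[0]] * y[iu[1]]
    x, cp, rows, cols = x[keep], cp[keep], iu[0][keep], iu[1][keep]

    slope, _ = _ols_line(x, cp)

    # per-individual sums over retained pairs, for the jackknife
    npairs = len(x)
    S = np.array([npairs, x.sum(), cp.sum(), (x * x).sum(), (x * cp).sum()])
    per = np.zeros((n, 5))
    contrib = np.column_stack([np.ones(npairs), x, cp, x * x, x * cp])
    np.add.at(per, rows, contrib)
    np.add.at(per, cols, contrib)

    loo = S[None, :] - per  # leave-one-out sums
    cnt, sx, sy, sxx, sxy = loo.T
    denom = sxx - sx * sx / cnt
    valid = denom > 0
    slopes = np.full(n, slope)
    slopes[valid] = (sxy[valid] - sx[valid] * sy[valid] / cnt[valid]) / denom[valid]
    se = np.sqrt((n - 1) / n * ((slopes - slopes.mean()) ** 2).sum())

    return HeritabilityEstimate(
        h2=float(slope), se=float(se), method="HE", n=n, m_snps=grm.m_snps
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    slope = (xc @ y) / (xc @ xc)
    return float(slope), float(y.mean() - slope * x.mean())


def reml_fit(
    grm: GRM,
    phenotype: np.ndarray,
    covariates=None,
    max_iter: int = 100,
    tol: float = 1e-6,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> HeritabilityEstimate:
    """Single-component average-information REML (GREML).

    Model: y = Xb + g + e, Var(y) = sigma_g² A + sigma_e² I.  The GRM is
    eigendecomposed once; every iteration then works with a diagonal
    covariance in the rotated basis.  AI updates proposing negative
    variances, or decreasing the restricted likelihood, fall back to an
    EM step; variances are clamped at a small positive boundary (and the
    estimate flagged) when the optimum sits at zero.  Convergence is a
    restricted-log-likelihood change below ``tol``.

    ``eig`` may carry a precomputed ``np.linalg.eigh(grm.matrix)`` result
    when several phenotypes are fitted against one GRM.
    """
    y = np.asarray(phenotype, dtype=float)
    n = grm.n
    if len(y) != n:
        raise DataError("phenotype length does not match GRM")
    X = _fixed_effects(covariates, n)
    p = X.shape[1]

    lam, U = np.linalg.eigh(grm.matrix) if eig is None else eig
    if lam.min() < -1e-6 * max(1.0, lam.max()):
        raise DataError(f"GRM not PSD to tolerance (min eigenvalue {lam.min():.3g})")
    lam = np.maximum(lam, 0.0)
    ys = U.T @ y
    Xs = U.T @ X

    vary = float(np.var(y, ddof=1))
    sg2, se2 = 0.5 * vary, 0.5 * vary
    floor = 1e-8 * vary
    ll_old, trace = -np.inf, []
    nr = len(ys) - p
    for it in range(max_iter):
        (ll, Py, dA, dI, aiL) = _reml_quantities(lam, ys, Xs, sg2, se2)
        trace.append((it, sg2, se2, ll))
        params = np.array([sg2, se2])
        if it > 0 and abs(ll - ll_old) < tol:
            break
        ll_old = ll
        grad = np.array([dA, dI])
        try:
            step = np.linalg.solve(aiL, grad)
        except np.linalg.LinAlgError:
            step = None
        accepted = False
        if step is not None:
            # damped AI step, clamped at the positivity boundary
            for alpha in (1.0, 0.5, 0.25, 0.1, 0.01):
                prop = np.maximum(params + alpha * step, floor)
                ll_new = _reml_quantities(lam, ys, Xs, prop[0], prop[1])[0]
                if ll_new >= ll - 1e-10:
                    sg2, se2 = prop
                    accepted = True
                    break
        if not accepted:
            # EM fallback (guaranteed uphill, slow near boundaries)
            prop = np.maximum(
                params + params**2 * grad * 2 / nr, floor
            )
            sg2, se2 = prop
        if np.max(np.abs(np.array([sg2, se2]) - params)) < 1e-12 * vary:
            break  # pinned at the boundary; likelihood cannot move
    else:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", trace=trace
        )

    boundary = sg2 <= 2 * floor or se2 <= 2 * floor
    total = sg2 + se2
    h2 = sg2 / total
    # SE via delta method on the inverse AI matrix
    _, _, _, _, aiL = _reml_quantities(lam, ys, Xs, sg2, se2)
    try:
        cov = np.linalg.inv(aiL)
        grad = np.array([se2, -sg2]) / total**2
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = np.nan
    est = HeritabilityEstimate(
        h2=float(h2),
        se=se_h2,
        method="REML",
        n=n,
        m_snps=grm.m_snps,
        converged=True,
        boundary=bool(boundary),
    )
    est.sigma_g2, est.sigma_e2, est.loglik, est.trace = sg2, se2, ll, trace
    return est


def _fixed_effects(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("fixed-effect design is rank deficient")
    return X


def _reml_quantities(lam, ys, Xs, sg2, se2):
    """Restricted loglik, Py, score vector and AI matrix, all in the eigenbasis."""
    d = sg2 * lam + se2
    Vinv_y = ys / d
    Vinv_X = Xs / d[:, None]
    XtVX = Xs.T @ Vinv_X
    XtVX_inv = np.linalg.inv(XtVX)
    beta = XtVX_inv @ (Vinv_X.T @ ys)
    Py = Vinv_y - Vinv_X @ beta

    n, p = Xs.shape
    resid_quad = float(ys @ Py)
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    ll = -0.5 * (np.log(d).sum() + logdet_XtVX + resid_quad)

    APy = lam * Py
    # tr(P A) = tr(V^-1 A) - tr((X'V^-1X)^-1 X'V^-1 A V^-1 X)
    VinvA = lam / d
    T = Vinv_X.T @ (lam[:, None] * Vinv_X)
    trPA = VinvA.sum() - np.trace(XtVX_inv @ T)
    T2 = Vinv_X.T @ Vinv_X
    trP = (1 / d).sum() - np.trace(XtVX_inv @ T2)

    PAPy = _apply_P(APy, d, Vinv_X, XtVX_inv)
    PPy = _apply_P(Py, d, Vinv_X, XtVX_inv)
    dA = -0.5 * (trPA - Py @ APy)
    dI = -0.5 * (trP - Py @ Py)
    ai = 0.5 * np.array(
        [
            [APy @ PAPy, APy @ PPy],
            [APy @ PPy, Py @ PPy],
        ]
    )
    return ll, Py, dA, dI, ai


def _apply_P(v, d, Vinv_X, XtVX_inv):
    Vinv_v = v / d
    return Vinv_v - Vinv_X @ (XtVX_inv @ (Vinv_X.T @ v))


def noLD_ldsc_h2(
    summary_stats: SummaryStats,
    n: int,
    m_snps: int | None = None,
    n_blocks: int = 200,
    free_intercept: bool = False,
    ld_scores: np.ndarray | None = None,
) -> HeritabilityEstimate:
    """LD-score-regression heritability for independent SNPs.

    With every LD score equal to 1 the regression of chi² on n·l/M
    degenerates to the closed form h² = M (mean chi² - 1)/n, with the
    intercept fixed at 1 (no stratification, no sample overlap).  A free
    intercept needs variation in the LD scores: pass ``ld_scores`` to
    enable it; constant scores make slope and intercept collinear and
    raise an error.
    """
    if n <= 0:
        raise DataError(f"sample size must be positive, got {n}")
    chi2 = summary_stats.chi2
    M = m_snps if m_snps is not None else len(chi2)
    if M <= 0:
        raise DataError("m_snps must be positive")

    if free_intercept:
        if ld_scores is None:
            ld_scores = np.ones(len(chi2))
        ld_scores = np.asarray(ld_scores, dtype=float)
        if np.ptp(ld_scores) < 1e-12:
            raise DataError(
                "free intercept is unidentifiable with constant LD scores "
                "(independent SNPs); fix the intercept at 1 instead"
            )
        x = n * ld_scores / M
        slope, _ = _ols_line(x, chi2)
        h2_blocks = _block_jackknife(
            lambda idx: _ols_line(x[idx], chi2[idx])[0], len(chi2), n_blocks
        )
        h2 = slope
    else:
        h2 = M * (chi2.mean() - 1.0) / n
        h2_blocks = _block_jackknife(
            lambda idx: M * (chi2[idx].mean() - 1.0) / n, len(chi2), n_blocks
        )
    se = _jackknife_se(h2_blocks)
    return HeritabilityEstimate(
        h2=float(h2), se=float(se), method="noLD-LDSC", n=n, m_snps=int(M)
    )


def _block_jackknife(stat, n_items: int, n_blocks: int) -> np.ndarray:
    n_blocks = min(n_blocks, n_items)
    edges = np.linspace(0, n_items, n_blocks + 1).astype(int)
    all_idx = np.arange(n_items)
    vals = []
    for b in range(n_blocks):
        mask = np.ones(n_items, dtype=bool)
        mask[edges[b] : edges[b + 1]] = False
        vals.append(stat(all_idx[mask]))
    return np.array(vals)


def _jackknife_se(vals: np.ndarray) -> float:
    g = len(vals)
    return np.sqrt((g - 1) / g * ((vals - vals.mean()) ** 2).sum())


def noLD_rg(
    stats_1: SummaryStats,
    stats_2: SummaryStats,
    n1: int,
    n2: int,
    m_snps: int | None = None,
    n_blocks: int = 200,
):
    """Genetic correlation between two traits from independent-SNP summary stats.

    r_g = M * mean(z1 z2) / (sqrt(n1 n2) * sqrt(h1² h2²)), the
    cross-trait LD-score regression slope with all LD scores 1 and no
    phenotypic-overlap intercept — hence the requirement that the two
    scans come from disjoint samples.  Returns (rg, se, clipped_flag);
    |r_g| may exceed 1 by sampling noise, in which case the clipped flag
    is set (the unclipped value is returned).
    """
    if stats_1.source_ids and stats_2.source_ids:
        if stats_1.source_ids & stats_2.source_ids:
            raise DataError("summary statistics share sample ids; rg assumes disjoint samples")
    t1 = stats_1.table.set_index("SNP")
    t2 = stats_2.table.set_index("SNP")
    shared = t1.index.intersection(t2.index)
    if len(shared) == 0:
        raise DataError("no shared SNPs")
    z1 = (t1.loc[shared, "BETA"] / t1.loc[shared, "SE"]).to_numpy()
    z2 = (t2.loc[shared, "BETA"] / t2.loc[shared, "SE"]).to_numpy()
    M = m_snps if m_snps is not None else len(shared)

    def compute(idx):
        mz = (z1[idx] * z2[idx]).mean()
        h1 = M * ((z1[idx] ** 2).mean() - 1) / n1
        h2 = M * ((z2[idx] ** 2).mean() - 1) / n2
        denom = np.sqrt(max(h1, 1e-12) * max(h2, 1e-12))
        return (M * mz / np.sqrt(n1 * n2)) / denom

    all_idx = np.arange(len(shared))
    rg = compute(all_idx)
    se = _jackknife_se(_block_jackknife(compute, len(shared), n_blocks))
    return float(rg), float(se), bool(abs(rg) > 1)


def obs_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale heritability for a binary trait.

    h²_l = h²_o · K²(1-K)² / (P(1-P) · z²) with z the standard-normal
    density at the threshold Phi^{-1}(1-K); K is the population
    prevalence, P the sample prevalence.
    """
    _check_prev(K, P)
    if h2_obs < 0:
        raise DataError("h2_obs must be >= 0")
    z = stats.norm.pdf(stats.norm.ppf(1 - K))
    return h2_obs * K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2)


def liability_to_obs(h2_liab: float, K: float, P: float) -> float:
    """Inverse of :func:`obs_to_liability`."""
    _check_prev(K, P)
    z = stats.norm.pdf(stats.norm.ppf(1 - K))
    return h2_liab * P * (1 - P) * z**2 / (K**2 * (1 - K) ** 2)


def _check_prev(K: float, P: float) -> None:
    for name, v in (("K", K), ("P", P)):
        if not 0 < v < 1:
            raise DataError(f"prevalence {name}={v} outside (0, 1)")


def estimates_table(estimates) -> pd.DataFrame:
    """Collect HeritabilityEstimate objects into the interchange TSV layout."""
    return pd.DataFrame(
        [
            {
                "method": e.method,
                "scale": e.scale,
                "h2": e.h2,
                "se": e.se,
                "n": e.n,
                "M": e.m_snps,
                "converged": e.converged,
                "boundary_flag": e.boundary,
            }
            for e in estimates
        ]
    )
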