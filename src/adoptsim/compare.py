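"""The adoption-design inference layer.

Everything that turns scores, phenotypes and group labels into the
result set of the natural experiment: group descriptives, the
variance-homogeneity test, the bootstrap comparison of polygenic R²
between adoptees and non-adoptees, additive/multiplicative
score-by-adoption interaction models with full covariate-interaction
(Keller) adjustment, the pooled-decile analysis, and stratified
prediction across birth-year (or any other) strata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, DegenerateFitError
from .pgs import incremental_r2
from .utils import standardize


@dataclass
class BootstrapR2Diff:
    """Bootstrap comparison of incremental R² between two groups."""

    r2_a: float
    r2_b: float
    se_a: float
    se_b: float
    z: float
    p: float
    n_a: int
    n_b: int
    reps: int
    degenerate_redraws: int = 0

    @property
    def diff(self) -> float:
        return self.r2_a - self.r2_b


@dataclass
class ComparisonReport:
    """Container mirroring the study's Results section."""

    descriptives: pd.DataFrame = None
    variance_test: dict = field(default_factory=dict)
    r2_comparison: BootstrapR2Diff = None
    interaction_additive: pd.DataFrame = None
    interaction_multiplicative: pd.DataFrame = None
    decile_table: pd.DataFrame = None
    stratified_r2: pd.DataFrame = None

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, pd.DataFrame):
                return v.to_dict(orient="list")
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return dataclasses.asdict(v)
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


def descriptive_compare(
    years: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    group: np.ndarray,
) -> pd.DataFrame:
    """Group differences in years of education, age and sex.

    Follows the original test assignment: a Wald test of the mean
    difference for years, a two-sample z test for age and a Wilcoxon
    rank-sum test for (binary) sex.  The rank-sum test on a 0/1 variable
    is equivalent to a proportion comparison up to ties — an odd but
    harmless choice, kept for fidelity.
    """
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise DataError(f"need exactly two groups, got {list(labels)}")
    g0, g1 = (group == labels[0]), (group == labels[1])
    if g0.sum() < 2 or g1.sum() < 2:
        raise DataError("each group needs n >= 2")

    rows = []
    for name, values, test in (
        ("years_edu", np.asarray(years, float), "wald"),
        ("age", np.asarray(age, float), "ztest"),
        ("sex", np.asarray(sex, float), "wilcoxon"),
    ):
        a, b = values[g0], values[g1]
        if test in ("wald", "ztest"):
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            z = (a.mean() - b.mean()) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            stat = z
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "variable": name,
                "test": test,
                f"mean_{labels[0]}": a.mean(),
                f"mean_{labels[1]}": b.mean(),
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def brown_forsythe(phenotype: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Variance-homogeneity test on absolute deviations from group medians.

    One-way ANOVA F on z_ij = |y_ij - median_j| — i.e. Levene's test
    with median centering, robust to the non-normal, lumpy distribution
    of years of education.
    """
    group = np.asarray(group)
    samples = [np.asarray(phenotype, float)[group == g] for g in np.unique(group)]
    if len(samples) < 2:
        raise DataError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise DataError("every group needs n >= 2")
    z = [np.abs(s - np.median(s)) for s in samples]
    if all(np.ptp(zi) == 0 for zi in z):
        raise DataError("zero within-group variance of |y - median| everywhere")
    F, p = stats.levene(*samples, center="median")
    return float(F), float(p)


def bootstrap_r2_diff(
    y_a,
    score_a,
    cov_a,
    y_b,
    score_b,
    cov_b,
    reps: int = 1000,
    seed: int = 0,
) -> BootstrapR2Diff:
    """Bootstrap SEs for the two incremental R²s and a normal difference test.

    Point estimates come from the unresampled data; within each group,
    individuals are resampled with replacement ``reps`` times and the
    incremental R² recomputed.  Replicates with a degenerate design
    (constant phenotype or score) are redrawn; more than 10% degenerate
    aborts.  z = (R²_A - R²_B) / sqrt(SE_A² + SE_B²), two-sided normal p.
    """
    if reps < 100:
        raise DataError("bootstrap reps must be >= 100")
    rng = np.random.default_rng(seed)
    r2_a = incremental_r2(y_a, score_a, cov_a).incremental
    r2_b = incremental_r2(y_b, score_b, cov_b).incremental
    se_a, bad_a = _boot_se(y_a, score_a, cov_a, reps, rng)
    se_b, bad_b = _boot_se(y_b, score_b, cov_b, reps, rng)
    z = (r2_a - r2_b) / np.sqrt(se_a**2 + se_b**2)
    p = 2 * stats.norm.sf(abs(z))
    return BootstrapR2Diff(
        r2_a=r2_a,
        r2_b=r2_b,
        se_a=se_a,
        se_b=se_b,
        z=float(z),
        p=float(p),
        n_a=len(np.asarray(y_a)),
        n_b=len(np.asarray(y_b)),
        reps=reps,
        degenerate_redraws=bad_a + bad_b,
    )


def _boot_se(y, score, cov, reps, rng):
    y = np.asarray(y, float)
    s = np.asarray(score, float)
    C = None if cov is None else np.asarray(cov, float)
    if C is not None and C.ndim == 1:
        C = C[:, None]
    n = len(y)
    X_full = np.column_stack(
        [np.ones(n)] + ([] if C is None else [C]) + [s]
    )
    k_red = X_full.shape[1] - 1
    vals = np.empty(reps)
    bad = 0
    for r in range(reps):
        for _attempt in range(100):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            Xb = X_full[idx]
            tss = ((yb - yb.mean()) ** 2).sum()
            if tss == 0 or np.ptp(Xb[:, -1]) == 0:
                bad += 1
                if bad > 0.1 * reps:
                    raise DataError(
                        f"more than 10% degenerate bootstrap replicates ({bad})"
                    )
                continue
            coef_f, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
            res_f = yb - Xb @ coef_f
            coef_r, *_ = np.linalg.lstsq(Xb[:, :k_red], yb, rcond=None)
            res_r = yb - Xb[:, :k_red] @ coef_r
            vals[r] = (res_r @ res_r - res_f @ res_f) / tss
            break
        else:
            raise DataError("could not draw a non-degenerate bootstrap replicate")
    return float(vals.std(ddof=1)), bad


def _keller_design(score, adopted, covariates):
    """Design matrix with score, moderator, covariates and ALL interactions."""
    s = standardize(np.asarray(score, float))
    a = np.asarray(adopted, float)
    cols = {"score": s, "adopted": a, "score:adopted": s * a}
    names = ["score", "adopted", "score:adopted"]
    if covariates is not None:
        C = pd.DataFrame(covariates).reset_index(drop=True)
        for c in C.columns:
            v = C[c].to_numpy(dtype=float)
            cols[str(c)] = v
            cols[f"score:{c}"] = s * v
            cols[f"adopted:{c}"] = a * v
            names += [str(c), f"score:{c}", f"adopted:{c}"]
    X = pd.DataFrame(cols, columns=names)
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns for the error message
        aliased = []
        keep = []
        for c in X.columns:
            trial = X[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) < len(keep) + 1:
                aliased.append(c)
            else:
                keep.append(c)
        raise DegenerateFitError(f"rank-deficient interaction design; aliased: {aliased}")
    return X


def interaction_additive(
    phenotype, score, adopted, covariates=None
) -> pd.DataFrame:
    """Linear score-by-adoption interaction with Keller covariate adjustment.

    Phenotype and score are standardized; the model contains main
    effects for score, adoption and every covariate, plus score x
    adoption (the headline term) and score x covariate and adoption x
    covariate for each covariate, so the focal interaction is not
    confounded by covariate interactions.
    """
    y = standardize(np.asarray(phenotype, float))
    X = _keller_design(score, adopted, covariates)
    fit = sm.OLS(y, X).fit()
    return _coef_table(fit)


def interaction_multiplicative(
    years, score, adopted, covariates=None, dichotomize_at: float = 20.0
) -> pd.DataFrame:
    """Logistic score-by-adoption interaction on degree attainment.

    The continuous outcome is dichotomized at ``dichotomize_at`` years
    (default: college/university degree).  Same Keller term set as the
    additive model; coefficients are log odds.
    """
    outcome = (np.asarray(years, float) >= dichotomize_at).astype(int)
    if outcome.min() == outcome.max():
        raise DataError(
            f"dichotomization at {dichotomize_at} leaves a single outcome class"
        )
    X = _keller_design(score, adopted, covariates)
    try:
        fit = sm.Logit(outcome, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises several separation flavours
        raise DegenerateFitError(
            f"logistic fit failed ({exc}); consider a penalized fallback"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise DegenerateFitError(
            "logistic fit did not converge (separation?); consider a penalized fallback"
        )
    return _coef_table(fit)


def _coef_table(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )


def decile_analysis(
    score, phenotype, adopted, n_deciles: int = 10
) -> pd.DataFrame:
    """Group phenotype means per decile of the *pooled* score distribution.

    The phenotype is standardized on the pooled sample; deciles are cut
    on the pooled score with stable-rank tie breaking.  Each decile gets
    a Welch two-sample test of the adopted vs non-adopted means and a
    Bonferroni-adjusted significance flag (n_deciles tests).  A decile
    with one group empty yields NaN test columns and the run continues.
    """
    s = np.asarray(score, float)
    a = np.asarray(adopted, bool)
    y = standardize(np.asarray(phenotype, float))
    if a.all() or not a.any():
        raise DataError("both groups must be present")
    n = len(s)
    ranks = np.argsort(np.argsort(s, kind="stable"), kind="stable")
    decile = np.minimum((ranks * n_deciles) // n, n_deciles - 1)

    rows = []
    for d in range(n_deciles):
        in_d = decile == d
        ya, yn = y[in_d & a], y[in_d & ~a]
        row = {
            "decile": d + 1,
            "n_adopted": len(ya),
            "n_nonadopted": len(yn),
            "mean_adopted": ya.mean() if len(ya) else np.nan,
            "mean_nonadopted": yn.mean() if len(yn) else np.nan,
            "se_adopted": ya.std(ddof=1) / np.sqrt(len(ya)) if len(ya) > 1 else np.nan,
            "se_nonadopted": yn.std(ddof=1) / np.sqrt(len(yn)) if len(yn) > 1 else np.nan,
        }
        if len(ya) > 1 and len(yn) > 1:
            t, p = stats.ttest_ind(ya, yn, equal_var=False)
            row["t"], row["p"] = float(t), float(p)
            row["significant_bonferroni"] = bool(p < 0.05 / n_deciles)
        else:
            row["t"] = row["p"] = np.nan
            row["significant_bonferroni"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_prediction(
    phenotype,
    score,
    covariates,
    strata,
    group=None,
    reps: int = 200,
    seed: int = 0,
    min_stratum_n: int = 100,
) -> pd.DataFrame:
    """Incremental R² (with bootstrap SE) per stratum, optionally per group.

    Strata must partition the sample (e.g. seven 5-year birth-year
    bins).  Strata below ``min_stratum_n`` are excluded with a log row
    (``excluded`` = True).  Pairwise z tests across strata within group
    are flagged at alpha = 0.05.
    """
    y = np.asarray(phenotype, float)
    s = np.asarray(score, float)
    strata = np.asarray(strata)
    groups = np.zeros(len(y), dtype=int) if group is None else np.asarray(group)
    C = None if covariates is None else np.asarray(covariates, float)
    rng = np.random.default_rng(seed)

    rows = []
    for g in np.unique(groups):
        for st in np.unique(strata):
            mask = (groups == g) & (strata == st)
            n = int(mask.sum())
            row = {"group": g, "stratum": st, "n": n, "excluded": n < min_stratum_n}
            if not row["excluded"]:
                res = incremental_r2(y[mask], s[mask], None if C is None else C[mask])
                se, _ = _boot_se(
                    y[mask], s[mask], None if C is None else C[mask], reps, rng
                )
                row.update({"incremental_r2": res.incremental, "se": se})
            else:
                row.update({"incremental_r2": np.nan, "se": np.nan})
            rows.append(row)
    out = pd.DataFrame(rows)

    # pairwise stratum differences within group
    flags = []
    for g in np.unique(groups):
        sub = out[(out["group"] == g) & (~out["excluded"])]
        for i, ri in sub.iterrows():
            for j, rj in sub.iterrows():
                if ri["stratum"] >= rj["stratum"]:
                    continue
                z = (ri["incremental_r2"] - rj["incremental_r2"]) / np.sqrt(
                    ri["se"] ** 2 + rj["se"] ** 2
                )
                p = 2 * stats.norm.sf(abs(z))
                flags.append(
                    {
                        "group": g,
                        "stratum_1": ri["stratum"],
                        "stratum_2": rj["stratum"],
                        "z": float(z),
                        "p": float(p),
                        "significant": bool(p < 0.05),
                    }
                )
    out.attrs["pairwise"] = pd.DataFrame(flags)
    return out
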