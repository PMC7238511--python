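"""End-to-end orchestration of the adoption natural experiment.

``run_experiment`` executes the full design on a simulated cohort:

    simulate -> variant QC -> split into groups a/b/c/d
             -> GWAS in b (optionally meta-analysed with a second,
                "external consortium" cohort)
             -> threshold training in c
             -> polygenic comparison, interaction, decile and variance
                analyses on a vs d
             -> GRM + HE/REML/no-LD-LDSC heritability in a and d

All randomness flows from a single master seed via hash-derived stage
seeds, so a rerun with the same config writes a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, io, pgs, qc, varcomp
from .compare import ComparisonReport
from .config import ExperimentConfig
from .errors import DataError
from .gwas import assoc_scan, meta_fixed
from .simdata import Cohort, simulate_cohort
from .utils import stage_rng


def split_groups(cohort: Cohort, group_sizes: dict, seed: int = 0) -> Cohort:
    """Label analysis groups: a = all adoptees; b/c/d random disjoint non-adoptees.

    The configured size of group a is informative only (every adoptee is
    analysed); b, c and d take their configured sizes from a random
    permutation of the non-adoptees.  Raises with counts when the
    non-adopted pool is too small.
    """
    rng = stage_rng(seed, "split")
    table = cohort.table
    adopted = table["adopted"].to_numpy().astype(bool)
    need = sum(group_sizes[g] for g in "bcd")
    non_idx = np.flatnonzero(~adopted)
    if len(non_idx) < need:
        raise DataError(
            f"need {need} non-adoptees for groups b+c+d, have {len(non_idx)}"
        )
    perm = rng.permutation(non_idx)
    labels = np.array([""] * len(table), dtype=object)
    labels[adopted] = "a"
    start = 0
    for g in "bcd":
        size = group_sizes[g]
        labels[perm[start : start + size]] = g
        start += size
    out = table.copy()
    out["group"] = labels
    # leakage guard: b/c/d must be pairwise disjoint
    for g1 in "bcd":
        for g2 in "bcd":
            if g1 < g2:
                ids1 = set(out.loc[out["group"] == g1, "iid"])
                ids2 = set(out.loc[out["group"] == g2, "iid"])
                assert not (ids1 & ids2), f"groups {g1},{g2} overlap"
    return dataclasses.replace(cohort, table=out)


@dataclass
class ExperimentResult:
    report: ComparisonReport
    cohort: Cohort
    pgs_model: pgs.PGSModel
    heritability: pd.DataFrame
    summary_stats: object
    seed: int


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the whole study design; optionally write artifacts to disk."""
    timings: dict[str, float] = {}
    t0 = time.time()

    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    cohort = simulate_cohort(sim_cfg)
    timings["simulate"] = time.time() - t0

    # variant QC on the cohort (sample MAF floor)
    t = time.time()
    geno, variants = qc.filter_maf(
        cohort.genotypes, cohort.variants, config.qc.maf_min
    )
    geno, variants = qc.filter_call_rate(geno, variants)
    cohort = dataclasses.replace(cohort, genotypes=geno, variants=variants)
    timings["qc_variants"] = time.time() - t

    t = time.time()
    cohort = split_groups(cohort, sim_cfg.group_sizes, seed=config.seed)
    timings["split"] = time.time() - t
    tab = cohort.table
    sel = {g: tab["group"].to_numpy() == g for g in "abcd"}
    covs = tab[["sex", "age"]].to_numpy(dtype=float)
    y = tab["edu_liability"].to_numpy()

    # GWAS in group b
    t = time.time()
    sstats = assoc_scan(
        cohort.genotypes[sel["b"]],
        y[sel["b"]],
        covs[sel["b"]],
        cohort.variants,
        sample_ids=tab.loc[sel["b"], "iid"],
    )
    if config.external_meta:
        ext_cfg = dataclasses.replace(
            sim_cfg,
            n_families=config.external_n_families,
            seed=config.seed + 104729,  # independent cohort, same generative law
        )
        ext = simulate_cohort(ext_cfg)
        ext_geno, ext_var = qc.filter_maf(ext.genotypes, ext.variants, config.qc.maf_min)
        shared = set(ext_var["snp"]) & set(cohort.variants["snp"])
        keep_ext = ext_var["snp"].isin(shared).to_numpy()
        keep_b = cohort.variants["snp"].isin(shared).to_numpy()
        ext_stats = assoc_scan(
            ext_geno[:, keep_ext][~ext.table["adopted"].astype(bool)],
            ext.table.loc[~ext.table["adopted"].astype(bool), "edu_liability"],
            ext.table.loc[~ext.table["adopted"].astype(bool), ["sex", "age"]],
            ext_var[keep_ext].reset_index(drop=True),
            sample_ids=("EXT:" + ext.table.loc[~ext.table["adopted"].astype(bool), "iid"]),
        )
        base = sstats.table[keep_b].reset_index(drop=True)
        sstats_b = type(sstats)(base, effect_scale=sstats.effect_scale, source_ids=sstats.source_ids)
        sstats = meta_fixed(sstats_b, ext_stats)
    timings["gwas"] = time.time() - t

    # threshold training in group c
    t = time.time()
    model = pgs.train_threshold(
        cohort.genotypes[sel["c"]],
        cohort.variants,
        y[sel["c"]],
        covs[sel["c"]],
        sstats,
        candidates=config.pgs_thresholds,
        ids=tab.loc[sel["c"], "iid"],
    )
    timings["pgs_train"] = time.time() - t

    # apply to a and d, then the comparison suite
    t = time.time()
    report = ComparisonReport()
    sc = {}
    for g in ("a", "d"):
        sc[g] = pgs.score(
            cohort.genotypes[sel[g]],
            cohort.variants,
            sstats,
            model.chosen_threshold,
            ids=tab.loc[sel[g], "iid"],
        )

    pool = sel["a"] | sel["d"]
    years = tab["years_edu"].to_numpy(dtype=float)
    report.descriptives = compare.descriptive_compare(
        years[pool],
        tab["age"].to_numpy()[pool],
        tab["sex"].to_numpy()[pool],
        np.where(sel["a"][pool], "adopted", "nonadopted"),
    )
    F, p_bf = compare.brown_forsythe(
        years[pool], np.where(sel["a"][pool], "adopted", "nonadopted")
    )
    report.variance_test = {
        "F": F,
        "p": p_bf,
        "var_adopted": float(years[sel["a"]].var(ddof=1)),
        "var_nonadopted": float(years[sel["d"]].var(ddof=1)),
    }
    report.r2_comparison = compare.bootstrap_r2_diff(
        y[sel["d"]],
        sc["d"]["std_score"].to_numpy(),
        covs[sel["d"]],
        y[sel["a"]],
        sc["a"]["std_score"].to_numpy(),
        covs[sel["a"]],
        reps=config.compare.bootstrap_reps,
        seed=config.seed,
    )
    pooled_scores = np.concatenate(
        [sc["a"]["raw_score"].to_numpy(), sc["d"]["raw_score"].to_numpy()]
    )
    pooled_y = np.concatenate([y[sel["a"]], y[sel["d"]]])
    pooled_years = np.concatenate([years[sel["a"]], years[sel["d"]]])
    pooled_adopted = np.concatenate(
        [np.ones(int(sel["a"].sum()), bool), np.zeros(int(sel["d"].sum()), bool)]
    )
    pooled_covs = np.concatenate([covs[sel["a"]], covs[sel["d"]]])
    report.interaction_additive = compare.interaction_additive(
        pooled_y, pooled_scores, pooled_adopted, pooled_covs
    )
    try:
        report.interaction_multiplicative = compare.interaction_multiplicative(
            pooled_years,
            pooled_scores,
            pooled_adopted,
            pooled_covs,
            dichotomize_at=config.compare.dichotomize_at,
        )
    except DataError:
        report.interaction_multiplicative = None
    report.decile_table = compare.decile_analysis(
        pooled_scores, pooled_y, pooled_adopted, config.compare.n_deciles
    )
    timings["compare"] = time.time() - t

    # heritability in a and d
    t = time.time()
    estimates = []
    for g in ("a", "d"):
        ids_g = tab.loc[sel[g], "iid"].to_numpy()
        # rare SNPs can be monomorphic within a small analysis group;
        # re-apply the MAF floor inside the subsample before the GRM
        geno_g, _ = qc.filter_maf(
            cohort.genotypes[sel[g]], cohort.variants, config.qc.maf_min
        )
        grm = varcomp.compute_grm(geno_g, ids=ids_g)
        # the relatedness cutoff must sit above the sampling noise of the
        # GRM entries (SD ~ 1/sqrt(M)); otherwise desk-scale SNP counts
        # would prune unrelated pairs wholesale.  4/sqrt(M) < 0.025 for
        # the SNP counts of a real biobank, so full scale is unaffected.
        eff_cutoff = max(config.qc.relatedness_cutoff, 4.0 / np.sqrt(grm.m_snps))
        kept = qc.greedy_unrelated(grm.matrix, grm.ids, cutoff=eff_cutoff)
        keep_mask = np.isin(grm.ids, kept)
        sub = varcomp.GRM(
            grm.matrix[np.ix_(keep_mask, keep_mask)], grm.ids[keep_mask], grm.m_snps
        )
        y_g = y[sel[g]][keep_mask]
        he = varcomp.he_regression(sub, y_g, cutoff=eff_cutoff)
        he.scale = f"observed:{g}"
        reml = varcomp.reml_fit(sub, y_g, covs[sel[g]][keep_mask])
        reml.scale = f"observed:{g}"
        estimates += [he, reml]
    h2_table = varcomp.estimates_table(estimates)
    timings["varcomp"] = time.time() - t

    result = ExperimentResult(
        report=report,
        cohort=cohort,
        pgs_model=model,
        heritability=h2_table,
        summary_stats=sstats,
        seed=config.seed,
    )
    if config.output_dir:
        _write_artifacts(config, result, timings)
    return result


def _write_artifacts(config: ExperimentConfig, result: ExperimentResult, timings):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = result.cohort
    io.write_cohort_table(out / "cohort.tsv", cohort.table)
    io.write_variants(out / "variants.tsv", cohort.variants)
    io.write_sumstats(out / "sumstats.tsv", result.summary_stats)
    result.pgs_model.training_r2.to_csv(out / "pgs_training.tsv", sep="\t", index=False)
    result.heritability.to_csv(out / "heritability.tsv", sep="\t", index=False)
    report = result.report.to_dict()
    report["pgs_chosen_threshold"] = result.pgs_model.chosen_threshold
    report["seed"] = result.seed
    io.write_report(out / "report.json", report)
    log = {
        "seed": result.seed,
        "scenario": config.scenario,
        "n_cohort": int(cohort.n),
        "m_snps_post_qc": int(cohort.m),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "versions": _versions(),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "adoptsim": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
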