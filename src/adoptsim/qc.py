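"""Variant and sample quality control.

Two filters matter for simulated cohorts: a minor-allele-frequency floor
and removal of related samples.  Relative removal is a greedy vertex
deletion on the graph of pairs whose genomic relatedness exceeds the
cutoff, extended with a protected-id preference so that adoptees (the
scarce group) are excluded last — mirroring a relatedness pruning run
"to minimize the exclusion of adoptees".

A genotype call-rate filter exists as an explicit pass-through:
missingness is not simulated by default, so there is nothing to drop,
but the pipeline stage is kept so real-data-shaped inputs flow through
the same sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError


def filter_maf(
    genotypes: np.ndarray, variants: pd.DataFrame, maf_min: float = 0.01
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop SNPs whose *sample* minor allele frequency is <= maf_min.

    Monomorphic SNPs always fail (MAF 0).  Column order is preserved.
    Returns the filtered genotype matrix and variant table; raises
    DataError if nothing survives.
    """
    geno = np.asarray(genotypes)
    p = geno.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = maf > maf_min
    if not keep.any():
        raise DataError(f"no SNP passes MAF > {maf_min}; check the input")
    return geno[:, keep], variants.loc[keep].reset_index(drop=True)


def filter_call_rate(
    genotypes: np.ndarray, variants: pd.DataFrame, min_call_rate: float = 0.98
) -> tuple[np.ndarray, pd.DataFrame]:
    """Call-rate filter; a no-op unless missing genotypes (<0) are present."""
    geno = np.asarray(genotypes)
    call_rate = (geno >= 0).mean(axis=0)
    keep = call_rate >= min_call_rate
    return geno[:, keep], variants.loc[keep].reset_index(drop=True)


def greedy_unrelated(
    grm: np.ndarray,
    ids: np.ndarray,
    cutoff: float = 0.025,
    protected_ids=(),
) -> list:
    """Greedy relative removal: retain a set with all pairwise relatedness <= cutoff.

    Builds the conflict graph of pairs above the cutoff and repeatedly
    deletes the unprotected vertex of highest degree (ties: fewest
    protected neighbours, then lowest id).  A protected vertex is deleted
    only when a conflict involves protected vertices exclusively.  The
    post-condition (no retained pair above the cutoff) is asserted before
    returning.
    """
    grm = np.asarray(grm, dtype=float)
    ids = np.asarray(ids)
    n = len(ids)
    if grm.shape != (n, n):
        raise DataError(f"GRM shape {grm.shape} does not match {n} ids")
    if not np.allclose(grm, grm.T, atol=1e-8):
        raise DataError("GRM is not symmetric")
    if len(set(ids)) != n:
        raise DataError("sample ids are not unique")
    protected = np.isin(ids, list(protected_ids))

    off = grm.copy()
    np.fill_diagonal(off, 0.0)
    adj = off > cutoff
    alive = np.ones(n, dtype=bool)
    degree = adj.sum(axis=1).astype(int)

    id_rank = np.empty(n, dtype=int)  # lowest-id tiebreak
    id_rank[np.argsort(ids, kind="stable")] = np.arange(n)
    while True:
        candidates = alive & (degree > 0) & ~protected
        if not candidates.any():
            candidates = alive & (degree > 0)  # all-protected conflicts
            if not candidates.any():
                break
        cand_idx = np.flatnonzero(candidates)
        prot_neighbors = adj[np.ix_(cand_idx, np.flatnonzero(alive & protected))].sum(axis=1)
        # rank: max degree, then fewest protected neighbours, then lowest id
        key = list(zip(-degree[cand_idx], prot_neighbors, id_rank[cand_idx]))
        victim = cand_idx[min(range(len(cand_idx)), key=lambda k: key[k])]
        alive[victim] = False
        degree[adj[victim]] -= 1
        adj[victim, :] = False
        adj[:, victim] = False
        degree[victim] = 0

    kept = np.flatnonzero(alive)
    sub = off[np.ix_(kept, kept)]
    assert sub.max(initial=0.0) <= cutoff, "relatedness certificate violated"
    return list(ids[kept])
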