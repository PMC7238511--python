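"""Flat-file interchange formats.

Everything is tab-delimited text with repr-faithful float formatting so
write -> read round-trips exactly:

* genotypes: PLINK-.raw-style TSV (FID IID PAT MAT SEX PHENOTYPE then
  one ``SNP_A1`` column of allele counts per variant) plus a variant
  table TSV (SNP A1 A2 MAF);
* summary statistics: SNP A1 A2 BETA SE P N, with a leading ``#``
  comment recording the effect scale;
* per-individual scores: IID raw_score std_score n_snps_used threshold;
* GRM: GCTA-compatible gzipped lower triangle (.grm.gz: i j M A_ij,
  1-based) with a companion .grm.id file;
* cohort phenotype/covariate table and the comparison report (JSON with
  sorted keys, so identical runs are byte-identical).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .gwas import SUMSTATS_COLUMNS, SummaryStats
from .varcomp import GRM


def _fmt(x) -> str:
    return repr(float(x))


# ---------------------------------------------------------------- genotypes
def write_genotypes(
    path, genotypes, variants: pd.DataFrame, ids, pedigree: pd.DataFrame | None = None
) -> None:
    """Write a PLINK-.raw-style TSV; counts are of the A1 allele."""
    path = Path(path)
    geno = np.asarray(genotypes)
    ids = np.asarray(ids)
    ped = None
    if pedigree is not None:
        ped = pedigree.set_index("iid")
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + [
        f"{s}_{a1}" for s, a1 in zip(variants["snp"], variants["a1"])
    ]
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, iid in enumerate(ids):
            pat = mat = "0"
            if ped is not None and iid in ped.index:
                pat, mat = ped.loc[iid, "bio_father"], ped.loc[iid, "bio_mother"]
            row = [str(iid), str(iid), str(pat), str(mat), "0", "-9"]
            row += [str(int(v)) for v in geno[i]]
            fh.write("\t".join(row) + "\n")


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a PLINK-.raw-style TSV -> (allele counts, IIDs, SNP_A1 column names)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise ParseError(f"unexpected genotype header in {path}", line=1)
        snp_cols = header[6:]
        ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, found {len(parts)}", line=ln
                )
            ids.append(parts[1])
            try:
                rows.append([int(v) for v in parts[6:]])
            except ValueError as exc:
                raise ParseError(f"non-integer allele count ({exc})", line=ln) from exc
    return np.array(rows, dtype=np.int8), np.array(ids), snp_cols


def write_variants(path, variants: pd.DataFrame) -> None:
    out = variants.copy()
    maf = np.minimum(out["freq"], 1 - out["freq"])
    pd.DataFrame(
        {"SNP": out["snp"], "A1": out["a1"], "A2": out["a2"], "MAF": [
            _fmt(v) for v in maf
        ]}
    ).to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    df = _read_tsv(path, ["SNP", "A1", "A2", "MAF"])
    return pd.DataFrame(
        {
            "snp": df["SNP"],
            "a1": df["A1"],
            "a2": df["A2"],
            "freq": df["MAF"].astype(float),
        }
    )


# ------------------------------------------------------------ cohort table
COHORT_COLUMNS = [
    "iid",
    "adopted",
    "group",
    "years_edu",
    "edu_liability",
    "sex",
    "age",
    "birth_year",
]


def write_cohort_table(path, table: pd.DataFrame) -> None:
    out = table[COHORT_COLUMNS].copy()
    for c in ("edu_liability", "age"):
        out[c] = out[c].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> pd.DataFrame:
    df = _read_tsv(path, COHORT_COLUMNS)
    for c, dtype in (
        ("adopted", int),
        ("years_edu", int),
        ("sex", int),
        ("birth_year", int),
    ):
        df[c] = df[c].astype(dtype)
    for c in ("edu_liability", "age"):
        df[c] = df[c].astype(float)
    return df


# --------------------------------------------------------- summary stats
def write_sumstats(path, ss: SummaryStats) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# effect_scale: {ss.effect_scale}\n")
        fh.write("\t".join(SUMSTATS_COLUMNS) + "\n")
        for row in ss.table.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(row.SNP),
                        str(row.A1),
                        str(row.A2),
                        _fmt(row.BETA),
                        _fmt(row.SE),
                        repr(float(row.P)),
                        str(int(row.N)),
                    ]
                )
                + "\n"
            )


def read_sumstats(path) -> SummaryStats:
    path = Path(path)
    scale = "unknown"
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        ln = 1
        if first.startswith("#"):
            if "effect_scale:" in first:
                scale = first.split("effect_scale:", 1)[1].strip()
            header_line = fh.readline().rstrip("\n")
            ln += 1
        else:
            header_line = first
        header = header_line.split("\t")
        if header != SUMSTATS_COLUMNS:
            raise ParseError(f"bad summary-stats header {header}", line=ln)
        rows = []
        for ln, line in enumerate(fh, start=ln + 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(SUMSTATS_COLUMNS):
                raise ParseError(
                    f"expected {len(SUMSTATS_COLUMNS)} columns, found {len(parts)}",
                    line=ln,
                )
            try:
                rows.append(
                    (
                        parts[0],
                        parts[1],
                        parts[2],
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"malformed numeric field ({exc})", line=ln) from exc
    table = pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)
    return SummaryStats(table, effect_scale=scale)


# ----------------------------------------------------------------- scores
def write_scores(path, scores: pd.DataFrame) -> None:
    out = scores.copy()
    out["raw_score"] = out["raw_score"].map(_fmt)
    if "std_score" in out:
        out["std_score"] = out["std_score"].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for c in ("raw_score", "std_score", "threshold"):
        if c in df:
            df[c] = df[c].astype(float)
    return df


# -------------------------------------------------------------------- GRM
def write_grm(prefix, grm: GRM) -> None:
    """GCTA layout: ``<prefix>.grm.gz`` lower triangle + ``<prefix>.grm.id``."""
    prefix = Path(prefix)
    with gzip.open(str(prefix) + ".grm.gz", "wt") as fh:
        for j in range(grm.n):
            for k in range(j + 1):
                fh.write(f"{j + 1}\t{k + 1}\t{grm.m_snps}\t{_fmt(grm.matrix[j, k])}\n")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix) -> GRM:
    prefix = Path(prefix)
    ids = []
    with open(str(prefix) + ".grm.id") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError("bad .grm.id line", line=ln)
            ids.append(parts[1])
    n = len(ids)
    A = np.zeros((n, n))
    m_snps = 0
    with gzip.open(str(prefix) + ".grm.gz", "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError("bad .grm.gz line", line=ln)
            j, k = int(parts[0]) - 1, int(parts[1]) - 1
            m_snps = int(parts[2])
            A[j, k] = A[k, j] = float(parts[3])
    return GRM(matrix=A, ids=np.array(ids), m_snps=m_snps)


# ----------------------------------------------------------- ids & report
def write_ids(path, ids) -> None:
    Path(path).write_text("\n".join(str(i) for i in ids) + "\n")


def read_ids(path) -> list[str]:
    return [l for l in Path(path).read_text().splitlines() if l]


def write_report(path, report_dict: dict) -> None:
    """Deterministic JSON: sorted keys, repr-faithful floats, trailing newline."""
    Path(path).write_text(
        json.dumps(_jsonable(report_dict), sort_keys=True, indent=1) + "\n"
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def _read_tsv(path, expected_columns) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(expected_columns):
            raise ParseError(f"bad header {header} in {path}", line=1)
        rows = []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, found {len(parts)}", line=ln
                )
            rows.append(parts)
    return pd.DataFrame(rows, columns=header)
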