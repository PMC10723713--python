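"""Readers/writers for the standard file formats and SNP harmonization.

Formats touched: GWAS summary-statistics tables (delimited text with a
configurable column mapping), genotype dosage matrices as TSV, PLINK
bed/bim/fam triples (2-bit SNP-major binary; read and written natively),
phenotype/covariate tables keyed by FID/IID, fitted-model JSON, and
score/result TSVs.

Alignment between base and target follows conventional PRS hygiene: SNPs
are matched by id; when both sides carry alleles, swapped effect/other
alleles flip the effect sign, strand-ambiguous A/T and C/G SNPs are
dropped, and irreconcilable allele pairs are dropped with a log message.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SummaryStats, TargetData
from .exceptions import AlignmentError, InvalidInputError
from .joint_model import FittedPRS

logger = logging.getLogger(__name__)

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_plink",
    "write_plink",
    "read_phenotype",
    "read_scores",
    "save_model",
    "load_model",
    "align",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_DEFAULT_COLUMNS = {
    "snp_id": ("snp_id", "snp", "id", "rsid", "markername"),
    "p": ("p", "pval", "p_value", "pvalue"),
    "effect": ("effect", "beta", "z", "b"),
    "se": ("se", "stderr"),
    "effect_allele": ("effect_allele", "a1", "allele1", "ea"),
    "other_allele": ("other_allele", "a2", "allele2", "oa"),
    "n": ("n", "n0", "samplesize"),
}


def read_sumstats(path, column_map: dict | None = None, n0: float | None = None,
                  sep: str | None = None) -> SummaryStats:
    """Read a delimited GWAS summary-statistics table.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.
    column_map : dict, optional
        Maps canonical names ("snp_id", "p", "effect", "se",
        "effect_allele", "other_allele", "n") to the file's column names.
        Unmapped canonical names are resolved case-insensitively against
        common synonyms.
    n0 : float, optional
        Base sample size; taken from the "n" column (median) when absent.

    Rows with unparseable or out-of-range p-values are dropped and counted;
    duplicate SNP ids keep the row with the smallest p.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    lower = {c.lower(): c for c in df.columns}
    resolved = {}
    column_map = column_map or {}
    for canon, synonyms in _DEFAULT_COLUMNS.items():
        if canon in column_map:
            resolved[canon] = column_map[canon]
        else:
            for s in synonyms:
                if s in lower:
                    resolved[canon] = lower[s]
                    break
    for required in ("snp_id", "p"):
        if required not in resolved or resolved[required] not in df.columns:
            raise InvalidInputError(f"cannot resolve mandatory column {required!r}")
    out = pd.DataFrame({"snp_id": df[resolved["snp_id"]].astype(str)})
    out["p"] = pd.to_numeric(df[resolved["p"]], errors="coerce")
    for opt in ("effect", "se"):
        if opt in resolved:
            out[opt] = pd.to_numeric(df[resolved[opt]], errors="coerce")
    for opt in ("effect_allele", "other_allele"):
        if opt in resolved:
            out[opt] = df[resolved[opt]].astype(str).str.upper()
    bad = out["p"].isna() | (out["p"] < 0) | (out["p"] > 1)
    if bad.any():
        logger.info("dropping %d rows with invalid p-values", int(bad.sum()))
        out = out[~bad]
    ndup = int(out["snp_id"].duplicated().sum())
    if ndup:
        logger.info("deduplicating %d SNP ids (smallest p kept)", ndup)
        out = out.sort_values(["p", "snp_id"], kind="stable").drop_duplicates(
            "snp_id", keep="first"
        )
        out = out.sort_index()
    if len(out) == 0:
        raise InvalidInputError("no valid rows in summary-statistics file")
    if n0 is None:
        if "n" in resolved:
            n0 = float(pd.to_numeric(df[resolved["n"]], errors="coerce").median())
        else:
            raise InvalidInputError("n0 not given and no sample-size column found")
    return SummaryStats(
        out.reset_index(drop=True), n0,
        {"source": str(path), "columns": resolved},
    )


def write_sumstats(ss: SummaryStats, path) -> None:
    tab = ss.table.copy()
    tab["n"] = ss.n0
    tab.to_csv(path, sep="\t", index=False)


def read_genotypes(path, format: str = "tsv") -> TargetData:
    """Read a genotype dosage matrix.

    "tsv": samples x SNPs with header SNP ids; an optional leading column
    named sample_id/IID supplies row ids. Missing dosages are mean-imputed
    per SNP (missingness logged; >10% missing in a SNP warns; all-missing
    SNPs are dropped).

    "bed": PLINK bed/bim/fam triple — `path` is the prefix or the .bed file.
    """
    if format == "bed":
        return read_plink(path)
    if format != "tsv":
        raise InvalidInputError(f"unknown genotype format: {format!r}")
    df = pd.read_csv(path, sep="\t")
    sample_ids = None
    first = df.columns[0].lower()
    if first in ("sample_id", "iid", "id"):
        sample_ids = tuple(df.iloc[:, 0].astype(str))
        df = df.iloc[:, 1:]
    return _impute_and_pack(
        df.to_numpy(dtype=float), tuple(df.columns), sample_ids
    )


def _impute_and_pack(X, snp_ids, sample_ids, alleles=None) -> TargetData:
    keep = []
    for j, sid in enumerate(snp_ids):
        col = X[:, j]
        miss = ~np.isfinite(col)
        rate = miss.mean()
        if rate == 1.0:
            logger.info("dropping all-missing SNP %s", sid)
            continue
        if rate > 0.10:
            logger.warning("SNP %s has %.1f%% missing dosages", sid, 100 * rate)
        if miss.any():
            col[miss] = col[~miss].mean()
        keep.append(j)
    X = X[:, keep]
    ids = tuple(snp_ids[j] for j in keep)
    if alleles is not None:
        alleles = {s: alleles[s] for s in ids}
    return TargetData(X, None, ids, sample_ids=sample_ids or (), alleles=alleles)


def write_genotypes_tsv(data: TargetData, path) -> None:
    df = pd.DataFrame(data.X, columns=list(data.snp_ids))
    df.insert(0, "sample_id", list(data.sample_ids))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam (SNP-major 2-bit codes). Codes per byte, LSB first:
# 00 = homozygous A1 (dosage 2), 10 = heterozygous (1),
# 11 = homozygous A2 (0), 01 = missing.
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _plink_prefix(path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix == ".bed" else p


def read_plink(path) -> TargetData:
    """Read a PLINK bed/bim/fam triple into a TargetData (dosage of A1)."""
    prefix = _plink_prefix(path)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    biallelic = bim["a1"].str.len().eq(1) & bim["a2"].str.len().eq(1)
    if not biallelic.all():
        logger.info("skipping %d non-biallelic bim rows", int((~biallelic).sum()))
    n = len(fam)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise InvalidInputError("not a SNP-major PLINK bed file")
    bpv = (n + 3) // 4  # bytes per variant
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bpv * len(bim):
        raise InvalidInputError("bed size inconsistent with bim/fam")
    body = body.reshape(len(bim), bpv)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(len(bim), bpv * 4)[:, :n]
    X = _CODE_TO_DOSAGE[codes].T.copy()  # samples x SNPs
    keep = np.flatnonzero(biallelic.to_numpy())
    X = X[:, keep]
    ids = tuple(bim["snp_id"].iloc[keep])
    alleles = {
        r.snp_id: (r.a1, r.a2) for r in bim.iloc[keep].itertuples()
    }
    sample_ids = tuple(fam["iid"])
    return _impute_and_pack(X, ids, sample_ids, alleles)


def write_plink(data: TargetData, prefix, positions=None, chrom: str = "1") -> None:
    """Write dosages (rounded to {0,1,2}) as a bed/bim/fam triple."""
    prefix = _plink_prefix(prefix)
    n, m = data.X.shape
    alleles = data.alleles or {}
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, sid in enumerate(data.snp_ids):
            a1, a2 = alleles.get(sid, ("A", "G"))
            pos = positions[j] if positions is not None else (j + 1) * 1000
            fh.write(f"{chrom}\t{sid}\t0\t{pos}\t{a1}\t{a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, sid in enumerate(data.sample_ids):
            ph = data.y[i] if data.y is not None else -9
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{ph}\n")
    dosage_to_code = {2: 0b00, 1: 0b10, 0: 0b11}
    bpv = (n + 3) // 4
    out = bytearray(_BED_MAGIC)
    D = np.clip(np.rint(data.X), 0, 2).astype(int)
    for j in range(m):
        row = bytearray(bpv)
        for i in range(n):
            code = dosage_to_code[D[i, j]]
            row[i // 4] |= code << ((i % 4) * 2)
        out.extend(row)
    prefix.with_suffix(".bed").write_bytes(bytes(out))


def read_phenotype(path, pheno_col: str | None = None) -> pd.DataFrame:
    """Read a FID/IID-keyed phenotype (or covariate) table."""
    df = pd.read_csv(path, sep=r"\s+|\t", engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "iid" not in cols:
        raise InvalidInputError("phenotype file needs an IID column")
    df = df.rename(columns={cols["iid"]: "IID"})
    df["IID"] = df["IID"].astype(str)
    if pheno_col is not None and pheno_col not in df.columns:
        raise InvalidInputError(f"phenotype column {pheno_col!r} not found")
    return df


def attach_phenotype(data: TargetData, pheno: pd.DataFrame,
                     pheno_col: str, covar_cols=()) -> TargetData:
    """Join a phenotype table onto target samples by IID."""
    tab = pheno.set_index("IID")
    try:
        sub = tab.loc[list(data.sample_ids)]
    except KeyError as e:
        raise AlignmentError(f"sample missing from phenotype table: {e}") from e
    y = sub[pheno_col].to_numpy(float)
    cov = sub[list(covar_cols)].to_numpy(float) if covar_cols else None
    return TargetData(data.X, y, data.snp_ids, cov, data.sample_ids,
                      tuple(covar_cols), data.alleles)


def read_scores(path) -> pd.DataFrame:
    """Externally computed scores as TSV (sample id, score)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InvalidInputError("score file needs (id, score) columns")
    df.columns = ["sample_id", "score"] + list(df.columns[2:])
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def save_model(model: FittedPRS, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path) -> FittedPRS:
    d = json.loads(Path(path).read_text())
    return FittedPRS(
        snp_ids=tuple(s["snp_id"] for s in d["snps"]),
        beta=np.array([s["beta"] for s in d["snps"]], dtype=float),
        intercept=float(d["intercept"]),
        eps_level=d["eps_level"],
        penalty=float(d["penalty"]),
        selection_r2=float(d["selection_r2"]),
        q=int(d["q"]),
        family=d.get("family", "gaussian"),
        method=d.get("method", "fnc_lasso"),
        covariate_effects=(
            None if d.get("covariate_effects") is None
            else np.asarray(d["covariate_effects"], dtype=float)
        ),
        provenance=d.get("provenance", {}),
    )


def align(sumstats: SummaryStats, target: TargetData):
    """Intersect and harmonize base and target SNPs.

    Matching is by id. When both sides carry alleles: identical pairs pass;
    swapped effect/other alleles flip the effect sign; strand-ambiguous
    A/T and C/G SNPs and irreconcilable pairs are dropped (logged).
    Idempotent: aligning an aligned pair is a no-op.
    """
    base_ids = set(sumstats.snp_ids)
    common = [s for s in target.snp_ids if s in base_ids]
    if not common:
        raise AlignmentError("no overlapping SNP ids between base and target")
    tab = sumstats.table.set_index("snp_id").loc[common].reset_index()
    has_alleles = (
        "effect_allele" in tab.columns
        and "other_allele" in tab.columns
        and target.alleles is not None
    )
    if has_alleles:
        keep, flip = [], []
        for i, sid in enumerate(common):
            ea = str(tab.at[i, "effect_allele"]).upper()
            oa = str(tab.at[i, "other_allele"]).upper()
            if (ea, oa) in _AMBIGUOUS:
                logger.info("dropping strand-ambiguous SNP %s (%s/%s)", sid, ea, oa)
                continue
            ta1, ta2 = (str(a).upper() for a in target.alleles[sid])
            if (ea, oa) == (ta1, ta2):
                keep.append(i); flip.append(False)
            elif (ea, oa) == (ta2, ta1):
                keep.append(i); flip.append(True)
            else:
                logger.info("dropping allele-mismatched SNP %s", sid)
        if not keep:
            raise AlignmentError("no SNPs survive allele harmonization")
        tab = tab.iloc[keep].reset_index(drop=True)
        flip = np.asarray(flip)
        if "effect" in tab.columns and flip.any():
            tab.loc[flip, "effect"] = -tab.loc[flip, "effect"]
            swapped = tab.loc[flip, "effect_allele"].copy()
            tab.loc[flip, "effect_allele"] = tab.loc[flip, "other_allele"].to_numpy()
            tab.loc[flip, "other_allele"] = swapped.to_numpy()
        common = list(tab["snp_id"])
    aligned_ss = SummaryStats(tab, sumstats.n0, dict(sumstats.provenance))
    aligned_target = target.restrict(common)
    return aligned_ss, aligned_target
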