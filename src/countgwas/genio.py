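"""File formats and genotype quality control.

Reads and writes PLINK .bed/.bim/.fam triples (bed v1.0, SNP-major) and a
tab-separated dosage table, plus gene intervals as BED and phenotype panels
as TSV. QC applies the conventional marker filters for a GWAS panel:
minor-allele frequency, call rate, a 1-df chi-square Hardy-Weinberg test,
and imputation quality.

Dosage TSV dialect: one row per SNP, leading columns ``snp_id, chrom, bp,
ea, oa, impute_r2`` followed by one column per sample id; missing calls are
"NA"; fractional dosages are written with 4 decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import SNP_MAP_COLUMNS, GeneSet, GenotypeMatrix, PhenotypePanel

PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit codes, SNP-major: 00 = 2 copies of allele 1 (effect allele),
# 01 = missing, 10 = het, 11 = 0 copies
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}
DOSAGE_DECIMALS = 4


@dataclass
class QcThresholds:
    """Marker-level QC cut-offs; markers are removed when MAF < ``maf_min``,
    call rate < ``call_rate_min``, HWE p < ``hwe_p_min`` or imputation
    R^2 <= ``impute_r2_min`` (strictly-greater quality is required)."""

    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 5.0e-7
    impute_r2_min: float = 0.8

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "impute_r2_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bed/bim/fam triple; fractional dosages are rounded to hard
    calls (the bed format stores genotypes, not dosages)."""
    prefix = Path(prefix)
    n, m = G.dosages.shape
    hard = np.round(G.dosages)
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[(hard == dos).T] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for offset in range(4):
        sl = codes[:, offset::4]
        packed[:, : sl.shape[1]] |= sl << (2 * offset)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": G.snp_map["chrom"],
            "snp_id": G.snp_map["snp_id"],
            "cm": 0,
            "bp": G.snp_map["bp"],
            "a1": G.snp_map["ea"],
            "a2": G.snp_map["oa"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes {raw[:3]!r} (expected SNP-major bed v1.0)")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise ValueError(f"{prefix}.bed: {body.size} data bytes, expected {m * n_bytes}")
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n), dtype=np.uint8)
    for offset in range(4):
        chunk = (body >> (2 * offset)) & 0b11
        cols = codes[:, offset::4]
        cols[:] = chunk[:, : cols.shape[1]]
    dosages = _CODE_TO_DOSAGE[codes].T
    snp_map = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "bp": bim["bp"],
            "ea": bim["a1"],
            "oa": bim["a2"],
            "impute_r2": 1.0,
        }
    )
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map, sample_ids=list(fam[1].astype(str)))


# ---------------------------------------------------------------------------
# dosage TSV


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    dos = np.round(G.dosages.T, DOSAGE_DECIMALS)
    df = pd.concat(
        [
            G.snp_map[list(SNP_MAP_COLUMNS)].reset_index(drop=True),
            pd.DataFrame(dos, columns=G.sample_ids),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=f"%.{DOSAGE_DECIMALS}f")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})
    meta = [c for c in SNP_MAP_COLUMNS if c in df.columns]
    if meta != list(SNP_MAP_COLUMNS):
        raise ValueError(f"{path}: dosage TSV must start with columns {SNP_MAP_COLUMNS}")
    sample_ids = [c for c in df.columns if c not in SNP_MAP_COLUMNS]
    return GenotypeMatrix(
        dosages=df[sample_ids].to_numpy(dtype=float).T,
        snp_map=df[list(SNP_MAP_COLUMNS)],
        sample_ids=sample_ids,
    )


def read_genotypes(path: str | Path, format: str = "plink-bed") -> GenotypeMatrix:
    """Load genotypes from ``plink-bed`` (path = prefix) or ``dosage-tsv``."""
    if format == "plink-bed":
        return _read_plink(Path(path))
    if format == "dosage-tsv":
        return _read_dosage_tsv(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotype / gene-set IO


def write_phenotypes(panel: PhenotypePanel, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path, timepoints: list[float]) -> PhenotypePanel:
    table = pd.read_csv(path, sep="\t", na_values="NA")
    return PhenotypePanel(table=table, timepoints=list(timepoints))


def write_gene_bed(genes: GeneSet, path: str | Path) -> None:
    df = genes.intervals.copy()
    df["score"] = df.pop("is_candidate").astype(int)
    df[["chrom", "start", "end", "name", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_bed(path: str | Path) -> GeneSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score"],
        dtype={"chrom": str},
    )
    df["is_candidate"] = df.pop("score").fillna(1).astype(int).astype(bool)
    return GeneSet(df)


# ---------------------------------------------------------------------------
# QC


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg
    proportions; monomorphic markers return 1 by convention."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorised HWE p per SNP on hard calls (fractional dosages rounded)."""
    hard = np.round(dosages)
    n_AA = np.nansum(hard == 2, axis=0).astype(float)
    n_Aa = np.nansum(hard == 1, axis=0).astype(float)
    n_aa = np.nansum(hard == 0, axis=0).astype(float)
    n = n_AA + n_Aa + n_aa
    n = np.where(n == 0, 1.0, n)
    p = (2 * n_AA + n_Aa) / (2 * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_AA = n * p * p
        e_Aa = 2 * n * p * (1 - p)
        e_aa = n * (1 - p) ** 2
        stat = (
            (n_AA - e_AA) ** 2 / e_AA
            + (n_Aa - e_Aa) ** 2 / e_Aa
            + (n_aa - e_aa) ** 2 / e_aa
        )
    out = chi2.sf(np.where(np.isfinite(stat), stat, 0.0), df=1)
    out[(p == 0) | (p == 1)] = 1.0
    return out


def qc_filter(
    G: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the marker filters; returns the retained panel and a per-SNP
    report (reason = first failed criterion, precedence
    maf -> call_rate -> hwe -> impute_r2)."""
    thr = thresholds or QcThresholds()
    maf = G.maf()
    call_rate = G.call_rate()
    hwe_p = _hwe_pvalues(G.dosages)
    r2 = G.snp_map["impute_r2"].to_numpy(dtype=float)

    reason = np.array([""] * G.n_snps, dtype=object)
    fail_maf = np.nan_to_num(maf, nan=0.0) < thr.maf_min
    fail_cr = call_rate < thr.call_rate_min
    fail_hwe = hwe_p < thr.hwe_p_min
    fail_r2 = ~(r2 > thr.impute_r2_min)
    reason[fail_r2] = "impute_r2"
    reason[fail_hwe] = "hwe"
    reason[fail_cr] = "call_rate"
    reason[fail_maf] = "maf"
    keep = ~(fail_maf | fail_cr | fail_hwe | fail_r2)

    report = pd.DataFrame(
        {
            "snp_id": G.snp_map["snp_id"],
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "impute_r2": r2,
            "status": np.where(keep, "pass", "fail"),
            "reason": reason,
        }
    )
    if not keep.any():
        warnings.warn("QC removed every SNP", stacklevel=2)
    return G.take_snps(np.flatnonzero(keep)), report
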