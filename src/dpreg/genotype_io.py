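"""Genotype file formats, quality control and phenotype normalization.

Supported on-disk formats are PLINK binary (bed/bim/fam, SNP-major) and the
BIMBAM mean-genotype text format (one SNP per row: id, allele1, allele2,
then one dosage per sample, ``NA`` for missing).  Dosages follow the
allele1 convention: a value of 2 means two copies of the first allele
listed in the .bim/BIMBAM record.

The QC pipeline mirrors standard GWAS practice: SNPs are removed when the
Hardy-Weinberg equilibrium p-value falls below 1e-4, the genotype call
rate below 95%, or the minor allele frequency below 1%.  Remaining missing
genotypes are mean-imputed per SNP, and phenotypes can be quantile
normalized to a standard normal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    EmptyPanelError,
    FormatError,
    InvalidParameterError,
)

__all__ = [
    "SNPRecord",
    "GenotypeMatrix",
    "read_plink",
    "write_plink",
    "read_bimbam",
    "write_bimbam",
    "read_phenotype",
    "read_covariates",
    "hwe_test",
    "snp_statistics",
    "apply_qc",
    "mean_impute",
    "quantile_normalize",
    "QuantileNormalizer",
    "center_genotypes",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK bed header
# 2-bit bed codes -> allele1 dosage: 00 hom-allele1, 01 missing, 10 het, 11 hom-allele2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class SNPRecord:
    id: str
    chromosome: str = "0"
    position: int = 0
    allele1: str = "A"
    allele2: str = "G"
    maf: float = float("nan")
    call_rate: float = float("nan")
    hwe_p: float = float("nan")


@dataclass
class GenotypeMatrix:
    """n-by-p dosage matrix (NaN = missing) with per-SNP metadata."""

    dosages: np.ndarray
    snps: list
    sample_ids: list

    def __post_init__(self) -> None:
        self.dosages = np.atleast_2d(np.asarray(self.dosages, dtype=float))
        if self.dosages.shape[1] != len(self.snps):
            raise InvalidParameterError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.snps)} SNP records"
            )
        if self.dosages.shape[0] != len(self.sample_ids):
            raise InvalidParameterError(
                f"{self.dosages.shape[0]} dosage rows but {len(self.sample_ids)} sample ids"
            )

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def snp_ids(self) -> list:
        return [s.id for s in self.snps]


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam fileset into dosages of the .bim first allele."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    n, p = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix.with_suffix('.bed')}: bad magic bytes "
                          f"{raw[:3].hex()} (expected SNP-major PLINK bed)")
    bytes_per_snp = (n + 3) // 4
    if len(raw) != 3 + bytes_per_snp * p:
        raise FormatError(
            f"{prefix.with_suffix('.bed')}: size {len(raw)} inconsistent with "
            f"{n} samples x {p} SNPs"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(p, bytes_per_snp * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()
    snps = [
        SNPRecord(id=r.id, chromosome=str(r.chrom), position=int(r.pos),
                  allele1=str(r.a1), allele2=str(r.a2))
        for r in bim.itertuples()
    ]
    sample_ids = [f"{f}_{i}" for f, i in zip(fam.fid, fam.iid)]
    return GenotypeMatrix(dosages=dosages, snps=snps, sample_ids=sample_ids)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam; dosages must be hard calls in {0, 1, 2, NaN}."""
    prefix = Path(prefix)
    hard = gm.dosages
    valid = np.isnan(hard) | np.isin(hard, (0.0, 1.0, 2.0))
    if not np.all(valid):
        raise FormatError("PLINK bed requires hard-call dosages in {0,1,2} or missing")
    n, p = gm.n, gm.p
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\t{s.allele1}\t{s.allele2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in gm.sample_ids:
            fid, _, iid = sid.partition("_")
            fh.write(f"{fid or sid}\t{iid or sid}\t0\t0\t0\t-9\n")
    code_of = {2.0: 0, 1.0: 2, 0.0: 3}
    bytes_per_snp = (n + 3) // 4
    body = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for j in range(p):
        for i in range(n):
            d = hard[i, j]
            code = 1 if np.isnan(d) else code_of[d]
            body[j, i // 4] |= code << ((i % 4) * 2)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(body.tobytes())


# ---------------------------------------------------------------------------
# BIMBAM mean-genotype text
# ---------------------------------------------------------------------------

def read_bimbam(path: str | Path, sample_ids: list | None = None) -> GenotypeMatrix:
    """Read a BIMBAM mean-genotype file (one SNP per row, 'NA' missing)."""
    path = Path(path)
    snps, cols = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.replace(",", " ").split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: need id, 2 alleles and >=1 dosage")
            snp_id, a1, a2 = parts[0], parts[1], parts[2]
            try:
                dos = np.array([np.nan if v.upper() == "NA" else float(v)
                                for v in parts[3:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric dosage") from exc
            snps.append(SNPRecord(id=snp_id, allele1=a1, allele2=a2))
            cols.append(dos)
    if not snps:
        raise FormatError(f"{path}: empty genotype file")
    lengths = {c.shape[0] for c in cols}
    if len(lengths) != 1:
        raise FormatError(f"{path}: rows have inconsistent sample counts {sorted(lengths)}")
    dosages = np.column_stack(cols)
    n = dosages.shape[0]
    if sample_ids is None:
        sample_ids = [f"sample_{i + 1}" for i in range(n)]
    elif len(sample_ids) != n:
        raise FormatError(f"{path}: {n} dosages per row but {len(sample_ids)} sample ids")
    return GenotypeMatrix(dosages=dosages, snps=snps, sample_ids=list(sample_ids))


def write_bimbam(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for j, s in enumerate(gm.snps):
            vals = " ".join(
                "NA" if np.isnan(d) else format(d, "g") for d in gm.dosages[:, j]
            )
            fh.write(f"{s.id} {s.allele1} {s.allele2} {vals}\n")


def read_phenotype(path: str | Path, column: int = 0) -> np.ndarray:
    """Read one trait column from a whitespace-delimited phenotype file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, na_values=["NA"])
    if column >= df.shape[1]:
        raise FormatError(f"{path}: no phenotype column {column} "
                          f"(file has {df.shape[1]})")
    return df.iloc[:, column].to_numpy(dtype=float)


def read_covariates(path: str | Path) -> np.ndarray:
    """Read an n-by-c covariate matrix (should include an intercept column)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, na_values=["NA"])
    return df.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_test(genotype_counts) -> float:
    """1-df chi-square Hardy-Weinberg goodness-of-fit p-value.

    ``genotype_counts`` is (n_AA, n_Aa, n_aa) for the allele1 homozygote,
    heterozygote and allele2 homozygote.  Monomorphic SNPs return 1 by
    convention.
    """
    n_aa_1, n_het, n_aa_2 = (float(c) for c in genotype_counts)
    if min(n_aa_1, n_het, n_aa_2) < 0:
        raise InvalidParameterError("genotype counts must be non-negative")
    total = n_aa_1 + n_het + n_aa_2
    if total < 1:
        raise InvalidParameterError("need at least one genotyped sample")
    freq = (2 * n_aa_1 + n_het) / (2 * total)
    if freq in (0.0, 1.0):
        return 1.0
    expected = total * np.array([freq**2, 2 * freq * (1 - freq), (1 - freq) ** 2])
    observed = np.array([n_aa_1, n_het, n_aa_2])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def snp_statistics(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Return a copy with per-SNP MAF, call rate and HWE p-value filled in.

    HWE uses hard-call counts (dosages rounded to the nearest integer), so
    it is only meaningful for called genotypes, not for imputed means.
    """
    d = gm.dosages
    observed = ~np.isnan(d)
    call_rate = observed.mean(axis=0)
    snps = []
    for j, s in enumerate(gm.snps):
        col = d[observed[:, j], j]
        if col.size == 0:
            snps.append(replace(s, maf=np.nan, call_rate=0.0, hwe_p=np.nan))
            continue
        freq = float(col.mean()) / 2.0
        maf = min(freq, 1.0 - freq)
        hard = np.clip(np.rint(col), 0, 2)
        counts = (int(np.sum(hard == 2)), int(np.sum(hard == 1)), int(np.sum(hard == 0)))
        snps.append(replace(s, maf=maf, call_rate=float(call_rate[j]),
                            hwe_p=hwe_test(counts)))
    return GenotypeMatrix(dosages=d.copy(), snps=snps, sample_ids=list(gm.sample_ids))


def apply_qc(
    gm: GenotypeMatrix,
    hwe_thresh: float = 1e-4,
    call_thresh: float = 0.95,
    maf_thresh: float = 0.01,
):
    """Drop SNPs failing HWE, call-rate or MAF filters.

    Returns (filtered GenotypeMatrix, report DataFrame).  The report lists
    every removed SNP with the first rule it failed, checked in the order
    HWE, call rate, MAF.
    """
    gm = snp_statistics(gm)
    keep, rows = [], []
    for j, s in enumerate(gm.snps):
        if np.isnan(s.hwe_p) or s.hwe_p < hwe_thresh:
            rows.append((s.id, "hwe", s.hwe_p))
        elif s.call_rate < call_thresh:
            rows.append((s.id, "call_rate", s.call_rate))
        elif np.isnan(s.maf) or s.maf < maf_thresh:
            rows.append((s.id, "maf", s.maf))
        else:
            keep.append(j)
    report = pd.DataFrame(rows, columns=["snp_id", "failed_rule", "value"])
    if not keep:
        raise EmptyPanelError("quality control removed every SNP")
    filtered = GenotypeMatrix(
        dosages=gm.dosages[:, keep],
        snps=[gm.snps[j] for j in keep],
        sample_ids=list(gm.sample_ids),
    )
    return filtered, report


def mean_impute(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by its SNP's observed mean."""
    d = gm.dosages.copy()
    for j in range(gm.p):
        col = d[:, j]
        missing = np.isnan(col)
        if missing.all():
            raise DegenerateDataError(
                f"SNP {gm.snps[j].id} has no observed genotypes (should fail call-rate QC)"
            )
        if missing.any():
            col[missing] = col[~missing].mean()
    return GenotypeMatrix(dosages=d, snps=list(gm.snps), sample_ids=list(gm.sample_ids))


# ---------------------------------------------------------------------------
# Phenotype normalization and genotype centering
# ---------------------------------------------------------------------------

def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Map values by rank to standard-normal quantiles.

    The value with (1-based, tie-averaged) rank r among n maps to
    ``Phi^-1((r - 0.5) / n)``; output order matches input order.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise InvalidParameterError("need at least 2 values to quantile normalize")
    if np.unique(values).size < 2:
        raise DegenerateDataError("all values identical: ranks are degenerate")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


@dataclass
class QuantileNormalizer:
    """Train/test-safe quantile normalization to a standard normal.

    ``fit`` stores the sorted training values against their normal scores;
    ``transform`` maps new values by monotone interpolation, so test-fold
    values never influence the learned mapping.
    """

    sorted_values_: np.ndarray | None = None
    scores_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "QuantileNormalizer":
        values = np.asarray(values, dtype=float).ravel()
        normalized = quantile_normalize(values)
        order = np.argsort(values, kind="stable")
        self.sorted_values_ = values[order]
        self.scores_ = normalized[order]
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.sorted_values_ is None:
            raise InvalidParameterError("QuantileNormalizer used before fit")
        values = np.asarray(values, dtype=float).ravel()
        return np.interp(values, self.sorted_values_, self.scores_)

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)


def center_genotypes(X, means: np.ndarray | None = None):
    """Subtract per-SNP means (training means when supplied).

    Accepts a GenotypeMatrix or a plain array without missing values;
    returns (centered array, means used).
    """
    if isinstance(X, GenotypeMatrix):
        X = X.dosages
    X = np.asarray(X, dtype=float)
    if np.any(np.isnan(X)):
        raise InvalidParameterError("impute missing genotypes before centering")
    if means is None:
        means = X.mean(axis=0)
    else:
        means = np.asarray(means, dtype=float)
        if means.shape != (X.shape[1],):
            raise InvalidParameterError(
                f"means has length {means.shape[0]} but X has {X.shape[1]} columns"
            )
    return X - means[None, :], means
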