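"""Genotype and phenotype input/output plus phenotype quality control.

Genotypes are biallelic SNP codes 0/1/2 (count of the reference allele).
The pipeline assumes imputed input: a missing genotype is a hard error.
Supported on-disk dialects are PLINK ``.raw`` additive coding, VCF 4.x
(biallelic sites, GT field) and a plain TSV (``sample_id`` plus one column
per SNP).  Chromosome assignments travel either inside the file (VCF) or
as a two-column TSV map (snp_id, chrom).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_chromosome_map",
    "write_chromosome_map",
    "read_phenotypes",
    "write_phenotypes",
    "filter_phenotype_outliers",
]


@dataclass
class GenotypeMatrix:
    """An n-individual by m-SNP matrix of allele counts with a chromosome map.

    Attributes
    ----------
    codes
        ``(n, m)`` integer matrix with entries in {0, 1, 2}, the count of the
        reference allele per individual and SNP.
    sample_ids, snp_ids
        Row and column labels, in file order.
    chromosome
        ``(m,)`` integer chromosome label per SNP.
    """

    codes: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chromosome: np.ndarray
    _freq: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        self.sample_ids = np.asarray(self.sample_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chromosome = np.asarray(self.chromosome)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (individuals x SNPs) matrix")
        bad = ~np.isin(self.codes, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype code {self.codes[i, j]!r} for sample "
                f"{self.sample_ids[i]!r} at SNP {self.snp_ids[j]!r} is not in "
                "{0,1,2}; this pipeline requires imputed, biallelic input"
            )
        n, m = self.codes.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("label lengths do not match the codes matrix")
        if len(self.chromosome) != m:
            raise ValueError("chromosome map length does not match SNP count")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per SNP, recomputed from the sample."""
        if self._freq is None:
            self._freq = self.codes.mean(axis=0) / 2.0
        return self._freq

    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome labels, in order of first appearance."""
        _, idx = np.unique(self.chromosome, return_index=True)
        return self.chromosome[np.sort(idx)]


@dataclass
class PhenotypeTable:
    """Pre-adjusted phenotypic residuals with an availability mask.

    ``y`` holds one record per individual (fixed non-genetic effects already
    removed upstream); ``mask`` is True where a phenotype is available.
    """

    sample_ids: np.ndarray
    y: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.y = np.asarray(self.y, dtype=float)
        if self.mask is None:
            self.mask = np.ones(len(self.y), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.sample_ids) == len(self.y) == len(self.mask)):
            raise ValueError("sample_ids, y and mask must have equal length")
        if not np.all(np.isfinite(self.y[self.mask])):
            raise ValueError("non-finite phenotype where mask is True")

    @property
    def n(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _as_chrom(values: Sequence, m: int) -> np.ndarray:
    if values is None:
        return np.ones(m, dtype=int)
    arr = np.asarray(values)
    return arr.astype(int) if arr.dtype.kind in "iuf" else arr


def read_chromosome_map(path: str | Path) -> pd.Series:
    """Read a two-column TSV (snp_id, chrom) into a snp_id-indexed Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "chrom"], dtype=str)
    return pd.Series(pd.to_numeric(df["chrom"]).astype(int).values, index=df["snp_id"].values)


def write_chromosome_map(gm: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame({"snp_id": gm.snp_ids, "chrom": gm.chromosome}).to_csv(
        path, sep="\t", header=False, index=False
    )


def _read_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    sample_ids = df.iloc[:, 0].to_numpy()
    snp_ids = df.columns[1:].to_numpy()
    codes = df.iloc[:, 1:].to_numpy()
    if codes.dtype.kind not in "iu":
        if not np.all(np.isfinite(codes.astype(float))):
            j = np.argwhere(~np.isfinite(codes.astype(float)))[0]
            raise ValueError(
                f"missing genotype for sample {sample_ids[j[0]]!r} at SNP "
                f"{snp_ids[j[1]]!r}"
            )
        codes = codes.astype(int)
    return codes, sample_ids, snp_ids


def _read_plink_raw(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # PLINK --recode A output: FID IID PAT MAT SEX PHENOTYPE then one column
    # per SNP named like "rs123_A"; NA marks a missing genotype.
    df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"not a PLINK .raw file: missing columns {missing}")
    sample_ids = df["IID"].to_numpy()
    snp_cols = [c for c in df.columns if c not in meta]
    snp_ids = np.array([c.rsplit("_", 1)[0] for c in snp_cols])
    codes = df[snp_cols].to_numpy()
    if np.issubdtype(codes.dtype, np.floating) and np.isnan(codes).any():
        i, j = np.argwhere(np.isnan(codes))[0]
        raise ValueError(
            f"missing genotype (NA) for sample {sample_ids[i]!r} at SNP "
            f"{snp_ids[j]!r}; impute before loading"
        )
    return codes.astype(int), sample_ids, snp_ids


def _read_vcf(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.asarray(vcf.samples)
    rows, snp_ids, chroms = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"non-biallelic record {rec.CHROM}:{rec.POS} ({rec.ID or '.'}) "
                f"with ALT={rec.ALT}; only biallelic SNPs are supported"
            )
        gt = rec.gt_types  # 0=hom-ref, 1=het, 2=hom-alt(3 in cyvcf2), 2=unknown
        if np.any(gt == 2):
            i = int(np.argwhere(gt == 2)[0][0])
            raise ValueError(
                f"missing genotype for sample {sample_ids[i]!r} at "
                f"{rec.CHROM}:{rec.POS}; impute before loading"
            )
        # count REF alleles: hom-ref -> 2, het -> 1, hom-alt -> 0
        codes = np.select([gt == 0, gt == 1, gt == 3], [2, 1, 0])
        rows.append(codes)
        snp_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
    codes = np.column_stack(rows) if rows else np.empty((len(sample_ids), 0), int)
    chrom_arr = np.array([int(c.lstrip("chr")) if c.lstrip("chr").isdigit() else c for c in chroms])
    return codes, sample_ids, np.asarray(snp_ids), chrom_arr


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    chromosome_map: str | Path | pd.Series | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix in one of the supported dialects.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``"tsv"``, ``"plink-raw"``, ``"vcf"``.
    chromosome_map
        Optional two-column TSV path (snp_id, chrom) or snp_id-indexed
        Series; required for per-chromosome epistasis partitioning when the
        format itself carries no chromosome (TSV, .raw).  Defaults to a
        single chromosome.

    Row/column order is the file order, so a write/read round trip is exact.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        codes, sample_ids, snp_ids = _read_tsv(path)
        chrom = None
    elif format == "plink-raw":
        codes, sample_ids, snp_ids = _read_plink_raw(path)
        chrom = None
    elif format == "vcf":
        codes, sample_ids, snp_ids, chrom = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    if chromosome_map is not None:
        cmap = (
            chromosome_map
            if isinstance(chromosome_map, pd.Series)
            else read_chromosome_map(chromosome_map)
        )
        missing = [s for s in snp_ids if s not in cmap.index]
        if missing:
            raise ValueError(f"chromosome map is missing SNPs: {missing[:5]}")
        chrom = cmap.loc[snp_ids].to_numpy()
    return GenotypeMatrix(codes, sample_ids, snp_ids, _as_chrom(chrom, codes.shape[1]))


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write genotypes as TSV or minimal VCF (chromosome map travels in VCF)."""
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(gm.codes, columns=gm.snp_ids)
        df.insert(0, "sample_id", gm.sample_ids)
        df.to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in gm.chromosomes():
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, gm.sample_ids))
                + "\n"
            )
            gt_of = {2: "0/0", 1: "0/1", 0: "1/1"}
            for j in range(gm.n_snps):
                gts = "\t".join(gt_of[int(g)] for g in gm.codes[:, j])
                fh.write(
                    f"{gm.chromosome[j]}\t{j + 1}\t{gm.snp_ids[j]}\tA\tC\t.\t.\t.\tGT\t{gts}\n"
                )
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a TSV with columns sample_id, y (blank/NA y means unavailable)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    y = pd.to_numeric(df["y"], errors="coerce").to_numpy()
    mask = np.isfinite(y)
    y = np.where(mask, y, 0.0)
    return PhenotypeTable(df["sample_id"].to_numpy(), y, mask)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "sample_id": pheno.sample_ids,
            "y": [v if m else "" for v, m in zip(pheno.y, pheno.mask)],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotype QC
# ---------------------------------------------------------------------------

def filter_phenotype_outliers(
    pheno: PhenotypeTable, k_sd: float = 4.0
) -> tuple[PhenotypeTable, list]:
    """Mask phenotypes farther than ``k_sd`` standard deviations from the mean.

    The mean and SD are computed once on the unfiltered masked values
    (single pass, not iterated).  Returns the filtered table and the list of
    removed sample ids.  With a constant phenotype vector (SD = 0) nothing is
    removed and a warning is logged.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    if pheno.mask.sum() < 2:
        raise ValueError("need at least two available phenotypes")
    vals = pheno.y[pheno.mask]
    mu, sd = vals.mean(), vals.std()
    if sd == 0:
        warnings.warn("phenotype SD is zero; no outliers removed", stacklevel=2)
        return PhenotypeTable(pheno.sample_ids, pheno.y, pheno.mask.copy()), []
    out = pheno.mask & (np.abs(pheno.y - mu) > k_sd * sd)
    removed = list(pheno.sample_ids[out])
    if removed:
        logger.info("removed %d phenotypes beyond %.3g SD", len(removed), k_sd)
    return PhenotypeTable(pheno.sample_ids, pheno.y, pheno.mask & ~out), removed
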