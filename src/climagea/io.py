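"""Genotype container and file IO (VCF v4.2, sample metadata, tabular files).

The in-memory genotype representation is a dense matrix of alternate-allele
dosages: rows are individuals, columns are biallelic SNPs, entries are
0/1/2 for diploid calls, 0/1 for hemizygous calls (females on the Z
chromosome), and -1 for missing.  Sample metadata (population, sex) and SNP
metadata (chromosome, position, alleles) travel with the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SAMPLE_COLUMNS = ["id", "population", "sex"]
SNP_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele dosage matrix with metadata.

    Parameters
    ----------
    samples : DataFrame with columns ``id``, ``population``, ``sex`` ('M'/'F').
    snps : DataFrame with columns ``id``, ``chrom``, ``pos``, ``ref``, ``alt``.
    G : int8 array of shape ``(n_samples, n_snps)``; -1 encodes missing.
    z_chrom : name of the Z-flagged chromosome, or None.
    z_females_masked : True once female Z calls have been set missing by QC
        (changes the call-rate denominator for Z SNPs to males only).
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    G: np.ndarray
    z_chrom: str | None = None
    z_females_masked: bool = False

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        for col in SNP_COLUMNS:
            if col not in self.snps.columns:
                raise ValueError(f"SNP metadata lacks column {col!r}")
        if self.G.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.G.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate individual ids")
        if self.snps["id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("SNP positions must be positive integers")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def is_z(self) -> np.ndarray:
        """Boolean mask over SNPs on the Z-flagged chromosome."""
        if self.z_chrom is None:
            return np.zeros(self.n_snps, dtype=bool)
        return (self.snps["chrom"] == self.z_chrom).to_numpy()

    def ploidy(self) -> np.ndarray:
        """Per-call ploidy (n_samples, n_snps): 1 for female Z calls else 2."""
        p = np.full(self.G.shape, 2, dtype=np.int8)
        z = self.is_z()
        if z.any():
            female = (self.samples["sex"] != "M").to_numpy()
            p[np.ix_(female, z)] = 1
        return p

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            samples=self.samples.iloc[index],
            G=self.G[index, :],
        )

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            snps=self.snps.iloc[index],
            G=self.G[:, index],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(self, samples=self.samples.copy(), snps=self.snps.copy(), G=self.G.copy())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write genotypes as uncompressed VCF v4.2 (GT only).

    Female Z calls are written hemizygously (single allele); missing calls as
    ``./.`` (diploid) or ``.`` (hemizygous).
    """
    samples = gm.samples["id"].tolist()
    z = gm.is_z()
    female = (gm.samples["sex"] != "M").to_numpy()
    dip_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    hap_codes = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=climagea\n")
        for chrom in pd.unique(gm.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        snps = gm.snps
        for i in range(gm.n_snps):
            row = snps.iloc[i]
            calls = []
            for k in range(gm.n_samples):
                g = int(gm.G[k, i])
                if z[i] and female[k]:
                    calls.append(hap_codes[g])
                else:
                    calls.append(dip_codes[g])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                "\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(vcf_path: str, meta_path: str, z_chrom: str | None = None) -> GenotypeMatrix:
    """Read an uncompressed VCF plus a sample-metadata TSV into a GenotypeMatrix.

    Hemizygous records (single-allele GT) are decoded as 0/1 dosages; any call
    containing a missing allele is decoded as missing.
    """
    import pysam

    meta = read_sample_metadata(meta_path)
    with pysam.VariantFile(vcf_path) as vf:
        sample_ids = list(vf.header.samples)
        records = list(vf.fetch()) if vf.index is not None else list(vf)
    meta = meta.set_index("id").loc[sample_ids].reset_index()

    snp_rows = []
    cols = []
    for rec in records:
        if len(rec.alts or ()) != 1:
            raise ValueError(f"non-biallelic record at {rec.chrom}:{rec.pos}")
        snp_rows.append(
            {"id": rec.id, "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0]}
        )
        col = np.empty(len(sample_ids), dtype=np.int8)
        for k, sid in enumerate(sample_ids):
            gt = rec.samples[sid]["GT"]
            if gt is None or any(a is None for a in gt):
                col[k] = MISSING
            else:
                col[k] = sum(gt)
        cols.append(col)
    G = np.stack(cols, axis=1) if cols else np.empty((len(sample_ids), 0), dtype=np.int8)
    snps = pd.DataFrame(snp_rows, columns=SNP_COLUMNS)
    return GenotypeMatrix(samples=meta, snps=snps, G=G, z_chrom=z_chrom)


# ---------------------------------------------------------------------------
# Tabular files
# ---------------------------------------------------------------------------

def write_sample_metadata(samples: pd.DataFrame, path: str) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"id": str, "population": str, "sex": str})
    return meta


def write_climate_table(climate: pd.DataFrame, path: str) -> None:
    climate.to_csv(path, sep="\t", index=True, index_label="site")


def read_climate_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="site")
    if df.index.duplicated().any():
        raise ValueError("duplicate site ids in climate table")
    if df.isna().any().any():
        raise ValueError("climate table contains missing cells")
    return df
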