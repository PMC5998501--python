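"""Core data containers: genotype panels and phenotype tables.

A :class:`GenotypePanel` holds biallelic SNP genotypes for a germplasm panel
as 0/1/2 counts of a designated allele (the "Q" allele), with ``-1`` marking
missing calls, alongside per-SNP metadata (chromosome, 1-based position,
optional sequencing depth and allele letters).  SNP identifiers follow the
``<chrom>_<position>`` convention (e.g. ``A3_115443958``).

Phenotypes travel as a long-format :class:`pandas.DataFrame` with columns
``accession, env, rep, trait, value`` — one row per replicate observation of
one trait in one environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

PHENO_COLUMNS = ["accession", "env", "rep", "trait", "value"]


@dataclass
class GenotypePanel:
    """Accessions x SNPs genotype matrix with SNP metadata.

    Parameters
    ----------
    codes
        ``int8`` array of shape ``(n_accessions, n_snps)`` holding counts of
        the designated Q allele (0, 1, 2) or ``MISSING`` (-1).
    accession_ids
        One identifier per row of ``codes``.
    snps
        DataFrame with at least columns ``id``, ``chrom``, ``pos`` (1-based,
        sorted within each chromosome).  Optional columns: ``depth`` (total
        sequencing depth per SNP), ``major``/``minor`` (allele letters).
    subpop_labels
        Optional integer subpopulation assignment per accession.
    """

    codes: np.ndarray
    accession_ids: list[str]
    snps: pd.DataFrame
    subpop_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D accessions x SNPs array")
        if self.codes.shape[0] != len(self.accession_ids):
            raise ValueError("codes rows do not match accession_ids")
        if self.codes.shape[1] != len(self.snps):
            raise ValueError("codes columns do not match snps table")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        for col in ("id", "chrom", "pos"):
            if col not in self.snps.columns:
                raise ValueError(f"snps table missing column {col!r}")
        self.snps = self.snps.reset_index(drop=True)
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be sorted within chromosome")
        if self.subpop_labels is not None:
            self.subpop_labels = np.asarray(self.subpop_labels)
            if self.subpop_labels.shape[0] != self.codes.shape[0]:
                raise ValueError("subpop_labels length mismatch")

    # -- basic shape ----------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["id"].tolist()

    # -- per-SNP summaries ---------------------------------------------
    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.codes != MISSING).mean(axis=0)

    def het_rate(self) -> np.ndarray:
        """Heterozygote fraction among non-missing calls per SNP."""
        called = self.codes != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, (self.codes == 1).sum(axis=0) / n_called, np.nan)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (Q) allele among non-missing calls."""
        called = self.codes != MISSING
        n_called = called.sum(axis=0)
        counts = np.where(called, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, counts / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------
    def take_snps(self, index) -> "GenotypePanel":
        """Return a new panel restricted to the given SNP indices/mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            codes=self.codes[:, index].copy(),
            accession_ids=list(self.accession_ids),
            snps=self.snps.iloc[index].reset_index(drop=True),
            subpop_labels=None if self.subpop_labels is None else self.subpop_labels.copy(),
        )

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snps["id"].to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(hits[0])

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the TSV matrix dialect: one row per SNP.

        Columns: ``chrom, pos, id`` then one 0/1/2/NA column per accession.
        """
        cols = {c: self.snps[c] for c in ("chrom", "pos", "id")}
        if "depth" in self.snps.columns:
            cols["depth"] = self.snps["depth"]
        geno = self.codes.T
        for j, acc in enumerate(self.accession_ids):
            cols[acc] = ["NA" if v == MISSING else int(v) for v in geno[:, j]]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta = df[["id", "chrom", "pos"]].copy()
        acc_cols = [c for c in df.columns if c not in ("chrom", "pos", "id", "depth")]
        codes = df[acc_cols].to_numpy(dtype=object)
        out = np.full(codes.shape, MISSING, dtype=np.int8)
        for j in range(codes.shape[1]):
            col = codes[:, j]
            ok = pd.notna(col) & (col != "NA")
            out[ok, j] = col[ok].astype(int)
        if "depth" in df.columns:
            meta["depth"] = df["depth"].to_numpy()
        return cls(codes=out.T, accession_ids=acc_cols, snps=meta)

    def to_vcf(self, path) -> None:
        """Write a minimal biallelic VCF (GT field only)."""
        snps = self.snps
        major = snps["major"] if "major" in snps.columns else pd.Series(["A"] * len(snps))
        minor = snps["minor"] if "minor" in snps.columns else pd.Series(["G"] * len(snps))
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in snps["chrom"].unique():
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.accession_ids) + "\n")
            for i in range(self.n_snps):
                # REF = counted (Q) allele so ALT dosage is 2 - code
                row = [
                    str(snps["chrom"].iloc[i]),
                    str(int(snps["pos"].iloc[i])),
                    str(snps["id"].iloc[i]),
                    str(major.iloc[i]),
                    str(minor.iloc[i]),
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                # GT written as count of ALT (minor) allele
                row += [gt_map[2 - c if c != MISSING else MISSING] for c in self.codes[:, i]]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        """Read a biallelic VCF; codes count the REF allele (Q = REF)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        accession_ids = list(vcf.samples)
        rows, recs = [], []
        for var in vcf:
            gt = np.asarray(var.gt_types)  # 0=hom ref,1=het,2=unknown,3=hom alt
            code = np.full(gt.shape, MISSING, dtype=np.int8)
            code[gt == 0] = 2
            code[gt == 1] = 1
            code[gt == 3] = 0
            rows.append(code)
            recs.append(
                {
                    "id": var.ID or f"{var.CHROM}_{var.POS}",
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "major": var.REF,
                    "minor": var.ALT[0] if var.ALT else ".",
                }
            )
        return cls(
            codes=np.array(rows, dtype=np.int8).T,
            accession_ids=accession_ids,
            snps=pd.DataFrame(recs),
        )


def make_snp_ids(chrom: np.ndarray, pos: np.ndarray) -> list[str]:
    """``<chrom>_<position>`` identifiers."""
    return [f"{c}_{int(p)}" for c, p in zip(chrom, pos)]


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table and return it.

    Requires columns ``accession, env, rep, trait, value``; environments
    numbered consecutively from 1; no duplicated
    (accession, env, rep, trait) rows.
    """
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if df.duplicated(subset=["accession", "env", "rep", "trait"]).any():
        raise ValueError("duplicate (accession, env, rep, trait) rows")
    envs = np.sort(df["env"].unique())
    if not np.array_equal(envs, np.arange(1, len(envs) + 1)):
        raise ValueError("environments must be numbered 1..E consecutively")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep="\t"))


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df)
    df.to_csv(path, sep="\t", index=False)
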