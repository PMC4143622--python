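"""Genotype container and PLINK text PED/MAP readers/writers.

Genotypes are held as an individuals-by-SNPs dosage matrix counting the
coded allele (0/1/2, NaN for missing) alongside the SNP map and pedigree
links. The coded allele for each SNP is the first non-missing allele
encountered in the PED file unless a reference-allele mapping is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeData", "read_ped_map", "write_ped_map"]

PED_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENO"]


@dataclass
class GenotypeData:
    """Dosage matrix with SNP map and pedigree structure.

    ``dosage`` has shape (n individuals, m SNPs) with entries in {0, 1, 2}
    or NaN for missing. ``pedigree`` is a DataFrame with columns FID, IID,
    PAT, MAT, SEX ("0" parent = founder). ``alleles`` is (m, 2): coded
    allele first, other allele second.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray
    dosage: np.ndarray
    pedigree: pd.DataFrame
    pheno: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.pos = np.asarray(self.pos, dtype=int)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length must match dosage columns")
        if len(self.pedigree) != n:
            raise ValueError("pedigree rows must match dosage rows")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self._check_parents()

    def _check_parents(self) -> None:
        for fid, fam in self.pedigree.groupby("FID"):
            members = set(fam["IID"])
            for _, row in fam.iterrows():
                for parent in (row["PAT"], row["MAT"]):
                    if parent != "0" and parent not in members:
                        raise ValueError(
                            f"parent {parent} of {row['IID']} not in family {fid}"
                        )

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def individual_ids(self) -> np.ndarray:
        return self.pedigree["IID"].to_numpy(dtype=object)

    @property
    def family_ids(self) -> np.ndarray:
        return self.pedigree["FID"].to_numpy(dtype=object)

    def row_index(self) -> dict:
        """(FID, IID) -> row number."""
        return {
            (f, i): r
            for r, (f, i) in enumerate(
                zip(self.pedigree["FID"], self.pedigree["IID"])
            )
        }


def read_ped_map(ped_path, map_path) -> GenotypeData:
    """Parse whitespace-delimited PLINK text PED + MAP files.

    PED rows are FID IID PAT MAT SEX PHENO then two allele columns per SNP;
    allele "0" means missing (either allele missing makes the genotype
    missing). The coded allele of each SNP is the first non-"0" allele
    seen scanning individuals in file order.
    """
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["CHR", "SNP", "CM", "BP"],
        dtype={"CHR": str, "SNP": str},
    )
    m = len(mp)
    rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {ln} has {len(parts)} fields, "
                    f"expected {6 + 2 * m} for {m} SNPs"
                )
            rows.append(parts)
    if not rows:
        raise ValueError(f"{ped_path}: no individuals")
    lead = pd.DataFrame([r[:6] for r in rows], columns=PED_LEAD)
    allele_block = np.array([r[6:] for r in rows], dtype=object).reshape(len(rows), m, 2)

    alleles = np.empty((m, 2), dtype=object)
    dosage = np.full((len(rows), m), np.nan)
    for s in range(m):
        a = allele_block[:, s, :]
        nonmiss = a[(a != "0")]
        uniq = list(dict.fromkeys(nonmiss))  # preserves first-seen order
        if len(uniq) > 2:
            raise ValueError(f"SNP {mp['SNP'][s]}: more than two alleles {uniq}")
        coded = uniq[0] if uniq else "A"
        other = uniq[1] if len(uniq) > 1 else ("B" if not uniq else uniq[0])
        alleles[s] = (coded, other)
        miss = (a[:, 0] == "0") | (a[:, 1] == "0")
        dosage[:, s] = (a[:, 0] == coded).astype(float) + (a[:, 1] == coded)
        dosage[miss, s] = np.nan

    pedigree = lead[["FID", "IID", "PAT", "MAT", "SEX"]].copy()
    pheno = pd.to_numeric(lead["PHENO"], errors="coerce").to_numpy()
    return GenotypeData(
        snp_ids=mp["SNP"].to_numpy(dtype=object),
        chrom=mp["CHR"].to_numpy(dtype=object),
        pos=mp["BP"].to_numpy(),
        alleles=alleles,
        dosage=dosage,
        pedigree=pedigree,
        pheno=pheno,
    )


def write_ped_map(geno: GenotypeData, ped_path, map_path) -> None:
    """Write PLINK text PED/MAP; inverse of :func:`read_ped_map`."""
    with open(map_path, "w") as fh:
        for s in range(geno.n_snps):
            fh.write(f"{geno.chrom[s]}\t{geno.snp_ids[s]}\t0\t{geno.pos[s]}\n")
    pheno = geno.pheno if geno.pheno is not None else np.zeros(geno.n_individuals)
    with open(ped_path, "w") as fh:
        for i in range(geno.n_individuals):
            row = geno.pedigree.iloc[i]
            ph = pheno[i]
            ph_str = "0" if np.isnan(ph) else (f"{ph:g}")
            fields = [row["FID"], row["IID"], row["PAT"], row["MAT"], str(row["SEX"]), ph_str]
            for s in range(geno.n_snps):
                d = geno.dosage[i, s]
                coded, other = geno.alleles[s]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    d = int(d)
                    fields += [coded] * d + [other] * (2 - d)
            fh.write(" ".join(map(str, fields)) + "\n")
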