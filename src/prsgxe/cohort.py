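"""Cohort container and on-disk formats.

A cohort bundles three aligned components: a genotype matrix (read and
written as VCF 4.2 with GT-only records), a pedigree (PLINK-style .fam,
sex coded 1=male / 2=female, missing parent = 0), and a phenotype /
environment table (TSV). Founder parents may appear in the pedigree and
genotypes without phenotype rows; all phenotyped individuals must exist in
the pedigree.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .ld import VARIANT_COLUMNS, GenotypeMatrix

__all__ = [
    "Pedigree",
    "Cohort",
    "PHENOTYPE_COLUMNS",
    "read_vcf",
    "write_vcf",
    "read_fam",
    "write_fam",
    "read_phenotypes",
    "write_phenotypes",
    "read_cohort",
    "write_cohort",
]

MALE = "male"
FEMALE = "female"

# canonical phenotype TSV layout; bmi_z / puberty are filled by the prepare
# stage and may be absent on first write
PHENOTYPE_COLUMNS = [
    "individual_id",
    "bmd_tb",
    "bmd_ls",
    "age",
    "sex",
    "bmi",
    "bmi_z",
    "tanner",
    "puberty",
    "mvpa",
    "calcium",
    "phosphorus",
    "ca_p_ratio",
]


@dataclass
class Pedigree:
    """Family structure table.

    Columns: family_id, individual_id, father_id, mother_id (empty string
    for founders), sex ('male'/'female'). Families are the clustering unit
    of every downstream regression.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"family_id", "individual_id", "father_id", "mother_id", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree lacks columns: {sorted(missing)}")
        t = self.table.reset_index(drop=True).copy()
        t["father_id"] = t["father_id"].fillna("")
        t["mother_id"] = t["mother_id"].fillna("")
        if t["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        bad_sex = set(t["sex"]) - {MALE, FEMALE}
        if bad_sex:
            raise ValueError(f"unrecognized sex codes: {sorted(bad_sex)}")
        ids = set(t["individual_id"])
        for col in ("father_id", "mother_id"):
            referenced = set(t[col]) - {""}
            orphan = referenced - ids
            if orphan:
                raise ValueError(f"{col} references unknown individuals: {sorted(orphan)}")
        self.table = t
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            r.individual_id: [p for p in (r.father_id, r.mother_id) if p]
            for r in self.table.itertuples()
        }
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for p in parents.get(node, []):
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError(f"pedigree cycle involving {node!r}")
                if s == 0:
                    visit(p)
            state[node] = 2

        for ind in parents:
            if state.get(ind, 0) == 0:
                visit(ind)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()

    def family_of(self) -> pd.Series:
        """individual_id -> family_id mapping (the GEE cluster labels)."""
        return self.table.set_index("individual_id")["family_id"]

    def founders(self) -> pd.DataFrame:
        t = self.table
        return t[(t["father_id"] == "") & (t["mother_id"] == "")]

    def children(self) -> pd.DataFrame:
        t = self.table
        return t[(t["father_id"] != "") | (t["mother_id"] != "")]


@dataclass
class Cohort:
    """Aligned genotype + pedigree + phenotype bundle."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        ped_ids = set(self.pedigree.individual_ids)
        geno_ids = set(self.genotypes.individual_ids)
        if geno_ids != ped_ids:
            raise ValueError("genotyped individuals do not match the pedigree")
        pheno_ids = set(self.phenotypes["individual_id"])
        if not pheno_ids <= ped_ids:
            raise ValueError("phenotyped individuals missing from the pedigree")

    def family_clusters(self, individual_ids=None) -> pd.Series:
        fam = self.pedigree.family_of()
        if individual_ids is None:
            individual_ids = list(self.phenotypes["individual_id"])
        return fam.loc[list(individual_ids)]


# ---------------------------------------------------------------------------
# VCF

def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype records."""
    v = genotypes.variants
    contigs = list(dict.fromkeys(str(c) for c in v["chrom"]))
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=prsgxe\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j, row in enumerate(v.itertuples()):
            gts = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP dosages (alt-allele counts) from a VCF."""
    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = dosage, 3 = missing
    individual_ids = list(vcf.samples)
    meta = []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"variant {rec.ID} is not biallelic")
        meta.append(
            {
                "id": rec.ID,
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        d = rec.gt_types.astype(float)
        d[d == 3] = np.nan
        rows.append(d)
    vcf.close()
    dosages = np.column_stack(rows) if rows else np.empty((len(individual_ids), 0))
    return GenotypeMatrix(dosages, individual_ids, pd.DataFrame(meta, columns=VARIANT_COLUMNS))


# ---------------------------------------------------------------------------
# FAM

_SEX_TO_FAM = {MALE: "1", FEMALE: "2"}
_FAM_TO_SEX = {"1": MALE, "2": FEMALE}


def write_fam(pedigree: Pedigree, path) -> None:
    """PLINK-style .fam: FID IID father mother sex(1/2) phenotype(-9)."""
    with open(path, "w") as fh:
        for r in pedigree.table.itertuples():
            fh.write(
                f"{r.family_id}\t{r.individual_id}\t{r.father_id or '0'}\t"
                f"{r.mother_id or '0'}\t{_SEX_TO_FAM[r.sex]}\t-9\n"
            )


def read_fam(path) -> Pedigree:
    t = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str,
    )
    t["father_id"] = t["father_id"].replace("0", "")
    t["mother_id"] = t["mother_id"].replace("0", "")
    unknown = set(t["sex"]) - set(_FAM_TO_SEX)
    if unknown:
        raise ValueError(f"unknown FAM sex codes: {sorted(unknown)}")
    t["sex"] = t["sex"].map(_FAM_TO_SEX)
    return Pedigree(t.drop(columns="phenotype"))


# ---------------------------------------------------------------------------
# Phenotype TSV

def write_phenotypes(phenotypes: pd.DataFrame, path, header_comment: str | None = None) -> None:
    cols = [c for c in PHENOTYPE_COLUMNS if c in phenotypes.columns]
    extra = [c for c in phenotypes.columns if c not in cols]
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        phenotypes[cols + extra].to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    t["individual_id"] = t["individual_id"].astype(str)
    return t


# ---------------------------------------------------------------------------
# Bundle

def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Persist a cohort as genotypes.vcf + pedigree.fam + phenotypes.tsv."""
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "fam": directory / "pedigree.fam",
        "pheno": directory / "phenotypes.tsv",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_fam(cohort.pedigree, paths["fam"])
    write_phenotypes(cohort.phenotypes, paths["pheno"])
    return paths


def read_cohort(directory=None, vcf=None, fam=None, pheno=None) -> Cohort:
    if directory is not None:
        directory = Path(directory)
        vcf = vcf or directory / "genotypes.vcf"
        fam = fam or directory / "pedigree.fam"
        pheno = pheno or directory / "phenotypes.tsv"
    return Cohort(read_vcf(vcf), read_fam(fam), read_phenotypes(pheno))
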