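import numpy as np
import pandas as pd
import pytest

from prsgxe.cohort import Cohort, Pedigree
from prsgxe.ld import GenotypeMatrix
from prsgxe.pipeline import prepare_phenotypes
from prsgxe.synthetic import RegionSpec, SimulationConfig, simulate_cohort


def genotype_matrix(dosages, positions=None, chrom="1", ids=None):
    """Build a GenotypeMatrix from a plain individuals x variants array."""
    dosages = np.asarray(dosages, dtype=float)
    n_var = dosages.shape[1]
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_var)]
    if ids is None:
        ids = [f"snp{j + 1}" for j in range(n_var)]
    variants = pd.DataFrame(
        {"id": ids, "chrom": chrom, "pos": positions, "ref": "G", "alt": "A"}
    )
    individual_ids = [f"I{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(dosages, individual_ids, variants)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_families=30, children_per_family=3, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A 30-family cohort with prepared analysis variables."""
    cohort = simulate_cohort(small_config)
    return Cohort(cohort.genotypes, cohort.pedigree, prepare_phenotypes(cohort.phenotypes))


def toy_cohort(dosage_matrix, y, families=None, positions=None, chrom="1", ids=None, rng=None):
    """Cohort wrapper around explicit dosages and an outcome vector.

    Families default to sibling pairs; covariates are benign fillers so the
    fixed covariate set stays estimable.
    """
    rng = rng or np.random.default_rng(0)
    geno = genotype_matrix(dosage_matrix, positions=positions, chrom=chrom, ids=ids)
    n = geno.n_individuals
    if families is None:
        families = [f"F{i // 2}" for i in range(n)]
    ped = Pedigree(
        pd.DataFrame(
            {
                "family_id": families,
                "individual_id": geno.individual_ids,
                "father_id": "",
                "mother_id": "",
                "sex": ["male" if i % 2 else "female" for i in range(n)],
            }
        )
    )
    pheno = pd.DataFrame(
        {
            "individual_id": geno.individual_ids,
            "bmd_tb": np.asarray(y, dtype=float),
            "bmd_ls": np.asarray(y, dtype=float),
            "age": rng.uniform(4, 19, n),
            "sex": ped.table["sex"],
            "bmi": 20.0,
            "bmi_z": rng.normal(size=n),
            "tanner": rng.integers(1, 6, n),
            "mvpa": rng.gamma(2.5, 33.0, n),
            "calcium": rng.normal(880, 100, n).clip(1),
            "phosphorus": rng.normal(1180, 100, n).clip(1),
        }
    )
    pheno["ca_p_ratio"] = pheno["calcium"] / pheno["phosphorus"]
    return Cohort(geno, ped, pheno)
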