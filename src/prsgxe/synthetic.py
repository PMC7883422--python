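"""Synthetic family-cohort generator.

Emulates the study design every downstream stage expects: nuclear families
with >= 3 children aged 4-19, LD-structured genotypes in ~1 Mb regions
around literature index SNPs, right-skewed accelerometer MVPA and dietary
calcium with shared-household (family) correlation, and BMD outcomes
generated from covariates, a per-risk-allele PRS effect, a PRS x MVPA
interaction, and a family random effect.

Genotypes come from a haplotype-pool mosaic: a pool of regional haplotypes
is built SNP-by-SNP with a copy-fidelity chain (adjacent SNPs share their
latent uniform with probability c, giving allele correlation c and r2 = c2
at equal allele frequencies; fidelity 1 with equal target frequencies gives
r2 = 1). Founders draw two pool haplotypes per region; children inherit one
whole regional haplotype from each parent — no recombination is modeled
within a region (<= 1 Mb, physically reasonable at this scale).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, gamma as gamma_dist

from .cohort import FEMALE, MALE, Cohort, Pedigree
from .ld import GenotypeMatrix
from .phenotypes import synthetic_lms_reference

__all__ = [
    "RegionSpec",
    "SimulationConfig",
    "stage_rng",
    "simulate_pedigrees",
    "simulate_region_haplotypes",
    "transmit_genotypes",
    "simulate_environment",
    "simulate_bmd",
    "simulate_cohort",
    "true_prs_entries",
    "default_region_specs",
]

# flanking-SNP risk-allele frequencies cycle through these so regions are
# fully determined by their spec (no hidden randomness in the design)
_FLANK_FREQS = (0.15, 0.35, 0.55, 0.75, 0.45, 0.25, 0.65, 0.85)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible generator for one named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class RegionSpec:
    """One fine-mapping region: an index SNP plus LD-linked flanking SNPs.

    ``risk_allele_freqs`` are the alt (= risk) allele frequencies of the
    region's SNPs in matrix order; the index SNP sits at ``index_col``.
    ``fidelities`` (length n_snps - 1) are copy probabilities between
    consecutive SNPs; by default they decay exponentially with inter-SNP
    distance at scale ``ld_scale_bp``.
    """

    chrom: str
    index_pos: int
    index_snp_id: str
    risk_allele_freqs: tuple
    outcome: str = "TBBMD"
    causal: bool = True
    positions: tuple | None = None
    snp_ids: tuple | None = None
    fidelities: tuple | None = None
    index_col: int | None = None
    spacing_bp: int = 10_000
    ld_scale_bp: float = 30_000.0

    @property
    def n_snps(self) -> int:
        return len(self.risk_allele_freqs)

    def resolved(self) -> "RegionSpec":
        """Fill in derived defaults (positions, ids, fidelities, index_col)."""
        n = self.n_snps
        mid = self.index_col if self.index_col is not None else n // 2
        positions = self.positions
        if positions is None:
            positions = tuple(self.index_pos + self.spacing_bp * (k - mid) for k in range(n))
        if positions[0] < 1:
            shift = 1 - positions[0]
            positions = tuple(p + shift for p in positions)
        snp_ids = self.snp_ids
        if snp_ids is None:
            snp_ids = tuple(
                self.index_snp_id if k == mid else f"{self.index_snp_id}_fl{k}"
                for k in range(n)
            )
        fid = self.fidelities
        if fid is None:
            fid = tuple(
                float(np.exp(-(positions[k + 1] - positions[k]) / self.ld_scale_bp))
                for k in range(n - 1)
            )
        return replace(
            self, positions=positions, snp_ids=snp_ids, fidelities=fid, index_col=mid
        )

    def validate(self) -> None:
        f = np.asarray(self.risk_allele_freqs, dtype=float)
        if f.size < 1:
            raise ValueError("region needs at least one SNP")
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("allele frequencies must lie strictly in (0, 1)")


# Table-style defaults: index SNP catalog used when none is supplied.
# (snp_id, chrom, pos, risk-allele freq, outcome)
_DEFAULT_INDEX = [
    ("rs452369", "2", 40_157_593, 0.24, "TBBMD"),
    ("rs529125", "6", 44_829_351, 0.87, "TBBMD"),
    ("rs2800718", "6", 127_079_180, 0.21, "TBBMD"),
    ("rs10953178", "7", 96_501_326, 0.36, "TBBMD"),
    ("rs950083", "10", 122_717_980, 0.74, "TBBMD"),
    ("rs12273330", "11", 46_340_356, 0.03, "TBBMD"),
    ("rs4394609", "1", 22_406_025, 0.93, "TBBMD"),
    ("rs914153", "2", 138_980_535, 0.70, "TBBMD"),
    ("rs370055571", "2", 39_258_582, 0.01, "TBBMD"),
    ("rs9846561", "3", 157_040_993, 0.96, "LSBMD"),
    ("rs16934799", "10", 77_448_298, 0.98, "LSBMD"),
    ("rs2087058", "12", 54_199_621, 0.54, "LSBMD"),
    ("rs1286083", "14", 90_976_435, 0.12, "LSBMD"),
    ("rs7071206", "10", 77_641_558, 0.75, "LSBMD"),
    ("rs6684375", "1", 22_379_941, 0.90, "LSBMD"),
]


def default_region_specs(n_flank: int = 6, outcomes: tuple = ("TBBMD", "LSBMD")) -> list[RegionSpec]:
    """One region per default index SNP with ``n_flank`` LD-linked neighbors."""
    specs = []
    for i, (snp_id, chrom, pos, freq, outcome) in enumerate(_DEFAULT_INDEX):
        if outcome not in outcomes:
            continue
        mid = n_flank // 2
        flanks = [_FLANK_FREQS[(i + k) % len(_FLANK_FREQS)] for k in range(n_flank)]
        freqs = tuple(flanks[:mid] + [freq] + flanks[mid:])
        specs.append(
            RegionSpec(
                chrom=chrom,
                index_pos=pos,
                index_snp_id=snp_id,
                risk_allele_freqs=freqs,
                outcome=outcome,
                index_col=mid,
            )
        )
    return specs


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Environment moments default to the cohort descriptives of the study
    population (MVPA 82.3 +/- 51.8 min/d, calcium 881.5 +/- 377.3 mg/d,
    Ca/P ratio 0.75 +/- 0.19). Phenotype-model coefficients are on the
    latent (inverse-normal) outcome scale; beta_G < 0 (risk alleles lower
    BMD) and beta_GE > 0 (high MVPA attenuates the genetic deficit) by
    default. ``env_family_rho`` is the shared-household correlation of
    environment variables on the Gaussian-copula scale.
    """

    n_families: int = 100
    children_per_family: int = 3
    haplotype_pool_size: int = 600
    region_specs: list = field(default_factory=default_region_specs)
    beta_0: float = 0.0
    beta_age: float = 0.04
    beta_sex: float = -0.10
    beta_bmiz: float = 0.10
    beta_puberty: float = 0.30
    beta_G: float = -0.20
    beta_E: float = 0.05
    beta_GE: float = 0.10
    beta_G_low: float | None = None   # stratum-specific PRS slopes (by median
    beta_G_high: float | None = None  # MVPA); override beta_G/beta_GE when set
    sigma_family: float = 0.7
    sigma_resid: float = 0.7
    mvpa_mean: float = 82.3
    mvpa_sd: float = 51.8
    calcium_mean: float = 881.5
    calcium_sd: float = 377.3
    ca_p_ratio_mean: float = 0.75
    ca_p_ratio_sd: float = 0.19
    env_family_rho: float = 0.5
    bmiz_mean: float = 0.5  # proband families enriched for overweight
    age_min: float = 4.0
    age_max: float = 19.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.children_per_family < 3:
            raise ValueError("study design requires >= 3 children per family")
        if self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be > 0")
        if self.sigma_family < 0:
            raise ValueError("sigma_family must be >= 0")
        if not 0 <= self.env_family_rho < 1:
            raise ValueError("env_family_rho must be in [0, 1)")
        for spec in self.region_specs:
            spec.validate()

    def index_snp_ids(self, outcome: str) -> list[str]:
        return [s.index_snp_id for s in self.region_specs if s.outcome == outcome and s.causal]


def true_prs_entries(config: SimulationConfig, outcome: str) -> list[tuple[str, str, float]]:
    """(snp_id, risk_allele, risk_allele_freq) for the generator's causal SNPs.

    The alt allele ('A' by construction, see :func:`transmit_genotypes`) is
    the risk allele; its frequency is the region target.
    """
    out = []
    for s in config.region_specs:
        if s.outcome == outcome and s.causal:
            r = s.resolved()
            out.append((s.index_snp_id, "A", float(r.risk_allele_freqs[r.index_col])))
    return out


# ---------------------------------------------------------------------------
# Pedigrees

def simulate_pedigrees(
    n_families: int, children_per_family: int, seed: int
) -> Pedigree:
    """Nuclear families: two founder parents plus ``children_per_family`` kids."""
    if n_families < 1 or children_per_family < 1:
        raise ValueError("counts must be positive")
    rng = stage_rng(seed, "pedigree")
    rows = []
    for i in range(n_families):
        fam = f"FAM{i:04d}"
        father = f"{fam}_FA"
        mother = f"{fam}_MO"
        rows.append((fam, father, "", "", MALE))
        rows.append((fam, mother, "", "", FEMALE))
        child_sex = rng.random(children_per_family) < 0.5
        for j in range(children_per_family):
            rows.append(
                (fam, f"{fam}_C{j + 1}", father, mother, FEMALE if child_sex[j] else MALE)
            )
    return Pedigree(
        pd.DataFrame(
            rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]
        )
    )


# ---------------------------------------------------------------------------
# Haplotypes and transmission

def simulate_region_haplotypes(
    region_spec: RegionSpec, pool_size: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Haplotype pool (pool_size x n_snps, uint8) from the copy-fidelity mosaic."""
    region_spec.validate()
    spec = region_spec.resolved()
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "haplotypes")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    n = spec.n_snps
    freqs = np.asarray(spec.risk_allele_freqs, dtype=float)
    haps = np.empty((pool_size, n), dtype=np.uint8)
    u = rng.random(pool_size)
    haps[:, 0] = u < freqs[0]
    for j in range(1, n):
        fresh = rng.random(pool_size)
        copy = rng.random(pool_size) < spec.fidelities[j - 1]
        u = np.where(copy, u, fresh)
        haps[:, j] = u < freqs[j]
    return haps


def transmit_genotypes(
    pedigree: Pedigree,
    haplotype_pools: list[tuple[RegionSpec, np.ndarray]],
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Drop haplotypes through the pedigree, one whole haplotype per region.

    Founders draw two pool haplotypes uniformly; each child receives one of
    the father's two regional haplotypes and one of the mother's, chosen
    uniformly and independently per region. Alleles are written as ref 'G',
    alt (= risk) 'A'; the dosage is the alt-allele count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "transmission")
    ped = pedigree.table
    founders = ped[(ped["father_id"] == "") & (ped["mother_id"] == "")]
    children = ped[(ped["father_id"] != "") | (ped["mother_id"] != "")]
    if ((children["father_id"] == "") | (children["mother_id"] == "")).any():
        raise ValueError("children must have both parents in the pedigree")
    founder_row = {ind: i for i, ind in enumerate(founders["individual_id"])}
    fidx = np.array([founder_row[f] for f in children["father_id"]], dtype=int)
    midx = np.array([founder_row[m] for m in children["mother_id"]], dtype=int)
    n_f, n_c = len(founders), len(children)

    meta_frames = []
    founder_blocks = []
    child_blocks = []
    for spec, pool in haplotype_pools:
        spec = spec.resolved()
        if pool.shape[0] < 1:
            raise ValueError("empty haplotype pool")
        if pool.shape[1] != spec.n_snps:
            raise ValueError("pool width does not match region spec")
        hap_a = pool[rng.integers(pool.shape[0], size=n_f)]
        hap_b = pool[rng.integers(pool.shape[0], size=n_f)]
        founder_blocks.append((hap_a + hap_b).astype(float))
        if n_c:
            pat = np.where(rng.integers(2, size=n_c)[:, None] == 0, hap_a[fidx], hap_b[fidx])
            mat = np.where(rng.integers(2, size=n_c)[:, None] == 0, hap_a[midx], hap_b[midx])
            child_blocks.append((pat + mat).astype(float))
        meta_frames.append(
            pd.DataFrame(
                {
                    "id": spec.snp_ids,
                    "chrom": spec.chrom,
                    "pos": spec.positions,
                    "ref": "G",
                    "alt": "A",
                }
            )
        )

    variants = pd.concat(meta_frames, ignore_index=True)
    founder_dos = np.hstack(founder_blocks)
    if n_c:
        child_dos = np.hstack(child_blocks)
        dosages = np.vstack([founder_dos, child_dos])
    else:
        dosages = founder_dos
    individual_ids = list(founders["individual_id"]) + list(children["individual_id"])

    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]
    # restore pedigree row order for individuals
    row_of = {ind: i for i, ind in enumerate(individual_ids)}
    perm = [row_of[ind] for ind in ped["individual_id"]]
    return GenotypeMatrix(dosages[perm, :], list(ped["individual_id"]), variants)


# ---------------------------------------------------------------------------
# Environment and covariates

def _truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a normal truncated at zero whose truncated moments match."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")

    def gap(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        a = -mu / sigma
        lam = norm.pdf(a) / norm.sf(a)
        m = mu + sigma * lam
        v = sigma**2 * (1 + a * lam - lam**2)
        return [m - mean, np.sqrt(max(v, 1e-12)) - sd]

    sol = optimize.fsolve(gap, [mean, np.log(sd)], full_output=False)
    return float(sol[0]), float(np.exp(sol[1]))


def _family_correlated_uniforms(
    rng: np.random.Generator, family_codes: np.ndarray, rho: float
) -> np.ndarray:
    """Gaussian-copula uniforms with within-family correlation ``rho``."""
    n = family_codes.size
    n_fam = int(family_codes.max()) + 1 if n else 0
    z_fam = rng.standard_normal(n_fam)
    z_ind = rng.standard_normal(n)
    z = np.sqrt(rho) * z_fam[family_codes] + np.sqrt(1 - rho) * z_ind
    return norm.cdf(z)


def simulate_environment(
    n: int,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    family_codes: np.ndarray | None = None,
    sex: np.ndarray | None = None,
) -> pd.DataFrame:
    """Environment and covariate draws for ``n`` children.

    MVPA is gamma-distributed (right-skewed, non-negative) with moments
    matched to the configured mean/SD; calcium and the Ca/P ratio are
    zero-truncated normals with matched truncated moments; phosphorus is
    derived as calcium / ratio. Within-family correlation (shared
    household) is induced through a Gaussian copula at
    ``config.env_family_rho``. Age is uniform on [age_min, age_max]; Tanner
    stage increases with age plus noise; BMI is generated from a synthetic
    LMS growth reference at a latent z ~ N(bmiz_mean, 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "environment")
    if family_codes is None:
        family_codes = np.arange(n)  # independent households
    family_codes = np.asarray(family_codes, dtype=int)
    rho = config.env_family_rho

    shape = (config.mvpa_mean / config.mvpa_sd) ** 2
    scale = config.mvpa_sd**2 / config.mvpa_mean
    u = _family_correlated_uniforms(rng, family_codes, rho)
    mvpa = gamma_dist.ppf(u, a=shape, scale=scale)

    mu_ca, sd_ca = _truncnorm_params(config.calcium_mean, config.calcium_sd)
    u = _family_correlated_uniforms(rng, family_codes, rho)
    z_ca = norm.ppf(u)
    calcium = _zero_truncated(mu_ca + sd_ca * z_ca, rng, mu_ca, sd_ca)

    mu_r, sd_r = _truncnorm_params(config.ca_p_ratio_mean, config.ca_p_ratio_sd)
    u = _family_correlated_uniforms(rng, family_codes, rho)
    ratio = _zero_truncated(mu_r + sd_r * norm.ppf(u), rng, mu_r, sd_r)
    phosphorus = calcium / ratio

    age = rng.uniform(config.age_min, config.age_max, size=n)
    if sex is None:
        sex = np.where(rng.random(n) < 0.5, FEMALE, MALE)
    tanner = np.clip(
        np.rint(1 + 4 * (age - 4) / 15 + rng.normal(0, 0.6, size=n)), 1, 5
    ).astype(int)

    bmi_z_true = rng.normal(config.bmiz_mean, 1.0, size=n)
    bmi = _bmi_from_z(age, sex, bmi_z_true)

    return pd.DataFrame(
        {
            "mvpa": mvpa,
            "calcium": calcium,
            "phosphorus": phosphorus,
            "ca_p_ratio": calcium / phosphorus,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "bmi_z_true": bmi_z_true,
            "tanner": tanner,
        }
    )


def _zero_truncated(
    x: np.ndarray, rng: np.random.Generator, mu: float, sd: float
) -> np.ndarray:
    """Resample any non-positive draws from the positive tail (rare by design)."""
    bad = x <= 0
    while bad.any():
        x = np.where(bad, mu + sd * rng.standard_normal(x.size), x)
        bad = x <= 0
    return x


_LMS_CACHE: dict = {}


def _bmi_from_z(age_years: np.ndarray, sex: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Invert the synthetic LMS reference at latent z-scores (vectorized)."""
    if "ref" not in _LMS_CACHE:
        ref = synthetic_lms_reference()
        _LMS_CACHE["ref"] = {
            s: ref.table[ref.table["sex"] == s]
            .sort_values("agemos")[["agemos", "L", "M", "S"]]
            .to_numpy(dtype=float)
            for s in (MALE, FEMALE)
        }
    months = np.asarray(age_years, dtype=float) * 12.0
    bmi = np.empty(months.shape)
    for s in (MALE, FEMALE):
        mask = np.asarray(sex) == s
        if not mask.any():
            continue
        tab = _LMS_CACHE["ref"][s]
        L = np.interp(months[mask], tab[:, 0], tab[:, 1])
        M = np.interp(months[mask], tab[:, 0], tab[:, 2])
        S = np.interp(months[mask], tab[:, 0], tab[:, 3])
        base = np.maximum(1.0 + L * S * z[mask], 0.05)  # guard extreme tails
        bmi[mask] = M * np.power(base, 1.0 / L)
    return bmi


# ---------------------------------------------------------------------------
# Phenotype (BMD) model

def simulate_bmd(
    covariates: pd.DataFrame,
    prs_scores: np.ndarray,
    mvpa: np.ndarray,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    family_codes: np.ndarray | None = None,
) -> np.ndarray:
    """Latent-scale BMD from the generating linear model.

    y = b0 + b_age*age + b_sex*1[female] + b_bmiz*z + b_pub*1[pubertal]
        + b_G*PRS + b_E*E' + b_GE*PRS*E' + u_fam + eps,
    with E' the MVPA standardized by the configured moments, u_fam shared
    within family, and eps iid. When ``beta_G_low``/``beta_G_high`` are set
    the genetic term is instead a stratum-specific slope by median MVPA
    (used for stratified-effect studies).
    """
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "bmd")
    n = len(covariates)
    prs_scores = np.asarray(prs_scores, dtype=float)
    mvpa = np.asarray(mvpa, dtype=float)
    if prs_scores.size != n or mvpa.size != n:
        raise ValueError("covariates, PRS and MVPA must be aligned on individuals")
    if family_codes is None:
        family_codes = np.arange(n)
    family_codes = np.asarray(family_codes, dtype=int)

    e_std = (mvpa - config.mvpa_mean) / config.mvpa_sd
    female = (covariates["sex"].to_numpy() == FEMALE).astype(float)
    pubertal = (covariates["tanner"].to_numpy() > 1).astype(float)
    z = covariates["bmi_z_true" if "bmi_z_true" in covariates else "bmi_z"].to_numpy(float)

    y = (
        config.beta_0
        + config.beta_age * covariates["age"].to_numpy(float)
        + config.beta_sex * female
        + config.beta_bmiz * z
        + config.beta_puberty * pubertal
        + config.beta_E * e_std
    )
    if config.beta_G_low is not None or config.beta_G_high is not None:
        if config.beta_G_low is None or config.beta_G_high is None:
            raise ValueError("set both beta_G_low and beta_G_high or neither")
        high = mvpa >= np.median(mvpa)
        slope = np.where(high, config.beta_G_high, config.beta_G_low)
        y = y + slope * prs_scores
    else:
        y = y + config.beta_G * prs_scores + config.beta_GE * prs_scores * e_std

    n_fam = int(family_codes.max()) + 1
    u_fam = rng.normal(0.0, config.sigma_family, size=n_fam)
    eps = rng.normal(0.0, config.sigma_resid, size=n)
    return y + u_fam[family_codes] + eps


# ---------------------------------------------------------------------------
# Full cohort

def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a complete cohort under ``config`` (deterministic per seed).

    Founder parents are genotyped but carry no phenotype rows; the
    phenotype table covers children only, mirroring a pediatric cohort
    whose parents contribute pedigree and genotypes.
    """
    ped = simulate_pedigrees(config.n_families, config.children_per_family, config.seed)
    hap_rng = stage_rng(config.seed, "haplotypes")
    pools = [
        (spec, simulate_region_haplotypes(spec, config.haplotype_pool_size, hap_rng))
        for spec in config.region_specs
    ]
    genotypes = transmit_genotypes(ped, pools, stage_rng(config.seed, "transmission"))

    children = ped.children()
    child_ids = list(children["individual_id"])
    fam_labels = children["family_id"].to_numpy()
    codes = pd.factorize(fam_labels)[0]

    env = simulate_environment(
        len(child_ids),
        config,
        stage_rng(config.seed, "environment"),
        family_codes=codes,
        sex=children["sex"].to_numpy(),
    )

    row = {ind: i for i, ind in enumerate(genotypes.individual_ids)}
    child_rows = [row[i] for i in child_ids]
    bmd = {}
    for k, outcome in enumerate(("TBBMD", "LSBMD")):
        snp_ids = config.index_snp_ids(outcome)
        if snp_ids:
            cols = [genotypes.column(s) for s in snp_ids]
            prs = genotypes.dosages[np.ix_(child_rows, cols)].sum(axis=1)
        else:
            prs = np.zeros(len(child_ids))
        bmd[outcome] = simulate_bmd(
            env,
            prs,
            env["mvpa"].to_numpy(),
            config,
            stage_rng(config.seed, f"bmd_{outcome}"),
            family_codes=codes,
        )

    phenotypes = pd.DataFrame(
        {
            "individual_id": child_ids,
            "bmd_tb": bmd["TBBMD"],
            "bmd_ls": bmd["LSBMD"],
            "age": env["age"],
            "sex": env["sex"],
            "bmi": env["bmi"],
            "tanner": env["tanner"],
            "mvpa": env["mvpa"],
            "calcium": env["calcium"],
            "phosphorus": env["phosphorus"],
            "ca_p_ratio": env["ca_p_ratio"],
        }
    )
    return Cohort(genotypes, ped, phenotypes)
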