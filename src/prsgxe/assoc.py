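"""Family-clustered association models.

Point estimates are ordinary least squares on the stacked data; inference
uses the cluster-robust sandwich variance aggregated over families
(equivalently, a linear GEE with independence working correlation), with
Wald z tests against the standard normal. All models adjust for the fixed
covariate set {age, sex, BMI z-score, puberty stage}; outcomes are
rank-based inverse-normal transformed BMD unless a caller supplies an
already-transformed vector (``transform_outcome=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from .cohort import FEMALE, Cohort
from .phenotypes import PUBERTAL, binarize_by_median, inverse_normal

__all__ = [
    "ModelSpec",
    "GxEFitResult",
    "COVARIATE_TERMS",
    "fit_clustered_lm",
    "snp_association",
    "env_main_effect",
    "gxe_interaction",
    "stratified_effects",
]

COVARIATE_TERMS = ["age", "female", "bmi_z", "pubertal"]

OUTCOME_COLUMNS = {"TBBMD": "bmd_tb", "LSBMD": "bmd_ls"}

GENETIC_TERMS = {"prs_continuous", "prs_binary", "snp_dosage", "none"}
ENV_TERMS = {"mvpa", "calcium", "ca_p_ratio", "none"}
ENV_CODINGS = {"continuous", "binary_median", "standardized"}


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: outcome, genetic term, environment term, coding."""

    outcome: str = "TBBMD"
    genetic_term: str = "prs_continuous"
    env_term: str = "mvpa"
    env_coding: str = "continuous"
    interaction: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.genetic_term not in GENETIC_TERMS:
            raise ValueError(f"unknown genetic term {self.genetic_term!r}")
        if self.env_term not in ENV_TERMS:
            raise ValueError(f"unknown environment term {self.env_term!r}")
        if self.env_coding not in ENV_CODINGS:
            raise ValueError(f"unknown env coding {self.env_coding!r}")
        if self.interaction and (self.genetic_term == "none" or self.env_term == "none"):
            raise ValueError("interaction requires both a genetic and an environment term")


@dataclass
class GxEFitResult:
    """Coefficient table with family-robust inference.

    ``table`` is indexed by term with columns beta, se, z, p. ``strata``
    is populated only by stratified fits (low/high environment groups).
    """

    table: pd.DataFrame
    n_individuals: int
    n_families: int
    n_dropped: int = 0
    se_type: str = "cluster"
    strata: dict | None = None
    model: str = ""

    def _term(self, name: str, col: str) -> float:
        return float(self.table.loc[name, col])

    @property
    def beta_g(self) -> float:
        return self._term("G", "beta")

    @property
    def p_g(self) -> float:
        return self._term("G", "p")

    @property
    def beta_interaction(self) -> float:
        return self._term("G:E", "beta")

    @property
    def p_interaction(self) -> float:
        return self._term("G:E", "p")

    def beta(self, term: str) -> float:
        return self._term(term, "beta")

    def p(self, term: str) -> float:
        return self._term(term, "p")


def _collinear_terms(X: pd.DataFrame) -> list[str]:
    """Columns made redundant by earlier ones (rank-revealing QR)."""
    a = X.to_numpy(dtype=float)
    _, r, piv = linalg.qr(a, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(a.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [X.columns[j] for j in sorted(piv[rank:])]


def fit_clustered_lm(
    y,
    design: pd.DataFrame,
    clusters,
    se_type: str = "cluster",
    model_name: str = "",
) -> GxEFitResult:
    """OLS point estimates with cluster-robust (sandwich) standard errors.

    ``design`` must contain an intercept column if one is wanted. Rows with
    any missing value in y, the design, or the cluster label are dropped
    (complete-case) and counted. ``se_type``: 'cluster' (family sandwich,
    no small-sample correction — the plain sandwich), 'hc0'
    (heteroskedasticity-robust, no clustering), or 'ols' (classical,
    homoskedastic). Inference is Wald z in all cases.
    """
    y = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
    design = design.reset_index(drop=True).astype(float)
    clusters = pd.Series(list(clusters)).reset_index(drop=True)
    if not (len(y) == len(design) == len(clusters)):
        raise ValueError("y, design and clusters must be aligned")

    keep = (~y.isna()) & (~design.isna().any(axis=1)) & (~clusters.isna())
    n_dropped = int((~keep).sum())
    y, design, clusters = y[keep], design[keep], clusters[keep]
    n = len(y)
    if n == 0:
        raise ValueError("no complete-case rows to fit")

    collinear = _collinear_terms(design)
    if collinear:
        raise ValueError(f"design is rank-deficient; collinear terms: {collinear}")

    codes = pd.factorize(clusters)[0]
    n_families = int(codes.max()) + 1
    if se_type == "cluster" and n_families < 2:
        raise ValueError("clustered variance needs at least 2 families")

    model = sm.OLS(y.to_numpy(), design.to_numpy())
    if se_type == "cluster":
        res = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": codes, "use_correction": False, "df_correction": False},
            use_t=False,
        )
    elif se_type == "hc0":
        res = model.fit(cov_type="HC0", use_t=False)
    elif se_type == "ols":
        res = model.fit(use_t=False)
    else:
        raise ValueError(f"unknown se_type {se_type!r}")

    table = pd.DataFrame(
        {
            "beta": res.params,
            "se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        },
        index=list(design.columns),
    )
    return GxEFitResult(
        table=table,
        n_individuals=n,
        n_families=n_families,
        n_dropped=n_dropped,
        se_type=se_type,
        model=model_name,
    )


# ---------------------------------------------------------------------------
# Design assembly from a cohort

def _covariate_frame(pheno: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=pheno.index)
    out["age"] = pheno["age"].astype(float)
    out["female"] = (pheno["sex"] == FEMALE).astype(float)
    if "bmi_z" in pheno:
        out["bmi_z"] = pheno["bmi_z"].astype(float)
    elif "bmi_z_true" in pheno:
        out["bmi_z"] = pheno["bmi_z_true"].astype(float)
    else:
        raise ValueError("phenotype table lacks a BMI z-score column (run prepare)")
    if "puberty" in pheno and pheno["puberty"].notna().any():
        out["pubertal"] = (pheno["puberty"] == PUBERTAL).astype(float)
    else:
        out["pubertal"] = (pheno["tanner"].astype(float) > 1).astype(float)
    return out


def _outcome_vector(pheno: pd.DataFrame, outcome: str, transform: bool) -> np.ndarray:
    col = OUTCOME_COLUMNS[outcome]
    y = pheno[col].to_numpy(dtype=float)
    return inverse_normal(y) if transform else y


def _env_vector(pheno: pd.DataFrame, env_term: str, coding: str) -> np.ndarray:
    e = pheno[env_term].to_numpy(dtype=float)
    if coding == "binary_median":
        return binarize_by_median(e)
    if coding == "standardized":
        mu = np.nanmean(e)
        sd = np.nanstd(e, ddof=1)
        if sd == 0:
            raise ValueError(f"{env_term} is constant; cannot standardize")
        return (e - mu) / sd
    return e


def _genetic_vector(pheno: pd.DataFrame, spec: ModelSpec, prs_scores) -> np.ndarray:
    if spec.genetic_term == "none":
        raise ValueError("model has no genetic term")
    if spec.genetic_term == "snp_dosage":
        g = np.asarray(prs_scores, dtype=float)  # caller supplies the dosage
    else:
        g = _align_scores(pheno, prs_scores)
    if spec.genetic_term == "prs_binary":
        g = binarize_by_median(g)
    return g


def _align_scores(pheno: pd.DataFrame, prs_scores) -> np.ndarray:
    """Accept a scores DataFrame/Series/array and align to phenotype rows."""
    if isinstance(prs_scores, pd.DataFrame):
        s = prs_scores.set_index("individual_id")["prs"]
        return s.reindex(pheno["individual_id"]).to_numpy(dtype=float)
    if isinstance(prs_scores, pd.Series):
        return prs_scores.reindex(pheno["individual_id"]).to_numpy(dtype=float)
    g = np.asarray(prs_scores, dtype=float)
    if g.size != len(pheno):
        raise ValueError("PRS scores are not aligned with the phenotype table")
    return g


def _clusters_for(cohort: Cohort, pheno: pd.DataFrame) -> pd.Series:
    return cohort.family_clusters(list(pheno["individual_id"])).reset_index(drop=True)


def snp_association(
    snp_id: str,
    outcome: str,
    cohort: Cohort,
    transform_outcome: bool = True,
    se_type: str = "cluster",
) -> GxEFitResult:
    """Single-SNP test: outcome ~ dosage + age + sex + BMI-z + puberty."""
    pheno = cohort.phenotypes.reset_index(drop=True)
    dosage = pd.Series(
        cohort.genotypes.dosage(snp_id), index=cohort.genotypes.individual_ids
    ).reindex(pheno["individual_id"]).to_numpy(dtype=float)
    obs = dosage[~np.isnan(dosage)]
    if obs.size < 2 or obs.var() == 0:
        raise ValueError(f"variant {snp_id!r} is monomorphic among phenotyped individuals")
    design = _covariate_frame(pheno)
    design.insert(0, "G", dosage)
    design.insert(0, "const", 1.0)
    y = _outcome_vector(pheno, outcome, transform_outcome)
    return fit_clustered_lm(
        y, design, _clusters_for(cohort, pheno), se_type=se_type,
        model_name=f"snp:{snp_id}~{outcome}",
    )


def env_main_effect(
    env_term: str,
    outcome: str,
    cohort: Cohort,
    env_coding: str = "continuous",
    transform_outcome: bool = True,
    se_type: str = "cluster",
) -> GxEFitResult:
    """Environment main-effect model: outcome ~ E + covariates."""
    pheno = cohort.phenotypes.reset_index(drop=True)
    design = _covariate_frame(pheno)
    design.insert(0, "E", _env_vector(pheno, env_term, env_coding))
    design.insert(0, "const", 1.0)
    y = _outcome_vector(pheno, outcome, transform_outcome)
    return fit_clustered_lm(
        y, design, _clusters_for(cohort, pheno), se_type=se_type,
        model_name=f"env:{env_term}~{outcome}",
    )


def gxe_interaction(
    model: ModelSpec,
    cohort: Cohort,
    prs_scores,
    transform_outcome: bool = True,
    se_type: str = "cluster",
) -> GxEFitResult:
    """PRS x environment interaction model: outcome ~ G + E + G:E + covariates."""
    if not model.interaction:
        raise ValueError("ModelSpec.interaction must be true for gxe_interaction")
    pheno = cohort.phenotypes.reset_index(drop=True)
    g = _genetic_vector(pheno, model, prs_scores)
    e = _env_vector(pheno, model.env_term, model.env_coding)
    design = _covariate_frame(pheno)
    design.insert(0, "G:E", g * e)
    design.insert(0, "E", e)
    design.insert(0, "G", g)
    design.insert(0, "const", 1.0)
    y = _outcome_vector(pheno, model.outcome, transform_outcome)
    return fit_clustered_lm(
        y, design, _clusters_for(cohort, pheno), se_type=se_type,
        model_name=f"gxe:{model.genetic_term}x{model.env_term}~{model.outcome}",
    )


def stratified_effects(
    model: ModelSpec,
    cohort: Cohort,
    prs_scores,
    transform_outcome: bool = True,
    se_type: str = "cluster",
) -> GxEFitResult:
    """Genetic main effect fit separately in low/high environment strata.

    Strata are defined by the median split of the environment variable
    (>= median -> high). Covariate effects are re-estimated within each
    stratum; family clustering is preserved. Requires
    ``env_coding='binary_median'``.
    """
    if model.env_coding != "binary_median":
        raise ValueError("stratified_effects requires env_coding='binary_median'")
    pheno = cohort.phenotypes.reset_index(drop=True)
    g = _genetic_vector(pheno, model, prs_scores)
    strata_flag = binarize_by_median(pheno[model.env_term].to_numpy(dtype=float))
    y_all = _outcome_vector(pheno, model.outcome, transform_outcome)
    clusters = _clusters_for(cohort, pheno)

    strata: dict[str, GxEFitResult] = {}
    for label, value in (("low", 0.0), ("high", 1.0)):
        mask = strata_flag == value
        sub = pheno[mask].reset_index(drop=True)
        if sub.empty or clusters[mask].nunique() < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 families")
        design = _covariate_frame(sub)
        design.insert(0, "G", g[mask])
        design.insert(0, "const", 1.0)
        strata[label] = fit_clustered_lm(
            y_all[mask],
            design,
            clusters[mask].reset_index(drop=True),
            se_type=se_type,
            model_name=f"stratum:{label}",
        )

    summary = pd.DataFrame(
        {
            "beta": [strata["low"].beta_g, strata["high"].beta_g],
            "se": [strata[k].table.loc["G", "se"] for k in ("low", "high")],
            "z": [strata[k].table.loc["G", "z"] for k in ("low", "high")],
            "p": [strata[k].p_g for k in ("low", "high")],
        },
        index=["G_low", "G_high"],
    )
    return GxEFitResult(
        table=summary,
        n_individuals=sum(s.n_individuals for s in strata.values()),
        n_families=clusters.nunique(),
        se_type=se_type,
        strata={k: (v.beta_g, float(v.table.loc["G", "se"]), v.p_g) for k, v in strata.items()},
        model=f"stratified:{model.genetic_term}|{model.env_term}~{model.outcome}",
    )
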