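"""End-to-end orchestration: simulate -> prepare -> build-prs -> test-interaction.

One :class:`RunConfig` (YAML-loadable) drives the whole pipeline and every
stochastic stage derives its generator from the single run seed, so a rerun
with identical config and inputs reproduces byte-identical outputs. Every
fine-mapping region decision, PRS composition and model fit is persisted as
TSV with a header comment carrying the seed and a config hash, enough to
replay any decision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, prs as prs_mod
from .cohort import Cohort, read_cohort, write_cohort, write_phenotypes
from .phenotypes import (
    LMSReference,
    binarize_by_median,
    bmi_zscore_bulk,
    puberty_binary,
    synthetic_lms_reference,
)
from .prs import SignificanceConfig, packaged_catalog, load_catalog
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunReport",
    "prepare_phenotypes",
    "run_pipeline",
    "summarize_cohort",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    vcf: str | None = None
    fam: str | None = None
    pheno: str | None = None
    catalog: str | None = None  # None -> packaged index-SNP catalog
    lms_ref: str | None = None  # None -> packaged synthetic reference
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    half_width_bp: int = 500_000
    r2_prune: float = 0.2
    outcomes: tuple = ("TBBMD", "LSBMD")
    env_terms: tuple = ("mvpa", "calcium", "ca_p_ratio")
    env_codings: tuple = ("continuous", "binary_median")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sig = SignificanceConfig(**raw.pop("significance", {}))
        for key in ("outcomes", "env_terms", "env_codings"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(significance=sig, **raw)

    def validate_paths(self) -> None:
        if not self.simulate:
            for name in ("vcf", "fam", "pheno"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config path {name!r} missing or absent: {p}")
        for name in ("catalog", "lms_ref"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # output location does not change the analysis
        d["significance"] = dataclasses.asdict(self.significance)
        blob = yaml.safe_dump(d, sort_keys=True, default_flow_style=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything a run produced, with enough detail to replay decisions."""

    config_hash: str
    seed: int
    n_individuals: int
    n_families: int
    n_variants: int
    decisions: list
    prs_definitions: dict
    scores: dict
    fits: pd.DataFrame
    cohort_summary: pd.DataFrame
    stage_counts: dict = field(default_factory=dict)


def prepare_phenotypes(pheno: pd.DataFrame, lms_ref: LMSReference | None = None) -> pd.DataFrame:
    """Derive analysis variables: BMI z-score, puberty class, Ca/P ratio."""
    if lms_ref is None:
        lms_ref = synthetic_lms_reference()
    out = pheno.copy()
    out["bmi_z"] = bmi_zscore_bulk(
        out["bmi"], out["age"].astype(float) * 12.0, out["sex"], lms_ref
    )
    out["puberty"] = [puberty_binary(t) for t in out["tanner"]]
    if "calcium" in out and "phosphorus" in out:
        out["ca_p_ratio"] = out["calcium"] / out["phosphorus"]
    return out


def _decisions_frame(decisions: list) -> pd.DataFrame:
    rows = []
    for d in decisions:
        rows.append(
            {
                "index_snp": d.index.snp_id,
                "outcome": d.index.outcome,
                "chrom": d.window.chrom,
                "window_start": d.window.start,
                "window_end": d.window.end,
                "anchor": d.anchor_id,
                "anchor_is_proxy": d.anchor_is_proxy,
                "vfs_snp": d.vfs_snp,
                "vfs_p": d.vfs_p,
                "r2_index_vfs": d.r2_index_vfs,
                "n_independent": d.n_independent,
                "p_threshold": d.p_threshold,
                "rule_fired": d.rule_fired,
                "included_snp": d.included_snp,
                "included_p": d.included_p,
                "log": d.conditional_log,
            }
        )
    return pd.DataFrame(rows)


def _fit_rows(fit: assoc.GxEFitResult, model_label: str) -> list[dict]:
    rows = []
    for term, r in fit.table.iterrows():
        rows.append(
            {
                "model": model_label,
                "term": term,
                "beta": r["beta"],
                "se": r["se"],
                "z": r["z"],
                "p": r["p"],
                "n": fit.n_individuals,
                "n_families": fit.n_families,
            }
        )
    return rows


def _write_tsv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order, persisting intermediate artifacts."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"prsgxe seed={config.seed} config={config.config_hash()}"

    # --- stage 1: cohort ---------------------------------------------------
    if config.simulate:
        sim = SimulationConfig(seed=config.seed, **config.sim_overrides)
        cohort = simulate_cohort(sim)
        write_cohort(cohort, outdir / "cohort")
    else:
        cohort = read_cohort(vcf=config.vcf, fam=config.fam, pheno=config.pheno)
    logger.info("cohort: %d individuals, %d families, %d variants",
                cohort.genotypes.n_individuals, cohort.pedigree.n_families,
                cohort.genotypes.n_variants)

    # --- stage 2: prepare analysis variables -------------------------------
    lms = LMSReference.from_tsv(config.lms_ref) if config.lms_ref else None
    cohort = Cohort(cohort.genotypes, cohort.pedigree,
                    prepare_phenotypes(cohort.phenotypes, lms))
    write_phenotypes(cohort.phenotypes, outdir / "phenotypes_prepared.tsv", stamp)

    # --- stage 3: fine mapping + PRS ----------------------------------------
    catalog = load_catalog(config.catalog) if config.catalog else packaged_catalog()
    decisions = []
    for entry in catalog:
        decisions.append(
            prs_mod.select_region_snp(
                entry, cohort, config.significance,
                half_width_bp=config.half_width_bp, r2_prune=config.r2_prune,
            )
        )
    if len(decisions) != len(catalog):
        raise RuntimeError("decision log does not cover the catalog")  # pragma: no cover
    _write_tsv(_decisions_frame(decisions), outdir / "region_decisions.tsv", stamp)

    prs_definitions: dict = {}
    scores: dict = {}
    for outcome in config.outcomes:
        try:
            definition = prs_mod.build_prs(decisions, outcome, cohort, config.significance)
        except ValueError as err:
            logger.warning("no PRS for %s: %s", outcome, err)
            continue
        prs_definitions[outcome] = definition
        s = prs_mod.score_prs(definition, cohort.genotypes)
        scores[outcome] = s
        _write_tsv(definition.entries, outdir / f"prs_definition_{outcome}.tsv", stamp)
        _write_tsv(s, outdir / f"prs_scores_{outcome}.tsv", stamp)

    # --- stage 4: association models ----------------------------------------
    fit_rows: list[dict] = []
    n_failed_fits = 0
    for outcome in config.outcomes:
        for env in config.env_terms:
            fit = assoc.env_main_effect(env, outcome, cohort)
            fit_rows += _fit_rows(fit, f"main:{env}~{outcome}")
        if outcome not in prs_definitions:
            continue
        prs_scores = scores[outcome]
        for env in config.env_terms:
            for coding in config.env_codings:
                spec = assoc.ModelSpec(outcome=outcome, env_term=env,
                                       env_coding=coding, interaction=True)
                jobs = [(f"gxe:{env}:{coding}~{outcome}",
                         lambda: assoc.gxe_interaction(spec, cohort, prs_scores))]
                if coding == "binary_median":
                    jobs.append((f"stratified:{env}~{outcome}",
                                 lambda: assoc.stratified_effects(spec, cohort, prs_scores)))
                for label, job in jobs:
                    try:
                        fit_rows += _fit_rows(job(), label)
                    except ValueError as err:
                        # degenerate grid cell (e.g. PRS constant within a
                        # stratum on a small cohort): record and continue
                        n_failed_fits += 1
                        logger.warning("skipping %s: %s", label, err)
    fits = pd.DataFrame(fit_rows)
    _write_tsv(fits, outdir / "model_fits.tsv", stamp)

    summary = summarize_cohort(cohort)
    _write_tsv(summary, outdir / "cohort_summary.tsv", stamp)

    return RunReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        n_individuals=cohort.genotypes.n_individuals,
        n_families=cohort.pedigree.n_families,
        n_variants=cohort.genotypes.n_variants,
        decisions=decisions,
        prs_definitions=prs_definitions,
        scores=scores,
        fits=fits,
        cohort_summary=summary,
        stage_counts={
            "catalog_entries": len(catalog),
            "regions_with_inclusion": sum(d.included_snp is not None for d in decisions),
            "phenotyped_individuals": len(cohort.phenotypes),
            "failed_fits": n_failed_fits,
        },
    )


_SUMMARY_VARS = [
    "age", "bmi", "prepubertal_pct", "calcium", "phosphorus",
    "ca_p_ratio", "mvpa", "bmd_tb", "bmd_ls",
]


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Cohort descriptives: mean +/- SD overall and by binary calcium / MVPA.

    Group contrasts use the family-clustered model's Wald test, so sibling
    correlation does not overstate the evidence for group differences.
    """
    pheno = cohort.phenotypes.reset_index(drop=True).copy()
    if "puberty" not in pheno or pheno["puberty"].isna().all():
        pheno["puberty"] = [puberty_binary(t) for t in pheno["tanner"]]
    pheno["prepubertal_pct"] = (pheno["puberty"] == "pre-pubertal").astype(float) * 100
    clusters = cohort.family_clusters(list(pheno["individual_id"])).reset_index(drop=True)

    groups = {
        "calcium": binarize_by_median(pheno["calcium"].to_numpy(float)),
        "mvpa": binarize_by_median(pheno["mvpa"].to_numpy(float)),
    }
    rows = []
    for var in _SUMMARY_VARS:
        if var not in pheno:
            continue
        x = pheno[var].to_numpy(dtype=float)
        row = {"variable": var, "mean": np.nanmean(x), "sd": np.nanstd(x, ddof=1)}
        for gname, flag in groups.items():
            hi, lo = x[flag == 1.0], x[flag == 0.0]
            row[f"high_{gname}_mean"] = np.nanmean(hi)
            row[f"low_{gname}_mean"] = np.nanmean(lo)
            design = pd.DataFrame({"const": 1.0, "group": flag})
            try:
                fit = assoc.fit_clustered_lm(x, design, clusters)
                row[f"p_{gname}"] = fit.p("group")
            except ValueError:
                row[f"p_{gname}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
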