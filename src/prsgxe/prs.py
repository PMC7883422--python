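"""Fine-mapping decision tree and site-specific PRS construction.

For each literature index SNP, a +/- 500 kb region is examined in-cohort:

* R2 — the index SNP (or, when it is not genotyped, a catalog-declared
  proxy) is included if its in-cohort association p-value beats the
  region's Bonferroni threshold (strict mode) or 0.05 (nominal mode);
* R3 — otherwise the region's lowest-p SNP ("VFS_SNP") is included as an
  independent signal if it is weakly linked to the index (r2 < 0.2) and
  beats the region threshold;
* R4 — if the VFS_SNP is strongly linked (r2 >= 0.2) and beats the region
  threshold, a conditional (joint) analysis of the anchor and the VFS_SNP
  decides which carries the signal.

Platform-wide hits (rule R1: GWAS p < 1e-7 / 1e-6, exome p < 9.2e-7 /
9.2e-6, strict/nominal) are merged at PRS-building time. Selected SNPs are
deduplicated, filtered to MAF >= 0.01, oriented so the risk allele is the
one associated with lower BMD, and scored as an unweighted risk-allele
count: PRS = SNP_1 + ... + SNP_n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import _covariate_frame, _outcome_vector, fit_clustered_lm, snp_association
from .cohort import Cohort
from .ld import RegionWindow, UndefinedLDError, count_independent_snps, genotype_r2, region_window

logger = logging.getLogger(__name__)

__all__ = [
    "IndexSNPEntry",
    "SignificanceConfig",
    "RegionDecision",
    "PRSDefinition",
    "region_p_threshold",
    "orient_risk_allele",
    "decide_region",
    "select_region_snp",
    "conditional_analysis",
    "apply_platform_rule",
    "build_prs",
    "score_prs",
    "load_catalog",
    "packaged_catalog",
]

RULE_PLATFORM = "R1_platform"
RULE_INDEX_OR_PROXY = "R2_index_or_proxy"
RULE_INDEPENDENT_VFS = "R3_independent_vfs"
RULE_CONDITIONAL = "R4_conditional"

# r2 gate between the VFS_SNP and the index: below -> independent signal
# (R3), at or above -> conditional arbitration (R4)
R2_INDEPENDENCE = 0.2
R2_COLLINEAR = 0.95


@dataclass(frozen=True)
class IndexSNPEntry:
    """One literature index SNP anchoring a fine-mapping region."""

    snp_id: str
    chrom: str
    pos: int
    outcome: str  # 'TBBMD' or 'LSBMD'
    source: str = "gwas_common"  # 'gwas_common' or 'exome'
    catalog_p: float | None = None
    proxy_id: str | None = None  # externally known proxy (r2 > 0.8) for an
    # index SNP absent from the genotype data


@dataclass(frozen=True)
class SignificanceConfig:
    """Inclusion thresholds for the decision tree and platform rule."""

    gwas_sig: float = 1.0e-7
    gwas_nominal: float = 1.0e-6
    exome_sig: float = 9.2e-7
    exome_nominal: float = 9.2e-6
    region_alpha: float = 0.05
    nominal_region: float = 0.05
    include_nominal: bool = True
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        if not self.gwas_sig < self.gwas_nominal:
            raise ValueError("gwas_sig must be below gwas_nominal")
        if not self.exome_sig < self.exome_nominal:
            raise ValueError("exome_sig must be below exome_nominal")


@dataclass
class RegionDecision:
    """Audited outcome of the decision tree for one index-SNP region."""

    index: IndexSNPEntry
    window: RegionWindow
    anchor_id: str | None = None
    anchor_is_proxy: bool = False
    vfs_snp: str | None = None
    vfs_p: float | None = None
    r2_index_vfs: float | None = None
    n_independent: int = 0
    p_threshold: float | None = None
    rule_fired: str | None = None
    included_snp: str | None = None
    included_p: float | None = None
    conditional_log: str = ""


@dataclass
class PRSDefinition:
    """Ordered SNP set (with risk-allele orientation) for one outcome."""

    outcome: str
    entries: pd.DataFrame  # snp_id, chrom, pos, risk_allele, risk_allele_freq,
    # rule_fired, selection_p
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.entries.empty:
            raise ValueError("empty PRS definition")
        if self.entries["snp_id"].duplicated().any():
            raise ValueError("duplicate SNPs in PRS definition")
        maf = np.minimum(
            self.entries["risk_allele_freq"], 1.0 - self.entries["risk_allele_freq"]
        )
        if (maf < 0.01 - 1e-12).any():
            raise ValueError("PRS definition contains a SNP with MAF < 0.01")

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, na_rep="NA")


def region_p_threshold(n_independent: int, region_alpha: float = 0.05) -> float:
    """Per-region Bonferroni threshold: alpha / number of independent SNPs."""
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    return region_alpha / n_independent


def orient_risk_allele(
    snp_id: str, outcome: str, cohort: Cohort, transform_outcome: bool = True
) -> str:
    """Allele whose dosage associates with lower BMD (the risk allele).

    Fits the covariate-adjusted single-SNP model; a negative alt-dosage
    coefficient makes alt the risk allele, positive makes ref the risk
    allele. An exactly zero coefficient falls back to alt with a warning.
    """
    fit = snp_association(snp_id, outcome, cohort, transform_outcome=transform_outcome)
    beta = fit.beta_g
    row = cohort.genotypes.variants.set_index("id").loc[snp_id]
    if beta == 0.0:
        logger.warning("SNP %s has exactly zero effect; risk allele set to alt", snp_id)
        return str(row["alt"])
    return str(row["alt"]) if beta < 0 else str(row["ref"])


def conditional_analysis(
    snp_a: str,
    snp_b: str,
    outcome: str,
    cohort: Cohort,
    transform_outcome: bool = True,
) -> tuple[str, str]:
    """Joint two-SNP model to pick the better signal; returns (winner, log).

    The winner has the smaller conditional p; ties break by larger
    |conditional beta|, then by smaller genomic position. Near-collinear
    pairs (r2 >= 0.95) skip the joint fit and are resolved by marginal
    p-value (then position), logged as such.
    """
    g_a = cohort.genotypes.dosage(snp_a)
    g_b = cohort.genotypes.dosage(snp_b)
    pos = cohort.genotypes.variants.set_index("id")["pos"]
    try:
        r2 = genotype_r2(g_a, g_b)
    except UndefinedLDError:
        r2 = float("nan")

    if not np.isnan(r2) and r2 >= R2_COLLINEAR:
        p_a = snp_association(snp_a, outcome, cohort, transform_outcome).p_g
        p_b = snp_association(snp_b, outcome, cohort, transform_outcome).p_g
        if p_a < p_b:
            winner = snp_a
        elif p_b < p_a:
            winner = snp_b
        else:
            winner = snp_a if pos[snp_a] <= pos[snp_b] else snp_b
        return winner, (
            f"collinear pair (r2={r2:.3f} >= {R2_COLLINEAR}); resolved by marginal p: "
            f"{snp_a} p={p_a:.3g}, {snp_b} p={p_b:.3g} -> {winner}"
        )

    pheno = cohort.phenotypes.reset_index(drop=True)
    ids = pheno["individual_id"]
    geno_index = {i: k for k, i in enumerate(cohort.genotypes.individual_ids)}
    rows = [geno_index[i] for i in ids]
    design = _covariate_frame(pheno)
    design.insert(0, "G_b", g_b[rows])
    design.insert(0, "G_a", g_a[rows])
    design.insert(0, "const", 1.0)
    y = _outcome_vector(pheno, outcome, transform_outcome)
    fit = fit_clustered_lm(y, design, cohort.family_clusters(list(ids)).reset_index(drop=True))
    p_a, p_b = fit.p("G_a"), fit.p("G_b")
    b_a, b_b = abs(fit.beta("G_a")), abs(fit.beta("G_b"))
    if p_a < p_b:
        winner = snp_a
    elif p_b < p_a:
        winner = snp_b
    elif b_a > b_b:
        winner = snp_a
    elif b_b > b_a:
        winner = snp_b
    else:
        winner = snp_a if pos[snp_a] <= pos[snp_b] else snp_b
    log = (
        f"conditional fit: {snp_a} beta={fit.beta('G_a'):.4f} p={p_a:.3g}; "
        f"{snp_b} beta={fit.beta('G_b'):.4f} p={p_b:.3g} -> {winner}"
    )
    return winner, log


def decide_region(
    index: IndexSNPEntry,
    window: RegionWindow,
    snp_table: pd.DataFrame,
    anchor_id: str | None,
    anchor_is_proxy: bool,
    r2_with_anchor: dict,
    n_independent: int,
    sig: SignificanceConfig,
    conditional,
) -> RegionDecision:
    """Pure decision core: replaying identical inputs reproduces the decision.

    ``snp_table`` has columns snp_id, pos, p, maf for the window's testable
    SNPs; ``r2_with_anchor`` maps snp_id -> r2 against the anchor;
    ``conditional`` is a callable (snp_a, snp_b) -> (winner, log) used only
    on the R4 path.
    """
    decision = RegionDecision(index=index, window=window, anchor_id=anchor_id,
                              anchor_is_proxy=anchor_is_proxy)
    table = snp_table[snp_table["maf"] >= sig.maf_min].reset_index(drop=True)
    if table.empty:
        decision.conditional_log = "no testable SNP in window after MAF filter"
        return decision

    decision.n_independent = max(int(n_independent), 1)
    decision.p_threshold = region_p_threshold(decision.n_independent, sig.region_alpha)
    by_id = table.set_index("snp_id")

    # R2: the anchor itself
    if anchor_id is not None and anchor_id in by_id.index:
        p_anchor = float(by_id.loc[anchor_id, "p"])
        gate = sig.nominal_region if sig.include_nominal else decision.p_threshold
        if p_anchor < gate:
            decision.rule_fired = RULE_INDEX_OR_PROXY
            decision.included_snp = anchor_id
            decision.included_p = p_anchor
            return decision

    # VFS_SNP: lowest in-cohort p in the window (ties by position)
    order = table.sort_values(["p", "pos"]).iloc[0]
    decision.vfs_snp = str(order["snp_id"])
    decision.vfs_p = float(order["p"])

    if decision.vfs_snp == anchor_id:
        decision.conditional_log = "VFS_SNP is the anchor and already failed its gate"
        return decision

    if anchor_id is None:
        # index absent and no declared proxy: the VFS_SNP can only enter as
        # an independent signal; its LD with the index is unknowable in-cohort
        if decision.vfs_p < decision.p_threshold:
            decision.rule_fired = RULE_INDEPENDENT_VFS
            decision.included_snp = decision.vfs_snp
            decision.included_p = decision.vfs_p
        else:
            decision.conditional_log = "no anchor and VFS_SNP above region threshold"
        return decision

    r2 = r2_with_anchor.get(decision.vfs_snp)
    decision.r2_index_vfs = r2
    if r2 is None:
        decision.conditional_log = "r2 between anchor and VFS_SNP undefined"
        return decision

    if decision.vfs_p >= decision.p_threshold:
        decision.conditional_log = "VFS_SNP above region threshold"
        return decision

    if r2 < R2_INDEPENDENCE:
        decision.rule_fired = RULE_INDEPENDENT_VFS
        decision.included_snp = decision.vfs_snp
        decision.included_p = decision.vfs_p
        return decision

    winner, log = conditional(anchor_id, decision.vfs_snp)
    decision.rule_fired = RULE_CONDITIONAL
    decision.included_snp = winner
    decision.included_p = float(by_id.loc[winner, "p"])
    decision.conditional_log = log
    return decision


def select_region_snp(
    index: IndexSNPEntry,
    cohort: Cohort,
    sig: SignificanceConfig = SignificanceConfig(),
    half_width_bp: int = 500_000,
    r2_prune: float = 0.2,
    transform_outcome: bool = True,
) -> RegionDecision:
    """Run the decision tree for one index-SNP region against a cohort."""
    window = region_window(index.chrom, index.pos, half_width_bp)
    geno = cohort.genotypes

    # association table over the window's polymorphic SNPs
    pheno_ids = list(cohort.phenotypes["individual_id"])
    geno_index = {i: k for k, i in enumerate(geno.individual_ids)}
    pheno_rows = [geno_index[i] for i in pheno_ids]
    rows = []
    for snp_id in geno.variants_in_window(window):
        d = geno.dosages[pheno_rows, geno.column(snp_id)]
        d = d[~np.isnan(d)]
        if d.size < 2 or d.var() == 0:
            continue  # monomorphic among phenotyped individuals
        fit = snp_association(snp_id, index.outcome, cohort, transform_outcome)
        rows.append(
            {
                "snp_id": snp_id,
                "pos": int(geno.variants.set_index("id").loc[snp_id, "pos"]),
                "p": fit.p_g,
                "maf": geno.maf(snp_id),
            }
        )
    snp_table = pd.DataFrame(rows, columns=["snp_id", "pos", "p", "maf"])

    anchor_id = None
    anchor_is_proxy = False
    if geno.has_variant(index.snp_id):
        anchor_id = index.snp_id
    elif index.proxy_id is not None and geno.has_variant(index.proxy_id):
        anchor_id = index.proxy_id
        anchor_is_proxy = True

    r2_with_anchor: dict[str, float] = {}
    if anchor_id is not None:
        g_anchor = geno.dosage(anchor_id)
        for snp_id in snp_table["snp_id"]:
            try:
                r2_with_anchor[snp_id] = genotype_r2(g_anchor, geno.dosage(snp_id))
            except UndefinedLDError:
                continue

    n_independent = count_independent_snps(window, geno, r2_prune) if len(snp_table) else 0

    def _conditional(a: str, b: str) -> tuple[str, str]:
        return conditional_analysis(a, b, index.outcome, cohort, transform_outcome)

    return decide_region(
        index, window, snp_table, anchor_id, anchor_is_proxy,
        r2_with_anchor, n_independent, sig, _conditional,
    )


def apply_platform_rule(scan_results: pd.DataFrame, sig: SignificanceConfig) -> pd.DataFrame:
    """Platform-wide hits (rule R1): GWAS/exome thresholds, strict or nominal.

    ``scan_results`` columns: snp_id, source ('gwas_common'/'exome'), p.
    Returns the retained rows (snp_id, source, p).
    """
    required = {"snp_id", "source", "p"}
    if not required <= set(scan_results.columns):
        raise ValueError(f"scan_results needs columns {sorted(required)}")
    gwas_gate = sig.gwas_nominal if sig.include_nominal else sig.gwas_sig
    exome_gate = sig.exome_nominal if sig.include_nominal else sig.exome_sig
    gate = scan_results["source"].map({"gwas_common": gwas_gate, "exome": exome_gate})
    if gate.isna().any():
        bad = sorted(set(scan_results.loc[gate.isna(), "source"]))
        raise ValueError(f"unknown platform tags: {bad}")
    return scan_results[scan_results["p"] < gate].reset_index(drop=True)


def build_prs(
    decisions: list,
    outcome: str,
    cohort: Cohort,
    sig: SignificanceConfig = SignificanceConfig(),
    platform_hits: pd.DataFrame | None = None,
    transform_outcome: bool = True,
) -> PRSDefinition:
    """Assemble the PRS definition for one outcome.

    The union of region-decision inclusions and platform-wide hits is
    deduplicated (keeping the smaller selection p), filtered to MAF >=
    ``sig.maf_min``, and oriented to the risk allele via
    :func:`orient_risk_allele`.
    """
    candidates: dict[str, tuple[float, str]] = {}  # snp_id -> (selection_p, rule)
    for d in decisions:
        if d.index.outcome != outcome or d.included_snp is None:
            continue
        p = d.included_p if d.included_p is not None else float("inf")
        prev = candidates.get(d.included_snp)
        if prev is None or p < prev[0]:
            candidates[d.included_snp] = (p, d.rule_fired)
    if platform_hits is not None:
        for r in platform_hits.itertuples():
            prev = candidates.get(r.snp_id)
            if prev is None or r.p < prev[0]:
                candidates[r.snp_id] = (float(r.p), RULE_PLATFORM)

    geno = cohort.genotypes
    vmeta = geno.variants.set_index("id")
    rows = []
    for snp_id, (p, rule) in candidates.items():
        if not geno.has_variant(snp_id):
            raise KeyError(f"selected SNP {snp_id!r} is missing from genotype data")
        if geno.maf(snp_id) < sig.maf_min:
            logger.info("dropping %s: MAF %.4f below %.2f", snp_id, geno.maf(snp_id), sig.maf_min)
            continue
        risk = orient_risk_allele(snp_id, outcome, cohort, transform_outcome)
        alt_f = geno.alt_freq(snp_id)
        risk_f = alt_f if risk == str(vmeta.loc[snp_id, "alt"]) else 1.0 - alt_f
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": vmeta.loc[snp_id, "chrom"],
                "pos": int(vmeta.loc[snp_id, "pos"]),
                "risk_allele": risk,
                "risk_allele_freq": risk_f,
                "rule_fired": rule,
                "selection_p": p,
            }
        )
    if not rows:
        raise ValueError(
            f"no SNPs selected for {outcome}; consider nominal thresholds "
            "(include_nominal=True) or a denser catalog"
        )
    entries = (
        pd.DataFrame(rows)
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    return PRSDefinition(outcome=outcome, entries=entries, provenance=list(decisions))


def score_prs(prs: PRSDefinition, genotypes) -> pd.DataFrame:
    """Unweighted risk-allele count per individual.

    Missing genotypes contribute the expected dosage 2 x risk_allele_freq
    (mean imputation) and are counted per individual in ``n_imputed`` so
    complete-case scoring stays recoverable. Scores lie in [0, 2n].
    """
    n_ind = genotypes.n_individuals
    total = np.zeros(n_ind)
    n_imputed = np.zeros(n_ind, dtype=int)
    vmeta = genotypes.variants.set_index("id")
    for e in prs.entries.itertuples():
        if not genotypes.has_variant(e.snp_id):
            raise KeyError(f"PRS SNP {e.snp_id!r} absent from genotype data")
        d = genotypes.dosage(e.snp_id).copy()
        if e.risk_allele == str(vmeta.loc[e.snp_id, "ref"]):
            d = 2.0 - d
        elif e.risk_allele != str(vmeta.loc[e.snp_id, "alt"]):
            raise ValueError(f"risk allele of {e.snp_id!r} matches neither VCF allele")
        miss = np.isnan(d)
        d[miss] = 2.0 * e.risk_allele_freq
        n_imputed += miss.astype(int)
        total += d
    return pd.DataFrame(
        {"individual_id": genotypes.individual_ids, "prs": total, "n_imputed": n_imputed}
    )


# ---------------------------------------------------------------------------
# Index-SNP catalog

def load_catalog(path) -> list[IndexSNPEntry]:
    """Read an index-SNP catalog TSV (snp_id, chrom, pos, outcome, source, ...)."""
    t = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    entries = []
    for r in t.itertuples():
        entries.append(
            IndexSNPEntry(
                snp_id=str(r.snp_id),
                chrom=str(r.chrom),
                pos=int(r.pos),
                outcome=str(r.outcome),
                source=str(getattr(r, "source", "gwas_common")),
                catalog_p=(None if pd.isna(getattr(r, "catalog_p", np.nan))
                           else float(r.catalog_p)),
                proxy_id=(None if pd.isna(getattr(r, "proxy_id", np.nan))
                          else str(r.proxy_id)),
            )
        )
    return entries


def packaged_catalog() -> list[IndexSNPEntry]:
    """The packaged index-SNP catalog (published PRS compositions)."""
    from importlib.resources import files

    return load_catalog(files("prsgxe.data") / "index_snp_catalog.tsv")
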