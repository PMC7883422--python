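import numpy as np
import pandas as pd
import pytest

from prsgxe.ld import region_window
from prsgxe.prs import (
    RULE_CONDITIONAL,
    RULE_INDEPENDENT_VFS,
    RULE_INDEX_OR_PROXY,
    IndexSNPEntry,
    PRSDefinition,
    SignificanceConfig,
    apply_platform_rule,
    build_prs,
    conditional_analysis,
    decide_region,
    orient_risk_allele,
    packaged_catalog,
    region_p_threshold,
    score_prs,
    select_region_snp,
)
from prsgxe.synthetic import SimulationConfig, default_region_specs
from prsgxe.experiments import simulate_and_score, true_prs_definition

from conftest import genotype_matrix, toy_cohort

STRICT = SignificanceConfig(include_nominal=False)
NOMINAL = SignificanceConfig(include_nominal=True)


def snp_table(rows):
    """rows: (snp_id, pos, p, maf)"""
    return pd.DataFrame(rows, columns=["snp_id", "pos", "p", "maf"])


def no_conditional(a, b):  # pragma: no cover - fixture guard
    raise AssertionError("conditional analysis must not run for this fixture")


INDEX = IndexSNPEntry("rs_idx", "1", 1_000_000, "TBBMD")
WINDOW = region_window("1", 1_000_000)


class TestRegionThreshold:
    @pytest.mark.parametrize(
        "n,alpha,expected", [(1, 0.05, 0.05), (10, 0.05, 0.005), (250, 0.05, 2.0e-4)]
    )
    def test_bonferroni(self, n, alpha, expected):
        assert region_p_threshold(n, alpha) == pytest.approx(expected)

    def test_zero_independent_rejected(self):
        with pytest.raises(ValueError):
            region_p_threshold(0)


class TestDecisionTree:
    """Hand-constructed regions tracing each rule of the selection tree."""

    def test_rule2_index_significant_strict(self):
        table = snp_table([("rs_idx", 1_000_000, 1e-4, 0.3), ("rs_a", 1_010_000, 0.2, 0.4)])
        d = decide_region(INDEX, WINDOW, table, "rs_idx", False, {}, 100, STRICT,
                         no_conditional)
        assert d.p_threshold == pytest.approx(5e-4)
        assert d.rule_fired == RULE_INDEX_OR_PROXY
        assert d.included_snp == "rs_idx"
        assert d.included_p == pytest.approx(1e-4)

    def test_nominal_vs_strict_gate(self):
        # index p = 0.01: above the Bonferroni threshold, below 0.05
        table = snp_table([("rs_idx", 1_000_000, 0.01, 0.3), ("rs_b", 1_020_000, 0.3, 0.4)])
        nominal = decide_region(INDEX, WINDOW, table, "rs_idx", False, {"rs_b": 0.01},
                                100, NOMINAL, no_conditional)
        assert nominal.rule_fired == RULE_INDEX_OR_PROXY
        assert nominal.included_snp == "rs_idx"
        strict = decide_region(INDEX, WINDOW, table, "rs_idx", False, {"rs_b": 0.01},
                               100, STRICT, no_conditional)
        assert strict.included_snp is None  # VFS is the failed index itself

    def test_absent_index_uses_declared_proxy(self):
        idx = IndexSNPEntry("rs_idx", "1", 1_000_000, "TBBMD", proxy_id="rs_proxy")
        table = snp_table([("rs_proxy", 1_005_000, 1e-4, 0.25)])
        d = decide_region(idx, WINDOW, table, "rs_proxy", True, {}, 50, STRICT,
                         no_conditional)
        assert d.rule_fired == RULE_INDEX_OR_PROXY
        assert d.included_snp == "rs_proxy"
        assert d.anchor_is_proxy

    def test_rule3_independent_vfs(self):
        table = snp_table(
            [("rs_idx", 1_000_000, 0.2, 0.3), ("rs_vfs", 1_050_000, 1e-5, 0.4)]
        )
        d = decide_region(INDEX, WINDOW, table, "rs_idx", False, {"rs_vfs": 0.05},
                         100, STRICT, no_conditional)
        assert d.vfs_snp == "rs_vfs"
        assert d.r2_index_vfs == pytest.approx(0.05)
        assert d.rule_fired == RULE_INDEPENDENT_VFS
        assert d.included_snp == "rs_vfs"

    def test_rule4_conditional_arbitration(self):
        table = snp_table(
            [("rs_idx", 1_000_000, 0.02, 0.3), ("rs_vfs", 1_050_000, 1e-5, 0.4)]
        )
        calls = []

        def conditional(a, b):
            calls.append((a, b))
            return b, "stub: B carries the conditional signal"

        d = decide_region(INDEX, WINDOW, table, "rs_idx", False, {"rs_vfs": 0.6},
                         100, STRICT, conditional)
        assert calls == [("rs_idx", "rs_vfs")]
        assert d.rule_fired == RULE_CONDITIONAL
        assert d.included_snp == "rs_vfs"
        assert d.conditional_log.startswith("stub")

    def test_maf_filter_excludes_rare_vfs(self):
        # the lowest-p SNP is too rare to enter the PRS; nothing else passes
        table = snp_table(
            [("rs_idx", 1_000_000, 0.4, 0.3), ("rs_rare", 1_030_000, 1e-8, 0.005)]
        )
        d = decide_region(INDEX, WINDOW, table, "rs_idx", False, {"rs_rare": 0.1},
                         100, STRICT, no_conditional)
        assert d.included_snp is None
        assert d.rule_fired is None

    def test_no_anchor_vfs_included_as_independent(self):
        idx = IndexSNPEntry("rs_missing", "1", 1_000_000, "TBBMD")
        table = snp_table([("rs_vfs", 1_040_000, 1e-6, 0.2)])
        d = decide_region(idx, WINDOW, table, None, False, {}, 20, STRICT,
                         no_conditional)
        assert d.rule_fired == RULE_INDEPENDENT_VFS
        assert d.included_snp == "rs_vfs"
        assert d.r2_index_vfs is None

    def test_empty_window_logged(self):
        d = decide_region(INDEX, WINDOW, snp_table([]), None, False, {}, 0, STRICT,
                         no_conditional)
        assert d.included_snp is None
        assert "no testable SNP" in d.conditional_log

    def test_decision_is_replayable(self):
        table = snp_table(
            [("rs_idx", 1_000_000, 0.02, 0.3), ("rs_vfs", 1_050_000, 1e-5, 0.4)]
        )
        args = (INDEX, WINDOW, table, "rs_idx", False, {"rs_vfs": 0.6}, 100, STRICT)
        d1 = decide_region(*args, lambda a, b: (a, "log"))
        d2 = decide_region(*args, lambda a, b: (a, "log"))
        assert d1 == d2


class TestConditionalAnalysis:
    def _pair_cohort(self, rng, beta_a=-0.3, copy_noise=0.4, n=400):
        a = rng.binomial(2, 0.5, n).astype(float)
        b = a.copy()
        flip = rng.random(n) < copy_noise
        b[flip] = rng.binomial(2, 0.5, flip.sum())
        y = beta_a * a + rng.normal(size=n)
        return toy_cohort(np.column_stack([a, b]), y, rng=rng)

    def test_causal_snp_beats_noisy_proxy(self):
        rng = np.random.default_rng(21)
        wins = 0
        reps = 200
        for _ in range(reps):
            cohort = self._pair_cohort(rng)
            winner, _ = conditional_analysis("snp1", "snp2", "TBBMD", cohort,
                                             transform_outcome=False)
            wins += winner == "snp1"
        assert wins / reps >= 0.90

    def test_independent_null_snp_p_uniform(self):
        rng = np.random.default_rng(22)
        from scipy.stats import kstest
        from prsgxe.assoc import fit_clustered_lm, _covariate_frame

        ps = []
        for _ in range(150):
            n = 300
            a = rng.binomial(2, 0.5, n).astype(float)
            b = rng.binomial(2, 0.5, n).astype(float)
            y = -0.3 * a + rng.normal(size=n)
            cohort = toy_cohort(np.column_stack([a, b]), y, rng=rng)
            ph = cohort.phenotypes
            design = _covariate_frame(ph)
            design.insert(0, "G_b", b)
            design.insert(0, "G_a", a)
            design.insert(0, "const", 1.0)
            fit = fit_clustered_lm(y, design,
                                   cohort.family_clusters(list(ph.individual_id)))
            ps.append(fit.p("G_b"))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_pair_falls_back_to_marginal(self):
        rng = np.random.default_rng(23)
        a = rng.binomial(2, 0.5, 200).astype(float)
        y = -0.3 * a + rng.normal(size=200)
        cohort = toy_cohort(np.column_stack([a, a]), y, rng=rng)
        winner, log = conditional_analysis("snp1", "snp2", "TBBMD", cohort,
                                           transform_outcome=False)
        assert winner == "snp1"  # tie on p, broken by smaller position
        assert "collinear" in log


class TestRiskAlleleOrientation:
    def _cohort(self, rng, flip_labels=False):
        n = 500
        dosage = rng.binomial(2, 0.4, n).astype(float)
        y = -0.4 * dosage + rng.normal(size=n)
        if flip_labels:
            geno_dos = (2 - dosage)[:, None]
        else:
            geno_dos = dosage[:, None]
        cohort = toy_cohort(geno_dos, y, rng=np.random.default_rng(0))
        if flip_labels:
            cohort.genotypes.variants.loc[0, ["ref", "alt"]] = ["A", "G"]
        return cohort

    def test_negative_alt_effect_picks_alt(self):
        cohort = self._cohort(np.random.default_rng(24))
        assert orient_risk_allele("snp1", "TBBMD", cohort) == "A"

    def test_label_swap_same_physical_allele(self):
        c1 = self._cohort(np.random.default_rng(24))
        c2 = self._cohort(np.random.default_rng(24), flip_labels=True)
        assert orient_risk_allele("snp1", "TBBMD", c1) == "A"
        assert orient_risk_allele("snp1", "TBBMD", c2) == "A"  # now the ref label


class TestPlatformRule:
    def test_threshold_gates(self):
        scan = pd.DataFrame(
            {
                "snp_id": ["c1", "c2", "e1", "e2"],
                "source": ["gwas_common", "gwas_common", "exome", "exome"],
                "p": [5e-8, 5e-7, 5e-6, 5e-7],
            }
        )
        strict = set(apply_platform_rule(scan, STRICT)["snp_id"])
        nominal = set(apply_platform_rule(scan, NOMINAL)["snp_id"])
        assert strict == {"c1", "e2"}
        assert nominal == {"c1", "c2", "e1", "e2"}
        assert strict <= nominal

    def test_unknown_platform_rejected(self):
        scan = pd.DataFrame({"snp_id": ["x"], "source": ["array"], "p": [1e-9]})
        with pytest.raises(ValueError, match="platform"):
            apply_platform_rule(scan, STRICT)


class TestScorePRS:
    def _definition(self, freqs=(0.24, 0.5, 0.8), risk=("A", "A", "G")):
        return PRSDefinition(
            outcome="TBBMD",
            entries=pd.DataFrame(
                {
                    "snp_id": [f"snp{i + 1}" for i in range(len(freqs))],
                    "chrom": "1",
                    "pos": [1000 * (i + 1) for i in range(len(freqs))],
                    "risk_allele": risk,
                    "risk_allele_freq": freqs,
                    "rule_fired": "R2_index_or_proxy",
                    "selection_p": 1e-4,
                }
            ),
        )

    def test_hand_sum(self):
        dosages = np.array([[2, 1, 0, 1, 2, 0, 1, 1, 2]], dtype=float)
        definition = PRSDefinition(
            outcome="TBBMD",
            entries=pd.DataFrame(
                {
                    "snp_id": [f"s{i}" for i in range(9)],
                    "chrom": "1",
                    "pos": np.arange(1, 10) * 1000,
                    "risk_allele": "A",
                    "risk_allele_freq": 0.5,
                    "rule_fired": "R1_platform",
                    "selection_p": 1e-8,
                }
            ),
        )
        geno = genotype_matrix(dosages, ids=[f"s{i}" for i in range(9)])
        assert score_prs(definition, geno)["prs"].iloc[0] == 10.0

    def test_ref_risk_allele_flipped(self):
        geno = genotype_matrix(np.array([[2.0, 2.0, 2.0]]))
        scores = score_prs(self._definition(), geno)
        # snp3's risk allele is the ref ('G'): dosage 2 alt -> 0 risk copies
        assert scores["prs"].iloc[0] == 4.0

    def test_missing_imputed_at_twice_freq(self):
        geno = genotype_matrix(np.array([[np.nan, 0.0, 0.0]]))
        scores = score_prs(self._definition(), geno)
        assert scores["prs"].iloc[0] == pytest.approx(2 * 0.24 + 0 + 2.0)
        assert scores["n_imputed"].iloc[0] == 1

    def test_absent_snp_is_configuration_error(self):
        geno = genotype_matrix(np.zeros((2, 2)))
        with pytest.raises(KeyError, match="snp3"):
            score_prs(self._definition(), geno)

    def test_bounds(self):
        rng = np.random.default_rng(25)
        geno = genotype_matrix(rng.integers(0, 3, (50, 3)).astype(float))
        s = score_prs(self._definition(), geno)["prs"]
        assert (s >= 0).all() and (s <= 6).all()

    def test_definition_rejects_low_maf(self):
        with pytest.raises(ValueError, match="MAF"):
            self._definition(freqs=(0.005, 0.5, 0.8))

    def test_definition_rejects_duplicates(self):
        entries = self._definition().entries
        dup = pd.concat([entries, entries.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            PRSDefinition(outcome="TBBMD", entries=dup)


# strong causal effects and low noise: a selection-power scenario
POWERED_CFG = dict(
    beta_G=-0.5, sigma_family=0.3, sigma_resid=0.4,
    n_families=150, children_per_family=5,
)


class TestEndToEndSelection:
    def test_causal_index_snps_recovered(self):
        common = {"rs452369", "rs529125", "rs2800718", "rs10953178",
                  "rs950083", "rs4394609", "rs914153"}
        catalog = [e for e in packaged_catalog() if e.outcome == "TBBMD"]
        per_seed = []
        for seed in range(6):
            cfg = SimulationConfig(
                seed=seed, region_specs=default_region_specs(outcomes=("TBBMD",)),
                **POWERED_CFG,
            )
            cohort, _ = simulate_and_score(cfg)
            hits = set()
            for entry in catalog:
                d = select_region_snp(entry, cohort, NOMINAL)
                if d.included_snp == entry.snp_id:
                    hits.add(entry.snp_id)
            per_seed.append(len(hits & common))
        assert sum(k >= 6 for k in per_seed) >= 5  # of 6 seeds
        assert max(per_seed) == 7

    def test_build_prs_dedup_and_maf(self):
        cfg = SimulationConfig(
            seed=1, region_specs=default_region_specs(outcomes=("TBBMD",)), **POWERED_CFG
        )
        cohort, _ = simulate_and_score(cfg)
        catalog = [e for e in packaged_catalog() if e.outcome == "TBBMD"]
        decisions = [select_region_snp(e, cohort, NOMINAL) for e in catalog]
        duplicated = decisions + decisions  # same SNPs twice
        definition = build_prs(duplicated, "TBBMD", cohort, NOMINAL)
        assert not definition.entries["snp_id"].duplicated().any()
        mafs = [cohort.genotypes.maf(s) for s in definition.entries["snp_id"]]
        assert min(mafs) >= 0.01
        # risk alleles oriented toward lower BMD: the generator's alt is causal
        idx_rows = definition.entries[
            definition.entries.snp_id.isin({"rs452369", "rs10953178"})
        ]
        assert (idx_rows["risk_allele"] == "A").all()

    def test_empty_selection_advises(self):
        rng = np.random.default_rng(26)
        n = 60
        cohort = toy_cohort(rng.binomial(2, 0.5, (n, 1)).astype(float),
                            rng.normal(size=n), rng=rng)
        with pytest.raises(ValueError, match="nominal"):
            build_prs([], "TBBMD", cohort, STRICT)

    def test_mean_prs_matches_closed_form(self):
        # founders drawn at the published TBBMD risk-allele frequencies
        cfg = SimulationConfig(
            n_families=200, seed=5,
            region_specs=default_region_specs(outcomes=("TBBMD",)),
        )
        cohort, _ = simulate_and_score(cfg)
        definition = true_prs_definition(cfg, "TBBMD")
        scores = score_prs(definition, cohort.genotypes)
        founders = set(cohort.pedigree.founders()["individual_id"])
        s = scores[scores.individual_id.isin(founders)]["prs"]
        expected = 2 * definition.entries["risk_allele_freq"].sum()
        sd = np.sqrt((2 * definition.entries.risk_allele_freq
                      * (1 - definition.entries.risk_allele_freq)).sum())
        assert abs(s.mean() - expected) <= 2.576 * sd / np.sqrt(len(s))
        assert s.min() >= 0 and s.max() <= 18
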