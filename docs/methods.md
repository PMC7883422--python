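# Methods

This note documents the models, conventions and numerical choices behind
`prsgxe`, and what the synthetic-data studies do and do not establish.

## Synthetic family cohorts

**Design.** Nuclear families: two genotyped founder parents and a
configurable number of children (default 3; the study design the generator
emulates enrolled families with at least three children aged 4–19). Only
children carry phenotypes; parents contribute pedigree structure and
genotypes.

**Genotypes.** Each fine-mapping region (one per index SNP, default: the
packaged 15-SNP catalog, 9 TBBMD + 6 LSBMD) gets a pool of haplotypes
(default 600) built SNP-by-SNP by a copy-fidelity mosaic: adjacent SNPs
share their latent uniform with probability c, so allele correlation between
adjacent SNPs is c and r² = c² when target frequencies are equal; r decays
multiplicatively along the chain. By default c = exp(−d/30 kb) for inter-SNP
distance d (SNPs at 10 kb spacing around the index). Founders draw two pool
haplotypes per region; children inherit one whole regional haplotype from
each parent, chosen uniformly — no recombination within a ≤1 Mb region,
which is physically reasonable at that scale (expected ≈0.01 crossovers per
meiosis per Mb) and makes the Mendelian and LD structure exactly auditable.
Marginal allele frequencies are exact by construction; the index SNPs use
the published risk-allele frequencies (0.24, 0.87, 0.21, 0.36, 0.74, 0.03,
0.93, 0.70, 0.01 for TBBMD). The alt allele is written as the risk allele.

**Environments.** MVPA is gamma-distributed (shape (μ/σ)², scale σ²/μ),
matching the reported cohort moments 82.3 ± 51.8 min/d — right-skewed and
non-negative, unlike a normal. Calcium (881.5 ± 377.3 mg/d) and the dietary
Ca/P ratio (0.75 ± 0.19) are zero-truncated normals whose *truncated*
moments are matched by solving for the underlying (μ, σ); phosphorus is
derived as calcium/ratio. All three are drawn through a Gaussian copula
with a family random effect at correlation ρ_env = 0.5 on the copula scale.
Children in one household share activity patterns and diet; published
sibling ICCs for accelerometer MVPA and for nutrient intakes run roughly
0.3–0.5, and we use the upper end as appropriate for nuclear families with
three or more co-resident children. This correlation is scientifically
load-bearing: it is what makes naive (non-clustered) standard errors
anti-conservative for the G×E term, the failure mode the clustered
estimator exists to fix.

**Covariates.** Age ~ U(4, 19); Tanner stage is a monotone function of age
plus noise, clipped to 1–5 (only its dichotomization at stage 1 vs >1 is
consumed downstream); BMI is generated by inverting a packaged synthetic
LMS reference at a latent z ~ N(0.5, 1) — the positive mean reflects a
proband design enriched for overweight. The synthetic LMS table has the
shape of a pediatric growth chart but is not the CDC reference and carries
no real-population meaning; users with CDC tables can supply them as TSV.

**Phenotype model.** On a latent (inverse-normal) scale,

y = β₀ + β_age·age + β_sex·1[female] + β_bmiz·z + β_pub·1[pubertal]
    + β_G·PRS + β_E·E′ + β_GE·PRS·E′ + u_fam + ε,

with E′ = (MVPA − μ)/σ standardized by the configured moments,
u_fam ~ N(0, σ²_family) shared within family, ε ~ N(0, σ²_resid). Defaults:
β_G = −0.2 per risk allele and β_GE = +0.1, matching the sign pattern and
per-SNP magnitudes reported for this design (negative genetic main effects
around −0.2 to −0.4, positive interactions); σ_family = σ_resid = 0.7
(within-family phenotype ICC 0.5, consistent with the high heritability of
pediatric BMD). A stratum-slope mode (β_G_low/β_G_high by median MVPA)
generates piecewise genetic effects for stratified-analysis studies.

**What the generator does not emulate.** Genome-wide polygenicity,
admixture and assortative mating; accelerometer time series (only the
energy-expenditure threshold classifier is provided); measurement error in
dietary recall; ascertainment through an overweight proband beyond the
shifted BMI-z mean. Passing tests therefore demonstrate correctness of the
estimators and decision logic under a clean data-generating process, not
robustness to those real-data complications.

## Analysis variables

* **LMS z-scores**: z = ((X/M)^L − 1)/(L·S), with the log-limit form
  ln(X/M)/S when |L| < 1e−8. Reference lookup uses the nearest tabulated
  age within 0.5 month, otherwise linear interpolation in age (monthly
  tables vs continuous synthetic ages).
* **Inverse-normal transform**: Φ⁻¹((r − 3/8)/(n + 1/4)) on average ranks
  (Blom offset, the GWAS-standard choice); missing values pass through.
* **Median binarization**: value ≥ sample median → high. With heavy ties
  the split is unbalanced by construction; an all-constant vector maps
  entirely to "high".
* **Activity classes**: per-minute energy expenditure cut at 0.01 / 0.04 /
  0.10 kcal/kg/min, lower bounds inclusive (the printed thresholds do not
  state inclusivity; a convention was required). MVPA = moderate +
  vigorous minutes.

## LD

r² is the composite squared Pearson correlation of unphased dosages over
pairwise-complete individuals — no phasing, no external reference panel
(the original analysis used a web LD service with ancestry-matched panels;
none is packaged, so all LD is in-cohort). Monomorphic pairs raise a
dedicated `UndefinedLDError` rather than returning 0. "Number of independent
SNPs" in a region uses greedy positional pruning at r² < 0.2 (SNPs visited
in position order; kept iff below-threshold against every kept SNP), which
is deterministic and, under chain-structured LD, equals the exhaustive
maximum keep-set (verified by enumeration in tests). Eigenvalue-based
effective-test counts were considered and left out of scope.

## Fine-mapping decision tree

Per region: the Bonferroni threshold is α/n_independent with α = 0.05.
Precedence is anchor-first: (R2) include the index SNP — or, if it is not
genotyped, a catalog-declared proxy — when its in-cohort p beats the
region threshold (strict mode) or 0.05 (nominal mode); else (R3) include
the region's lowest-p SNP when r² < 0.2 against the anchor and p below the
region threshold; else (R4) when r² ≥ 0.2 and p below threshold, a joint
regression of anchor and VFS_SNP decides the better signal (smaller
conditional p; ties by larger |β|, then smaller position; pairs with
r² ≥ 0.95 skip the joint fit and fall back to marginal p). Regions can
also contribute nothing. Platform-wide hits (GWAS p < 1e−7 strict /
1e−6 nominal; exome p < 9.2e−7 / 9.2e−6) merge at PRS-building time,
where the union is deduplicated by smaller selection p, filtered to
MAF ≥ 0.01 (computed over all genotyped individuals), and oriented so the
risk allele is the one whose dosage lowers BMD. Because the in-cohort r²
to an ungenotyped index SNP is uncomputable, absent-index regions without
a declared proxy treat the VFS_SNP as an independent signal and record the
r² as undefined. Every decision is logged with all inputs (anchor, VFS,
r², n_independent, threshold, rule, conditional fit) and is a pure
function of them, so logged decisions replay exactly.

Note one asymmetry: nominal and strict modes may include *different* SNPs
from the same region (nominal can admit the index under its looser gate
where strict would have promoted the VFS_SNP), so strict-mode selections
are not always a subset of nominal-mode selections region by region; the
platform rule is strictly nested.

## Scoring

PRS = unweighted sum of risk-allele dosages; a missing genotype contributes
its expectation 2·(risk-allele frequency) and is counted per individual, so
complete-case scores remain recoverable. Scores are bounded by [0, 2·n_SNPs]
and invariant to ref/alt label swaps in the VCF.

## Family-clustered regression

Point estimates are OLS; the variance is the plain cluster-robust sandwich
over families with no small-sample correction, so singleton clusters
reproduce HC0 exactly; inference is Wald z. This matches large-sample GEE
practice for family data. Two small-sample properties are documented
limitations, measured on the generator at the study's scale:

* With ~100 families, the uncorrected sandwich Wald-z test of a
  *continuous* G×E term (skewed gamma environment times sib-correlated PRS)
  has true size ≈ 0.08 at nominal 0.05, shrinking to ≈ 0.067 at 300
  families. The package's primary interaction test — continuous PRS ×
  median-binarized MVPA, the coding of the headline analysis it
  implements — is correctly sized (≈ 0.066 at 100 families, inside the
  binomial 99% band for 500 replicates) while naive non-clustered OLS on
  the same fits rejects at ≈ 0.10.
* The sandwich SE underestimates the sampling SD of the interaction
  estimate by ~3% at 150 families (SD/mean-SE ≈ 1.03 over 1000
  replicates), comfortably within the 15% calibration bound asserted in
  tests.

Complete-case rows only (dropped rows are counted); rank-deficient designs
raise an error naming the collinear terms. Stratified analyses re-estimate
all covariate effects within each median-split stratum, preserving family
clustering, and require at least two families per stratum.

Coefficients are reported on the inverse-normal outcome scale. Raw-scale
(g/cm²) effects would require a back-transformation that the analysis this
package implements does not define; calibration and recovery simulations
therefore fit the generator's latent outcome directly — re-ranking an
already-normal variable is an approximately affine transform that only
rescales coefficients by 1/SD(y).

## Replicated studies and problem sizes

The simulation studies in `prsgxe.experiments` (also run by
`scripts/acceptance.py` and the acceptance tests) use: 500 null replicates
at 100 families × 5 children with σ_family = 1 for size; 400 replicates at
150 families × 5 (n = 750 children) with β_G = −0.3, β_GE = +0.2 for
recovery — 400 rather than 200 so the Monte-Carlo error of the SD/SE ratio
(~3.5%) is small against the 15% bound; 200 replicates for stratified
ordering (−0.3 vs −0.1); 250 families for the founder PRS closed form
(mean = 2·Σf = 8.18 for the 9-SNP TBBMD set). Only TBBMD regions are
simulated in replicated studies, since the quantities measured concern the
TBBMD PRS. One replicate simulates, scores and fits in ~40 ms, so the full
battery runs in about a minute on one CPU.

## Determinism

A single run seed drives every stage through named, independently derived
generator streams (`SeedSequence([seed, crc32(stage)])`); identical
configuration reproduces byte-identical output files, which the pipeline
stamps with the seed and a config hash.
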