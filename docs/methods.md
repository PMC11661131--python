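# Methods

## The longitudinal kinship mixed model

Daily endpoints on a panel of fully inbred strains are modeled per mouse
*i* and day *j* as

    Y_ij = x_ij'α + γ·SNP + β₀ᵢ + β₁ᵢ·d_j + ε_ij,

with fixed covariates x (intercept, age in weeks, sex, active-lever side,
testing chamber, cohort, day as a continuous variable) and per-mouse random
intercepts/day-slopes whose joint covariance decomposes into a kinship
block and an individual block:

    Cov(β₀, β₁) = Σ_G ⊗ K + Σ_E ⊗ I_n,
    Σ_G = [[σ₁², σ₅²], [σ₅², σ₃²]],  Σ_E = [[σ₂², σ₆²], [σ₆², σ₄²]],

where K is the mouse-expanded genetic relatedness matrix (GRM) and
ε ~ N(0, σ²). Chamber and cohort enter the fit as unordered categories with
a first-level reference. The day covariate is the raw session index
1..T; the slope variances are therefore small numbers relative to the
intercept variances (a slope SD of 0.06 on a unit-variance trait moves a
mouse by ~0.6 SD over ten days).

### REML evaluation

With a balanced day grid (every mouse observed on the same days — the
design this panel produces; missing endpoint cells drop the mouse from the
mapping stage) the observation covariance factorizes as
V = K ⊗ A + I ⊗ B with A = FΣ_G F', B = FΣ_E F' + σ²I_T and F = [1 d].
After one eigendecomposition K = U S U', V block-diagonalizes into n
T×T blocks M_i = F(s_iΣ_G + Σ_E)F' + σ²I, each a rank-2 update of the
identity, inverted analytically through a 2×2 Woodbury identity. A full
REML evaluation is therefore O(n·p²); unbalanced data fall back to an
explicitly assembled dense covariance (used by the no-kinship time-course
test when cells are missing). The two 2×2 blocks are parameterized by their
Cholesky factors and the residual by its log, giving an unconstrained
7-parameter optimization (L-BFGS-B, three starts — moderate/low/high
genetic fractions of the phenotypic variance — convergence tolerance 1e-8
on the restricted likelihood). PSD of the implied blocks is guaranteed by
the parameterization.

### Scan, threshold, inflation, loci

Variance components are estimated once under the no-SNP null and plugged
into every per-SNP Wald test, the strategy of standard mixed-model GWAS
software; γ is tested one SNP at a time. Because the strain dosage is
constant within a mouse and across days, each SNP test reduces to inner
products against three precomputed vectors, and a scan over m SNPs is one
(n × n_strains)·(n_strains × m) matrix product. Missing genotype calls
drop the affected strains' mice for that SNP (exact, via a per-missing-
pattern refactorization); monomorphic-after-drop SNPs are emitted with
p = 1 and a flag.

A strong QTL's own chromosome inside the GRM lets the kinship variance
component absorb part of the QTL signal and deflate its Wald statistic
(proximal contamination); leave-one-chromosome-out (LOCO) kinship — each
chromosome tested under a null whose GRM excludes it, later fits
warm-started from the previous chromosome — is provided for that reason
(`fit_loco_nulls` / `wald_scan_loco` / `permutation_threshold_loco`, and a
pipeline toggle). It is, however, **not** the default protocol here: when
the polygenic background is kinship-structured genome-wide — exactly what
the panel generator produces — excluding a chromosome leaves that
chromosome's share of heritable variance unmodeled, and because the tested
SNP's own LD block is part of that share, null statistics inflate
(λ ≈ 1.15–1.4 on this generator's 4-chromosome genome) while the
permutation distribution, which severs the genotype-phenotype link, does
not, so the familywise error at the permutation threshold exceeds its
nominal level. The single-GRM scan is the correctly specified and
familywise-calibrated analysis for these panels and is what the power
protocol and the calibration checks use; LOCO's power advantage is real
only when its inflation is acceptable or the genome is large enough to
dilute the left-out share.

The genome-wide 5% threshold permutes the strain-to-genotype assignment,
keeping each mouse's longitudinal record, covariates and the
phenotype-side covariance intact, and takes the 0.95 empirical quantile of
the per-permutation max |Z|. Genotype columns are mean-imputed inside
permutations so the same observations enter every replicate (with the drop
rule, a permuted incomplete column would change which mice are excluded,
breaking exchangeability of the max statistic). Fixed effects are re-fit
per SNP within each permutation; variance components are plugged in from
the unpermuted null. The genomic inflation factor is median(Z²)/0.4549
(the χ²₁ median). Suprathreshold SNPs under 2 Mb apart chain into loci;
the locus peak is the smallest p, ties broken by lowest position.

### Degrees of freedom

The time-course test (fixed day effect, no kinship terms) reports a
Satterthwaite-type t test: df = 2g²/Var(g) with g the estimated variance
of the day coefficient, Var(g) by the delta method from the numeric
gradient of g in the variance parameters and the inverse observed REML
information. Kenward-Roger would differ negligibly at panel scale; the
df method is recorded in the output.

## Endpoint normalization

Endpoints are normalized by the rank-based inverse normal transform with
Blom offsets, Φ⁻¹((r − 3/8)/(n + 1/4)), tied values sharing their mean
rank; percent active presses (100·active/(active+inactive)) is undefined
when a mouse made no presses and such cells are excluded before the
transform. Association mapping normalizes within each testing day (the SNP
effect is a within-day contrast). The per-day transform centers every day
at zero by construction, so the time-course test — whose target *is* the
between-day trend — instead normalizes pooled across all mouse-days, which
is rank-equivalent within day and preserves the trend. This distinction is
load-bearing: a per-day-normalized day-trend test would be identically
powerless.

## Molecular traits

Transcripts are kept when ≥ 6 reads and TPM > 0.1 in ≥ 20% of samples
(boundary inclusive, TPM strictly greater). Exon inclusion ψ =
inclusion/(inclusion+exclusion); exons need ≥ 5 reads in every sample and
non-zero SD of ψ, and each transcript contributes its highest-SD exon.
Editing sites are retained when ≥ 10% of samples have data; the
ascertainment rate is the mean detected fraction over retained sites, in
percent. Retained trait rows are quantile normalized per trait by the same
rank-inverse-normal transform (plain, not GC/length-conditional: the
synthetic data carry no GC structure). Mapping uses a single-random-effect
kinship LMM per trait: the sample-level GRM is eigendecomposed once and
reused, the variance ratio δ is REML-profiled per trait on a log grid with
bounded refinement, and each SNP is a rotated weighted regression with the
residual variance re-profiled per SNP. Covariates are sequencing batch and
sex. cis = within 2 Mb of the trait anchor (transcription start for
expression; exon midpoint for ψ; site position for editing). Trans-hotspot
bins are tested against a Poisson null with the genome-wide mean count of
distinct regulated genes per bin and Benjamini-Hochberg FDR; enrichments
(cis eQTL x cis ψQTL coincidence at the gene level; editing-site region
class x coincidence) are Fisher exact tests, with a 0.5 continuity
correction on the odds ratio only when a cell is zero (flagged). A
coincidence window of 0 degenerates to exact co-location.

## TWAS, fine-mapping, colocalization

Cis weights are fit on covariate-residualized expression averaged to
strain means. Residualization follows Frisch–Waugh (expression *and*
expanded dosages are projected off batch/sex), so an exactly cis-linear
expression stays exactly linear in the residualized dosages. Two candidate
models — a BLUP-style ridge whose penalty m(1−h²)/h² is tied to the cis
heritability estimated on the training strains (zero weights when h² is
undetectable, < 0.01), and a top-SNP model — compete in nested 5-fold
cross-validation: inner folds select the method, outer folds produce the
reported predictive R², so model selection cannot inflate it (under pure
noise the reported R² is ≤ 0 in ~90% of replicates). The gene-level
statistic is Z = w'z/√(w'Rw) with R the panel LD of the cis SNPs;
Bonferroni significance is over genes tested, and genes with no predictive
model are not tested.

Gene fine-mapping enumerates all causal-gene subsets S of a region (≤ 20
genes) under z|S ~ N(0, R + W·R_S R_S') with independent per-gene causal
prior 1/G and reports pip(g) = posterior mass of subsets containing g,
the empty model included. Colocalization assumes one causal variant per
study per window (≤ 200 SNPs per side); the LD-aware Bayes factor
N(z; 0, R + W r_j r_j')/N(z; 0, R) reduces exactly, by Sherman–Morrison
with R⁻¹r_j = e_j, to logBF_j = ½[W z_j²/(1+W) − log(1+W)], a function of
the marginal Z alone; configurations {null, causal@1..m} get a uniform
prior and CLPP_j is the product of the two studies' posteriors. The
effect-size prior variance W defaults to 5.2² on the noncentrality scale —
the scale eCAVIAR-class methods use — so genome-wide-significant signals
dominate the null; a near-unit W would make the null model absorb
essentially any realistic signal and no planted effect could ever reach
the CLPP > 0.01 or pip > 0.8 support thresholds.

## The synthetic panel

The generator emulates a hybrid-diversity-panel design: 32 inbred + 52
recombinant-inbred strains by default, ~6 mice per strain (3 per sex), 10
daily sessions, age ~ N(11.3, 0.5²) weeks, lever side counterbalanced
across strain × sex, chambers assigned at random, cohorts in blocks of 3
strains. The desk-scale genome is 4 chromosomes × 50 Mb at 100 kb spacing
(~2,000 SNPs; the emulated study used ~340,000): SNPs form 20-SNP
exchangeable LD blocks with within-block latent correlation 0.8 —
controllable LD for threshold and permutation behavior, with no claim of
matching real mouse LD. RI strains are per-chromosome two-founder mosaics
with Poisson(2) crossovers. Genotype calls are 0/2 (inbred homozygotes),
2% missing at random by default. Default truth: variance components
(0.15, 0.15, 0.004, 0.004, 0.01, 0.01) plus residual 0.5 — roughly equal
kinship and individual shares, intercept-slope correlation ~0.4, per-day
phenotypic variance ~1.3 with about a third of strain-level variance
genetic, values chosen once as representative of a moderately heritable
normalized behavioral endpoint. Phenotypes are drawn exactly from the
mapping model (rotated per-eigencomponent 2×2 draws), so parameter
recovery is a clean test of the estimator. Planted QTLs are calibrated
against the analytic day-averaged phenotypic variance so "a QTL explaining
10% of variance" holds exactly regardless of the chosen SNP's allele
frequency.

What the generator does not emulate — realistic recombination maps and LD
decay, X-dosage effects, count-valued session data (counts are attached
only as monotone transforms of the latent endpoint for exercising the
rank-based pipeline), catheter attrition, GC/length biases in expression —
bounds what passing tests show: they validate the estimators and their
calibration under the stated model, not robustness to real-data artifacts.

## Problem sizes used by the test suite

Oracle-equivalence tests run at ≤ 500 observations against an
independently coded dense-covariance implementation (agreement to 1e-6).
Parameter recovery uses 100 fresh panels at the emulated study scale
(84 strains × 6 mice × 10 days), asserting each component's mean within 3
Monte-Carlo SEs of truth. Null calibration scans 10⁴ LD-free SNPs on a
100-strain panel (KS uniformity, λ = 1 ± 0.05) and measures the familywise
error over 60 null panels with per-panel permutation thresholds. The power
computation — 100 strains, 10% effect, single-GRM scan against a 5%
genome-wide threshold from 100 permutations — runs 150 replicates in the
test suite and 200 in `scripts/acceptance.py`.

## Known limitations

Wald normal tails are slightly heavy at strain-level effective sample
sizes (the implied per-SNP threshold sits ~1.4–1.8× above the Šidák bound
on LD-free panels); the permutation threshold absorbs this in practice.
Per-SNP REML (rather than plugged-in components) and Kenward-Roger df are
not implemented. The dense fallback for unbalanced data scales as O(N³)
and is intended for behavioral-scale, not genome-scale, fits. Subset
enumeration in fine-mapping is exponential in region size and capped at 20
genes.
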