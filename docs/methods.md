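# Methods

## Model and procedure

`casevar` targets SNPs whose genotype groups differ in *phenotypic
variance* rather than mean. For a dichotomous disease phenotype the
procedure is two-staged because raw 0/1 outcomes carry both additive
polygenic structure and fixed-effect structure (sex, cohort, ancestry)
that would masquerade as variance heterogeneity.

### Stage 1: liability partition

The observed 0/1 phenotype is modelled with a one-component linear mixed
model, `y = Xβ + g + e`, `g ~ N(0, A σ²_g)`. The GRM is

    A_jk = (1/m_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

with `p_i` the sample allele frequency and `m_jk` the per-pair count of
SNPs non-missing in both samples; monomorphic SNPs are skipped. Because
columns are centred at sample frequencies, GRM rows sum to zero exactly, so
the off-diagonal mean is −mean(diag)/(n−1) — an O(1/n) structural feature,
not a bug, and the property the unit tests assert.

Relatedness pruning is greedy: while any off-diagonal exceeds the cutoff
(default 0.15), remove the sample participating in the most violating
pairs, ties broken toward the lower sample index. This is deterministic;
the exact removal order of equivalent tools is unspecified, so determinism
was preferred. *Caveat:* off-diagonal GRM noise has SD ≈ 1/√m. The 0.15
default presumes a chip-scale panel (m ≳ 10⁴); on small simulated panels a
cutoff well above 1/√m must be passed explicitly or pruning will remove
unrelated samples wholesale.

PCs are the top eigenvectors of the pruned GRM (default 10), computed after
pruning so a single sample set flows through the whole stage; the same
eigendecomposition is reused for the REML rotation.

REML is average-information with safeguards: one EM step first; if an AI
step leaves the parameter space the violating component is pinned at a
small positive floor (non-negativity by projection) and a constrained
Newton step is taken in the free component — this reaches boundary optima
(σ²_g ≈ 0) directly instead of crawling toward them with EM; any step that
would decrease the restricted likelihood falls back to EM, so the
likelihood path is non-decreasing. Convergence: relative log-likelihood
change < 1e-8, max 100 iterations; non-convergence is flagged, never
silent. BLUP is `ĝ = σ̂²_g A V⁻¹(y − Xβ̂)` and the residuals
`e = y − Xβ̂ − ĝ = σ̂²_e V⁻¹(y − Xβ̂)` — hence exactly orthogonal to every
fixed-effect column and mean-zero, which the tests verify.

Residuals live on the observed 0/1 scale; only the heritability estimate is
transformed to the liability scale, by
`h²_l = h²_obs · K²(1−K)² / (z² P(1−P))` (prevalence `K`, sample case
fraction `P`, `z` the standard normal density at the liability threshold),
which also corrects for case-control ascertainment. The variance scan is
median-based and scale-robust, so the choice of residual scale is benign.
The transform is a first-order approximation: in simulation its bias is
smallest near K = 0.5 (measured mean estimate 0.294 at K = 0.5 vs 0.286 at
K = 0.3 for a true 0.3 over 20 replicates), which is why the recovery
checks sample the population at K = 0.5.

### Stage 2: Brown-Forsythe scan

Per SNP, `Z_i = |e_i − median(e in genotype group of i)|` and

    T² = (N−k) Σ_j n_j (Z̄_j − Z̄)² / [(k−1) Σ_i (Z_i − Z̄_g(i))²].

Genotype groups smaller than `group_min` (default 2) are dropped with k and
df reduced; k < 2 or a zero denominator yields an explicit skip reason
("monomorphic" / "degenerate") rather than a p-value. P-values come from
F(k−1, N−k): the statistic as written is the Brown-Forsythe F, exact-level
under normal groups and conservative at finite N; the χ²ₖ₋₁ limit of
(k−1)·T² is honoured as a large-N property (KS-tested at N = 10,000) rather
than used for inference. Median centring (not mean) is deliberate — it is
what makes the test robust to the decidedly non-normal residuals of a 0/1
phenotype.

Thresholds: 5.0e-08 genome-wide and 2.5e-05 chip-wide (a
permutation-derived suggestive level for a ~196k-SNP immune-disease
genotyping chip). λ_GC is the median of the 1-df χ² quantiles implied by
the p-values over 0.4549; multi-df statistics pass through their p-values
first. Lead SNPs are greedy 1-Mb clumps by smallest p.

**A calibration caveat found in development:** with an exactly balanced
case/control ratio the stage-1 residuals are symmetric-bimodal and every
genotype-group median falls in a density gap; median estimation then has
non-vanishing variance and the scan becomes severely conservative
(λ ≈ 0.14 observed). At realistic case fractions (the emulated study's is
0.17) the median sits inside the continuous control cluster and the scan is
well calibrated (pooled type-I 0.053, λ 1.006 at n = 2000; 0.043, λ 1.025
at n = 1000). Balanced 50/50 designs should be analysed with caution.

### Cross-validation

Ten iterations of case/control-stratified 50/50 splits; both halves rerun
the *entire* pipeline (GRM, pruning, PCs, REML, residuals, scan at the
candidate SNPs). "Discovered" credits an iteration when either half passes
the threshold, validation is P < 0.05 in the complementary half; both
halves' p-values are kept in the report so either convention can be
reconstructed. Per-iteration seeds descend from the master seed. Note that
halves overlap ~50% across iterations, so half-run p-values are dependent;
calibration checks on the null validation rate use a binomial band widened
for that design effect.

### Interaction tests

Logistic model `logit P(case) = µ + βX + β_g G + β_f F + β_gf G:F` with G a
categorical 3-level genotype factor (the coding that yields df = 2 against
sex, 10 against six cohorts, 8 against five, 4 for GxG). `β_gf = 0` is
tested by likelihood ratio with df equal to the number of estimable
interaction columns; empty genotype-by-factor cells drop their column with
the df reduction recorded. A block Wald test is reported as a secondary
output. Complete or quasi-complete separation (common for strong planted
interactions: the rare double-homozygote cell saturates) flags the result
non-estimable rather than reporting an unstable p. The logistic "random
error" is Bernoulli variation and carries no parameter. Screens over k lead
SNPs apply a Bonferroni threshold of 0.05/k per factor.

## Synthetic data

The simulator draws independent biallelic SNPs under HWE with frequencies
uniform in `maf_range` (no frequency spectrum or LD is claimed — SNPs are
exchangeable, which is exactly what null-calibration needs and a known
limitation for anything LD-dependent). Liability is

    l = β_sex·1[male] + cohort effect + g_add + Σ_v (β_add g_v + β_gxe g_v E_v) + ε,

with the realized polygenic values rescaled so their variance fraction
equals `h2_liability` exactly, `ε ~ N(0, 1−h²)`, and each variance-QTL's
exposure `E_v ~ Bernoulli(exposure_prevalence)` latent — downstream stages
never see it, which is the point: the scan must flag the interaction
without the exposure. Cases are `l > Φ⁻¹(1−K)` (threshold of the
unit-variance polygenic core; fixed effects and vQTL terms shift
individuals relative to it). Ascertainment draws the target case/control
counts per cohort from an oversampled population and raises a named error
on shortfall; omitting the targets yields a population sample. All
randomness descends from one seed via spawned generators.

Defaults mirror the emulated six-cohort study: prevalence K = 0.01,
GRM cutoff 0.15, 10 PCs, thresholds 5.0e-08 / 2.5e-05, 10 CV iterations,
and a `table1_config()` helper reproducing the six cohorts' ascertained
case/control counts (totals 3,323 / 15,785 / 19,108) and per-cohort male
fractions (combined 59.5%). Test and acceptance simulations raise K to
0.2–0.5 purely to keep the pre-ascertainment population small; ascertained
counts, not K, drive the checks that use them.

What passing tests show — and what they do not: calibration, power,
recovery and df bookkeeping hold under independent SNPs, binary latent
exposures and Gaussian liability residuals. Real data add LD (clumping
windows matter), population structure beyond 10 PCs, genotyping artefacts,
and exposures that are neither binary nor independent of covariates; none
of those are exercised here.

## Problem sizes and numerical choices

- Null calibration: five replicate pipelines of 2,000 samples x 2,000 SNPs
  pooled, because λ_GC from a single 2,000-SNP scan has sampling SD ≈ 0.05
  — a [0.95, 1.05] band is only meaningful on pooled scans.
- Heritability recovery: n = 2,000, m = 1,000 (200 causal), 10 replicates.
- χ² limit: N = 10,000 Gaussian null residuals, 2,000 SNPs — the claim
  concerns the statistic's distribution, so no mixed model is fitted.
- Cross-validation demonstration: n = 2,000 (halves of 1,000), m = 1,200
  so the 0.15 relatedness cutoff sits ≈ 5 SD above GRM noise.
- REML floor 1e-8·var(y); convergence tolerance 1e-8; HWE exact test
  anchored at the conditional mode so the recurrence cannot overflow;
  F-test p-values floored at the smallest positive double.

## PLINK conventions

bed is SNP-major, standard 2-bit encoding (00 two copies of A1, 01 missing,
10 het, 11 none); dosage counts A1, which the fixture writer always sets to
the simulated minor allele, so round-trips are exact. fam uses 1=male /
2=female and 1=control / 2=case / 0 or −9 missing; bim positions are
1-based. Merging intersects variant ids, flips dosages where alleles are
swapped, and drops (with a warning and a count) variants whose alleles
cannot be reconciled by a swap. HWE is tested on all samples by default —
`hwe_controls_only` switches to the controls-only convention. QC order is
one deterministic pass: sample call rate, then variant MAF / call rate /
HWE / autosome filters evaluated jointly on the sample-filtered matrix,
which makes the filter idempotent.
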