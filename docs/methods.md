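# Methods

## Model

`rrgwas` fits a random regression mixed model (RRM) to a longitudinal
trait and then tests each SNP for a time-varying additive effect.

A record of individual *k* at age *t* is decomposed as

    y_tk = F_i + f(t) + r_a(t; k) + r_pe(t; k) + e_tk

* `F_i`: time-constant fixed factor effects (e.g. birth-year or farm
  classes), entered as dummy columns with the first level dropped.
* `f(t)`: a fixed population-mean curve.
* `r_a(t; k)`: the additive-genetic curve of individual *k*; its
  coefficients `a_k` have covariance `A ⊗ D` across individuals, with `A`
  the pedigree numerator relationship matrix.
* `r_pe(t; k)`: the permanent-environment curve, coefficients `p_k` with
  covariance `I ⊗ P` (individual-specific, shared across that individual's
  repeated records).
* `e`: i.i.d. residual with a single variance `σ²_e`, homogeneous across
  ages. Stage-specific residual variances are deliberately not offered —
  the model's residual structure is `R = I σ²_e`.

All curves use the normalized Legendre basis
`φ_l(x) = sqrt((2l+1)/2) P_l(x)` on age standardized linearly to
`[−1, 1]`; this is the Kirkpatrick covariance-function convention standard
in animal-breeding RRMs, and makes `∫ φ_i φ_j = δ_ij`. Ages outside the
standardization interval raise rather than extrapolate. "Order" means
polynomial degree; a curve of order *m* has *m*+1 coefficients, and orders
are capped at (number of distinct ages − 1) — with four measurement ages a
degree-5 curve is not identifiable, so attempting one is an error, not a
warning.

## Relationship matrix

`A` is built by the tabular method (founders 1 on the diagonal,
`a_ii = 1 + 0.5 a_sd`, `a_ij = 0.5 (a_js + a_jd)`); its inverse is built
directly from the pedigree by Henderson's rules with the inbreeding
correction, using the Mendelian-sampling variance
`m_i = 1 − 0.25 (a_ss + a_dd)` over the known parents. Individuals that
appear only as parents are auto-inserted as founders. Non-phenotyped
pedigree members stay in the equations (they link relatives and receive
breeding-value estimates); the REML likelihood itself uses the A-submatrix
of phenotyped individuals, which is the exact marginal covariance. A
genomic relationship matrix is intentionally out of scope: the model is
defined on pedigree A.

## REML

Variance components `(D, P, σ²_e)` maximize the restricted likelihood.
The engine exploits that `V` is *linear* in every parameter:

* **Balanced data** (every individual measured at the same ages, the
  designed study layout): with `A = U S U'`, rotating records by
  `U' ⊗ I_T` decouples the model into independent per-individual `T × T`
  blocks `V_b = s_b Φ_a D Φ_a' + Φ_p P Φ_p' + σ²_e I`. Each iteration is
  O(n), so a 400-individual fit takes seconds.
* **Unbalanced data** falls back to a single dense block over all records.
  Both paths share the same score/average-information code and agree with
  a dense explicit-V oracle to ~1e-10 (tested).

Updates are average-information (AI) Newton steps with step halving that
never accepts a likelihood decrease; after every step `D` and `P` are
projected to the nearest PSD matrix (eigenvalue floor `1e-8 · s²_y`) and
`σ²_e` floored likewise. Convergence: `|Δ logRL| < 1e-8` or maximum
relative parameter change `< 1e-6`; default cap 200 iterations, after
which a diagnostic error carries the logRL trajectory. If no improving
step exists along the AI direction the fit is declared converged at a
boundary (typical when a component is truly ~0). Starting values are
scale-aware: `D = 0.3 s²_y I/(m_r1+1)`, `P = 0.3 s²_y I/(m_r2+1)`,
`σ²_e = 0.4 s²_y`, with `s²_y` the pooled phenotypic variance.

Model selection: `AIC = −2 logRL + 2 n_vc` and
`BIC = −2 logRL + n_vc log(N_records)` with `n_vc` the number of free
(co)variance parameters; `select_orders` fits every candidate order triple
and picks the BIC argmin (AIC reported). Because REML likelihoods with
different fixed-effect designs are not comparable, candidates that change
`order_fixed` should be compared with that caveat in mind (the classical
test-day-model practice of ranking whole candidate specifications by
AIC/BIC is followed).

## Genome scan

Each SNP adds a fixed term `x_k · SNP(t)`, `SNP(t) = Σ_l η_l φ_l(t*)`,
with `x_k` the 0/1/2 dosage (mean-imputed where missing). Variance
components are held at the null REML estimates — the standard two-step
strategy — and the augmented mixed model equations are re-solved *exactly*
per SNP via a Schur complement on the Cholesky factor of the null
coefficient matrix (no score-test approximation; at chip scale with a few
hundred individuals exactness is cheap). The joint Wald statistic
`W = η̂' Cov(η̂)⁻¹ η̂` with `Cov(η̂) = σ²_e M⁻¹` (M the Schur complement) is
referred to chi-square with `snp_order + 1` degrees of freedom.

The SNP-curve order defaults to `min(order_fixed, n_distinct_ages − 1)`,
i.e. the SNP curve shares the mean-curve order by default but is
configurable. A fixed-VC likelihood-ratio mode (`method="lrt"`) exists for
cross-checking the algebra; with known V the two statistics coincide.
Monomorphic SNPs and SNPs whose covariates are collinear with the null
design (Schur complement eigenvalue below `1e-10` of its scale) are
reported as NOT TESTABLE (`p = NaN`) rather than raising, and are excluded
from both counts of the significance rule. Additive coding only; no
dominance term.

## Significance

The headline rule is the proportion-based threshold
`p_thr = FDR × n / m`, with `n = #{p < 0.05}`, `m` the number of testable
SNPs, and FDR defaulting to 0.05; a SNP is significant when
`p < p_thr` (strict). This is not classical step-up FDR control; it is
implemented verbatim as the package's primary rule, and classical
Benjamini–Hochberg (via `statsmodels.stats.multitest`) is provided
alongside as the standard comparator.

## Quality control

Six filters in a fixed, recorded order: individual missingness (> 10%),
then per-SNP: missing map position, call rate (< 95%), MAF (< 1%),
Hardy–Weinberg exact-test p (< 1e-6), Mendelian error rate (> 2%); then
duplicate-position collapse (highest call rate kept, ties broken by
snp_id). Sample filters run before variant filters, mirroring PLINK's
behavior; the order is a convention of this package and every removal is
tallied per criterion. The HWE test is the exact conditional test
(two-sided sum of heterozygote configurations no more probable than the
observed one, no mid-p), computed with log-gamma arithmetic and verified
against a rational-arithmetic enumeration oracle. Mendelian rates use
trios where both parents are genotyped (one comparison per trio per SNP)
and parent–offspring duos otherwise (error = opposite homozygotes).
Missing dosages are never imputed before QC; mean imputation happens only
at scan/PCA time.

## Stratification

Genotype PCA with Patterson scaling: each SNP column is mean-imputed,
centered by `2p̂` and divided by `sqrt(2p̂(1−p̂))`; scores come from the SVD
with signs fixed by making each component's largest-magnitude loading
positive (deterministic output). The first two PCs are attached as
time-constant covariates by default (configurable); PC-by-age
interactions are not modeled.

## Synthetic data generator

The generator emulates the targeted study design — a pedigreed population
with body weight at 0/6/12/18 months — and is itself first-class, tested
code:

* **Pedigree**: discrete non-overlapping generations; sex alternates with
  birth order (making generation sizes exactly predictable); each dam is
  mated to one random sire; configurable founders, generations and litter
  size.
* **Genotypes**: gene dropping. Founder haplotypes are Bernoulli draws at
  per-SNP frequencies uniform on `maf_range`; offspring inherit one random
  allele per parent per SNP, so Mendelian consistency is exact until the
  optional genotyping-error and missingness layers are applied — which is
  what lets the QC Mendel filter be exercised honestly.
* **Phenotypes**: drawn from the exact generative RRM: `a ~ N(0, A ⊗ D)`
  via Cholesky factors of A and D, `p ~ N(0, I ⊗ P)`, i.i.d. residuals,
  plus optional QTN curves `x · SNP(t)` and factor effects. A truth ledger
  (all drawn coefficients) allows exact reconstruction of every record —
  asserted in the tests.

One master seed spawns independent sub-streams (pedigree / gene drop /
phenotypes), so components can be regenerated in isolation. Default
parameters are conventions chosen to look like a beef-cattle growth study:
mean weights ≈ 40/190/330/430 kg at the four ages (the default fixed curve
interpolates these), `D = [[300, 120], [120, 120]]`,
`P = [[200, 80], [80, 100]]`, `σ²_e = 150` kg², giving phenotypic SD
growing from ≈ 20 to ≈ 33 kg and `h²(t)` ≈ 0.3–0.5. They are invented
plumbing — not estimates from any real dataset, which reports none.

What the generator does **not** emulate: linkage disequilibrium beyond
pedigree co-transmission, selection, genotype-by-environment interaction,
age-heterogeneous residuals, and real chip ascertainment. Passing tests
therefore demonstrate correctness of the estimator and test under the
model's own assumptions, calibration under polygenic family structure, and
robustness to the simulated missingness/error processes — not performance
under model misspecification.

## Problem sizes and numerical choices

The statistical checks run at deliberate desk scale, chosen as the
package's own test conditions: solver-exactness on 100 random instances of
≤ 20 individuals; REML recovery and scan calibration/power at 402
individuals × 4 ages (134 founders, two generations) with 2,000 null SNPs
or 300 SNPs + 1 QTN over 20 seeds. The planted QTN adds a constant 14 kg
per allele at MAF ≈ 0.3, i.e. ≈ 4–11% of phenotypic variance depending on
age.

Degenerate inputs: all-missing SNPs make MAF/imputation raise; a
single-age dataset collapses to an ordinary animal model in which only the
total variance is identified (the engine still converges; the split is
arbitrary); zero-variance traits yield NaN skewness/kurtosis in the
descriptive report rather than errors. Ties in duplicate-position removal
are broken lexicographically so QC is reproducible. λ_GC uses the exact
chi-square(1) median from scipy rather than the 0.4549 approximation.

## Known limitations

* Eq-by-eq exact per-SNP refits scale linearly in SNPs with a dense
  Cholesky backsolve; hundreds of thousands of SNPs at thousands of
  individuals would want a sparse or low-rank update backend.
* The Wald test treats null variance components as known; this is the
  standard two-step approximation and is slightly conservative/liberal in
  small samples (the calibration tests bound the effect at the tested
  scale).
* Per-group mean curves (`f(t)_j` varying by group) are not fitted by
  default; factors act as intercept shifts. This matches the minimal
  published model description; a per-group-curve option would be the
  natural extension.
* BIC/AIC order selection refits variance components per candidate
  (joint, not sequential, re-estimation).
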