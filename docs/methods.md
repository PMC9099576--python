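# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Stage 1: repeatability animal model and HYS BLUEs

Each phenotype is analyzed univariately with fixed NSL (lactation number x
stage of lactation; stage classes are 30.4-day bins — 365/12 — with class
13 open-ended to the 540-day editing horizon, and lactation capped at
"fourth or later", giving 52 classes) and fixed HYS, plus additive genetic,
cow permanent-environment and residual effects.

*Identifiability.* NSL and HYS jointly contain the intercept. During both
sampling and solving, the first NSL level is held at zero; afterwards the
NSL solutions are recentered to sum to zero and the shift is moved into the
HYS block. HYS BLUEs are therefore directly comparable stand-alone
environment levels, which is what the downstream covariates require.
Reported standard errors are square roots of the coefficient-matrix inverse
diagonal times the residual variance, for the constrained parameterization;
the recentring shift is not propagated into them.

*Gibbs sampler.* Location effects are updated by single-site Gauss–Seidel
sweeps on the mixed-model equations with the inverse relationship matrix
held in sparse (CSR) form; variances are drawn from scaled-inverse
chi-square full conditionals with the flat-prior convention df = −2,
scale = 0. The default chain is 35,000 iterations, 5,000 burn-in, thinning
10; the desk-scale pipeline uses 800/300/2 per phenotype, which the
parameter-recovery tests show is sufficient at these data sizes. Geweke
z-scores (first 10% vs last 50%, AR-based spectral density at frequency
zero with AIC order selection) are attached to every returned component; a
convergence warning fires only when all three components exceed the
threshold.

*Editing.* All rules — the 540-day cutoff, the minimum records per cow, the
minimum HYS size, and the 5-SD spectral outlier rule — are iterated jointly
to a fixed point, so editing is exactly idempotent. The spectral rule can
optionally be restricted to a single first pass
(`EditThresholds(iterate_spectral=False)`), recomputing no column
statistics after removals. The pipeline's desk-scale defaults relax the
class-size thresholds (8 records per cow, 8 per HYS) because simulated
contemporary groups of ~20 records would otherwise be halved; the
full-scale defaults (12 / 20) remain on the `EditThresholds` type. A
reduced-data rule for variance-component estimation (herds with at least a
configurable number of HYS classes; classical value 30) is available and
off by default at desk scale.

*Two-step estimation.* Variance components are estimated once per phenotype
and then fixed for the BLUE extraction solve — the standard two-pass
design. The MME coefficient matrix is dense; this is intentional: the
package targets desk-scale experiments (≈ 10^3–10^4 equations), not
national evaluations.

## Stage 2: hysDYD and EDC

DYDs are NSL-corrected daughter means per sire-by-HYS cell; the HYS effect
is deliberately left in, since it is what the stage-3 environmental kernel
models. The effective daughter contribution is the repeatability-weighted
daughter count `EDC = sum_d n_d/(n_d + lambda_p)` with
`lambda_p = se2/(sa2 + sp2)`: each daughter's contribution rises from
n/(n+lambda_p) toward 1 with her record count. Published EDC formulas
differ in how they treat dam information and multi-generation progeny; the
interface accepts any callable strategy, and the default is this monotone,
calibrated measure, which is all the downstream uses (a 1.6 cutoff and
residual weighting) require. EDC enters stage 3 as residual weights,
Var(eps_ij) = seps2 / EDC_ij. The four condensation filters are applied
jointly and iterated to a fixed point, which is order-independent because
each rule only ever removes rows.

## Kernels

VanRaden method 1 with observed allele frequencies; markers with call rate
< 0.90 or MAF < 0.05 are dropped and remaining missing genotypes
mean-imputed per marker. The environmental kernel is the literal linear
kernel E = XX' on standardized covariates. Two interpretation points are
configurable:

- `scale_by_p` divides E by the number of covariates. Without it, the
  AWN kernel (p = 100–1060 columns) has diagonal ≈ p while PROD (p = 2) has
  diagonal ≈ 2, so raw variance components are not comparable across
  models; predictions and accuracies are unaffected because the scale is
  absorbed by the variance parameter.
- Principal-component scores are re-standardized to unit variance before
  forming XX' (default), treating them like every other covariate; the raw
  behaviour (`restandardize_pc=False`) reproduces the AWN kernel exactly at
  full rank.

The interaction kernel is the element-wise (Hadamard) product of the
observation-level genetic and environmental kernels, PSD by the Schur
product theorem.

## RKHS Gibbs sampler

Each kernel is eigendecomposed once (K = FF', eigenvalues below
1e-8 x max dropped — PC kernels are legitimately rank-deficient) and the
effect is sampled as regression coefficients on F. Two implementation
choices matter for accuracy per CPU second:

- Before sampling, each term's factor columns are rotated into the
  eigenbasis of U'WU on the training rows. The coefficient prior is
  isotropic, so the model is unchanged, but the term's coefficients become
  conditionally independent and the single-site sweep performs an exact
  block update — mixing no longer degrades with kernel rank.
- Posterior means of coefficients and intercept are Rao-Blackwellized
  (averages of full-conditional means rather than draws).

Together these make the fixed-variance sampler agree with closed-form
Gaussian posteriors to ~1e-3 within a few tens of thousands of iterations,
which is how the oracle tests pin the implementation down.

Variance full conditionals are scaled-inverse chi-square. The default
hyper-prior is mildly informative (df = 5, prior variance split: half the
phenotypic variance to the residual, the rest equally across kernel terms,
each scaled by the mean kernel diagonal); a flat prior (df = −2, scale 0)
is available but discouraged for low-rank terms, whose variance then has
too few degrees of freedom to be stable. Chains default to 75,000 /
25,000 / 10; pipeline fits use 1,500 / 500 / 2. The residual variance is
floored at 1e-12 inside the sampler so degenerate (constant) data collapse
gracefully.

Masked (validation) rows are simply excluded from the likelihood; their
sires and HYS classes remain in the kernels, so their effects are inferred
through the covariance structure — this is what makes prediction into new
herds possible, and a byte-equality test confirms masked phenotypes cannot
leak into the fit.

Variance *proportions* are ratios of posterior-mean component variances
(kernel terms plus residual). With unscaled E kernels these shares inherit
the kernel-scale caveat above; comparisons across models should either use
`scale_by_p` kernels or be read qualitatively.

## Cross-validation design

Sampling is uniform without replacement over sires and over herds; a
sampled herd turns all of its HYS classes "new". The scheme is four
*sections*, not four equal folds: with sampling fractions ps and ph the
expected record shares are (1−ps)(1−ph), (1−ps)ph, ps(1−ph), ps·ph by
linearity of expectation, independent of how records are distributed. At
the reference sizes (100/483 sires, 100/406 herds) the expected training
share is 59.8%. Replicate seeds spawn deterministically from the master
seed; all models see the same partitions, so per-replicate accuracies are
paired across models. Degenerate sections (empty, or constant predictions)
are recorded as missing rather than silently zero.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a tuning
surface. Defaults: 200 unrelated genotyped sires x 6 daughters (unknown
dams), 60 herds over 2 years x 4 calendar-quarter seasons, 400 independent
SNPs with allele frequencies U(0.05, 0.5), 100 wavenumbers, 12–15 monthly
records per cow.

- Trait variance components are (sa2, sp2, shys2, se2) = (2, 2, 3, 6) for
  milk yield (h2 = 0.20, r2 = 0.40) and (0.11, 0.23, 0.08, 0.66) for
  somatic cell score (h2 = 0.11, r2 = 0.34) — classical estimates for
  these traits, including the small HYS variance of SCS.
- Wavenumber heritabilities follow a piecewise profile imitating the
  canonical milk-FTIR shape (plateau ≈ 0.18, a null water-absorption band,
  a higher plateau ≈ 0.35, a second narrow null band, an irregular tail);
  per-wavenumber permanent-environment variance is 0.4 x sa2 so
  repeatability tracks heritability and null bands stay null.
- A latent herd-environment factor f (default 3 dimensions, 70% of its
  variance persistent at herd level) drives both trait HYS effects (90% of
  HYS variance by default; 100% in the engineered qualitative-ordering
  configuration) and spectral HYS effects (50%), with independent noise
  filling the remainder. This is the mechanism that makes spectra
  informative about trait environments, and its share is the knob that
  controls how much an environmental kernel can possibly help.
- Sire trait breeding values are sums of SNP effects, rescaled so their
  realized variance equals sa2 exactly (exact-variance scaling, as in
  common trait simulators); daughters get half the sire value plus a
  Mendelian deviate of variance 0.75 sa2 (unknown-dam convention).
  Wavenumber breeding values are pedigree-only normals: their genetic
  component is removed by stage 1 and never predicted genomically.
- Daughters of a sire are clustered in 2 herds and calve in seasonal
  batches (group start month ± 2). Without batch calving, sire-by-HYS
  cells almost never contain more than one daughter and the EDC ≥ 1.6
  filter empties the condensed dataset; with it, the condensed table has
  the qualitative shape of real progeny-test data (cells of 2–4 daughters,
  EDC ≈ 1.6–2, sires in ~8 HYS across 2 herds).
- Optional sire-by-environment interaction is a reaction norm: sire slopes
  on f with total variance gxe_sd^2, zero by default.

What the generator does **not** emulate: FTIR absorbance units or
instrument noise, linkage disequilibrium between markers, genetic
correlations among traits and wavenumbers, dam pedigree information,
herd-size heterogeneity, and cow culling/turnover (cows persist for one
recording spell). Passing tests therefore demonstrate internal correctness
and the qualitative behaviour of the design under the stated generating
mechanism — not performance on real milk-recording data.

## Problem sizes and determinism

Test and pipeline problem sizes (hundreds of sires, ~15,000 test-day
records, 100 wavenumbers, 5 replicates, short documented chains) were
chosen so a full study runs in about 90 seconds on one core while keeping
every estimate comfortably inside its tolerance; the full-scale chain
settings remain the type-level defaults. All randomness flows from
explicit seeds: fixed-seed byte reproducibility is asserted for the
generator, the samplers, and the replicated cross-validation.

## Known limitations

- The dense-matrix MME path does not scale past ~10^5 equations by design.
- The EDC is an approximation to published effective-daughter-contribution
  algebra (see stage 2 above), adequate for threshold-and-weight use.
- Flat variance priors in the RKHS sampler are unstable for kernels of
  rank ≤ ~5; use the default informative prior there.
- Variance proportions mix kernel scales unless `scale_by_p` is set.
- Posterior-mean heritabilities carry the usual small positive skew of
  flat-prior variance ratios at moderate family counts; the recovery tests
  quantify it (mean absolute error ≈ 0.04 at 600 cows).
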