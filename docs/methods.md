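# Methods

This note documents the statistical machinery behind gsemkit: the models,
the estimation choices that were genuinely open, the synthetic data the
tests rely on, and what passing those tests does and does not establish.

## Summary-statistics harmonization

Each trait's summary statistics are restricted to a reference SNP panel and
re-signed so that every Z-statistic refers to the panel's first allele.
Records match the panel either directly, with effect/other alleles swapped
(sign flip), or after strand complementation (A<->T, C<->G per base).
Strand-ambiguous variants (A/T and C/G pairs) are removed outright: without
allele frequencies their orientation is undecidable, and frequency-based
resolution is deliberately out of scope. Filters: imputation INFO >= 0.9
and MAF >= 0.01 (both applied only when the column exists), duplicate SNP
ids keep the first occurrence, and a Z is derived from beta/SE or, failing
that, from a signed beta with its p-value (z = sign(beta) * Phi^-1(1-p/2)).
Case-control traits analysed on effective sample size
4/(1/cases + 1/controls) (summed over cohorts for meta-analyses) carry a
sample prevalence of 0.5 downstream, the ascertainment-correcting
convention for effective-N analyses.

## Multivariable LD score regression

For traits a, b and SNP j the moment model is
E[z_aj z_bj] = sqrt(N_a N_b) cov_g(a,b) l_j / M + C_ab, with l_j the LD
score, M the SNP count the heritability refers to, and C_ab an intercept
(~1 on the diagonal; off-diagonal it absorbs sample overlap times
phenotypic correlation). All k(k+1)/2 regressions run on the SNPs common to
every trait, in genome order, so one block partition serves the whole
matrix.

Estimation choices, each of which was measured before adoption:

- **Weights.** Overcounting weights 1/max(l_j, 1) times heteroskedasticity
  weights 1/var_j, where var_j = 2 E[chi2_j]^2 for a trait with itself and
  E[chi2_a] E[chi2_b] + E[z_a z_b]^2 for a pair, with fitted means floored
  at 1 (the model variance of a z-product cannot fall below ~1; an
  unfloored noisy intercept can otherwise hand a few low-LD SNPs absurd
  weights).
- **Cross-fitted weighting schedule.** Weights estimated from the same
  observations they weight bias the slope upward by a few tenths of a
  percent — invisible on real data, but detectable by a 100-replicate
  recovery simulation. The blocks are therefore split into two interleaved
  half-genomes; each half's weights come from the other half's fit (two
  refinement sweeps), and the reported estimate is the average of the two
  half-estimates. This is first-order free of weight-estimation bias and
  measured at near-oracle efficiency.
- **Jackknife.** Delete-one-block over 200 contiguous blocks (genome
  order). The full sampling covariance V of the half-vectorized S is the
  jackknife covariance of all pair estimates on the shared partition;
  half-vectorization is column-major over the lower triangle throughout the
  package (a bit-level contract the SEM layer depends on). Empirical-SD to
  mean-SE ratios sit within a few percent of 1 in the recovery studies.
- **Outlier guard.** SNPs with chi2 above max(80, 0.001 N, 100 * median
  chi2) are dropped from the common set. On GWAS-scale data (median chi2
  near 0.5) the median term is inert and the guard is the conventional
  max(80, 0.001 N); the median term prevents the guard from truncating
  strongly powered inputs wholesale.
- **Liability scale.** h2_liab = h2_obs * K^2(1-K)^2 / (P(1-P) phi(z_K)^2).
  Matrix conversion scales each binary trait's row/column of S by sqrt(c),
  so the diagonal gains the full factor and genetic correlations are
  untouched; V scales by the matching products. No case-control covariance
  correction beyond the P term.
- **Standardization.** R_ab = S_ab / sqrt(S_aa S_bb). V_R uses the full
  delta method for off-diagonal moments — the negative cross terms from the
  h2 denominators matter; dropping them (fixed-factor scaling) overstates
  correlation variances by ~50% at desk scale and makes downstream tests
  conservative. Diagonal moments of R are exactly 1; their V_R entries keep
  the relative variance of h2 so DWLS weights stay strictly positive.

Known behavior: with very strong per-SNP signal the intercepts (which are
extrapolations to zero LD) are noisy and can sit far from 1 in any single
replicate; the null simulation recovers mean intercept 1 to Monte-Carlo
precision.

## DWLS structural equation models

Models are written in a one-path-per-line text syntax (`F =~ a + b`,
`x ~~ y`, `0.5*` fixes a value, a shared `label*` imposes equality by
parameter sharing — which keeps the degree-of-freedom accounting exact for
1-df difference tests). Internally a RAM-style parameterization
Sigma = (I+A) S (I+A)^T restricted to observed rows supports loadings,
factor correlations, observed-latent covariances and residual (co)variances
in one frame; latents are scale-set by fixing their variance to 1, so all
reported loadings and factor correlations are standardized.

- **Estimator.** Minimize the diagonally weighted least squares criterion
  with D = diag(V_R); BFGS with an explicit finite-difference moment
  Jacobian, starts at observed moments for covariances, 0.5 for loadings,
  max 500 iterations, gradient tolerance 1e-8. Non-convergence raises with
  the final gradient norm. Negative residual variances are reported with a
  Heywood flag, never bounded.
- **Chi-square.** The residual-based quadratic form
  T = r' [V+ − V+ J (J' V+ J)+ J' V+] r, with J the moment Jacobian at the
  solution and pseudo-inverses for rank adjustment. This statistic is
  asymptotically chi^2_df for any consistent point estimator, so it remains
  calibrated even though the point estimates use only diag(V_R); the
  type-I error of the 1-df constrained-vs-saturated test measured over 500
  full-chain replicates is 0.04-0.05 at alpha = 0.05.
- **SEs** are sandwich estimates using the full V_R.
- **Fit indices.** AIC = chi2 + 2q; CFI = 1 − max(chi2−df,0)/max(chi2_indep
  −df_indep, chi2−df, 0) against the zero-correlation independence model;
  SRMR = root mean square of the correlation residuals. A saturated model
  has chi2 = 0 and df = 0 identically.

## Factor analysis

Kaiser rule on the unreduced correlation matrix with strict inequality
(identity retains zero factors). Extraction is principal-axis factoring
with squared-multiple-correlation communalities (via statsmodels), rotation
is classic pairwise varimax with Kaiser normalization — the explicit
per-pair angle update escapes the symmetric stationary points where
gradient-projection rotation stalls on exactly block-structured toys —
followed by a promax (power 4) oblique transformation, which yields the
pattern matrix and factor correlations. Column signs are fixed so each
factor's largest-magnitude loading is positive, making reruns bit
identical. Variance explained is the mean communality diag(L Phi L')/p.
Jackknifed correlation matrices are routinely indefinite, so inputs are
projected to the nearest PSD matrix (eigenvalue floor 1e-6) first and the
Frobenius distance moved is reported. The confirmatory model keeps pattern
loadings >= 0.30, frees all factor correlations and residual variances, and
reports variables with no loading above the cutoff as excluded.

## Colocalization

Wakefield log ABF per SNP: 0.5 log(1−r) + z^2 r/2 with r = W/(W+varbeta).
Effect-size prior variance W = 0.2^2 for binary traits (log-odds scale) and
(0.15 sdY)^2 for quantitative traits, sdY^2 estimated by regressing
2 maf (1−maf) n on 1/varbeta through the origin. Hypothesis masses are
accumulated with log-sum-exp; the two-distinct-variants mass uses
log(e^{s1+s2} − e^{s12}) via log1p, and a single-SNP locus has exactly zero
H3 mass. Priors default to p1 = p2 = 1e-4, p12 = 1e-5 with p12 <=
min(p1, p2) enforced. Posteriors are verified against brute-force
enumeration over all causal-configuration pairs to 1e-10. Locus definition
is greedy clumping (p < 5e-8 leads, 250-kb merging, 1-Mb windows); a
user-supplied locus list can replace it to reproduce published loci.
Lead variants missing from a trait take the best LD proxy with r^2 >= 0.8
from a supplied table, or the locus is reported unanalysable.

## Synthetic data

The generator produces data from exactly the moment models above, which is
both its strength and its limit.

- **LD scores**: gamma(shape 3, mean 100), laid out on 22 autosomes in
  proportion to real chromosome lengths so odd/even splits and region
  exclusions are non-trivial. Desk-scale defaults: M = 20 000 SNPs,
  N = 50 000, chosen so a full multi-trait replicate runs in well under a
  second and 100-500-replicate studies fit in minutes on one CPU.
- **Z-scores**: per SNP, a k-vector from N(0, C0 + l_j C1), C1 from the
  generating correlation matrix and heritabilities, C0 from sample-overlap
  fractions times phenotypic correlations. Everything is seeded and bit
  reproducible.
- **Coloc loci**: AR(1) LD (rho = 0.9), causal variants placed per
  hypothesis (shared SNP at the centre for H4; quarter-point SNPs in
  negligible LD for H3), marginal effects propagated through the LD matrix,
  varbeta = 1/(2 maf (1−maf) n) with unit trait SD.
- **Regional signal embedding**: redraws two traits' Z-scores inside one
  region with the cross-trait covariance boosted by the inverse of the
  region's LD-score share, so the genome-wide rg is driven entirely by that
  region; requesting more signal than the region can carry (local
  correlation > 1) raises with the minimum share required. This enables the
  region-exclusion experiment: excluding the region must null the target
  pair's rg while an unrelated pair moves within its SE.
- **The canonical four-factor truth** (13 risk factors on 4 correlated
  factors — socioeconomic, mood, cardiometabolic, smoking-related — with
  two cross-loading variables and one near-isolated variable whose single
  loading of 0.25 falls below the 0.30 cutoff) has four eigenvalues above 1
  with margin on both sides (1.14 vs 0.92), so Kaiser retention is stable
  under estimation noise.

What passing the tests shows: the estimators are unbiased and their
uncertainty is calibrated *under the generating model* — real GWAS data add
model misspecification the generator deliberately omits (no realistic joint
MAF/LD spectra, no annotation-dependent architecture, no population
stratification beyond a constant intercept shift, no selection). Recovery
here validates the inference chain, not the polygenic model itself.

## Pipeline conventions

- FDR families (Benjamini-Hochberg, alpha 0.05) follow the reporting
  structure: one family per outcome over the risk-factor correlations, one
  over the constrained-model comparisons, one per outcome over the latent
  factors. The family composition is configurable since reasonable
  alternatives exist.
- The h2 Z > 4 power gate applies to the genome-wide LDSC run only;
  odd/even-autosome and region-exclusion reruns inherit the screened trait
  set (subset reruns at half the SNPs occasionally produce heavy-tailed
  jackknife SEs that would spuriously trip a re-applied gate).
- Colocalization is triggered when a risk factor is significant with both
  outcomes, overridable in config.
- A ResultBundle serializes to sorted-key JSON; identical config + seed
  reproduces it byte for byte, and provenance records the config hash,
  seed and package version.

## Known limitations

No partitioned heritability, no constrained-intercept LDSC, no computation
of LD scores from genotypes, no maximum-likelihood or full-WLS SEM
estimators, no multi-causal (SuSiE-style) colocalization, no genome-build
liftover. The chi-square and CFI of other SEM software follow different
conventions; agreement is asserted at the level of calibration properties,
not statistic-for-statistic equality.
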