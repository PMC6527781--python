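# Methods

## Model and estimator

The per-SNP analysis assumes the standard animal-model decomposition of a
yield deviation: `y = mu + g(SNP class) + a + e`, with `a` the additive
polygenic value (`var(a) = sigma_a^2 A` for relationship matrix `A`) and `e`
iid residuals. Exact inference is GLS with `V = sigma_a^2 Z A Z' +
sigma_e^2 I`, or equivalently the mixed-model equations (MME): the two BLUE
routes are algebraically identical, and the `oracle` module implements both
densely to certify that identity on every random test instance.

AGLS approximates the MME route by substituting an externally estimated
polygenic value, `2*PTA`, for the BLUP: the adjusted phenotype is
`y* = y - 2*PTA`, after which each SNP is an ordinary one-way cell-means fit.
When the PTAs equal the BLUP exactly (reliability 1), the substitution is not
an approximation at all — the cell means of `y - a_hat` *are* the MME BLUE —
which is what the oracle tests exploit. At reliability below 1 the adjusted
phenotype keeps a residual polygenic component; because that component is
independent of any null SNP's genotypes, the contrast t-tests remain
calibrated (verified by the null simulations), while stratification
correction degrades gracefully with reliability.

### Parameterization and rank

The design `(mu, g11, g12, g22)` is rank-deficient; the generalized-inverse
notation of the estimator leaves the parameterization open. We use the
cell-means parameterization: no explicit intercept, one mean per observed
genotype class, `k` = number of classes present. All reported quantities
(contrasts, alpha, delta) are invariant to this choice, `(X'X)` is diagonal
(`(X'X)_gg^-` has entries `1/n_class`), and the degrees of freedom are
`n - k`.

### Tests

- Additive contrast `s_a = (P11/p1, 0.5 P12 (p2-p1)/(p1 p2), -P22/p2)`,
  valid under Hardy-Weinberg disequilibrium; a genotype class with zero
  frequency automatically receives zero weight, so the additive test needs
  only two classes present.
- Dominance contrast `s_d = (-0.5, 1, -0.5)`, requiring all three classes;
  a SNP is flagged `dominance_untestable` unless each class has at least
  `min_class_count` (default 5) called individuals. The default is a
  small-sample guard; at national scale every class is huge and the flag
  never triggers.
- Residual variance `v^2 = RSS/(n-k)` is per SNP, from the same SNP's fit,
  not pooled across SNPs.
- Two-sided p-values from the t distribution with `n-k` df. The t tail is
  used at every df for uniformity (at df > 1e6 a normal tail would be
  numerically indistinguishable).

### Extreme p-values

Below `p = 1e-308` the double-precision tail underflows. Such rows switch to
the empirical power law `log10(1/p) = 0.2416 t^1.9713` and are flagged
`empirical_p_used`. Over the representable range (large df, t in [5, 37])
the law correlates with the exact `-log10 p` at r > 0.9999; the coefficients
are configurable, and `fit_empirical_tail()` can refit them from a run's own
representable (t, log10(1/p)) pairs by least squares on the log-log scale.

## Allelic decomposition

From the class means and genotype frequencies: `mu1 = (P11/p1) g11 +
0.5 (P12/p1) g12`, `mu2 = 0.5 (P12/p2) g12 + (P22/p2) g22`,
`mu = p1 mu1 + p2 mu2`, `a_i = mu_i - mu`, `alpha = mu1 - mu2`,
`delta = g12 - (g11+g22)/2`. Exact identities maintained and property-tested:
`alpha = a1 - a2 = s_a' g`; `p1 a1 + p2 a2 = 0`; relabeling the alleles flips
the sign of `alpha` and leaves `delta` unchanged.

Comparable allelic effects replace `mu` with `mu_all`, the unweighted mean of
`mu` over the trait's reporting SNP set — the SNPs with MAF at or above the
reporting threshold (default 0.05), since cross-SNP comparison is only done
among reported SNPs. MAF gates *reporting of effect sizes* only (the
`effect_suppressed_low_maf` flag); it never gates testing, because the
additive t already accounts for allele-frequency variation while raw allelic
effects do not.

### Qualitative labels

The allelic-pattern typology (symmetric / asymmetric / uni-allelic) is
conceptual; we operationalize it with the magnitude ratio
`r = min(|a1*|,|a2*|)/max(|a1*|,|a2*|)`: uni-allelic for `r <= 0.2`,
symmetric for `r >= 0.8` with opposing signs, asymmetric otherwise;
thresholds configurable. Dominance modes use the heterozygote's position:
overdominant outside both homozygotes, complete within
`0.05 * |g11 - g22|` of one homozygote (same tolerance declares `delta = 0`
as "none"), partial otherwise.

## Conditional analysis

For an index SNP, each individual's adjusted phenotype loses the fitted
genotypic value of its index genotype; individuals with a missing index
genotype are dropped from both arms. The region is re-scanned with identical
machinery. A (SNP, trait) effect is "top fraction" (default 1%) when its
unconditional rank is within `ceil(fraction * tested SNPs)`; survival after
conditioning is judged against the unconditional trait-specific log10(1/p)
cutoff (the weakest top-fraction value), i.e. a fixed notion of "top"
rather than re-ranking the conditional scan. Conditioning is idempotent, and
a SNP in perfect LD with the index has all residual class means equal, hence
exactly zero contrasts — the limit the planted-region tests exercise.

## Synthetic cohorts

The generator emulates: biallelic genotypes drawn per SNP from
`(p1^2 + f p1 p2, 2 p1 p2 (1-f), p2^2 + f p1 p2)` (inbreeding-style HWD via
`f`; `f = 0` is HWE); optional LD blocks by copying a source SNP's column
with flip noise; per-trait polygenic values summed over many small
background-locus effects and rescaled to `sigma_a^2` (an explicit
multivariate-normal mode with a supplied relationship matrix exists for
oracle tests — the dense-`A` route is exactly what is infeasible at national
scale, and the background-locus construction keeps memory flat); PTAs as
`0.5 (r a/sigma_a + sqrt(1-r^2) z) sigma_a` so that `corr(2 PTA, a) = r =
sqrt(reliability)`; and planted effects whose class values
`g = x(-2p2, p1-p2, 2p1) + (0, delta, 0)` are solved so the decomposition
under the *realized* frequencies returns the requested `alpha` exactly
(the construction leaves `delta` untouched).

Defaults: 5,000 individuals x 2,000 SNPs, allele frequencies uniform on
(0.05, 0.95), `sigma_a^2 = 0.3`, `sigma_e^2 = 0.7` (heritability 0.3, typical
of production traits on a standardized scale), PTA reliability 0.8 (typical
of genomically tested cows). One `numpy.random.default_rng(seed)` (PCG64)
stream drives everything, so a fixed seed reproduces the cohort, the truth
record and the downstream result tables byte for byte.

What the generator does **not** emulate: realistic pedigrees and
generation-over-generation selection; coalescent LD structure (LD is planted
as exact copies with optional flip noise); the error structure of real PTAs,
which come from an evaluation over tens of millions of animals and are not
simply "truth plus independent noise"; missing-genotype patterns of chip
imputation. Passing tests therefore demonstrate the estimator's algebra,
calibration and LD logic under the assumed model — not robustness to
pedigree confounding or imputation artifacts.

## Numerical choices and degenerate inputs

- Missingness: pairwise deletion per SNP (frequencies and fits use called
  genotypes with non-missing phenotype and PTA only); individuals absent
  from any table are dropped per trait with logged counts.
- Monomorphic-in-sample SNPs produce a frequencies-only result row (no
  tests); the additive contrast is undefined and raises if requested
  directly.
- `v^2 = 0` (noise-free data): a zero contrast gives `t = 0`; a non-zero
  contrast gives `t = inf` with infinite log10(1/p).
- Generalized inverses in the oracle use eigen-decomposition with relative
  rank tolerance 1e-10; the oracle enforces an `n <= 2000` cap — it is a
  test instrument, not a production path.
- Ranks are 1-based dense ranks per trait by descending log10(1/p); ties
  break by |alpha| descending, then snp_id — ties are essentially impossible
  at realistic sample sizes, but the chain makes output deterministic.
- The Bonferroni threshold is reported exactly (`alpha/(n_snps x n_traits)`)
  and rounded to one order of magnitude, the operational form used for
  significance flags.

## Problem sizes used in the automated checks

Calibration runs use 2,000 null SNPs at n = 2,000 with reliability 0.8;
effect recovery uses 200 replicates of n = 2,000 at MAF 0.3; the oracle
comparison uses 50 instances with n between 30 and 200; the end-to-end
pipeline check runs 5,000 individuals x 2,000 SNPs x 2 traits. These sizes
give tight Monte-Carlo intervals (binomial half-width ~0.01 on a type-I rate
of 0.05) while keeping the full suite fast on a single CPU.

## Known limitations

- AGLS inherits whatever biases the external PTAs carry; with reliability
  well below 1, stratification correction is partial.
- The dominance test is only as good as the heterozygote class size; the
  `min_class_count` guard is crude at desk scale.
- Conditional analysis removes one index SNP's effects; multi-SNP joint
  conditioning and stepwise selection are out of scope.
- No variance-component estimation: `sigma_a^2`/`sigma_e^2` enter only the
  simulator and the oracle, never the scan itself (the scan needs neither).
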