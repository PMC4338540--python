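# Methods

## Data model

A cohort bundle holds five tables aligned to one ordered sample list:
log2-scale expression (genes × samples), binary lesion calls
(samples × lesions, each lesion labelled `genetic` or `cytogenetic`),
clinical variables with declared value domains (`real`, `positive`,
`unit-interval`, `binary`) and explicit missing values, demographics
(sex, 1 = female; age in integer years) and right-censored survival
(days, status 1 = event). Alignment always uses the *sorted* intersection
of sample IDs so that loading is order-independent and auditable. Missing
values are never imputed anywhere: each model filters to its own complete
cases, and per-analysis availability masks are exposed through
`align_and_mask`. Disease samples without mutation data may enter the PCA
but are excluded from regression fits by default.

## Expression deconvolution

Per gene, ordinary least squares of expression on
(intercept, disease indicator, recurrent lesions, sex, age), solved
through one shared QR factorisation of the design. Lesions carried by
fewer than `min_recurrence = 5` samples are dropped; a rank-deficient
design is an error that names the collinear columns. The disease
indicator lets normal controls identify changes common to all disease
samples; if the bundle has no normals it is constant and dropped with a
warning.

**Moderation.** Residual variances s_g² with d_g degrees of freedom are
assumed exchangeable under a scaled-inverse-χ²(d₀, s₀²) prior. (d₀, s₀²)
are estimated by matching the mean and variance of log s_g² to the log-F
distribution implied by the prior, using digamma/trigamma identities and
a Newton inversion of the trigamma function; when the observed spread of
log variances is no wider than χ² sampling noise the estimate is d₀ = ∞
(complete shrinkage). Posterior variances are
s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g); moderated t statistics use s̃_g
with d₀ + d_g degrees of freedom, and a moderated F over the genomic
(genetic + cytogenetic) block uses the reduced-vs-full residual sum of
squares divided by s̃_g². d₀ = 0 reproduces ordinary statistics exactly
and d₀ = ∞ the fully pooled limit; both are exposed as overrides. The
implementation is cross-checked in the test suite against Bioconductor
limma's eBayes on a shared fixture.

The moderated F spans only the genomic block because it gates "associated
with at least one driver"; disease, sex and age are tested by their own t
statistics. Benjamini-Hochberg step-up adjustment is applied per design
column (and to the F p-values), and per-lesion target sets are the genes
with q < 0.05, with signed log fold change. Per-gene explained variance
is reported as the genomic partial R² = (RSS_reduced − RSS_full)/TSS —
the reduced model keeps intercept, disease, sex and age — with the
full-model R² as a companion column; constant genes get R² = 0 with a
warning. The permutation check re-runs the entire chain with lesion
columns permuted across samples (independently per column by default; a
joint-block option preserves co-mutation structure) and records the
discovery count distribution.

PCA of gene-centred expression is computed by SVD with a fixed sign
convention (largest-magnitude gene loading positive) so outputs are
bit-reproducible; variance fractions always sum to 1 over the full
spectrum.

## Co-mutation structure

Pairwise lesion co-occurrence uses the Haldane-Anscombe-corrected odds
ratio (½ added to every 2×2 cell), which stays finite for empty cells in
small cohorts. Target-set overlap is the Jaccard index — the overlap
statistic is a documented package choice, with a hypergeometric
enrichment p-value emitted alongside for robustness. The summary couples
the two: Spearman rank correlation between log-OR and overlap across all
pairs, with a permutation p-value obtained by relabelling pairs. Venn
region counts are provided for 2-4 sets and always sum to the union.

## Phenotype models

The transform f is selected from the declared domain: identity for real,
log for positive, logit for unit-interval or dichotomous variables;
logit-boundary values are clipped by ε = half the smallest nonzero
distance of any observation from {0, 1}, floored at 1e-3. The "GLM" is
Gaussian least squares on the transformed response (transform-then-fit);
only truly dichotomous responses use a binomial likelihood with an L1
logistic path.

The LASSO path minimises (1/2n)‖y − b₀ − Xb‖² + λ‖b‖₁ on unit-variance
covariates over 100 log-spaced penalties from λ_max = max|X'y|/n down to
10⁻³λ_max, via coordinate descent with warm starts (tolerance 1e-10);
KKT subgradient conditions are property-tested along the whole path.
Inclusion order is the first grid point at which a covariate becomes
nonzero, ties broken by entry magnitude. The intercept is unpenalized and
coefficients are reported back on the original covariate scale.

The cross-validated generalized R² is the Cox-Snell likelihood-ratio form
R² = 1 − exp(−(2/n)(ℓ_model − ℓ_null)), chosen because it reduces
algebraically to the classical R² in the Gaussian case when the variance
is profiled, and extends unchanged to the binomial case; it is isolated
behind one function (`generalized_r2`) so a deviance-ratio alternative
could be swapped in. Held-out folds may legitimately produce negative
values. λ_opt maximises the mean out-of-fold R² over five folds
(deterministic given the seed); the largest λ within one s.d. of the
maximum is reported as λ_1se. Expression enters as the first 20
cohort-wide PC scores (fixed, not recomputed per fold; a per-fold variant
would guard against the mild leakage of unsupervised scores but the
scores are computed without the response).

Variance attribution decomposes the fitted linear predictor by covariate
group: share_g = Σ_h Cov(r_.g, r_.h)/Var(z). Shares are signed (negative
for anti-correlated groups) and sum exactly to the in-sample total R².

## Survival models

The "shared prior on coefficient variances" is implemented as a single
ridge precision τ common to all coefficients of the Cox partial
likelihood — the simplest model consistent with that structure, and
leakage-free because τ is always chosen by inner fivefold
Verweij-van Houwelingen cross-validated partial likelihood on training
folds only (grid 0.25-64 on standardized covariates). Fitting is damped
Newton on the Breslow partial likelihood, normalised per event so the
convergence criterion (max |gradient| ≤ 1e-8) is independent of cohort
size; the penalized objective is non-decreasing across iterations by step
halving. τ = 0 is the unpenalized MLE; τ = ∞ is handled as an exact
limit with all coefficients pinned at zero (constant risk, C = ½).
Covariates are standardized internally and coefficients reported on the
original scale. Risk orientation: higher linear predictor = higher
hazard = shorter survival.

Harrell's C counts pairs where the earlier time is an observed event;
tied times are not comparable, and tied risks count ½. It agrees exactly
with an O(n²) brute-force pair loop on random censored instances
including ties. Outer cross-validation uses five shuffled folds (drawn
without event stratification; folds are redrawn, bounded, if a training
part has fewer than two events), reporting per-fold C, their mean and the
s.d. of the mean. Risk-variance decomposition mirrors the phenotype
attribution: s_g = Σ_h Cov[r_.g, r_.h], summing exactly to Var(r), and
reducing to Var[r_.g] for uncorrelated groups. Kaplan-Meier curves for
risk terciles use the product-limit estimator with a stochastic-ordering
check. Genotype-predicted expression regresses each PC score on the
lesion matrix by OLS and feeds the predicted scores back as a covariate
class, so the prognostic value of the genotype-attributable part of the
transcriptome can be compared with raw genotype and observed expression.

## Synthetic cohorts

Defaults are desk-scale but structurally faithful: 150 disease samples,
17 normal controls, 2000 genes, 16 lesions (12 point mutations, 4
cytogenetic alterations) with MDS-like marginal frequencies (5-22%) and
pairwise log-odds interactions encoding spliceosome mutual exclusivity
and a few co-occurring pairs. Lesions are drawn by sequential conditional
logistic sampling in a fixed order: lesion j is Bernoulli with logit
α_j + Σ_{i<j} w_ij x_i, with α_j calibrated by root-finding so marginal
frequencies match; this controls pairwise odds ratios in sign and
approximate magnitude without an exact Ising sampler. Expression is the
additive model itself plus two dense latent factors (loading scale 0.15)
and gene noise drawn from scaled-inverse-χ²(4, 0.25) — exactly the family
the moderation stage assumes, enabling direct recovery tests of
(d₀, s₀²). Effect sizes default to N(0, 0.7²) on 50 target genes per
lesion (log2 units, the scale of typical driver-associated fold changes);
a fixed-magnitude ±effect option supports recovery experiments.
Phenotypes (haemoglobin, platelets, neutrophils, marrow blasts, ring
sideroblasts, WBC) are drawn on the transformed scale with plausible
lesion coefficients — including a strong SF3B1 → ring-sideroblast link —
then inverse-transformed and masked completely at random at 2-10%.
Survival is exponential with rate h₀·exp(r), h₀ = 1/1500 days⁻¹, risk
assembled from lesion, latent-factor and demographic coefficients;
censoring is independent exponential with its hazard calibrated by
root-finding to the target censored fraction (default 0.4). Every
generator is a pure function of (config, seed), with per-stage
independent streams so toggling one stage never shifts another's draws.

What the generator does **not** emulate: probe-level microarray
artifacts, subclonal mutation fractions, informative censoring,
non-additive epistatic expression effects, and any coupling between
co-mutation and target-set overlap (the default structure correlation is
therefore a calibrated null; the positive-coupling scenario is exercised
by a dedicated constructed simulation in the tests). Passing tests
demonstrate correctness of the machinery under the assumed generative
family, not robustness to real-data violations of it.

## Numerical choices and degenerate inputs

- BH adjustment uses stable mergesort ordering; q-values are clipped at 1
  and monotone by construction.
- Trigamma inversion: Newton from y₀ = 0.5 + 1/x with asymptotic
  shortcuts for extreme arguments.
- PCA sign fixed by the largest-magnitude loading; SVD-based, never
  forming the gene-gene covariance.
- λ grid: 100 points, λ_max from the KKT bound, floor ratio 1e-3.
- Lasso ties in inclusion order broken by entry magnitude and recorded.
- Cox: Breslow ties (standard and differentiable); per-event scaled
  objective; step halving with 40 max halvings; `tau=inf` exact limit.
- Terciles undefined for constant risks (error); KM grids fall back to
  all observed times when there are no events.
- Constant genes: R² defined 0 with warning. All-zero-variance gene sets:
  error.
- TSV output uses fixed `%.6g` formatting and `NA` markers so identical
  seeds yield byte-identical trees.

## Problem sizes used by tests and the acceptance script

Null calibration runs 150 + 17 samples × 2000 genes with 20 permutations;
effect recovery 200 + 17 × 2000 with 100 fixed-magnitude targets per
lesion; hazard-share recovery n = 2000 with true variance proportions
0.7/0.2/0.1; the expression-mediated prognosis comparison n = 200 × 1000
genes over 100 train/test splits; the end-to-end determinism check uses
the default cohort. These sizes make every check reproducible on a single
CPU in minutes while keeping Monte-Carlo error well inside the asserted
margins.

## Known limitations

- The moment-based prior estimator can return d₀ = ∞ on very small gene
  sets; downstream code treats this as the fully pooled limit.
- The binomial LASSO path refits per penalty (no warm starts), which is
  adequate for the small designs used here but slower than the Gaussian
  path.
- Complete-case filtering per class means survival-model classes may be
  scored on slightly different sample subsets when clinical missingness
  differs.
- The ridge Cox model assumes proportional hazards and uses a single
  shared τ; group-specific precisions are not implemented.
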