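# Methods

## Data model and conventions

All expression values live on the natural-log scale internally; the
loader rescales base-2 or base-10 input on read so that the fold-change
selectors' thresholds (which compare `exp(dhat)` with a ratio φ) have a
single unambiguous meaning.  A dataset is an m × n control matrix and an
m × n′ treatment matrix; for paired designs n = n′ and column j of one
matrix is matched with column j of the other, so the per-replicate
log-ratio is d₍ᵢⱼ₎ = x′₍ᵢⱼ₎ − x₍ᵢⱼ₎.  Missing cells are NaN; every
statistic is computed per-gene on complete cases, and a gene with fewer
than two usable replicates per side is reported as undefined (NaN plus a
warning), never silently dropped.  Gene order is preserved end to end.

## Selectors

**Hard fold change.**  π = 0 iff exp(|d̂|) ≥ φ, with the boundary counted
as differential and down-regulation treated symmetrically.  The φ = 1
rule therefore calls every gene with d̂ ≠ 0 differential.

**Smooth fold-change shrinkage.**  π(d̂) = min(1, exp(−(d̂ + 1))), i.e.
π = 1/(e·exp(d̂)) capped at one — a smooth, strictly decreasing function
of the signed fold-change scale exp(d̂).  The complement 1 − π is the
shrinkage weight applied to d̂ in prediction: strong up-regulation keeps
nearly the full estimate (d̂ = 2 → weight 0.95), while weak or negative
estimates are shrunk hard (d̂ = 0.5 → 0.78, d̂ = −0.5 → 0.39).  The rule
is deliberately ad hoc — a smooth stand-in for the hard threshold — and
its asymmetry in the sign of d̂ is a property of the rule, not a bug:
the argument is the signed estimate, not |d̂|.  Genes with d̂ ≤ −1 get
π = 1 under the cap.

**Bayes factor.**  Each gene in isolation, normal errors, equal
within-group variance (unpaired).  With SSR_H = Σd² (or pooled-mean
residual SS) and SSR_H′ = Σ(d − d̄)² (or within-group residual SS), a
Jeffreys prior on the variance and a unit-information Zellner g-prior on
the mean(-difference) parameter give the closed form

    BF(H : H′) = √(1+g) · (Q / SSR_H)^(Neff/2),
    Q = SSR_H′ + (SSR_H − SSR_H′)/(1+g),

with (g, Neff) = (n, n) paired and (N, N−1) unpaired (N = n + n′; one
degree of freedom is spent integrating the flat common mean).  Equal
prior mass on the hypotheses makes the posterior probability
BF/(1+BF).  The unit-information choice makes the Bayes factor behave
like BIC asymptotically while remaining a proper integrated likelihood
ratio; it depends on the data only through the SSR ratio and is exactly
scale-invariant.  Tests validate it against direct numerical integration
of the same integrated likelihoods.

**BIC / AICc weights.**  BIC = N·ln(SSR/N) + k·ln N and
AICc = N·ln(SSR/N) + 2k + 2k(k+1)/(N−k−1), with the maximum-likelihood
variance inside the log and additive constants dropped (only differences
enter the weights).  Parameter counts: (1, 2) paired, (2, 3) unpaired.
π = ω/(1+ω) with ω = exp(−Δ/2) the evidence ratio.  SSR = 0 saturates
the probability to 0 or 1 with a warning; an AICc denominator
N − k − 1 < 1 for the whole design (e.g. paired n = 3) raises an error,
while individual genes below the bound (missing cells) are masked.

**Classical tests.**  One-sided (upper-tail) p-values from the paired or
pooled-variance two-sample t-test, and from the Wilcoxon signed-rank /
rank-sum tests (exact small-sample distributions without ties, normal
approximation with tie correction otherwise; zero differences dropped
before ranking).

**Moderated t.**  Gene variances are modelled as scaled inverse-χ² draws
with prior df d₀ and scale s₀²; (d₀, s₀²) are estimated by matching the
mean and variance of log s² to the implied scaled-F law via
digamma/trigamma equations (the port reproduces the reference R
implementation's hyperparameters and t-statistics to machine precision;
a cross-check test runs the original through Rscript).  When the
observed spread of log s² does not exceed sampling noise, d₀ = ∞ and
s₀² = mean(s²), so identical variances shrink to themselves.  Moderated
t = d̂ / √(s̃²·v) with s̃² = (d₀s₀² + df·s²)/(d₀ + df) and v the
unscaled variance of d̂; p-values use df + d₀ degrees of freedom.

**Moderated-t posterior odds.**  The odds of differential expression

    ω_i = (1−π₀)/π₀ · √r · [(t² + d) / (r·t² + d)]^((d+1)/2),
    r = v/(v + v₀),

where v₀ (the unscaled prior variance of the effect under H′) is
estimated from the top 1 % of |t| by quantile matching, clamped to
(0.1, 4)²/s₀².  π(H₀) is found by fixed-point iteration of the mean
posterior null probability: start at 0.9, update
π_k = mean_i (1 + ω_i(π_{k−1}))⁻¹, stop when |Δ| < 1/1000, when the
update is exactly zero, or when the difference changes sign (cap 100
iterations, error on non-convergence).  The selector output is the local
FDR form (1 + ω_i)⁻¹.

**Local FDR.**  z = Φ⁻¹(1 − p) with p clipped to [10⁻¹², 1 − 10⁻¹²].
The marginal density f(z) is fit by Poisson regression of counts in 120
equal-width bins on a natural cubic spline basis with 7 df; log-density
is interpolated linearly at gene z-values.  Theoretical null: f₀ =
N(0,1), with π₀ the minimum of f̂/φ over the central bins, capped at 1 —
a central-matching estimate justified by f ≥ π₀·f₀ everywhere.
Empirical null: (center, spread, proportion) by truncated-normal maximum
likelihood on the central quantile interval.  The central interval
defaults to the middle 50 % of genes (a quarter excluded per flank);
narrower windows leave the null scale badly identified, which we
verified on shifted/scaled synthetic nulls.  Local fdr = min(1,
π₀·f₀(z)/f̂(z)).  At least 200 genes with defined p-values are required.

## Cross validation

Paired data: n folds, each dropping one pair; the selector is completely
re-fit inside each fold — moderated-t hyperparameters, π(H₀), and the
local-FDR density all see only the reduced data, so no information leaks
from the held-out replicate.  Unpaired data: all n·n′ folds dropping one
column from each group; the held-out quantity is x′₍ᵢⱼ′₎ − x₍ᵢⱼ₎.  Genes
missing in a fold contribute only their defined folds, and per-gene fold
counts are reported.

Summaries: the default report is the **absolute error ratio** — total
error over the total of a base selector (default: t-statistic local FDR,
the same base the gold standard uses) — plus the mean and the
half-sample mode of per-gene error ratios.  Genes whose base error is
exactly zero are excluded from ratio summaries with an explicit count
(the ratio is undefined there; exclusion-with-count keeps the summary
honest without inventing an epsilon).  The half-sample mode recursively
keeps the narrowest ceil(k/2)-point window of the sorted sample until at
most three points remain, then returns their mean; width ties take the
leftmost window so the estimator is deterministic.

## Posterior predictive expected squared error

The gold-standard model is the t-statistic local-FDR selector with
theoretical null; its π weights a two-component predictive mixture for
the next log-difference, and PPESE = (prediction − mixture mean)² +
mixture variance.  Conditional predictives under improper reference
priors:

| component | distribution | variance |
|---|---|---|
| paired null | t_n(0, Σd²/n) | Σd²/(n−2) |
| paired alternative | t_{n−1}(d̄, s²(1+1/n)) | s²(1+1/n)(n−1)/(n−3) |
| unpaired alternative | difference of two shifted-scaled t | sum of the two group predictive variances |
| unpaired null | no closed form | Gibbs-sampled E[σ² + σ′²] |

The unpaired null (common mean μ flat, variances with Jeffreys priors
σ⁻²σ′⁻²) is sampled by alternating the normal full conditional of μ with
scaled-inverse-χ² conditionals for each variance — a Gibbs sampler
targeting the same posterior as the multi-chain procedure it replaces;
defaults keep 10 chains × 100 draws after 20 burn-in (K = 1000), with
overdispersed starts and a Monte-Carlo standard error computed from the
spread of per-chain means.  Correctness is established against an exact
2-D quadrature of the posterior (μ integrated analytically, log-sum-exp
on a 400² grid in log-variance space), and against the closed-form
scaled-inverse-χ² posterior when the variances are constrained equal.

Genes with infinite predictive variance (any required df ≤ 2, i.e.
paired n ≤ 3 for the alternative component) are excluded from totals
with a reported count; designs with n ≥ 5 replicates are unaffected.
Because the gold standard's own prediction equals the mixture mean by
construction, its PPESE is exactly the mixture variance — the attainable
floor — so its total is minimal by definition; the informative content
of the assessment is the *ordering of the other selectors above that
floor*, which on synthetic data tracks the cross-validation ordering.

A known pathology: with n = n′ = 2 the posterior mean of σ² + σ′²
diverges logarithmically under these priors, so neither the sampler nor
the quadrature has a finite target; the engines require n ≥ 3 per group
and flag smaller designs.

## Synthetic data generator

Per gene: σᵢ² ~ d₀s₀²/χ²(d₀) (defaults d₀ = 4, s₀² = 0.05 — moderate
between-gene variance heterogeneity around typical log-scale microarray
noise), null with probability π₀ (δᵢ = 0), else δᵢ ~ N(0, effect_sd²)
with effect_sd = 1 (a two-sided spread of roughly e-fold effects);
replicates are normal around δᵢ.  The generator deliberately matches the
assumptions the gold-standard model states (lognormal expression, few
substantially changed genes), which makes that model well-specified by
construction; misspecification can be probed with the
unequal-group-variances toggle.  The paired channel split (baseline
channel plus d) is cosmetic — only differences reach any downstream
computation.  Presets mirror the shapes of two benchmark designs: a
paired dual-channel tomato-ripening study (m = 13440, n = 5–6, π₀ ≈ 0.9)
and the MAQC rat-liver two-group comparison (m ≈ 27000, n = n′ = 6,
π₀ ≈ 0.6).  What passing tests on this generator do **not** show:
robustness to array artifacts (dye bias, spatial effects), correlated
genes, heavy-tailed effects, or pre-processing choices — all out of
scope.

## Study sizes used by the automated checks

The ranking study in the acceptance tests uses 20 seeds of m = 1000
genes, n = n′ = 6 unpaired, π₀ = 0.9, effect_sd = 1 — large enough for
stable local-FDR fits in every fold while keeping a full 20-seed sweep
of 36-fold cross validation plus MCMC at desk scale.  Checks performed:
the gold standard attains the minimal total PPESE in every run; both
hierarchical selectors in the suite beat every hard fold-change
threshold in total CV error in at least 18 of 20 runs; the CV and PPESE
totals are positively rank-correlated across the suite.  The
oracle-equivalence check compares Gibbs and quadrature on 20 synthetic
genes within 3 Monte-Carlo standard errors; hyperparameter recovery uses
m = 5000 (d₀ within ±25 %, s₀² within ±10 %; gold-standard π₀ estimate
in [0.8, 1.0] at truth 0.9 and directionally lower at truth 0.6).

## Numerical choices and edge cases

- Probabilities are computed from log-odds with the numerically stable
  two-branch logistic form; p-values are clipped before the z-transform.
- The trigamma inverse uses Newton iterations (50 max, tolerance 1e-8).
- The empirical-null optimiser is Nelder-Mead on (δ, log σ) with the
  null proportion profiled out analytically.
- Result tables serialise floats with `repr`, the shortest decimal
  string that round-trips exactly.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); repeated runs are bit-identical.

## Known limitations

- The Bayes factor's prior scale is a package choice (unit information);
  other proper priors shift the absolute probabilities, though not the
  SSR-ratio monotonicity.  No prior-sensitivity sweep is provided.
- The effect-size prior convention inside the moderated-t odds follows
  the reference implementation's top-fraction heuristic; it affects π
  mainly through the π(H₀) calibration.
- The PPESE engine inherits the pragmatic inconsistency of combining an
  empirical-Bayes π with improper conditional priors; it is a ranking
  device, not a full Bayesian analysis.
- Technical-replicate averaging, normalisation and background correction
  are upstream of this package: the loader accepts pre-averaged,
  pre-normalised values only.
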