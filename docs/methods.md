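# Methods

## The model

A sample of angles θ₁…θₙ (radians, reduced to [0, 2π)) is embedded as the
n×2 response matrix Y with rows (cos θᵢ, sin θᵢ) — the x/y components of
unit vectors on the circle. A multivariate linear model Y = XB + U is
fitted by least squares to a design X containing an intercept column of
ones, treatment-coded factors (first sorted level as reference), uncentred
covariates, and interactions as element-wise products of coded columns.

Each term t, *including the intercept*, is tested with Pillai's trace on
its sequential (Type-I) hypothesis SSCP: Hₜ is the increment in explained
SSCP when t's columns are added after all preceding terms, computed from
one QR decomposition of X (the columns of Q spanning term t's block give
Hₜ = (Qₜᵀ Y)ᵀ(Qₜᵀ Y)). E = (Y − XB)ᵀ(Y − XB) is the residual SSCP. With
the intercept in the partition, Σₜ Hₜ + E = YᵀY holds exactly, and
df_error = n − rank(X).

With p = 2 response channels, V = tr(H(H+E)⁻¹) is converted to the
standard approximate F:

    s = min(2, q),  m = (|2 − q| − 1)/2,  n* = (df_error − 3)/2
    F = ((2n* + s + 1)/(2m + s + 1)) · (V/s)/(1 − V/s)
    df1 = s(2m + s + 1),  df2 = s(2n* + s + 1)

For the intercept (q = 1) this is algebraically identical to the
one-sample Hotelling T² test of mean (cos, sin) = (0, 0), which is the
sense in which a significant intercept means "the mean vector differs from
the centre of the unit circle", i.e. non-uniform orientation. The output
matches R's `summary.manova(..., intercept = TRUE, test = "Pillai")`
digit-for-digit (verified during development on shared datasets).

### Interpretation caveats baked into the defaults

- **Sequential SS**: p-values depend on term order; the intercept is always
  first (its H is the grand-mean SSCP), matching the convention of the
  standard MANOVA summary.
- **Uncentred covariates**: the intercept hypothesis is "mean response is
  (0,0) at covariate value 0 and reference factor levels". The CLI warns
  when a fitted covariate has nonzero mean.
- **Degenerate fits**: a singular residual SSCP (all angles identical, or a
  saturated design) raises `DegenerateResponseError`; a term with
  V/s = 1 is reported as p = 0 with a `degenerate` flag rather than an
  exception, since it occurs on toy data.

## Monte-Carlo calibration

The theory F-test assumes bivariate-normal errors; (cos, sin) responses
violate this, inflating the intercept test's type-I error below n ≈ 15
(about 0.07–0.08 at n = 5). `mc_calibrated_manova` corrects this by
simulation: keeping the design fixed, B (default 9999) replacement
responses are drawn from Uniform[0, 2π), the full analysis is recomputed,
and each term's observed theory p is ranked against that term's null
p-values, lower tail, with the +1/≥ tie convention:
p_mc = (1 + #{p_null ≤ p_obs})/(B + 1). This is valid (p_mc ≥ 1/(B+1)) and
exact up to MC error by exchangeability under the null.

The null is "uniform response on the fixed design", not a permutation
scheme, and calibration is per term against the term's own null
distribution of p-values.

## Reference tests

- **Rayleigh**: Z = n·r̄², p from the Greenwood–Durand corrected exponential
  series p = e^{−Z}[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
  clamped to [0, 1] — the de-facto standard in circular software.
- **Hermans–Rasson (variant 2)**:
  T = (1/n) Σᵢ Σⱼ [ ||θᵢ−θⱼ| − π| − π/2 − 2.895(|sin(θᵢ−θⱼ)| − 2/π) ]
  over all ordered pairs including i = j. The i = j terms contribute a
  constant and the ordered double-count a factor 2 relative to some
  published codings; both cancel in the Monte-Carlo p-value, which is the
  only way this statistic is converted to a p (B uniform null samples of
  the same n, upper tail). The constant 2.895 is a literature value,
  surfaced as `HERMANS_RASSON_CONSTANT` so it can be corrected without a
  code change.

## Samplers

- von Mises via the Best–Fisher wrapped-Cauchy envelope rejection algorithm
  (`numpy.random.Generator.vonmises`); κ = 0 is exactly uniform.
- Wrapped skew normal in the (ξ location, ω > 0 scale, α shape) convention:
  z = δ|u₀| + √(1−δ²)u₁ with δ = α/√(1+α²) (the delta representation of
  the skew normal), then θ = (ξ + ωz) mod 2π. Tests validate first
  trigonometric moments against the skew-normal characteristic function,
  not stream-level equality with any other generator.
- Mixtures assign each draw to a component by a vectorised multinomial
  (i.i.d. semantics, not stratified).

All samplers are driven by `numpy.random.Generator`; a fixed seed
reproduces output bitwise.

## The simulation study

The power harness estimates rejection proportions at α = 0.05 over many
replicates (default 9999; the heavier omnibus checks in the test suite use
1000–2000 replicates with tolerance bands widened to the corresponding
binomial MC standard errors). Scenario suites and their sample-size grids:

| scenario | generator | n grid |
|---|---|---|
| uniform (continuous, and 10°-binned) | Uniform[0, 2π) | 5–100 (binned: min 10) |
| unimodal | vm(μ=0, κ=1); wsn(ξ=0, ω=2, α=30) | 5, 10, 15, 25, 50, 100 |
| bimodal | equal vm mixture at 0°,180° / 0°,240°, κ=1 | 10–200 |
| trimodal | equal vm mixture at 0°,120°,240° / 0°,120°,270°, κ=1 | 15–300 |

The hypothetical study has two groups × ages 1–5 (equal cell allocation,
n_total/10 per cell), headings vm(group mean, κ(age)) with κ linear in age
between a per-group (κ_start, κ_end) — linearity being the simplest
reading of a concentration that "increases each year". Group mean-direction
offsets are constant across ages. The fitted model is intercept + age
(covariate) + group (factor); Rayleigh and HR run on the pooled headings
for the intercept comparison.

Two performance choices, which do not change any single-call API:

- Monte-Carlo null distributions (HR statistics; per-term null p-values)
  depend only on n and the fixed design, so inside a rejection-rate loop
  they are computed once and shared across replicates; each replicate's
  p-value remains exchangeable with the shared nulls. Binned scenarios
  deliberately keep *continuous*-uniform nulls — that mismatch is exactly
  what exposes the HR test's level inflation on rounded data.
- The calibrated MANOVA inside power loops uses B = 999 nulls per
  configuration by default (a full B = 9999 per replicate is quadratic);
  the per-call default remains 9999.

Binning maps each angle to the nearest multiple of the bin width, exact
midpoints rounding to the upper bin — the natural model of field
measurements recorded to the nearest 10°. Ties are not jittered.

## Model selection

Stage 1 fits the full model and computes, per term and response channel,
the partial η² = SSₜᵣ/(SSₜᵣ + SS_resid,r) from the sequential partition
(equal to the classical one-way ANOVA η² in the one-factor case).
Candidates are ranked by the mean of the two channels' η² (a `max`
aggregation is available) and the top_n kept (guard: top_n ≤ 15, since
stage 2 is exhaustive). Candidate order is canonicalised before the full
fit, so the report is invariant to the order candidates are supplied in.

Stage 2 fits every subset of the retained candidates (intercept always
included; subsets containing an interaction without all its main effects
are skipped — marginality) and ranks them by the mean over channels of the
Gaussian AIC, AICᵣ = n·log(2π·RSSᵣ/n) + n + 2(k+1), which counts the
variance parameter and so is comparable to R's `AIC()`. Ties break by
fewer terms, then lexicographic term names. Interactions are never
auto-generated; list them explicitly as candidates. Covariates that are
themselves circular should be supplied as their cos/sin (or axial cos/sin)
components, transformed before screening.

## What the synthetic data do and do not show

The generators reproduce the distributional shapes of the validation
study — unimodal, skewed, multimodal, age/group-structured von Mises — as
clean i.i.d. draws. Real orientation data add features not emulated here:
measurement rounding beyond the 10° binning option, serial dependence and
repeated measures of individuals (a random-effects MANOVA is *not*
validated and not provided), unbalanced cells, and covariate error. Passing
the suite therefore demonstrates correctness of the algebra and the
operating characteristics under i.i.d. sampling, not robustness to those
features.

## Numerical notes

- Rank deficiency is detected from the QR diagonal with tolerance
  max(n,k)·eps·max|diag(R)| and reported with the offending term's name.
- Pillai algebra on 2×2 SSCPs uses closed-form inverses; the vectorised
  batch path is tested to 1e-9 against the per-sample fit.
- Mean directions of samples with r̄ < 1e-12 are reported as undefined
  rather than an arbitrary angle.
- MC p-values use the +1/tie-inclusive convention throughout, so p = 0 is
  unattainable and p ≥ 1/(B+1).

## Known limitations

Only Pillai's trace is offered (no Wilks/Hotelling–Lawley/Roy); sums of
squares are sequential only (no Type II/III); no random effects or
repeated measures; no circular confidence intervals, circular-circular
correlation or density estimation; selection offers plain AIC only (no
AICc/BIC). The symmetric-multimodal blind spot of the intercept test is a
property of the method, not the implementation: transform the data (e.g.
axial doubling) or use the HR test when symmetric multimodality is
plausible and no covariates are needed.
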