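# Methods

This note documents the models behind `slidenorm`, the numerical choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Data model

All operations act on a cell quantification table: one row per segmented
cell, a slide identifier, one non-negative intensity column per marker
channel, and optional labels (epithelium/stroma tissue class, manual
marker-positive flags for immune channels, tumor-region flag). Raw
intensities are integer-valued median pixel intensities within the segmented
cell mask. Slides are treated as exchangeable batches (opaque string IDs, no
ordering); the slide is the only batch level modeled — image-level nesting
within a slide is not represented. Zeros are data, never missing values: on
every scale used here a zero is a meaningfully low intensity. An all-zero
slide-channel is flagged at validation because mean division is undefined
there; the transforms raise a degenerate-slide error rather than emit NaN.

## Transformations

Three strictly monotone per-slide-channel maps of the raw scale:
`log10(y+1)` (the +1 because raw values are integers, so 0 maps to 0);
`y/μ_ic` (slide-channel mean division; every slide's mean becomes exactly 1);
and `log10(y/μ_ic + 1/2)` (cells above half the slide mean become positive,
the rest negative, bounded below by `log10(1/2)`). `μ_ic` is always the mean
of the *raw* values of that slide-channel, captured when the transform spec
is fitted and serialized with it, so the identical normalization can be
replayed on held-out cells from the same slides. Monotonicity guarantees
within-slide cell rankings are preserved by every transform.

## ComBat adaptation

Per channel, the location-scale model `Y = α_c + γ_ic + δ_ic ε`,
`ε ~ N(0,1)`, with Gaussian mean effects `γ_ic ~ N(γ̄_c, τ̄²_c)` and
inverse-gamma variance effects `δ²_ic ~ IG(ω̄_c, β̄_c)`.

*Standardization.* `α̂_c` is the cell-weighted grand mean; `σ̂²_c` is the
mean squared within-slide residual (1/N denominator);
`Z = (Y − α̂_c)/σ̂_c`. Division is by the standard deviation, not the
variance: the working assumption `Z_ic(u) ~ N(γ_ic, δ²_ic)` is only
dimensionally consistent on the sd-standardized scale, matching the original
Johnson et al. ComBat. The naive mean effects `γ̂_ic` are per-slide means of
`Z` (the raw-scale slide mean is recovered as `α̂_c + σ̂_c γ̂_ic`); the naive
variance effects `δ̂²_ic` are per-slide sample variances of `Z`.

*Hyperparameters.* Method of moments: `γ̄ = mean(γ̂)`, `τ̄² = var(γ̂)`
(n−1 denominator); with `m, v` the mean and variance of `δ̂²`,
`ω̄ = m²/v + 2` and `β̄ = m(ω̄ − 1)`, so the implied prior mean is `m`.
If `v = 0` (no spread in the slide variances) moment matching is undefined;
the prior is then set flat (`ω̄ = 1, β̄ = 0`), which makes the variance
update return the within-slide mean square — i.e. no pooling.

*EB fixed point.* Initialized at the naive estimates, alternating

```
δ²*_i = (β̄ + ½ Σ_u (Z_iu − γ*_i)²) / (U_i/2 + ω̄ − 1)
γ*_i  = (U_i τ̄² γ̂_i + δ²*_i γ̄) / (U_i τ̄² + δ²*_i)
```

until the largest absolute parameter change is below `tol = 1e-5` (maximum
100 iterations; non-convergence warns and returns the last iterate). `γ*` is
a convex combination of `γ̂` and `γ̄`, so shrinkage
`|γ* − γ̄| ≤ |γ̂ − γ̄|` holds exactly, and `γ* → γ̂` as `τ̄² → ∞` or
`U → ∞`.

*Hyperparameter iteration.* The hyperparameters are estimated once, from the
naive per-slide effects, and held fixed while the batch parameters are
iterated to convergence. The alternative — re-running the moment matching on
the current *shrunk* effects between fixed points — was implemented and
rejected as the default: because shrinkage contracts the spread of the
estimates on every round, the re-fitted prior variance shrinks geometrically
and the variance prior collapses (`ω̄` diverges), completely pooling the
slide variance effects even when their true spread is several times their
sampling noise. That variant remains available as
`reestimate_hyperparams=True` for comparison.

*Adjustment.* `Y* = (σ̂_c/δ̂*_ic)(Z − γ*_ic) + α̂_c`. With null effects
(`γ* = 0, δ²* = 1`) this inverts the standardization exactly. Adjusted
values may be negative under the Gaussian model; `clip_nonnegative=True`
clamps at zero for users needing raw-scale semantics. Because the adjustment
subtracts the *shrunk* mean effect, per-slide means retain a residual gap of
order `(1 − w) γ̂_ic` with `w = Uτ̄²/(Uτ̄² + δ²*)`; at thousands of cells
per slide `w ≈ 1` and the refitted slide-level variance proportion is zero
to many decimals.

## Density registration

Per channel, a common grid of 512 equally spaced points spans the pooled
[min, max]. Each slide's histogram (128 equal-width bins) is least-squares
projected onto a 21-function cubic B-spline basis (17 equally spaced
interior knots); fitted values are clamped at zero — least-squares fits can
dip negative — and renormalized to integrate to 1 by the trapezoid rule. The
registration target `f̄` is the pointwise mean of the slide fits, computed
once from the unwarped fits (an `iterations` option recomputes the target
from warped data).

The warp family is `ϕ(x) = a + (b−a) W(x)/W(b)` with
`W(x) = ∫_a^x exp{β₁h₁(y) + β₂h₂(y)} dy`, where `h₁, h₂` are the two hat
functions of a linear B-spline basis with no interior knots (exactly 2
degrees of freedom; the exponent is linear in `y`). The positive integrand
makes `ϕ` strictly increasing, and the normalization fixes `ϕ(a)=a`,
`ϕ(b)=b`, so the endpoint constraints absorb the integral's lower limit and
the constants `C₀, C₁`. `(β₁, β₂)` minimize the trapezoid quadrature of
`∫ (f_ic(ϕ(y)) − f̄(y))² dy` by L-BFGS-B with box bounds `[−5, 5]`,
multi-started from the identity (the objective is smooth in 2 parameters; the
extra starts guard against the rare local minimum). If no start succeeds, the
identity warp is returned with a warning. `β₁ = β₂ = 0` gives `ϕ = identity`
exactly.

*Transport direction.* The fitted warp satisfies `f_ic(ϕ(y)) ≈ f̄(y)`: `ϕ`
maps target-frame coordinates into the slide's frame (for a slide shifted
right of the target by `s`, the optimum is `ϕ(y) ≈ y + s`). Observations
therefore move into the target frame through the *inverse* warp,
`Y* = ϕ⁻¹(Y)`, and that is the default: applying `ϕ` forward would move a
shifted slide further from the average, and cross-slide alignment (the AD
statistic) would worsen rather than improve. The forward application
`Y* = ϕ(Y)` is exposed as `direction="forward"` for completeness. Either
way the transport is a monotone interpolation of the tabulated warp, so
within-slide rank order is preserved, and out-of-domain values are clamped
to the endpoints (counted and warned).

## Evaluation framework

*Anderson–Darling.* The Scholz–Stephens k-sample statistic in its midrank
(ties-corrected) form — median pixel intensities are integers, so ties are
heavy. The standardized version `T = (A² − (k−1))/σ_N` is the default
(its null distribution is sample-size free); the raw `A²` is available via
`standardized=False`. Magnitudes are not comparable across implementations
that choose differently. Larger = slide distributions more separated.

*Otsu thresholds.* 256 equal-width bins over the observed range per group
(imaging convention); every interior bin edge is a candidate split
(class 0: `y < t`, matching histogram bin membership), and the edge
maximizing `ω₀ω₁(μ₀−μ₁)²` wins, ties to the smallest edge. Class means use
exact value sums per bin, so the result equals an exhaustive edge scan. The
discordance score for a channel is the mean over slides of the proportion of
a slide's cells whose call `I(y > o)` differs between the slide-specific and
the pooled-global threshold; the global threshold pools all cells. A slide
with a degenerate (constant) channel is scored 0 against the global calls
with a warning. Marker-positive accuracy compares pooled-threshold calls to
the manual labels.

*Variance proportions.* A one-way random-intercept model fitted by REML
(statsmodels MixedLM), reporting `σ²_slide/(σ²_slide + σ²_res)`. Two
numerical guards: L-BFGS can fail with a singular score exactly on the zero
boundary, and can also stall there spuriously while reporting an infinite
restricted likelihood — the model is therefore also fitted with the
derivative-free Powell optimizer, non-finite likelihoods are discarded, and
the best remaining fit wins; if every fit fails, the one-way ANOVA moment
estimator (clamped at zero) is used with a warning. Boundary estimates of
zero are legitimate and reported as 0.

*Embeddings.* A seeded subsample (default 10%, stratified by slide so small
slides are kept) of the four class-discriminating markers is embedded with
UMAP (2 components, 15 neighbors, min-dist 0.1, Euclidean, fixed seed) and
clustered by k-means with k = number of distinct labels; the adjusted Rand
index (Hubert–Arabie, via scikit-learn) scores cluster/label agreement. Low
is desirable for slide IDs (slides should be unpredictable after
normalization), high for tissue classes.

Orientation summary: AD, discordance, slide-ARI and slide variance
proportion are smaller-is-better; accuracy and tissue-ARI larger-is-better.

## Synthetic generator

Defaults are the study conditions used throughout the tests: 20 slides ×
2000 cells, six channels. Per cell and channel the log-intensity is
`m_class + γ_ic + δ_ic s_class z` with `z ~ N(0,1)`; `exp` of it is rounded
to the nearest non-negative integer, giving right-skewed integer data on a
median-pixel-like scale (background ≈ exp(3) ≈ 20 counts, positive ≈
exp(4.5) ≈ 90). Slide mean effects are `γ_ic ~ N(0, τ²)` with τ = 0.5 by
default; variance effects `δ²_ic ~ IG(ω=60, β=59)` (prior mean ≈ 1, sd ≈
0.13 — a mild, realistic dispersion chosen once). Two latent tissue classes
(epithelium/stroma, 50/50) differ in positivity on the four designated
tissue channels (85% in-class vs 5% out-of-class); immune-style channels
have class-independent positive fractions and emit manual positive flags
with a 2% flip noise. All randomness derives from one seed.

What it does *not* emulate: spatial structure and cell–cell interactions,
image-level nesting within slides, marker crosstalk/bleed-through,
segmentation errors, and the long heavy tails of some real channels. Passing
tests on this generator show the algorithms remove the batch structure they
model — not that they are robust to everything real MxIF data contains.

## Problem sizes and determinism

Test and acceptance runs use 20 slides × 2000 cells (the package's chosen
study scale for synthetic work; fits run in seconds), with smaller tables
for oracle comparisons (≤ 5 slides × 100 cells for the EB fixed point,
pooled ≤ 100 points for the direct AD formula, ≤ 10⁴ cells for exhaustive
Otsu scans). Everything except the UMAP step is deterministic given the
input; UMAP and k-means are seeded, so repeated runs with one seed are
identical (across library versions, embedding coordinates may drift).

## Known limitations

- Registration assumes densities are smooth on the working scale; on
  heavily right-skewed (untransformed or mean-divided) data the B-spline fit
  and the 2-df warp family are too rigid, and alignment gains are small —
  use the log-family transforms first.
- ComBat's Gaussian working model is misspecified for bimodal and skewed
  channels; it removes slide variance by construction but can distort
  mixture structure (and removes any biology confounded with slide).
- The mean-division transforms are undefined for an all-zero slide-channel;
  such slides must be excluded from that channel.
- No covariate-preserving ComBat (no design matrix of biological
  covariates), no reference-batch variant, no count-model (ComBat-seq style)
  variant, no multi-Otsu thresholding, no landmark registration.
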