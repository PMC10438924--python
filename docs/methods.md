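# Methods

This note documents the statistical procedures and the neurogenesis model
implemented in `cortexdensity`: what is computed, under which assumptions,
which parameters matter, and where the open design choices were resolved.

## Lognormality testing

A group of positive densities (one species' areas, or one area's counting
frames) is tested for lognormality by a fixed pipeline:

1. take the natural logarithm of the densities;
2. z-score with the sample mean and sample standard deviation (ddof = 1);
3. remove samples with |z| ≥ 3 in a single pass — the z-scores are
   computed once from the full sample and not recomputed after removal,
   so the exclusion is idempotent and flags exactly the extreme,
   cytoarchitectonically distinct areas (V1-like outliers) it is meant
   to flag;
4. apply the Shapiro–Wilk test to the retained values.

The Shapiro–Wilk statistic and p-value come from scipy's implementation
of the Royston AS R94 algorithm, validated in the test suite against R's
`shapiro.test` and calibrated on simulated null data (rejection rate at
α = 0.05 inside the binomial band). Valid sample sizes are 3–5000;
groups outside this range produce a per-group diagnostic rather than
aborting the run. Verdicts are reported at α = 0.05 and α = 0.001.

Cross-group comparisons use the plain two-sample two-sided
Kolmogorov–Smirnov test on the z-scored log densities. Formally the KS
null distribution does not account for the standardization; the plain
test is applied deliberately, as is standard in this setting. Probability
plots use Filliben order-statistic medians, (i − 0.3175)/(n + 0.365) with
adjusted endpoints, and report the linearity correlation of the point
set. No multiple-testing correction is applied across areas; per-area
p-values are reported raw and summarized by significance band.

## Distribution comparison

Seven families with support on the positive half-line are fitted by
maximum likelihood: lognormal, truncated normal, inverse normal (inverse
Gaussian), gamma, inverse gamma, Lévy, and Weibull. Each family estimates
k = 2 parameters:

- lognormal and inverse normal use closed-form MLEs (the lognormal MLE
  uses the 1/n variance of the logs);
- gamma, inverse gamma and Weibull are fitted numerically with the
  location pinned to 0;
- the truncated normal is a normal truncated at 0 with location and scale
  free (the truncation point is fixed and not counted in k), maximized by
  Nelder–Mead in (loc, ln scale) with five seeded restarts;
- the Lévy family (location, scale) is fitted by profile likelihood: the
  scale MLE is closed-form given the location, and the one-dimensional
  profile is maximized over locations below the sample minimum.

Models are ranked by AIC = 2k − 2 ln L and compared through the relative
likelihood L_r = exp((AIC_min − AIC_i)/2); families with L_r < 0.05 are
flagged as significantly worse than the best model. Plain AIC is used
(not AICc). Ties in the minimum AIC are broken lexicographically by
family name, which affects only the "best" label, never the L_r values.
A local-optimum property test perturbs every fitted parameter by ±1% and
asserts the likelihood never increases.

On lognormal data the inverse normal and inverse gamma are close enough
to be statistically indistinguishable at the sample sizes typical of
across-area tables (~100–150 areas); with much larger samples (n ≈ 500)
the inverse gamma becomes separable from the lognormal. The comparison
tests therefore check the three-way indistinguishability at n = 116.

## The neurogenesis model

**Within an area.** Progenitor density in a radial unit follows

    d/dt ρ_P = (λ_P − λ_N + σ ξ) ρ_P,

with ξ a zero-mean, unit-strength Gaussian white noise. Under the
Stratonovich interpretation (noise with small but finite correlation
time) the chain rule is the ordinary one, so ln ρ_P performs a Brownian
motion with drift: ρ_P is exactly lognormal at every time with
μ_P(t) = ln ρ₀ + (λ_P − λ_N) t and σ_P(t)² = σ² t (constant rates).

Neurons are post-mitotic; their density is the path integral
ρ_N(t) = ∫₀ᵗ λ_N ρ_P(s) ds. Its first two moments have constant-rate
closed forms (with a = σ²/2, Δλ = λ_P − λ_N, b = Δλ + a, c = Δλ + 3a,
E(r, t) = (e^{rt} − 1)/r):

    ⟨ρ_N⟩  = λ_N ρ₀ E(b, t),
    ⟨ρ_N²⟩ = (2 λ_N² ρ₀² / c) [E(b + c, t) − E(b, t)],

verified in the tests against 2-D quadrature of the covariance integral.
The moment-matched lognormal has σ_N² = ln(⟨ρ_N²⟩/⟨ρ_N⟩²) and
μ_N = ln⟨ρ_N⟩ − σ_N²/2; for λ_P = λ_N the moment ratio reduces exactly
to 1 + 2u/3 + u²/6 with u = e^{σ²t/2} − 1, which is used for numerical
stability at small σ²t. The approximation is good but not exact: the
log of the simulated integral retains a small positive skewness
(≈ 0.14 at the calibrated parameters and t = 45 d), which the
Shapiro–Wilk test detects roughly half the time at n = 2000. See
"Known limitations".

**Simulation.** The canonical integrator steps the *log* density with
exact Gaussian increments, Δln ρ_P = (λ_P − λ_N)Δt + σ√Δt·G, which is
the exact solution of the Stratonovich SDE for constant coefficients and
keeps paths strictly positive; ρ_N accumulates λ_N ρ_P Δt with the
left-endpoint value, mirroring Euler-style stepping. A direct Itô
Euler–Maruyama mode on the density is available behind a flag for
comparison; its progenitor mean lacks the factor e^{σ²t/2} (≈ 9% at
t = 45 d), while the across-area mean–variance correlation is
insensitive to the choice. The default step is Δt = 0.05 day; halving it
changes the t = 45 d mean of ρ_N by less than Monte-Carlo resolution.

**Across areas.** The auxiliary variable y(t) = ln(⟨ρ_N(t)⟩/ρ₀) maps
proliferation time monotonically to log mean density; for λ_P = λ_N = λ,

    y(t) = ln(2λ/σ²) + ln(e^{σ²t/2} − 1),
    t(y) = (2/σ²) ln(1 + (σ²/2λ) e^y).

Placing y ~ Normal(μ_y, σ_y²) across areas makes the area-mean density
lognormal, ln⟨ρ_N⟩ ~ Normal(ln ρ₀ + μ_y, σ_y²), and induces, by the
monotone change of variables, the proliferation-time density
p(t) = |dy/dt| N(y(t) | μ_y, σ_y²) and the density of the within-area
log-variance p(σ_N²) = N(f⁻¹(σ_N²) | μ_y, σ_y²)/|f′|, where
f(y) = σ_N²(t(y)) and

    f⁻¹(v) = ln(λ/σ²) + ln(√(8(3eᵛ − 1)) − 4)

(evaluated as 24w/(√(16 + 24w) + 4), w = eᵛ − 1, to stay accurate for
small v). y(t) approaches ln(λt) for σ²t ≪ 1 (lognormal left tail of
p(t)) and ln(2λ/σ²) + σ²t/2 for σ²t ≫ 1 (Gaussian right tail).
Normalization integrals cap the time support at 300 days; the mass
beyond is < 1e−12 at the calibrated parameters.

The full cortex simulation draws one proliferation time per area by
inverse transform (y ~ Normal, t = t(y)), a Poisson(36.6) number of
counting frames per area (redrawn until ≥ 3 so within-area statistics
are always defined), and one independent SDE realization per frame; all
paths advance over a shared time grid, each path's final step shortened
to land on its own proliferation time. The simulated cortex serializes
to the same long-format table as experimental data, so the entire
testing and comparison pipeline runs unchanged on model output. The
model's signature is a positive correlation between per-area ln(mean ρ)
and var(ln ρ) (both increase with proliferation time); the implementation
reports Pearson r with a one-sided p-value from the t-distributed Wald
statistic r√((n − 2)/(1 − r²)).

## Parameter estimation

Defaults (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| ℓ (day) | 1.5 | progenitor cell-cycle length → λ = ln 2/ℓ ≈ 0.462/day |
| t½ (day) | 45 | median proliferation time per area |
| window (day) | [30, 60] | plausible range of proliferation times |
| tail mass | 0.02 | probability allowed outside the window |
| Δt (day) | 0.05 | integration step |
| ρ₀ (cells/mm³) | 3.8e3 | initial progenitor density |

The recipe: (i) λ = ln 2/ℓ; (ii) μ̂_y = mean over areas of f⁻¹(v_i),
the exact MLE under the σ_N² likelihood because the Jacobian does not
depend on μ_y (verified against direct numerical maximization);
(iii) σ from the median constraint y(t½) = μ̂_y; (iv) σ_y² from the
tail-mass equality Φ((y(30) − μ_y)/σ_y) + 1 − Φ((y(60) − μ_y)/σ_y) =
0.02; (v) ρ₀ = exp(mean ln⟨ρ_N⟩ − μ̂_y).

Steps (ii) and (iii) are mutually dependent — f⁻¹ contains σ. A naive
alternation can start outside the admissible domain (μ̂_y evaluated at a
provisional σ may fall below the σ → 0 limit ln(λt½) of y(t½), where no
root exists). The dependence, however, cancels exactly: both μ̂_y and
y(t½) carry the same additive −2 ln σ, so the median constraint
determines σ in closed form,

    σ² = (2/t½) ln(1 + e^T),   T = mean_i ln g(v_i) − ln 2,
    g(v) = √(8(3eᵛ − 1)) − 4,

and μ̂_y follows by substitution. `estimate_all` uses this joint
solution and reports both constraint residuals (< 1e−8). The standalone
root solvers (`solve_sigma`, `solve_sigma_y`) use bracketed Brent
iteration with analytic monotonicity guarantees and 1e−12 tolerances.

The tail constraint is solved as an equality at 2%; σ_y² is a convention
fixed by the window and tail mass, not a quantity estimated from the
spread of the data.

## Synthetic data

`generate_species_table` draws one density per area with
ln ρ ~ Normal(log_mean, log_sd²); defaults log_mean = 11.3, log_sd = 0.3
put geometric-mean densities at plausible cortical magnitudes
(~8×10⁴ cells/mm³, consistent with ln ρ₀ + μ_y at the calibrated model
parameters) without copying any species' actual values. Outliers are
injected as z-offsets on the log scale so the |z| ≥ 3 exclusion rule's
behavior is exactly controllable. `generate_cortex_table` wraps the full
model simulation (114 areas, Poisson(36.6) frames).

What the generators do *not* emulate: spatial arrangement and
area-to-area covariance, layer-resolved depth profiles, inter-subject
variability, measurement error of counting methods, and glia-specific
proliferation dynamics. Passing tests on generated data therefore show
that the pipeline is correct and calibrated under its own model
assumptions, not that any particular real data set satisfies them.

## Problem sizes and numerical choices

Monte-Carlo checks use 10⁵ paths for moment oracles (3-standard-error
bands), 20 seeds for calibration fractions, and 114-area cortices (the
study-scale configuration) for recovery tests; the acceptance script
averages the mean–variance correlation over 40 independent cortex
simulations. Quadrature oracles use adaptive Gauss–Kronrod integration
at 1e−10 relative tolerance. Degenerate inputs (σ = 0, σ_y² = 0, zero
variance groups) are handled by exact limit branches rather than
epsilon-regularization; zero-variance correlations return NaN.

## Known limitations

- ρ_N is the integral of a correlated lognormal process and is only
  approximately lognormal. The matched-moment approximation leaves a
  residual log-skewness of ≈ 0.14 at the calibrated parameters, so a
  Shapiro–Wilk test at n = 2000 distinguishes the simulated densities
  from an exact lognormal in roughly half of realizations; within-area
  samples (n ≈ 37) are far below that detection threshold.
- The constant-rate, λ_P = λ_N simplification is used for all closed
  forms and estimation; the general time-dependent theory is exercised
  only through quadrature oracles in the tests.
- Apoptosis, tangential migration, volumetric growth, and area-specific
  proliferation rates are outside the model.
- Estimates are point values; no uncertainty quantification is provided.
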