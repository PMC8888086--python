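# Methods

## Model

The power-modified Lindley (PML) family is the law of `T^(1/α)` for `T`
modified-Lindley with rate `θ`.  Both parameters are dimensionless and
strictly positive; construction rejects anything else, including
non-finite values.  With `u = θ x^α`,

```
F(x) = 1 − e^(−u)(1 + u e^(−u)/(θ+1)),
f(x) = θα/(θ+1) e^(−2u) x^(α−1) ((1+θ)e^u + 2u − 1).
```

`α = 1` reduces to the modified Lindley pointwise; the family is closed
under power transforms (`X^(1/c) ~ PML(cα, θ)`), which the tests exercise
through quantiles.

### Numerical choices

* **Log-space density.**  The bracket `(1+θ)e^u + 2u − 1` overflows for
  moderate `u`; the log-density divides it by `e^u` first:
  `log f = log(θα/(1+θ)) + (α−1)log x − u + log((1+θ) + (2u−1)e^(−u))`.
  The survival function is likewise computed as
  `e^(−u) + u e^(−2u)/(θ+1)` and the hazard as `exp(logpdf − logsf)`, so it
  stays finite deep in the tail where density and survival underflow
  together.
* **Quantile.**  No closed inverse exists (the cdf mixes `e^(−u)` and
  `e^(−2u)`).  The root of `F(x) = p` is bracketed by geometric expansion
  from the natural scale `(1/θ)^(1/α)` and resolved by vectorised
  bisection to full floating-point resolution (the round-trip
  `F(F⁻¹(p)) = p` holds to 1e−10).
* **Moments.**  Raw moments use the closed form
  `μ'_r = Γ(r/α+1)/θ^(r/α) (1 + (r/α)/(2^(r/α+1)(1+θ)))` — re-derived from
  the density, because circulated versions of this formula carry a garbled
  exponent — and are verified against quadrature, which is the arbiter.
  Incomplete moments use *non-regularised* incomplete gamma functions
  (SciPy's regularised routines are rescaled by `Γ(s)`).  The identity
  `ψ_s(t) + ϑ_s(t) = μ'_s` is tested to 1e−10.
* **MGF.**  Computed by adaptive quadrature, not the power series: the
  series' radius of convergence is uncharacterised, so it is kept only as
  a small-`|t|` cross-check.  The integral converges iff `α > 1`, or
  `α = 1` with `t < θ`, or `t ≤ 0`; arguments outside this region raise.
* **Degenerate inputs.**  `x = 0` is legal for the cdf (returns 0) but not
  the density or hazard: the density limit at 0 depends on `α` (0, finite
  or +∞), and returning it is deliberately not attempted.

## Maximum likelihood

The log-likelihood is the sum of log-densities.  (Some circulated
presentations of this likelihood omit the `(α−1)Σ log x_i` term and the
matching `Σ log x_i` in the α-score; the implementation keeps the correct
form, which equals `Σ log f` by construction.)  The analytic score is
implemented in the same overflow-safe form as the density and is tested
against central finite differences at 1e−5 relative.

Optimisation runs on `(log α, log θ)` — positivity for free, and the
likelihood surface is flat in `θ` near 0 on the raw scale — with L-BFGS-B
from four deterministic starts (`α ∈ {0.5, 1, 2, 4}`, `θ` seeded by
inverting the leading term of `E[X^α]`), followed by a Nelder-Mead polish
whenever the gradient is not already negligible.  A bare Newton-Raphson on
the score equations is retained as `method="newton"` for comparison with
older analyses.  The `converged` flag requires the score norm at the
optimum to be below `1e−4·n`; non-convergence is reported, never silently
returned.

Standard errors come from the **observed information** (central-difference
Jacobian of the analytic score at the optimum), not the expected Fisher
information: the expectations have no tractable closed form for this
family, and the observed information is the standard field practice.
Confidence intervals are Wald, `estimate ± z_{γ/2}·se`.

### Comparator families

Four alternatives ship for model comparison, with the parametrisations
fixed as: power Lindley (exponent `β`, rate `θ` inside `e^(−θx^β)`),
Weibull `F = 1 − e^(−(x/λ)^β)`, inverse Weibull `F = e^(−(λ/x)^β)`, Lomax
`F = 1 − (1 + x/λ)^(−β)`.  Weibull/inverse-Weibull/Lomax log-densities are
delegated to `scipy.stats`; the power Lindley is written out.  The Weibull
fit is cross-checked against `scipy.stats.weibull_min.fit(floc=0)` in the
tests — an independent route to the same MLE.

### Goodness of fit

`gof` computes the classical one-sample statistics on the sorted sample:
the two-sided KS sup-distance, the Cramér–von Mises statistic
`1/(12n) + Σ(F(x_(i)) − (2i−1)/(2n))²`, and the Anderson–Darling
statistic.  The KS p-value uses the asymptotic Kolmogorov distribution of
`√n·D` even though parameters were estimated — matching how these numbers
are usually reported — and a warning states that it is therefore not
calibration-valid.  CvM/AD are the uncorrected classical statistics;
small-sample corrected variants sit behind `corrected=True`.  Fitted cdf
values at 0 or 1 are clamped to `[1e−15, 1−1e−15]` with a warning.

### Reproducibility of published fits for these datasets

The published point estimates for the packaged datasets (PML on the
COVID-19, jute and bank samples, and the joint stress-strength fits) are
**not** stationary points of the likelihood of the printed data: the
analytic score there is far from zero (COVID: `∇ℓ ≈ (5.0, 109.1)`), the
likelihood is strictly higher at this package's optimum (−20.35 vs
−20.76), and an independent R `optim` run (BFGS and Nelder-Mead,
`reltol=1e−14`) agrees with this package to five significant figures.
The KS statistics recomputed *at the published parameter values* match the
published KS values to four decimals, which isolates the discrepancy to
the original optimiser stopping short of the optimum.  The power-Lindley
fit on the COVID data is reproduced exactly (β = 3.8650, θ = 0.0947).
One consequence: at full convergence the power Lindley attains a higher
likelihood and smaller KS distance than PML on the COVID sample, so the
"PML fits best" ranking does not survive proper optimisation.  This
package always reports full-convergence values.

## Bayesian estimation

Independent gamma priors `α ~ Gamma(w₁, q₁)`, `θ ~ Gamma(w₂, q₂)` (shape,
**rate** — the rate convention is forced by the moment identities
`mean = w/q`, `var = w/q²` used in elicitation).  The posterior kernel is
built directly as likelihood × prior; a circulated closed-form kernel for
this model carries an `e^(−α(Σln x + q₁))` factor that contradicts the
likelihood's `Πx^(α−1)` term for data above 1, so it is not used.

**Elicitation.**  The hyperparameters are moment-matched (`w = m²/s²`,
`q = m/s²`, sample variance with `k−1`) against `k` replicate estimates.
The replicates for a single observed dataset are generated by
nonparametric bootstrap refits of the MLE (default `k = 100`, seeded) —
a data-driven choice that satisfies the moment equations exactly and is
fully reproducible; other sources of replicates can be passed in directly.
Zero-variance replicates raise an error instructing a manual prior.

**Sampler.**  Gaussian random walk on `(log α, log θ)` with the log-scale
Jacobian added to the target, so positivity needs no rejection handling.
The chain starts at the MLE; proposal scales start at `2.4·se/estimate`
and adapt toward ~0.3 acceptance every 100 iterations **during burn-in
only**, then freeze — detailed balance holds for every retained draw.
Defaults: 10,000 iterations, 2,000 burn-in.  The generic kernel is
validated on a conjugate target (exponential likelihood × gamma prior)
where the posterior mean and variance are known exactly.

**Loss-based estimators.**  SELF → posterior mean; LINEX →
`−(1/c)·log E[e^(−cΩ)]` via log-sum-exp; entropy → `(E[Ω^(−b)])^(−1/b)`,
with `b = −1` returning the mean exactly.  Jensen orderings (LINEX below
the mean for `c > 0`, entropy at or below the mean for `b ≥ −1`) are
property-tested.  Default asymmetry constants `c, b = ±1.5`.

**HPD intervals.**  Chen–Shao: among sorted-draw windows
`(ω_(j), ω_(j+m))` with `m = ⌈(1−γ)A⌉`, the shortest wins, ties to the
smallest index.  The HPD is never wider than the equal-tailed interval at
the same level (tested).

## Stress-strength reliability

With a common shape, `R = P(Y < X)` depends only on the rates.  The
closed form was obtained by integrating the base modified-Lindley cdf
against the base pdf term by term (two exponential-polynomial integrals);
it satisfies `R(θ, θ) = 1/2` exactly, `R(a, b) + R(b, a) = 1`, and agrees
with adaptive quadrature of `∫F_Y f_X` to 1e−10 on a 20×20 log-grid — all
asserted in tests.  A second evaluator, `reliability_as_printed`,
transcribes the erroneous closed form that circulates for this model
(which fails the 1/2 identity, giving ≈0.396 at equal unit rates); it is
retained because published tables reflect it, every call warns, and the
CLI labels its output non-validated.  The transcription is the unique
reading of the ambiguous source expression that reproduces those published
table values.

Joint MLE maximises the three-parameter likelihood in log space from
three deterministic starts (common `α` seeded at the mean of the marginal
shape fits).  The delta method gives
`σ_R² = Bᵀ I⁻¹ B` with `B = (0, ∂R/∂θ₁, ∂R/∂θ₂)` — the first component is
identically zero because `R` is free of `α` — where the partial
derivatives are hand-differentiated from the closed form (term-by-term)
and verified against finite differences at 1e−6.  The reported interval
for `R` is clipped to `[0, 1]`; the unclipped interval is retained and
used for the coverage test (nominal 95% covering 90–98% at `n = m = 140`).
Unequal shapes (`α_x ≠ α_y`) are out of scope: the α-free reduction
requires a common exponent.

## Synthetic data and the simulation engine

Samples are generated by the inverse-cdf transform of uniforms — exact,
not approximate — so the generator inherits the quantile's accuracy; the
generator is the same code path users call as `PML.rvs`.  What it does
*not* emulate: real lifetime data are typically censored, rounded and
contaminated; all simulated samples here are complete, exact i.i.d. draws.
Passing tests therefore certify the estimators under the model, not
robustness to misspecification.

The engine draws `L` replicates per cell (truth × size), refits each, and
reports `bias = mean(est) − truth`, `mse = mean((est − truth)²)` and the
mean interval length (Wald for the MLE, HPD for Bayesian estimators, which
is an assumption — reduced-length per-replicate chains of 3,000/1,000 with
`k = 50` bootstrap elicitation keep the Bayesian arm affordable).
Replicate failures are excluded and counted; a cell losing more than 10%
of replicates is flagged.  Child seeds come from `SeedSequence.spawn`, so
reports are bit-reproducible.

The default `L = 500` (configurable) is a deliberate reduction from the
5,000 used in large published studies: the engine's acceptance checks are
directional (bias/MSE monotone in `n`, coverage within [90%, 98%]) rather
than cell-value reproductions, because published cell values for this
model are internally inconsistent (e.g. a rate-parameter bias that fails
to shrink with `n`, and stress-strength "Mean" columns that match neither
reliability evaluator's truth).  At `L = 500` the directional assertions
hold with wide margin.

## Known limitations

* Wald intervals and delta-method intervals are first-order asymptotics;
  no profile-likelihood or bootstrap intervals are provided.
* The KS/CvM/AD p-values ignore parameter estimation (by design, with a
  warning); parametric-bootstrap calibration is out of scope.
* Model selection criteria (AIC/BIC) are not reported.
* MCMC diagnostics are limited to the acceptance rate and trace plots;
  no R-hat / ESS machinery is bundled.
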