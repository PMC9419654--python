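# Methods

## Model

The package works with the time-inhomogeneous lognormal diffusion

    dX(t) = h(t) X(t) dt + σ X(t) dW(t),     X(t₀) = X₀,

whose relative drift `h(t) = P(t)e^{-Q(t)}/(η + e^{-Q(t)})` is the growth
rate of the multi-sigmoidal logistic curve; `Q(t) = Σ_{i=1..p} βᵢ tⁱ` has
no constant term and a positive leading coefficient, so `Q → ∞` and the
mean saturates at the carrying capacity `E[X₀](η + e^{-Q(t₀)})/η`.  The
model assumes multiplicative Gaussian noise with constant intensity σ on
the log scale and an initial state that is either fixed (`X₀ = x₀`) or
lognormal.  Under either start, all finite-dimensional laws are
lognormal, with exact transition

    log X(t) | X(s) = z  ~  N( log z + H(s,t),  σ²(t-s) ),
    H(s,t) = log[(η+e^{-Q(s)})/(η+e^{-Q(t)})] - σ²(t-s)/2.

Everything downstream exploits this closed form; no time-discretization
approximation enters anywhere except the Volterra quadrature of the
first-passage density.

`log(η + e^{-Q})` is always evaluated as `logaddexp(log η, -Q)` and the
ratio `(η - e^{-Q})/(η + e^{-Q})` as `tanh((Q + log η)/2)`, so transient
negative excursions of `Q` (non-monotone curves) cannot overflow.

The leading-coefficient constraint `β_p > 0` is enforced when a
coefficient set is constructed as a model object.  Estimation routines
deliberately relax it (`require_positive_leading=False`): on noisy data
the score equations of an overparametrized degree typically have their
root at a slightly negative `β_p`, which is perfectly evaluable on a
bounded window — it just has no carrying capacity, which is one reason
such degrees lose the information-criterion comparison.

## Simulation

Paths are sampled by chaining exact lognormal transitions on the
requested grid; a master seed spawns one RNG substream per path, so a
panel is bit-reproducible and path `i` does not depend on how many paths
are drawn.  The built-in study design covers the 32 combinations of
`β₁ ∈ {0.1, 0.5}`, `β₂ ∈ {-0.009, -0.007}`, `β₃ ∈ {0.0002, 0.0003}`,
`η ∈ {e⁻¹, e⁻³}`, `σ ∈ {0.01, 0.05}`, with `x₀ = 5` on an equidistant
grid over `[0, 50]` (defaults: 200 paths, 501 points).

The generator emulates panels of independent trajectories observed
without measurement error at known times, with exactly lognormal
transition noise.  Real growth data (e.g. cumulative case counts) add
features it does not model: reporting noise and revisions, weekday
cycles, correlated shocks across paths, and non-multiplicative
catastrophes.  Passing tests therefore demonstrate correctness of the
estimators under the model, not robustness to those violations.

## Likelihood and estimation

For `d` paths observed at times `t_{ij}` the increments are reduced by
`v_{ij} = Δ^{-1/2} log(x_{i,j+1}/x_{ij})`, turning the transition part of
the likelihood into a Gaussian sum.  The part depending on
`ξ = (η, β, σ²)` is

    L̃(ξ) = -(n/2) log σ² - (Z₁ + Φ - 2Γ) / (2σ²),

with `n = Σ(nᵢ - 1)` transitions; its critical points solve `p + 2`
equations — one in σ² (quadratic, with a closed-form nonnegative root
used by the profiled solver) and `p + 1` from the θ-gradient.  The
aggregates `Z₂ = Σ v√Δ` and `Z₃ = Σ Δ` (total elapsed time summed over
paths) tie the raw blocks `A, B, C` to `Φ, Γ` through identities that the
test suite checks to 1e-10.  The estimates of a lognormal initial law are
the sample mean and (divisor `d`) variance of the log initial values.

One sign subtlety: the derivative of the per-step transition mean with
respect to η is `+D₀` while the β-derivatives are `-D_l` (the shared
building block `D` has the η-component with opposite orientation, since
`∂/∂η log(η + e^{-Q}) > 0`).  The score system is insensitive — negating
one equation leaves its zero set unchanged — but the Fisher matrix is
not, and `fisher_information` uses the correct mixed signs; a
finite-difference brute-force oracle pins this down in the tests.

**Starting values.**  Approximating the carrying capacity by the final
sample mean `m_N`, the transform `-log(m_N/m_j - 1)` is `Q(t_j) + log η`,
so an ordinary polynomial regression yields starting values for
`(β, log η)`; pairs with `m_j ≥ m_N` are dropped (their logarithm is
undefined — noise can push late means above the final value).  The
starting σ² is the through-origin regression slope of
`2 log(m_j/m_j^g) - σ₀²` on `t_j` (arithmetic over geometric
cross-section means estimate the log-scale variance `σ₀² + σ²t`), floored
at 1e-8; σ₀² defaults to the initial-law variance estimate.

**Newton–Raphson.**  Damped Newton on the score system: central
finite-difference Jacobian (relative step 1e-6), step halving (max 50)
accepting only residual-norm decreases, convergence at
`‖residual‖∞ < 1e-10` or step below 1e-12, at most 200 iterations;
non-convergence is returned as a flagged result with diagnostics, never
silently.  Two numerical choices matter in practice:

- *time rescaling*: all times are shifted to `t - t₀` and divided by the
  panel's span, so the Vandermonde-like structure of the θ-equations
  stays well conditioned at degrees 5-6 (on the raw clock, `t⁶ ≈ 10¹⁰`
  makes the finite-difference Jacobian unusable); coefficients are mapped
  back afterwards.  Fitted polynomials are therefore polynomials in
  `t - t₀`.
- *profiling (optional)*: substituting the closed-form σ²(θ) root each
  iteration reduces the system to `p + 1` equations; on the panels tested
  both variants converge to the same solution.

**Simulated annealing.**  Minimizes `-L̃` inside a box: geometric cooling
`T ← 0.95 T` from a pilot-estimated `T₀ = -Δf⁺/log 0.9` (mean positive
increment over a 100-move random walk), 50 moves per stage, stopping on
stagnation (50 consecutive moves leaving the incumbent value unchanged
within 1e-12), 1000 stages, or `T ≤ 1e-7`.  Proposals are uniform in a
box of half-width 0.1 × interval length per coordinate, clipped to the
bounds.  Because single runs are noisy, the estimate averages 10
independent runs (a best-of-run option and an optional single Newton
polish exist but are off by default).

**Bounding box.**  η is bounded by the range over paths of
`(x_{i,last}/x_{i,first} - 1)⁻¹`; σ² by `(0, 0.01)`.  For β we bound each
coefficient by the hull over paths of per-path polynomial-regression
estimates (each path supplies its own carrying-capacity proxy and
regression).  A pooled-regression confidence interval — the natural
first idea — is badly anti-conservative here: the sample means at
different times share the same underlying paths, so the regression errors
are strongly serially correlated and the log transform amplifies noise
near saturation; empirically such intervals almost never contain the
generating coefficients, whereas the per-path hull (the same
range-over-paths idea as the η bound) covers them reliably at both the
50-path and 200-path design scales.  Single-path panels fall back to the
0.999-level regression interval.

## Asymptotics

`I(ξ)` is assembled exactly from the per-step mean gradients
(`Ξ = Σ Δ⁻¹ (∂m)(∂m)ᵀ`, corner `n/(2σ²) - Z₃/4`, all divided by σ²) and
inverted after diagonal equilibration — the raw matrix mixes scales like
`t⁶` and σ⁻⁴, so equilibration is what keeps 95 % intervals usable at
degree 3 and beyond; a pseudo-inverse with a warning is the fallback past
condition 1e12.  Delta-method intervals accept an analytic or
finite-difference gradient.  The initial-law estimates have exact
pivots: normal for the location, `χ²_{d-1}` for the variance.  A
scaled-down coverage experiment (40 seeded panels) keeps the nominal 95 %
interval for β₁ honest in the test suite.

## Goodness of fit and degree selection

Four measures compare a fitted process with its panel: mean absolute
relative error between sample and fitted mean curves (RAE); AIC
`2(p+2) - 2L` and BIC `(p+2)log n - 2L` on the full log-likelihood (the
reduced one when the start is degenerate — the initial factor then
carries no information); and the resistor-average distance — the harmonic
mean of the two directed Kullback–Leibler divergences — between the
lognormal law implied by the cross-section moments (`μ̂_t = log m_g(t)`,
`σ̂_t² = 2 log(m/m_g)`) and the fitted law, tracked over time (a flag
substitutes the exact generating law when it is known).

Selection fits every degree in range and picks the BIC minimizer, with
AIC, then the median distance, then the smaller degree as tie-breaks.
RAE is reported but never decisive: it improves essentially monotonically
with degree.  The same is true, more weakly, of the distance measure once
overparametrized degrees actually converge — with the rescaled solver
they do, and their extra coefficients sit near zero — which is why an
explicitly penalized criterion has to anchor the rule.

## First-passage time

For a constant boundary `S > x₀` and fixed start, `log X` is a
deterministic drift plus `σW`, so the crossing is that of a standard
Wiener process through the moving boundary
`b(u) = [log(S/x₀) - H(t₀, t₀+u)]/σ`, with `b'(u) = (σ/2) - h(t₀+u)/σ`.
The density solves a second-kind Volterra equation with the classical
Wiener kernel `Ψ(u|y,s) = φ(b(u); y, u-s)[b'(u)/2 - (b(u)-y)/(2(u-s))]`;
the kernel vanishes on the diagonal, so the composite-trapezoid recursion
is explicit.  Sanity is pinned by two independent routes: the
inverse-Gaussian closed form for a constant Wiener boundary (special
case) and a 20,000-path exact-simulation Monte-Carlo comparison of the
cumulative (Kolmogorov–Smirnov distance < 0.02 required).

**Localization and truncation.**  The crossing-probability function
`FPTL(t) = P[X(t) > S | X(t₀) = x₀]` localizes the density: the grid's
scale is set by the width of its rise (default step: rise width / 1000),
and the recursion stops once the accumulated mass exceeds 0.99 and the
density has fallen below 1e-4 of its peak.  The run refuses a result
whose mass falls outside `[0.99, 1.001]` (coarse step or truncated
window).  When `S` lies below the carrying capacity, the density has a
long thin right tail: on the Wiener clock the boundary rises at the slow
rate σ/2, so paths that miss the main window cross over a scale of
hundreds of time units (and a small fraction, reported as
`1 - total_mass`, never crosses).  Consequently the *standard deviation
of the truncated density is not a stable summary*: it grows with the
truncation horizon long after the mean, mode and deciles have stabilized
(for the worked example: sd ≈ 1.00 at T = 44, 1.43 at T = 200, 1.82 at
T = 500, while the mean moves only from 40.19 to 40.24).  The reported
summaries are those of the trimmed, renormalized density; users who need
tail-sensitive moments should extend `horizon` and pass an explicit
`step`, and should treat the sd as conditional on the reported window.

Mode is refined by three-point parabolic interpolation around the grid
argmax; deciles invert the piecewise-linear cumulative.  Only constant
boundaries with `S > x₀` are in scope; the kernel interface is the
extension point for time-varying boundaries.

## Problem sizes used in the checks

The acceptance script and end-to-end tests use 50 paths × 201 points for
parameter recovery and degree selection, 50 paths × 361 points (step 0.1)
for the simulate-fit-FPT chain, 20,000 paths at step 0.005 for the
Monte-Carlo first-passage oracle, and ~4,500-9,000 grid points for the
Volterra recursion — sizes at which every stochastic tolerance asserted
in the tests holds with margin across the seeds tried.

## Known limitations

- The observation grid must share a common first time across paths;
  ragged interiors are supported, the degree-selection moments require a
  common grid.
- The β bounding box and the initial guesses assume growth data that
  approach saturation within the window; strongly censored growth (final
  mean far from the carrying capacity) biases the regression transform.
- Downward crossings (`S < x₀`) and time-varying boundaries are not
  implemented.
- The SA method's averaged-runs estimator can average across distinct
  local maxima if the likelihood is multi-modal within the box; the
  best-of-run option is the remedy when that is suspected.
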