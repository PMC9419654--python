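# msldiff

Inference and first-passage-time analysis for **lognormal diffusion
processes with a multi-sigmoidal logistic mean** — stochastic growth
models for populations that saturate after passing through several
distinct growth phases (multi-wave epidemics, stage-wise tumour or
microbial growth, adoption curves with successive pushes).

## The model

The deterministic backbone is the multi-sigmoidal logistic curve: with a
polynomial `Q(t) = β₁t + β₂t² + … + β_p tᵖ` (no constant term, `β_p > 0`)
and `P = dQ/dt`, the curve solves `l'(t) = h(t) l(t)` with relative growth
rate

    h(t) = P(t) e^{-Q(t)} / (η + e^{-Q(t)}),   η > 0,

so that `l(t) = l₀ (η + e^{-Q(t₀)}) / (η + e^{-Q(t)})`, saturating at the
carrying capacity `l₀ (η + e^{-Q(t₀)}) / η` with up to `p - 1` inflection
points.  Perturbing the growth equation with multiplicative white noise
gives the SDE

    dX(t) = h(t) X(t) dt + σ X(t) dW(t),

whose solution is an exactly lognormal diffusion: `log X(t)` is Gaussian
with drift accumulated through
`H(s,t) = log[(η+e^{-Q(s)})/(η+e^{-Q(t)})] - σ²(t-s)/2`.

The package provides:

- `process` — the curve, its inflection points, and the exact transition
  and marginal laws, means and percentiles of the diffusion;
- `simulate` — exact (discretization-free) path sampling, the 32-case
  simulation design, and Monte-Carlo first-passage sampling;
- `likelihood` — the v-transform of a panel of paths, the closed-form
  reduced log-likelihood, the nonlinear score system in
  `ξ = (η, β, σ²)`, regression-based starting values, and a damped
  Newton–Raphson fitter;
- `annealing` — simulated-annealing maximization of the reduced
  log-likelihood over a data-driven bounding box;
- `asymptotics` — Fisher information `I(ξ)`, delta-method confidence
  intervals, and the exact laws of the initial-distribution estimates;
- `goodness` — RAE, AIC, BIC, the resistor-average (symmetrized
  Kullback–Leibler) distance between sample and fitted laws over time,
  and BIC-driven polynomial-degree selection;
- `fpt` — the first-passage-time density through a constant boundary
  `S > x₀` via a second-kind Volterra integral equation solved by the
  composite trapezoid recursion, localized by the crossing-probability
  function;
- `panelio` / `cli` — long-format CSV panels and a `msldiff` command-line
  tool (`simulate`, `fit`, `select`, `fpt`, `ci`).

## Worked example

Simulate 50 sample paths of the cubic-polynomial process
(`β = (0.1, -0.009, 0.0002)`, `η = e⁻¹`, `σ = 0.01`, `X(0) = 5`), fit by
maximum likelihood, and approximate the first-passage density through
`S = 15`:

```python
import math
import numpy as np
from msldiff import (InitialLaw, PolynomialCoefficients, ProcessParams,
                     BoundarySpec, simulate_paths, fit_newton_raphson,
                     fpt_density, fpt_summaries)

params = ProcessParams(eta=math.exp(-1),
                       beta=PolynomialCoefficients((0.1, -0.009, 0.0002)),
                       sigma2=0.01 ** 2)
times = np.linspace(0.0, 50.0, 201)
panel = simulate_paths(params, InitialLaw.degenerate(5.0), times,
                       n_paths=50, seed=3)

fit = fit_newton_raphson(panel, p=3)
print(fit.xi_hat.eta, fit.xi_hat.beta.beta, math.sqrt(fit.xi_hat.sigma2))
# 0.363252 (0.0988516, -0.0088662, 0.0001974) 0.01009

dens = fpt_density(fit.xi_hat, BoundarySpec(S=15.0, x0=5.0, t0=0.0))
summary = fpt_summaries(dens)
# mean 40.11608   sd 1.04460   mode 39.83927
# d10 38.91460    d50 40.00736 d90 41.42545   total_mass 0.99951
```

The fit recovers the generating parameters to ~1 % from 50 noisy paths;
the first-passage summaries say the estimated population crosses the
level 15 around `t ≈ 40` with an ~80 % probability window of roughly
`[38.9, 41.4]`.  `total_mass` is the probability that the boundary is
crossed inside the reported grid; the small remainder sits in a long thin
right tail (see `docs/methods.md`).

The same workflow from the shell:

```sh
msldiff simulate --case 1 --n-paths 50 --n-times 201 --seed 3 --out panel.csv
msldiff select panel.csv --pmin 2 --pmax 6 --out degrees.csv
msldiff fit panel.csv --degree 3 --out fit.txt
msldiff fpt --eta 0.363252 --beta 0.0988516,-0.0088662,0.0001974 \
            --sigma2 1.018e-4 --x0 5 --boundary 15 --out fpt.csv
msldiff ci panel.csv --degree 3 --out intervals.csv
```

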