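"""Simulated-annealing maximization of the reduced log-likelihood.

The search minimizes f = -Ltilde over a bounded box: the eta interval
comes from the per-path endpoint ratios, the beta intervals from
0.999-level confidence intervals of the polynomial regression used for
the initial guesses, and sigma^2 is confined to (0, 0.01).  Cooling is
geometric; moves are uniform draws in a box-fraction neighborhood,
clipped to the bounds.  Because the algorithm is stochastic, the final
estimate averages several independent runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .likelihood import (MLEFit, VStatistics, _fit_loglik, _sample_means,
                         alpha_mle, v_transform)
from .process import PolynomialCoefficients, ProcessParams
from .simulate import SamplePanel


@dataclass
class SAConfig:
    p0: float = 0.9                # initial acceptance probability
    gamma: float = 0.95            # geometric cooling factor
    chain_length: int = 50         # moves per temperature stage
    T_final: float = 1e-7          # stopping temperature
    max_iter: int = 1000           # maximum temperature stages
    repeats: int = 10              # independent runs averaged
    neighborhood_frac: float = 0.1  # half-width fraction of each interval
    seed: int = 0
    best_of: bool = False          # return best-likelihood run, not average
    newton_polish: bool = False    # one Newton refinement of the average
    equal_tol: float = 1e-12       # tolerance of stopping rule (i)
    pilot_moves: int = 100

    def __post_init__(self):
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")


@dataclass
class Bounds:
    """Closed search intervals for eta, beta_1..beta_p and sigma^2."""

    eta: tuple[float, float]
    beta: list[tuple[float, float]]
    sigma2: tuple[float, float]

    def __post_init__(self):
        for lo, hi in [self.eta, *self.beta, self.sigma2]:
            if not lo < hi:
                raise ValueError(f"degenerate bound interval ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.eta[0], *(b[0] for b in self.beta),
                         self.sigma2[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.eta[1], *(b[1] for b in self.beta),
                         self.sigma2[1]])

    def contains(self, vec) -> bool:
        vec = np.asarray(vec, dtype=float)
        return bool(np.all(vec >= self.lower) and np.all(vec <= self.upper))


def _single_path_beta_regression(t: np.ndarray, x: np.ndarray, p: int):
    """Polynomial-regression estimate of beta from one trajectory.

    Approximates the carrying capacity by the path's last value and
    regresses -log[(x_N/x_j - 1) eta_i] on (t, ..., t^p) without an
    intercept; returns None when too few usable points remain.
    """
    ts = t - t[0]
    xN = x[-1]
    if xN <= x[0]:
        return None
    eta_i = 1.0 / (xN / x[0] - 1.0)
    keep = (x < xN) & (ts > 0)
    tj, xj = ts[keep], x[keep]
    if len(tj) < p + 1:
        return None
    y = -np.log((xN / xj - 1.0) * eta_i)
    design = np.vander(tj, p + 1, increasing=True)[:, 1:]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def parameter_bounds(panel: SamplePanel, p: int,
                     sigma2_upper: float = 0.01,
                     conf_level: float = 0.999) -> Bounds:
    """Bounded parametric space for the annealing search.

    eta: interval spanned by (x_{i,last}/x_{i,first} - 1)^{-1} over paths
    (paths that did not grow are excluded with a warning).  beta: the
    hull over paths of per-path polynomial-regression estimates of the
    coefficients — the same range-over-paths construction as the eta
    bound, which (unlike confidence intervals of the regression on the
    pooled sample means, whose errors are serially correlated across
    times) covers the generating coefficients reliably.  With a single
    path the 0.999-level regression confidence interval is used instead.
    sigma^2: (0, upper).
    """
    ratios = []
    for i, x in enumerate(panel.values):
        if x[-1] <= x[0]:
            warnings.warn(f"path {i} did not grow (x_last <= x_first); "
                          "excluded from the eta bound")
            continue
        ratios.append(1.0 / (x[-1] / x[0] - 1.0))
    if not ratios:
        raise ValueError("no growing path available to bound eta")
    a, b = min(ratios), max(ratios)
    if not a < b:  # single usable path: widen by a minimal pad
        pad = max(1e-6, 0.05 * a)
        a, b = a - pad, a + pad
        a = max(a, 1e-12)

    estimates = []
    for t, x in zip(panel.times, panel.values):
        coef = _single_path_beta_regression(t, x, p)
        if coef is not None:
            estimates.append(coef)
    if len(estimates) >= 2:
        est = np.asarray(estimates)
        beta_bounds = list(zip(est.min(axis=0), est.max(axis=0)))
    else:
        # single usable path: fall back to the regression's own intervals
        times, m, _ = _sample_means(panel)
        mN = float(m[-1])
        eta_hat = 1.0 / (mN / float(m[0]) - 1.0)
        keep = (m < mN) & (times > 0)
        t_j, m_j = times[keep], m[keep]
        y = -np.log((mN / m_j - 1.0) * eta_hat)
        design = np.vander(t_j, p + 1, increasing=True)[:, 1:]
        ols = sm.OLS(y, design).fit()
        ci = np.asarray(ols.conf_int(alpha=1.0 - conf_level))
        beta_bounds = [(float(lo), float(hi)) for lo, hi in ci]
    # intervals must be non-degenerate for the sampler
    beta_bounds = [
        (float(lo), float(hi)) if lo < hi else (float(lo) - 1e-9,
                                                float(hi) + 1e-9)
        for lo, hi in beta_bounds
    ]
    return Bounds(eta=(a, b), beta=beta_bounds, sigma2=(0.0, sigma2_upper))


def initial_temperature(objective, bounds: Bounds, config: SAConfig,
                        rng: np.random.Generator) -> float:
    """T0 = -mean positive increment / log p0, from a pilot random walk."""
    lower, upper = bounds.lower, bounds.upper
    width = config.neighborhood_frac * (upper - lower)
    x = rng.uniform(lower, upper)
    x[-1] = max(x[-1], 1e-12)
    f = objective(x)
    increments = []
    for _ in range(config.pilot_moves):
        x_new = np.clip(x + rng.uniform(-width, width), lower, upper)
        x_new[-1] = max(x_new[-1], 1e-12)
        f_new = objective(x_new)
        if f_new > f:
            increments.append(f_new - f)
        x, f = x_new, f_new  # accept everything in the pilot
    if increments:
        return float(np.mean(increments) / (-math.log(config.p0)))
    # all pilot moves were improving: fall back to the objective scale
    return max(abs(f), 1.0) / (-math.log(config.p0))


def _objective_factory(vstats: VStatistics):
    """Fast -Ltilde(xi) on a parameter vector [eta, beta.., sigma2].

    Avoids the full block computation: Ltilde only needs the per-step
    log-ratios lam, so Q is evaluated by Horner at the step endpoints and
    A, B, C are reduced directly.
    """
    t_lo, t_hi = vstats.t_lo, vstats.t_hi
    delta, v = vstats.delta, vstats.v
    sqrt_delta = np.sqrt(delta)
    Z1, Z2, Z3, n = vstats.Z1, vstats.Z2, vstats.Z3, vstats.n

    def objective(x: np.ndarray) -> float:
        eta, sigma2 = x[0], x[-1]
        if eta <= 0 or sigma2 <= 0:
            return float("inf")
        beta = x[1:-1]
        log_eta = math.log(eta)
        q_lo = np.zeros_like(t_lo)
        q_hi = np.zeros_like(t_hi)
        for b in beta[::-1]:
            q_lo = t_lo * (b + q_lo)
            q_hi = t_hi * (b + q_hi)
        lam = np.logaddexp(log_eta, -q_lo) - np.logaddexp(log_eta, -q_hi)
        m = lam - sigma2 / 2.0 * delta
        quad = Z1 + float(np.sum(m * m / delta)) \
            - 2.0 * float(np.sum(v * m / sqrt_delta))
        val = -n / 2.0 * math.log(sigma2) - quad / (2.0 * sigma2)
        return -val if np.isfinite(val) else float("inf")

    return objective


def _anneal_once(objective, bounds: Bounds, config: SAConfig,
                 rng: np.random.Generator):
    lower, upper = bounds.lower, bounds.upper
    width = config.neighborhood_frac * (upper - lower)
    T = initial_temperature(objective, bounds, config, rng)
    x = rng.uniform(lower, upper)
    x[-1] = max(x[-1], 1e-12)
    f = objective(x)
    best_x, best_f = x.copy(), f
    stagnant = 0
    acceptance_log = []
    for _ in range(config.max_iter):
        accepted = 0
        for _ in range(config.chain_length):
            x_new = np.clip(x + rng.uniform(-width, width), lower, upper)
            x_new[-1] = max(x_new[-1], 1e-12)
            f_new = objective(x_new)
            df = f_new - f
            if df <= 0 or rng.random() < math.exp(-df / T):
                if abs(f_new - f) < config.equal_tol:
                    stagnant += 1
                else:
                    stagnant = 0
                x, f = x_new, f_new
                accepted += 1
                if f < best_f:
                    best_x, best_f = x.copy(), f
            else:
                stagnant += 1
        acceptance_log.append(accepted / config.chain_length)
        if stagnant >= config.chain_length:
            break
        T *= config.gamma
        if T <= config.T_final:
            break
    return best_x, best_f, acceptance_log


def fit_simulated_annealing(panel: SamplePanel, p: int,
                            config: SAConfig | None = None,
                            bounds: Bounds | None = None) -> MLEFit:
    """SA maximization of Ltilde; averages ``config.repeats`` runs."""
    config = config or SAConfig()
    if bounds is None:
        bounds = parameter_bounds(panel, p)
    vstats = v_transform(panel)
    objective = _objective_factory(vstats)
    master = np.random.SeedSequence(config.seed)
    estimates, values = [], []
    for ss in master.spawn(config.repeats):
        rng = np.random.default_rng(ss)
        x_best, f_best, _ = _anneal_once(objective, bounds, config, rng)
        estimates.append(x_best)
        values.append(f_best)
    estimates = np.asarray(estimates)
    if config.best_of:
        x_hat = estimates[int(np.argmin(values))]
    else:
        x_hat = estimates.mean(axis=0)
    x_hat = np.clip(x_hat, bounds.lower, bounds.upper)
    x_hat[-1] = max(x_hat[-1], 1e-12)
    if config.newton_polish:
        from .likelihood import fit_newton_raphson
        polished = fit_newton_raphson(panel, p, x0=x_hat, max_iter=1)
        x_hat = polished.xi_hat.as_vector()
    xi = ProcessParams(eta=float(x_hat[0]),
                       beta=PolynomialCoefficients(tuple(x_hat[1:-1])),
                       sigma2=float(x_hat[-1]))
    alpha = alpha_mle(vstats)
    from .likelihood import system_residuals
    return MLEFit(alpha_hat=alpha, xi_hat=xi,
                  loglik=_fit_loglik(vstats, alpha, xi),
                  method="sa", converged=True,
                  iterations=config.repeats,
                  residual_norm=float(np.max(np.abs(
                      system_residuals(vstats, xi)))),
                  t0=panel.t0,
                  message=f"average of {config.repeats} runs")
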