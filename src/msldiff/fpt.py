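r"""First-passage-time density through a constant boundary.

On the log scale the diffusion started at a fixed x0 is a deterministic
drift plus a scaled Wiener process, so the first passage of X(t) through
a constant level S > x0 is the first passage of a standard Wiener process
W(u), u = t - t0, through the moving boundary

    b(u) = [log(S/x0) - H(t0, t0 + u)] / sigma,        b(0) > 0.

The FPT density g then solves a second-kind Volterra integral equation
with the classical Wiener kernel

    Psi(u | y, s) = phi(b(u); y, u - s) [ b'(u)/2 - (b(u) - y) / (2(u-s)) ],
    g(u) = -2 Psi(u | 0, 0) + 2 \int_0^u g(s) Psi(u | b(s), s) ds,

discretized by the composite trapezoid rule (the kernel vanishes on the
diagonal, so the recursion is explicit).  A localization function — the
probability P[X(t) > S | X(t0) = x0] as a function of t — identifies the
window where the density concentrates, which fixes the integration step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .process import ProcessParams, growth_rate_h, H_xi, carrying_capacity


class BoundaryUnreachable(RuntimeError):
    """The localization function never rises above threshold: effectively
    no passage within the searched horizon."""


@dataclass(frozen=True)
class BoundarySpec:
    """Constant boundary S with initial condition X(t0) = x0, S > x0."""

    S: float
    x0: float
    t0: float = 0.0

    def __post_init__(self):
        if not self.S > 0 or not self.x0 > 0:
            raise ValueError("S and x0 must be positive")
        if self.S == self.x0:
            raise ValueError("boundary must differ from the initial value")
        if self.S < self.x0:
            raise ValueError("only upward crossings (S > x0) are supported")


@dataclass
class FPTDensity:
    """Approximated first-passage density on a uniform grid."""

    grid: np.ndarray
    density: np.ndarray
    cumulative: np.ndarray
    step: float
    total_mass: float

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


def fptl(params: ProcessParams, boundary: BoundarySpec, t):
    """Localization function P[X(t) > S | X(t0) = x0] for t > t0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= boundary.t0):
        raise ValueError("fptl is defined for t > t0 only")
    dt = t - boundary.t0
    sigma = math.sqrt(params.sigma2)
    # C(t): standardized log-distance of the boundary under the transition law
    drift = np.asarray(H_xi(params, boundary.t0, t), dtype=float)
    c = (math.log(boundary.S / boundary.x0) - drift) / (sigma * np.sqrt(dt))
    return norm.sf(c)


def locate_fpt_window(params: ProcessParams, boundary: BoundarySpec,
                      search_horizon: float, eps: float = 1e-4,
                      n_grid: int = 5001, full: bool = False):
    """Window [t_lower, t_upper] containing essentially all the FPT mass.

    From the first time the localization function exceeds ``eps`` up to
    the first time after its maximum where it falls below ``eps`` times
    the maximum.  When the boundary lies below the carrying capacity the
    localization function plateaus near its maximum and decays only on
    very long time scales; the upper end is then capped at the horizon
    (the density solver trims the grid where the density itself dies
    out).  Raises :class:`BoundaryUnreachable` when the function never
    exceeds ``eps`` (e.g. S above the carrying capacity).

    With ``full=True`` also returns the time of the localization maximum.
    """
    t0 = boundary.t0
    grid = np.linspace(t0, search_horizon, n_grid)[1:]
    vals = fptl(params, boundary, grid)
    vmax = float(vals.max())
    if vmax <= eps:
        raise BoundaryUnreachable(
            f"localization max {vmax:.3e} <= eps={eps:.1e} on "
            f"({t0}, {search_horizon}]: boundary S={boundary.S} effectively "
            f"unreachable (carrying capacity "
            f"{carrying_capacity(params, boundary.x0, t0):.4g})")
    k_max = int(vals.argmax())
    above = np.nonzero(vals > eps)[0]
    t_lower = float(grid[above[0]])
    after = np.nonzero(vals[k_max:] < eps * vmax)[0]
    if len(after):
        t_upper = float(grid[k_max + after[0]])
    else:
        t_upper = float(grid[-1])
    if full:
        return t_lower, t_upper, float(grid[k_max])
    return t_lower, t_upper


def _volterra_density(params: ProcessParams, boundary: BoundarySpec,
                      t_upper: float, h: float,
                      tail_frac: float | None = None):
    """Trapezoid recursion for the Volterra equation on [t0, t_upper].

    With ``tail_frac`` set, the recursion stops early once the running
    cumulative exceeds 0.99 and the density has decayed below
    ``tail_frac`` times its running maximum (the residual mass sits in a
    long, thin tail; it is reported through the total mass).
    """
    t0 = boundary.t0
    sigma = math.sqrt(params.sigma2)
    n = int(math.ceil((t_upper - t0) / h))
    u = h * np.arange(1, n + 1)            # clock u = t - t0, u > 0
    t = t0 + u
    logratio = math.log(boundary.S / boundary.x0)
    # b(u) and b'(u) on the Wiener clock
    drift = np.asarray(H_xi(params, t0, t), dtype=float)  # includes -s^2 u/2
    b = (logratio - drift) / sigma
    bprime = (-np.asarray(growth_rate_h(params, t), dtype=float)
              + params.sigma2 / 2.0) / sigma
    g = np.zeros(n)
    sqrt2pi = math.sqrt(2.0 * math.pi)
    cum = 0.0
    g_max = 0.0
    n_used = n
    for k in range(n):
        uk, bk, bpk = u[k], b[k], bprime[k]
        # inhomogeneous term: -2 Psi(u_k | 0, 0)
        f0 = math.exp(-bk * bk / (2.0 * uk)) / (sqrt2pi * math.sqrt(uk))
        gk = -2.0 * f0 * (bpk / 2.0 - bk / (2.0 * uk))
        if k > 0:
            du = uk - u[:k]
            dy = bk - b[:k]
            fk = np.exp(-dy * dy / (2.0 * du)) / (sqrt2pi * np.sqrt(du))
            psi = fk * (bpk / 2.0 - dy / (2.0 * du))
            gk += 2.0 * h * float(psi @ g[:k])
        g[k] = gk
        if k > 0:
            cum += (g[k] + g[k - 1]) / 2.0 * h
        g_max = max(g_max, gk)
        if (tail_frac is not None and cum > 0.99 and g_max > 0
                and gk < tail_frac * g_max):
            n_used = k + 1
            break
    return t[:n_used], g[:n_used]


def fpt_density(params: ProcessParams, boundary: BoundarySpec,
                step: float | None = None, horizon: float | None = None,
                eps: float = 1e-4, n_steps_window: int = 4000,
                tail_frac: float = 1e-4) -> FPTDensity:
    """FPT density through the constant boundary via the Volterra recursion.

    The grid runs from t0 over the localized window with a uniform step
    (default: the width of the localization rise divided by
    ``n_steps_window / 4``, i.e. well below the density's own scale) and
    is trimmed where the density has decayed below ``tail_frac`` of its
    peak; any residual mass in the long thin tail shows up as
    ``1 - total_mass``.  Refuses when the accumulated probability mass
    falls short of 0.99, which signals a too-coarse step or a truncated
    window.
    """
    if horizon is None:
        # generous default: far beyond the localization maximum
        horizon = boundary.t0 + 1000.0
    t_lo, t_hi, t_peak = locate_fpt_window(params, boundary, horizon,
                                           eps=eps, full=True)
    if step is not None:
        h = step
    else:
        # the rise of the localization function sets the density's scale
        h = (t_peak - t_lo) / (n_steps_window / 4.0)
    t, g = _volterra_density(params, boundary, t_hi, h, tail_frac=tail_frac)
    if g.min() < -1e-12:
        raise RuntimeError(
            f"density went negative ({g.min():.3e}): decrease the step")
    g = np.clip(g, 0.0, None)
    cum = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2.0 * h)])
    mass = float(cum[-1])
    if mass < 0.99:
        raise RuntimeError(
            f"accumulated FPT mass {mass:.4f} < 0.99: refine the step "
            f"(h={h:.3g}) or extend the window [{t_lo:.3g}, {t_hi:.3g}]")
    if mass > 1.0 + 1e-3:
        raise RuntimeError(
            f"accumulated FPT mass {mass:.4f} exceeds 1: the step "
            f"(h={h:.3g}) is too coarse for the density's scale")
    return FPTDensity(grid=t, density=g, cumulative=cum, step=h,
                      total_mass=mass)


def fpt_summaries(dens: FPTDensity) -> dict[str, float]:
    """Mean, sd, mode and deciles of the (normalized) FPT density."""
    if dens.total_mass < 0.99:
        raise ValueError("insufficient mass for summaries")
    t, g = dens.grid, dens.density / dens.total_mass
    h = dens.step
    mean = float(np.trapezoid(t * g, t))
    var = float(np.trapezoid((t - mean) ** 2 * g, t))
    sd = math.sqrt(max(var, 0.0))
    # mode: parabolic interpolation around the grid argmax
    k = int(np.argmax(g))
    if 0 < k < len(g) - 1:
        y0, y1, y2 = g[k - 1], g[k], g[k + 1]
        denom = y0 - 2.0 * y1 + y2
        offset = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        mode = float(t[k] + offset * h)
    else:
        mode = float(t[k])
    cdf = dens.cumulative / dens.total_mass
    deciles = {}
    for q, name in [(0.1, "d10"), (0.5, "d50"), (0.9, "d90")]:
        deciles[name] = float(np.interp(q, cdf, t))
    return {"mean": mean, "sd": sd, "mode": mode, **deciles,
            "total_mass": dens.total_mass}
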