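"""Multi-sigmoidal logistic curve and the associated lognormal diffusion.

The deterministic growth curve solves l'(t) = h(t) l(t) with rate

    h(t) = P(t) e^{-Q(t)} / (eta + e^{-Q(t)}),

where Q(t) = sum_{i=1}^p beta_i t^i has no constant term and P = dQ/dt.
Replacing the deterministic drive by a multiplicative white noise of
intensity sigma yields the SDE dX = h(t) X dt + sigma X dW whose solution
is lognormal at every time: log X(t) is Gaussian with drift accumulated
through H(s, t) below.  All distributional quantities here are exact
(closed form), no quadrature is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm


@dataclass(frozen=True)
class PolynomialCoefficients:
    """Coefficients (beta_1, ..., beta_p) of Q(t) = sum beta_i t^i.

    The leading coefficient must be positive so that Q(t) -> +inf and the
    growth curve saturates at a finite carrying capacity.  Estimation
    routines may construct transient coefficient sets with
    ``require_positive_leading=False``: on noisy data the likelihood
    equations for an overfitted degree can have their solution at a
    (slightly) negative leading coefficient, which is perfectly evaluable
    on a bounded time window but has no carrying capacity.
    """

    beta: tuple[float, ...]
    require_positive_leading: bool = True

    def __post_init__(self):
        beta = tuple(float(b) for b in self.beta)
        object.__setattr__(self, "beta", beta)
        if len(beta) < 1:
            raise ValueError("at least one polynomial coefficient is required")
        if self.require_positive_leading and not beta[-1] > 0:
            raise ValueError(
                f"leading coefficient must be positive, got beta_p={beta[-1]}"
            )

    @property
    def degree(self) -> int:
        return len(self.beta)


@dataclass(frozen=True)
class ProcessParams:
    """Full diffusion parameter set xi = (eta, beta_1..beta_p, sigma^2)."""

    eta: float
    beta: PolynomialCoefficients
    sigma2: float

    def __post_init__(self):
        if not self.eta > 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")

    @property
    def degree(self) -> int:
        return self.beta.degree

    def as_vector(self) -> np.ndarray:
        return np.array([self.eta, *self.beta.beta, self.sigma2])

    @classmethod
    def from_vector(cls, vec) -> "ProcessParams":
        vec = np.asarray(vec, dtype=float)
        return cls(eta=vec[0], beta=PolynomialCoefficients(tuple(vec[1:-1])),
                   sigma2=vec[-1])


@dataclass(frozen=True)
class InitialLaw:
    """Initial state X(t0): degenerate at x0, or lognormal(mu0, sigma0sq)."""

    kind: str
    x0: float = float("nan")
    mu0: float = float("nan")
    sigma0sq: float = 0.0

    @classmethod
    def degenerate(cls, x0: float) -> "InitialLaw":
        if not x0 > 0:
            raise ValueError("x0 must be positive")
        return cls(kind="degenerate", x0=x0, mu0=math.log(x0), sigma0sq=0.0)

    @classmethod
    def lognormal(cls, mu0: float, sigma0sq: float) -> "InitialLaw":
        if not sigma0sq > 0:
            raise ValueError("sigma0sq must be positive for a lognormal start")
        return cls(kind="lognormal", x0=math.exp(mu0), mu0=mu0,
                   sigma0sq=sigma0sq)

    @property
    def mean(self) -> float:
        if self.kind == "degenerate":
            return self.x0
        return math.exp(self.mu0 + self.sigma0sq / 2.0)


@dataclass(frozen=True)
class LognormalLaw:
    """One-dimensional lognormal law Lambda_1(mu, s2) on the log scale."""

    mu: float
    s2: float

    def __post_init__(self):
        if not self.s2 > 0:
            raise ValueError("log-scale variance must be positive")

    @property
    def mean(self) -> float:
        return math.exp(self.mu + self.s2 / 2.0)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        s = math.sqrt(self.s2)
        return np.where(
            x > 0,
            np.exp(-((np.log(np.where(x > 0, x, 1.0)) - self.mu) ** 2)
                   / (2 * self.s2)) / (np.where(x > 0, x, 1.0) * s
                                       * math.sqrt(2 * math.pi)),
            0.0,
        )

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        s = math.sqrt(self.s2)
        return np.where(x > 0,
                        norm.cdf((np.log(np.where(x > 0, x, 1.0)) - self.mu) / s),
                        0.0)

    def ppf(self, q):
        return np.exp(self.mu + math.sqrt(self.s2) * norm.ppf(q))


def eval_Q(beta: PolynomialCoefficients, t):
    """Q(t) = sum_i beta_i t^i evaluated by Horner's scheme."""
    t = np.asarray(t, dtype=float)
    # Horner for a polynomial with no constant term: t*(b1 + t*(b2 + ...))
    acc = np.zeros_like(t)
    for b in reversed(beta.beta):
        acc = t * (b + acc)
    return acc


def eval_P(beta: PolynomialCoefficients, t):
    """P(t) = dQ/dt = sum_i i beta_i t^{i-1}."""
    t = np.asarray(t, dtype=float)
    acc = np.zeros_like(t)
    for i, b in reversed(list(enumerate(beta.beta, start=1))):
        acc = acc * t + i * b
    return acc


def _eval_dP(beta: PolynomialCoefficients, t):
    """Second derivative of Q."""
    t = np.asarray(t, dtype=float)
    acc = np.zeros_like(t)
    for i, b in reversed(list(enumerate(beta.beta, start=1))):
        if i >= 2:
            acc = acc * t + i * (i - 1) * b
    return acc


def log_eta_plus_exp_negQ(eta: float, Q):
    """log(eta + e^{-Q}) via log-add-exp; stable for strongly negative Q."""
    return np.logaddexp(math.log(eta), -np.asarray(Q, dtype=float))


def growth_rate_h(params: ProcessParams, t):
    """Relative growth rate h(t) of the deterministic curve."""
    Q = eval_Q(params.beta, t)
    P = eval_P(params.beta, t)
    # e^{-Q}/(eta+e^{-Q}) = expit(-(Q + log eta))
    return P * expit(-(Q + math.log(params.eta)))


def multisigmoidal_logistic(params: ProcessParams, l0: float, t0: float, t):
    """Deterministic curve l(t) = l0 (eta+e^{-Q(t0)})/(eta+e^{-Q(t)})."""
    a0 = log_eta_plus_exp_negQ(params.eta, eval_Q(params.beta, t0))
    at = log_eta_plus_exp_negQ(params.eta, eval_Q(params.beta, t))
    return l0 * np.exp(a0 - at)


def carrying_capacity(params: ProcessParams, l0: float, t0: float) -> float:
    """Limit of the curve as t -> inf: l0 (eta + e^{-Q(t0)}) / eta."""
    a0 = log_eta_plus_exp_negQ(params.eta, eval_Q(params.beta, t0))
    return float(l0 * np.exp(a0 - math.log(params.eta)))


def inflection_residual(params: ProcessParams, t):
    """Residual whose zeros are candidate inflection times of the curve.

    dP/dt - P^2 (eta - e^{-Q})/(eta + e^{-Q}); the bracket equals
    tanh((Q + log eta)/2), which is overflow-safe on both tails.
    """
    Q = eval_Q(params.beta, t)
    P = eval_P(params.beta, t)
    dP = _eval_dP(params.beta, t)
    return dP - P ** 2 * np.tanh((Q + math.log(params.eta)) / 2.0)


def find_inflections(params: ProcessParams, t_lo: float, t_hi: float,
                     n_grid: int = 2000) -> list[float]:
    """All sign-change roots of the inflection residual in [t_lo, t_hi]."""
    if not t_lo < t_hi:
        raise ValueError("t_lo must be less than t_hi")
    grid = np.linspace(t_lo, t_hi, n_grid)
    res = inflection_residual(params, grid)
    roots: list[float] = []
    sign = np.sign(res)
    for k in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = brentq(lambda x: float(inflection_residual(params, x)),
                      grid[k], grid[k + 1], xtol=1e-12, rtol=1e-15)
        roots.append(float(root))
    return sorted(roots)


def H_xi(params: ProcessParams, s, t):
    """Accumulated log-drift H(s, t) of log X between times s <= t.

    Closed form: log[(eta+e^{-Q(s)})/(eta+e^{-Q(t)})] - sigma^2 (t-s)/2.
    """
    a_s = log_eta_plus_exp_negQ(params.eta, eval_Q(params.beta, s))
    a_t = log_eta_plus_exp_negQ(params.eta, eval_Q(params.beta, t))
    return a_s - a_t - params.sigma2 / 2.0 * (np.asarray(t, float)
                                              - np.asarray(s, float))


def transition_law(params: ProcessParams, z: float, s: float,
                   t: float) -> LognormalLaw:
    """Conditional law of X(t) given X(s) = z, for s < t."""
    if not s < t:
        raise ValueError(f"transition requires s < t, got s={s}, t={t}")
    if not z > 0:
        raise ValueError("conditioning state z must be positive")
    return LognormalLaw(mu=math.log(z) + float(H_xi(params, s, t)),
                        s2=params.sigma2 * (t - s))


def process_mean(params: ProcessParams, init: InitialLaw, t0: float, t):
    """E[X(t)]: the initial mean carried along the deterministic curve."""
    return multisigmoidal_logistic(params, init.mean, t0, t)


def process_percentile(params: ProcessParams, init: InitialLaw, alpha: float,
                       t0: float, t):
    """alpha-percentile of X(t) for a (possibly degenerate) initial law."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    dt = np.asarray(t, float) - t0
    a0 = log_eta_plus_exp_negQ(params.eta, eval_Q(params.beta, t0))
    at = log_eta_plus_exp_negQ(params.eta, eval_Q(params.beta, t))
    z = norm.ppf(alpha)
    return np.exp(a0 - at) * np.exp(
        init.mu0 - params.sigma2 / 2.0 * dt
        + z * np.sqrt(init.sigma0sq + params.sigma2 * dt)
    )
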