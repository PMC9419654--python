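"""Likelihood machinery and the Newton-Raphson maximum-likelihood fitter.

A panel of d sample paths observed at discrete times is reduced by the
change of variables

    v0_i = x_{i,1},
    v_ij = dt_ij^{-1/2} log(x_{i,j+1} / x_{ij}),

under which the transition part of the log-likelihood becomes a Gaussian
sum.  The part depending on the process parameters xi = (eta, beta,
sigma^2) is

    Ltilde(xi) = -(n/2) log sigma^2 - (Z1 + Phi - 2 Gamma) / (2 sigma^2),

whose critical points solve a nonlinear system of p+2 equations: one
scalar equation in sigma^2 (with the closed-form positive root of
``sigma2_given_theta``) and p+1 equations indexed by l = 0..p coming from
the gradient in theta = (eta, beta).  The fitter runs damped Newton steps
on that system starting from regression-based initial values.

All times are shifted internally so that the first observation sits at 0;
the fitted polynomial is therefore a polynomial in t - t0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .process import (InitialLaw, LognormalLaw, PolynomialCoefficients,
                      ProcessParams, eval_Q, log_eta_plus_exp_negQ)
from .simulate import SamplePanel


@dataclass
class VStatistics:
    """Flattened step statistics of a panel after the v-transform."""

    v0: np.ndarray          # (d,) raw first observations x_{i,1}
    t_lo: np.ndarray        # (n,) left endpoint of each step (shifted, t0=0)
    t_hi: np.ndarray        # (n,) right endpoint of each step
    delta: np.ndarray       # (n,) step lengths
    v: np.ndarray           # (n,) scaled log-increments
    first_times: np.ndarray  # (d,) shifted first time of each path (zeros)
    last_times: np.ndarray   # (d,) shifted last time of each path
    t0: float               # original time origin of the panel

    @property
    def d(self) -> int:
        return len(self.v0)

    @property
    def n(self) -> int:
        return len(self.v)

    @property
    def Z1(self) -> float:
        return float(np.sum(self.v ** 2))

    @property
    def Z2(self) -> float:
        return float(np.sum(self.v * np.sqrt(self.delta)))

    @property
    def Z3(self) -> float:
        """Total elapsed time summed over paths (equals sum of all deltas)."""
        return float(np.sum(self.last_times - self.first_times))


@dataclass
class LikelihoodBlocks:
    """Per-step and aggregated quantities entering the likelihood system."""

    lam: np.ndarray      # (n,) log[(eta+e^{-Q(t_j)})/(eta+e^{-Q(t_{j+1})})]
    D: np.ndarray        # (p+1, n) per-step, per-l finite differences
    A: float             # sum lam^2 / delta
    B: float             # sum v lam / sqrt(delta)
    C: float             # sum lam
    W: np.ndarray        # (p+1,) per-path endpoint differences
    Y: np.ndarray        # (p+1,) sum (-lam/delta) D_l
    X: np.ndarray        # (p+1,) sum (v/sqrt(delta)) D_l

    def m_xi(self, sigma2: float) -> np.ndarray:
        """Per-step transition means m = lam - sigma^2 delta / 2."""
        return self.lam - sigma2 / 2.0 * self._delta

    _delta: np.ndarray = field(default=None, repr=False)

    def Phi(self, sigma2: float, vstats: VStatistics) -> float:
        m = self.m_xi(sigma2)
        return float(np.sum(m ** 2 / vstats.delta))

    def Gamma(self, sigma2: float, vstats: VStatistics) -> float:
        m = self.m_xi(sigma2)
        return float(np.sum(vstats.v * m / np.sqrt(vstats.delta)))

    def Yxi(self, sigma2: float) -> float:
        return float(np.sum(self.m_xi(sigma2)))


def v_transform(panel: SamplePanel) -> VStatistics:
    """Reduce a panel to the flattened step statistics."""
    t0 = panel.t0
    v0 = np.array([x[0] for x in panel.values])
    t_lo, t_hi, delta, v = [], [], [], []
    first, last = [], []
    for t, x in zip(panel.times, panel.values):
        ts = t - t0
        dt = np.diff(ts)
        t_lo.append(ts[:-1])
        t_hi.append(ts[1:])
        delta.append(dt)
        v.append(np.log(x[1:] / x[:-1]) / np.sqrt(dt))
        first.append(ts[0])
        last.append(ts[-1])
    return VStatistics(
        v0=v0,
        t_lo=np.concatenate(t_lo),
        t_hi=np.concatenate(t_hi),
        delta=np.concatenate(delta),
        v=np.concatenate(v),
        first_times=np.array(first),
        last_times=np.array(last),
        t0=t0,
    )


def alpha_mle(vstats: VStatistics) -> tuple[float, float]:
    """MLEs of the lognormal initial law: mean and variance of log v0.

    The variance uses divisor d (the maximum-likelihood convention), so a
    single path gives sigma1sq = 0.
    """
    logs = np.log(vstats.v0)
    mu1 = float(np.mean(logs))
    sigma1sq = float(np.mean((logs - mu1) ** 2))
    return mu1, sigma1sq


def _theta_step_quantities(vstats: VStatistics, eta: float,
                           beta: PolynomialCoefficients):
    """lam and the (p+1, n) D-matrix for all steps at a given theta."""
    log_eta = math.log(eta)
    Q_lo = eval_Q(beta, vstats.t_lo)
    Q_hi = eval_Q(beta, vstats.t_hi)
    a_lo = np.logaddexp(log_eta, -Q_lo)
    a_hi = np.logaddexp(log_eta, -Q_hi)
    lam = a_lo - a_hi
    p = beta.degree
    n = vstats.n
    D = np.empty((p + 1, n))
    # l = 0: no e^{-Q} factor; term is -1/(eta + e^{-Q})
    D[0] = -np.exp(-a_hi) + np.exp(-a_lo)
    # l >= 1: term is -t^l e^{-Q}/(eta + e^{-Q}) = -t^l expit(-(Q + log eta))
    sig_lo = expit(-(Q_lo + log_eta))
    sig_hi = expit(-(Q_hi + log_eta))
    pow_lo = np.ones(n)
    pow_hi = np.ones(n)
    for l in range(1, p + 1):
        pow_lo = pow_lo * vstats.t_lo
        pow_hi = pow_hi * vstats.t_hi
        D[l] = -pow_hi * sig_hi + pow_lo * sig_lo
    return lam, D


def likelihood_blocks(vstats_or_panel, theta) -> LikelihoodBlocks:
    """All block quantities (lam, D, A, B, C, W, Y, X) at theta=(eta, beta)."""
    vstats = (vstats_or_panel if isinstance(vstats_or_panel, VStatistics)
              else v_transform(vstats_or_panel))
    eta, beta = theta
    if not eta > 0:
        raise ValueError("eta must be positive")
    if not isinstance(beta, PolynomialCoefficients):
        beta = PolynomialCoefficients(tuple(beta))
    lam, D = _theta_step_quantities(vstats, eta, beta)
    sqrt_d = np.sqrt(vstats.delta)
    A = float(np.sum(lam ** 2 / vstats.delta))
    B = float(np.sum(vstats.v * lam / sqrt_d))
    C = float(np.sum(lam))
    # W_l telescopes over each path to the endpoint difference
    log_eta = math.log(eta)
    p = beta.degree
    d = vstats.d
    W = np.empty(p + 1)
    Q_first = eval_Q(beta, vstats.first_times)
    Q_last = eval_Q(beta, vstats.last_times)
    a_first = np.logaddexp(log_eta, -Q_first)
    a_last = np.logaddexp(log_eta, -Q_last)
    W[0] = float(np.sum(-np.exp(-a_last) + np.exp(-a_first)))
    sig_first = expit(-(Q_first + log_eta))
    sig_last = expit(-(Q_last + log_eta))
    pf = np.ones(d)
    pl = np.ones(d)
    for l in range(1, p + 1):
        pf = pf * vstats.first_times
        pl = pl * vstats.last_times
        W[l] = float(np.sum(-pl * sig_last + pf * sig_first))
    Y = D @ (-lam / vstats.delta)
    X = D @ (vstats.v / sqrt_d)
    return LikelihoodBlocks(lam=lam, D=D, A=A, B=B, C=C, W=W, Y=Y, X=X,
                            _delta=vstats.delta)


def reduced_log_likelihood(vstats_or_panel, xi: ProcessParams) -> float:
    """Ltilde(xi): the xi-dependent part of the log-likelihood."""
    vstats = (vstats_or_panel if isinstance(vstats_or_panel, VStatistics)
              else v_transform(vstats_or_panel))
    if not xi.sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    blocks = likelihood_blocks(vstats, (xi.eta, xi.beta))
    return _reduced_from_blocks(vstats, blocks, xi.sigma2)


def _reduced_from_blocks(vstats: VStatistics, blocks: LikelihoodBlocks,
                         sigma2: float) -> float:
    quad = (vstats.Z1 + blocks.Phi(sigma2, vstats)
            - 2.0 * blocks.Gamma(sigma2, vstats))
    return -vstats.n / 2.0 * math.log(sigma2) - quad / (2.0 * sigma2)


def log_likelihood(vstats_or_panel, alpha: tuple[float, float],
                   xi: ProcessParams) -> float:
    """Full log-likelihood L_V(alpha, xi), lognormal initial law.

    alpha = (mu1, sigma1sq) with sigma1sq > 0; a degenerate initial state
    is handled by ``reduced_log_likelihood`` instead.
    """
    vstats = (vstats_or_panel if isinstance(vstats_or_panel, VStatistics)
              else v_transform(vstats_or_panel))
    mu1, sigma1sq = alpha
    if not sigma1sq > 0:
        raise ValueError("sigma1sq must be positive; use the reduced "
                         "log-likelihood for a degenerate initial state")
    logs = np.log(vstats.v0)
    d, n = vstats.d, vstats.n
    return (reduced_log_likelihood(vstats, xi)
            - (n + d) / 2.0 * math.log(2 * math.pi)
            - d / 2.0 * math.log(sigma1sq)
            - float(np.sum(logs))
            - float(np.sum((logs - mu1) ** 2)) / (2.0 * sigma1sq))


def sigma2_given_theta(blocks: LikelihoodBlocks,
                       vstats: VStatistics) -> float:
    """Closed-form positive root of the sigma^2 likelihood equation."""
    q = vstats.Z1 + blocks.A - 2.0 * blocks.B
    n, Z3 = vstats.n, vstats.Z3
    q = max(q, 0.0)  # nonnegative in exact arithmetic (sum of squares)
    return 2.0 * (-n + math.sqrt(n * n + Z3 * q)) / Z3


def system_residuals(vstats_or_panel, xi: ProcessParams) -> np.ndarray:
    """The p+2 likelihood equations evaluated at xi (zero at the MLE)."""
    vstats = (vstats_or_panel if isinstance(vstats_or_panel, VStatistics)
              else v_transform(vstats_or_panel))
    blocks = likelihood_blocks(vstats, (xi.eta, xi.beta))
    s2 = xi.sigma2
    first = (s2 * (vstats.n + s2 / 4.0 * vstats.Z3)
             - vstats.Z1 - blocks.A + 2.0 * blocks.B)
    rest = blocks.Y + s2 / 2.0 * blocks.W + blocks.X
    return np.concatenate([[first], rest])


def _sample_means(panel: SamplePanel):
    """Common grid (shifted to start at 0), arithmetic and geometric means."""
    times = panel.common_times - panel.t0
    mat = panel.value_matrix()
    m = mat.mean(axis=0)
    mg = np.exp(np.log(mat).mean(axis=0))
    return times, m, mg


def initial_theta_guess(panel: SamplePanel, p: int,
                        carrying: float | None = None):
    """Regression-based starting values for (eta, beta).

    With the carrying capacity approximated by the final sample mean m_N
    (or supplied explicitly), -log(m_N/m_j - 1) is a polynomial in t plus
    log eta; ordinary least squares on the usable pairs yields the guess.
    Pairs with m_j >= m_N are dropped (their logarithm is undefined).
    """
    times, m, _ = _sample_means(panel)
    mN = float(m[-1]) if carrying is None else float(carrying)
    t_j = times[:-1] if carrying is None else times
    m_j = m[:-1] if carrying is None else m
    keep = m_j < mN
    t_j, m_j = t_j[keep], m_j[keep]
    if len(t_j) < p + 2:
        raise ValueError(
            f"insufficient usable pairs for degree {p}: need >= {p + 2}, "
            f"have {len(t_j)} after dropping m_j >= m_N")
    y = -np.log(mN / m_j - 1.0)
    design = np.vander(t_j, p + 1, increasing=True)  # [1, t, ..., t^p]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    eta0 = float(np.exp(coef[0]))
    return eta0, np.asarray(coef[1:], dtype=float)


def initial_sigma2_guess(panel: SamplePanel, sigma0sq: float = 0.0,
                         floor: float = 1e-8) -> float:
    """Starting value for sigma^2 from the growth of cross-section spread.

    For lognormal cross-sections, 2 log(m_j / m_j^g) estimates the
    log-scale variance sigma0sq + sigma^2 t_j; a through-the-origin
    regression of that quantity (minus sigma0sq) on t_j gives the slope.
    """
    times, m, mg = _sample_means(panel)
    s2_j = 2.0 * np.log(m / mg) - sigma0sq
    keep = times > 0
    t, y = times[keep], s2_j[keep]
    denom = float(np.sum(t * t))
    slope = float(np.sum(t * y)) / denom if denom > 0 else 0.0
    return max(slope, floor)


@dataclass
class MLEFit:
    """Result of a maximum-likelihood fit."""

    alpha_hat: tuple[float, float]
    xi_hat: ProcessParams
    loglik: float
    method: str
    converged: bool
    iterations: int
    residual_norm: float
    t0: float = 0.0
    message: str = ""

    @property
    def initial_law(self) -> InitialLaw:
        mu1, s1sq = self.alpha_hat
        if s1sq > 0:
            return InitialLaw.lognormal(mu1, s1sq)
        return InitialLaw.degenerate(math.exp(mu1))

    def report(self) -> dict[str, float]:
        out = {"eta": self.xi_hat.eta}
        for k, b in enumerate(self.xi_hat.beta.beta, start=1):
            out[f"beta_{k}"] = b
        out.update({
            "sigma2": self.xi_hat.sigma2,
            "mu1": self.alpha_hat[0],
            "sigma1sq": self.alpha_hat[1],
            "loglik": self.loglik,
            "converged": float(self.converged),
            "iterations": float(self.iterations),
            "residual_norm": self.residual_norm,
        })
        return out


def _fit_loglik(vstats: VStatistics, alpha, xi: ProcessParams) -> float:
    """Full log-likelihood when the initial law is non-degenerate, else
    the reduced log-likelihood (the initial factor carries no information)."""
    if alpha[1] > 0:
        return log_likelihood(vstats, alpha, xi)
    return reduced_log_likelihood(vstats, xi)


def _fd_jacobian(fun, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with relative steps."""
    f0 = fun(x)
    J = np.empty((len(f0), len(x)))
    for k in range(len(x)):
        h = rel_step * max(abs(x[k]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        J[:, k] = (fun(xp) - fun(xm)) / (2 * h)
    return J


def fit_newton_raphson(panel: SamplePanel, p: int,
                       tol: float = 1e-10, max_iter: int = 200,
                       max_halvings: int = 50, profile_sigma2: bool = False,
                       x0: np.ndarray | None = None) -> MLEFit:
    """Damped Newton-Raphson solve of the likelihood system.

    By default all p+2 unknowns (eta, beta, sigma^2) are iterated on the
    full system; with ``profile_sigma2`` the closed-form sigma^2 root is
    substituted at every iteration and only the p+1 theta-equations are
    solved, which improves conditioning.

    Internally time is rescaled to [0, 1] so that the Vandermonde-type
    structure of the theta-equations stays well conditioned at higher
    degrees; the returned coefficients are mapped back to the panel's
    (t - t0) clock.
    """
    time_scale = max(float(t[-1] - t[0]) for t in panel.times)
    scaled = SamplePanel(times=[(t - panel.t0) / time_scale
                                for t in panel.times],
                         values=[x.copy() for x in panel.values],
                         metadata=panel.metadata)
    vstats = v_transform(scaled)
    if x0 is None:
        eta0, beta0 = initial_theta_guess(scaled, p)
        _, s1sq0 = alpha_mle(vstats)
        s20 = initial_sigma2_guess(scaled, sigma0sq=s1sq0)
        x0 = np.array([eta0, *beta0, s20])
    else:
        # user-supplied start is on the (t - t0) clock: rescale it
        x0 = np.asarray(x0, dtype=float).copy()
        pows = time_scale ** np.arange(1, len(x0) - 1)
        x0[1:-1] = x0[1:-1] * pows
        x0[-1] = x0[-1] * time_scale
    x0 = np.asarray(x0, dtype=float)

    def clip_valid(x: np.ndarray) -> bool:
        return x[0] > 0 and (profile_sigma2 or x[-1] > 0)

    if profile_sigma2:
        def residuals(x):
            eta, beta = x[0], x[1:]
            blocks = likelihood_blocks(vstats, (eta, _coerce_beta(beta)))
            s2 = sigma2_given_theta(blocks, vstats)
            return blocks.Y + s2 / 2.0 * blocks.W + blocks.X
        x = x0[:-1]
    else:
        def residuals(x):
            return system_residuals(vstats, _params_from_vec(x))
        x = x0.copy()

    res = residuals(x)
    norm = float(np.max(np.abs(res)))
    it = 0
    message = ""
    while norm >= tol and it < max_iter:
        it += 1
        J = _fd_jacobian(residuals, x)
        try:
            step = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -res, rcond=None)[0]
        lam_step = 1.0
        accepted = False
        for _ in range(max_halvings):
            x_new = x + lam_step * step
            if clip_valid(x_new):
                try:
                    res_new = residuals(x_new)
                except (ValueError, FloatingPointError):
                    res_new = None
                if res_new is not None and np.all(np.isfinite(res_new)):
                    norm_new = float(np.max(np.abs(res_new)))
                    if norm_new < norm:
                        x, res, norm = x_new, res_new, norm_new
                        accepted = True
                        break
            lam_step /= 2.0
        if not accepted:
            message = "step halving failed to reduce the residual"
            break
        if np.max(np.abs(lam_step * step)) < 1e-12:
            break
    converged = norm < max(tol, 1e-8)
    if not converged and not message:
        message = f"residual norm {norm:.3e} above tolerance after {it} iterations"

    if profile_sigma2:
        eta, beta = x[0], x[1:]
        blocks = likelihood_blocks(vstats, (eta, _coerce_beta(beta)))
        s2 = max(sigma2_given_theta(blocks, vstats), 1e-14)
        x = np.array([eta, *beta, s2])
    # map the scaled-clock solution back to the (t - t0) clock
    pows = time_scale ** np.arange(1, len(x) - 1)
    x_out = x.copy()
    x_out[1:-1] = x[1:-1] / pows
    x_out[-1] = max(x[-1] / time_scale, 1e-300)
    xi = _params_from_vec(x_out)
    alpha = alpha_mle(vstats)
    vstats_orig = v_transform(panel)
    return MLEFit(alpha_hat=alpha, xi_hat=xi,
                  loglik=_fit_loglik(vstats_orig, alpha, xi),
                  method="newton", converged=bool(converged),
                  iterations=it, residual_norm=norm, t0=panel.t0,
                  message=message)


def _coerce_beta(beta_arr) -> PolynomialCoefficients:
    # iterates may leave the admissible region (beta_p <= 0); keep them
    # evaluable — every likelihood quantity is finite on a bounded window
    return PolynomialCoefficients(tuple(np.asarray(beta_arr, dtype=float)),
                                  require_positive_leading=False)


def _params_from_vec(x: np.ndarray) -> ProcessParams:
    return ProcessParams(eta=float(x[0]), beta=_coerce_beta(x[1:-1]),
                         sigma2=float(max(x[-1], 1e-300)))
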