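"""Fisher information, delta-method confidence intervals, and the exact
small-sample laws of the initial-distribution estimates.

The MLE of xi = (eta, beta, sigma^2) is asymptotically normal with
covariance I(xi)^{-1}.  For this process the information matrix has the
closed form

    I(xi) = (1/sigma^2) [[ Xi,            -(1/2) dgamma ],
                         [ -(1/2) dgamma', n/(2 sigma^2) - Z3/4 ]],

with Xi the sum over steps of outer products of the theta-gradient of the
transition mean (scaled by 1/dt) and dgamma the plain sum of those
gradients.  The estimates of the lognormal initial law have exact laws:
mu1_hat is normal and d sigma1sq_hat / sigma1sq is chi-square(d-1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .likelihood import MLEFit, VStatistics, likelihood_blocks, v_transform
from .process import ProcessParams
from .simulate import SamplePanel

DEFAULT_LEVELS = (0.95, 0.90, 0.75)


@dataclass
class FisherInfo:
    matrix: np.ndarray   # (p+2, p+2), includes the 1/sigma^2 prefactor
    Xi: np.ndarray       # (p+1, p+1) theta block (before the prefactor)
    dgamma: np.ndarray   # (p+1,) sum of theta-gradients of the step means
    corner: float        # n/(2 sigma^2) - Z3/4 (before the prefactor)

    def covariance(self, cond_limit: float = 1e12) -> np.ndarray:
        """Inverse information; the matrix is equilibrated by its diagonal
        first (polynomial bases make the raw scaling enormous), and a
        pseudo-inverse with a warning is used when even the equilibrated
        matrix is numerically singular (collinear basis)."""
        diag = np.diag(self.matrix)
        if np.any(diag <= 0):
            warnings.warn("information matrix has a non-positive diagonal; "
                          "using a pseudo-inverse — intervals unreliable")
            return np.linalg.pinv(self.matrix)
        scale = np.sqrt(diag)
        equil = self.matrix / np.outer(scale, scale)
        cond = np.linalg.cond(equil)
        if not np.isfinite(cond) or cond > cond_limit:
            warnings.warn(
                f"information matrix ill-conditioned (cond={cond:.2e} after "
                "equilibration); using a pseudo-inverse — intervals may be "
                "unreliable")
            inv = np.linalg.pinv(equil)
        else:
            inv = np.linalg.inv(equil)
        return inv / np.outer(scale, scale)


def fisher_information(panel_or_vstats, xi: ProcessParams) -> FisherInfo:
    """Assemble I(xi) for the observed sampling scheme."""
    vstats = (panel_or_vstats if isinstance(panel_or_vstats, VStatistics)
              else v_transform(panel_or_vstats))
    blocks = likelihood_blocks(vstats, (xi.eta, xi.beta))
    # theta-gradient of the step mean, one column per step: the eta
    # component is +D_0 while the beta_l components are -D_l (the sign
    # difference comes from d/d eta log(eta + e^{-Q}) being positive)
    grad_m = np.vstack([blocks.D[0], -blocks.D[1:]])
    G = grad_m / np.sqrt(vstats.delta)
    Xi = G @ G.T
    dgamma = grad_m.sum(axis=1)
    corner = vstats.n / (2.0 * xi.sigma2) - vstats.Z3 / 4.0
    p1 = Xi.shape[0]
    mat = np.empty((p1 + 1, p1 + 1))
    mat[:p1, :p1] = Xi
    mat[:p1, p1] = -0.5 * dgamma
    mat[p1, :p1] = -0.5 * dgamma
    mat[p1, p1] = corner
    mat /= xi.sigma2
    return FisherInfo(matrix=mat, Xi=Xi, dgamma=dgamma, corner=corner)


def asymptotic_ci(fit: MLEFit, panel: SamplePanel,
                  levels=DEFAULT_LEVELS) -> dict:
    """Per-parameter normal confidence intervals from I(xi_hat)^{-1}.

    Returns {"params": names, "estimate": values, "se": standard errors,
    "intervals": {level: [(lo, hi), ...]}}.
    """
    info = fisher_information(panel, fit.xi_hat)
    cov = info.covariance()
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    est = fit.xi_hat.as_vector()
    p = fit.xi_hat.degree
    names = ["eta"] + [f"beta_{k}" for k in range(1, p + 1)] + ["sigma2"]
    intervals = {}
    for level in np.atleast_1d(levels):
        z = norm.ppf((1.0 + level) / 2.0)
        intervals[float(level)] = [(float(e - z * s), float(e + z * s))
                                   for e, s in zip(est, se)]
    return {"params": names, "estimate": est, "se": se,
            "intervals": intervals}


def delta_method_ci(fit: MLEFit, panel: SamplePanel, g,
                    grad=None, level: float = 0.95,
                    rel_step: float = 1e-6) -> tuple[float, float]:
    """Normal interval for a scalar function g(xi_hat) via the delta method."""
    x = fit.xi_hat.as_vector()
    if grad is None:
        gvec = np.empty(len(x))
        for k in range(len(x)):
            h = rel_step * max(abs(x[k]), 1e-8)
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            gvec[k] = (g(xp) - g(xm)) / (2 * h)
    else:
        gvec = np.asarray(grad(x), dtype=float)
    cov = fisher_information(panel, fit.xi_hat).covariance()
    var = float(gvec @ cov @ gvec)
    sd = math.sqrt(max(var, 0.0))
    z = norm.ppf((1.0 + level) / 2.0)
    center = float(g(x))
    return (center - z * sd, center + z * sd)


def initial_law_ci(mu1_hat: float, sigma1sq_hat: float, d: int,
                   level: float = 0.95):
    """Exact intervals for the lognormal initial-law parameters.

    mu1: normal pivot with plug-in variance sigma1sq_hat / d.
    sigma1sq: chi-square(d-1) pivot for d * sigma1sq_hat / sigma1sq.
    """
    if d < 2:
        raise ValueError("at least two paths are required")
    z = norm.ppf((1.0 + level) / 2.0)
    half = z * math.sqrt(max(sigma1sq_hat, 0.0) / d)
    mu_int = (mu1_hat - half, mu1_hat + half)
    if sigma1sq_hat <= 0:
        warnings.warn("sigma1sq_hat is zero (degenerate start); interval "
                      "collapses to a point")
        return mu_int, (0.0, 0.0)
    qs = chi2.ppf([(1.0 + level) / 2.0, (1.0 - level) / 2.0], df=d - 1)
    s_int = (d * sigma1sq_hat / qs[0], d * sigma1sq_hat / qs[1])
    return mu_int, s_int
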