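"""Exact trajectory sampling and the standard simulation-study panels.

Because the transition law of the diffusion is lognormal in closed form,
paths are drawn by chaining exact transitions (no Euler discretization
bias): log X(t_{j+1}) = log X(t_j) + H(t_j, t_{j+1}) + sigma sqrt(dt) Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .process import (InitialLaw, PolynomialCoefficients, ProcessParams,
                      H_xi)


@dataclass
class SamplePanel:
    """d discrete-time trajectories with a common first observation time.

    ``times`` and ``values`` are parallel lists of one array per path; the
    grids may be ragged but must share the first time t0 and be strictly
    increasing, with positive values throughout.
    """

    times: list[np.ndarray]
    values: list[np.ndarray]
    metadata: str = ""

    def __post_init__(self):
        if len(self.times) != len(self.values) or len(self.times) < 1:
            raise ValueError("panel needs >= 1 path with matching times/values")
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.values = [np.asarray(x, dtype=float) for x in self.values]
        t0 = self.times[0][0]
        for i, (t, x) in enumerate(zip(self.times, self.values)):
            if t.shape != x.shape or t.ndim != 1 or len(t) < 2:
                raise ValueError(f"path {i}: times/values must be 1-d, >= 2 obs")
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"path {i}: times must be strictly increasing")
            if abs(t[0] - t0) > 1e-12:
                raise ValueError(f"path {i}: first time {t[0]} differs from t0={t0}")
            if not np.all(x > 0):
                raise ValueError(f"path {i}: all values must be positive")

    @property
    def t0(self) -> float:
        return float(self.times[0][0])

    @property
    def d(self) -> int:
        return len(self.times)

    @property
    def n_steps(self) -> int:
        """Total number of transitions, n = sum_i (n_i - 1)."""
        return sum(len(t) - 1 for t in self.times)

    @property
    def common_times(self) -> np.ndarray:
        """Shared observation grid; raises if the grids are ragged."""
        t = self.times[0]
        for other in self.times[1:]:
            if len(other) != len(t) or not np.allclose(other, t):
                raise ValueError("panel paths are not on a common time grid")
        return t

    def value_matrix(self) -> np.ndarray:
        """(d, N) matrix of observations; requires a common grid."""
        self.common_times
        return np.vstack(self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (t, x) in enumerate(zip(self.times, self.values)):
            rows.append(pd.DataFrame({"path_id": i, "time": t, "value": x}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: str = "") -> "SamplePanel":
        times, values = [], []
        for _, grp in df.groupby("path_id", sort=True):
            grp = grp.sort_values("time")
            times.append(grp["time"].to_numpy(dtype=float))
            values.append(grp["value"].to_numpy(dtype=float))
        return cls(times=times, values=values, metadata=metadata)


def simulate_paths(params: ProcessParams, init: InitialLaw, times,
                   n_paths: int, seed: int) -> SamplePanel:
    """Draw ``n_paths`` exact trajectories on the given increasing grid.

    One master seed spawns an independent substream per path, so the panel
    is reproducible and path i does not depend on how many paths follow it.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be a strictly increasing 1-d grid")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    dt = np.diff(times)
    drift = np.asarray(H_xi(params, times[:-1], times[1:]), dtype=float)
    scale = math.sqrt(params.sigma2) * np.sqrt(dt)
    streams = np.random.SeedSequence(seed).spawn(n_paths)
    paths = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        if init.kind == "degenerate":
            logx0 = math.log(init.x0)
        else:
            logx0 = init.mu0 + math.sqrt(init.sigma0sq) * rng.standard_normal()
        incr = drift + scale * rng.standard_normal(len(dt))
        logx = logx0 + np.concatenate([[0.0], np.cumsum(incr)])
        paths.append(np.exp(logx))
    return SamplePanel(times=[times.copy() for _ in range(n_paths)],
                       values=paths,
                       metadata=f"simulated(seed={seed}, d={n_paths})")


# The 32 parameter combinations of the simulation design: beta1, beta2,
# beta3, eta and sigma each take two values, nested in that order, with
# x0 = 5 and an equidistant grid on [0, 50].
_B1 = (0.1, 0.5)
_B2 = (-0.009, -0.007)
_B3 = (0.0002, 0.0003)
_ETA = (math.exp(-1), math.exp(-3))
_SIGMA = (0.01, 0.05)

CASE_X0 = 5.0
CASE_T_RANGE = (0.0, 50.0)


def case_params(case: int) -> ProcessParams:
    """Parameter set for one of the 32 standard simulation cases."""
    if not 1 <= case <= 32:
        raise ValueError(f"case must be in 1..32, got {case}")
    k = case - 1
    b1 = _B1[k // 16]
    b2 = _B2[(k // 8) % 2]
    b3 = _B3[(k // 4) % 2]
    eta = _ETA[(k // 2) % 2]
    sigma = _SIGMA[k % 2]
    return ProcessParams(eta=eta,
                         beta=PolynomialCoefficients((b1, b2, b3)),
                         sigma2=sigma ** 2)


def make_case_panel(case: int, n_paths: int = 200, n_times: int = 501,
                    seed: int = 0) -> SamplePanel:
    """Simulate a panel under one of the 32 standard cases (x0 = 5)."""
    params = case_params(case)
    times = np.linspace(*CASE_T_RANGE, n_times)
    panel = simulate_paths(params, InitialLaw.degenerate(CASE_X0), times,
                           n_paths, seed)
    panel.metadata = f"case{case}(seed={seed}, d={n_paths}, N={n_times})"
    return panel


def first_passage_times_mc(params: ProcessParams, x0: float, t0: float,
                           S: float, horizon: float, dt: float,
                           n_paths: int, seed: int) -> np.ndarray:
    """Monte-Carlo first up-crossing times of a constant boundary S > x0.

    Simulates fine-grained exact transitions for all paths in lock-step and
    records the first grid time at which each path exceeds S.  Paths that
    never cross within the horizon yield NaN.
    """
    if not S > x0:
        raise ValueError("requires S > x0 (upward crossing)")
    n_steps = int(math.ceil((horizon - t0) / dt))
    times = t0 + dt * np.arange(n_steps + 1)
    drift = np.asarray(H_xi(params, times[:-1], times[1:]), dtype=float)
    scale = math.sqrt(params.sigma2 * dt)
    rng = np.random.default_rng(seed)
    logx = np.full(n_paths, math.log(x0))
    logS = math.log(S)
    fpt = np.full(n_paths, np.nan)
    alive = np.ones(n_paths, dtype=bool)
    for j in range(n_steps):
        logx[alive] = (logx[alive] + drift[j]
                       + scale * rng.standard_normal(alive.sum()))
        crossed = alive & (logx > logS)
        fpt[crossed] = times[j + 1]
        alive &= ~crossed
        if not alive.any():
            break
    return fpt
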