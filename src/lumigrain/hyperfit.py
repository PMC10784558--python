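"""Hyperbolic-relaxation fitting of delayed-luminescence decay traces.

The decay law is ``I(t) = I0 / (1 + t/tau)**beta``.  Fitting is unweighted
nonlinear least squares; goodness metrics follow the residual-degrees-of-
freedom convention ``RMSE = sqrt(SSE / (N - 3))`` for the three fitted
parameters.  The integral intensity over [0, T] has the closed form

    E(T) = tau*I0/(beta-1) * (1 - (1 + T/tau)**(1-beta))        (beta != 1)
    E(T) = tau*I0 * ln(1 + T/tau)                               (beta == 1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .signal import DLSignal

__all__ = [
    "HyperbolicParams",
    "HyperbolicFitResult",
    "intensity",
    "integral_intensity",
    "fit_hyperbolic",
]

_BETA_ONE_TOL = 1e-8


@dataclass(frozen=True)
class HyperbolicParams:
    I0: float
    tau: float
    beta: float

    def __post_init__(self) -> None:
        if self.I0 <= 0 or self.tau <= 0 or self.beta <= 0:
            raise ValueError("all hyperbolic parameters must be strictly positive")


@dataclass(frozen=True)
class HyperbolicFitResult:
    params: HyperbolicParams
    sse: float
    rmse: float
    r2: float
    e_T: float
    converged: bool
    n_points: int

    def to_dict(self) -> dict:
        return {
            "I0": self.params.I0,
            "tau": self.params.tau,
            "beta": self.params.beta,
            "sse": self.sse,
            "rmse": self.rmse,
            "r2": self.r2,
            "e_T": self.e_T,
            "converged": self.converged,
            "n_points": self.n_points,
        }


def intensity(params: HyperbolicParams, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the decay law at time(s) ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = params.I0 / (1.0 + t / params.tau) ** params.beta
    return float(out) if out.ndim == 0 else out


def integral_intensity(params: HyperbolicParams, T: float) -> float:
    """Closed-form integral of the decay law over [0, T]."""
    if T <= 0:
        raise ValueError("T must be positive")
    I0, tau, beta = params.I0, params.tau, params.beta
    if abs(beta - 1.0) < _BETA_ONE_TOL:
        return tau * I0 * np.log1p(T / tau)
    return tau * I0 / (beta - 1.0) * (1.0 - (1.0 + T / tau) ** (1.0 - beta))


def _initial_guess(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    i0 = max(float(values[0]), 1e-3)
    below = np.nonzero(values < i0 / 2.0)[0]
    tau = float(times[below[0]]) if below.size and times[below[0]] > 0 else 1.0
    return np.array([i0, tau, 1.0])


def fit_hyperbolic(signal: DLSignal) -> HyperbolicFitResult:
    """Fit the decay law to a (preprocessed) trace by least squares.

    Initialization: I0 from the first sample, tau from the half-decay time,
    beta = 1.  All parameters are bounded below by 1e-6.  Non-convergence is
    reported through the ``converged`` flag rather than an exception.
    """
    times, values = signal.times, signal.values
    n = len(signal)
    if n < 10:
        raise ValueError("signal too short to fit (need >= 10 points)")
    if np.allclose(values, values[0]):
        raise ValueError("degenerate (constant) signal cannot be fitted")

    def residuals(p: np.ndarray) -> np.ndarray:
        i0, tau, beta = p
        return i0 / (1.0 + times / tau) ** beta - values

    res = least_squares(
        residuals,
        _initial_guess(times, values),
        bounds=(1e-6, np.inf),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    params = HyperbolicParams(I0=float(res.x[0]), tau=float(res.x[1]), beta=float(res.x[2]))
    sse = float(np.sum(res.fun**2))
    rmse = float(np.sqrt(sse / (n - 3)))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot
    e_T = integral_intensity(params, float(times[-1]) + signal.dt)
    return HyperbolicFitResult(
        params=params,
        sse=sse,
        rmse=rmse,
        r2=r2,
        e_T=e_T,
        converged=bool(res.success),
        n_points=n,
    )
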