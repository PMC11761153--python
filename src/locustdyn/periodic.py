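"""Basic offspring ratio for the seasonally forced system.

For the linearization of the forced model at extinction, split into a
nonnegative recruitment matrix F(t) (the new-egg row) and a transfer
matrix V(t) (with -V(t) cooperative), both periodic with the forcing
period. The basic offspring ratio N0w is the spectral radius of the
next-generation integral operator on periodic functions; numerically it
is the unique lambda > 0 at which the monodromy of

    dW/dt = [-V(t) + F(t)/lambda] W,   W(0) = I

has spectral radius 1. rho(lambda) is monotone decreasing, so the root is
found by bracketed bisection. With zero forcing amplitude the ratio
collapses to the autonomous basic offspring number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .forcing import TemperatureForcing, seasonal_temperature
from .params import ModelParams
from .responses import ThermalParamSet

__all__ = [
    "PeriodicLinearization",
    "build_periodic_linearization",
    "monodromy_spectral_radius",
    "floquet_spectral_radius",
    "periodic_offspring_ratio",
]


@dataclass
class PeriodicLinearization:
    """Periodic recruitment/transfer matrix pair for the forced system."""

    period: float
    F: Callable[[float], np.ndarray]
    V: Callable[[float], np.ndarray]

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")


def build_periodic_linearization(thermal: ThermalParamSet, forcing: TemperatureForcing,
                                 constants: ModelParams,
                                 period: float | None = None) -> PeriodicLinearization:
    """Assemble F(t), V(t) from the response curves and the forcing.

    F(t) has a single nonzero row: new eggs recruited from solitarious
    adults at rate (1-eta)*phi(T(t)) and from gregarious adults at rate
    (1-eta)*psi*phi(T(t)). V(t) carries the compartment outflow aggregates
    on the diagonal and the stage-progression couplings off it. The period
    defaults to the forcing period (365/omega days).
    """
    if period is None:
        period = forcing.period
    eta, psi, theta = constants.eta, constants.psi, constants.theta
    b1, b2 = constants.beta_1, constants.beta_2

    def F(t: float) -> np.ndarray:
        T = seasonal_temperature(forcing, t)
        phi = thermal.phi(T)
        M = np.zeros((5, 5))
        M[0, 3] = (1.0 - eta) * phi
        M[0, 4] = (1.0 - eta) * psi * phi
        return M

    def V(t: float) -> np.ndarray:
        T = seasonal_temperature(forcing, t)
        r = thermal.rates(T)
        c1 = r["sigma"] + r["mu_e"]
        c2 = r["gamma_h"] + r["mu_h"]
        c3 = r["gamma_b"] + r["mu_b"]
        c4 = b1 + r["mu_s"]
        c5 = b2 + r["mu_g"]
        return np.array([
            [c1, 0.0, 0.0, 0.0, 0.0],
            [-theta * r["sigma"], c2, 0.0, 0.0, 0.0],
            [-(1.0 - theta) * r["sigma"], 0.0, c3, 0.0, 0.0],
            [0.0, -r["gamma_h"], 0.0, c4, -b2],
            [0.0, 0.0, -r["gamma_b"], -b1, c5],
        ])

    return PeriodicLinearization(period=float(period), F=F, V=V)


def _log_monodromy_radius(lin: PeriodicLinearization,
                          coeff: Callable[[float], np.ndarray],
                          rtol: float, atol: float, n_chunks: int = 12) -> float:
    """log of the spectral radius of the one-period monodromy of
    dW/dt = coeff(t) W, integrated with per-chunk renormalization so the
    result stays representable even for strongly growing or decaying
    systems."""

    def fun(t, w):
        return (coeff(t) @ w.reshape(5, 5)).ravel()

    W = np.eye(5)
    log_scale = 0.0
    edges = np.linspace(0.0, lin.period, n_chunks + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(fun, (a, b), W.ravel(), method="DOP853", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"monodromy integration failed on [{a}, {b}]: {sol.message}")
        W = sol.y[:, -1].reshape(5, 5)
        s = float(np.max(np.abs(W)))
        if s == 0.0:
            return -np.inf
        W /= s
        log_scale += np.log(s)
    rho = float(np.max(np.abs(np.linalg.eigvals(W))))
    if rho == 0.0:
        return -np.inf
    return log_scale + float(np.log(rho))


def monodromy_spectral_radius(lin: PeriodicLinearization, lambda_: float,
                              rtol: float = 1e-10, atol: float = 1e-12) -> float:
    """Spectral radius of the one-period monodromy of
    dW/dt = [-V(t) + F(t)/lambda] W (may overflow to inf for extreme
    lambda; comparisons against 1 remain meaningful)."""
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    lr = _log_monodromy_radius(lin, lambda t: -lin.V(t) + lin.F(t) / lambda_, rtol, atol)
    return float(np.exp(lr)) if lr < 700.0 else np.inf


def floquet_spectral_radius(lin: PeriodicLinearization,
                            rtol: float = 1e-10, atol: float = 1e-12) -> float:
    """Spectral radius of the monodromy of the unscaled linearization
    dx/dt = [F(t) - V(t)] x; < 1 means the extinction state is stable."""
    lr = _log_monodromy_radius(lin, lambda t: lin.F(t) - lin.V(t), rtol, atol)
    return float(np.exp(lr)) if lr < 700.0 else np.inf


def periodic_offspring_ratio(lin: PeriodicLinearization,
                             bracket: tuple[float, float] = (1e-6, 1e3),
                             tolerance: float = 1e-6) -> float:
    """The basic offspring ratio N0w: the lambda with monodromy spectral
    radius 1.

    The root is located on log(rho) by geometric bracket expansion from
    lambda = 1 (rho is monotone decreasing in lambda, which is checked on
    the final bracket), then polished with Brent's method to the given
    relative tolerance. Returns 0 when recruitment is absent (rho < 1 for
    every lambda down to the lower bracket edge).
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError(f"invalid bracket {bracket}")
    rtol_i, atol_i = 1e-10, 1e-12

    def g(lam: float) -> float:
        return _log_monodromy_radius(lin, lambda t: -lin.V(t) + lin.F(t) / lam,
                                     rtol_i, atol_i)

    lam = min(max(1.0, lo), hi)
    val = g(lam)
    if val == 0.0:
        return float(lam)
    factor = 4.0
    if val > 0.0:  # root lies at larger lambda
        a, ga = lam, val
        while True:
            b = min(a * factor, hi)
            gb = g(b)
            if gb <= 0.0 or b >= hi:
                break
            a, ga = b, gb
        if gb > 0.0:
            raise ValueError(
                f"bracket does not straddle the threshold: log rho({b}) = {gb:.3e} > 0"
            )
    else:  # root at smaller lambda, or no recruitment at all
        b, gb = lam, val
        while True:
            a = max(b / factor, lo)
            ga = g(a)
            if ga >= 0.0 or a <= lo:
                break
            b, gb = a, ga
        if ga < 0.0:
            # rho < 1 all the way down to the bracket edge: recruitment is
            # absent (or negligible); the ratio is 0 by convention.
            if ga == -np.inf or g(lo) < 0.0:
                return 0.0
            raise ValueError(
                f"bracket does not straddle the threshold: log rho({a}) = {ga:.3e} < 0"
            )
    if ga < gb:
        raise ValueError("monodromy radius is not decreasing across the bracket")
    return float(brentq(g, a, b, rtol=tolerance, xtol=tolerance * lo))
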