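"""Nonlinear least-squares estimation of thermal-response parameters.

The fitted curves in this package came from temperature-versus-duration
tables that are not redistributed here, so a fixture generator produces
synthetic stand-ins: noiseless or noisy samples from a known curve, for
parameter-recovery experiments. Fitting uses bounded trust-region least
squares (scipy ``least_squares`` with the ``trf`` method); any subset of
parameters can be held fixed, matching the practice of fixing the falling
exponent m = 0.5 in the development-curve fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .responses import (
    AllahyariParams,
    GaussianFecundityParams,
    MortalityWindowParams,
    allahyari_rate,
    gaussian_fecundity,
    mortality_window,
)

__all__ = ["FitResult", "generate_fixture_table", "fit_thermal_curve"]

# family -> (parameter names, evaluator, default (low, high) bounds)
_FAMILIES = {
    "gaussian": (
        ("Emax", "Topt", "Tw"),
        lambda p, T: gaussian_fecundity(GaussianFecundityParams(**p), T),
        {"Emax": (1e-6, 10.0), "Topt": (10.0, 45.0), "Tw": (1e-3, 20.0)},
    ),
    "allahyari": (
        ("P", "n", "m", "Tmin", "Tmax"),
        lambda p, T: allahyari_rate(AllahyariParams(**p), T),
        {"P": (1e-6, 5.0), "n": (1e-3, 10.0), "m": (1e-3, 10.0),
         "Tmin": (0.0, 25.0), "Tmax": (35.0, 60.0)},
    ),
    "mortality_window": (
        ("M", "Q", "Tmin", "Tmax"),
        lambda p, T: mortality_window(MortalityWindowParams(**p), T),
        {"M": (1e-3, 2.0), "Q": (0.1, 10.0), "Tmin": (0.0, 25.0), "Tmax": (35.0, 60.0)},
    ),
}


def _evaluate(curve_family: str, params: dict, T):
    names, fn, _ = _FAMILIES[curve_family]
    return fn({k: params[k] for k in names}, T)


def generate_fixture_table(curve_family: str, true_params: dict, temperatures,
                           noise_sd: float = 0.0, seed: int | None = None) -> pd.DataFrame:
    """Synthetic temperature-rate table sampled from a known curve.

    Rates are ``curve(true_params, T)`` plus Gaussian noise of standard
    deviation ``noise_sd`` (rate units), truncated at 0. An explicit
    ``seed`` is required whenever ``noise_sd > 0``; the table is then
    reproducible. Columns: ``T_celsius``, ``rate_per_day``.
    """
    if curve_family not in _FAMILIES:
        raise ValueError(f"unknown curve family {curve_family!r}")
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size == 0:
        raise ValueError("temperature grid must not be empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rate = np.asarray(_evaluate(curve_family, dict(true_params), temperatures), dtype=float)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("an explicit seed is required for a noisy fixture")
        rng = np.random.default_rng(seed)
        rate = np.maximum(rate + rng.normal(0.0, noise_sd, size=rate.shape), 0.0)
    return pd.DataFrame({"T_celsius": temperatures, "rate_per_day": rate})


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus residual summary."""

    family: str
    params: dict
    sse: float
    converged: bool
    message: str
    n_points: int


def fit_thermal_curve(table: pd.DataFrame, curve_family: str,
                      fixed: dict | None = None,
                      bounds: dict | None = None,
                      initial_guess: dict | None = None) -> FitResult:
    """Fit a response curve to a (T, rate) table by bounded least squares.

    ``fixed`` pins parameters at given values (e.g. ``{"m": 0.5}``);
    ``bounds`` overrides the per-parameter default (low, high) boxes;
    ``initial_guess`` overrides the default mid-bounds start. Residuals
    are minimized in rate space. Non-convergence is reported explicitly in
    the result (``converged=False`` with the best iterate), never as a
    silent success.
    """
    if curve_family not in _FAMILIES:
        raise ValueError(f"unknown curve family {curve_family!r}")
    names, _, default_bounds = _FAMILIES[curve_family]
    fixed = dict(fixed or {})
    free = [k for k in names if k not in fixed]
    T = np.asarray(table["T_celsius"], dtype=float)
    y = np.asarray(table["rate_per_day"], dtype=float)
    if T.size < len(free) + 1:
        raise ValueError(f"need at least {len(free) + 1} points to fit {len(free)} parameters")

    bnds = {**default_bounds, **(bounds or {})}
    lo = np.array([bnds[k][0] for k in free])
    hi = np.array([bnds[k][1] for k in free])
    if initial_guess:
        x0 = np.array([initial_guess.get(k, 0.5 * (bnds[k][0] + bnds[k][1])) for k in free])
    else:
        x0 = 0.5 * (lo + hi)
    x0 = np.clip(x0, lo, hi)

    def resid(x):
        p = dict(zip(free, x))
        p.update(fixed)
        return np.asarray(_evaluate(curve_family, p, T)) - y

    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    params = dict(zip(free, res.x))
    params.update(fixed)
    return FitResult(family=curve_family,
                     params={k: float(params[k]) for k in names},
                     sse=float(np.sum(res.fun**2)),
                     converged=bool(res.success),
                     message=res.message,
                     n_points=int(T.size))
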