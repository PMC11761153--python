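"""Right-hand sides and numerical integration of the locust system.

Five compartments track the population by stage and phase: eggs ``E``,
solitarious hoppers ``H``, gregarious hoppers/bands ``B``, solitarious
adults ``S`` and gregarious adults/swarms ``G`` (densities, m^-2):

    dE/dt = (1-eta)*phi*(1 - E/K)*(S + psi*G) - (sigma + mu_e)*E
    dH/dt = theta*sigma*E - (gamma_h + mu_h)*H
    dB/dt = (1-theta)*sigma*E - (gamma_b + mu_b)*B
    dS/dt = gamma_h*H + beta_2*G - (beta_1 + mu_s)*S
    dG/dt = gamma_b*B + beta_1*S - (beta_2 + mu_g)*G

In the non-autonomous variant every rate except theta, beta_1, beta_2,
psi, eta and K is evaluated from a temperature-response curve at the
seasonal temperature T(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .forcing import TemperatureForcing, seasonal_temperature
from .params import ModelParams
from .responses import ThermalParamSet

__all__ = ["StageState", "Trajectory", "rhs_autonomous", "rhs_nonautonomous", "simulate"]

STATE_NAMES = ("E", "H", "B", "S", "G")

#: Negativity tolerance: components within this of zero are clipped to 0;
#: anything more negative raises.
NEG_TOL = 1e-9


@dataclass(frozen=True)
class StageState:
    """Compartment densities at one time point (locusts m^-2)."""

    E: float
    H: float
    B: float
    S: float
    G: float

    def __post_init__(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"state must be finite, got {arr}")
        if np.any(arr < 0):
            raise ValueError(f"state components must be nonnegative, got {arr}")

    def to_array(self) -> np.ndarray:
        return np.array([self.E, self.H, self.B, self.S, self.G], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StageState":
        arr = np.asarray(arr, dtype=float)
        return cls(*arr)

    @property
    def total(self) -> float:
        return float(np.sum(self.to_array()))


def _rhs_arrays(y: np.ndarray, r: dict, theta, beta_1, beta_2, psi, eta, K) -> np.ndarray:
    E, H, B, S, G = y
    recruit = (1.0 - eta) * r["phi"] * (1.0 - E / K) * (S + psi * G)
    return np.array([
        recruit - (r["sigma"] + r["mu_e"]) * E,
        theta * r["sigma"] * E - (r["gamma_h"] + r["mu_h"]) * H,
        (1.0 - theta) * r["sigma"] * E - (r["gamma_b"] + r["mu_b"]) * B,
        r["gamma_h"] * H + beta_2 * G - (beta_1 + r["mu_s"]) * S,
        r["gamma_b"] * B + beta_1 * S - (beta_2 + r["mu_g"]) * G,
    ])


def rhs_autonomous(state, params: ModelParams):
    """Time-derivative of the autonomous system at ``state``.

    ``state`` may be a :class:`StageState` or a length-5 array; the return
    type matches the input.
    """
    as_state = isinstance(state, StageState)
    y = state.to_array() if as_state else np.asarray(state, dtype=float)
    rates = {k: getattr(params, k) for k in
             ("phi", "sigma", "mu_e", "gamma_h", "mu_h", "gamma_b", "mu_b", "mu_s", "mu_g")}
    dy = _rhs_arrays(y, rates, params.theta, params.beta_1, params.beta_2,
                     params.psi, params.eta, params.K)
    return dy


def rhs_nonautonomous(t: float, state, thermal: ThermalParamSet,
                      forcing: TemperatureForcing, constants: ModelParams):
    """Time-derivative of the seasonally forced system at time ``t`` (days).

    Temperature-dependent rates come from ``thermal`` evaluated at
    ``T(t)``; the phase-transition and demographic constants (theta,
    beta_1, beta_2, psi, eta, K) come from ``constants``. With an
    all-constant thermal set this reduces exactly to
    :func:`rhs_autonomous`.
    """
    y = state.to_array() if isinstance(state, StageState) else np.asarray(state, dtype=float)
    T = seasonal_temperature(forcing, t)
    rates = thermal.rates(T)
    return _rhs_arrays(y, rates, constants.theta, constants.beta_1, constants.beta_2,
                       constants.psi, constants.eta, constants.K)


@dataclass
class Trajectory:
    """Integrated trajectory: times (days) and a (n_times, 5) state array."""

    times: np.ndarray
    states: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 5):
            raise ValueError("states must have shape (len(times), 5)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        """Total population N(t) = E + H + B + S + G."""
        return self.states.sum(axis=1)

    def final_state(self) -> StageState:
        return StageState.from_array(np.maximum(self.states[-1], 0.0))

    def to_frame(self):
        """DataFrame with columns t_days, E, H, B, S, G, N (and T_celsius
        for forced runs)."""
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "t_days", self.times)
        df["N"] = self.total
        forcing = self.metadata.get("forcing")
        if forcing is not None:
            df["T_celsius"] = seasonal_temperature(forcing, self.times)
        return df


class IntegrationError(RuntimeError):
    """Solver failure or negativity beyond tolerance; carries diagnostics."""


def simulate(initial: StageState, *, params: ModelParams | None = None,
             thermal: ThermalParamSet | None = None,
             forcing: TemperatureForcing | None = None,
             t_span: tuple[float, float] = (0.0, 365.0),
             t_eval: Sequence[float] | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "RK45", max_step: float = np.inf) -> Trajectory:
    """Integrate the locust system with an adaptive Runge-Kutta solver.

    Autonomous runs pass ``params``; seasonally forced runs pass
    ``thermal`` + ``forcing`` + ``params`` (the latter supplying the
    temperature-independent constants). Components that dip within
    ``NEG_TOL`` of zero (scaled by the problem magnitude) are clipped to
    0 in the output; larger negativity raises :class:`IntegrationError`.
    """
    if params is None:
        raise ValueError("params is required (it supplies the constant coefficients)")
    forced = thermal is not None
    if forced and forcing is None:
        raise ValueError("a TemperatureForcing is required for a thermal run")

    if forced:
        def fun(t, y):
            return rhs_nonautonomous(t, y, thermal, forcing, params)
    else:
        def fun(t, y):
            return rhs_autonomous(y, params)

    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 501)
    t_eval = np.asarray(t_eval, dtype=float)

    sol = solve_ivp(fun, t_span, initial.to_array(), method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol, max_step=max_step)
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")

    states = sol.y.T
    scale = max(1.0, float(np.max(np.abs(states))))
    floor = -NEG_TOL * scale
    if np.any(states < floor):
        worst = float(states.min())
        raise IntegrationError(
            f"negativity beyond tolerance: min component {worst:.3e} < {floor:.3e}"
        )
    states = np.maximum(states, 0.0)

    meta = {"method": method, "rtol": rtol, "atol": atol,
            "params": params.to_dict(), "forced": forced}
    if forced:
        meta["forcing"] = forcing
    return Trajectory(times=sol.t, states=states, metadata=meta)
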