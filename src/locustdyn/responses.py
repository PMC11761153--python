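"""Temperature-response curves for the locust vital rates.

Four curve families cover the nine temperature-dependent rates of the
model:

* Gaussian fecundity ``phi(T) = Emax * exp(-((T - Topt)/Tw)^2)`` for the
  egg-laying rate of adult females;
* the Allahyari development curve ``P * x^n * (1 - x^m)`` with
  ``x = (T - Tmin)/(Tmax - Tmin)`` for egg hatching and hopper/band
  development, zero outside the lethal window;
* a logistic mortality window for egg and hopper mortality, U-shaped with
  a plateau ``~ 1 - M`` inside the lethal window and saturating at 1
  beyond it;
* an anchored mortality window for adult mortality, rescaled so its
  interior minimum equals a prescribed baseline mortality.

Default parameter sets are the fitted values for the desert locust
(Schistocerca gregaria): see the module constants below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

__all__ = [
    "GaussianFecundityParams",
    "AllahyariParams",
    "MortalityWindowParams",
    "ThermalParamSet",
    "gaussian_fecundity",
    "allahyari_rate",
    "mortality_window",
    "adult_mortality",
    "build_thermal_param_set",
    "curve_to_frame",
]

# Exponent clip keeps exp() finite; beyond this the window is saturated anyway.
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class GaussianFecundityParams:
    """Gaussian fecundity curve: Emax at Topt, width Tw (degC)."""

    Emax: float
    Topt: float
    Tw: float

    def __post_init__(self) -> None:
        if self.Emax < 0:
            raise ValueError("Emax must be nonnegative")
        if self.Tw <= 0:
            raise ValueError("Tw must be positive")

    def __call__(self, T):
        return gaussian_fecundity(self, T)


@dataclass(frozen=True)
class AllahyariParams:
    """Unimodal development-rate curve between lethal temperatures.

    rate(T) = P * x^n * (1 - x^m),  x = (T - Tmin) / (Tmax - Tmin),
    clamped to 0 outside (Tmin, Tmax).
    """

    P: float
    n: float
    m: float
    Tmin: float
    Tmax: float

    def __post_init__(self) -> None:
        if self.P < 0:
            raise ValueError("P must be nonnegative")
        if self.n <= 0 or self.m <= 0:
            raise ValueError("exponents n, m must be positive")
        if self.Tmin >= self.Tmax:
            raise ValueError("Tmin must be below Tmax")

    def __call__(self, T):
        return allahyari_rate(self, T)


@dataclass(frozen=True)
class MortalityWindowParams:
    """U-shaped mortality window between lethal temperatures.

    The ``normalized`` variant (default) evaluates

        clamp(1 - M * exp(1 - (1 + e^((Tmin-T)/Q)) * (1 + e^((T-Tmax)/Q))), 0, 1)

    which has an interior plateau near ``max(0, 1 - M)`` and rises to 1
    beyond the lethal bounds. The ``as_printed`` variant evaluates
    ``1 - M * exp((1 + e^((Tmin-T)/Q)) * (1 + e^((T-Tmax)/Q)))`` verbatim;
    it is retained as a diagnostic (its values leave [0, 1] and its shape
    is inverted) and is returned unclamped.
    """

    M: float
    Q: float
    Tmin: float
    Tmax: float
    variant: str = "normalized"

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError("Q must be positive")
        if self.Tmin >= self.Tmax:
            raise ValueError("Tmin must be below Tmax")
        if self.variant not in ("normalized", "as_printed"):
            raise ValueError(f"unknown mortality-window variant {self.variant!r}")

    def __call__(self, T):
        return mortality_window(self, T)


def gaussian_fecundity(params: GaussianFecundityParams, T):
    """Egg-laying rate (eggs female^-1 day^-1) at temperature T (degC)."""
    T = np.asarray(T, dtype=float)
    z = (T - params.Topt) / params.Tw
    out = params.Emax * np.exp(-(z * z))
    return out.item() if out.ndim == 0 else out


def allahyari_rate(params: AllahyariParams, T):
    """Development rate (day^-1) at temperature T; 0 outside the window."""
    T = np.asarray(T, dtype=float)
    x = (T - params.Tmin) / (params.Tmax - params.Tmin)
    inside = (x > 0.0) & (x < 1.0)
    xs = np.where(inside, x, 0.5)  # dummy value avoids 0**negative warnings
    val = params.P * xs**params.n * (1.0 - xs**params.m)
    out = np.where(inside, np.maximum(val, 0.0), 0.0)
    return out.item() if out.ndim == 0 else out


def _window_product(params: MortalityWindowParams, T):
    lo = np.clip((params.Tmin - T) / params.Q, -_EXP_CLIP, _EXP_CLIP)
    hi = np.clip((T - params.Tmax) / params.Q, -_EXP_CLIP, _EXP_CLIP)
    return (1.0 + np.exp(lo)) * (1.0 + np.exp(hi))


def mortality_window(params: MortalityWindowParams, T):
    """Mortality rate at temperature T.

    Normalized variant returns values in [0, 1]; as_printed returns the
    verbatim expression, unclamped.
    """
    T = np.asarray(T, dtype=float)
    prod = _window_product(params, T)
    if params.variant == "as_printed":
        out = 1.0 - params.M * np.exp(np.clip(prod, -_EXP_CLIP, _EXP_CLIP))
    else:
        out = np.clip(1.0 - params.M * np.exp(np.clip(1.0 - prod, -_EXP_CLIP, _EXP_CLIP)), 0.0, 1.0)
    return out.item() if out.ndim == 0 else out


def _window_interior_minimum(window: MortalityWindowParams) -> float:
    grid = np.linspace(window.Tmin, window.Tmax, 2001)
    return float(np.min(mortality_window(window, grid)))


@dataclass(frozen=True)
class AnchoredWindowParams:
    """Adult mortality: U-shaped window anchored at a baseline rate.

    Returns ``baseline + (1 - baseline) * w(T)`` where ``w`` is the
    normalized mortality window rescaled so that its interior minimum is 0.
    The minimum over T equals ``baseline`` and the value saturates at 1
    beyond the lethal bounds. No functional form for adult mortality is
    reported for the desert locust; this anchored family is a declared
    modeling choice that reproduces the observed U-shape with minimal
    mortality in the 20-40 degC range.
    """

    baseline: float
    window: MortalityWindowParams = field(
        default_factory=lambda: MortalityWindowParams(M=1.0, Q=1.5, Tmin=20.0, Tmax=40.0)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline < 1.0):
            raise ValueError(f"baseline mortality must lie in (0, 1), got {self.baseline}")

    def __call__(self, T):
        return adult_mortality(self.baseline, self.window, T)


def adult_mortality(baseline: float, window: MortalityWindowParams, T):
    """Adult mortality rate (day^-1): baseline inside the thermal optimum,
    saturating at 1 at the lethal bounds."""
    if not (0.0 < baseline < 1.0):
        raise ValueError(f"baseline mortality must lie in (0, 1), got {baseline}")
    T = np.asarray(T, dtype=float)
    norm = MortalityWindowParams(
        M=window.M, Q=window.Q, Tmin=window.Tmin, Tmax=window.Tmax, variant="normalized"
    )
    m = np.asarray(mortality_window(norm, T), dtype=float)
    m_min = _window_interior_minimum(norm)
    w = (m - m_min) / (1.0 - m_min) if m_min < 1.0 else np.zeros_like(m)
    out = baseline + (1.0 - baseline) * np.clip(w, 0.0, 1.0)
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fitted / default parameter sets (desert locust)
# ---------------------------------------------------------------------------

#: Fecundity, solitarious females: 400 eggs over a 3-month lifespan.
FECUNDITY_SOLITARIOUS = GaussianFecundityParams(Emax=4.4444, Topt=30.0, Tw=8.0)
#: Fecundity, gregarious females: 140 eggs over a 3-month lifespan.
FECUNDITY_GREGARIOUS = GaussianFecundityParams(Emax=1.5556, Topt=30.0, Tw=8.0)

#: Egg hatching rate fitted to temperature-versus-hatching-day data.
EGG_HATCH = AllahyariParams(P=0.2658, n=1.5818, m=0.5, Tmin=15.1, Tmax=42.9187)
#: Hopper/band development rate (one fitted curve, shared by both phases).
HOPPER_DEVELOPMENT = AllahyariParams(P=0.1192, n=1.3176, m=0.5, Tmin=15.0, Tmax=45.012)

#: Egg mortality windows; the egg-viability bounds double as lethal bounds.
EGG_MORTALITY_SOLITARIOUS = MortalityWindowParams(M=1.19, Q=1.5, Tmin=15.1, Tmax=42.9187)
EGG_MORTALITY_GREGARIOUS = MortalityWindowParams(M=0.91, Q=1.5, Tmin=15.1, Tmax=42.9187)

#: Hopper mortality windows.
HOPPER_MORTALITY_SOLITARIOUS = MortalityWindowParams(M=0.1525, Q=2.0, Tmin=15.0, Tmax=35.0)
HOPPER_MORTALITY_GREGARIOUS = MortalityWindowParams(M=0.282, Q=2.0, Tmin=15.0, Tmax=35.0)


@dataclass(frozen=True)
class Constant:
    """A temperature-independent rate."""

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"constant rate must be finite and nonnegative, got {self.value}")

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        out = np.full_like(T, self.value)
        return out.item() if out.ndim == 0 else out


Curve = Union[Constant, GaussianFecundityParams, AllahyariParams, MortalityWindowParams, AnchoredWindowParams]

_RATE_SYMBOLS = ("phi", "sigma", "gamma_h", "gamma_b", "mu_e", "mu_h", "mu_b", "mu_s", "mu_g")


@dataclass(frozen=True)
class ThermalParamSet:
    """One response curve (or constant) per temperature-dependent rate.

    The nine symbols mirror the model's temperature-dependent parameters:
    fecundity ``phi``, hatching ``sigma``, development ``gamma_h``/``gamma_b``,
    and the five stage mortalities.
    """

    phi: Curve
    sigma: Curve
    gamma_h: Curve
    gamma_b: Curve
    mu_e: Curve
    mu_h: Curve
    mu_b: Curve
    mu_s: Curve
    mu_g: Curve

    def rates(self, T) -> dict:
        """Evaluate every rate at temperature T (degC); all finite, >= 0."""
        out = {}
        for name in _RATE_SYMBOLS:
            v = getattr(self, name)(T)
            out[name] = v
        return out

    def is_constant(self) -> bool:
        return all(isinstance(getattr(self, name), Constant) for name in _RATE_SYMBOLS)


_FAMILIES = {
    "constant": (Constant, ("value",)),
    "gaussian": (GaussianFecundityParams, ("Emax", "Topt", "Tw")),
    "allahyari": (AllahyariParams, ("P", "n", "m", "Tmin", "Tmax")),
    "mortality_window": (MortalityWindowParams, ("M", "Q", "Tmin", "Tmax")),
}


def _build_curve(symbol: str, block) -> Curve:
    if isinstance(block, (int, float)):
        return Constant(float(block))
    if not isinstance(block, dict):
        raise ValueError(f"curve block for {symbol!r} must be a number or a mapping")
    block = dict(block)
    family = block.pop("family", None)
    if family == "anchored_window":
        try:
            baseline = float(block.pop("baseline"))
        except KeyError:
            raise ValueError(f"curve for {symbol!r}: anchored_window requires 'baseline'") from None
        window = MortalityWindowParams(
            M=float(block.pop("M", 1.0)),
            Q=float(block.pop("Q", 1.5)),
            Tmin=float(block.pop("Tmin", 20.0)),
            Tmax=float(block.pop("Tmax", 40.0)),
        )
        if block:
            raise ValueError(f"curve for {symbol!r}: unknown keys {sorted(block)}")
        return AnchoredWindowParams(baseline=baseline, window=window)
    if family not in _FAMILIES:
        raise ValueError(
            f"curve for {symbol!r}: unknown family {family!r}; "
            f"expected one of {sorted(_FAMILIES) + ['anchored_window']}"
        )
    cls, fields_ = _FAMILIES[family]
    kwargs = {}
    for f in fields_:
        if f not in block:
            raise ValueError(f"curve for {symbol!r} (family {family}): missing parameter {f!r}")
        kwargs[f] = float(block.pop(f))
    if family == "mortality_window" and "variant" in block:
        kwargs["variant"] = str(block.pop("variant"))
    if block:
        raise ValueError(f"curve for {symbol!r}: unknown keys {sorted(block)}")
    return cls(**kwargs)


def build_thermal_param_set(config: dict | None = None, defaults=None) -> ThermalParamSet:
    """Assemble a :class:`ThermalParamSet` from a configuration mapping.

    ``config`` maps rate symbols to either a bare number (constant rate) or
    a curve block ``{"family": ..., <parameters>}``. Symbols not named
    default to the constants in ``defaults`` (a ``ModelParams``; the
    baseline set when omitted).
    """
    from .params import derive_baseline_params

    config = dict(config or {})
    baseline = defaults if defaults is not None else derive_baseline_params()
    curves = {}
    for symbol in _RATE_SYMBOLS:
        if symbol in config:
            curves[symbol] = _build_curve(symbol, config.pop(symbol))
        else:
            curves[symbol] = Constant(getattr(baseline, symbol))
    if config:
        raise ValueError(f"unknown rate symbols in thermal config: {sorted(config)}")
    return ThermalParamSet(**curves)


def curve_to_frame(curve: Curve, T_grid):
    """Sample a curve on a temperature grid as a two-column DataFrame
    (columns ``T_celsius``, ``rate_per_day``)."""
    import pandas as pd

    T_grid = np.asarray(T_grid, dtype=float)
    return pd.DataFrame({"T_celsius": T_grid, "rate_per_day": np.asarray(curve(T_grid))})
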