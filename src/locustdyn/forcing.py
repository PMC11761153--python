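"""Seasonal mean-temperature forcing.

The non-autonomous model is driven by a smooth annual temperature signal

    T(t) = T0 * [1 + T1 * cos(2*pi*(omega*t + kappa)/365)]   (multiplicative)
    T(t) = T0 + T1 * cos(2*pi*(omega*t + kappa)/365)         (additive)

with ``T0`` the mean annual temperature (degC), ``T1`` the variation about
the mean (dimensionless in the multiplicative form, degC in the additive
form), ``omega`` the periodicity multiplier (the signal repeats every
``365/omega`` days) and ``kappa`` a phase shift in days.

The additive form is provided because reported amplitudes are sometimes
stated in degC; in the multiplicative form an amplitude of 2 would mean a
+/-200% swing about the mean, so both variants are exposed and experiments
record which one was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TemperatureForcing", "seasonal_temperature"]

_VARIANTS = ("multiplicative", "additive")


@dataclass(frozen=True)
class TemperatureForcing:
    """Parameters of the seasonal temperature signal.

    Attributes
    ----------
    T0 : float
        Mean annual temperature, degC. Must be positive.
    T1 : float
        Amplitude about the mean (fraction of ``T0`` in the multiplicative
        variant, degC in the additive variant).
    omega : float
        Periodicity multiplier; the period is ``365/omega`` days. Positive.
    kappa : float
        Phase shift, days.
    variant : str
        ``"multiplicative"`` (default) or ``"additive"``.
    """

    T0: float
    T1: float = 0.0
    omega: float = 1.0
    kappa: float = 0.0
    variant: str = "multiplicative"

    def __post_init__(self) -> None:
        for name in ("T0", "T1", "omega", "kappa"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"forcing parameter {name!r} must be finite, got {v!r}")
        if self.T0 <= 0:
            raise ValueError(f"T0 must be positive, got {self.T0}")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")

    @property
    def period(self) -> float:
        """Period of the signal in days (365/omega)."""
        return 365.0 / self.omega


def seasonal_temperature(forcing: TemperatureForcing, t):
    """Evaluate the seasonal temperature signal at time ``t`` (days).

    Accepts scalar or array ``t``; returns degC with the same shape.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time t must be finite")
    c = np.cos(2.0 * np.pi * (forcing.omega * t + forcing.kappa) / 365.0)
    if forcing.variant == "multiplicative":
        out = forcing.T0 * (1.0 + forcing.T1 * c)
    else:
        out = forcing.T0 + forcing.T1 * c
    return out.item() if out.ndim == 0 else out


def constant_forcing(T0: float) -> TemperatureForcing:
    """A zero-amplitude forcing pinned at ``T0`` degC."""
    return TemperatureForcing(T0=T0, T1=0.0)
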