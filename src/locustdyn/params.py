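"""Constant model parameters and their life-history derivations.

The autonomous model is parameterized by fifteen constants (all rates in
day^-1, densities in locusts m^-2). Several baseline values are derived
from primary life-history quantities:

* band mortality aggregates per-instar and per-moult survival across the
  five hopper instars and four moults;
* solitarious hopper mortality applies one fewer moult to the band value;
* fecundity rates divide eggs per generation by the adult lifespan in days;
* the gregarious/solitarious fecundity ratio gives the modification
  factor ``psi = 140/400 = 0.35``;
* the egg carrying capacity multiplies maximum eggs per pod by maximum
  pod density, ``K = 160 * 500 = 80,000`` eggs m^-2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "InstarSurvivalSchedule",
    "ModelParams",
    "aggregate_stage_mortality",
    "solitarious_hopper_mortality",
    "fecundity_from_lifespan",
    "derive_baseline_params",
]


@dataclass(frozen=True)
class InstarSurvivalSchedule:
    """Per-instar mortality fractions plus a shared per-moult mortality.

    Field data for gregarious bands: 70% first-instar, 20% second-instar,
    10% third-to-fifth-instar mortality and 5% at each of four moults.
    """

    instar_mortalities: Sequence[float]
    moult_mortality: float
    n_moults: int

    def __post_init__(self) -> None:
        if len(self.instar_mortalities) == 0:
            raise ValueError("instar mortality schedule must not be empty")
        for m in self.instar_mortalities:
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"instar mortality {m} outside [0, 1]")
        if not 0.0 <= self.moult_mortality <= 1.0:
            raise ValueError("moult mortality outside [0, 1]")
        if self.n_moults < 0:
            raise ValueError("n_moults must be nonnegative")


#: Field schedule for gregarious bands (five instars, four moults).
BAND_SCHEDULE = InstarSurvivalSchedule(
    instar_mortalities=(0.7, 0.2, 0.1, 0.1, 0.1), moult_mortality=0.05, n_moults=4
)


def aggregate_stage_mortality(schedule: InstarSurvivalSchedule) -> float:
    """Total stage mortality 1 - S_m^n * prod(1 - M_i) over the schedule."""
    survival = (1.0 - schedule.moult_mortality) ** schedule.n_moults
    survival *= float(np.prod([1.0 - m for m in schedule.instar_mortalities]))
    return 1.0 - survival


def solitarious_hopper_mortality(mu_b: float) -> float:
    """Solitarious hopper mortality from band mortality: mu_b * 0.95 * 0.9
    (one fewer moult in the solitarious development)."""
    if not 0.0 <= mu_b <= 1.0:
        raise ValueError(f"mu_b must lie in [0, 1], got {mu_b}")
    return mu_b * 0.95 * 0.9


def fecundity_from_lifespan(eggs_per_generation: float, lifespan_months: float) -> float:
    """Daily fecundity rate: eggs per generation over lifespan in days
    (months x 30)."""
    if eggs_per_generation < 0:
        raise ValueError("eggs_per_generation must be nonnegative")
    if lifespan_months <= 0:
        raise ValueError("lifespan must be positive")
    return eggs_per_generation / (lifespan_months * 30.0)


_FIELDS = (
    "phi", "psi", "eta", "K", "sigma", "mu_e", "theta",
    "gamma_h", "gamma_b", "mu_h", "mu_b", "mu_s", "mu_g", "beta_1", "beta_2",
)


@dataclass(frozen=True)
class ModelParams:
    """Constant parameter set of the autonomous model.

    phi: egg oviposition rate (day^-1); psi: gregarious fecundity
    modification (dimensionless); eta: adult male ratio; K: egg carrying
    capacity (m^-2); sigma: egg hatching rate; mu_e: egg mortality; theta:
    portion of hatchlings that are solitarious; gamma_h/gamma_b: hopper and
    band development rates; mu_h/mu_b: hopper and band mortalities;
    mu_s/mu_g: adult mortalities; beta_1: gregarization rate; beta_2:
    dissociation rate (all rates day^-1).
    """

    phi: float
    psi: float
    eta: float
    K: float
    sigma: float
    mu_e: float
    theta: float
    gamma_h: float
    gamma_b: float
    mu_h: float
    mu_b: float
    mu_s: float
    mu_g: float
    beta_1: float
    beta_2: float

    def __post_init__(self) -> None:
        for name in _FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name!r} must be finite and nonnegative, got {v}")
        for name in ("psi", "eta", "theta"):
            if getattr(self, name) > 1.0:
                raise ValueError(f"parameter {name!r} must lie in [0, 1]")
        if self.K <= 0:
            raise ValueError("K must be positive")

    def replace(self, **overrides) -> "ModelParams":
        """A copy with the given fields overridden."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in _FIELDS}


def derive_baseline_params(beta_in_hours: bool = False) -> ModelParams:
    """The baseline constant-parameter set, with derived entries recomputed
    from their life-history sources and cross-checked against the tabled
    values (4-decimal agreement).

    ``beta_in_hours`` applies an hours-to-days conversion (x24) to the
    phase-transition rates, for exploring the alternative reading of their
    tabled unit.
    """
    mu_b = aggregate_stage_mortality(BAND_SCHEDULE)
    mu_h = solitarious_hopper_mortality(mu_b)
    phi_sol_max = fecundity_from_lifespan(400, 3)
    phi_greg_max = fecundity_from_lifespan(140, 3)
    psi = phi_greg_max / phi_sol_max  # = 140/400

    checks = {"mu_b": (mu_b, 0.8575), "mu_h": (mu_h, 0.7332),
              "phi_max": (phi_sol_max, 4.4444), "psi": (psi, 0.35)}
    for name, (got, tabled) in checks.items():
        if abs(got - tabled) > 5e-5:
            raise AssertionError(f"derived {name}={got:.6f} disagrees with tabled {tabled}")

    beta = 0.25 * (24.0 if beta_in_hours else 1.0)
    return ModelParams(
        phi=3.556,
        psi=round(psi, 4),
        eta=0.483,
        K=160.0 * 500.0,
        sigma=0.0714,
        mu_e=0.33,
        theta=0.65,
        gamma_h=0.0263,
        gamma_b=0.0243,
        mu_h=round(mu_h, 4),
        mu_b=round(mu_b, 4),
        mu_s=0.0083,
        mu_g=0.0111,
        beta_1=beta,
        beta_2=beta,
    )
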