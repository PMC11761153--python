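"""Seasonally forced dynamics and the periodic offspring ratio.

Drives the egg-hatching rate through its thermal response curve under an
annual temperature cycle, integrates the forced system, and computes the
basic offspring ratio N0w of the periodic linearization: the threshold
quantity that decides whether the seasonal extinction state is stable.
"""

import numpy as np

from locustdyn import (
    StageState,
    TemperatureForcing,
    build_periodic_linearization,
    build_thermal_param_set,
    derive_baseline_params,
    offspring_number_closed_form,
    periodic_offspring_ratio,
    simulate,
)

params = derive_baseline_params().replace(phi=25.0, mu_h=0.25, mu_b=0.3)
thermal = build_thermal_param_set(
    {"sigma": {"family": "allahyari", "P": 0.2658, "n": 1.5818, "m": 0.5,
               "Tmin": 15.1, "Tmax": 42.9187}},
    defaults=params)
forcing = TemperatureForcing(T0=28, T1=6, omega=1, kappa=0, variant="additive")

lin = build_periodic_linearization(thermal, forcing, params)
n0w = periodic_offspring_ratio(lin)
n0_const = offspring_number_closed_form(params).N0
print(f"autonomous N0 at the mean temperature scenario: {n0_const:.4f}")
print(f"periodic offspring ratio N0w under seasonal hatching: {n0w:.4f}")

grid = np.linspace(0, 365 * 6, 365 * 6 + 1)
traj = simulate(StageState(E=800, H=0, B=0, S=10, G=10), params=params,
                thermal=thermal, forcing=forcing, t_span=(0, grid[-1]), t_eval=grid)
last_year = traj.to_frame().iloc[-365:]
peak = last_year.loc[last_year["N"].idxmax()]
print(f"final-year peak density N = {peak['N']:.0f} per m^2 at T = {peak['T_celsius']:.1f} degC")
drift = abs(traj.total[-1] - traj.total[-366]) / traj.total[-1]
print(f"year-over-year drift of the final state: {100 * drift:.3f}%")
print("\nN0w > 1: the forced population settles onto an annual cycle whose")
print("peaks track the hatching optimum rather than dying out.")
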