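"""Evaluate the four thermal response-curve families at a few temperatures.

Prints the fecundity, hatching, development and mortality rates of desert
locusts across a temperature sweep. The numbers show the thermal optimum
near 30 degC: fecundity and hatching peak there, mortality has its
U-shaped minimum across 20-40 degC, and every rate collapses (or
saturates, for mortality) beyond the lethal bounds.
"""

import numpy as np

from locustdyn import adult_mortality, allahyari_rate, gaussian_fecundity, mortality_window
from locustdyn.responses import (
    EGG_HATCH,
    EGG_MORTALITY_GREGARIOUS,
    FECUNDITY_SOLITARIOUS,
    HOPPER_DEVELOPMENT,
    MortalityWindowParams,
)

adult_window = MortalityWindowParams(M=1.0, Q=1.5, Tmin=20.0, Tmax=40.0)

print(f"{'T (degC)':>9} {'phi_S':>8} {'sigma':>8} {'gamma':>8} {'mu_e,greg':>10} {'mu_s':>8}")
for T in np.arange(10, 51, 5):
    print(f"{T:9.0f} "
          f"{gaussian_fecundity(FECUNDITY_SOLITARIOUS, T):8.4f} "
          f"{allahyari_rate(EGG_HATCH, T):8.4f} "
          f"{allahyari_rate(HOPPER_DEVELOPMENT, T):8.4f} "
          f"{mortality_window(EGG_MORTALITY_GREGARIOUS, T):10.4f} "
          f"{adult_mortality(0.0083, adult_window, T):8.4f}")

print("\nColumns: solitarious fecundity (eggs/female/day), egg hatching and")
print("hopper development rates (1/day), gregarious egg mortality and")
print("solitarious adult mortality (1/day). All rates are temperature windows:")
print("zero or maximal outside the viable range, optimal near 30 degC.")
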