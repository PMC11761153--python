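"""Recover thermal-response parameters from a synthetic rate table.

Generates a noisy temperature-versus-hatching-rate table from the known
egg development curve, refits the curve with the falling exponent fixed
at m = 0.5, and prints true versus recovered parameters.
"""

import numpy as np

from locustdyn import fit_thermal_curve, generate_fixture_table

truth = {"P": 0.2658, "n": 1.5818, "m": 0.5, "Tmin": 15.1, "Tmax": 42.9187}
table = generate_fixture_table("allahyari", truth, np.linspace(16, 42, 30),
                               noise_sd=0.001, seed=42)
print("synthetic table: 30 points on 16-42 degC, Gaussian noise sd 0.001 /day")

fit = fit_thermal_curve(table, "allahyari", fixed={"m": 0.5})
print(f"converged: {fit.converged}, SSE = {fit.sse:.3e}\n")
print(f"{'parameter':>10} {'true':>10} {'recovered':>10} {'rel err':>9}")
for k, v in truth.items():
    r = fit.params[k]
    err = abs(r - v) / abs(v)
    print(f"{k:>10} {v:10.4f} {r:10.4f} {100 * err:8.2f}%")

print("\nWith noise at ~4% of the curve maximum the lethal bounds and the")
print("shape exponent are recovered to a few percent; noiseless tables are")
print("recovered to solver precision (see the test suite).")
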