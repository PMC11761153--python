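# locustdyn

Temperature-driven population dynamics of the desert locust
(*Schistocerca gregaria*), for quantitative ecologists and pest-management
modellers. The package implements a stage-structured, dual-phase
compartment model — eggs *E*, solitarious hoppers *H*, gregarious
hoppers/bands *B*, solitarious adults *S* and gregarious adults/swarms
*G* — together with the thermal response curves that make its vital rates
temperature-dependent, and the threshold and sensitivity machinery used to
analyse it.

## The model

The autonomous system (densities per m², rates per day):

```
dE/dt = (1-η) φ (1 - E/K) (S + ψG) - (σ + μe) E
dH/dt = θ σ E - (γh + μh) H
dB/dt = (1-θ) σ E - (γb + μb) B
dS/dt = γh H + β₂ G - (β₁ + μs) S
dG/dt = γb B + β₁ S - (β₂ + μg) G
```

Females (fraction 1−η) lay eggs logistically against the egg carrying
capacity *K*; gregarious females lay at a fraction ψ of the solitarious
rate. Hatchlings split θ : 1−θ between the solitarious and gregarious
hopper lines; adults exchange phase through gregarization (β₁) and
dissociation (β₂). In the seasonally forced variant every rate except θ,
β₁, β₂, ψ, η, K follows a thermal response curve evaluated at
T(t) = T₀[1 + T₁ cos(2π(ωt+κ)/365)] (an additive variant T₀ + T₁ cos(·)
is also provided).

Core analysis quantities:

* **Basic offspring number** N₀ = N₀S + N₀G — expected lifetime female
  offspring per female, the spectral radius of the next-generation matrix
  R V⁻¹ at the extinction state. N₀ < 1 means extinction, N₀ > 1 a stable
  positive equilibrium; the fecundity threshold φ\* solves N₀ = 1 and the
  transcritical bifurcation there is forward (center-manifold
  coefficients a < 0 < b).
* **Periodic offspring ratio** N₀ω — the seasonal analogue, computed as
  the λ at which the monodromy of dW/dt = [−V(t) + F(t)/λ]W has spectral
  radius 1.
* **Thermal response curves** — Gaussian fecundity, the Allahyari
  development curve P·xⁿ(1−xᵐ) between lethal temperatures, and logistic
  mortality windows, with nonlinear least-squares fitting and a synthetic
  fixture generator for parameter-recovery experiments.
* **PRCC sensitivity** — Latin-hypercube sampling over the documented
  parameter ranges and partial rank correlation of N₀ with each parameter.

## Worked example

```python
from locustdyn import (derive_baseline_params, offspring_number_closed_form,
                       offspring_number_ngm, phi_star)

base = derive_baseline_params()
for name, p in {"extinction (phi=1.75)": base.replace(phi=1.75),
                "persistence (phi=25, mu_h=0.25, mu_b=0.3)":
                    base.replace(phi=25.0, mu_h=0.25, mu_b=0.3)}.items():
    ns = offspring_number_closed_form(p)
    print(name, round(ns.N0, 4), round(offspring_number_ngm(p), 4))
print("phi* =", round(phi_star(base), 4))
```

prints

```
extinction (phi=1.75) 0.3624 0.3624
persistence (phi=25, mu_h=0.25, mu_b=0.3) 14.1865 14.1865
phi* = 4.8286
```

The first scenario sits below the N₀ = 1 threshold (every trajectory
decays to extinction), the second far above it (all trajectories converge
to the positive equilibrium); the closed form and the independent
next-generation-matrix computation agree to machine precision, and
baseline fecundity (3.556) lies below the threshold φ\* ≈ 4.83. The
`examples/` directory holds one short script per capability — response
curves, offspring numbers, autonomous and seasonal simulation, curve
fitting, PRCC — each printing the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```sh
locustdyn params                 # baseline parameter set as YAML
locustdyn threshold --config cfg.yaml
locustdyn simulate --config cfg.yaml --out-dir out/
locustdyn periodic-threshold | prcc | fit | experiment ...
```

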