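# Methods

## Model and assumptions

The package models a homogeneously mixed desert locust population in five
compartments (eggs, solitarious hoppers, gregarious hoppers/bands,
solitarious adults, gregarious adults/swarms). Egg deposition is
logistic against an egg carrying capacity *K*; only females (fraction
1−η) oviposit, gregarious females at a fraction ψ of the solitarious
rate. Hatchlings split between phases by a fixed proportion θ; phase
transitions happen in the adult stage only (gregarization β₁,
dissociation β₂). Temperature is the single environmental driver: soil
moisture is assumed adequate so air temperature proxies soil temperature
at pod depth, and all other environmental factors sit at their optima.
The state is a density (per m²); no spatial structure, migration or
control interventions are represented.

Time is measured in days throughout; all rates are per day.

## Parameters

The baseline constant set (units per day unless noted):

| symbol | meaning | baseline | provenance |
|---|---|---|---|
| φ | egg-laying rate | 3.556 | eggs per generation / lifespan; bounds 0.933–4.44 |
| ψ | gregarious fecundity factor | 0.35 | 140/400 eggs per generation |
| η | adult male ratio | 0.483 | survey sex ratios 0.302–0.501 |
| K | egg carrying capacity (m⁻²) | 80 000 | 160 eggs/pod × 500 pods/m² |
| σ | egg hatching rate | 0.0714 | 1 / two-week mean incubation |
| μe | egg mortality | 0.33 | field loss estimates 0.05–0.65 |
| θ | solitarious hatchling share | 0.65 | assumed |
| γh, γb | hopper/band development | 0.0263, 0.0243 | 1 / development duration |
| μh, μb | hopper/band stage mortality | 0.7332, 0.8575 | instar/moult survival product |
| μs, μg | adult mortality | 0.0083, 0.0111 | 1 / 90–150-day lifespan |
| β₁, β₂ | phase transition rates | 0.25 | tabulated as hr⁻¹; read as day⁻¹ (below) |

Derived entries are recomputed from their life-history sources at build
time and cross-checked against the tabulated values at 4-decimal
precision: band mortality is 1 − S_m⁴·∏Sᵢ over five instar survivals
(0.3, 0.8, 0.9, 0.9, 0.9) and four moults at 0.95, giving 0.8575;
solitarious hoppers apply one fewer moult (×0.95×0.9 → 0.7332, applied
multiplicatively to the mortality as the source derivation does).

β₁, β₂ are tabulated as 0.25 hr⁻¹ while every other rate is daily; the
package reads them as 0.25 day⁻¹ for dimensional consistency (a ×24
conversion is available via `derive_baseline_params(beta_in_hours=True)`
for exploration).

## Thermal response curves

Four families cover the nine temperature-dependent rates:

* **Gaussian fecundity** Emax·exp(−((T−Topt)/Tw)²), with Topt = 30 °C,
  Tw = 8 °C; Emax = 4.4444 for solitarious and 1.5556 for gregarious
  females. (One source passage swaps these two labels; the package
  follows the life-history derivation — 400 vs 140 eggs per generation —
  under which solitarious females are the more fecund, consistent with
  the model's own assumption. The discrepancy is documented, not
  resolved.)
* **Allahyari development curve** P·xⁿ(1−xᵐ) with
  x = (T−Tmin)/(Tmax−Tmin), clamped to zero outside the lethal window.
  Egg hatching: P = 0.2658, n = 1.5818, m = 0.5, Tmin = 15.1 °C,
  Tmax = 42.9187 °C. Hopper development: P = 0.1192, n = 1.3176,
  m = 0.5, Tmin = 15 °C, Tmax = 45.012 °C; one fitted curve is shared by
  both phases (no separate gregarious fit is reported).
* **Mortality window.** The printed form of the egg/hopper mortality
  curve, 1 − M·exp((1+e^((Tmin−T)/Q))(1+e^((T−Tmax)/Q))), is negative in
  the window interior and inverted in shape (the exponent is ≥ 1 with a
  positive sign), so the package defaults to a *normalized* variant,
  clamp(1 − M·exp(1 − (1+e^((Tmin−T)/Q))(1+e^((T−Tmax)/Q))), 0, 1),
  which restores the described U-shape — plateau near max(0, 1−M) inside
  the window, saturation at 1 beyond the lethal bounds — while keeping
  the printed parameters and their ordering role (gregarious eggs,
  M = 0.91, die more than solitarious, M = 1.19, at every temperature).
  The verbatim form is retained as an `as_printed` diagnostic variant,
  returned unclamped. Egg windows default to the egg-viability bounds
  (15.1, 42.9187 °C) since no lethal bounds are stated for them; hopper
  windows use Q = 2, Tmin = 15, Tmax = 35 with M = 0.1525 (solitarious)
  and 0.282 (gregarious).
* **Anchored adult mortality.** No functional form is reported for adult
  mortality; the package's declared modelling choice rescales the
  normalized window (default bounds 20–40 °C) so its interior minimum
  equals the tabulated baseline rate (0.0083 or 0.0111 day⁻¹) and its
  value saturates at 1 at the lethal bounds, reproducing the described
  U-shape. It is config-overridable like every other curve.

## Threshold analysis

N₀ is computed two ways: the closed-form decomposition N₀S + N₀G, and
the spectral radius of R V⁻¹ assembled numerically; the two agree to
1e-10 relative on randomized parameter draws and the second serves as a
permanent cross-check. The closed form requires c₄c₅ > β₁β₂ (adult
transfer block invertible), which holds whenever either adult mortality
is positive.

The fecundity threshold φ\* is the exact solution of N₀(φ) = 1. The
transcription of this expression in the source text transposes γh and γb
in the denominator (evaluating it gives N₀(φ\*) ≈ 1.03 at baseline); the
package uses the consistent expression, for which N₀(φ\*) = 1 holds to
machine precision and is asserted at every call.

The positive equilibrium uses E\*\* = K(1 − 1/N₀) and the hopper balance
equations; the two adult densities are obtained by solving the 2×2 adult
balance linear system directly, because the transcribed closed forms for
S\*\*, G\*\* are typographically garbled. The zero-residual property
(‖RHS‖∞ < 1e-9·K) is the ground truth and is enforced.

Stability verdicts use the analytic Jacobian (validated against central
differences) with "stable" meaning every eigenvalue real part below
−1e-9, a floating-point margin. At the threshold the center-manifold
coefficients are a = −2(1−η)φ\*/K·v₁u₁(u₄+ψu₅) and b = (1−η)v₁(u₄+ψu₅),
with u, v the right/left null vectors of the threshold Jacobian
normalized to fifth component 1. That Jacobian is an irreducible Metzler
matrix, so Perron–Frobenius makes both null vectors strictly positive;
hence v₁ > 0, a < 0 < b, and the bifurcation is always forward for valid
parameters. A sign rule quoted in the source literature,
sign((β₂μs−β₁μg)/(c₅−ψc₄)), contradicts this whenever it is negative;
the package reports both the numeric sign and the rule's sign with an
agreement flag rather than forcing them to match, and additionally
verifies the numeric v₁ against the exact component
(c₄c₅−β₁β₂)v₅/((1−η)φ\*(ψc₄+β₂)) derived from vᵀJ = 0.

Reference scenario values: with baseline parameters and φ = 1.75 the
package computes N₀ = 0.3624; with φ = 25, μh = 0.25, μb = 0.3 it
computes N₀ = 14.1865 (closed form and NGM identical). Values of 0.2636
and 16.2066 have circulated for these two scenarios; they are not
reproducible from the stated parameter sets under either the closed form
or the NGM (no single parameter reinterpretation explains both), so the
package reports its computed values alongside the NGM cross-check and
notes the discrepancy instead of forcing agreement.

## Periodic offspring ratio

For the forced linearization at extinction, F(t) carries the new-egg row
((1−η)φ(T(t)) and (1−η)ψφ(T(t)) against the two adult columns) and V(t)
the transfer terms. N₀ω is evaluated through the standard λ-scaled
monodromy characterization: the unique λ > 0 with
ρ(Φ_{−V+F/λ}(ω)) = 1, rather than by discretizing the integral
next-generation operator directly (well-conditioned and desk-scale).
Monodromy integration uses DOP853 at rtol 1e-10/atol 1e-12 over the
forcing period (365/ω days) in 12 renormalized chunks, accumulating the
log of the scale so strongly growing or decaying systems stay
representable; root finding is geometric bracket expansion from λ = 1
(ρ is monotone decreasing in λ, checked on the final bracket) followed
by Brent's method at 1e-6 relative tolerance. Zero recruitment returns
N₀ω = 0 by convention. With zero forcing amplitude the ratio reproduces
the autonomous N₀ to better than 1e-6 relative.

## Simulation

Integration uses adaptive explicit Runge–Kutta (RK45 by default,
rtol 1e-8, atol 1e-10) with dense output onto a requested grid. The egg
logistic term is evaluated as written even if E transiently exceeds K
(the term then pushes E back); there is no hard cap. Components within
1e-9 of zero (scaled by the trajectory magnitude) are clipped to zero;
anything more negative raises an integration error. Reference horizons:
4000 days suffice for the extinction scenario to fall below 1e-6·K
(slowest decay mode ~adult mortality, timescale ~120 days) and 3000 days
for the persistence scenario to reach its equilibrium within far better
than 1%.

## Curve fitting and synthetic fixtures

The raw temperature–duration tables behind the fitted curves are not
redistributed, so parameter-recovery experiments run on synthetic
fixtures: noiseless or Gaussian-noise samples (truncated at zero) from a
known curve, seeded explicitly — the generator emulates the shape and
sampling density of such tables, not their exact values, so recovery
results certify the estimator, not the original data. Fitting is bounded
trust-region least squares in rate space (duration-space fitting was
considered and left out; rate space matches the fixture noise model),
default boxes Tmin ∈ [0, 25], Tmax ∈ [35, 60], P ∈ (0, 5], exponents
∈ (0, 10], initial guess at mid-bounds, with any parameter subset
fixable (m = 0.5 mirrors the development-curve fits). Noiseless tables
are recovered to solver precision. Recovery accuracy under noise depends
on the noise-to-signal ratio: at sd 0.005 day⁻¹ the Gaussian fecundity
curve (scale 4.44) is recovered with median relative error ~1e-4, while
the egg-hatching curve (maximum 0.0265 day⁻¹, i.e. ~19% relative noise)
shows ~7–9% median error that is pure estimation variance — fits reach
SSE at or below the generating truth's — not optimizer failure.

## Sensitivity analysis

PRCC of N₀ over Latin-hypercube draws from the documented parameter
ranges (n = 1000, seeded). ψ, μh and μb have no documented range and are
assigned ±20% of baseline, flagged as assumed; θ spans (0.01, 0.99).
The response is the closed-form N₀ (trajectory-based sensitivity is out
of scope). Coefficient signs reproduce the analytic monotonicity of N₀
(positive for φ, ψ, σ, γh, γb; negative for η, μe, μh, μb, μs, μg), and
K — structurally absent from N₀ — yields a null coefficient within
3/√n.

## Synthetic data and what passing tests show

The package's stochastic inputs (fixture tables, LHS draws) are fully
synthetic and seeded. They emulate the *structure* of field-derived
inputs — smooth thermal performance curves sampled with independent
Gaussian error, uniform parameter uncertainty boxes — but not
measurement artefacts (heteroscedastic or duration-space error,
correlated residuals, digitization bias) or ecological realism
(weather-station temperature series, spatial heterogeneity). Passing
tests therefore certify the mathematics and the estimators under the
stated idealizations, not predictive accuracy for field populations.

## Known limitations

* The forced model inherits the dimensional ambiguity of the
  multiplicative temperature signal: an amplitude quoted in °C only
  makes sense in the additive variant, so both are exposed and runs
  record which was used; which variant produced previously published
  seasonal simulations cannot be determined.
* Adult thermal mortality uses the package's anchored-window family; no
  empirical functional form was available to fit.
* Global stability beyond N₀ thresholds is supported by simulation
  evidence only; no Lyapunov certification is attempted.
* PRCC is computed for the autonomous N₀; sensitivity of the periodic
  ratio N₀ω is not implemented.
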