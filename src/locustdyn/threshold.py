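"""Basic offspring number, equilibria, stability and bifurcation analysis
of the autonomous model.

The basic offspring number N0 — the expected lifetime female offspring of
one female — is the spectral radius of the next-generation matrix R V^-1
built from the recruitment and transfer Jacobians at the extinction
equilibrium. It splits into solitarious and gregarious contributions,

    N0 = N0S + N0G,

    N0S = (1-eta) phi [theta sigma gamma_h c3 c5 + (1-theta) sigma gamma_b beta_2 c2]
          / (c1 c2 c3 (c4 c5 - beta_1 beta_2)),
    N0G = (1-eta) psi phi [(1-theta) sigma gamma_b c2 c4 + theta sigma gamma_h beta_1 c3]
          / (c1 c2 c3 (c4 c5 - beta_1 beta_2)),

with the rate aggregates c1 = sigma + mu_e, c2 = gamma_h + mu_h,
c3 = gamma_b + mu_b, c4 = beta_1 + mu_s, c5 = beta_2 + mu_g. The closed
form is validated at run time against the numerically computed spectral
radius. N0 = 1 separates extinction from persistence; the fecundity value
phi* at which N0 crosses 1 is the transcritical bifurcation threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import StageState, rhs_autonomous
from .params import ModelParams

__all__ = [
    "RateAggregates",
    "OffspringNumbers",
    "BifurcationReport",
    "StabilityReport",
    "rate_aggregates",
    "offspring_number_closed_form",
    "offspring_number_ngm",
    "phi_star",
    "nontrivial_equilibrium",
    "jacobian_autonomous",
    "stability_report",
    "bifurcation_coefficients",
]

#: "Stable" requires every eigenvalue real part below this margin.
STABILITY_MARGIN = -1e-9


@dataclass(frozen=True)
class RateAggregates:
    """Outflow aggregates of the five compartments (day^-1)."""

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float


def rate_aggregates(params: ModelParams) -> RateAggregates:
    """c1..c5: total outflow rate from each compartment."""
    return RateAggregates(
        c1=params.sigma + params.mu_e,
        c2=params.gamma_h + params.mu_h,
        c3=params.gamma_b + params.mu_b,
        c4=params.beta_1 + params.mu_s,
        c5=params.beta_2 + params.mu_g,
    )


@dataclass(frozen=True)
class OffspringNumbers:
    """Basic offspring number and its phase decomposition."""

    N0S: float
    N0G: float
    N0: float
    aggregates: RateAggregates


def _adult_denominator(params: ModelParams, agg: RateAggregates) -> float:
    return agg.c4 * agg.c5 - params.beta_1 * params.beta_2


def offspring_number_closed_form(params: ModelParams) -> OffspringNumbers:
    """Closed-form N0S, N0G and N0 = N0S + N0G.

    Requires c4*c5 > beta_1*beta_2 (equivalently mu_s, mu_g not both zero),
    which makes the adult transfer block invertible.
    """
    agg = rate_aggregates(params)
    det = _adult_denominator(params, agg)
    if det <= 0:
        raise ValueError(
            f"adult transfer block degenerate: c4*c5 - beta_1*beta_2 = {det:.3e} <= 0"
        )
    den = agg.c1 * agg.c2 * agg.c3 * det
    fem = (1.0 - params.eta) * params.phi
    n0s = fem * (params.theta * params.sigma * params.gamma_h * agg.c3 * agg.c5
                 + (1.0 - params.theta) * params.sigma * params.gamma_b * params.beta_2 * agg.c2) / den
    n0g = fem * params.psi * ((1.0 - params.theta) * params.sigma * params.gamma_b * agg.c2 * agg.c4
                              + params.theta * params.sigma * params.gamma_h * params.beta_1 * agg.c3) / den
    return OffspringNumbers(N0S=n0s, N0G=n0g, N0=n0s + n0g, aggregates=agg)


def _ngm_matrices(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Recruitment Jacobian R and transfer Jacobian V at the origin."""
    agg = rate_aggregates(params)
    R = np.zeros((5, 5))
    R[0, 3] = (1.0 - params.eta) * params.phi
    R[0, 4] = (1.0 - params.eta) * params.phi * params.psi
    V = np.array([
        [agg.c1, 0.0, 0.0, 0.0, 0.0],
        [-params.theta * params.sigma, agg.c2, 0.0, 0.0, 0.0],
        [-(1.0 - params.theta) * params.sigma, 0.0, agg.c3, 0.0, 0.0],
        [0.0, -params.gamma_h, 0.0, agg.c4, -params.beta_2],
        [0.0, 0.0, -params.gamma_b, -params.beta_1, agg.c5],
    ])
    return R, V


def offspring_number_ngm(params: ModelParams) -> float:
    """N0 as the spectral radius of R V^-1, computed numerically.

    Serves as the independent oracle for the closed form.
    """
    R, V = _ngm_matrices(params)
    if abs(np.linalg.det(V)) < 1e-300:
        raise ValueError("transfer matrix V is singular")
    K = R @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def phi_star(params: ModelParams) -> float:
    """Fecundity threshold phi* at which N0 = 1.

    Obtained by solving N0 = 1 for phi:

        phi* = c1 c2 c3 (mu_s c5 + beta_1 mu_g)
               / ((1-eta) sigma [theta gamma_h c3 (beta_1 psi + c5)
                                 + (1-theta) gamma_b c2 (beta_2 + c4 psi)])

    (the numerator equals the adult determinant: mu_s c5 + beta_1 mu_g
    = c4 c5 - beta_1 beta_2). The identity N0(phi*) = 1 is enforced as a
    cross-check at call time.
    """
    agg = rate_aggregates(params)
    den = (1.0 - params.eta) * params.sigma * (
        params.theta * params.gamma_h * agg.c3 * (params.beta_1 * params.psi + agg.c5)
        + (1.0 - params.theta) * params.gamma_b * agg.c2 * (params.beta_2 + agg.c4 * params.psi)
    )
    if den <= 0:
        raise ValueError("phi* undefined: zero denominator (sigma or development rates vanish)")
    num = agg.c1 * agg.c2 * agg.c3 * _adult_denominator(params, agg)
    ps = num / den
    check = offspring_number_closed_form(params.replace(phi=ps)).N0
    if abs(check - 1.0) > 1e-8:
        warnings.warn(f"phi* consistency check failed: N0(phi*) = {check!r}", RuntimeWarning)
    return ps


def nontrivial_equilibrium(params: ModelParams) -> StageState:
    """The positive equilibrium P**, defined for N0 > 1.

    E** = K (1 - 1/N0); hopper stages follow from their balance equations
    and the two adult densities solve the linear adult balance
    (c4 S = gamma_h H + beta_2 G; c5 G = gamma_b B + beta_1 S). The
    returned state zeroes the autonomous right-hand side to within
    1e-9 * K.
    """
    ns = offspring_number_closed_form(params)
    if ns.N0 <= 1.0:
        raise ValueError(f"no positive equilibrium: N0 = {ns.N0:.4f} <= 1")
    agg = ns.aggregates
    E = params.K * (1.0 - 1.0 / ns.N0)
    H = params.theta * params.sigma * E / agg.c2
    B = (1.0 - params.theta) * params.sigma * E / agg.c3
    A = np.array([[agg.c4, -params.beta_2], [-params.beta_1, agg.c5]])
    S, G = np.linalg.solve(A, np.array([params.gamma_h * H, params.gamma_b * B]))
    state = StageState(E=E, H=H, B=B, S=S, G=G)
    resid = float(np.max(np.abs(rhs_autonomous(state, params))))
    if resid > 1e-9 * params.K:
        raise AssertionError(f"equilibrium residual {resid:.3e} exceeds 1e-9*K")
    return state


def jacobian_autonomous(state, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of the autonomous right-hand side at ``state``."""
    y = state.to_array() if isinstance(state, StageState) else np.asarray(state, dtype=float)
    E, H, B, S, G = y
    agg = rate_aggregates(params)
    fem = (1.0 - params.eta) * params.phi
    J = np.zeros((5, 5))
    J[0, 0] = -fem * (S + params.psi * G) / params.K - agg.c1
    J[0, 3] = fem * (1.0 - E / params.K)
    J[0, 4] = fem * params.psi * (1.0 - E / params.K)
    J[1, 0] = params.theta * params.sigma
    J[1, 1] = -agg.c2
    J[2, 0] = (1.0 - params.theta) * params.sigma
    J[2, 2] = -agg.c3
    J[3, 1] = params.gamma_h
    J[3, 3] = -agg.c4
    J[3, 4] = params.beta_2
    J[4, 2] = params.gamma_b
    J[4, 3] = params.beta_1
    J[4, 4] = -agg.c5
    return J


@dataclass(frozen=True)
class StabilityReport:
    """Jacobian spectrum at an equilibrium and the stability verdict."""

    eigenvalues: np.ndarray
    max_real_part: float
    stable: bool


def stability_report(params: ModelParams, point: StageState) -> StabilityReport:
    """Eigenvalues of the Jacobian at ``point`` and a stability verdict.

    ``point`` must be an equilibrium (residual below 1e-6 * K is
    enforced). For the origin the verdict provably matches the sign of
    N0 - 1.
    """
    resid = float(np.max(np.abs(rhs_autonomous(point, params))))
    if resid > 1e-6 * params.K:
        raise ValueError(f"point is not an equilibrium: residual {resid:.3e}")
    eig = np.linalg.eigvals(jacobian_autonomous(point, params))
    mx = float(np.max(eig.real))
    return StabilityReport(eigenvalues=eig, max_real_part=mx, stable=mx < STABILITY_MARGIN)


@dataclass(frozen=True)
class BifurcationReport:
    """Transcritical bifurcation diagnostics at phi = phi*.

    ``u`` and ``v`` are the right and left null vectors of the origin
    Jacobian at the threshold (both normalized to fifth component 1);
    ``a`` and ``b`` are the center-manifold coefficients

        a = -2 (1-eta) phi*/K * v1 u1 (u4 + psi u5),
        b = (1-eta) v1 (u4 + psi u5).

    They carry opposite signs, determined by sign(v1): v1 > 0 yields
    a < 0 < b, a forward (supercritical) transcritical bifurcation.

    ``v1_sign_rule`` records the sign of
    (beta_2 mu_s - beta_1 mu_g) / (c5 - psi c4), a closed sign rule quoted
    in the source literature for this model; it disagrees with the numeric
    eigenvector whenever it is negative, because the threshold Jacobian is
    an irreducible Metzler matrix whose dominant (zero) eigenvalue carries
    strictly positive left and right eigenvectors (Perron-Frobenius), so
    v1 > 0 always. ``v1_rule_agrees`` flags the comparison; the
    classification follows the numeric vector.
    """

    phi_star: float
    u: np.ndarray
    v: np.ndarray
    v1_sign: int
    v1_sign_rule: int
    v1_rule_agrees: bool
    a: float
    b: float
    classification: str


def _null_vector(M: np.ndarray) -> np.ndarray:
    """Null vector of a (numerically) rank-4 5x5 matrix via SVD."""
    _, s, vt = np.linalg.svd(M)
    if s[-2] < 1e-8 * max(s[0], 1.0):
        raise ValueError("zero eigenvalue is not simple: degenerate bifurcation")
    return vt[-1]


def bifurcation_coefficients(params: ModelParams) -> BifurcationReport:
    """Center-manifold coefficients a, b of the transcritical bifurcation
    at phi = phi*.

    The numeric v1 is cross-checked against the exact left-eigenvector
    component derived from v^T J = 0,

        v1 = (c4 c5 - beta_1 beta_2) v5 / ((1-eta) phi* (psi c4 + beta_2)),

    which is strictly positive for any valid parameter set. The quoted
    closed sign rule sign((beta_2 mu_s - beta_1 mu_g)/(c5 - psi c4)) is
    also evaluated and reported; see :class:`BifurcationReport`.
    """
    ps = phi_star(params)
    at_star = params.replace(phi=ps)
    J = jacobian_autonomous(StageState(0, 0, 0, 0, 0), at_star)

    u = _null_vector(J)
    v = _null_vector(J.T)
    if abs(u[4]) < 1e-12 or abs(v[4]) < 1e-12:
        raise ValueError("fifth component vanishes; cannot apply the u5, v5 > 0 normalization")
    u = u / u[4]
    v = v / v[4]

    agg = rate_aggregates(params)
    det = _adult_denominator(params, agg)
    v1_exact = det / ((1.0 - params.eta) * ps * (params.psi * agg.c4 + params.beta_2))
    if abs(v[0] - v1_exact) > 1e-8 * max(1.0, abs(v1_exact)):
        raise AssertionError(
            f"numeric v1 = {v[0]:.6e} disagrees with the exact component {v1_exact:.6e}"
        )

    num = params.beta_2 * params.mu_s - params.beta_1 * params.mu_g
    den = agg.c5 - params.psi * agg.c4
    rule_sign = int(np.sign(num) * np.sign(den))
    v1_sign = 0 if abs(v[0]) < 1e-12 else int(np.sign(v[0]))

    fem = 1.0 - params.eta
    lever = u[3] + params.psi * u[4]
    a = -2.0 * fem * ps / params.K * v[0] * u[0] * lever
    b = fem * v[0] * lever

    if v1_sign > 0:
        cls = "forward (a < 0 < b): supercritical transcritical bifurcation"
    elif v1_sign < 0:
        cls = "a > 0 > b: no forward bifurcation at this parameter set"
    else:
        cls = "degenerate: v1 = 0 boundary case"
    return BifurcationReport(phi_star=ps, u=u, v=v, v1_sign=v1_sign,
                             v1_sign_rule=rule_sign,
                             v1_rule_agrees=(v1_sign == rule_sign),
                             a=float(a), b=float(b), classification=cls)
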