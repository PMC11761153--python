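"""Latin-hypercube sampling and PRCC sensitivity of the offspring number.

Partial rank correlation coefficients measure the monotone association
between each input parameter and a model output while adjusting for the
other inputs: all columns are rank-transformed, each parameter's ranks and
the output's ranks are residualized against the remaining parameters'
ranks by linear regression, and the two residual vectors are correlated.
Inputs are drawn by Latin-hypercube sampling over the documented parameter
ranges; the default response is the basic offspring number N0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .params import ModelParams, derive_baseline_params
from .threshold import offspring_number_closed_form

__all__ = [
    "ParameterRanges",
    "PRCCResult",
    "default_ranges",
    "lhs_sample",
    "prcc",
    "prcc_offspring_number",
]


@dataclass(frozen=True)
class ParameterRanges:
    """(low, high) sampling windows plus fixed values for the rest.

    ``assumed`` names parameters whose window is not documented and was
    assigned as +/-20% of baseline.
    """

    ranges: dict
    fixed: dict = field(default_factory=dict)
    assumed: tuple = ()

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")

    @property
    def names(self) -> list:
        return list(self.ranges)


def default_ranges() -> ParameterRanges:
    """Documented sampling windows for the model parameters.

    psi, mu_h and mu_b have no documented range and get +/-20% of their
    baseline values (flagged in ``assumed``); theta spans its full [0, 1]
    support (open slightly to keep both phases present).
    """
    base = derive_baseline_params()
    pm20 = lambda v: (0.8 * v, 1.2 * v)
    return ParameterRanges(
        ranges={
            "phi": (0.933, 4.44),
            "psi": pm20(base.psi),
            "eta": (0.302, 0.501),
            "K": (16000.0, 80000.0),
            "sigma": (0.0154, 0.1),
            "mu_e": (0.05, 0.65),
            "theta": (0.01, 0.99),
            "gamma_h": (0.0208, 0.0333),
            "gamma_b": (0.0175, 0.04),
            "mu_h": pm20(base.mu_h),
            "mu_b": pm20(base.mu_b),
            "mu_s": (0.0067, 0.0111),
            "mu_g": (0.0067, 0.0111),
            "beta_1": (0.125, 0.25),
            "beta_2": (0.125, 0.25),
        },
        fixed={},
        assumed=("psi", "mu_h", "mu_b"),
    )


def lhs_sample(ranges: ParameterRanges, n: int, seed: int) -> pd.DataFrame:
    """Latin-hypercube draws: one value per equal-probability bin per
    parameter, bins independently permuted across parameters."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    names = ranges.names
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    lo = np.array([ranges.ranges[k][0] for k in names])
    hi = np.array([ranges.ranges[k][1] for k in names])
    return pd.DataFrame(qmc.scale(unit, lo, hi), columns=names)


@dataclass(frozen=True)
class PRCCResult:
    """Per-parameter partial rank correlation coefficients."""

    coefficients: pd.Series
    n: int
    output_name: str
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.coefficients.index,
            "prcc": self.coefficients.values,
            "n": self.n,
        })


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y against [1, X] by least squares."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise ValueError("rank-deficient regressor matrix: degenerate design")
    return y - A @ coef


def prcc(draws: pd.DataFrame, outputs, output_name: str = "N0",
         seed: int | None = None) -> PRCCResult:
    """PRCC of each parameter column against the output vector.

    Ranks use average tie handling. Requires at least 3 more rows than
    parameters so the partial regressions are overdetermined.
    """
    y = np.asarray(outputs, dtype=float)
    if len(y) != len(draws):
        raise ValueError("outputs length must match number of draws")
    k = draws.shape[1]
    if len(y) < k + 3:
        raise ValueError(f"need at least {k + 3} rows for {k} parameters")
    ranks = np.column_stack([rankdata(draws[c]) for c in draws.columns])
    yr = rankdata(y)
    coeffs = {}
    for j, name in enumerate(draws.columns):
        others = np.delete(ranks, j, axis=1)
        rx = _residualize(ranks[:, j], others)
        ry = _residualize(yr, others)
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        coeffs[name] = float(np.dot(rx, ry) / denom) if denom > 0 else 0.0
    return PRCCResult(coefficients=pd.Series(coeffs), n=len(y),
                      output_name=output_name, seed=seed)


def prcc_offspring_number(n: int = 1000, seed: int = 0,
                          ranges: ParameterRanges | None = None) -> PRCCResult:
    """PRCC of the basic offspring number N0 over the default parameter
    windows (or ``ranges``)."""
    ranges = ranges or default_ranges()
    draws = lhs_sample(ranges, n, seed)
    base = derive_baseline_params().to_dict()
    outputs = np.empty(n)
    for i, row in enumerate(draws.itertuples(index=False)):
        p = dict(base)
        p.update(row._asdict())
        p.update(ranges.fixed)
        outputs[i] = offspring_number_closed_form(ModelParams(**p)).N0
    return prcc(draws, outputs, output_name="N0", seed=seed)
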