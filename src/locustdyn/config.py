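"""Run-configuration parsing and validation (YAML key-value documents).

A run configuration names an experiment and optionally overrides constant
parameters, thermal response curves, the temperature forcing, solver
settings and initial states. Unknown keys are rejected; all defaults are
resolved so a parsed specification is complete and can be re-serialized
and re-parsed to an identical specification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .forcing import TemperatureForcing
from .params import ModelParams, derive_baseline_params

__all__ = ["RunSpec", "parse_config", "parse_config_dict", "serialize_spec"]

_EXPERIMENTS = (
    "threshold", "simulate", "periodic_threshold", "prcc",
    "extinction", "persistence",
    "seasonal_fecundity", "seasonal_hatching", "seasonal_hopper_development", "seasonal_band_development",
)

_TOP_KEYS = {"experiment", "params", "thermal", "forcing", "solver", "initial", "seed", "n_samples"}
_FORCING_KEYS = {"T0", "T1", "omega", "kappa", "variant"}
_SOLVER_KEYS = {"rtol", "atol", "t_end", "n_points", "method"}

_SOLVER_DEFAULTS = {"rtol": 1e-8, "atol": 1e-10, "t_end": 2000.0, "n_points": 501,
                    "method": "RK45"}


@dataclass(frozen=True)
class RunSpec:
    """A fully validated run specification with all defaults resolved."""

    experiment: str
    params: ModelParams
    thermal: dict | None
    forcing: TemperatureForcing | None
    solver: dict
    initial: tuple
    seed: int | None
    n_samples: int


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"config key {name!r}: value {value} outside [{lo}, {hi}]")


def parse_config_dict(doc: dict) -> RunSpec:
    """Validate a configuration mapping into a :class:`RunSpec`."""
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}; "
                         f"expected a subset of {sorted(_TOP_KEYS)}")
    experiment = doc.get("experiment", "threshold")
    if experiment not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; expected one of {_EXPERIMENTS}")

    overrides = dict(doc.get("params") or {})
    base = derive_baseline_params().to_dict()
    unknown = set(overrides) - set(base)
    if unknown:
        raise ValueError(f"unknown model parameters: {sorted(unknown)}")
    for name in ("psi", "eta", "theta"):
        if name in overrides:
            _check_range(f"params.{name}", float(overrides[name]), 0.0, 1.0)
    base.update({k: float(v) for k, v in overrides.items()})
    params = ModelParams(**base)

    thermal = doc.get("thermal")
    if thermal is not None:
        if not isinstance(thermal, dict):
            raise ValueError("'thermal' must be a mapping of rate symbols to curve blocks")
        from .responses import build_thermal_param_set
        build_thermal_param_set(thermal)  # validate eagerly; rebuilt lazily by drivers
        thermal = dict(thermal)

    forcing_doc = doc.get("forcing")
    forcing = None
    if forcing_doc is not None:
        unknown = set(forcing_doc) - _FORCING_KEYS
        if unknown:
            raise ValueError(f"unknown forcing keys: {sorted(unknown)}")
        forcing = TemperatureForcing(
            T0=float(forcing_doc.get("T0", 30.0)),
            T1=float(forcing_doc.get("T1", 0.0)),
            omega=float(forcing_doc.get("omega", 1.0)),
            kappa=float(forcing_doc.get("kappa", 0.0)),
            variant=str(forcing_doc.get("variant", "multiplicative")),
        )
    if thermal is not None and forcing is None:
        forcing = TemperatureForcing(T0=30.0)

    solver_doc = dict(doc.get("solver") or {})
    unknown = set(solver_doc) - _SOLVER_KEYS
    if unknown:
        raise ValueError(f"unknown solver keys: {sorted(unknown)}")
    solver = dict(_SOLVER_DEFAULTS)
    solver.update(solver_doc)
    solver["rtol"] = float(solver["rtol"])
    solver["atol"] = float(solver["atol"])
    solver["t_end"] = float(solver["t_end"])
    solver["n_points"] = int(solver["n_points"])
    if solver["t_end"] <= 0:
        raise ValueError("solver.t_end must be positive")

    initial = doc.get("initial")
    if initial is None:
        # spread-out positive initial states as fractions of K
        fracs = (0.001, 0.01, 0.1)
        initial = tuple(
            {"E": f * params.K, "H": 0.2 * f * params.K, "B": 0.2 * f * params.K,
             "S": 0.05 * f * params.K, "G": 0.05 * f * params.K}
            for f in fracs
        )
    else:
        states = []
        for entry in initial:
            unknown = set(entry) - {"E", "H", "B", "S", "G"}
            if unknown:
                raise ValueError(f"unknown state components: {sorted(unknown)}")
            states.append({k: float(entry.get(k, 0.0)) for k in ("E", "H", "B", "S", "G")})
        initial = tuple(states)

    seed = doc.get("seed")
    if seed is not None:
        seed = int(seed)
    n_samples = int(doc.get("n_samples", 1000))
    return RunSpec(experiment=experiment, params=params, thermal=thermal,
                   forcing=forcing, solver=solver, initial=initial,
                   seed=seed, n_samples=n_samples)


def parse_config(path) -> RunSpec:
    """Parse and validate a YAML run-configuration file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return parse_config_dict(doc)


def serialize_spec(spec: RunSpec) -> dict:
    """Round-trippable plain mapping for a :class:`RunSpec`."""
    doc = {
        "experiment": spec.experiment,
        "params": spec.params.to_dict(),
        "solver": dict(spec.solver),
        "initial": [dict(s) for s in spec.initial],
        "n_samples": spec.n_samples,
    }
    if spec.thermal is not None:
        doc["thermal"] = spec.thermal
    if spec.forcing is not None:
        doc["forcing"] = {k: getattr(spec.forcing, k) for k in
                          ("T0", "T1", "omega", "kappa", "variant")}
    if spec.seed is not None:
        doc["seed"] = spec.seed
    return doc
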