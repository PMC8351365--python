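"""Scenario configuration: plain-text (YAML) input for the CLI.

A scenario file has a flat block of economic parameters, a distribution
block naming a built-in family, the physician count and an optional
simulation block::

    parameters:
      B: 10.0
      l: 2.0
      p_a: 0.7
      r: 0.3
      a_bar: 0.4
    distribution:
      family: uniform          # uniform | triangular | beta
    N: 100
    simulation:                # optional
      n_patients: 20000
      n_draws: 400
      seed: 7

Unknown keys anywhere are rejected; every component invariant is enforced
at load time, before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .distributions import (
    UncertaintyDistribution,
    scaled_beta_uncertainty,
    triangular_uncertainty,
    uniform_uncertainty,
)
from .params import EconomicParameters, ParameterError

__all__ = ["ConfigError", "ScenarioConfig", "load_scenario"]


class ConfigError(ValueError):
    """Malformed or invalid scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    params: EconomicParameters
    dist: UncertaintyDistribution
    N: int
    n_patients: Optional[int] = None
    n_draws: Optional[int] = None
    seed: Optional[int] = None

    @property
    def has_simulation(self) -> bool:
        return self.n_patients is not None


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_scenario(path) -> ScenarioConfig:
    """Load and fully validate a scenario file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of blocks")
    _check_keys(raw, {"parameters", "distribution", "N", "simulation"}, "config")
    for block in ("parameters", "distribution", "N"):
        if block not in raw:
            raise ConfigError(f"missing required block: {block}")

    pblock = raw["parameters"]
    if not isinstance(pblock, dict):
        raise ConfigError("parameters must be a mapping")
    _check_keys(pblock, {"B", "l", "p_a", "r", "a_bar"}, "parameters")
    try:
        params = EconomicParameters(
            B=float(pblock["B"]),
            l=float(pblock["l"]),
            p_a=float(pblock["p_a"]),
            r=float(pblock["r"]),
            a_bar=float(pblock["a_bar"]),
        )
    except KeyError as exc:
        raise ConfigError(f"missing parameter: {exc.args[0]}") from exc
    except ParameterError as exc:
        raise ConfigError(f"invalid parameters: {exc}") from exc

    dblock = raw["distribution"]
    if not isinstance(dblock, dict) or "family" not in dblock:
        raise ConfigError("distribution must be a mapping with a 'family' key")
    family = dblock["family"]
    if family == "uniform":
        _check_keys(dblock, {"family"}, "distribution")
        dist = uniform_uncertainty(params.b_max)
    elif family == "triangular":
        _check_keys(dblock, {"family"}, "distribution")
        dist = triangular_uncertainty(params.b_max)
    elif family == "beta":
        _check_keys(dblock, {"family", "alpha", "beta"}, "distribution")
        try:
            dist = scaled_beta_uncertainty(
                params.b_max, float(dblock["alpha"]), float(dblock["beta"])
            )
        except KeyError as exc:
            raise ConfigError(
                f"beta distribution requires shape parameter: {exc.args[0]}"
            ) from exc
    else:
        raise ConfigError(
            f"unknown distribution family: {family!r} "
            "(expected uniform, triangular or beta)"
        )

    N = raw["N"]
    if not isinstance(N, int) or N < 1:
        raise ConfigError("N must be a positive integer")

    sim = {"n_patients": None, "n_draws": None, "seed": None}
    if "simulation" in raw and raw["simulation"] is not None:
        sblock = raw["simulation"]
        if not isinstance(sblock, dict):
            raise ConfigError("simulation must be a mapping")
        _check_keys(sblock, {"n_patients", "n_draws", "seed"}, "simulation")
        sim["n_patients"] = int(sblock.get("n_patients", 10_000))
        sim["n_draws"] = int(sblock.get("n_draws", 200))
        sim["seed"] = int(sblock.get("seed", 0))
        if sim["n_patients"] < 1 or sim["n_draws"] < 1:
            raise ConfigError("simulation sizes must be positive")

    return ScenarioConfig(params=params, dist=dist, N=N, **sim)
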