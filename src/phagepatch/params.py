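"""Metapopulation parameter set, validation, and config-file round-tripping.

All rates are per hour; resources are in units of host-cell yield (one unit
of resource is consumed per host division).  Config files (YAML or JSON) may
use either the short symbol names used throughout the code (``lam_p``) or
spelled-out aliases (``phage_decay_rate``); unknown keys are rejected so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["MetapopParams", "ConfigError", "load_params", "dump_params"]


class ConfigError(ValueError):
    """Raised for malformed or invalid parameter configuration."""


@dataclass(frozen=True)
class MetapopParams:
    """Parameters of the patch-metapopulation simulation.

    Fixed defaults (``Y``, ``K``, ``d``, ``k``, ``sigma``, ``beta``,
    ``F_A``) are the reference values of the model; the remaining rates are
    the ones varied across parameter sets, and their defaults here are a
    representative stable-coexistence configuration (see
    :mod:`phagepatch.fixtures`).

    Attributes
    ----------
    Y : float
        Resource endowment per patch, in host-yield units.
    v : float
        Host arrival-rate coefficient: each patch receives hosts of a type
        at rate ``v`` times that type's abundance in the medium (per hour).
    r_A, r_B : float
        Maximum host division rates; realized growth is Michaelis–Menten
        in the remaining resource with half-saturation ``K``.
    K : float
        Half-saturation constant for host growth (resource units).
    d : float
        Host detachment-rate coefficient (per hour); the per-capita
        detachment rate is ``d * k / (k + x)``, rising as resource ``x``
        runs out, with half-saturation ``k``.
    k : float
        Half-saturation constant for detachment (resource units).
    sigma : float
        Per-capita resource decay rate (per hour).
    phi : float
        Phage arrival-rate coefficient (per hour per medium phage).
    alpha : float
        Per-capita rate at which phage leave a patch (per hour).
    lam_p, lam_h : float
        Per-capita decay rates of phage and hosts (per hour).
    theta : float
        Infection-rate coefficient (per hour per phage per host).
    chi : int
        Cycles between scheduled patch additions.
    beta : float
        Burst rate of infected cells inside a patch (per hour); the default
        is effectively zero on patch timescales, so most lysis happens when
        infected cells detach or their patch is culled.
    F_A, F_B : float
        Mean fecundities (Poisson burst-size means) on hosts A and B.
    cycle_length : float
        Duration of one simulation cycle in hours (default 20 min).
    """

    Y: float = 200.0
    v: float = 1e-4
    r_A: float = 0.3
    r_B: float = 0.3
    K: float = 40.0
    d: float = 0.00167
    k: float = 10.0
    sigma: float = 8.33e-6
    phi: float = 1e-4
    alpha: float = 0.02
    lam_p: float = 0.002
    lam_h: float = 2e-4
    theta: float = 0.002
    chi: int = 60
    beta: float = 8.33e-6
    F_A: float = 50.0
    F_B: float = 10.0
    cycle_length: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in (
            "Y", "v", "r_A", "r_B", "K", "d", "k", "sigma", "phi",
            "alpha", "lam_p", "lam_h", "theta", "beta", "F_A", "F_B",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ConfigError(f"parameter {name!r} must be >= 0, got {value}")
        if self.Y < 1:
            raise ConfigError("Y must be >= 1")
        if self.chi < 1 or int(self.chi) != self.chi:
            raise ConfigError("chi must be a positive integer number of cycles")
        if self.cycle_length <= 0:
            raise ConfigError("cycle_length must be positive")

    def replace(self, **kwargs) -> "MetapopParams":
        return dataclasses.replace(self, **kwargs)

    def to_array(self) -> np.ndarray:
        """Pack parameters into the float64 layout the kernels expect."""
        return np.array(
            [
                self.Y, self.v, self.r_A, self.r_B, self.K, self.d,
                self.k, self.sigma, self.phi, self.alpha, self.lam_p,
                self.lam_h, self.theta, float(self.chi), self.beta,
                self.F_A, self.F_B, self.cycle_length,
            ],
            dtype=np.float64,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# spelled-out aliases accepted in config files, mapped to field names
_ALIASES = {
    "resource_abundance": "Y",
    "host_arrival_rate": "v",
    "host_a_division_rate": "r_A",
    "host_b_division_rate": "r_B",
    "growth_half_saturation": "K",
    "detachment_rate": "d",
    "detachment_half_saturation": "k",
    "resource_decay_rate": "sigma",
    "phage_arrival_rate": "phi",
    "phage_exit_rate": "alpha",
    "phage_decay_rate": "lam_p",
    "host_decay_rate": "lam_h",
    "infection_rate": "theta",
    "patch_addition_period": "chi",
    "burst_rate": "beta",
    "fecundity_a": "F_A",
    "fecundity_b": "F_B",
    "cycle_length": "cycle_length",
}

_FIELDS = {f.name for f in dataclasses.fields(MetapopParams)}


def _normalize_keys(raw: dict) -> dict:
    out = {}
    for key, value in raw.items():
        name = _ALIASES.get(key, key)
        if name not in _FIELDS:
            raise ConfigError(f"unknown parameter {key!r} in config")
        if name in out:
            raise ConfigError(f"parameter {key!r} given more than once")
        out[name] = value
    return out


def load_params(path: str | Path) -> MetapopParams:
    """Parse a YAML or JSON config into a validated parameter set.

    Missing keys take the package defaults; unknown keys are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text) if text.strip() else {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping of parameters")
    try:
        return MetapopParams(**_normalize_keys(raw))
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def dump_params(params: MetapopParams, path: str | Path) -> None:
    """Write a parameter set to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
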