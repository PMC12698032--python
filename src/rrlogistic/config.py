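"""Structured configuration for simulation runs.

A run is fully specified by a nested mapping (YAML on disk) with sections
``domain``, ``demography``, ``kernel``, ``dispersal``, ``movement`` and
``sim``.  Validation is strict: unknown keys or inconsistent movement
triples are rejected before any stepping happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .geometry_kernels import DispersalSpec, Domain, KernelSpec
from .movement import MovementParams

__all__ = ["DemographyParams", "SimConfig", "load_config"]


@dataclass(frozen=True)
class DemographyParams:
    """Demographic rates: constant birth b, baseline death d0 and the
    competition strength gamma multiplying the kernel-weighted neighbour sum."""

    b: float
    d0: float
    gamma: float
    kernel: KernelSpec
    dispersal: DispersalSpec

    def __post_init__(self) -> None:
        if self.b < 0 or self.d0 < 0 or self.gamma < 0:
            raise ValueError("rates b, d0, gamma must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to run one realisation of the model."""

    domain: Domain
    demography: DemographyParams
    movement: MovementParams
    n0: int = 700
    events: int = 1_000_000
    seed: int | None = None
    burn_in: float = 0.5
    replicates: int = 1
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("initial population size must be >= 0")
        if self.events < 0:
            raise ValueError("event budget must be >= 0")
        if not 0.0 <= self.burn_in < 1.0:
            raise ValueError("burn_in fraction must lie in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        mv: dict[str, Any] = {"mode": self.movement.mode}
        if self.movement.mode == "OU":
            mv["tau"] = self.movement.tau
            mv["sigma_r2"] = self.movement.sigma_r2
        elif self.movement.mode == "BM":
            mv["D"] = self.movement.D
        disp: dict[str, Any] = {
            "family": self.demography.dispersal.family,
            "sigma_d": self.demography.dispersal.sigma_d,
        }
        if self.demography.dispersal.family == "gamma_distance":
            disp["shape"] = self.demography.dispersal.shape
        return {
            "domain": {"L": self.domain.L},
            "demography": {
                "b": self.demography.b,
                "d0": self.demography.d0,
                "gamma": self.demography.gamma,
            },
            "kernel": {
                "family": self.demography.kernel.family,
                "sigma_q": self.demography.kernel.sigma_q,
                "trunc_mult": self.demography.kernel.trunc_mult,
            },
            "dispersal": disp,
            "movement": mv,
            "sim": {
                "n0": self.n0,
                "events": self.events,
                "seed": self.seed,
                "burn_in": self.burn_in,
                "replicates": self.replicates,
                "record_stride": self.record_stride,
            },
        }


def _section(data: Mapping[str, Any], name: str, allowed: set[str], required: bool = True) -> dict:
    sec = data.get(name)
    if sec is None:
        if required:
            raise ValueError(f"config missing required section {name!r}")
        return {}
    if not isinstance(sec, Mapping):
        raise ValueError(f"config section {name!r} must be a mapping")
    unknown = set(sec) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    return dict(sec)


def config_from_dict(data: Mapping[str, Any]) -> SimConfig:
    unknown = set(data) - {"domain", "demography", "kernel", "dispersal", "movement", "sim"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    dom = _section(data, "domain", {"L", "periodic"}, required=False)
    demo = _section(data, "demography", {"b", "d0", "gamma"})
    kern = _section(data, "kernel", {"family", "sigma_q", "trunc_mult"})
    disp = _section(data, "dispersal", {"family", "sigma_d", "shape"})
    mv = _section(data, "movement", {"mode", "tau", "sigma_r2", "D"})
    sim = _section(
        data, "sim",
        {"n0", "events", "seed", "burn_in", "replicates", "record_stride"},
        required=False,
    )

    domain = Domain(L=float(dom.get("L", 1.0)), periodic=bool(dom.get("periodic", True)))
    kernel = KernelSpec(
        sigma_q=float(kern["sigma_q"]),
        trunc_mult=float(kern.get("trunc_mult", 2.45)),
        family=kern.get("family", "gaussian"),
    )
    dkw: dict[str, Any] = {
        "sigma_d": float(disp["sigma_d"]),
        "family": disp.get("family", "gaussian"),
    }
    if "shape" in disp:
        dkw["shape"] = float(disp["shape"])
    dispersal = DispersalSpec(**dkw)
    demography = DemographyParams(
        b=float(demo["b"]), d0=float(demo["d0"]), gamma=float(demo["gamma"]),
        kernel=kernel, dispersal=dispersal,
    )
    mkw: dict[str, Any] = {"mode": str(mv["mode"])}
    for key in ("tau", "sigma_r2", "D"):
        if mv.get(key) is not None:
            mkw[key] = float(mv[key])
    movement = MovementParams(**mkw)
    seed = sim.get("seed")
    return SimConfig(
        domain=domain,
        demography=demography,
        movement=movement,
        n0=int(sim.get("n0", 700)),
        events=int(sim.get("events", 1_000_000)),
        seed=None if seed is None else int(seed),
        burn_in=float(sim.get("burn_in", 0.5)),
        replicates=int(sim.get("replicates", 1)),
        record_stride=int(sim.get("record_stride", 1)),
    )


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)
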