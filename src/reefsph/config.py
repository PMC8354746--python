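"""Run configuration: structured YAML in, validated dataclasses out.

A run configuration mirrors the simulator's building blocks — domain
geometry, fluid constants, kernel ratio, ecological rules, stepping and
output options.  Loading fills documented defaults, rejects unknown
keys, and surfaces invariant violations with the offending key named.
Every output file records the configuration hash so runs are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .domain import DomainSpec
from .goldilocks import GoldilocksConfig
from .kernel import KernelSpec
from .solver import FluidProperties

__all__ = ["KernelConfig", "StepConfig", "OutputConfig", "RunConfig",
           "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class KernelConfig:
    h_over_dx: float = 1.3    # smoothing length as a multiple of dx

    def __post_init__(self) -> None:
        if self.h_over_dx <= 0:
            raise ValueError("h_over_dx must be positive")


@dataclass(frozen=True)
class StepConfig:
    cfl_coeff: float = 0.25
    n_euler: int = 50         # Euler-corrector cadence of the Verlet scheme
    smooth_every: int = 1     # density-smoothing cadence, steps

    def __post_init__(self) -> None:
        if not (0 < self.cfl_coeff <= 1):
            raise ValueError("cfl_coeff must lie in (0, 1]")
        if self.n_euler < 1 or self.smooth_every < 1:
            raise ValueError("n_euler and smooth_every must be >= 1")


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "out"
    snapshot_steps: Tuple[int, ...] = ()
    vtk: bool = False


@dataclass(frozen=True)
class RunConfig:
    domain: DomainSpec = field(default_factory=DomainSpec)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    goldilocks: GoldilocksConfig = field(default_factory=GoldilocksConfig)
    step: StepConfig = field(default_factory=StepConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0             # reserved for optional lattice jitter

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(self.kernel.h_over_dx * self.domain.dx)

    @property
    def hash(self) -> str:
        return config_hash(self)


_TUPLE_KEYS = {"body_force", "snapshot_steps"}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"{path or 'config'}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_KEYS and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path or 'config'}: {exc}") from exc


_SECTIONS = {
    "domain": DomainSpec, "fluid": FluidProperties, "kernel": KernelConfig,
    "goldilocks": GoldilocksConfig, "step": StepConfig, "output": OutputConfig,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing sections and keys take their documented defaults; unknown
    keys anywhere are rejected with the key named.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"config: unknown section(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name], name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)


def _as_plain(obj):
    d = dataclasses.asdict(obj)

    def conv(v):
        if isinstance(v, tuple):
            return [conv(x) for x in v]
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        return v

    return conv(d)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_plain(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Deterministic short hash of the full configuration."""
    blob = json.dumps(_as_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
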