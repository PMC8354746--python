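"""Growth-scenario geometry and boundary conditions.

The scenario domain is a rectangular water column over a flat seabed:
fluid particles fill the interior on a regular lattice, static wall
particles form the seabed below y = 0 and a ceiling above y = height,
and an optional half-disc of live-coral particles (the "seed" colony)
sits proud of the seabed at the domain midpoint.

Flow is driven by a parabolic inlet profile on the left (zero at the
seabed, peak at the top) and a fast lid current along the upper
boundary.  The outlet on the right recycles outflowing fluid particles
back to the inlet with the inlet-profile velocity, so the total particle
count never changes; neighbour queries treat x as periodic to keep
kernel support full across the seam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kernel import KernelSpec
from .particles import ParticleSystem, Phase
from .solver import FluidProperties, VerletIntegrator

__all__ = ["DomainSpec", "build_domain", "apply_boundary_conditions", "inlet_profile"]


@dataclass(frozen=True)
class DomainSpec:
    """Geometry and forcing of the growth-scenario domain.

    Defaults give the full-scale scenario: a 10 x 5 m^2 water column at
    particle spacing 0.05 m (exactly 20 000 fluid particles) with a
    50 cm/s upper-boundary current.  ``seed_radius = 0`` builds a plain
    channel; growth scenarios set it explicitly (0.25 m at full scale).
    """

    width: float = 10.0
    height: float = 5.0
    dx: float = 0.05
    wall_layers: int = 3
    lid_speed: float = 0.5          # m/s along the upper boundary
    inlet_peak: Optional[float] = None  # parabola peak; defaults to lid_speed
    seed_radius: float = 0.0        # half-disc radius of the coral seed, m
    inlet_rows: int = 3             # inlet band thickness in particle rows
    lid_rows: int = 3               # prescribed lid band thickness in rows
    init_profile: bool = False      # start fluid on the parabolic profile

    def __post_init__(self) -> None:
        for name in ("width", "height", "dx"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("width", "height"):
            ratio = getattr(self, name) / self.dx
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of dx")
        if self.lid_speed <= 0:
            raise ValueError("lid_speed must be positive")
        if self.wall_layers < 1:
            raise ValueError("wall_layers must be >= 1")
        if 0.0 < self.seed_radius < self.dx:
            raise ValueError("seed_radius smaller than dx: seed must contain at least one particle")

    @property
    def peak(self) -> float:
        return self.lid_speed if self.inlet_peak is None else self.inlet_peak

    @property
    def nx(self) -> int:
        return round(self.width / self.dx)

    @property
    def ny(self) -> int:
        return round(self.height / self.dx)


def inlet_profile(y, spec: DomainSpec):
    """Parabolic inlet speed: zero at the seabed, peak at the top.

    u(y) = peak * (y/H) * (2 - y/H) on [0, H]; the vertex sits at the
    upper boundary so the profile blends into the lid current.
    """
    yn = np.clip(np.asarray(y, dtype=float) / spec.height, 0.0, 1.0)
    return spec.peak * yn * (2.0 - yn)


def seed_site_mask(xs: np.ndarray, ys: np.ndarray, spec: DomainSpec) -> np.ndarray:
    """Lattice sites inside the half-disc coral seed (centred on the
    seabed midpoint, bulging into the flow)."""
    if spec.seed_radius <= 0:
        return np.zeros(xs.shape, dtype=bool)
    cx = 0.5 * spec.width
    return (ys > 0) & ((xs - cx) ** 2 + ys**2 <= spec.seed_radius**2)


def build_domain(spec: DomainSpec, fluid: FluidProperties,
                 kernel: Optional[KernelSpec] = None) -> ParticleSystem:
    """Assemble the particle system: fluid lattice, seabed/ceiling walls,
    coral seed.

    Every interior lattice site becomes one particle: FLUID outside the
    seed half-disc, LIVE_CORAL inside it.  Each particle carries mass
    ``rho0 * dx**2`` and starts at the reference density.
    """
    dx = spec.dx
    if kernel is not None:
        need = math.ceil(kernel.support_radius / dx)
        if spec.wall_layers < need:
            raise ValueError(
                f"wall_layers={spec.wall_layers} thinner than kernel support ({need} rows)")

    ix, iy = np.meshgrid(np.arange(spec.nx), np.arange(spec.ny), indexing="ij")
    fx = (ix.ravel() + 0.5) * dx
    fy = (iy.ravel() + 0.5) * dx
    seed = seed_site_mask(fx, fy, spec)

    wx, wk = np.meshgrid(np.arange(spec.nx), np.arange(spec.wall_layers), indexing="ij")
    bed_x = (wx.ravel() + 0.5) * dx
    bed_y = -(wk.ravel() + 0.5) * dx
    ceil_x = bed_x.copy()
    ceil_y = spec.height + (wk.ravel() + 0.5) * dx

    xs = np.concatenate([fx, bed_x, ceil_x])
    ys = np.concatenate([fy, bed_y, ceil_y])
    n_int, n_bed = fx.size, bed_x.size
    n = xs.size

    phase = np.full(n, int(Phase.WALL), dtype=np.int8)
    phase[:n_int] = int(Phase.FLUID)
    phase[:n_int][seed] = int(Phase.LIVE_CORAL)

    v = np.zeros((n, 2))
    if spec.init_profile:
        fluid_rows = np.flatnonzero(phase[:n_int] == int(Phase.FLUID))
        v[fluid_rows, 0] = inlet_profile(fy[fluid_rows], spec)
    # ceiling wall carries the lid current in the SPH sums (prescribed,
    # positions fixed)
    v[n_int + n_bed:, 0] = spec.lid_speed

    system = ParticleSystem(
        x=np.column_stack([xs, ys]),
        v=v,
        rho=np.full(n, fluid.rho0),
        p=np.zeros(n),
        m=np.full(n, fluid.rho0 * dx * dx),
        phase=phase,
        streak=np.zeros(n, dtype=np.int32),
        dx=dx,
        bounds=(0.0, spec.width, 0.0, spec.height),
        period_x=spec.width,
    )
    return system


def apply_boundary_conditions(system: ParticleSystem, spec: DomainSpec,
                              t: float = 0.0,
                              integrator: Optional[VerletIntegrator] = None) -> None:
    """Recycle outflow and prescribe band velocities, in place.

    Fluid particles leaving through the outlet (x >= width) re-enter at
    the inlet with the inlet-profile velocity and their current density;
    fluid in the inlet band carries the parabolic profile, fluid in the
    lid band the lid current.  Wall and coral velocities stay fixed.
    With ``inlet_rows=0`` the channel is purely periodic: recycled
    particles keep their own velocity and only the lid band is forced.
    """
    fm = system.fluid_mask
    x = system.x

    # recycle through the periodic seam
    out = fm & ((x[:, 0] >= spec.width) | (x[:, 0] < 0.0))
    if np.any(out):
        x[out, 0] = np.mod(x[out, 0], spec.width)
        if spec.inlet_rows > 0:
            system.v[out, 0] = inlet_profile(x[out, 1], spec)
            system.v[out, 1] = 0.0

    inlet_band = fm & (x[:, 0] < spec.inlet_rows * spec.dx)
    system.v[inlet_band, 0] = inlet_profile(x[inlet_band, 1], spec)
    system.v[inlet_band, 1] = 0.0

    lid_band = fm & (x[:, 1] >= spec.height - spec.lid_rows * spec.dx)
    system.v[lid_band, 0] = spec.lid_speed
    system.v[lid_band, 1] = 0.0

    # solid phases never move
    bmask = system.mask(Phase.LIVE_CORAL, Phase.DEAD_CORAL)
    system.v[bmask] = 0.0

    if integrator is not None:
        prescribed = np.flatnonzero(out | inlet_band | lid_band | bmask)
        integrator.sync_prescribed(prescribed, system)
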