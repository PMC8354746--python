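"""Analytic validation cases and frozen rule fixtures.

The solver's accuracy is checked against closed-form laminar solutions —
a body-force-driven plane channel (Poiseuille) and a hydrostatic tank —
which exercise the continuity/momentum discretisation, the equation of
state, and the boundary treatment at desk scale.  The ecological rules
are exercised on a small hand-laid particle arrangement whose expected
outcomes come from an independent plain-loop rule oracle, so growth and
death are testable without running a full reef scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .goldilocks import GoldilocksConfig, _SolverLoop
from .kernel import KernelSpec
from .particles import ParticleSystem, Phase
from .solver import FluidProperties, tait_pressure

__all__ = [
    "AnalyticCase", "FrozenFlowFixture", "build_channel", "build_tank",
    "poiseuille_case", "hydrostatic_case", "frozen_growth_fixture",
    "rule_eval_oracle", "reduced_scenario", "run_reduced_scenario",
]


@dataclass
class AnalyticCase:
    """A validation case with a closed-form reference solution."""

    name: str
    params: Dict[str, float]
    analytic: Callable
    error: float                 # relative error in the stated norm
    tolerance: float
    profile: Optional[pd.DataFrame] = None
    extra: Dict[str, float] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.error <= self.tolerance


# ---------------------------------------------------------------------------
# Geometry builders for validation runs
# ---------------------------------------------------------------------------

def _lattice(nx: int, ny: int, dx: float, y0: float = 0.0):
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return (ix.ravel() + 0.5) * dx, y0 + (iy.ravel() + 0.5) * dx


def build_channel(width: float, height: float, dx: float,
                  props: FluidProperties, wall_layers: int = 3) -> ParticleSystem:
    """Periodic-in-x plane channel: static no-slip walls above and below."""
    nx, ny = round(width / dx), round(height / dx)
    fx, fy = _lattice(nx, ny, dx)
    wx, wk = np.meshgrid(np.arange(nx), np.arange(wall_layers), indexing="ij")
    bx = (wx.ravel() + 0.5) * dx
    lo_y = -(wk.ravel() + 0.5) * dx
    hi_y = height + (wk.ravel() + 0.5) * dx
    xs = np.concatenate([fx, bx, bx])
    ys = np.concatenate([fy, lo_y, hi_y])
    n = xs.size
    phase = np.full(n, int(Phase.WALL), dtype=np.int8)
    phase[: fx.size] = int(Phase.FLUID)
    return ParticleSystem(
        x=np.column_stack([xs, ys]), v=np.zeros((n, 2)),
        rho=np.full(n, props.rho0), p=np.zeros(n),
        m=np.full(n, props.rho0 * dx * dx), phase=phase,
        streak=np.zeros(n, dtype=np.int32), dx=dx,
        bounds=(0.0, width, 0.0, height), period_x=width,
    )


def build_tank(width: float, depth: float, dx: float, props: FluidProperties,
               wall_layers: int = 3,
               rho_profile: Optional[Callable] = None) -> ParticleSystem:
    """Closed tank (bottom + side walls, open top), non-periodic."""
    nx, ny = round(width / dx), round(depth / dx)
    fx, fy = _lattice(nx, ny, dx)
    # bottom
    bx, bk = np.meshgrid(np.arange(-wall_layers, nx + wall_layers),
                         np.arange(wall_layers), indexing="ij")
    bot_x = (bx.ravel() + 0.5) * dx
    bot_y = -(bk.ravel() + 0.5) * dx
    # sides (full fluid height plus headroom)
    sy, sk = np.meshgrid(np.arange(ny + wall_layers), np.arange(wall_layers),
                         indexing="ij")
    side_y = (sy.ravel() + 0.5) * dx
    left_x = -(sk.ravel() + 0.5) * dx
    right_x = width + (sk.ravel() + 0.5) * dx
    xs = np.concatenate([fx, bot_x, left_x, right_x])
    ys = np.concatenate([fy, bot_y, side_y, side_y])
    n = xs.size
    phase = np.full(n, int(Phase.WALL), dtype=np.int8)
    phase[: fx.size] = int(Phase.FLUID)
    rho = np.full(n, props.rho0)
    if rho_profile is not None:
        rho = rho_profile(ys)
    return ParticleSystem(
        x=np.column_stack([xs, ys]), v=np.zeros((n, 2)),
        rho=rho, p=np.zeros(n),
        m=np.full(n, props.rho0 * dx * dx), phase=phase,
        streak=np.zeros(n, dtype=np.int32), dx=dx,
        bounds=(0.0, width, 0.0, depth), period_x=None,
    )


# ---------------------------------------------------------------------------
# Poiseuille channel
# ---------------------------------------------------------------------------

def poiseuille_case(height: float = 0.1, body_force: float = 0.8,
                    props: Optional[FluidProperties] = None,
                    resolution: int = 20, width_rows: int = 16,
                    h_over_dx: float = 1.3, settle_times: float = 4.0,
                    init_profile: bool = False,
                    max_steps: int = 200000) -> AnalyticCase:
    """Body-force-driven laminar channel vs the analytic parabola.

    The steady solution of a plane channel of height ``H`` driven by a
    constant streamwise acceleration ``g`` with no-slip walls is
    ``u(y) = (g / 2 nu) * y * (H - y)`` with peak ``g H^2 / (8 nu)``.
    The numeric profile is the per-row mean streamwise velocity after
    integrating for ``settle_times`` viscous times ``H^2 / nu``.
    Reports the relative L2 error and, in ``extra``, the maximum density
    deviation from the reference (percent).

    ``init_profile`` seeds the fluid with the analytic parabola so large
    cases need only relax to the discrete steady state (about one
    viscous time) instead of spinning up from rest; the error is still
    measured against the analytic solution after integration.
    """
    if props is None:
        # low-Reynolds regime: peak 0.1 m/s, Re = 1
        props = FluidProperties(rho0=1000.0, mu=10.0, cs=1.0, epsilon=0.01)
    g = body_force
    props = FluidProperties(rho0=props.rho0, mu=props.mu, cs=props.cs,
                            gamma=props.gamma, epsilon=props.epsilon,
                            body_force=(props.rho0 * g, 0.0))
    nu = props.nu
    dx = height / resolution
    width = width_rows * dx
    system = build_channel(width, height, dx, props)
    kernel = KernelSpec(h_over_dx * dx)
    # cadence-1 corrector: the leapfrog velocity mode is parasitically
    # unstable at the viscous cell Fourier numbers of this stiff regime
    loop = _SolverLoop(system, kernel, props, spec=None, n_euler=1)
    if init_profile:
        fm0 = system.fluid_mask
        y0 = system.x[fm0, 1]
        system.v[fm0, 0] = (g / (2.0 * nu)) * y0 * (height - y0)

    # mirror (ghost) velocities on the wall rows: wall row k carries the
    # negative of fluid row k's mean streamwise velocity, which pins the
    # no-slip plane at the wall surface instead of half a spacing inside
    fm = system.fluid_mask
    wall = ~fm
    frow = np.clip((system.x[fm, 1] / dx - 0.5).round().astype(int), 0, resolution - 1)
    wy = system.x[wall, 1]
    wrow = np.where(wy < 0, (-wy / dx - 0.5).round().astype(int),
                    ((wy - height) / dx - 0.5).round().astype(int))

    def mirror_walls() -> None:
        row_mean = np.zeros(resolution)
        np.add.at(row_mean, frow, system.v[fm, 0])
        counts = np.bincount(frow, minlength=resolution).astype(float)
        row_mean /= np.maximum(counts, 1.0)
        lookup = np.where(wy < 0, row_mean[np.clip(wrow, 0, resolution - 1)],
                          row_mean[np.clip(resolution - 1 - wrow, 0, resolution - 1)])
        system.v[wall, 0] = -lookup

    t_end = settle_times * height**2 / nu
    steps = 0
    while loop.t < t_end and steps < max_steps:
        mirror_walls()
        loop.step()
        steps += 1
    system.v[wall] = 0.0

    fm = system.fluid_mask
    y = system.x[fm, 1]
    vx = system.v[fm, 0]
    edges = np.linspace(0.0, height, resolution + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(y, edges) - 1, 0, resolution - 1)
    u_num = np.array([vx[which == k].mean() if np.any(which == k) else np.nan
                      for k in range(resolution)])

    def u_exact(yy):
        return (g / (2.0 * nu)) * yy * (height - yy)

    u_ana = u_exact(centers)
    ok = np.isfinite(u_num)
    err = float(np.linalg.norm(u_num[ok] - u_ana[ok]) / np.linalg.norm(u_ana[ok]))
    dev = float(np.max(np.abs(system.rho[fm] - props.rho0)) / props.rho0 * 100.0)
    profile = pd.DataFrame({"y": centers, "u_num": u_num, "u_exact": u_ana})
    return AnalyticCase(
        name="poiseuille", analytic=u_exact, error=err, tolerance=0.05,
        params={"height": height, "g": g, "nu": nu, "resolution": resolution,
                "cs": props.cs, "u_peak": g * height**2 / (8 * nu)},
        profile=profile,
        extra={"max_density_deviation_pct": dev,
               "n_particles": int(system.n), "steps": steps},
    )


# ---------------------------------------------------------------------------
# Hydrostatic tank
# ---------------------------------------------------------------------------

def hydrostatic_case(depth: float = 0.2, props: Optional[FluidProperties] = None,
                     gravity: float = 9.81, resolution: int = 10,
                     settle_time: float = 2.0, max_steps: int = 200000) -> AnalyticCase:
    """Water column at rest: settled pressure vs rho0 * g * d.

    The tank is initialised with the Tait-consistent hydrostatic density
    profile and relaxed under gravity with an elevated viscosity; the
    pressure averaged over a thin slab at mid-depth is compared with the
    incompressible hydrostatic value.  ``extra`` reports the surface
    pressure and maximum density deviation from the reference (percent).
    """
    if props is None:
        # cs chosen so g*d/cs^2 <= 1%: density stays weakly compressible.
        # The elevated viscosity damps the free-surface relaxation; at sea
        # water viscosity the surface ringing grows until particles eject.
        props = FluidProperties(rho0=1000.0, mu=50.0, cs=15.0, epsilon=0.01)
    props = FluidProperties(rho0=props.rho0, mu=props.mu, cs=props.cs,
                            gamma=props.gamma, epsilon=props.epsilon,
                            body_force=(0.0, -props.rho0 * gravity))
    dx = depth / resolution
    width = depth  # square tank

    def rho_profile(y):
        head = np.clip(depth - y, 0.0, None)
        return props.rho0 * (1.0 + props.rho0 * gravity * head / props.B) ** (1.0 / props.gamma)

    system = build_tank(width, depth, dx, props, rho_profile=rho_profile)
    kernel = KernelSpec(1.3 * dx)
    loop = _SolverLoop(system, kernel, props, spec=None, n_euler=1)
    steps = 0
    while loop.t < settle_time and steps < max_steps:
        loop.step()
        steps += 1

    fm = system.fluid_mask
    y = system.x[fm, 1]
    p = tait_pressure(system.rho[fm], props)
    d_probe = 0.5 * depth
    slab = np.abs((depth - y) - d_probe) < dx
    p_num = float(np.mean(p[slab]))
    p_exact = props.rho0 * gravity * d_probe
    surface = y > depth - 1.5 * dx
    dev = float(np.max(np.abs(system.rho[fm] - props.rho0)) / props.rho0 * 100.0)
    return AnalyticCase(
        name="hydrostatic",
        analytic=lambda d: props.rho0 * gravity * d,
        error=abs(p_num - p_exact) / p_exact, tolerance=0.10,
        params={"depth": depth, "g": gravity, "cs": props.cs,
                "resolution": resolution},
        extra={"p_mid_num": p_num, "p_mid_exact": p_exact,
               "p_surface": float(np.mean(p[surface])),
               "max_density_deviation_pct": dev, "steps": steps},
    )


# ---------------------------------------------------------------------------
# Reduced-scale habitat-engineering scenario
# ---------------------------------------------------------------------------

def reduced_scenario(death_interval: Optional[int] = None,
                     n_growth_steps: int = 25):
    """Canonical desk-scale growth scenario: (domain, fluid, kernel, rules).

    A 1.2 x 0.6 m lid-driven channel, purely periodic in x, with a 0.1 m
    coral seed on the bed.  The lid current (0.15 m/s) is chosen so the
    optimal feeding band [3, 6] cm/s sits at seed-crest height — the
    scale mapping that preserves the full-scale scenario's ecology in a
    domain small enough for test-budget runs.  The fluid starts on the
    parabolic profile (the viscous spin-up from the lid alone would
    dwarf the run).  The sound speed (3 m/s) keeps the flow weakly
    compressible with a wide margin over every observed speed.
    """
    from .domain import DomainSpec
    spec = DomainSpec(width=1.2, height=0.6, dx=0.025, seed_radius=0.1,
                      lid_speed=0.15, inlet_rows=0, init_profile=True)
    props = FluidProperties(rho0=1000.0, mu=1.0, cs=3.0, epsilon=0.01)
    kernel = KernelSpec(1.3 * spec.dx)
    rules = GoldilocksConfig(settle_steps=150, avg_window=50,
                             n_growth_steps=n_growth_steps,
                             death_interval=death_interval,
                             max_initial_steps=600, steady_window=150)
    return spec, props, kernel, rules


def run_reduced_scenario(death_interval: Optional[int] = None,
                         n_growth_steps: int = 25, **kwargs):
    """Run :func:`reduced_scenario`, snapshotting the final state."""
    from .goldilocks import run_scenario
    spec, props, kernel, rules = reduced_scenario(death_interval, n_growth_steps)
    kwargs.setdefault("snapshot_steps", (n_growth_steps,))
    kwargs.setdefault("n_euler", 10)
    return run_scenario(spec, props, kernel, rules, **kwargs)


# ---------------------------------------------------------------------------
# Frozen growth/death rule fixture
# ---------------------------------------------------------------------------

@dataclass
class FrozenFlowFixture:
    """Hand-laid particle arrangement with oracle-computed expected outcomes."""

    system: ParticleSystem
    mean_speeds: np.ndarray          # per-particle buffered mean speed, m/s
    band: Tuple[float, float]
    proximity_dx: float
    expected_convert: np.ndarray     # fluid indices the oracle says convert

    def as_tables(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        s = self.system
        particles = pd.DataFrame({
            "id": np.arange(s.n), "x": s.x[:, 0], "y": s.x[:, 1],
            "phase": [Phase(int(p)).name for p in s.phase],
            "mean_speed": self.mean_speeds,
        })
        expected = pd.DataFrame({
            "id": np.arange(s.n),
            "converts": np.isin(np.arange(s.n), self.expected_convert),
        })
        return particles, expected


def rule_eval_oracle(positions: np.ndarray, phases: np.ndarray,
                     mean_speeds: np.ndarray, band: Tuple[float, float],
                     proximity: float) -> np.ndarray:
    """Direct plain-loop evaluation of the growth rule.

    Independent of the engine's vectorised/KD-tree path: for every fluid
    particle, scan all coral particles for one within the proximity
    radius, then test the speed band.  Returns converting fluid indices.
    """
    out = []
    coral = [k for k in range(len(phases))
             if phases[k] in (int(Phase.LIVE_CORAL), int(Phase.DEAD_CORAL))]
    for i in range(len(phases)):
        if phases[i] != int(Phase.FLUID):
            continue
        near = False
        for c in coral:
            d = math.hypot(positions[i, 0] - positions[c, 0],
                           positions[i, 1] - positions[c, 1])
            if d <= proximity:
                near = True
                break
        if near and band[0] <= mean_speeds[i] <= band[1]:
            out.append(i)
    return np.asarray(out, dtype=np.intp)


def frozen_growth_fixture(band: Tuple[float, float] = (0.03, 0.06),
                          proximity_dx: float = 1.5,
                          dx: float = 0.05) -> FrozenFlowFixture:
    """One live coral at the origin plus three fluid particles at
    distances {1.0, 1.4, 1.6} dx carrying buffered mean speeds
    {0.02, 0.045, 0.07} m/s.

    With the default band and proximity, only the particle at 1.4 dx
    with 0.045 m/s both lies within reach and feeds in the optimal band.
    """
    dists = np.array([1.0, 1.4, 1.6]) * dx
    speeds = np.array([0.02, 0.045, 0.07])
    angles = np.deg2rad([30.0, 150.0, 270.0])
    fx = dists * np.cos(angles)
    fy = dists * np.sin(angles)
    xs = np.concatenate([[0.0], fx])
    ys = np.concatenate([[0.0], fy])
    n = xs.size
    phase = np.full(n, int(Phase.FLUID), dtype=np.int8)
    phase[0] = int(Phase.LIVE_CORAL)
    system = ParticleSystem(
        x=np.column_stack([xs, ys]), v=np.zeros((n, 2)),
        rho=np.full(n, 1000.0), p=np.zeros(n), m=np.full(n, 1000.0 * dx * dx),
        phase=phase, streak=np.zeros(n, dtype=np.int32), dx=dx,
        bounds=(-1.0, 1.0, -1.0, 1.0), period_x=None,
    )
    mean_speeds = np.concatenate([[0.0], speeds])
    expected = rule_eval_oracle(system.x, system.phase, mean_speeds, band,
                                proximity_dx * dx)
    return FrozenFlowFixture(system=system, mean_speeds=mean_speeds, band=band,
                             proximity_dx=proximity_dx, expected_convert=expected)
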