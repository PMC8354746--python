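"""Goldilocks growth and death rules, and the scenario driver.

A cold-water coral polyp feeds well only in a narrow band of current
speeds (3-6 cm/s in the model): slower flow lets prey evade capture,
faster flow sweeps the tentacles back.  The model turns this into two
particle rules evaluated at scheduled "growth-steps" once the flow has
settled:

* growth — a fluid particle within ``proximity`` (1.5 dx) of any coral
  particle whose time-averaged local speed lies inside the optimal band
  is converted to live coral;
* death — a live coral particle that sees no adjacent fluid in the band
  for ``K`` consecutive growth-events (its energetic reserve running
  out) is converted to dead framework.  Interior coral with no adjacent
  fluid at all is suboptimal by construction.

Both rules convert particles in place, so the total particle count is
constant for the whole run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .domain import DomainSpec, apply_boundary_conditions, build_domain
from .kernel import KernelSpec
from .particles import (NeighborList, ParticleSystem, Phase, build_cell_list,
                        phase_counts)
from .solver import (FluidProperties, VerletIntegrator, compute_dt,
                     compute_rates, kinetic_energy, smooth_density,
                     update_pressure)

__all__ = [
    "GoldilocksConfig", "ScenarioResult", "steady_state_reached",
    "local_mean_speed", "growth_event", "death_event", "run_scenario",
]


@dataclass(frozen=True)
class GoldilocksConfig:
    """Parameters of the ecological rules and their scheduling.

    ``death_interval`` is the number of consecutive suboptimal
    growth-events a live coral survives (its energetic reserve);
    ``None`` disables the death rule entirely.
    """

    v_opt_min: float = 0.03        # m/s, lower edge of the optimal band
    v_opt_max: float = 0.06        # m/s, upper edge
    proximity_dx: float = 1.5      # adjacency radius in particle spacings
    settle_steps: int = 300        # solver steps between growth events
    avg_window: int = 50           # steps over which local speeds are averaged
    death_interval: Optional[int] = None   # K; None = no death rule
    steady_tol: float = 0.02       # relative KE change for steadiness
    steady_window: int = 100       # KE averaging window, steps
    max_initial_steps: int = 20000  # cap on the initial settling phase
    n_growth_steps: int = 60
    cap_per_event: Optional[int] = None   # limit conversions per event
    streak_reset: bool = True      # one optimal evaluation resets the streak
    death_cadence: str = "every_event"    # or "interval": kill only every K events

    def __post_init__(self) -> None:
        if not (0.0 < self.v_opt_min < self.v_opt_max):
            raise ValueError("need 0 < v_opt_min < v_opt_max")
        if self.proximity_dx <= 0:
            raise ValueError("proximity must be positive")
        if self.death_interval is not None and self.death_interval < 1:
            raise ValueError("death_interval must be >= 1 (or None)")
        if self.death_cadence not in ("every_event", "interval"):
            raise ValueError(f"unknown death_cadence {self.death_cadence!r}")

    def proximity(self, dx: float) -> float:
        return self.proximity_dx * dx


@dataclass
class ScenarioResult:
    """Per-growth-step phase counts and event history of one scenario run."""

    counts: pd.DataFrame            # columns: step, fluid, live_coral, dead_coral, wall, live_dead_ratio
    events: pd.DataFrame            # columns: step, particle, transition
    extinction_step: Optional[int]  # first growth-step with zero live coral
    snapshots: Dict[int, ParticleSystem]
    config_hash: str = ""

    @property
    def final_counts(self) -> pd.Series:
        return self.counts.iloc[-1]


def steady_state_reached(kinetic_energy_history, steady_tol: float,
                         window: int) -> bool:
    """Whether the domain kinetic energy has stopped changing.

    Compares the mean KE over the last ``window`` steps with the mean
    over the preceding ``window`` steps; steadiness is a relative change
    below ``steady_tol``.  Histories shorter than two windows (including
    an empty history) are not steady.
    """
    ke = np.asarray(kinetic_energy_history, dtype=float)
    if ke.size < 2 * window or window < 1:
        return False
    recent = float(np.mean(ke[-window:]))
    previous = float(np.mean(ke[-2 * window:-window]))
    scale = max(abs(previous), 1e-300)
    return abs(recent - previous) / scale < steady_tol


def _mean_speeds(avg_buffer: np.ndarray) -> np.ndarray:
    """Collapse a (window, n) instantaneous-speed buffer to per-particle means."""
    buf = np.asarray(avg_buffer, dtype=float)
    return buf.mean(axis=0) if buf.ndim == 2 else buf


def _tree_points(x: np.ndarray, period_x: Optional[float], cutoff: float):
    """Wrap coordinates for torus KD-tree queries (periodic in x)."""
    if period_x is None:
        return x, None
    pts = x.copy()
    pts[:, 0] = np.mod(pts[:, 0], period_x)
    ymin = pts[:, 1].min()
    pts[:, 1] = pts[:, 1] - ymin + 10.0 * cutoff
    return pts, (period_x, 1.0e6)


def _adjacency(system: ParticleSystem, src_idx: np.ndarray, dst_idx: np.ndarray,
               radius: float) -> List[np.ndarray]:
    """For each particle in ``src_idx``, the ``dst_idx`` members within
    ``radius`` (periodic-aware).  Returns global indices."""
    if src_idx.size == 0:
        return []
    if dst_idx.size == 0:
        return [np.empty(0, dtype=np.intp)] * src_idx.size
    all_pts = np.vstack([system.x[src_idx], system.x[dst_idx]])
    pts, box = _tree_points(all_pts, system.period_x, radius)
    src_pts, dst_pts = pts[:src_idx.size], pts[src_idx.size:]
    tree = cKDTree(dst_pts, boxsize=box)
    hits = tree.query_ball_point(src_pts, radius)
    return [dst_idx[np.sort(np.asarray(h, dtype=np.intp))] for h in hits]


def local_mean_speed(system: ParticleSystem, avg_buffer: np.ndarray,
                     coral_particle: int,
                     proximity: Optional[float] = None,
                     cfg: Optional[GoldilocksConfig] = None):
    """Buffered mean speeds of the fluid particles adjacent to one coral.

    Returns ``(indices, speeds)`` where ``indices`` are global fluid
    particle indices within the proximity radius of ``coral_particle``
    and ``speeds`` their mean speed over the averaging buffer.
    """
    if proximity is None:
        cfg = cfg or GoldilocksConfig()
        proximity = cfg.proximity(system.dx)
    means = _mean_speeds(avg_buffer)
    fluid_idx = np.flatnonzero(system.fluid_mask)
    adj = _adjacency(system, np.asarray([coral_particle]), fluid_idx, proximity)
    idx = adj[0]
    return idx, means[idx]


def growth_event(system: ParticleSystem, cfg: GoldilocksConfig,
                 mean_speeds: np.ndarray) -> np.ndarray:
    """Convert qualifying fluid particles to live coral, in place.

    A fluid particle qualifies when it lies within the proximity radius
    of at least one coral particle (live or dead) and its buffered mean
    speed falls inside the optimal band.  All conversions are decided
    from the pre-event state and applied simultaneously.  Returns the
    converted particle indices.
    """
    means = _mean_speeds(mean_speeds)
    prox = cfg.proximity(system.dx)
    fluid_idx = np.flatnonzero(system.fluid_mask)
    coral_idx = np.flatnonzero(system.coral_mask)
    if fluid_idx.size == 0 or coral_idx.size == 0:
        return np.empty(0, dtype=np.intp)
    adj = _adjacency(system, coral_idx, fluid_idx, prox)
    adjacent = np.unique(np.concatenate([a for a in adj])) if adj else np.empty(0, np.intp)
    if adjacent.size == 0:
        return np.empty(0, dtype=np.intp)
    in_band = (means[adjacent] >= cfg.v_opt_min) & (means[adjacent] <= cfg.v_opt_max)
    convert = adjacent[in_band]
    if cfg.cap_per_event is not None:
        convert = convert[: cfg.cap_per_event]
    system.convert(convert, Phase.LIVE_CORAL)
    return convert


def death_event(system: ParticleSystem, cfg: GoldilocksConfig,
                mean_speeds: np.ndarray, event_index: int = 0,
                fluid_idx: Optional[np.ndarray] = None) -> np.ndarray:
    """Update suboptimal streaks and convert exhausted live coral to dead.

    A live coral particle is "optimal" at this event iff at least one
    adjacent fluid particle (within proximity, pre-event state) has its
    buffered mean speed inside the band; interior coral with no adjacent
    fluid is suboptimal by construction.  Streaks reset on an optimal
    evaluation (unless ``streak_reset`` is off) and a particle dies when
    its streak reaches ``death_interval``.  Returns the indices killed.
    """
    if cfg.death_interval is None:
        return np.empty(0, dtype=np.intp)
    means = _mean_speeds(mean_speeds)
    prox = cfg.proximity(system.dx)
    live_idx = np.flatnonzero(system.phase == int(Phase.LIVE_CORAL))
    if live_idx.size == 0:
        return np.empty(0, dtype=np.intp)
    if fluid_idx is None:
        fluid_idx = np.flatnonzero(system.fluid_mask)
    adj = _adjacency(system, live_idx, fluid_idx, prox)
    for k, coral in enumerate(live_idx):
        nbrs = adj[k]
        optimal = False
        if nbrs.size:
            sp = means[nbrs]
            optimal = bool(np.any((sp >= cfg.v_opt_min) & (sp <= cfg.v_opt_max)))
        if optimal and cfg.streak_reset:
            system.streak[coral] = 0
        elif not optimal:
            system.streak[coral] += 1
    doomed = live_idx[system.streak[live_idx] >= cfg.death_interval]
    if cfg.death_cadence == "interval" and (event_index + 1) % cfg.death_interval != 0:
        return np.empty(0, dtype=np.intp)
    system.convert(doomed, Phase.DEAD_CORAL)
    return doomed


# ---------------------------------------------------------------------------
# Scenario driver
# ---------------------------------------------------------------------------

class _SolverLoop:
    """Bundles the solver state needed to advance the flow between events."""

    def __init__(self, system: ParticleSystem, kernel: KernelSpec,
                 props: FluidProperties, spec: Optional[DomainSpec],
                 cfl_coeff: float = 0.25, n_euler: int = 50,
                 smooth_every: int = 1, skin_dx: float = 0.5,
                 dt_every: int = 10):
        self.system = system
        self.kernel = kernel
        self.props = props
        self.spec = spec
        self.cfl_coeff = cfl_coeff
        self.smooth_every = max(1, smooth_every)
        self.dt_every = max(1, dt_every)
        self.integrator = VerletIntegrator(n_euler=n_euler)
        self.cutoff = kernel.support_radius + skin_dx * system.dx
        self.skin = skin_dx * system.dx
        self.nl: Optional[NeighborList] = None
        self._x_ref: Optional[np.ndarray] = None
        self.dt = 0.0
        self.step_count = 0
        self.t = 0.0
        self.ke_history: List[float] = []

    def _ensure_neighbors(self) -> None:
        if self.nl is None or self._x_ref is None:
            rebuild = True
        else:
            drift = np.abs(self.system.x - self._x_ref).max()
            rebuild = drift > 0.5 * self.skin
        if rebuild:
            self.nl = build_cell_list(self.system, self.cutoff)
            self._x_ref = self.system.x.copy()

    def step(self, speed_accum: Optional[np.ndarray] = None) -> None:
        sysm = self.system
        self._ensure_neighbors()
        update_pressure(sysm, self.props)
        drho, acc = compute_rates(sysm, self.nl, self.kernel, self.props)
        if self.step_count % self.dt_every == 0 or self.dt == 0.0:
            self.dt = compute_dt(sysm, self.props, self.kernel, self.cfl_coeff).dt
        self.integrator.step(sysm, drho, acc, self.dt)
        if self.step_count % self.smooth_every == 0:
            sysm.rho[:] = smooth_density(sysm, self.nl, self.kernel, self.props.epsilon)
        if self.spec is not None:
            apply_boundary_conditions(sysm, self.spec, self.t, self.integrator)
        self.t += self.dt
        self.step_count += 1
        self.ke_history.append(kinetic_energy(sysm))
        if speed_accum is not None:
            speed_accum += np.hypot(sysm.v[:, 0], sysm.v[:, 1])

    def run(self, n_steps: int, avg_window: int = 0) -> Optional[np.ndarray]:
        """Advance ``n_steps``; if ``avg_window`` > 0, return mean particle
        speeds over the trailing ``avg_window`` steps."""
        accum = None
        for k in range(n_steps):
            remaining = n_steps - k
            if avg_window and remaining == avg_window:
                accum = np.zeros(self.system.n)
            self.step(accum if (accum is not None) else None)
        return accum / avg_window if accum is not None else None


def run_scenario(spec: DomainSpec, props: FluidProperties, kernel: KernelSpec,
                 cfg: GoldilocksConfig, *, cfl_coeff: float = 0.25,
                 n_euler: int = 50, smooth_every: int = 1,
                 snapshot_steps: Tuple[int, ...] = (),
                 config_hash: str = "", progress: bool = False) -> ScenarioResult:
    """Run the full habitat-engineering scenario.

    Alternates solver settling phases with growth/death events: the flow
    first settles to steadiness (bounded by ``max_initial_steps``), then
    every ``settle_steps`` solver steps the local mean speeds over the
    trailing ``avg_window`` steps feed one growth event (and death
    event, when the death rule is active).  Deterministic for a given
    configuration — the core loop contains no randomness.
    """
    system = build_domain(spec, props, kernel)
    apply_boundary_conditions(system, spec, 0.0)
    loop = _SolverLoop(system, kernel, props, spec, cfl_coeff=cfl_coeff,
                       n_euler=n_euler, smooth_every=smooth_every)

    # initial settling to steady flow
    while loop.step_count < cfg.max_initial_steps:
        loop.step()
        if (loop.step_count % cfg.steady_window == 0
                and steady_state_reached(loop.ke_history, cfg.steady_tol,
                                         cfg.steady_window)):
            break

    rows = []
    event_rows = []
    snapshots: Dict[int, ParticleSystem] = {}
    extinction: Optional[int] = None

    def record(step: int) -> None:
        c = phase_counts(system)
        rows.append({
            "step": step, "fluid": c["fluid"], "live_coral": c["live_coral"],
            "dead_coral": c["dead_coral"], "wall": c["wall"],
            "live_dead_ratio": c["live_dead_ratio"], "total": c["total"],
        })

    record(0)
    if 0 in snapshot_steps:
        snapshots[0] = system.copy()

    for event in range(1, cfg.n_growth_steps + 1):
        means = loop.run(cfg.settle_steps, avg_window=cfg.avg_window)
        fluid_before = np.flatnonzero(system.fluid_mask)
        grown = growth_event(system, cfg, means)
        died = death_event(system, cfg, means, event_index=event - 1,
                           fluid_idx=fluid_before)
        apply_boundary_conditions(system, spec, loop.t, loop.integrator)
        loop.nl = None  # phases changed; force neighbour refresh bookkeeping
        for g in grown:
            event_rows.append({"step": event, "particle": int(g),
                               "transition": "FLUID->LIVE_CORAL"})
        for d in died:
            event_rows.append({"step": event, "particle": int(d),
                               "transition": "LIVE_CORAL->DEAD_CORAL"})
        record(event)
        if extinction is None and rows[-1]["live_coral"] == 0:
            extinction = event
        if event in snapshot_steps:
            snapshots[event] = system.copy()
        if progress:
            r = rows[-1]
            print(f"growth-step {event}: fluid={r['fluid']} live={r['live_coral']} "
                  f"dead={r['dead_coral']}")

    counts = pd.DataFrame(rows)
    events = pd.DataFrame(event_rows, columns=["step", "particle", "transition"])
    return ScenarioResult(counts=counts, events=events, extinction_step=extinction,
                          snapshots=snapshots, config_hash=config_hash)
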