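"""Particle state container, phase taxonomy and neighbour search.

The simulator tracks four particle phases: moving FLUID particles, static
WALL (seabed/ceiling) boundary particles, and the two coral phases —
LIVE_CORAL and DEAD_CORAL — which are hydrodynamically identical solid
boundaries but differ ecologically.  The only phase transitions the model
permits are FLUID -> LIVE_CORAL (growth) and LIVE_CORAL -> DEAD_CORAL
(death); the total particle count never changes during a run.

State is stored struct-of-arrays for vectorised solver kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Phase", "ParticleSystem", "NeighborList", "build_cell_list", "phase_counts"]

# Virtual torus extent used for periodic-in-x KD-tree queries; the y
# coordinate is shifted into [0, _Y_PAD) so it never wraps.
_Y_PAD = 1.0e6


class Phase(IntEnum):
    FLUID = 0
    WALL = 1
    LIVE_CORAL = 2
    DEAD_CORAL = 3


#: Transitions the growth/death rules may apply.
ALLOWED_TRANSITIONS = {
    (Phase.FLUID, Phase.LIVE_CORAL),
    (Phase.LIVE_CORAL, Phase.DEAD_CORAL),
}

#: Phases treated as solid boundary by the solver (zero prescribed motion
#: unless a band velocity is externally imposed).
BOUNDARY_PHASES = (Phase.WALL, Phase.LIVE_CORAL, Phase.DEAD_CORAL)


@dataclass
class ParticleSystem:
    """Struct-of-arrays particle state.

    Attributes
    ----------
    x : ndarray (n, 2)
        Positions, metres.
    v : ndarray (n, 2)
        Velocities, m/s.  Boundary-phase particles keep zero (or
        externally prescribed) velocity.
    rho : ndarray (n,)
        Densities, kg/m^3.
    p : ndarray (n,)
        Pressures, Pa (updated from rho via the equation of state).
    m : ndarray (n,)
        Masses, kg per unit depth; fixed at rho0 * dx**2.
    phase : ndarray (n,) int8
    streak : ndarray (n,) int32
        Consecutive suboptimal growth-events for live coral; zero for all
        other phases.
    dx : float
        Initial particle spacing, metres.
    bounds : tuple (xmin, xmax, ymin, ymax)
        Fluid-domain bounds, metres (walls may lie outside).
    period_x : float or None
        If set, the domain is treated as periodic in x with this length
        for neighbour queries and particle recycling.
    """

    x: np.ndarray
    v: np.ndarray
    rho: np.ndarray
    p: np.ndarray
    m: np.ndarray
    phase: np.ndarray
    streak: np.ndarray
    dx: float
    bounds: tuple
    period_x: Optional[float] = None

    def __post_init__(self) -> None:
        n = self.x.shape[0]
        for name in ("v",):
            if getattr(self, name).shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2)")
        for name in ("rho", "p", "m", "phase", "streak"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if np.any(self.rho <= 0):
            raise ValueError("densities must be positive")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def mask(self, *phases: Phase) -> np.ndarray:
        out = np.zeros(self.n, dtype=bool)
        for ph in phases:
            out |= self.phase == int(ph)
        return out

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.phase == int(Phase.FLUID)

    @property
    def coral_mask(self) -> np.ndarray:
        return self.mask(Phase.LIVE_CORAL, Phase.DEAD_CORAL)

    @property
    def boundary_mask(self) -> np.ndarray:
        return self.phase != int(Phase.FLUID)

    def convert(self, indices: Sequence[int], new_phase: Phase) -> None:
        """Apply a phase transition to ``indices``, enforcing the taxonomy.

        Raises ``ValueError`` for any transition other than
        FLUID -> LIVE_CORAL or LIVE_CORAL -> DEAD_CORAL.  Converted
        particles keep mass and last density; velocity is zeroed and the
        suboptimal streak reset.
        """
        idx = np.asarray(indices, dtype=np.intp)
        if idx.size == 0:
            return
        for ph in np.unique(self.phase[idx]):
            if (Phase(int(ph)), new_phase) not in ALLOWED_TRANSITIONS:
                raise ValueError(
                    f"illegal phase transition {Phase(int(ph)).name} -> {new_phase.name}"
                )
        self.phase[idx] = int(new_phase)
        self.v[idx] = 0.0
        self.streak[idx] = 0

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            x=self.x.copy(), v=self.v.copy(), rho=self.rho.copy(), p=self.p.copy(),
            m=self.m.copy(), phase=self.phase.copy(), streak=self.streak.copy(),
            dx=self.dx, bounds=self.bounds, period_x=self.period_x,
        )


@dataclass
class NeighborList:
    """Directed neighbour pairs within a cutoff, ordered by particle index.

    ``i`` and ``j`` are parallel arrays: particle ``j[k]`` lies within
    ``cutoff`` of particle ``i[k]`` (self-pairs excluded).  ``start`` is a
    CSR-style offset array so the neighbours of particle ``q`` are
    ``j[start[q]:start[q+1]]``, sorted ascending.
    """

    i: np.ndarray
    j: np.ndarray
    start: np.ndarray
    cutoff: float
    n: int

    def neighbors_of(self, q: int) -> np.ndarray:
        return self.j[self.start[q]:self.start[q + 1]]


def _query_pairs(x: np.ndarray, cutoff: float, period_x: Optional[float]) -> np.ndarray:
    if period_x is None:
        tree = cKDTree(x)
        return tree.query_pairs(cutoff, output_type="ndarray")
    # Torus query: wrap x into [0, L), shift y positive, pad y so it
    # never wraps within the cutoff.
    pts = x.copy()
    pts[:, 0] = np.mod(pts[:, 0], period_x)
    ymin = pts[:, 1].min()
    pts[:, 1] = pts[:, 1] - ymin + 10.0 * cutoff
    tree = cKDTree(pts, boxsize=(period_x, _Y_PAD))
    return tree.query_pairs(cutoff, output_type="ndarray")


def build_cell_list(system: ParticleSystem, cutoff: float) -> NeighborList:
    """All particle pairs within ``cutoff`` (excluding self), deterministic.

    Backed by a KD-tree; respects ``system.period_x`` with minimum-image
    convention in x.  ``cutoff`` should be at least the kernel support
    radius so every SPH pair sum sees its full stencil.
    """
    if not (np.isfinite(cutoff) and cutoff > 0):
        raise ValueError(f"cutoff must be positive, got {cutoff!r}")
    pairs = _query_pairs(system.x, cutoff, system.period_x)
    if pairs.size == 0:
        i = np.empty(0, dtype=np.intp)
        j = np.empty(0, dtype=np.intp)
    else:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]]).astype(np.intp)
        j = np.concatenate([pairs[:, 1], pairs[:, 0]]).astype(np.intp)
        order = np.lexsort((j, i))
        i, j = i[order], j[order]
    start = np.zeros(system.n + 1, dtype=np.intp)
    np.add.at(start, i + 1, 1)
    np.cumsum(start, out=start)
    return NeighborList(i=i, j=j, start=start, cutoff=float(cutoff), n=system.n)


def pair_displacements(system: ParticleSystem, nl: NeighborList):
    """Displacements ``x_i - x_j`` and distances for every directed pair.

    Uses the minimum-image convention in x when the system is periodic.
    """
    d = system.x[nl.i] - system.x[nl.j]
    if system.period_x is not None:
        L = system.period_x
        d[:, 0] -= L * np.round(d[:, 0] / L)
    r = np.hypot(d[:, 0], d[:, 1])
    return d, r


def phase_counts(system: ParticleSystem) -> dict:
    """Per-phase counts plus the live:dead habitat-structure ratio.

    The ratio is ``inf`` when dead coral is absent but live coral is
    present, and ``nan`` when both are absent.
    """
    counts = {ph.name.lower(): int(np.sum(system.phase == int(ph))) for ph in Phase}
    live, dead = counts["live_coral"], counts["dead_coral"]
    if dead > 0:
        ratio = live / dead
    elif live > 0:
        ratio = float("inf")
    else:
        ratio = float("nan")
    counts["live_dead_ratio"] = ratio
    counts["total"] = system.n
    return counts
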