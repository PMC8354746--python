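"""Weakly-compressible SPH core.

Continuity and momentum are evolved in Lagrangian form and closed with
Tait's equation of state, so pressure follows algebraically from density
and no pressure-Poisson solve is needed.  Viscosity uses the Morris
laminar form (no artificial viscosity), density drift is controlled by a
gentle pairwise smoothing filter, and time integration is a Verlet
scheme with a periodic Euler corrector.  The time step obeys an
acoustic CFL cap plus viscous-diffusion and body-force caps.

Boundary-phase particles (walls, coral) take part in every pair sum and
evolve their density, but their positions and velocities stay prescribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .kernel import ALPHA_2D, KernelSpec
from .particles import NeighborList, ParticleSystem, Phase, pair_displacements

__all__ = [
    "FluidProperties", "StepControl", "tait_pressure", "continuity_rhs",
    "momentum_rhs", "smooth_density", "compute_dt", "VerletIntegrator",
]


@dataclass(frozen=True)
class FluidProperties:
    """Fluid constants of the weakly-compressible model.

    ``cs`` is an artificial speed of sound, chosen at least 10x the
    expected maximum flow speed so density variations stay within ~1% of
    the reference density.  ``B = rho0 * cs**2 / gamma`` is the Tait
    reference pressure.
    """

    rho0: float = 1000.0          # reference density, kg/m^3
    mu: float = 1.0e-3            # dynamic viscosity, Pa s
    cs: float = 10.0              # artificial speed of sound, m/s
    gamma: float = 7.0            # Tait exponent (water)
    epsilon: float = 0.01         # density-smoothing factor
    body_force: Tuple[float, float] = (0.0, 0.0)  # force per unit volume / rho0 -> m/s^2 when divided by rho

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.cs <= 0 or self.gamma <= 0:
            raise ValueError("rho0, cs and gamma must be positive")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError(f"epsilon must lie in [0, 1), got {self.epsilon}")

    @property
    def B(self) -> float:
        """Tait reference pressure rho0*cs^2/gamma, Pa."""
        return self.rho0 * self.cs**2 / self.gamma

    @property
    def nu(self) -> float:
        """Kinematic viscosity mu/rho0, m^2/s."""
        return self.mu / self.rho0


def tait_pressure(rho, props: FluidProperties):
    """Tait equation of state p = B((rho/rho0)^gamma - 1).

    Strictly increasing in density; zero at the reference density.
    Raises on non-positive density, which signals solver blow-up.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0) or not np.all(np.isfinite(rho)):
        raise FloatingPointError("non-positive or non-finite density in equation of state")
    p = props.B * ((rho / props.rho0) ** props.gamma - 1.0)
    return float(p) if p.ndim == 0 else p


# ---------------------------------------------------------------------------
# Pair-sum kernels (numba).  `fgrad` below is (1/r) dW/dr for the Wendland
# C2 kernel: fgrad = -(5 alpha / h^4) (1 - q/2)^3, finite at r = 0.
# ---------------------------------------------------------------------------

@njit(cache=False)
def _rates_kernel(ii, jj, dxv, rr, vel, rho, p, m, mu, h, drho, acc):
    """Accumulate continuity and momentum right-hand sides over directed pairs.

    Returns the number of coincident (r == 0) pairs encountered.
    """
    c = -(5.0 * ALPHA_2D) / h**4
    bad = 0
    for k in range(ii.shape[0]):
        i = ii[k]
        j = jj[k]
        r = rr[k]
        q = r / h
        if q >= 2.0:
            continue
        if r <= 0.0:
            bad += 1
            continue
        t = 1.0 - 0.5 * q
        fgrad = c * t * t * t            # (1/r) dW/dr
        gx = fgrad * dxv[k, 0]
        gy = fgrad * dxv[k, 1]
        vijx = vel[i, 0] - vel[j, 0]
        vijy = vel[i, 1] - vel[j, 1]
        # continuity: drho_i/dt = sum_j m_j v_ij . grad_i W_ij
        drho[i] += m[j] * (vijx * gx + vijy * gy)
        # pressure term, symmetric form
        pc = -m[j] * (p[j] / rho[j] ** 2 + p[i] / rho[i] ** 2)
        # Morris laminar viscosity
        vc = m[j] * (2.0 * mu) / (rho[i] * rho[j]) * fgrad
        acc[i, 0] += pc * gx + vc * vijx
        acc[i, 1] += pc * gy + vc * vijy
    return bad


@njit(cache=False)
def _smooth_kernel(ii, jj, rr, rho, m, h, corr):
    a = ALPHA_2D / h**2
    for k in range(ii.shape[0]):
        i = ii[k]
        j = jj[k]
        q = rr[k] / h
        if q >= 2.0:
            continue
        t = 1.0 - 0.5 * q
        w = a * t * t * t * t * (1.0 + 2.0 * q)
        corr[i] += m[j] * (rho[i] - rho[j]) * w / (0.5 * (rho[i] + rho[j]))


def _pair_arrays(system: ParticleSystem, nl: NeighborList):
    d, r = pair_displacements(system, nl)
    return nl.i, nl.j, d, r


def continuity_rhs(system: ParticleSystem, nl: NeighborList, kernel: KernelSpec) -> np.ndarray:
    """Per-particle density rate d(rho)/dt from the SPH continuity equation."""
    ii, jj, d, r = _pair_arrays(system, nl)
    drho = np.zeros(system.n)
    acc = np.zeros((system.n, 2))
    p = np.zeros(system.n)           # pressure irrelevant for continuity
    rho = system.rho
    _rates_kernel(ii, jj, d, r, system.v, rho, p, system.m, 0.0, kernel.h, drho, acc)
    return drho


def momentum_rhs(system: ParticleSystem, nl: NeighborList, kernel: KernelSpec,
                 props: FluidProperties, include_body_force: bool = True) -> np.ndarray:
    """Per-particle acceleration: symmetric pressure gradient + Morris
    viscosity + body force.

    Pressures must be current (``system.p`` from ``tait_pressure``).
    Raises on coincident particle pairs, which indicate instability.
    """
    ii, jj, d, r = _pair_arrays(system, nl)
    drho = np.zeros(system.n)
    acc = np.zeros((system.n, 2))
    bad = _rates_kernel(ii, jj, d, r, system.v, system.rho, system.p,
                        system.m, props.mu, kernel.h, drho, acc)
    if bad:
        raise FloatingPointError(f"{bad} coincident particle pair(s): solver unstable")
    if include_body_force:
        F = np.asarray(props.body_force)
        acc += F[None, :] / system.rho[:, None]
    return acc


def compute_rates(system: ParticleSystem, nl: NeighborList, kernel: KernelSpec,
                  props: FluidProperties):
    """Fused continuity + momentum evaluation (one pass over pairs)."""
    ii, jj, d, r = _pair_arrays(system, nl)
    drho = np.zeros(system.n)
    acc = np.zeros((system.n, 2))
    bad = _rates_kernel(ii, jj, d, r, system.v, system.rho, system.p,
                        system.m, props.mu, kernel.h, drho, acc)
    if bad:
        raise FloatingPointError(f"{bad} coincident particle pair(s): solver unstable")
    F = np.asarray(props.body_force)
    acc += F[None, :] / system.rho[:, None]
    return drho, acc


def smooth_density(system: ParticleSystem, nl: NeighborList, kernel: KernelSpec,
                   epsilon: float) -> np.ndarray:
    """Pairwise density filter: rho_i - eps * sum_j m_j (rho_i - rho_j) W_ij / mean(rho_i, rho_j).

    Leaves a uniform density field unchanged and is the identity at
    ``epsilon = 0``; damps short-wavelength density noise that would
    otherwise feed straight into the stiff equation of state.
    """
    if not (0.0 <= epsilon < 1.0):
        raise ValueError(f"epsilon must lie in [0, 1), got {epsilon}")
    ii, jj, d, r = _pair_arrays(system, nl)
    corr = np.zeros(system.n)
    _smooth_kernel(ii, jj, r, system.rho, system.m, kernel.h, corr)
    return system.rho - epsilon * corr


@dataclass
class StepControl:
    """Adaptive time-step bookkeeping.

    ``dt = cfl_coeff * min(cap_cfl, cap_visc, cap_force)`` with
    cap_cfl = h/(cs + |v|max), cap_visc = 0.25 h^2 rho_min / mu and
    cap_force = sqrt(h / |F/rho|max); inactive caps are infinite.
    """

    cfl_coeff: float = 0.25
    dt: float = 0.0
    cap_cfl: float = np.inf
    cap_visc: float = np.inf
    cap_force: float = np.inf


def compute_dt(system: ParticleSystem, props: FluidProperties, kernel: KernelSpec,
               cfl_coeff: float = 0.25) -> StepControl:
    """Stable time step from acoustic, viscous and body-force caps."""
    if system.n == 0:
        raise ValueError("empty particle system")
    h = kernel.h
    vmax = float(np.max(np.hypot(system.v[:, 0], system.v[:, 1])))
    cap_cfl = h / (props.cs + vmax)
    # 0.25 prefactor keeps the Verlet scheme's effective 2*dt velocity
    # update inside the viscous-diffusion stability limit
    cap_visc = 0.25 * h**2 * float(np.min(system.rho)) / props.mu if props.mu > 0 else np.inf
    F = np.asarray(props.body_force)
    fmag = float(np.linalg.norm(F)) / float(np.min(system.rho))
    cap_force = np.sqrt(h / fmag) if fmag > 0 else np.inf
    dt = cfl_coeff * min(cap_cfl, cap_visc, cap_force)
    return StepControl(cfl_coeff=cfl_coeff, dt=dt, cap_cfl=cap_cfl,
                       cap_visc=cap_visc, cap_force=cap_force)


class VerletIntegrator:
    """Verlet time integration with a periodic Euler corrector.

    The leapfrog-like update
        v^{n+1}   = v^{n-1} + 2 dt a^n
        x^{n+1}   = x^n + dt v^n + dt^2/2 a^n
        rho^{n+1} = rho^{n-1} + 2 dt (drho/dt)^n
    decouples even and odd steps; every ``n_euler`` steps (and on the
    first step) a plain Euler update re-synchronises them.  Boundary
    phases never move; their density still evolves through continuity.
    """

    def __init__(self, n_euler: int = 50):
        self.n_euler = int(n_euler)
        self._v_prev: Optional[np.ndarray] = None
        self._rho_prev: Optional[np.ndarray] = None
        self._count = 0

    def reset(self) -> None:
        self._v_prev = None
        self._rho_prev = None
        self._count = 0

    def step(self, system: ParticleSystem, drho: np.ndarray, acc: np.ndarray,
             dt: float) -> None:
        """Advance the system in place by one step of size ``dt``."""
        if dt < 0 or not np.isfinite(dt):
            raise ValueError(f"invalid time step {dt!r}")
        if dt == 0.0:
            return
        mobile = system.fluid_mask
        v_old = system.v.copy()
        rho_old = system.rho.copy()

        use_euler = (self._v_prev is None) or (self._count % self.n_euler == self.n_euler - 1)
        if use_euler:
            v_new = system.v + dt * acc
            rho_new = system.rho + dt * drho
        else:
            v_new = self._v_prev + 2.0 * dt * acc
            rho_new = self._rho_prev + 2.0 * dt * drho

        system.x[mobile] += dt * v_old[mobile] + 0.5 * dt**2 * acc[mobile]
        system.v[mobile] = v_new[mobile]
        system.rho[:] = rho_new      # density evolves for all phases
        if not (np.all(np.isfinite(system.x)) and np.all(np.isfinite(system.v))
                and np.all(np.isfinite(system.rho))):
            raise FloatingPointError("non-finite state after integration step")

        self._v_prev = v_old
        self._rho_prev = rho_old
        self._count += 1

    def sync_prescribed(self, indices: np.ndarray, system: ParticleSystem) -> None:
        """Pin the stored previous state of externally prescribed particles.

        Called after boundary conditions overwrite velocities so the next
        Verlet update does not reintroduce stale values.
        """
        if self._v_prev is not None and indices.size:
            self._v_prev[indices] = system.v[indices]


def update_pressure(system: ParticleSystem, props: FluidProperties) -> None:
    system.p[:] = tait_pressure(system.rho, props)


def kinetic_energy(system: ParticleSystem) -> float:
    """Total kinetic energy of fluid particles, J per unit depth."""
    fm = system.fluid_mask
    v2 = np.einsum("ij,ij->i", system.v[fm], system.v[fm])
    return float(0.5 * np.sum(system.m[fm] * v2))
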