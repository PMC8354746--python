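"""WCSPH core: equation of state, pair sums vs brute force, stepping."""

import numpy as np
import pytest

from conftest import random_cloud
from oracles import brute_continuity, brute_momentum, brute_smoothed_density

from reefsph.kernel import KernelSpec
from reefsph.particles import ParticleSystem, Phase, build_cell_list
from reefsph.solver import (FluidProperties, VerletIntegrator, compute_dt,
                            continuity_rhs, momentum_rhs, smooth_density,
                            tait_pressure, update_pressure)

KSPEC = KernelSpec(1.3 * 0.05)


def dense_cloud(n, seed, dx=0.05):
    """Random cloud packed so particles actually interact."""
    rng = np.random.default_rng(seed)
    side = dx * np.sqrt(n) * 1.2
    sys_ = random_cloud(n, rng, box=side, dx=dx)
    return sys_


class TestTaitEOS:
    props = FluidProperties(rho0=1000.0, cs=10.0, gamma=7.0)

    def test_reference_density_gives_zero_pressure(self):
        assert tait_pressure(1000.0, self.props) == pytest.approx(0.0)

    def test_reference_pressure_constant(self):
        assert self.props.B == pytest.approx(1000.0 * 100.0 / 7.0, rel=1e-12)
        assert self.props.B == pytest.approx(14285.714285714286)

    def test_one_percent_compression(self):
        # p = B (1.01^7 - 1)
        expected = self.props.B * (1.01**7 - 1.0)
        assert tait_pressure(1010.0, self.props) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.031e3, rel=1e-2)

    def test_strictly_increasing_in_density(self):
        rho = np.linspace(900, 1100, 101)
        p = tait_pressure(rho, self.props)
        assert np.all(np.diff(p) > 0)

    def test_nonpositive_density_raises(self):
        with pytest.raises(FloatingPointError):
            tait_pressure(-5.0, self.props)
        with pytest.raises(FloatingPointError):
            tait_pressure(np.array([1000.0, 0.0]), self.props)


class TestPairSumsAgainstBruteForce:
    """Criterion: vectorised RHS equals all-pairs evaluation to 1e-12 relative."""

    props = FluidProperties(rho0=1000.0, mu=1.0e-3, cs=10.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_continuity_matches_brute_force(self, seed):
        sys_ = dense_cloud(50, seed)
        nl = build_cell_list(sys_, KSPEC.support_radius)
        got = continuity_rhs(sys_, nl, KSPEC)
        want = brute_continuity(sys_.x, sys_.v, sys_.m, KSPEC)
        scale = np.max(np.abs(want))
        np.testing.assert_allclose(got, want, atol=1e-12 * scale)

    @pytest.mark.parametrize("seed", [4, 5, 6])
    def test_momentum_matches_brute_force(self, seed):
        sys_ = dense_cloud(50, seed)
        update_pressure(sys_, self.props)
        nl = build_cell_list(sys_, KSPEC.support_radius)
        got = momentum_rhs(sys_, nl, KSPEC, self.props)
        want = brute_momentum(sys_.x, sys_.v, sys_.rho, sys_.p, sys_.m,
                              self.props.mu, KSPEC)
        scale = np.max(np.abs(want))
        np.testing.assert_allclose(got, want, atol=1e-12 * scale)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_density_smoothing_matches_brute_force(self, seed):
        sys_ = dense_cloud(50, seed)
        nl = build_cell_list(sys_, KSPEC.support_radius)
        got = smooth_density(sys_, nl, KSPEC, 0.01)
        want = brute_smoothed_density(sys_.x, sys_.rho, sys_.m, KSPEC, 0.01)
        np.testing.assert_allclose(got, want, rtol=1e-12)


class TestContinuityProperties:
    def test_uniform_velocity_gives_zero_density_rate(self):
        sys_ = dense_cloud(40, 11)
        sys_.v[:] = [0.3, -0.1]
        nl = build_cell_list(sys_, KSPEC.support_radius)
        np.testing.assert_allclose(continuity_rhs(sys_, nl, KSPEC), 0.0, atol=1e-14)

    def test_head_on_approach_compresses_both(self):
        x = np.array([[0.0, 0.0], [0.05, 0.0]])
        v = np.array([[0.1, 0.0], [-0.1, 0.0]])
        sys_ = ParticleSystem(x=x, v=v, rho=np.full(2, 1000.0), p=np.zeros(2),
                              m=np.full(2, 2.5), phase=np.zeros(2, np.int8),
                              streak=np.zeros(2, np.int32), dx=0.05,
                              bounds=(0, 1, 0, 1))
        nl = build_cell_list(sys_, KSPEC.support_radius)
        drho = continuity_rhs(sys_, nl, KSPEC)
        assert np.all(drho > 0)


class TestMomentumProperties:
    props = FluidProperties(rho0=1000.0, mu=1.0e-3, cs=10.0)

    def test_uniform_state_at_reference_density_gives_zero_acceleration(self):
        # p = 0 everywhere and no velocity differences: no net force
        sys_ = dense_cloud(40, 21)
        sys_.v[:] = [0.05, 0.02]
        sys_.rho[:] = 1000.0
        update_pressure(sys_, self.props)
        nl = build_cell_list(sys_, KSPEC.support_radius)
        props0 = FluidProperties(rho0=1000.0, mu=1.0e-3, cs=10.0)
        acc = momentum_rhs(sys_, nl, KSPEC, props0)
        # pairwise antisymmetry cancels identically for equal masses
        np.testing.assert_allclose(acc, 0.0, atol=1e-9)

    def test_pairwise_momentum_conservation(self):
        # closed two-particle system: m_i a_i = -m_j a_j to machine precision
        x = np.array([[0.0, 0.0], [0.04, 0.02]])
        sys_ = ParticleSystem(x=x, v=np.array([[0.1, 0.0], [-0.05, 0.03]]),
                              rho=np.array([1005.0, 995.0]), p=np.zeros(2),
                              m=np.array([2.5, 2.5]), phase=np.zeros(2, np.int8),
                              streak=np.zeros(2, np.int32), dx=0.05,
                              bounds=(0, 1, 0, 1))
        update_pressure(sys_, self.props)
        nl = build_cell_list(sys_, KSPEC.support_radius)
        acc = momentum_rhs(sys_, nl, KSPEC, self.props)
        np.testing.assert_allclose(sys_.m[0] * acc[0], -sys_.m[1] * acc[1],
                                   atol=1e-12 * np.max(np.abs(acc)))

    def test_closed_system_conserves_linear_momentum(self):
        sys_ = dense_cloud(60, 22)
        update_pressure(sys_, self.props)
        nl = build_cell_list(sys_, KSPEC.support_radius)
        acc = momentum_rhs(sys_, nl, KSPEC, self.props, include_body_force=False)
        total = np.sum(sys_.m[:, None] * acc, axis=0)
        # compare against the largest single-particle force
        scale = np.max(np.abs(sys_.m[:, None] * acc))
        np.testing.assert_allclose(total, 0.0, atol=1e-11 * max(scale, 1.0))

    def test_coincident_particles_raise(self):
        x = np.zeros((2, 2))
        sys_ = ParticleSystem(x=x, v=np.zeros((2, 2)), rho=np.full(2, 1000.0),
                              p=np.zeros(2), m=np.full(2, 2.5),
                              phase=np.zeros(2, np.int8),
                              streak=np.zeros(2, np.int32), dx=0.05,
                              bounds=(0, 1, 0, 1))
        nl = build_cell_list(sys_, KSPEC.support_radius)
        with pytest.raises(FloatingPointError):
            momentum_rhs(sys_, nl, KSPEC, self.props)


class TestDensitySmoothing:
    def test_uniform_field_unchanged(self):
        sys_ = dense_cloud(30, 31)
        sys_.rho[:] = 1000.0
        nl = build_cell_list(sys_, KSPEC.support_radius)
        np.testing.assert_allclose(smooth_density(sys_, nl, KSPEC, 0.01), 1000.0)

    def test_epsilon_zero_is_identity(self):
        sys_ = dense_cloud(30, 32)
        nl = build_cell_list(sys_, KSPEC.support_radius)
        np.testing.assert_array_equal(smooth_density(sys_, nl, KSPEC, 0.0), sys_.rho)

    def test_invalid_epsilon_rejected(self):
        sys_ = dense_cloud(5, 33)
        nl = build_cell_list(sys_, KSPEC.support_radius)
        with pytest.raises(ValueError):
            smooth_density(sys_, nl, KSPEC, 1.5)


class TestTimeStep:
    def test_matches_stated_arithmetic(self):
        # acoustic-limited: dt = 0.25 * h / (cs + vmax)
        sys_ = dense_cloud(10, 41, dx=0.05)
        sys_.v[:] = 0.0
        sys_.v[0] = [0.5, 0.0]
        sys_.rho[:] = 1000.0
        props = FluidProperties(rho0=1000.0, mu=1e-6, cs=10.0)
        spec = KernelSpec(0.065)
        sc = compute_dt(sys_, props, spec, cfl_coeff=0.25)
        assert sc.dt == pytest.approx(0.25 * 0.065 / 10.5, rel=1e-12)

    def test_monotone_in_sound_speed(self):
        sys_ = dense_cloud(10, 42)
        spec = KernelSpec(0.065)
        dt1 = compute_dt(sys_, FluidProperties(cs=10.0, mu=1e-6), spec).dt
        dt2 = compute_dt(sys_, FluidProperties(cs=20.0, mu=1e-6), spec).dt
        assert dt2 < dt1

    def test_zero_body_force_deactivates_force_cap(self):
        sys_ = dense_cloud(10, 43)
        sc = compute_dt(sys_, FluidProperties(cs=10.0), KernelSpec(0.065))
        assert sc.cap_force == np.inf
        assert sc.dt == pytest.approx(sc.cfl_coeff * min(sc.cap_cfl, sc.cap_visc))

    def test_empty_system_rejected(self):
        empty = ParticleSystem(
            x=np.empty((0, 2)), v=np.empty((0, 2)), rho=np.empty(0),
            p=np.empty(0), m=np.empty(0), phase=np.empty(0, np.int8),
            streak=np.empty(0, np.int32), dx=0.05, bounds=(0, 1, 0, 1))
        with pytest.raises(ValueError):
            compute_dt(empty, FluidProperties(), KernelSpec(0.065))


class TestVerletIntegration:
    def test_ballistic_particle_matches_half_g_t_squared(self):
        g = 2.0
        props = FluidProperties(rho0=1000.0, mu=0.0, cs=10.0,
                                body_force=(0.0, -1000.0 * g))
        sys_ = ParticleSystem(
            x=np.array([[0.5, 0.5]]), v=np.zeros((1, 2)),
            rho=np.full(1, 1000.0), p=np.zeros(1), m=np.full(1, 2.5),
            phase=np.zeros(1, np.int8), streak=np.zeros(1, np.int32),
            dx=0.05, bounds=(0, 1, 0, 1))
        integ = VerletIntegrator(n_euler=50)
        dt = 1.0e-3
        for _ in range(100):
            acc = np.array([[0.0, -g]]) * (1000.0 / sys_.rho[0])
            integ.step(sys_, np.zeros(1), acc, dt)
        t = 100 * dt
        assert sys_.x[0, 1] - 0.5 == pytest.approx(-0.5 * g * t**2, rel=1e-4)
        assert sys_.v[0, 1] == pytest.approx(-g * t, rel=1e-4)

    def test_wall_particle_never_moves(self):
        sys_ = ParticleSystem(
            x=np.array([[0.5, 0.5]]), v=np.zeros((1, 2)),
            rho=np.full(1, 1000.0), p=np.zeros(1), m=np.full(1, 2.5),
            phase=np.full(1, int(Phase.WALL), np.int8),
            streak=np.zeros(1, np.int32), dx=0.05, bounds=(0, 1, 0, 1))
        integ = VerletIntegrator()
        for _ in range(10):
            integ.step(sys_, np.zeros(1), np.full((1, 2), 5.0), 1e-3)
        np.testing.assert_array_equal(sys_.x, [[0.5, 0.5]])
        np.testing.assert_array_equal(sys_.v, [[0.0, 0.0]])

    def test_zero_dt_is_identity(self, rng):
        sys_ = dense_cloud(5, 51)
        x0, v0 = sys_.x.copy(), sys_.v.copy()
        VerletIntegrator().step(sys_, np.zeros(5), np.ones((5, 2)), 0.0)
        np.testing.assert_array_equal(sys_.x, x0)
        np.testing.assert_array_equal(sys_.v, v0)

    def test_nonfinite_state_aborts(self):
        sys_ = dense_cloud(3, 52)
        with pytest.raises(FloatingPointError):
            VerletIntegrator().step(sys_, np.full(3, np.nan), np.zeros((3, 2)), 1e-3)


def test_mass_is_invariant_under_stepping():
    sys_ = dense_cloud(20, 61)
    m0 = sys_.m.copy()
    integ = VerletIntegrator()
    for _ in range(5):
        integ.step(sys_, np.zeros(20), np.zeros((20, 2)), 1e-3)
    np.testing.assert_array_equal(sys_.m, m0)
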