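"""Membrane pressure, lubrication drainage and the linear dispersion oracle."""

import dataclasses

import numpy as np
import pytest

from smacsim.boundary import BoundaryCondition
from smacsim.engine import SolverConfig, State, Stepper
from smacsim.grid import Grid
from smacsim.mechanics import (
    MechanicsConfig,
    PositivityError,
    dispersion_rate,
    height_rhs,
    pressure,
)
from smacsim.parameters import DimensionlessGroups


@pytest.fixture(scope="module")
def mech(groups):
    return MechanicsConfig.from_groups(groups)


class TestPressure:
    def test_relaxed_short_bonds_no_pressure(self, periodic32, mech):
        # flat film at the short-bond height with only short bonds attached
        h = np.full(periodic32.shape, mech.lam1)
        C1 = np.full(periodic32.shape, 0.7)
        C2 = np.zeros(periodic32.shape)
        p = pressure(h, C1, C2, mech, periodic32)
        assert np.allclose(p, 0.0, atol=1e-12)

    def test_stretched_short_bonds(self, periodic32, mech, params):
        # flat film at the tall-bond height: short bonds stretched by l2-l1
        h = np.ones(periodic32.shape)
        C1 = np.ones(periodic32.shape)
        C2 = np.zeros(periodic32.shape)
        p = pressure(h, C1, C2, mech, periodic32)
        assert np.allclose(p, 1.0 - mech.lam1, atol=1e-12)
        # dimensional check: (1 - lam1) p0 = 7.2 Pa
        assert (1.0 - mech.lam1) * params.p0 == pytest.approx(7.2, rel=1e-12)

    def test_bending_of_sinusoid(self, mech):
        g = Grid(128)
        k = 2 * np.pi
        a = 1e-3
        h = mech.lam1 + a * np.sin(k * g.x)
        p = pressure(h, np.zeros(g.shape), np.zeros(g.shape), mech, g)
        expected = a * mech.B * k**4 * np.sin(k * g.x)
        assert np.allclose(p, expected, atol=2e-3 * a * mech.B * k**4)

    def test_linearity_in_densities(self, periodic32, mech, rng):
        h = 0.5 + 0.1 * rng.random(periodic32.shape)
        C1a, C2a = rng.random(periodic32.shape), rng.random(periodic32.shape)
        C1b, C2b = rng.random(periodic32.shape), rng.random(periodic32.shape)
        lhs = pressure(h, C1a + C1b, C2a + C2b, mech, periodic32)
        rhs = (pressure(h, C1a, C2a, mech, periodic32)
               + pressure(h, C1b, C2b, mech, periodic32)
               - pressure(h, np.zeros_like(C1a), np.zeros_like(C2a), mech, periodic32))
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestHeightRhs:
    def test_uniform_pressure_gives_zero(self, periodic32, mech):
        h = np.full(periodic32.shape, 0.5)
        p = np.full(periodic32.shape, 2.0)
        assert np.allclose(height_rhs(h, p, mech, periodic32), 0.0, atol=1e-12)

    def test_closed_boundary_conserves_volume(self, mech, bc_closed, rng):
        g = Grid(32, "disk")
        h = 0.5 + 0.2 * rng.random(g.shape)
        p = rng.normal(size=g.shape)
        out = height_rhs(h, p, mech, g, bc_closed)
        assert abs(g.integrate(out)) < 1e-12

    def test_nonpositive_height_rejected(self, periodic32, mech):
        h = np.zeros(periodic32.shape)
        with pytest.raises(PositivityError):
            height_rhs(h, np.ones(periodic32.shape), mech, periodic32)


class TestDispersionRate:
    def test_pure_bending_reduction(self):
        cfg = MechanicsConfig(B=1e-3, eps=1.0)
        k, h0 = 7.0, 0.8
        assert dispersion_rate(k, h0, 0.0, 0.0, cfg) == pytest.approx(
            -(1.0 / 12.0) * h0**3 * cfg.B * k**6, rel=1e-12
        )

    def test_always_stabilizing_and_monotone(self):
        cfg = MechanicsConfig(B=1e-4, eps=1.0, Gamma=0.5)
        ks = np.linspace(0.5, 50, 40)
        rates = np.array([dispersion_rate(k, 0.6, 0.8, 0.4, cfg) for k in ks])
        assert (rates < 0).all()
        assert (np.diff(rates) < 0).all()

    def test_invalid_arguments(self):
        cfg = MechanicsConfig(B=1e-4, eps=1.0)
        with pytest.raises(ValueError):
            dispersion_rate(-1.0, 0.5, 0.0, 0.0, cfg)


def simulate_decay_rate(B, C1, h0, k_mode, n=256, steps=60, theta=0.5):
    """Integrate a small sinusoid with frozen densities; return the fitted
    exponential decay rate of the mode amplitude."""
    grid = Grid(n, ny=16)
    groups = DimensionlessGroups(
        B=B, eps=1.0, lam1=1.0 / 3.0, Pe=1e4, M=2.0, tau=1.0,
        c10=1.0, c20=2.0,
    )
    cfg = MechanicsConfig.from_groups(groups)
    k = 2 * np.pi * k_mode
    omega = dispersion_rate(k, h0, C1, 0.0, cfg)
    dt = 0.05 / abs(omega)
    solver = SolverConfig(
        t_end=steps * dt, dt_init=dt, dt_max=dt, theta=theta,
        evolve_c=False, max_dh=1.0,
    )
    stepper = Stepper(groups, grid, None, solver)
    amp0 = 1e-4
    h = h0 + amp0 * np.sin(k * grid.x)
    state = State(0.0, h, np.full(grid.shape, C1), np.zeros(grid.shape))
    times, amps = [], []

    basis = np.sin(k * grid.x)
    norm = np.sum(basis * basis)

    def record(t, hv, C1v, C2v):
        arr = stepper.disc.from_vec(hv)
        times.append(t)
        amps.append(np.sum((arr - h0) * basis) / norm)

    stepper.advance_to(state, solver.t_end, dt, 0, on_accept=record)
    slope = np.polyfit(times, np.log(np.abs(amps)), 1)[0]
    return slope, omega


class TestLinearDispersion:
    """The integrator reproduces the closed-form linear relaxation rate."""

    @pytest.mark.parametrize("B,C1,h0,k_mode", [
        (1e-3, 0.0, 0.6, 4),    # bending dominated
        (1e-8, 1.0, 0.6, 4),    # spring dominated
    ])
    def test_simulated_decay_matches_closed_form(self, B, C1, h0, k_mode):
        slope, omega = simulate_decay_rate(B, C1, h0, k_mode)
        assert slope == pytest.approx(omega, rel=0.01)


class TestNonlinearInvariants:
    def test_volume_conserved_over_full_run(self, bc_closed):
        """Closed rim: cleft volume is conserved through the nonlinear
        drainage dynamics."""
        g = Grid(32, "disk")
        groups = DimensionlessGroups(
            B=1e-6, eps=1.0, lam1=1.0 / 3.0, Pe=1e4, M=2.0, tau=1.0,
        )
        solver = SolverConfig(t_end=50.0, dt_init=1e-3, dt_max=5.0,
                              evolve_c=False, max_dh=0.05)
        stepper = Stepper(groups, g, bc_closed, solver)
        h = 0.5 + 0.05 * np.sin(2 * np.pi * g.x) * np.sin(2 * np.pi * g.y)
        state = State(0.0, h, np.full(g.shape, 0.5), np.full(g.shape, 0.2))
        v0 = g.integrate(np.where(g.interior_mask, state.h, 0.0))
        out, _, _ = stepper.advance_to(state, solver.t_end, solver.dt_init, 0)
        v1 = g.integrate(np.where(g.interior_mask, out.h, 0.0))
        assert abs(v1 - v0) / v0 < 1e-8

    def test_relaxation_to_flat_equilibrium(self, bc_closed):
        """Uniform springs, closed rim: the film flattens and pressure
        gradients vanish."""
        g = Grid(32, "disk")
        groups = DimensionlessGroups(
            B=1e-6, eps=1.0, lam1=1.0 / 3.0, Pe=1e4, M=2.0, tau=1.0,
        )
        solver = SolverConfig(t_end=400.0, dt_init=1e-2, dt_max=20.0,
                              evolve_c=False, max_dh=0.05)
        stepper = Stepper(groups, g, bc_closed, solver)
        h = 0.5 + 0.05 * np.sin(2 * np.pi * g.x)
        state = State(0.0, h, np.full(g.shape, 0.5), np.zeros(g.shape))

        def grad_norm(st):
            p = stepper.pressure_field(st)
            d = stepper.disc
            return np.linalg.norm(d.G @ d.to_vec(np.nan_to_num(p)))

        g0 = grad_norm(state)
        out, _, _ = stepper.advance_to(state, solver.t_end, solver.dt_init, 0)
        m = g.interior_mask
        v0 = state.h[m].mean()
        assert out.h[m].std() < 1e-8
        assert out.h[m].mean() == pytest.approx(v0, rel=1e-8)
        assert grad_norm(out) < 1e-8 * g0
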