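"""Initial conditions, time stepping, archiving and restart."""

import dataclasses

import h5py
import numpy as np
import pytest

from smacsim.boundary import BoundaryCondition
from smacsim.engine import (
    ArchiveError,
    InitialCondition,
    RunArchive,
    SolverConfig,
    State,
    Stepper,
    checkpoint_roundtrip,
    make_initial_condition,
    resume,
    run,
    simulate,
    step,
)
from smacsim.grid import Grid
from smacsim.kinetics import kinetics_fixed_point


@pytest.fixture(scope="module")
def disk24():
    return Grid(24, "disk")


def short_solver(t_end=3000.0, **kw):
    return SolverConfig(t_end=t_end, snapshot_every=kw.pop("snapshot_every", t_end / 4), **kw)


class TestInitialCondition:
    def test_no_bumps_gives_flat_film(self, disk24):
        st = make_initial_condition(InitialCondition(n_bumps=0), disk24)
        assert np.allclose(st.h, 0.5)
        assert np.allclose(st.C1, 0.01)

    def test_bump_amplitudes_within_range(self, disk24):
        for seed in range(5):
            st = make_initial_condition(InitialCondition(seed=seed), disk24)
            assert 0.575 <= st.h.max() <= 0.6
            assert st.h.min() >= 0.5 - 1e-12

    def test_seed_determinism(self, disk24):
        a = make_initial_condition(InitialCondition(seed=7), disk24)
        b = make_initial_condition(InitialCondition(seed=7), disk24)
        assert np.array_equal(a.h, b.h)
        assert np.array_equal(a.C1, b.C1)

    def test_random_placement_determinism(self, disk24):
        ic = InitialCondition(seed=11, placement="random")
        a = make_initial_condition(ic, disk24)
        b = make_initial_condition(ic, disk24)
        assert np.array_equal(a.h, b.h)
        # different seed moves the bumps
        c = make_initial_condition(dataclasses.replace(ic, seed=12), disk24)
        assert not np.array_equal(a.h, c.h)

    def test_under_resolved_bumps_rejected(self):
        grid = Grid(16, "disk")
        with pytest.raises(ValueError):
            make_initial_condition(InitialCondition(width=0.05), grid)


class TestStepping:
    def test_equilibrium_state_preserved(self, groups, periodic32):
        """A flat film with densities at their kinetic fixed point is a
        steady state of the coupled update."""
        stepper = Stepper(groups, periodic32, None, short_solver())
        h0 = 0.5
        c1 = kinetics_fixed_point(h0, stepper.kin1)
        c2 = kinetics_fixed_point(h0, stepper.kin2)
        state = State(0.0, np.full(periodic32.shape, h0),
                      np.full(periodic32.shape, c1), np.full(periodic32.shape, c2))
        out, _, _ = stepper.advance_to(state, 50.0, 1.0, 0)
        assert np.allclose(out.h, h0, atol=1e-12)
        assert np.allclose(out.C1, c1, atol=1e-10)
        assert np.allclose(out.C2, c2, atol=1e-10)

    def test_single_step_advances_time(self, groups, periodic32):
        state = State(0.0, np.full(periodic32.shape, 0.5),
                      np.full(periodic32.shape, 0.01), np.full(periodic32.shape, 0.01))
        out = step(state, groups, periodic32, dt=0.5)
        assert out.t == pytest.approx(0.5)

    def test_volume_conserved_per_step_with_full_physics(self, groups, disk24, bc_closed):
        stepper = Stepper(groups, disk24, bc_closed, short_solver(500.0))
        state = make_initial_condition(InitialCondition(seed=1), disk24)
        m = disk24.interior_mask
        v = [state.h[m].sum()]

        def record(t, hv, C1v, C2v):
            v.append(hv.sum())

        stepper.advance_to(state, 500.0, 0.01, 0, on_accept=record)
        v = np.asarray(v)
        assert np.max(np.abs(v - v[0]) / v[0]) < 1e-10


class TestDeterminismAndRestart:
    def test_identical_seed_gives_identical_series(self, groups, disk24, bc_open):
        ic = InitialCondition(seed=5)
        solver = short_solver(1000.0)
        _, s1 = simulate(groups, disk24, ic, bc_open, solver)
        _, s2 = simulate(groups, disk24, ic, bc_open, solver)
        for key in s1:
            assert np.array_equal(s1[key], s2[key])

    def test_restart_is_bit_identical(self, params, groups, disk24, bc_open, tmp_path):
        ic = InitialCondition(seed=5)
        full = short_solver(2000.0, snapshot_every=500.0)
        half = dataclasses.replace(full, t_end=1000.0)

        arch_a = run(params, disk24, ic, bc_open, full, tmp_path / "a.h5", groups=groups)
        arch_b = run(params, disk24, ic, bc_open, half, tmp_path / "b.h5", groups=groups)
        resume(arch_b, t_end=2000.0)

        sa, pa, _, _ = arch_a.load_state(-1)
        sb, pb, _, _ = arch_b.load_state(-1)
        assert sa.t == sb.t
        for x, y in ((sa.h, sb.h), (sa.C1, sb.C1), (sa.C2, sb.C2), (pa, pb)):
            assert np.array_equal(np.nan_to_num(x), np.nan_to_num(y))

    def test_series_csv_is_reproducible(self, params, groups, disk24, bc_open, tmp_path):
        ic = InitialCondition(seed=5)
        solver = short_solver(500.0)
        a = run(params, disk24, ic, bc_open, solver, tmp_path / "a.h5", groups=groups)
        b = run(params, disk24, ic, bc_open, solver, tmp_path / "b.h5", groups=groups)
        assert a.series_csv_path.read_bytes() == b.series_csv_path.read_bytes()
        header = a.series_csv_path.read_text().splitlines()[0]
        assert header == "t_dimensionless,t_minutes,N1,N2"


@pytest.fixture(scope="module")
def archive(params, groups, disk24, bc_open, tmp_path_factory):
    path = tmp_path_factory.mktemp("arch") / "run.h5"
    return run(params, disk24, InitialCondition(seed=1), bc_open,
               short_solver(800.0, snapshot_every=400.0), path, groups=groups)


def test_closed_boundary_arrests_pattern(params, groups, bc_closed, tmp_path):
    """Sealing the rim arrests the pattern: the per-interval field change in
    the last tenth of a 40-minute run is far below that of the early
    cluster-forming phase (arrest is asymptotic; the absolute change keeps
    shrinking)."""
    grid = Grid(32, "disk")
    t_end = 40.0 * 60.0 / params.tau_mu
    solver = SolverConfig(t_end=t_end, snapshot_every=t_end / 10.0)
    arch = run(params, grid, InitialCondition(seed=1), bc_closed, solver,
               tmp_path / "closed.h5", groups=groups)
    idx = arch.snapshot_indices()
    s0 = arch.load_state(idx[1])[0]
    s1 = arch.load_state(idx[2])[0]
    a = arch.load_state(idx[-2])[0]
    b = arch.load_state(idx[-1])[0]
    m = grid.interior_mask
    for early0, early1, late0, late1 in (
        (s0.h, s1.h, a.h, b.h),
        (s0.C1, s1.C1, a.C1, b.C1),
        (s0.C2, s1.C2, a.C2, b.C2),
    ):
        d_early = np.max(np.abs(early1[m] - early0[m]))
        d_late = np.max(np.abs(late1[m] - late0[m]))
        assert d_late < 0.2 * d_early


class TestArchive:
    def test_checkpoint_roundtrip(self, archive):
        state = checkpoint_roundtrip(archive)
        again = checkpoint_roundtrip(archive)
        assert state.t == again.t
        assert np.array_equal(np.nan_to_num(state.h), np.nan_to_num(again.h))

    def test_layout(self, archive):
        with h5py.File(archive.path, "r") as f:
            assert "config/json" in f
            assert {"N1", "N2", "hmin", "hmax"} <= set(f["series"])
            snap = f["snapshots"][sorted(f["snapshots"], key=int)[-1]]
            assert {"h", "C1", "C2", "p"} <= set(snap)
            assert "t" in snap.attrs

    def test_truncated_archive_raises(self, archive, tmp_path):
        corrupt = tmp_path / "corrupt.h5"
        data = archive.path.read_bytes()
        corrupt.write_bytes(data[: len(data) // 3])
        with pytest.raises(ArchiveError):
            checkpoint_roundtrip(corrupt)

    def test_series_time_is_monotone(self, archive):
        df = archive.series()
        assert (np.diff(df["t"]) > 0).all()
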