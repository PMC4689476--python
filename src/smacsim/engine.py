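"""Coupled time integration of gap height and bound-receptor densities.

The stepper advances the stiff height equation with a linearly-implicit
theta scheme (backward Euler by default) solved by quasi-Newton iteration:
the Jacobian of the lubrication operator -- built with lagged mobility h^3 and
frozen densities -- is refactorised only when the time step or the
coefficients change appreciably, while the residual always uses the current
nonlinear right-hand side.  Receptor densities are split per step into
explicit upwind transport (advection + sliding, CFL limited), implicit
constant-coefficient diffusion, and an exact pointwise relaxation of the
linear binding kinetics, which keeps the densities inside [0, ctot] without a
kinetic time-step restriction.

The time step adapts: halved on rejection (height positivity, bound
violations, Newton failure, or an excessive per-step height change), grown by
a fixed factor after a run of accepted steps, and clipped to the CFL limit
and the next snapshot time.  Snapshot times are deterministic
synchronisation points at which all cached factorisations are dropped, so a
run restarted from any archived snapshot reproduces the original trajectory
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import kinetics as kin
from .boundary import BoundaryCondition
from .grid import DISK, Grid
from .kinetics import KineticsConfig
from .mechanics import MechanicsConfig, PositivityError
from .operators import Discretization, get_discretization
from .parameters import (
    DimensionlessGroups,
    PhysicalParameters,
    default_parameters,
    dimensionless_groups,
)

logger = logging.getLogger(__name__)

__all__ = [
    "State",
    "InitialCondition",
    "SolverConfig",
    "StiffnessError",
    "ArchiveError",
    "make_initial_condition",
    "Stepper",
    "step",
    "run",
    "simulate",
    "resume",
    "RunArchive",
    "checkpoint_roundtrip",
]


class StiffnessError(RuntimeError):
    """Raised when the adaptive time step underflows."""


class ArchiveError(RuntimeError):
    """Raised for corrupt or incomplete run archives."""


@dataclass
class State:
    """Instantaneous solver state: time (tau_mu units), gap height (l2 units)
    and bound densities (C0 units) on the full grid."""

    t: float
    h: np.ndarray
    C1: np.ndarray
    C2: np.ndarray

    def copy(self) -> "State":
        return State(self.t, self.h.copy(), self.C1.copy(), self.C2.copy())

    def validate(self, grid: Grid, ctot1: float, ctot2: float, tol: float = 1e-9) -> None:
        m = grid.interior_mask
        if np.any(self.h[m] <= 0):
            raise PositivityError("gap height must be strictly positive")
        for C, ctot, name in ((self.C1, ctot1, "C1"), (self.C2, ctot2, "C2")):
            if np.any(C[m] < -tol) or np.any(C[m] > ctot + tol):
                raise ValueError(f"{name} outside [0, ctot]")


@dataclass(frozen=True)
class InitialCondition:
    """Initial membrane shape and bound densities.

    A flat film at ``base_h`` decorated with ``n_bumps`` Gaussian bumps of
    width ~ ``width`` (fraction of L; the bump standard deviation is
    width/2) and amplitudes drawn uniformly from ``amp_range`` (l2 units).
    Bound densities start uniform at ``C_init``.  ``placement`` is either the
    fixed hexagonal arrangement at radius 0.3 or seeded uniform-random
    placement inside radius 0.35.
    """

    n_bumps: int = 6
    width: float = 0.1
    amp_range: tuple[float, float] = (0.075, 0.1)
    base_h: float = 0.5
    C_init: float = 0.01
    seed: int = 0
    placement: str = "hex"

    def __post_init__(self) -> None:
        if self.n_bumps < 0:
            raise ValueError("n_bumps must be non-negative")
        if self.placement not in ("hex", "random"):
            raise ValueError("placement must be 'hex' or 'random'")
        if not self.amp_range[0] <= self.amp_range[1]:
            raise ValueError("amp_range must be ordered")


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive IMEX solver settings (times in tau_mu units)."""

    t_end: float
    snapshot_every: float | None = None
    dt_init: float = 1e-2
    dt_max: float = 2e3
    newton_tol: float = 1e-8
    max_newton: int = 8
    seed: int = 0
    theta: float = 1.0
    cfl_safety: float = 0.8
    max_dh: float = 0.02
    h_min: float = 1e-3
    refresh_interval: int = 40
    grow_every: int = 5
    grow_factor: float = 1.2
    evolve_c: bool = True
    bound_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if not 0 < self.dt_init <= self.dt_max:
            raise ValueError("need 0 < dt_init <= dt_max")
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0.5, 1]")

    @property
    def snapshot_dt(self) -> float:
        return self.snapshot_every if self.snapshot_every else self.t_end


def make_initial_condition(ic: InitialCondition, grid: Grid) -> State:
    """Deterministic seeded initial state (identical seed -> identical state)."""
    if ic.n_bumps > 0 and ic.width < 2 * grid.dx:
        raise ValueError(
            f"bump width {ic.width} under-resolved: needs at least 2 dx = {2 * grid.dx}"
        )
    rng = np.random.default_rng(ic.seed)
    h = np.full(grid.shape, float(ic.base_h))
    cy = 0.5 * grid.ny * grid.dx
    if ic.placement == "hex":
        angles = 2 * np.pi * np.arange(max(ic.n_bumps, 1)) / max(ic.n_bumps, 1)
        centers = np.stack([0.5 + 0.3 * np.cos(angles), cy + 0.3 * np.sin(angles)], axis=1)
        centers = centers[: ic.n_bumps]
    else:
        rr = 0.35 * np.sqrt(rng.uniform(size=ic.n_bumps))
        th = rng.uniform(0, 2 * np.pi, size=ic.n_bumps)
        centers = np.stack([0.5 + rr * np.cos(th), cy + rr * np.sin(th)], axis=1)
    widths = ic.width * rng.uniform(0.8, 1.2, size=ic.n_bumps)
    amps = rng.uniform(ic.amp_range[0], ic.amp_range[1], size=ic.n_bumps)
    for (cx, cyy), w, a in zip(centers, widths, amps):
        sigma = w / 2.0
        r2 = (grid.x - cx) ** 2 + (grid.y - cyy) ** 2
        h += a * np.exp(-r2 / (2 * sigma**2))
    C = np.full(grid.shape, float(ic.C_init))
    return State(t=0.0, h=h, C1=C, C2=C.copy())


# ---------------------------------------------------------------------------
# stepper
# ---------------------------------------------------------------------------


class Stepper:
    """Advances (h, C1, C2) under one fixed configuration."""

    def __init__(
        self,
        groups: DimensionlessGroups,
        grid: Grid,
        bc: BoundaryCondition | None = None,
        solver: SolverConfig | None = None,
        kin1: KineticsConfig | None = None,
        kin2: KineticsConfig | None = None,
    ):
        self.groups = groups
        self.grid = grid
        self.bc = bc if bc is not None else BoundaryCondition()
        self.solver = solver if solver is not None else SolverConfig(t_end=1.0)
        self.disc: Discretization = get_discretization(grid, self.bc)
        self.mech_cfg = MechanicsConfig.from_groups(groups)
        self.kin1 = kin1 if kin1 is not None else KineticsConfig.for_species(groups, 1)
        self.kin2 = kin2 if kin2 is not None else KineticsConfig.for_species(groups, 2)
        self._open = grid.geometry == DISK and self.bc.is_open
        self._interior = np.ones(self.disc.n_nodes, dtype=bool)
        if self._open:
            self._interior[self.disc.ring_idx] = False
        # diffusion operator (ring rows pinned for the open variant)
        L = self.disc.laplacian_matrix(None)[0].tolil()
        if self._open:
            L[self.disc.ring_idx, :] = 0.0
        self._L_C = L.tocsr()
        self.reset_caches()
        # per-run counters
        self.n_accept = 0
        self.n_reject = 0
        self.n_factor = 0
        self.n_clamped = 0

    # -- cache management ------------------------------------------------
    def reset_caches(self) -> None:
        self._lu = None
        self._lu_dt = None
        self._J = None
        self._h_ref = None
        self._steps_since_build = 0
        self._diff_lu: dict[tuple[int, float], object] = {}

    # -- pieces ----------------------------------------------------------
    def _pressure_terms(self, C1: np.ndarray, C2: np.ndarray):
        """Diagonal spring part of the pressure operator (vector form)."""
        diag = C1 + self.mech_cfg.lam1 * C2
        aff = -(C1 * self.mech_cfg.lam1 + self.mech_cfg.lam1 * C2)
        return diag, aff

    def _pressure_vec(self, h: np.ndarray, diag: np.ndarray, aff: np.ndarray) -> np.ndarray:
        d = self.disc
        cfg = self.mech_cfg
        bih_mat, bih_aff = d.biharmonic_parts()
        p = cfg.B * (bih_mat @ h + bih_aff) + diag * h + aff
        if cfg.Gamma > 0:
            h_dir = self.bc.h_edge if self._open else None
            L, La = d.laplacian_matrix(h_dir)
            p -= cfg.Gamma * cfg.eps**2 * (L @ h + La)
        if self._open:
            p[d.ring_idx] = self.bc.p_edge
        return p

    def _height_tendency(self, h: np.ndarray, diag: np.ndarray, aff: np.ndarray):
        """Exact nonlinear drainage tendency N(h) and the pressure used."""
        d = self.disc
        p = self._pressure_vec(h, diag, aff)
        dirichlet_p = self.bc.p_edge if self._open else None
        N = (self.mech_cfg.eps**2 / 12.0) * d.div_flux_vec(h**3, p, dirichlet_p)
        if self._open:
            N[d.ring_idx] = 0.0
        return N, p

    def _build_factorization(self, h: np.ndarray, diag: np.ndarray, dt: float) -> None:
        d = self.disc
        cfg = self.mech_cfg
        P = cfg.B * d.biharmonic_parts()[0] + sp.diags(diag)
        if cfg.Gamma > 0:
            h_dir = self.bc.h_edge if self._open else None
            P = P - cfg.Gamma * cfg.eps**2 * d.laplacian_matrix(h_dir)[0]
        Df = d.div_flux_matrix(h**3, dirichlet=self._open)
        J = (cfg.eps**2 / 12.0) * (Df @ P)
        if self._open:
            keep = np.ones(d.n_nodes)
            keep[d.ring_idx] = 0.0
            J = sp.diags(keep) @ J
        A = sp.eye(d.n_nodes, format="csr") - dt * self.solver.theta * J
        self._lu = spla.splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A")
        self._lu_dt = dt
        self._h_ref = h.copy()
        self._steps_since_build = 0
        self.n_factor += 1

    def _ensure_factorization(self, h: np.ndarray, diag: np.ndarray, dt: float) -> bool:
        """Refresh the height-system factorization if too stale to serve as a
        quasi-Newton preconditioner; returns True if it is exact for ``dt``."""
        stale = (
            self._lu is None
            or abs(dt / self._lu_dt - 1.0) > 0.25
            or self._steps_since_build >= self.solver.refresh_interval
            or np.max(np.abs(h - self._h_ref)) > 0.15
        )
        if stale:
            self._build_factorization(h, diag, dt)
        return self._lu_dt == dt

    def _diffusion_solve(self, C: np.ndarray, species: int, dt: float) -> np.ndarray:
        cfg = self.kin1 if species == 1 else self.kin2
        nu = (cfg.lam1 / cfg.lam) / cfg.Pe
        key = (species, dt)
        lu = self._diff_lu.get(key)
        if lu is None:
            A = sp.eye(self.disc.n_nodes, format="csr") - dt * nu * self._L_C
            lu = spla.splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A")
            if len(self._diff_lu) > 16:
                self._diff_lu.clear()
            self._diff_lu[key] = lu
        return lu.solve(C)

    def _kinetics_update(self, C: np.ndarray, h: np.ndarray, species: int,
                         dt: float) -> np.ndarray:
        cfg = self.kin1 if species == 1 else self.kin2
        kon = kin.on_rate(h, cfg)
        koff = kin.off_rate(h, cfg)
        b = kon + koff
        with np.errstate(invalid="ignore", divide="ignore"):
            cfp = np.where(b > 0, cfg.ctot * kon / np.maximum(b, 1e-300), 0.0)
        return np.where(b > 0, cfp + (C - cfp) * np.exp(-b * dt), C)

    # -- single attempted step ------------------------------------------
    def _solve_height(self, hv, diag, aff, N0, dt: float):
        """Implicit theta update of h via quasi-Newton with a (possibly
        stale) factorization as preconditioner; exact-dt rebuild on failure."""
        sol = self.solver
        exact = self._ensure_factorization(hv, diag, dt)
        for _retry in range(2):
            h_new = hv + self._lu.solve(dt * N0)
            for _ in range(sol.max_newton):
                if np.any(h_new <= sol.h_min):
                    break
                N_k, _ = self._height_tendency(h_new, diag, aff)
                r = h_new - hv - dt * (sol.theta * N_k + (1 - sol.theta) * N0)
                if np.max(np.abs(r)) <= sol.newton_tol:
                    return h_new
                h_new = h_new - self._lu.solve(r)
            if exact:
                return None
            self._build_factorization(hv, diag, dt)
            exact = True
        return None

    def _attempt(self, hv, C1v, C2v, dt: float, precomp):
        """Try one step of size dt; returns (h, C1, C2) or None on rejection."""
        sol = self.solver
        d = self.disc
        diag, aff, N0, p0 = precomp

        h_new = self._solve_height(hv, diag, aff, N0, dt)
        if h_new is None or np.any(h_new <= sol.h_min):
            return None
        if np.max(np.abs(h_new - hv)) > sol.max_dh:
            return None

        if not sol.evolve_c:
            return h_new, C1v.copy(), C2v.copy()

        # --- receptors: explicit transport, implicit diffusion, exact kinetics
        out = []
        for species, Cv in ((1, C1v), (2, C2v)):
            cfg = self.kin1 if species == 1 else self.kin2
            u = kin.transport_face_velocity(d, hv, p0, cfg)
            C_t = Cv + dt * d.transport_vec(Cv, u, conservative=True)
            lo, hi = C_t.min(), C_t.max()
            if lo < -1e-3 * cfg.ctot or hi > (1 + 1e-3) * cfg.ctot:
                return None
            C_t = self._diffusion_solve(C_t, species, dt)
            C_t = self._kinetics_update(C_t, h_new, species, dt)
            clip = np.clip(C_t, 0.0, cfg.ctot)
            self.n_clamped += int(np.sum(clip != C_t))
            if self._open:
                clip[d.ring_idx] = self.bc.C_edge
            out.append(clip)
        return h_new, out[0], out[1]

    def _cfl_dt(self, hv, p0) -> float:
        if not self.solver.evolve_c:
            return math.inf
        d = self.disc
        speed = 0.0
        for cfg in (self.kin1, self.kin2):
            u = kin.transport_face_velocity(d, hv, p0, cfg)
            speed = max(speed, d.max_face_speed(u))
        if speed <= 0:
            return math.inf
        return self.solver.cfl_safety * d.dx / speed

    # -- dt ladder --------------------------------------------------------
    # Step sizes live on the geometric ladder dt_init * grow_factor^k so that
    # repeated dt values hit the factorization caches.
    def _rung(self, dt: float) -> int:
        sol = self.solver
        return round(math.log(dt / sol.dt_init) / math.log(sol.grow_factor))

    def _rung_floor(self, dt: float) -> int:
        sol = self.solver
        return math.floor(math.log(dt / sol.dt_init) / math.log(sol.grow_factor) + 1e-12)

    def _dt_of(self, k: int) -> float:
        sol = self.solver
        return min(sol.dt_init * sol.grow_factor**k, sol.dt_max)

    @property
    def _k_max(self) -> int:
        sol = self.solver
        return self._rung_floor(sol.dt_max)

    # -- public stepping -------------------------------------------------
    def advance_to(self, state: State, t_target: float, dt: float, streak: int,
                   on_accept=None):
        """Integrate from ``state.t`` to ``t_target``; returns
        (state, dt, streak).  ``on_accept(t, h, C1, C2)`` runs after each
        accepted step (node-vector arguments)."""
        sol = self.solver
        d = self.disc
        hv = d.to_vec(state.h)
        C1v = d.to_vec(state.C1)
        C2v = d.to_vec(state.C2)
        t = state.t
        k = min(self._rung(dt), self._k_max)
        while t < t_target - 1e-12 * max(1.0, t_target):
            diag, aff = self._pressure_terms(C1v, C2v)
            N0, p0 = self._height_tendency(hv, diag, aff)
            precomp = (diag, aff, N0, p0)
            dt_cfl = self._cfl_dt(hv, p0)
            if math.isfinite(dt_cfl) and dt_cfl < self._dt_of(k):
                k = min(k, self._rung_floor(dt_cfl))
            rejected = 0
            while True:
                dt_use = min(self._dt_of(k), t_target - t)
                result = self._attempt(hv, C1v, C2v, dt_use, precomp)
                if result is not None:
                    break
                self.n_reject += 1
                rejected += 1
                streak = 0
                k -= 4  # one rejection ~ halves the step (1.2^4 ~ 2.07)
                if self._dt_of(k) < 1e-12:
                    state_fail = State(
                        t, d.from_vec(hv), d.from_vec(C1v), d.from_vec(C2v)
                    )
                    raise StiffnessError(
                        f"time step underflow at t={t:.6g}", state_fail
                    ) from None
            hv, C1v, C2v = result
            t += dt_use
            self.n_accept += 1
            streak = streak + 1 if rejected == 0 else 1
            self._steps_since_build += 1
            if streak % sol.grow_every == 0:
                k = min(k + 1, self._k_max)
            logger.debug("step accepted: t=%.6g dt=%.3g rung=%d streak=%d",
                         t, dt_use, k, streak)
            if on_accept is not None:
                on_accept(t, hv, C1v, C2v)
        out = State(t, d.from_vec(hv), d.from_vec(C1v), d.from_vec(C2v))
        return out, self._dt_of(k), streak

    def pressure_field(self, state: State) -> np.ndarray:
        d = self.disc
        diag, aff = self._pressure_terms(d.to_vec(state.C1), d.to_vec(state.C2))
        p = self._pressure_vec(d.to_vec(state.h), diag, aff)
        return d.from_vec(p, fill=0.0)

    def totals(self, C1v: np.ndarray, C2v: np.ndarray) -> tuple[float, float]:
        a = self.disc.dx**2
        return float(C1v.sum() * a), float(C2v.sum() * a)


def step(state: State, groups: DimensionlessGroups, grid: Grid,
         bc: BoundaryCondition | None = None,
         solver: SolverConfig | None = None,
         dt: float | None = None) -> State:
    """Advance one accepted step (convenience wrapper around Stepper)."""
    solver = solver if solver is not None else SolverConfig(t_end=state.t + 1.0)
    stepper = Stepper(groups, grid, bc, solver)
    dt0 = dt if dt is not None else solver.dt_init
    new_state, _, _ = stepper.advance_to(state, state.t + dt0, dt0, 0)
    return new_state


# ---------------------------------------------------------------------------
# run archive (HDF5 + CSV)
# ---------------------------------------------------------------------------


def _flatten_config(cfg: dict, prefix: str = "") -> dict:
    out = {}
    for key, val in cfg.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            out.update(_flatten_config(val, name + "."))
        else:
            out[name] = val
    return out


class RunArchive:
    """Reader/writer for a simulation archive.

    HDF5 layout: ``/config`` (flattened key-value attributes plus the exact
    JSON dataset used for restarts), ``/t`` and ``/series/{N1,N2,hmin,hmax}``
    per accepted step, and ``/snapshots/<k>/{h,C1,C2,p}`` with solver-state
    attributes for bit-identical restart.  The time series is mirrored to a
    CSV with columns t_dimensionless, t_minutes, N1, N2.
    """

    def __init__(self, path):
        self.path = Path(path)

    # -- writing ----------------------------------------------------------
    @classmethod
    def create(cls, path, config: dict) -> "RunArchive":
        arch = cls(path)
        with h5py.File(arch.path, "w") as f:
            g = f.create_group("config")
            g.create_dataset("json", data=json.dumps(config))
            for key, val in _flatten_config(config).items():
                try:
                    g.attrs[key] = val if val is not None else "none"
                except TypeError:
                    g.attrs[key] = str(val)
            f.create_group("snapshots")
        return arch

    def write_snapshot(self, index: int, state: State, p: np.ndarray,
                       dt: float, streak: int) -> None:
        with h5py.File(self.path, "a") as f:
            g = f["snapshots"].create_group(str(index))
            g.attrs["t"] = state.t
            g.attrs["dt"] = dt
            g.attrs["streak"] = streak
            for name, arr in (("h", state.h), ("C1", state.C1),
                              ("C2", state.C2), ("p", p)):
                g.create_dataset(name, data=arr)

    def write_series(self, t, N1, N2, hmin, hmax, tau_mu: float) -> None:
        with h5py.File(self.path, "a") as f:
            for name, data in (("t", t),):
                if name in f:
                    del f[name]
                f.create_dataset(name, data=np.asarray(data))
            if "series" in f:
                del f["series"]
            g = f.create_group("series")
            for name, data in (("N1", N1), ("N2", N2), ("hmin", hmin), ("hmax", hmax)):
                g.create_dataset(name, data=np.asarray(data))
        csv_path = self.series_csv_path
        t_arr = np.asarray(t)
        with open(csv_path, "w") as fh:
            fh.write("t_dimensionless,t_minutes,N1,N2\n")
            for ti, n1, n2 in zip(t_arr, N1, N2):
                fh.write(f"{ti!r},{ti * tau_mu / 60.0!r},{n1!r},{n2!r}\n")

    @property
    def series_csv_path(self) -> Path:
        return self.path.with_name(self.path.stem + "_series.csv")

    # -- reading ----------------------------------------------------------
    def config(self) -> dict:
        try:
            with h5py.File(self.path, "r") as f:
                return json.loads(f["config/json"][()])
        except (OSError, KeyError) as exc:
            raise ArchiveError(f"cannot read archive config from {self.path}") from exc

    def snapshot_indices(self) -> list[int]:
        with h5py.File(self.path, "r") as f:
            return sorted(int(k) for k in f["snapshots"])

    def load_state(self, index: int = -1):
        """Return ``(State, pressure, dt, streak)`` for a snapshot."""
        try:
            indices = self.snapshot_indices()
            if not indices:
                raise ArchiveError(f"archive {self.path} holds no snapshots")
            key = str(indices[index] if index < 0 else index)
            with h5py.File(self.path, "r") as f:
                g = f["snapshots"][key]
                state = State(
                    t=float(g.attrs["t"]), h=g["h"][()], C1=g["C1"][()], C2=g["C2"][()]
                )
                return state, g["p"][()], float(g.attrs["dt"]), int(g.attrs["streak"])
        except (OSError, KeyError) as exc:
            raise ArchiveError(f"corrupt or incomplete archive {self.path}") from exc

    def series(self):
        """Time series as a pandas DataFrame (t, t_minutes, N1, N2, hmin, hmax)."""
        import pandas as pd

        try:
            with h5py.File(self.path, "r") as f:
                t = f["t"][()]
                data = {name: f["series"][name][()] for name in ("N1", "N2", "hmin", "hmax")}
        except (OSError, KeyError) as exc:
            raise ArchiveError(f"corrupt or incomplete archive {self.path}") from exc
        cfg = self.config()
        tau_mu = float(cfg.get("tau_mu", 1.0))
        df = pd.DataFrame({"t": t, **data})
        df.insert(1, "t_minutes", df["t"] * tau_mu / 60.0)
        return df


def checkpoint_roundtrip(archive: RunArchive | str | Path, index: int = -1) -> State:
    """Load a snapshot back into a State (raises ArchiveError if corrupt)."""
    arch = archive if isinstance(archive, RunArchive) else RunArchive(archive)
    return arch.load_state(index)[0]


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


def _config_dict(params, groups, grid, ic, bc, solver) -> dict:
    return {
        "params": dataclasses.asdict(params),
        "groups": dataclasses.asdict(groups),
        "grid": {"n": grid.n, "geometry": grid.geometry, "ny": grid.ny},
        "ic": dataclasses.asdict(ic),
        "bc": dataclasses.asdict(bc),
        "solver": dataclasses.asdict(solver),
        "tau_mu": params.tau_mu,
    }


def _configs_from_dict(cfg: dict):
    params = PhysicalParameters(**cfg["params"])
    groups = DimensionlessGroups(**cfg["groups"])
    grid = Grid(**cfg["grid"])
    ic_raw = dict(cfg["ic"])
    ic_raw["amp_range"] = tuple(ic_raw["amp_range"])
    ic = InitialCondition(**ic_raw)
    bc = BoundaryCondition(**cfg["bc"])
    solver = SolverConfig(**cfg["solver"])
    return params, groups, grid, ic, bc, solver


class _SeriesRecorder:
    def __init__(self, stepper: Stepper):
        self.stepper = stepper
        self.t: list[float] = []
        self.N1: list[float] = []
        self.N2: list[float] = []
        self.hmin: list[float] = []
        self.hmax: list[float] = []

    def __call__(self, t, hv, C1v, C2v) -> None:
        n1, n2 = self.stepper.totals(C1v, C2v)
        self.t.append(t)
        self.N1.append(n1)
        self.N2.append(n2)
        self.hmin.append(float(hv.min()))
        self.hmax.append(float(hv.max()))


def _drive(stepper: Stepper, state: State, archive: RunArchive, recorder,
           solver: SolverConfig, tau_mu: float, dt: float, streak: int,
           first_index: int) -> State:
    """Snapshot-to-snapshot integration loop with partial flush on failure."""
    snap_dt = solver.snapshot_dt
    index = first_index
    try:
        while state.t < solver.t_end - 1e-9 * solver.t_end:
            t_next = min(state.t + snap_dt, solver.t_end)
            state, dt, streak = stepper.advance_to(state, t_next, dt, streak, recorder)
            stepper.reset_caches()  # deterministic restart sync point
            archive.write_snapshot(index, state, stepper.pressure_field(state), dt, streak)
            logger.info(
                "snapshot %d at t=%.6g (%.3g min): N1=%.6g N2=%.6g dt=%.3g "
                "accepts=%d rejects=%d factorizations=%d",
                index, state.t, state.t * tau_mu / 60.0,
                recorder.N1[-1] if recorder.N1 else float("nan"),
                recorder.N2[-1] if recorder.N2 else float("nan"),
                dt, stepper.n_accept, stepper.n_reject, stepper.n_factor,
            )
            index += 1
    except StiffnessError as exc:
        fail_state = exc.args[1] if len(exc.args) > 1 else state
        archive.write_snapshot(index, fail_state, stepper.pressure_field(fail_state),
                               dt, streak)
        archive.write_series(recorder.t, recorder.N1, recorder.N2,
                             recorder.hmin, recorder.hmax, tau_mu)
        raise
    archive.write_series(recorder.t, recorder.N1, recorder.N2,
                         recorder.hmin, recorder.hmax, tau_mu)
    return state


def run(
    params: PhysicalParameters | None,
    grid: Grid,
    ic: InitialCondition,
    bc: BoundaryCondition,
    solver: SolverConfig,
    out_path,
    groups: DimensionlessGroups | None = None,
) -> RunArchive:
    """Integrate the coupled system to ``solver.t_end`` and archive the run.

    ``groups`` overrides the dimensionless numbers derived from ``params``
    (the physical parameters are still used for unit conversion in outputs).
    """
    params = params if params is not None else default_parameters()
    groups = groups if groups is not None else dimensionless_groups(params)
    stepper = Stepper(groups, grid, bc, solver)

    state = make_initial_condition(ic, grid)
    if stepper._open:
        ring = grid.boundary_ring
        state.h[ring[:, 0], ring[:, 1]] = bc.h_edge
        state.C1[ring[:, 0], ring[:, 1]] = bc.C_edge
        state.C2[ring[:, 0], ring[:, 1]] = bc.C_edge
    state.validate(grid, groups.c10, groups.c20)

    archive = RunArchive.create(out_path, _config_dict(params, groups, grid, ic, bc, solver))
    archive.write_snapshot(0, state, stepper.pressure_field(state), solver.dt_init, 0)
    recorder = _SeriesRecorder(stepper)
    _drive(stepper, state, archive, recorder, solver, params.tau_mu,
           solver.dt_init, 0, first_index=1)
    return archive


def simulate(
    groups: DimensionlessGroups,
    grid: Grid,
    ic: InitialCondition,
    bc: BoundaryCondition,
    solver: SolverConfig,
):
    """Integrate without archiving; returns ``(final State, series dict)``.

    The series dict holds per-accepted-step arrays t, N1, N2, hmin, hmax
    (N_i are dimensionless domain totals, sum C_i dx^2).  Used by parameter
    sweeps and tests where no run archive is needed.
    """
    stepper = Stepper(groups, grid, bc, solver)
    state = make_initial_condition(ic, grid)
    if stepper._open:
        ring = grid.boundary_ring
        state.h[ring[:, 0], ring[:, 1]] = bc.h_edge
        state.C1[ring[:, 0], ring[:, 1]] = bc.C_edge
        state.C2[ring[:, 0], ring[:, 1]] = bc.C_edge
    state.validate(grid, groups.c10, groups.c20)
    recorder = _SeriesRecorder(stepper)
    dt, streak = solver.dt_init, 0
    snap_dt = solver.snapshot_dt
    while state.t < solver.t_end - 1e-9 * solver.t_end:
        t_next = min(state.t + snap_dt, solver.t_end)
        state, dt, streak = stepper.advance_to(state, t_next, dt, streak, recorder)
        stepper.reset_caches()
    series = {
        "t": np.asarray(recorder.t),
        "N1": np.asarray(recorder.N1),
        "N2": np.asarray(recorder.N2),
        "hmin": np.asarray(recorder.hmin),
        "hmax": np.asarray(recorder.hmax),
    }
    return state, series


def resume(archive: RunArchive | str | Path,
           t_end: float | None = None) -> RunArchive:
    """Continue an archived run from its last snapshot.

    With the original ``t_end`` (or beyond), reproduces the uninterrupted
    trajectory bit-identically, because snapshots are synchronisation points.
    """
    arch = archive if isinstance(archive, RunArchive) else RunArchive(archive)
    cfg = arch.config()
    params, groups, grid, ic, bc, solver = _configs_from_dict(cfg)
    if t_end is not None:
        solver = dataclasses.replace(solver, t_end=t_end)
    state, _, dt, streak = arch.load_state(-1)
    indices = arch.snapshot_indices()
    stepper = Stepper(groups, grid, bc, solver)
    recorder = _SeriesRecorder(stepper)
    # reload series rows up to the resume time
    try:
        df = arch.series()
        keep = df["t"] <= state.t + 1e-12
        recorder.t = list(df["t"][keep])
        recorder.N1 = list(df["N1"][keep])
        recorder.N2 = list(df["N2"][keep])
        recorder.hmin = list(df["hmin"][keep])
        recorder.hmax = list(df["hmax"][keep])
    except ArchiveError:
        pass  # no series yet (e.g. resuming right after creation)
    _drive(stepper, state, arch, recorder, solver, params.tau_mu,
           dt, streak, first_index=indices[-1] + 1)
    return arch
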