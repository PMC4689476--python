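"""Discrete differential operators with boundary handling.

All operators are second-order centred finite differences on the collocated
grid, assembled from a single signed face-incidence matrix ``G`` (one row per
pair of adjacent active nodes).  This gives every flux-form operator the
telescoping property: under no-flux boundaries the domain sum of a flux
divergence vanishes to round-off, which is what makes the nonlinear drainage
solver conserve cleft volume exactly.

Boundary closure:

* periodic square - faces wrap, no boundary terms;
* disk, ``open_pinned`` - Dirichlet ghost values beyond the rim (height,
  pressure and densities fixed), and the torque-free condition (zero Laplacian
  of the height at the rim) closes the biharmonic stencil;
* disk, ``closed_free`` - reflected ghosts, i.e. zero normal flux and zero
  bending moment/force; boundary faces simply drop out of ``G``.

Advection of bound receptors uses first-order upwinding for monotonicity and
is available in conservative flux form ``-div(C u)`` (used by the engine) as
well as the plain characteristic form ``-u . grad C``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .boundary import BoundaryCondition
from .grid import DISK, Field, Grid, PERIODIC_SQUARE, as_array

__all__ = [
    "Discretization",
    "get_discretization",
    "laplacian",
    "biharmonic",
    "div_flux",
    "advect",
]


class Discretization:
    """Sparse operators for one (grid, boundary-condition) pair."""

    def __init__(self, grid: Grid, bc: BoundaryCondition | None = None):
        self.grid = grid
        self.bc = bc if bc is not None else BoundaryCondition()
        mask = grid.interior_mask
        ny, nx = grid.shape
        self.dx = grid.dx

        idx = -np.ones(grid.shape, dtype=np.int64)
        idx[mask] = np.arange(mask.sum())
        self.index_map = idx
        self.n_nodes = int(mask.sum())

        # --- faces between adjacent active nodes --------------------------
        pairs_a: list[np.ndarray] = []
        pairs_b: list[np.ndarray] = []

        def _add(a_idx: np.ndarray, b_idx: np.ndarray) -> None:
            keep = (a_idx >= 0) & (b_idx >= 0)
            pairs_a.append(a_idx[keep])
            pairs_b.append(b_idx[keep])

        _add(idx[:, :-1].ravel(), idx[:, 1:].ravel())      # x faces
        _add(idx[:-1, :].ravel(), idx[1:, :].ravel())      # y faces
        if grid.geometry == PERIODIC_SQUARE:
            _add(idx[:, -1].ravel(), idx[:, 0].ravel())    # x wrap
            _add(idx[-1, :].ravel(), idx[0, :].ravel())    # y wrap
        self.face_a = np.concatenate(pairs_a)
        self.face_b = np.concatenate(pairs_b)
        self.n_faces = self.face_a.size

        rows = np.repeat(np.arange(self.n_faces), 2)
        cols = np.stack([self.face_a, self.face_b], axis=1).ravel()
        vals = np.tile(np.array([-1.0, 1.0]), self.n_faces)
        self.G = sp.csr_matrix((vals, (rows, cols)), shape=(self.n_faces, self.n_nodes))
        self.GT = self.G.T.tocsr()

        # --- missing-neighbour counts (disk rim) --------------------------
        if grid.geometry == DISK:
            pad = np.pad(mask, 1, constant_values=False)
            n_ext = (
                (~pad[:-2, 1:-1]).astype(float)
                + (~pad[2:, 1:-1])
                + (~pad[1:-1, :-2])
                + (~pad[1:-1, 2:])
            )
            self.n_ext = n_ext[mask]
            ring = grid.boundary_ring
            self.ring_idx = idx[ring[:, 0], ring[:, 1]]
        else:
            self.n_ext = np.zeros(self.n_nodes)
            self.ring_idx = np.empty(0, dtype=np.int64)

        self._L_neu = (-(self.GT @ self.G) / self.dx**2).tocsr()
        self._bih_cache: dict[tuple, tuple] = {}

    # -- array <-> vector ------------------------------------------------
    def to_vec(self, f) -> np.ndarray:
        arr = as_array(f)
        if arr.shape != self.grid.shape:
            raise ValueError(f"field shape {arr.shape} != grid shape {self.grid.shape}")
        return arr[self.grid.interior_mask].astype(float, copy=True)

    def from_vec(self, vec: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.grid.shape, fill)
        out[self.grid.interior_mask] = vec
        return out

    # -- Laplacian -------------------------------------------------------
    def laplacian_matrix(self, dirichlet: float | None = None):
        """5-point Laplacian as ``(matrix, affine)`` so that
        ``lap(f) = matrix @ f + affine``.

        ``dirichlet=None`` uses reflected ghosts (or periodic wrap);
        a float imposes that ghost value beyond the disk rim.
        """
        if dirichlet is None or self.grid.geometry != DISK:
            return self._L_neu, np.zeros(self.n_nodes)
        L = self._L_neu - sp.diags(self.n_ext) / self.dx**2
        aff = self.n_ext * dirichlet / self.dx**2
        return L.tocsr(), aff

    def lap(self, f, dirichlet: float | None = None) -> np.ndarray:
        L, aff = self.laplacian_matrix(dirichlet)
        return L @ self.to_vec(f) + aff

    # -- biharmonic ------------------------------------------------------
    def biharmonic_parts(self, h_dirichlet: float | None = None):
        """Biharmonic as ``(matrix, affine)``.

        For ``open_pinned`` the inner Laplacian uses the Dirichlet ghost
        ``h_dirichlet`` (defaults to the configured rim height), the rim value
        of the Laplacian is forced to zero (torque-free edge) and the outer
        Laplacian uses zero ghosts; otherwise both Laplacians use reflected
        ghosts / periodic wrap.
        """
        open_disk = self.grid.geometry == DISK and self.bc.is_open
        if open_disk and h_dirichlet is None:
            h_dirichlet = self.bc.h_edge
        key = (open_disk, h_dirichlet)
        if key in self._bih_cache:
            return self._bih_cache[key]
        if not open_disk:
            mat = (self._L_neu @ self._L_neu).tocsr()
            aff = np.zeros(self.n_nodes)
        else:
            L_in, a_in = self.laplacian_matrix(h_dirichlet)
            z = np.ones(self.n_nodes)
            z[self.ring_idx] = 0.0
            Z = sp.diags(z)
            L_out, _ = self.laplacian_matrix(0.0)
            mat = (L_out @ (Z @ L_in)).tocsr()
            aff = L_out @ (z * a_in)
        self._bih_cache[key] = (mat, aff)
        return mat, aff

    def bih(self, f, h_dirichlet: float | None = None) -> np.ndarray:
        mat, aff = self.biharmonic_parts(h_dirichlet)
        return mat @ self.to_vec(f) + aff

    # -- flux-form divergence -------------------------------------------
    def face_mean(self, node_vec: np.ndarray) -> np.ndarray:
        return 0.5 * (node_vec[self.face_a] + node_vec[self.face_b])

    def div_flux_vec(
        self,
        coef: np.ndarray,
        g: np.ndarray,
        dirichlet_g: float | None = None,
    ) -> np.ndarray:
        """``div(coef * grad g)`` on node vectors; arithmetic-mean face
        coefficients; optional Dirichlet value of ``g`` beyond the rim
        (mirrored coefficient), through which flux can leave the domain."""
        if np.any(coef < 0):
            raise ValueError("div_flux coefficient must be non-negative")
        cf = self.face_mean(coef)
        out = -(self.GT @ (cf * (self.G @ g))) / self.dx**2
        if dirichlet_g is not None and self.grid.geometry == DISK:
            out = out + coef * self.n_ext * (dirichlet_g - g) / self.dx**2
        return out

    def div_flux_matrix(self, coef: np.ndarray, dirichlet: bool = False):
        """Sparse matrix of ``g -> div(coef grad g)`` (affine part excluded;
        with ``dirichlet`` the rim-ghost value enters the affine term
        ``coef*n_ext*g_edge/dx^2`` handled by the caller)."""
        if np.any(coef < 0):
            raise ValueError("div_flux coefficient must be non-negative")
        cf = self.face_mean(coef)
        M = -(self.GT @ sp.diags(cf) @ self.G) / self.dx**2
        if dirichlet and self.grid.geometry == DISK:
            M = M - sp.diags(coef * self.n_ext) / self.dx**2
        return M.tocsr()

    # -- upwind transport -------------------------------------------------
    def transport_vec(
        self, C: np.ndarray, u_face: np.ndarray, conservative: bool = True
    ) -> np.ndarray:
        """Receptor transport tendency for face-normal velocities ``u_face``
        (positive from face_a to face_b).

        conservative: ``-div(C u)``; otherwise ``-u . grad C``.  Both use
        first-order upwind face values of ``C``.
        """
        C_up = np.where(u_face > 0, C[self.face_a], C[self.face_b])
        out = (self.GT @ (u_face * C_up)) / self.dx
        if not conservative:
            # -u.grad C = -div(Cu) + C div(u), with div(u) = -(G^T u)/dx
            out = out - C * ((self.GT @ u_face) / self.dx)
        return out

    def pressure_velocity_face(self, u_factor: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Face velocity ``u = -(u_factor) grad p`` with arithmetic-mean
        face factor."""
        return -self.face_mean(u_factor) * (self.G @ p) / self.dx

    def max_face_speed(self, u_face: np.ndarray) -> float:
        return float(np.max(np.abs(u_face))) if u_face.size else 0.0


@lru_cache(maxsize=8)
def get_discretization(grid: Grid, bc: BoundaryCondition | None = None) -> Discretization:
    return Discretization(grid, bc)


# ---------------------------------------------------------------------------
# public array-in / array-out operators
# ---------------------------------------------------------------------------


def _wrap(disc: Discretization, vec: np.ndarray, f) -> np.ndarray | Field:
    arr = disc.from_vec(vec, fill=0.0)
    if isinstance(f, Field):
        return Field(arr, f.role)
    return arr


def laplacian(f, grid: Grid, bc: BoundaryCondition | None = None,
              dirichlet: float | None = None):
    """Second-order 5-point Laplacian of a field."""
    disc = get_discretization(grid, bc)
    return _wrap(disc, disc.lap(as_array(f), dirichlet), f)


def biharmonic(f, grid: Grid, bc: BoundaryCondition | None = None,
               h_dirichlet: float | None = None):
    """Biharmonic (Laplacian applied twice) with the boundary closure of the
    active boundary condition."""
    disc = get_discretization(grid, bc)
    return _wrap(disc, disc.bih(as_array(f), h_dirichlet), f)


def div_flux(coef, g, grid: Grid, bc: BoundaryCondition | None = None,
             dirichlet_g: float | None = None):
    """Conservative flux-form divergence ``div(coef grad g)``."""
    disc = get_discretization(grid, bc)
    out = disc.div_flux_vec(disc.to_vec(coef), disc.to_vec(g), dirichlet_g)
    return _wrap(disc, out, g)


def advect(u_factor, p, C, grid: Grid, bc: BoundaryCondition | None = None,
           conservative: bool = False):
    """Pressure-driven receptor advection.

    Returns the tendency for velocity ``u = -(u_factor) grad p``: by default
    the characteristic form ``(u_factor) grad p . grad C = -u . grad C`` with
    first-order upwinding of ``grad C`` against the flow; with
    ``conservative=True`` the flux form ``-div(C u)``.
    """
    disc = get_discretization(grid, bc)
    uf = disc.pressure_velocity_face(disc.to_vec(u_factor), disc.to_vec(p))
    out = disc.transport_vec(disc.to_vec(C), uf, conservative=conservative)
    return _wrap(disc, out, C)
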