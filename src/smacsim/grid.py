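"""Discrete 2-D domains and scalar fields.

Two geometries are supported: a periodic unit square (cheap, used for
parameter sweeps and operator verification) and a disk of diameter 1 (in units
of the lateral domain size ``L``) embedded in the unit square by masking, which
mirrors the circular contact zone of a cell pressed against a bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["Grid", "Field", "PERIODIC_SQUARE", "DISK"]

PERIODIC_SQUARE = "periodic_square"
DISK = "disk"


@dataclass(frozen=True)
class Grid:
    """Uniform collocated Cartesian grid on [0, 1] x [0, ly].

    Parameters
    ----------
    n : points along x; the spacing is ``dx = 1/n`` (x-extent fixed at 1,
        i.e. one cell-contact diameter ``L``).
    geometry : ``"periodic_square"`` or ``"disk"``.  The disk is the centred
        inscribed disk of diameter 1; nodes outside it are masked off.
    ny : points along y (defaults to ``n``; must equal ``n`` for the disk).
    """

    n: int
    geometry: str = PERIODIC_SQUARE
    ny: int | None = None

    def __post_init__(self) -> None:
        if self.n < 16:
            raise ValueError(f"grid must have at least 16 points per side, got n={self.n}")
        if self.geometry not in (PERIODIC_SQUARE, DISK):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.ny is None:
            object.__setattr__(self, "ny", self.n)
        if self.geometry == DISK and self.ny != self.n:
            raise ValueError("disk geometry requires a square grid (ny == n)")

    @property
    def dx(self) -> float:
        return 1.0 / self.n

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape of fields on this grid, (ny, nx)."""
        return (self.ny, self.n)

    @cached_property
    def x(self) -> np.ndarray:
        """Cell-centre x coordinates, shape (ny, nx), units of L."""
        xs = (np.arange(self.n) + 0.5) * self.dx
        return np.broadcast_to(xs[None, :], self.shape).copy()

    @cached_property
    def y(self) -> np.ndarray:
        ys = (np.arange(self.ny) + 0.5) * self.dx
        return np.broadcast_to(ys[:, None], self.shape).copy()

    @cached_property
    def interior_mask(self) -> np.ndarray:
        """Boolean mask of active nodes."""
        if self.geometry == PERIODIC_SQUARE:
            return np.ones(self.shape, dtype=bool)
        r2 = (self.x - 0.5) ** 2 + (self.y - 0.5 * self.ny * self.dx) ** 2
        return r2 <= 0.25 + 1e-12

    @cached_property
    def boundary_ring(self) -> np.ndarray:
        """Indices (row, col) of active nodes with an inactive 4-neighbour,
        ordered by polar angle about the centre.  Empty for periodic grids."""
        if self.geometry == PERIODIC_SQUARE:
            return np.empty((0, 2), dtype=int)
        m = self.interior_mask
        pad = np.pad(m, 1, constant_values=False)
        nb_missing = (
            (~pad[:-2, 1:-1]) | (~pad[2:, 1:-1]) | (~pad[1:-1, :-2]) | (~pad[1:-1, 2:])
        )
        ring = m & nb_missing
        jj, ii = np.nonzero(ring)
        theta = np.arctan2(
            self.y[jj, ii] - 0.5 * self.ny * self.dx, self.x[jj, ii] - 0.5
        )
        order = np.argsort(theta, kind="stable")
        return np.stack([jj[order], ii[order]], axis=1)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dx

    def integrate(self, values: np.ndarray) -> float:
        """Domain integral of a field (masked sum times cell area)."""
        return float(np.sum(values[self.interior_mask]) * self.cell_area)

    def validate_field(self, values: np.ndarray) -> None:
        if values.shape != self.shape:
            raise ValueError(f"field shape {values.shape} does not match grid {self.shape}")
        if not np.all(np.isfinite(values[self.interior_mask])):
            raise ValueError("field contains non-finite values on the interior mask")


@dataclass
class Field:
    """A scalar field on a grid with a semantic role.

    Thin wrapper used at API boundaries; the numerical kernels operate on the
    bare ``values`` array.
    """

    values: np.ndarray
    role: str = "generic"  # height | pressure | density1 | density2 | generic

    @staticmethod
    def full(grid: Grid, fill: float, role: str = "generic") -> "Field":
        return Field(np.full(grid.shape, float(fill)), role)


def as_array(f) -> np.ndarray:
    """Accept a Field or a bare ndarray."""
    return f.values if isinstance(f, Field) else np.asarray(f, dtype=float)
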