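"""Membrane mechanics and lubrication flow (dimensionless form).

The membrane pressure balances bending, optional tension, and the two
receptor-spring populations,

    p = B lap^2 h - Gamma eps^2 lap h + C1 (h - lam1) + lam1 C2 (h - 1),

with h in units of the long-bond length l2, densities in units of C0 and
pressure in units of p0 = C0 kappa l2.  The factor lam1 = l1/l2 in front of
the C2 spring term is the softer stiffness of the longer bond
(kappa_2 = (l1/l2) kappa).  Fluid drainage in the cleft follows the thin-film
lubrication law, which after the same scalings reads

    dh/dt = (eps^2 / 12) div( h^3 grad p ),

with time in units of the hydrodynamic drainage time tau_mu and eps = l2/L.

``dispersion_rate`` is the closed-form linear relaxation rate of a small
height perturbation about a flat film with frozen uniform densities; it is
negative for every wavenumber (bending, tension and springs are all
stabilising) and serves as an independent oracle for the time integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .boundary import BoundaryCondition
from .grid import DISK, Field, Grid
from .operators import Discretization, get_discretization

__all__ = [
    "MechanicsConfig",
    "PositivityError",
    "pressure",
    "height_rhs",
    "dispersion_rate",
    "pressure_operator",
]


class PositivityError(RuntimeError):
    """Raised when the film height loses positivity."""


@dataclass(frozen=True)
class MechanicsConfig:
    """Dimensionless mechanics groups.

    B : bending/spring pressure ratio; Gamma : tension/spring ratio;
    lam1 : bond-length ratio l1/l2; eps : gap aspect ratio l2/L.
    """

    B: float
    eps: float
    lam1: float = 1.0 / 3.0
    Gamma: float = 0.0

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise ValueError("B must be positive")
        if not 0 < self.lam1 < 1:
            raise ValueError("lam1 must lie in (0, 1)")
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if self.Gamma < 0:
            raise ValueError("Gamma must be non-negative")

    @classmethod
    def from_groups(cls, groups) -> "MechanicsConfig":
        return cls(B=groups.B, eps=groups.eps, lam1=groups.lam1, Gamma=groups.Gamma)


def pressure_operator(disc: Discretization, C1: np.ndarray, C2: np.ndarray,
                      cfg: MechanicsConfig):
    """Affine map ``h -> p`` as ``(matrix, affine)`` on node vectors.

    For the open (pinned) disk boundary the rim rows are replaced by the
    Dirichlet pressure value, so the lubrication flux at the first interior
    node sees the rim pressure.
    """
    bih_mat, bih_aff = disc.biharmonic_parts()
    spring_diag = C1 + cfg.lam1 * C2
    mat = cfg.B * bih_mat + sp.diags(spring_diag)
    aff = cfg.B * bih_aff - (C1 * cfg.lam1 + cfg.lam1 * C2)
    if cfg.Gamma > 0:
        h_dir = disc.bc.h_edge if (disc.grid.geometry == DISK and disc.bc.is_open) else None
        L, L_aff = disc.laplacian_matrix(h_dir)
        mat = mat - cfg.Gamma * cfg.eps**2 * L
        aff = aff - cfg.Gamma * cfg.eps**2 * L_aff
    if disc.grid.geometry == DISK and disc.bc.is_open:
        keep = np.ones(disc.n_nodes)
        keep[disc.ring_idx] = 0.0
        mat = sp.diags(keep) @ mat
        aff = keep * aff
        aff[disc.ring_idx] = disc.bc.p_edge
    return mat.tocsr(), aff


def pressure(h, C1, C2, cfg: MechanicsConfig, grid: Grid,
             bc: BoundaryCondition | None = None):
    """Membrane pressure field from height and bound densities."""
    disc = get_discretization(grid, bc)
    mat, aff = pressure_operator(disc, disc.to_vec(C1), disc.to_vec(C2), cfg)
    p = mat @ disc.to_vec(h) + aff
    out = disc.from_vec(p, fill=0.0)
    return Field(out, "pressure") if isinstance(h, Field) else out


def height_rhs(h, p, cfg: MechanicsConfig, grid: Grid,
               bc: BoundaryCondition | None = None):
    """Lubrication drainage tendency ``(eps^2/12) div(h^3 grad p)``."""
    disc = get_discretization(grid, bc)
    hv = disc.to_vec(h)
    if np.any(hv <= 0):
        raise PositivityError("film height must be strictly positive")
    bc_ = disc.bc
    dirichlet_p = bc_.p_edge if (grid.geometry == DISK and bc_.is_open) else None
    out = cfg.eps**2 / 12.0 * disc.div_flux_vec(hv**3, disc.to_vec(p), dirichlet_p)
    arr = disc.from_vec(out, fill=0.0)
    return Field(arr, "height") if isinstance(h, Field) else arr


def dispersion_rate(k: float, h0: float, C1: float, C2: float,
                    cfg: MechanicsConfig) -> float:
    """Linear relaxation rate of mode ``exp(i k x)`` about a flat film.

    omega(k) = -(eps^2/12) h0^3 k^2 (B k^4 + Gamma eps^2 k^2 + C1 + lam1 C2),
    in units of 1/tau_mu; always non-positive.
    """
    if k <= 0 or h0 <= 0:
        raise ValueError("k and h0 must be positive")
    stiff = cfg.B * k**4 + cfg.Gamma * cfg.eps**2 * k**2 + C1 + cfg.lam1 * C2
    return -(cfg.eps**2 / 12.0) * h0**3 * k**2 * stiff
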