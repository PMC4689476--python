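"""Height-gated receptor binding kinetics and bound-density transport.

Bond formation and rupture are gated by the local gap height: a receptor of
natural length l_i binds fastest where the membranes are separated by exactly
l_i, with Gaussian fall-off of relative width sigma_on (and a three-fold
slower, broader off-rate of width sigma_off).  In units of 1/tau_mu,

    K_on  = tau exp(-((lam - h)/(sigma_on  lam))^2)
    K_off = (tau/3) exp(-((lam - h)/(sigma_off lam))^2)

with lam = l_i/l2 and tau = tau_mu/tau_k.  sigma_off = inf selects the
constant-off-rate variant.  This gating is what sorts the two bond species
into non-overlapping domains: at the tall-bond height the short bond can
neither form nor (once formed elsewhere) break, and vice versa.

The full bound-density tendency combines pressure-driven advection, molecular
diffusion, thermodynamic sliding down height gradients, and the binding
source, each nondimensionalised with D_i = (l1/l_i) D and
kappa_i = (l1/l_i) kappa:

    dC/dt = -div(C u) + (lam1/lam)(1/Pe) lap C
            + (eps^2/M)(lam1/lam)^2 div(C (h - lam) grad h)
            + (ctot - C) K_on - C K_off,        u = -eps^2 lam h grad p.

The free receptor pool is well mixed: only the bound density is a field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boundary import BoundaryCondition
from .grid import Field, Grid, as_array
from .operators import Discretization, get_discretization

__all__ = [
    "KineticsConfig",
    "on_rate",
    "off_rate",
    "kinetics_fixed_point",
    "concentration_rhs",
    "transport_face_velocity",
]


@dataclass(frozen=True)
class KineticsConfig:
    """Per-species kinetic and transport groups (dimensionless).

    lam is l_i/l2 (lam1 for the short species, 1 for the long one); ctot the
    total density C_{i,0}/C0.  off_factor is the on/off prefactor ratio
    (bonds break ``off_factor`` times slower than they form).
    """

    tau: float
    lam: float
    ctot: float
    sigma_on: float = 0.2
    sigma_off: float = 0.6
    off_factor: float = 3.0
    Pe: float = 5.4e4
    M: float = 2.0
    eps: float = 4.5e-3
    lam1: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not self.tau >= 0:  # tau = 0 switches the kinetics off entirely
            raise ValueError("tau must be non-negative")
        if not self.sigma_on > 0:
            raise ValueError("sigma_on must be positive")
        if not self.sigma_off > 0:
            raise ValueError("sigma_off must be positive (inf allowed)")
        if not self.off_factor > 0:
            raise ValueError("off_factor must be positive")
        if not 0 < self.lam <= 1:
            raise ValueError("lam must lie in (0, 1]")
        if not self.ctot > 0:
            raise ValueError("ctot must be positive")

    @classmethod
    def for_species(cls, groups, species: int, tau: float | None = None) -> "KineticsConfig":
        """Build the config of species 1 (short bond) or 2 (long bond) from a
        :class:`~smacsim.parameters.DimensionlessGroups`."""
        if species == 1:
            lam, ctot = groups.lam1, groups.c10
        elif species == 2:
            lam, ctot = 1.0, groups.c20
        else:
            raise ValueError("species must be 1 or 2")
        return cls(
            tau=groups.tau if tau is None else tau,
            lam=lam,
            ctot=ctot,
            sigma_on=groups.sigma_on,
            sigma_off=groups.sigma_off,
            Pe=groups.Pe,
            M=groups.M,
            eps=groups.eps,
            lam1=groups.lam1,
        )


def _gauss(h: np.ndarray, lam: float, sigma: float) -> np.ndarray:
    if math.isinf(sigma):
        return np.ones_like(h)
    z = (lam - h) / (sigma * lam)
    return np.exp(-(z * z))


def on_rate(h, cfg: KineticsConfig):
    """Binding rate K_on(h) in units of 1/tau_mu (peaked at h = lam)."""
    arr = as_array(h)
    out = cfg.tau * _gauss(arr, cfg.lam, cfg.sigma_on)
    return Field(out, "generic") if isinstance(h, Field) else out


def off_rate(h, cfg: KineticsConfig):
    """Unbinding rate K_off(h) in units of 1/tau_mu; constant tau/off_factor
    when sigma_off is infinite."""
    arr = as_array(h)
    out = (cfg.tau / cfg.off_factor) * _gauss(arr, cfg.lam, cfg.sigma_off)
    return Field(out, "generic") if isinstance(h, Field) else out


def kinetics_fixed_point(h, cfg: KineticsConfig, with_flag: bool = False):
    """Pointwise equilibrium bound density ctot K_on/(K_on + K_off).

    Where both rates underflow (gap far from the bond length) the fixed point
    is reported as 0; ``with_flag=True`` additionally returns the validity
    mask (False where the rates vanished).
    """
    arr = np.asarray(as_array(h), dtype=float)
    kon = on_rate(arr, cfg)
    koff = off_rate(arr, cfg)
    denom = kon + koff
    ok = denom > 0
    out = np.zeros_like(arr)
    np.divide(cfg.ctot * kon, denom, out=out, where=ok)
    if arr.ndim == 0:
        out = float(out)
        ok = bool(ok)
    if with_flag:
        return out, ok
    return out


def transport_face_velocity(disc: Discretization, h: np.ndarray, p: np.ndarray,
                            cfg: KineticsConfig) -> np.ndarray:
    """Total face-normal drift velocity (advection + sliding) of one species.

    Advection by the cleft flow, u_adv = -eps^2 lam h grad p, plus the
    Einstein-relation sliding drift u_sl = -(eps^2/M)(lam1/lam)^2 (h-lam) grad h.
    """
    u_adv = disc.pressure_velocity_face(cfg.eps**2 * cfg.lam * h, p)
    slide_coef = (cfg.eps**2 / cfg.M) * (cfg.lam1 / cfg.lam) ** 2
    u_sl = -slide_coef * (disc.face_mean(h) - cfg.lam) * (disc.G @ h) / disc.dx
    return u_adv + u_sl


def concentration_rhs(h, p, C, cfg: KineticsConfig, grid: Grid,
                      bc: BoundaryCondition | None = None,
                      conservative: bool = True):
    """Full bound-density tendency dC/dt for one species.

    Used directly by tests and explicit diagnostics; the production stepper
    applies the same pieces in split (IMEX) form.
    """
    disc = get_discretization(grid, bc)
    hv, pv, Cv = disc.to_vec(h), disc.to_vec(p), disc.to_vec(C)
    tol = 1e-9
    if np.any(Cv < -tol) or np.any(Cv > cfg.ctot + tol):
        raise ValueError("bound density outside [0, ctot]")
    if np.any(hv <= 0):
        raise ValueError("film height must be strictly positive")

    u = transport_face_velocity(disc, hv, pv, cfg)
    out = disc.transport_vec(Cv, u, conservative=conservative)
    nu = (cfg.lam1 / cfg.lam) / cfg.Pe
    out = out + nu * disc.lap(disc.from_vec(Cv, fill=0.0))
    out = out + (cfg.ctot - Cv) * on_rate(hv, cfg) - Cv * off_rate(hv, cfg)
    arr = disc.from_vec(out, fill=0.0)
    return Field(arr, "generic") if isinstance(C, Field) else arr
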