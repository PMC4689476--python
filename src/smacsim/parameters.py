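"""Dimensional parameters, dimensionless groups and scaling-law predictions.

The model lives in the narrow fluid cleft between a T-cell membrane and a
ligand-coated substrate.  Two bond species span the gap: TCR-pMHC (species 1,
natural length ``l1`` ~ 15 nm) and LFA-ICAM (species 2, ``l2`` ~ 45 nm).
Everything downstream of this module works in dimensionless variables:
horizontal lengths in units of the cell size ``L``, the gap height in units of
``l2``, pressure in units of ``p0 = C0*kappa*l2``, time in units of the
hydrodynamic drainage time ``tau_mu = mu/(C0*kappa*l2)`` and densities in units
of the reference receptor density ``C0``.

This module is the single place where dimensional constants enter; it computes
the dimensionless groups that the solver consumes and the closed-form scaling
predictions (cluster size ``l_c``, cluster drainage time ``tau_c``, cell-scale
drainage time ``tau_L``) used to interpret simulations.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "PhysicalParameters",
    "DimensionlessGroups",
    "ScalingPredictions",
    "InvalidParameterError",
    "bending_modulus",
    "dimensionless_groups",
    "scaling_predictions",
    "nondimensionalize",
    "dimensionalize",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]


class InvalidParameterError(ValueError):
    """Raised when a physical parameter set violates its invariants."""


# Hydrodynamic time for the default set is tau_mu = mu/(C0*kappa*l2) = 3.7037e-3 s;
# the default kinetic time is chosen as tau_mu/15 so that the default
# dimensionless ratio tau = tau_mu/tau_k equals the baseline value 15.
_DEFAULT_TAU_K = 4e-2 / (2e14 * 1.2e-6 * 45e-9) / 15.0


@dataclass(frozen=True)
class PhysicalParameters:
    """Dimensional material constants (SI units throughout).

    Attributes
    ----------
    mu : fluid viscosity of the cleft fluid, Pa*s.
    E : membrane Young's modulus, Pa.  The default reproduces a bending
        modulus Bm = E*b^3/(12*(1-nu^2)) of 4.5e-21 J.
    b : membrane thickness, m.
    nu : Poisson ratio of the membrane (0 < nu < 1).
    kappa : reference protein spring stiffness, N/m.  Species stiffnesses are
        kappa_i = (l1/l_i)*kappa (softer for longer bonds).
    C0 : reference receptor number density, 1/m^2.
    C10, C20 : total (bound + free) densities of species 1 and 2, 1/m^2.
    l1, l2 : natural bond lengths of species 1 and 2, m (l1 < l2).
    D : reference in-membrane diffusivity, m^2/s; D_i = (l1/l_i)*D.
    tau_k : kinetic on-time, s (bond formation time at optimal gap height).
    L : lateral domain (cell contact) size, m.
    kBT : thermal energy, J.
    gamma : membrane tension, N/m (0 disables the tension term).
    sigma_on, sigma_off : relative widths of the height-gated on/off rate
        distributions (dimensionless).
    """

    mu: float = 4e-2
    E: float = 79101.5625  # gives Bm = E b^3/(12(1-nu^2)) = 4.5e-21 J
    b: float = 8e-9
    nu: float = 0.5
    kappa: float = 1.2e-6
    C0: float = 2e14
    C10: float = 2e14
    C20: float = 4e14
    l1: float = 15e-9
    l2: float = 45e-9
    D: float = 5e-13
    tau_k: float = _DEFAULT_TAU_K
    L: float = 1e-5
    kBT: float = 4.34e-21
    gamma: float = 0.0
    sigma_on: float = 0.2
    sigma_off: float = 0.6

    def __post_init__(self) -> None:
        positive = (
            "mu", "E", "b", "kappa", "C0", "C10", "C20",
            "l1", "l2", "D", "tau_k", "L", "kBT", "sigma_on",
        )
        for name in positive:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
        if not 0 < self.nu < 1:
            raise InvalidParameterError(f"nu must lie in (0, 1), got {self.nu!r}")
        if not self.l1 < self.l2:
            raise InvalidParameterError("l1 must be smaller than l2")
        if self.gamma < 0:
            raise InvalidParameterError("gamma must be non-negative")
        # sigma_off may be math.inf (constant off-rate variant)
        if not self.sigma_off > 0:
            raise InvalidParameterError("sigma_off must be positive (inf allowed)")

    # derived per-species quantities -------------------------------------
    def kappa_i(self, species: int) -> float:
        """Spring stiffness of species ``i``: kappa_i = (l1/l_i)*kappa."""
        return self.kappa * self.l1 / self._li(species)

    def D_i(self, species: int) -> float:
        """Diffusivity of species ``i``: D_i = (l1/l_i)*D."""
        return self.D * self.l1 / self._li(species)

    def _li(self, species: int) -> float:
        if species == 1:
            return self.l1
        if species == 2:
            return self.l2
        raise ValueError(f"species must be 1 or 2, got {species!r}")

    @property
    def tau_mu(self) -> float:
        """Hydrodynamic drainage time mu/(C0*kappa*l2), s."""
        return self.mu / (self.C0 * self.kappa * self.l2)

    @property
    def p0(self) -> float:
        """Pressure scale C0*kappa*l2, Pa."""
        return self.C0 * self.kappa * self.l2


@dataclass(frozen=True)
class DimensionlessGroups:
    """Dimensionless numbers governing the patterning dynamics.

    ``B`` (bending/spring pressure ratio) and ``tau`` (hydrodynamic/kinetic
    time ratio) are the two control parameters of the phase diagram; the rest
    enter quantitatively but not qualitatively.
    """

    B: float
    eps: float          # l2 / L, gap aspect ratio
    lam1: float         # l1 / l2
    Pe: float           # advection / diffusion
    M: float            # sliding mobility / diffusion
    tau: float          # tau_mu / tau_k
    Gamma: float = 0.0  # tension / spring pressure ratio
    c10: float = 1.0    # C10 / C0
    c20: float = 2.0    # C20 / C0
    sigma_on: float = 0.2
    sigma_off: float = 0.6

    def __post_init__(self) -> None:
        for name in ("B", "eps", "lam1", "Pe", "M", "tau"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.Gamma < 0:
            raise InvalidParameterError("Gamma must be non-negative")


@dataclass(frozen=True)
class ScalingPredictions:
    """Closed-form scaling-law predictions (SI units)."""

    tau_mu: float  # hydrodynamic time, s
    p0: float      # pressure scale, Pa
    Bm: float      # bending modulus, J
    l_c: float     # cluster length (Bm/(C0*kappa))^(1/4), m
    tau_c: float   # cluster drainage time 12*(l_c/l2)^2*tau_mu, s
    tau_L: float   # cell-scale drainage time 12*(L/l2)^2*tau_mu, s


def bending_modulus(params: PhysicalParameters) -> float:
    """Bending modulus Bm = E*b^3 / (12*(1 - nu^2)) in joules."""
    if not (params.E > 0 and params.b > 0):
        raise InvalidParameterError("E and b must be strictly positive")
    return params.E * params.b**3 / (12.0 * (1.0 - params.nu**2))


def dimensionless_groups(params: PhysicalParameters) -> DimensionlessGroups:
    """Compute every dimensionless group from a dimensional parameter set."""
    Bm = bending_modulus(params)
    denom_B = params.kappa * params.C0 * params.L**4
    Dmu = params.D * params.mu
    if denom_B == 0 or Dmu == 0 or params.l2 == 0 or params.tau_k == 0:
        raise InvalidParameterError("zero denominator in dimensionless group")
    return DimensionlessGroups(
        B=Bm / denom_B,
        eps=params.l2 / params.L,
        lam1=params.l1 / params.l2,
        Pe=params.L**2 * params.C0 * params.kappa * params.l2 / Dmu,
        M=params.kBT * params.C0 * params.l2 / Dmu,
        tau=params.tau_mu / params.tau_k,
        Gamma=params.gamma / (params.kappa * params.C0 * params.l2**2),
        c10=params.C10 / params.C0,
        c20=params.C20 / params.C0,
        sigma_on=params.sigma_on,
        sigma_off=params.sigma_off,
    )


def scaling_predictions(params: PhysicalParameters) -> ScalingPredictions:
    """Evaluate the length and time scaling laws.

    ``l_c = (Bm/(C0*kappa))^(1/4)`` balances bending and spring pressure;
    drainage times carry the lubrication prefactor 12:
    ``tau_c = 12*(l_c/l2)^2*tau_mu`` and ``tau_L = 12*(L/l2)^2*tau_mu``.
    """
    Bm = bending_modulus(params)
    tau_mu = params.tau_mu
    l_c = (Bm / (params.C0 * params.kappa)) ** 0.25
    return ScalingPredictions(
        tau_mu=tau_mu,
        p0=params.p0,
        Bm=Bm,
        l_c=l_c,
        tau_c=12.0 * (l_c / params.l2) ** 2 * tau_mu,
        tau_L=12.0 * (params.L / params.l2) ** 2 * tau_mu,
    )


_SCALE_KINDS = ("length_xy", "height", "pressure", "time", "density")


def _scale(params: PhysicalParameters, kind: str) -> float:
    if kind == "length_xy":
        return params.L
    if kind == "height":
        return params.l2
    if kind == "pressure":
        return params.p0
    if kind == "time":
        return params.tau_mu
    if kind == "density":
        return params.C0
    raise ValueError(f"unknown kind {kind!r}; expected one of {_SCALE_KINDS}")


def nondimensionalize(params: PhysicalParameters, quantity, kind: str):
    """Divide a dimensional quantity by its characteristic scale."""
    return quantity / _scale(params, kind)


def dimensionalize(params: PhysicalParameters, quantity, kind: str):
    """Inverse of :func:`nondimensionalize`."""
    return quantity * _scale(params, kind)


# ---------------------------------------------------------------------------
# flat TOML config I/O
# ---------------------------------------------------------------------------

_FIELDS = [f.name for f in dataclasses.fields(PhysicalParameters)]


def load_parameters(path) -> PhysicalParameters:
    """Read a flat key = value TOML file into :class:`PhysicalParameters`.

    Unknown keys are rejected.  ``sigma_off = "inf"`` selects the constant
    off-rate variant.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return parameters_from_dict(raw)


def parameters_from_dict(raw: dict) -> PhysicalParameters:
    unknown = set(raw) - set(_FIELDS)
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
    clean = {}
    for key, value in raw.items():
        if isinstance(value, str) and value.lower() in ("inf", "infinity"):
            value = math.inf
        clean[key] = float(value)
    return PhysicalParameters(**clean)


def save_parameters(params: PhysicalParameters, path) -> None:
    """Write parameters as a flat TOML file (keys named as the fields)."""
    lines = []
    for name in _FIELDS:
        value = getattr(params, name)
        if math.isinf(value):
            lines.append(f'{name} = "inf"')
        else:
            lines.append(f"{name} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def default_parameters() -> PhysicalParameters:
    """The packaged default parameter set (read from the shipped TOML file)."""
    ref = resources.files("smacsim.data") / "default_params.toml"
    with resources.as_file(ref) as path:
        return load_parameters(path)
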