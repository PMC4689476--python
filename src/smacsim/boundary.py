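"""Boundary-condition variants at the synapse edge.

``open_pinned`` is the default condition: the membrane is pinned at half the
long-bond height, the edge is torque free (zero Laplacian of the height),
pressure is atmospheric so fluid drains freely through the rim, and the bound
densities are held at their far-field equilibrium.  ``closed_free`` instead
seals the rim: no fluid flux, no bending moment or shear force, and no
receptor flux, which conserves cleft volume and arrests the pattern.

On periodic grids the variant is irrelevant (there is no edge).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BoundaryCondition", "OPEN_PINNED", "CLOSED_FREE"]

OPEN_PINNED = "open_pinned"
CLOSED_FREE = "closed_free"


@dataclass(frozen=True)
class BoundaryCondition:
    """Edge treatment for disk domains.

    Attributes
    ----------
    variant : ``"open_pinned"`` (Dirichlet h, p, C at the rim) or
        ``"closed_free"`` (reflected ghosts: zero flux of fluid and receptors,
        zero bending moment and force).
    h_edge : pinned rim height in units of l2 (open variant).
    p_edge : rim pressure in units of p0 (open variant).
    C_edge : rim bound density in units of C0 (open variant; both species).
    """

    variant: str = OPEN_PINNED
    h_edge: float = 0.5
    p_edge: float = 0.0
    C_edge: float = 0.01

    def __post_init__(self) -> None:
        if self.variant not in (OPEN_PINNED, CLOSED_FREE):
            raise ValueError(f"unknown boundary variant {self.variant!r}")
        if self.h_edge <= 0:
            raise ValueError("h_edge must be positive")

    @property
    def is_open(self) -> bool:
        return self.variant == OPEN_PINNED
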