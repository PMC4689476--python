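"""Phase-diagram sweeps over the (tau, B) control plane.

Each sweep cell runs the coupled solver from the standard six-bump initial
condition to the evaluation time (40 dimensional minutes by default, the
stage of a mature synapse) and classifies the final pattern.  Failures in
individual cells are recorded and the sweep continues.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import pandas as pd

from .boundary import BoundaryCondition
from .engine import InitialCondition, SolverConfig, simulate
from .grid import Grid
from .parameters import DimensionlessGroups, PhysicalParameters, default_parameters, dimensionless_groups
from .patterns import AnalysisConfig, classify_pattern, report_row

logger = logging.getLogger(__name__)

__all__ = ["phase_diagram", "sweep_point"]


def sweep_point(
    tau: float,
    B: float,
    grid: Grid,
    bc: BoundaryCondition,
    ic: InitialCondition,
    solver: SolverConfig,
    base_groups: DimensionlessGroups | None = None,
    analysis: AnalysisConfig | None = None,
):
    """Run one (tau, B) cell; returns ``(final_state, PatternReport)``."""
    base = base_groups if base_groups is not None else dimensionless_groups(default_parameters())
    groups = dataclasses.replace(base, tau=tau, B=B)
    state, _ = simulate(groups, grid, ic, bc, solver)
    return state, classify_pattern(state, grid, groups, analysis)


def phase_diagram(
    tau_list,
    B_list,
    grid: Grid,
    bc: BoundaryCondition | None = None,
    ic: InitialCondition | None = None,
    solver: SolverConfig | None = None,
    base_groups: DimensionlessGroups | None = None,
    params: PhysicalParameters | None = None,
    analysis: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Run the grid of simulations and classify each cell.

    Duplicate (tau, B) pairs are deduplicated with a warning; a failing cell
    is recorded with regime ``"failed"`` and the sweep continues.  The
    default evaluation time is 40 dimensional minutes.
    """
    params = params if params is not None else default_parameters()
    bc = bc if bc is not None else BoundaryCondition()
    ic = ic if ic is not None else InitialCondition()
    if solver is None:
        solver = SolverConfig(t_end=40.0 * 60.0 / params.tau_mu)

    pairs: list[tuple[float, float]] = []
    for tau in tau_list:
        for B in B_list:
            if (tau, B) in pairs:
                warnings.warn(f"duplicate sweep cell (tau={tau}, B={B}) skipped")
                continue
            pairs.append((float(tau), float(B)))
    if not pairs:
        raise ValueError("empty sweep")

    rows = []
    for tau, B in pairs:
        try:
            _, report = sweep_point(tau, B, grid, bc, ic, solver, base_groups, analysis)
            rows.append(report_row(tau, B, report))
            logger.info("sweep cell tau=%g B=%g -> %s", tau, B, report.regime)
        except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
            logger.warning("sweep cell tau=%g B=%g failed: %s", tau, B, exc)
            rows.append({"tau": tau, "B": B, "regime": "failed"})
    return pd.DataFrame(rows)
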