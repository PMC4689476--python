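"""Quantitative pattern metrics: receptor totals, cluster inventory,
SMAC (bulls-eye) detection, regime classification and phase-diagram sweeps.

The simulated patterns are categorised into the experimentally motivated
regimes of the (tau, B) phase diagram:

* ``no_pattern`` - binding too slow relative to drainage; densities stay
  quasi-uniform and low;
* ``intermediate`` - long-lived LFA-rich clusters with diffuse structure;
* ``kinetic_clusters`` - dispersed micro-scale TCR clusters;
* ``bullseye`` - the mature synapse: a central TCR-rich disk surrounded by
  an LFA-rich annulus (cSMAC/pSMAC).

None of these labels has a unique quantitative definition in the field, so
the thresholds used here (density fraction 0.3 for a cluster, 4-pixel minimum
cluster, 0.2 max-density cutoff for "no pattern", 60% angular coverage for
the annulus) are fixed documented constants, exposed in :class:`AnalysisConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .engine import State
from .grid import Grid, as_array
from .parameters import PhysicalParameters

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "ClusterSet",
    "PatternReport",
    "AnalysisConfig",
    "bound_totals",
    "find_clusters",
    "classify_pattern",
    "cluster_size_scaling",
    "REGIMES",
]

REGIMES = ("no_pattern", "intermediate", "kinetic_clusters", "bullseye")

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class AnalysisConfig:
    """Fixed constants of the pattern metrics."""

    threshold_frac: float = 0.3   # cluster = connected C > frac*ctot
    min_pixels: int = 4           # discard smaller components
    no_pattern_frac: float = 0.2  # no pattern if max C1 below frac*ctot
    annulus_coverage: float = 0.6  # bulls-eye needs >= this angle fraction of LFA
    n_angle_bins: int = 36


@dataclass(frozen=True)
class Cluster:
    """One connected super-threshold component of a bound-density field."""

    label: int
    area: float                 # L^2 units
    equiv_diameter: float       # L units; diameter of the equal-area disk
    centroid: tuple[float, float]  # (x, y) in L units
    mean_density: float         # C0 units
    n_pixels: int
    species: int

    def receptor_count(self, params: PhysicalParameters) -> float:
        """Absolute number of receptors in the cluster."""
        return self.mean_density * self.area * params.C0 * params.L**2


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    species: int
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def total_area(self) -> float:
        return sum(c.area for c in self.clusters)

    @property
    def mean_diameter(self) -> float:
        if not self.clusters:
            return float("nan")
        return float(np.mean([c.equiv_diameter for c in self.clusters]))


@dataclass
class PatternReport:
    regime: str
    n_clusters_1: int
    n_clusters_2: int
    mean_diameter_1: float   # L units
    mean_diameter_2: float
    tcr_centroid_radius: float  # L units, offset of the C1 centroid from the domain centre
    lfa_ring_coverage: float    # fraction of angular bins occupied
    overlap_index: float        # max(C1*C2)/(ctot1*ctot2)


def bound_totals(state: State, grid: Grid, params: PhysicalParameters,
                 ctot_scale: float = 1.0) -> tuple[float, float]:
    """Absolute bound-receptor counts (N1, N2) = (sum C_i dx^2) * C0 * L^2."""
    m = grid.interior_mask
    a = grid.cell_area
    factor = params.C0 * params.L**2
    n1 = float(np.sum(state.C1[m]) * a) * factor
    n2 = float(np.sum(state.C2[m]) * a) * factor
    return n1, n2


def find_clusters(C, grid: Grid, ctot: float, threshold_frac: float = 0.3,
                  min_pixels: int = 4, species: int = 0) -> ClusterSet:
    """Connected components (8-connectivity) of ``C > threshold_frac*ctot``.

    Components smaller than ``min_pixels`` pixels are discarded.  Areas and
    diameters are in units of L (the domain side).
    """
    arr = as_array(C)
    mask = np.zeros(grid.shape, dtype=bool)
    m = grid.interior_mask
    if np.any(arr[m] < -1e-9) or np.any(arr[m] > ctot * (1 + 1e-6) + 1e-9):
        raise ValueError("density outside [0, ctot]")
    mask[m] = arr[m] > threshold_frac * ctot
    labels, n = ndimage.label(mask, structure=_EIGHT)
    clusters = []
    if n:
        idx = np.arange(1, n + 1)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, idx)
        means = ndimage.mean(arr, labels, idx)
        coms = ndimage.center_of_mass(mask, labels, idx)  # (row, col)
        a_cell = grid.cell_area
        for lab, npix, mean, com in zip(idx, sizes, means, coms):
            if npix < min_pixels:
                continue
            area = float(npix) * a_cell
            clusters.append(
                Cluster(
                    label=int(lab),
                    area=area,
                    equiv_diameter=float(2.0 * np.sqrt(area / np.pi)),
                    centroid=((com[1] + 0.5) * grid.dx, (com[0] + 0.5) * grid.dx),
                    mean_density=float(mean),
                    n_pixels=int(npix),
                    species=species,
                )
            )
    return ClusterSet(clusters, species, threshold_frac * ctot)


def _center(grid: Grid) -> tuple[float, float]:
    return 0.5, 0.5 * grid.ny * grid.dx


def classify_pattern(state: State, grid: Grid, groups,
                     cfg: AnalysisConfig | None = None) -> PatternReport:
    """Classify a late-time state into one of the phase-diagram regimes.

    Decision rules (operational definitions): ``no_pattern`` if the TCR field
    never exceeds ``no_pattern_frac*ctot1``; ``bullseye`` if a TCR cluster
    covers the domain centre while LFA occupies at least
    ``annulus_coverage`` of the angular bins at larger radius;
    ``kinetic_clusters`` if at least 3 disjoint TCR clusters exist without a
    bulls-eye; otherwise ``intermediate``.
    """
    cfg = cfg if cfg is not None else AnalysisConfig()
    ctot1, ctot2 = groups.c10, groups.c20
    m = grid.interior_mask
    C1 = np.where(m, np.nan_to_num(state.C1, nan=0.0), 0.0)
    C2 = np.where(m, np.nan_to_num(state.C2, nan=0.0), 0.0)

    cs1 = find_clusters(C1, grid, ctot1, cfg.threshold_frac, cfg.min_pixels, species=1)
    cs2 = find_clusters(C2, grid, ctot2, cfg.threshold_frac, cfg.min_pixels, species=2)

    cx, cy = _center(grid)
    r = np.hypot(grid.x - cx, grid.y - cy)
    theta = np.arctan2(grid.y - cy, grid.x - cx)

    # density-weighted TCR centroid offset (asymmetry diagnostic)
    w1 = C1.sum()
    if w1 > 0:
        tcr_rad = float(np.hypot((C1 * grid.x).sum() / w1 - cx,
                                 (C1 * grid.y).sum() / w1 - cy))
    else:
        tcr_rad = float("nan")

    # central TCR cluster: one whose equivalent circle covers the domain
    # centre (robust to pixel-scale holes and mild asymmetry)
    mask1 = C1 > cfg.threshold_frac * ctot1
    labels1, _ = ndimage.label(mask1, structure=_EIGHT)
    central_label, r_central = 0, 0.0
    for c in cs1:
        off = np.hypot(c.centroid[0] - cx, c.centroid[1] - cy)
        if off < c.equiv_diameter / 2:
            central_label = c.label
            r_central = float(np.max(r[labels1 == c.label]))
            break
    has_central = central_label > 0

    # LFA angular coverage outside the central cluster radius
    mask2 = (C2 > cfg.threshold_frac * ctot2) & (r > r_central)
    if mask2.any():
        bins = ((theta[mask2] + np.pi) / (2 * np.pi) * cfg.n_angle_bins).astype(int)
        bins = np.clip(bins, 0, cfg.n_angle_bins - 1)
        coverage = float(np.unique(bins).size / cfg.n_angle_bins)
    else:
        coverage = 0.0

    overlap = float(np.max(C1 * C2) / (ctot1 * ctot2))

    if float(C1.max()) < cfg.no_pattern_frac * ctot1:
        regime = "no_pattern"
    elif has_central and coverage >= cfg.annulus_coverage:
        regime = "bullseye"
    elif len(cs1) >= 3:
        regime = "kinetic_clusters"
    else:
        regime = "intermediate"

    return PatternReport(
        regime=regime,
        n_clusters_1=len(cs1),
        n_clusters_2=len(cs2),
        mean_diameter_1=cs1.mean_diameter,
        mean_diameter_2=cs2.mean_diameter,
        tcr_centroid_radius=tcr_rad,
        lfa_ring_coverage=coverage,
        overlap_index=overlap,
    )


def dispersed_diameters(state: State, grid: Grid, groups,
                        cfg: AnalysisConfig | None = None,
                        max_diameter: float = 0.4) -> list[float]:
    """Equivalent diameters of dispersed micro-clusters (both species).

    The quarter-power scaling law predicts the micro-cluster nucleation
    scale, not the size of the coalesced cSMAC disk or pSMAC ring, so
    domain-scale structures are excluded: clusters wider than
    ``max_diameter`` (in L units) and clusters covering their own centroid
    region at the pattern centre (the central coalesced domain, identified as
    a cluster whose centroid lies within its own radius of the domain
    centre).
    """
    cfg = cfg if cfg is not None else AnalysisConfig()
    cx, cy = _center(grid)
    out: list[float] = []
    for species, C, ctot in ((1, state.C1, groups.c10), (2, state.C2, groups.c20)):
        cs = find_clusters(np.nan_to_num(C, nan=0.0), grid, ctot,
                           cfg.threshold_frac, cfg.min_pixels, species=species)
        for c in cs:
            if c.equiv_diameter > max_diameter:
                continue
            if np.hypot(c.centroid[0] - cx, c.centroid[1] - cy) < c.equiv_diameter / 2:
                continue
            out.append(c.equiv_diameter)
    return out


def cluster_size_scaling(B_values, diameters) -> float:
    """Log-log slope of cluster diameter versus bending group B.

    ``diameters`` may contain NaN for sweeps without clusters; at least two
    valid points are required.
    """
    B_values = np.asarray(B_values, dtype=float)
    d = np.asarray(diameters, dtype=float)
    ok = np.isfinite(d) & (d > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-empty cluster sets to fit a slope")
    slope = np.polyfit(np.log(B_values[ok]), np.log(d[ok]), 1)[0]
    return float(slope)


def report_row(tau: float, B: float, report: PatternReport) -> dict:
    """Flatten a report to one CSV row of a phase-diagram sweep."""
    return {
        "tau": tau,
        "B": B,
        "regime": report.regime,
        "n_clusters_1": report.n_clusters_1,
        "n_clusters_2": report.n_clusters_2,
        "mean_diam_1": report.mean_diameter_1,
        "mean_diam_2": report.mean_diameter_2,
        "tcr_centroid_radius": report.tcr_centroid_radius,
        "lfa_ring_coverage": report.lfa_ring_coverage,
        "overlap": report.overlap_index,
    }
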