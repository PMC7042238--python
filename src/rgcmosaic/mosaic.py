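"""Spatial survival statistics of an RGC mosaic.

Three parameters summarise survival in a whole-mount: cell density
(cells/mm^2), the nearest-neighbour distance (NND) of every cell, and
the regularity index RI = mean(NND) / SD(NND).  RI is ~1.91 for a
random (Poisson) mosaic — the closed form is sqrt(pi / (4 - pi)) — and
larger for regular mosaics, so it tracks mosaic degradation
independently of absolute density.

Conventions (fixed and documented): Euclidean NND with no edge
correction, sample (n-1) standard deviation by default with a
population-SD switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointSet",
    "MosaicStats",
    "nearest_neighbour_distances",
    "density",
    "regularity_index",
    "mosaic_stats",
    "POISSON_RI",
]

#: Regularity index of a 2D Poisson point process, sqrt(pi/(4-pi)).
POISSON_RI = float(np.sqrt(np.pi / (4.0 - np.pi)))


class DegenerateMosaicError(ValueError):
    """Raised when RI is undefined (zero NND standard deviation)."""


@dataclass(frozen=True)
class PointSet:
    """Planar point pattern (um coordinates) with its reference area."""

    points: np.ndarray
    region_area_mm2: float

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        if self.region_area_mm2 <= 0:
            raise ValueError("region_area_mm2 must be > 0")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MosaicStats:
    n: int
    density_cells_per_mm2: float
    nnd_um: np.ndarray
    mean_nnd_um: float
    sd_nnd_um: float
    regularity_index: float


def nearest_neighbour_distances(ps: PointSet) -> np.ndarray:
    """Distance from each point to its closest other point (KD-tree;
    no edge correction).  Requires n >= 2."""
    if ps.n < 2:
        raise ValueError(f"need at least 2 points for NND, got {ps.n}")
    d, _ = cKDTree(ps.points).query(ps.points, k=2)
    return d[:, 1]


def density(ps: PointSet) -> float:
    """Cell count divided by the reference area, in cells/mm^2."""
    return ps.n / ps.region_area_mm2


def regularity_index(nnds: np.ndarray, sample_sd: bool = True) -> float:
    """mean(NND) / SD(NND); sample (n-1) SD unless ``sample_sd`` is
    False.  Errors on degenerate (zero-variance) mosaics."""
    nnds = np.asarray(nnds, dtype=float)
    if nnds.size < 2:
        raise ValueError("need at least 2 NND values")
    sd = float(np.std(nnds, ddof=1 if sample_sd else 0))
    if sd == 0.0:
        raise DegenerateMosaicError(
            "regularity index undefined: all nearest-neighbour distances equal"
        )
    return float(np.mean(nnds)) / sd


def mosaic_stats(ps: PointSet, sample_sd: bool = True) -> MosaicStats:
    """Full summary: n, density, per-cell NNDs, their mean/SD and RI.

    For n < 2 the NND-derived fields are NaN (density is still valid);
    RI is also NaN when the NND variance vanishes.
    """
    dens = density(ps)
    if ps.n < 2:
        return MosaicStats(ps.n, dens, np.empty(0), np.nan, np.nan, np.nan)
    nnds = nearest_neighbour_distances(ps)
    mean = float(np.mean(nnds))
    sd = float(np.std(nnds, ddof=1 if sample_sd else 0))
    ri = mean / sd if sd > 0 else np.nan
    return MosaicStats(ps.n, dens, nnds, mean, sd, ri)
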