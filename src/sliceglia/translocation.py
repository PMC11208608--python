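"""Depth-resolved microglial redistribution in slice cross-sections.

After acute slice preparation, microglial cell bodies and processes
redistribute across the slice depth.  On re-sectioned cross-sections this is
quantified by (1) a measuring grid that divides the slice thickness into
seven equal zones with per-zone cell counts, percentages and process
densities, (2) the minimal total displacement needed to transform the
0-min depth distribution into the late-timepoint one (sorted-rank matching,
the 1-D optimal transport), and (3) the percentage of image area covered by
binarized microglial processes.

Depth is measured from the top surface, increasing downward; zone 1 is the
top zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellMap",
    "GridProfile",
    "DisplacementSummary",
    "zone_profile",
    "minimal_displacement",
    "area_coverage",
]

#: The measuring grid divides the slice thickness into seven equal zones.
N_ZONES_DEFAULT = 7


@dataclass(frozen=True)
class CellMap:
    """Cell-body depths (µm from the top surface) within a slice of known thickness."""

    depths: np.ndarray
    slice_thickness: float

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", depths)
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        bad = np.nonzero((depths < 0) | (depths > self.slice_thickness))[0]
        if bad.size:
            raise ValueError(
                f"cell {bad[0]} at depth {depths[bad[0]]} µm lies outside "
                f"[0, {self.slice_thickness}] µm"
            )


@dataclass(frozen=True)
class GridProfile:
    """Per-zone counts, percentages and optional process densities."""

    zone_edges: np.ndarray  # n_zones + 1 edges, µm
    counts: np.ndarray
    percent: np.ndarray
    density: np.ndarray | None = None


@dataclass(frozen=True)
class DisplacementSummary:
    """Signed per-cell displacements (µm) under sorted-rank matching.

    Displacements are ``sorted(t1) - sorted(t0)`` elementwise in the depth
    coordinate (µm from the top surface), so negative values are movement
    toward the top.
    """

    per_cell: np.ndarray
    total_abs: float
    mean_abs: float


def zone_profile(
    cell_map: CellMap,
    n_zones: int = N_ZONES_DEFAULT,
    process_image: np.ndarray | None = None,
) -> GridProfile:
    """Cell counts and percentages per equal-width depth zone.

    Zones are half-open ``[lo, hi)`` except the last, which is closed, so a
    boundary cell is counted exactly once.  When ``process_image`` is given
    (rows spanning the slice thickness top to bottom), the per-zone
    integrated fluorescence density of processes is also reported.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    edges = np.linspace(0.0, cell_map.slice_thickness, n_zones + 1)
    counts, _ = np.histogram(cell_map.depths, bins=edges)
    total = counts.sum()
    percent = 100.0 * counts / total if total > 0 else np.zeros(n_zones)
    density = None
    if process_image is not None:
        img = np.asarray(process_image, dtype=float)
        row_edges = np.linspace(0, img.shape[0], n_zones + 1).round().astype(int)
        density = np.array(
            [img[row_edges[i] : row_edges[i + 1]].sum() for i in range(n_zones)]
        )
    return GridProfile(zone_edges=edges, counts=counts, percent=percent, density=density)


def minimal_displacement(
    depths_t0: np.ndarray,
    depths_t1: np.ndarray,
) -> DisplacementSummary:
    """Minimal per-cell travel to turn the t0 depth distribution into the t1 one.

    Both depth sets are sorted ascending and subtracted elementwise
    (rank matching).  In one dimension this monotone assignment minimizes the
    total absolute movement over all pairings, so the summed magnitude is the
    least total distance the population must have travelled.  Requires equal
    cell counts at the two timepoints.
    """
    t0 = np.sort(np.asarray(depths_t0, dtype=float))
    t1 = np.sort(np.asarray(depths_t1, dtype=float))
    if t0.size != t1.size:
        raise ValueError(
            f"cell counts differ between timepoints ({t0.size} vs {t1.size}); "
            "the matching requires identical counts"
        )
    per_cell = t1 - t0
    return DisplacementSummary(
        per_cell=per_cell,
        total_abs=float(np.abs(per_cell).sum()),
        mean_abs=float(np.abs(per_cell).mean()) if per_cell.size else 0.0,
    )


def area_coverage(mask: np.ndarray) -> float:
    """Percent of pixels covered by a binarized process mask."""
    arr = np.asarray(mask)
    if arr.size == 0:
        raise ValueError("empty mask")
    values = np.unique(arr)
    if values.size > 2:
        raise ValueError("mask must be two-valued (binarized)")
    return 100.0 * float(np.count_nonzero(arr)) / arr.size
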