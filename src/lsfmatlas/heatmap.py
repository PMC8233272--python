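"""Cell-density heatmaps in atlas space.

A heatmap is built by summing uniform-value spheres (default radius 20 um)
around the atlas-space centers of detected cells; group contrasts are
voxelwise differences of group-mean heatmaps.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .types import Volume, as_spacing


@dataclasses.dataclass
class Heatmap:
    """Sphere-density map with bookkeeping of how many cells were rendered."""

    density: np.ndarray
    spacing_um: tuple[float, float, float]
    n_cells_rendered: int
    n_cells_skipped: int = 0

    def as_volume(self) -> Volume:
        return Volume(self.density, self.spacing_um)


def sphere_offsets(radius_um: float, spacing_um) -> np.ndarray:
    """Integer (z, y, x) offsets whose voxel centers lie within radius_um (closed ball)."""
    spacing = as_spacing(spacing_um)
    r = [int(np.floor(radius_um / s)) for s in spacing]
    zz, yy, xx = np.mgrid[-r[0] : r[0] + 1, -r[1] : r[1] + 1, -r[2] : r[2] + 1]
    d2 = (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    keep = d2 <= radius_um**2 + 1e-9
    return np.column_stack([zz[keep], yy[keep], xx[keep]]).astype(np.int64)


def render_heatmap(
    cell_centers_atlas: np.ndarray,
    shape: Sequence[int],
    spacing_um=20.0,
    radius_um: float = 20.0,
) -> Heatmap:
    """Sum unit spheres around cell centers.

    Each cell adds 1 to every voxel whose center lies within ``radius_um``
    (Euclidean, physical units) of the cell's voxel; spheres are clipped at
    the volume border and overlaps sum.  Centers outside the volume are
    skipped and counted.  At 20 um spacing and 20 um radius the digital
    ball is the center voxel plus its six face neighbors (7 voxels).
    """
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    shape = tuple(int(s) for s in shape)
    centers = np.atleast_2d(np.asarray(cell_centers_atlas, dtype=float)).reshape(-1, 3)
    density = np.zeros(shape, dtype=np.float64)
    offs = sphere_offsets(radius_um, spacing_um)
    bounds = np.asarray(shape)
    rendered = skipped = 0
    for c in centers:
        ci = np.round(c).astype(np.int64)
        if np.any(ci < 0) or np.any(ci >= bounds):
            skipped += 1
            continue
        pts = ci[None, :] + offs
        ok = np.all((pts >= 0) & (pts < bounds[None, :]), axis=1)
        np.add.at(density, tuple(pts[ok].T), 1.0)
        rendered += 1
    return Heatmap(density, as_spacing(spacing_um), rendered, skipped)


@dataclasses.dataclass
class DifferenceMap:
    """Signed voxelwise group contrast of mean density maps."""

    data: np.ndarray
    spacing_um: tuple[float, float, float]


def group_difference(heatmaps_a: Sequence[Heatmap], heatmaps_b: Sequence[Heatmap]) -> DifferenceMap:
    """Voxelwise mean(A) - mean(B)."""
    if not heatmaps_a or not heatmaps_b:
        raise ValueError("both groups need at least one heatmap")
    shapes = {h.density.shape for h in list(heatmaps_a) + list(heatmaps_b)}
    if len(shapes) > 1:
        raise ValueError(f"heatmap shapes differ: {sorted(shapes)}")
    mean_a = np.mean([h.density for h in heatmaps_a], axis=0)
    mean_b = np.mean([h.density for h in heatmaps_b], axis=0)
    return DifferenceMap(mean_a - mean_b, heatmaps_a[0].spacing_um)
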