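"""Manual segmentation (MS) pathway.

The reader outlines the ill-defined lesion border as a polygon; the polygon is
then refined against the calibrated threshold by probing the signal intensity
in a small window (5 mm^2, as on the workstation) around each boundary vertex
and nudging the vertex along its outward normal until the window mean sits at
the threshold.  Areas are continuous shoelace areas of the vertex polygons —
workstation planimetry — so the manual measurement deliberately includes
sub-threshold voxels enclosed by the drawn border.  This is the mechanism
behind the systematic MS > CAS volume ordering on heterogeneous lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage

from .image_model import MS_ROLE, RegionSpec, VoxelGrid, rasterize_union
from .reference_calibration import ThresholdSpec
from .segmentation_cas import LesionQuant, relative_involvement


@dataclass(frozen=True)
class BoundaryProbe:
    """Parameters of the boundary-refinement probe.

    ``window_area``: area of the sampling window (mm^2), default 5 as on the
    workstation.  ``window_depth``: extent of the window along the boundary
    normal (mm); the tangential extent is ``window_area / window_depth`` so the
    window's aspect follows the local boundary.  ``step``: initial vertex
    displacement per move (mm); ``None`` means half the smaller in-plane pixel
    spacing.  The per-vertex step is halved on each direction reversal, so the
    walk settles onto the threshold isocontour instead of oscillating.
    """

    window_area: float = 5.0
    step: float | None = None
    max_iterations: int = 50
    window_depth: float = 1.0

    def __post_init__(self) -> None:
        if self.window_area <= 0:
            raise ValueError("window_area must be positive")
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.window_depth <= 0:
            raise ValueError("window_depth must be positive")


def polygon_area(region: RegionSpec) -> float:
    """Continuous shoelace area of the vertex polygon (mm^2)."""
    area = float(region.polygon().area)
    if area == 0.0:
        warnings.warn(f"degenerate polygon {region.label!r} has zero area", stacklevel=2)
    return area


def _window_mean(
    image: np.ndarray,
    grid: VoxelGrid,
    center: np.ndarray,
    tangent: np.ndarray,
    normal: np.ndarray,
    probe: BoundaryProbe,
) -> float:
    length = probe.window_area / probe.window_depth
    st = np.linspace(-length / 2, length / 2, 9)
    su = np.linspace(-probe.window_depth / 2, probe.window_depth / 2, 5)
    ss, uu = np.meshgrid(st, su, indexing="ij")
    pts = center + ss[..., None] * tangent + uu[..., None] * normal
    coords = np.stack(
        [pts[..., 0].ravel() / grid.pixel_spacing_row,
         pts[..., 1].ravel() / grid.pixel_spacing_col]
    )
    samples = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    return float(samples.mean())


def refine_boundary(
    grid: VoxelGrid,
    region: RegionSpec,
    threshold: ThresholdSpec,
    probe: BoundaryProbe = BoundaryProbe(),
) -> RegionSpec:
    """Refine a drawn lesion polygon against the threshold isocontour.

    Each vertex moves along its outward normal: outward when the probe-window
    mean SI exceeds the threshold (lesion signal spills past the border),
    inward when it falls below (border encloses normal marrow); a window mean
    exactly at the threshold leaves the vertex in place.  A move that would
    make the polygon self-intersect is rejected.  Iteration stops at
    equilibrium (no vertex moved) or ``max_iterations``.
    """
    if region.role != MS_ROLE:
        raise ValueError(f"refine_boundary expects role {MS_ROLE!r}, got {region.role!r}")
    if not 0 <= region.slice_index < grid.n_slices:
        raise ValueError("region slice outside grid")
    image = grid.intensities[region.slice_index]
    verts = region.vertices_mm.copy()
    n = len(verts)
    step0 = probe.step
    if step0 is None:
        step0 = 0.5 * min(grid.pixel_spacing_row, grid.pixel_spacing_col)
    steps = np.full(n, step0)
    last_dir = np.zeros(n)
    min_step = step0 / 16.0
    eps = max(1e-3, 0.25 * probe.window_depth)

    for _ in range(probe.max_iterations):
        poly = shapely.Polygon(verts)
        moved = False
        for i in range(n):
            tangent = verts[(i + 1) % n] - verts[(i - 1) % n]
            norm = np.hypot(*tangent)
            if norm < 1e-12:
                continue
            tangent = tangent / norm
            normal = np.array([tangent[1], -tangent[0]])
            # orient outward: a point nudged along the normal must leave the polygon
            if poly.covers(shapely.Point(verts[i] + eps * normal)):
                normal = -normal
                if poly.covers(shapely.Point(verts[i] + eps * normal)):
                    centroid = np.asarray(poly.centroid.coords[0])
                    away = verts[i] - centroid
                    if np.hypot(*away) < 1e-12:
                        continue
                    normal = away / np.hypot(*away)
            mean_si = _window_mean(image, grid, verts[i], tangent, normal, probe)
            if mean_si > threshold.value:
                direction = 1.0
            elif mean_si < threshold.value:
                direction = -1.0
            else:
                continue
            if last_dir[i] * direction < 0:
                steps[i] = max(min_step, steps[i] / 2.0)
            last_dir[i] = direction
            candidate = verts[i] + direction * steps[i] * normal
            trial = verts.copy()
            trial[i] = candidate
            try:
                ring = shapely.LinearRing(trial)
            except Exception:
                continue
            if not ring.is_simple:
                continue
            verts = trial
            moved = True
        if not moved:
            break
    return replace(region, vertices_mm=verts)


def measure_ms(
    regions: Sequence[RegionSpec],
    targets: Sequence[RegionSpec],
    grid: VoxelGrid,
) -> LesionQuant:
    """Measure manually segmented lesion polygons against the target region.

    Per-slice area is the sum of polygon areas on that slice; volume uses the
    slice pitch exactly as in the CAS quantification, and the relative percent
    shares the CAS denominator (rasterized target region volume) so the two
    methods are directly comparable.
    """
    if not targets:
        raise ValueError("no target regions supplied")
    for r in regions:
        if r.role != MS_ROLE:
            raise ValueError(f"region {r.label!r} has role {r.role!r}; expected {MS_ROLE!r}")
    target_slices = sorted({t.slice_index for t in targets})
    for r in regions:
        if r.slice_index not in target_slices:
            raise ValueError(
                f"ms_bml polygon {r.label!r} on slice {r.slice_index} has no target region"
            )
    region_mask = rasterize_union(targets, grid)
    region_volume = region_mask.count * grid.voxel_volume
    if region_volume == 0:
        raise ValueError("target regions rasterize to zero volume")
    per_slice = {s: 0.0 for s in target_slices}
    for r in regions:
        per_slice[r.slice_index] += polygon_area(r)
    total_volume = sum(per_slice.values()) * grid.slice_pitch
    return LesionQuant(
        per_slice_areas=per_slice,
        total_volume=total_volume,
        region_volume=region_volume,
        relative_percent=relative_involvement(total_volume, region_volume),
        n_clusters=len(regions),
        method_tag="MS",
    )
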