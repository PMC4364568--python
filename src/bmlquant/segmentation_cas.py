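"""Computer-assisted segmentation (CAS).

Voxels inside the target subregions whose signal intensity strictly exceeds
the reference threshold are extracted; scattered clusters of fewer than five
interconnected voxels are discarded as noise; the remainder is quantified as
per-slice areas, a pitch-based volume, and the lesion volume as a percentage
of the analysed condyle/plateau volume (relative involvement).

Volumes use the effective slice pitch (thickness + interslice gap) for both
the lesion and the region, so the relative percentage is pitch-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image_model import TARGET_ROLES, BinaryMask, RegionSpec, VoxelGrid, rasterize_union
from .reference_calibration import ThresholdSpec

CONNECTIVITIES = ("volumetric_26", "in_slice_8")


def connectivity_structure(connectivity: str) -> np.ndarray:
    """Neighbourhood footprint for cluster labelling.

    ``volumetric_26``: full 3-D adjacency across the analysed slices (the
    method computes three-dimensional volumes).  ``in_slice_8``: 8-connectivity
    within each slice only — selectable because the interslice gap makes
    cross-slice adjacency debatable.
    """
    if connectivity == "volumetric_26":
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == "in_slice_8":
        s = np.zeros((3, 3, 3), dtype=bool)
        s[1] = True
        return s
    raise ValueError(f"unknown connectivity {connectivity!r}; expected one of {CONNECTIVITIES}")


@dataclass
class LesionQuant:
    """Quantified lesion burden for one compartment.

    ``per_slice_areas`` maps analysed slice index to lesion area (mm^2);
    ``total_volume`` and ``region_volume`` are mm^3; ``relative_percent`` is
    lesion volume as a percentage of the region volume (0-100, full
    precision — integer rounding happens only at report time).
    """

    per_slice_areas: dict[int, float]
    total_volume: float
    region_volume: float
    relative_percent: float
    n_clusters: int
    method_tag: str = "CAS"

    def __post_init__(self) -> None:
        if not 0 <= self.relative_percent <= 100 + 1e-9:
            raise ValueError("relative_percent must lie in [0, 100]")
        if self.total_volume > self.region_volume * (1 + 1e-9):
            raise ValueError("lesion volume exceeds region volume")

    def to_dict(self) -> dict:
        return {
            "method": self.method_tag,
            "per_slice_areas_mm2": {str(k): v for k, v in self.per_slice_areas.items()},
            "total_volume_mm3": self.total_volume,
            "region_volume_mm3": self.region_volume,
            "relative_percent": self.relative_percent,
            "relative_percent_rounded": round_half_up(self.relative_percent),
            "n_clusters": self.n_clusters,
        }


def round_half_up(x: float) -> int:
    """Report rounding to integer percent: halves round up, as in the figure
    captions (13.7% -> 14%)."""
    return int(math.floor(x + 0.5))


def segment_above_threshold(
    grid: VoxelGrid, targets: Sequence[RegionSpec], threshold: ThresholdSpec
) -> BinaryMask:
    """Select voxels inside the target polygons with SI strictly above T."""
    if not targets:
        raise ValueError("no target regions supplied")
    roles = {r.role for r in targets}
    if len(roles) > 1:
        raise ValueError(f"target regions have mixed roles: {sorted(roles)}")
    if next(iter(roles)) not in TARGET_ROLES:
        raise ValueError(f"role {next(iter(roles))!r} is not a target role")
    region = rasterize_union(targets, grid)
    return BinaryMask(region.flags & (grid.intensities > threshold.value))


def filter_small_clusters(
    mask: BinaryMask, min_size: int = 5, connectivity: str = "volumetric_26"
) -> BinaryMask:
    """Drop connected components smaller than ``min_size`` voxels as noise.

    Components of exactly ``min_size`` voxels are kept untouched ("less than
    five interconnected voxels" excluded, default min_size=5).
    """
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    labels, n = ndimage.label(mask.flags, structure=connectivity_structure(connectivity))
    if n == 0:
        return BinaryMask(mask.flags.copy())
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return BinaryMask(keep[labels])


def count_clusters(mask: BinaryMask, connectivity: str = "volumetric_26") -> int:
    _, n = ndimage.label(mask.flags, structure=connectivity_structure(connectivity))
    return int(n)


def quantify(
    mask: BinaryMask,
    targets: Sequence[RegionSpec],
    grid: VoxelGrid,
    *,
    method_tag: str = "CAS",
    connectivity: str = "volumetric_26",
) -> LesionQuant:
    """Turn a (filtered) lesion mask into areas, volumes and relative percent.

    Per-slice area = selected-voxel count x pixel area; volume = area x pitch
    summed over the analysed slices; the region volume comes from the
    rasterized target polygons with the same pitch.
    """
    region = rasterize_union(targets, grid)
    if np.any(mask.flags & ~region.flags):
        raise ValueError("mask extends outside the target regions")
    region_volume = region.count * grid.voxel_volume
    if region_volume == 0:
        raise ValueError("target regions rasterize to zero volume")
    slice_list = sorted({r.slice_index for r in targets})
    per_slice = {
        s: float(mask.flags[s].sum()) * grid.pixel_area for s in slice_list
    }
    total_volume = sum(per_slice.values()) * grid.slice_pitch
    return LesionQuant(
        per_slice_areas=per_slice,
        total_volume=total_volume,
        region_volume=region_volume,
        relative_percent=relative_involvement(total_volume, region_volume),
        n_clusters=count_clusters(mask, connectivity),
        method_tag=method_tag,
    )


def relative_involvement(bml_measure: float, region_measure: float) -> float:
    """Lesion burden as a percent of the region, 100*bml/region.

    Works for areas (mm^2, single slice) or volumes (mm^3) as long as both
    arguments share units.  Full precision; use :func:`round_half_up` at
    report time.
    """
    if region_measure <= 0:
        raise ValueError("region measure must be positive")
    if bml_measure < 0:
        raise ValueError("lesion measure must be non-negative")
    if bml_measure > region_measure * (1 + 1e-9):
        raise ValueError("lesion measure exceeds region measure")
    return 100.0 * bml_measure / region_measure
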