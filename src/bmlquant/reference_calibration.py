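"""Reference signal-intensity calibration.

Bone marrow lesions appear hyperintense on fluid-sensitive (STIR) images, but
signal intensities are arbitrary units, so each examination is calibrated
against the reader's own reference: unaffected *lateral* femoral condyle or
tibial plateau marrow.  The segmentation cutoff is then

    T = mean_SI + k * SD_SI

with k = 1 for the manual method and k = 2 for the computer-assisted method.
The SD uses the sample (n-1) denominator, matching the convention of
workstation ROI statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_model import REFERENCE_ROLES, RegionSpec, VoxelGrid, rasterize_union


@dataclass(frozen=True)
class ReferenceStats:
    """Mean and sample SD of reference-marrow signal intensity."""

    mean_si: float
    sd_si: float
    n_voxels: int
    slice_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError("reference statistics need at least 2 voxels")
        if self.sd_si < 0:
            raise ValueError("sd_si must be non-negative")

    def to_dict(self) -> dict:
        return {
            "mean_si": self.mean_si,
            "sd_si": self.sd_si,
            "n_voxels": self.n_voxels,
            "slice_indices": list(self.slice_indices),
        }


@dataclass(frozen=True)
class ThresholdSpec:
    """Segmentation cutoff T = mean + k*SD, kept at full floating precision."""

    value: float
    k: float
    source: ReferenceStats

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        expected = self.source.mean_si + self.k * self.source.sd_si
        if not np.isclose(self.value, expected, rtol=1e-9, atol=1e-9):
            raise ValueError(f"threshold {self.value} inconsistent with mean + k*SD = {expected}")

    def to_dict(self) -> dict:
        return {"value": self.value, "k": self.k, **self.source.to_dict()}


def compute_region_stats(grid: VoxelGrid, regions: Sequence[RegionSpec]) -> ReferenceStats:
    """Pool reference regions into one voxel population and compute mean/SD.

    All regions must share a single reference role (the femoral and tibial
    references calibrate their own compartments and are never pooled).  The
    regions passed in determine the slice protocol: one central lateral slice
    for the manual method, two adjacent central slices pooled for CAS.
    """
    if not regions:
        raise ValueError("no reference regions supplied")
    roles = {r.role for r in regions}
    if len(roles) > 1:
        raise ValueError(f"reference regions have mixed roles: {sorted(roles)}")
    role = next(iter(roles))
    if role not in REFERENCE_ROLES:
        raise ValueError(f"role {role!r} is not a reference role")
    mask = rasterize_union(regions, grid)
    values = grid.intensities[mask.flags]
    if values.size == 0:
        raise ValueError("reference regions rasterize to an empty voxel set")
    if values.size < 2:
        raise ValueError("reference regions cover fewer than 2 voxels")
    return ReferenceStats(
        mean_si=float(values.mean()),
        sd_si=float(values.std(ddof=1)),
        n_voxels=int(values.size),
        slice_indices=tuple(sorted({r.slice_index for r in regions})),
    )


def compute_threshold(stats: ReferenceStats, k: float) -> ThresholdSpec:
    """T = mean + k*SD, unrounded (figure captions print integers only
    because the printed means and SDs are integers)."""
    if k <= 0:
        raise ValueError("k must be positive")
    return ThresholdSpec(value=stats.mean_si + k * stats.sd_si, k=float(k), source=stats)
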