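"""Core data structures and I/O for MR slice stacks and ROI polygons.

Coordinate convention
---------------------
All in-plane coordinates are physical millimetres ``(row_mm, col_mm)`` with the
origin at the *center* of voxel ``(slice 0, row 0, col 0)``.  The voxel center
of index ``(r, c)`` therefore sits at ``(r * pixel_spacing_row,
c * pixel_spacing_col)``.  Indexing is 0-based throughout.  Slices are assumed
to advance laterally to medially by the convention of the ROI file; this is not
enforced.

Rasterization selects a voxel iff its center lies inside the polygon
(even-odd rule for the simple polygons admitted here); a center exactly on a
polygon edge counts as inside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

REFERENCE_ROLES = frozenset({"reference_femur", "reference_tibia"})
TARGET_ROLES = frozenset({"target_femur_medial", "target_tibia_medial"})
MS_ROLE = "ms_bml"
ROLES = REFERENCE_ROLES | TARGET_ROLES | {MS_ROLE}


@dataclass(frozen=True)
class GridGeometry:
    """Physical geometry of a slice stack (all lengths in mm)."""

    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness: float
    interslice_gap: float = 0.0


@dataclass
class VoxelGrid:
    """A 3-D single-channel MR slice stack with physical geometry.

    ``intensities`` is indexed ``(slice, row, col)`` and holds arbitrary-unit
    signal intensities.  The effective slice pitch — the per-slice volume
    multiplier — is ``slice_thickness + interslice_gap``, so the unimaged gap
    tissue is attributed to the adjacent slice.
    """

    intensities: np.ndarray
    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness: float
    interslice_gap: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3-D (slice, row, col); got ndim={self.intensities.ndim}"
            )
        if not (self.pixel_spacing_row > 0 and self.pixel_spacing_col > 0):
            raise ValueError("pixel spacings must be positive")
        if not self.slice_thickness > 0:
            raise ValueError("slice_thickness must be positive")
        if self.interslice_gap < 0:
            raise ValueError("interslice_gap must be non-negative")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def slice_pitch(self) -> float:
        """Effective per-slice extent, thickness + gap (mm)."""
        return self.slice_thickness + self.interslice_gap

    @property
    def pixel_area(self) -> float:
        """In-plane area of one voxel (mm^2)."""
        return self.pixel_spacing_row * self.pixel_spacing_col

    @property
    def voxel_volume(self) -> float:
        """Volume attributed to one voxel, pixel area x pitch (mm^3)."""
        return self.pixel_area * self.slice_pitch

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            self.pixel_spacing_row,
            self.pixel_spacing_col,
            self.slice_thickness,
            self.interslice_gap,
        )


@dataclass
class RegionSpec:
    """A per-slice closed polygon with a role label.

    ``vertices_mm`` is an ordered ``(n, 2)`` array of ``(row_mm, col_mm)``
    points; the polygon is implicitly closed.  Roles distinguish reference
    marrow regions, target (analysed) subregions, and manually drawn lesions.
    """

    label: str
    role: str
    slice_index: int
    vertices_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        self.vertices_mm = np.asarray(self.vertices_mm, dtype=np.float64)
        if self.vertices_mm.ndim != 2 or self.vertices_mm.shape[1] != 2:
            raise ValueError("vertices_mm must be an (n, 2) array of (row_mm, col_mm)")
        if len(self.vertices_mm) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if not np.all(np.isfinite(self.vertices_mm)):
            raise ValueError("vertices must be finite")
        ring = shapely.LinearRing(self.vertices_mm)
        if not ring.is_simple:
            raise ValueError(f"polygon {self.label!r} is self-intersecting")

    def polygon(self) -> Polygon:
        """Shapely polygon in (row_mm, col_mm) coordinates."""
        return Polygon(self.vertices_mm)


@dataclass
class BinaryMask:
    """Boolean voxel-selection result congruent with a :class:`VoxelGrid`."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 3:
            raise ValueError("mask must be 3-D (slice, row, col)")

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.flags | other.flags)


# ---------------------------------------------------------------------------
# Image stack I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    geometry_override: GridGeometry | None = None,
    *,
    interslice_gap: float = 0.4,
) -> VoxelGrid:
    """Read a 3-D slice stack from NIfTI-1 or multi-page TIFF.

    NIfTI geometry is taken from the header zooms, interpreted as
    ``(slice pitch, row spacing, col spacing)``; the pitch is split into
    thickness + gap using ``interslice_gap`` (default 0.4 mm, the protocol
    value).  TIFF carries no reliable 3-D geometry, so ``geometry_override``
    is mandatory there.  An explicit override always wins.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected 3-D NIfTI, got shape {data.shape}")
        if geometry_override is not None:
            geom = geometry_override
        else:
            pitch, sp_row, sp_col = (float(z) for z in img.header.get_zooms()[:3])
            thickness = pitch - interslice_gap
            if thickness <= 0:
                raise ValueError(
                    f"slice pitch {pitch} mm incompatible with interslice gap {interslice_gap} mm"
                )
            geom = GridGeometry(sp_row, sp_col, thickness, interslice_gap)
    elif suffixes.endswith((".tif", ".tiff")):
        data = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a multi-page TIFF stack, got shape {data.shape}")
        if geometry_override is None:
            raise ValueError("TIFF stacks carry no 3-D geometry; geometry_override is required")
        geom = geometry_override
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    return VoxelGrid(
        data,
        pixel_spacing_row=geom.pixel_spacing_row,
        pixel_spacing_col=geom.pixel_spacing_col,
        slice_thickness=geom.slice_thickness,
        interslice_gap=geom.interslice_gap,
    )


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid to NIfTI (affine diag(pitch, row, col)) or TIFF."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(
            [grid.slice_pitch, grid.pixel_spacing_row, grid.pixel_spacing_col, 1.0]
        )
        nib.save(nib.Nifti1Image(grid.intensities, affine), str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), grid.intensities.astype(np.float32))
    else:
        raise ValueError(f"unsupported image format: {path.name}")


# ---------------------------------------------------------------------------
# ROI polygon I/O
# ---------------------------------------------------------------------------

def read_regions(path: str | Path) -> list[RegionSpec]:
    """Read ROI polygons from the JSON schema.

    Schema: ``{"regions": [{"label": str, "role": str, "slice_index": int,
    "vertices_mm": [[row, col], ...]}, ...]}``.  Input order is preserved.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "regions" not in doc:
        raise ValueError("ROI file must be a JSON object with a 'regions' list")
    regions = []
    for i, entry in enumerate(doc["regions"]):
        try:
            regions.append(
                RegionSpec(
                    label=str(entry["label"]),
                    role=str(entry["role"]),
                    slice_index=int(entry["slice_index"]),
                    vertices_mm=np.asarray(entry["vertices_mm"], dtype=np.float64),
                )
            )
        except KeyError as exc:
            raise ValueError(f"region {i}: missing field {exc}") from exc
    return regions


def write_regions(regions: Sequence[RegionSpec], path: str | Path) -> None:
    doc = {
        "regions": [
            {
                "label": r.label,
                "role": r.role,
                "slice_index": r.slice_index,
                "vertices_mm": np.asarray(r.vertices_mm).tolist(),
            }
            for r in regions
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(region: RegionSpec, grid: VoxelGrid) -> BinaryMask:
    """Rasterize a polygon onto the voxel lattice of ``grid``.

    A voxel is selected iff its center lies inside the polygon or exactly on
    its boundary; selection is confined to ``region.slice_index``.  A region
    falling entirely outside the grid extent yields an empty mask with a
    warning rather than an error.
    """
    flags = np.zeros(grid.shape, dtype=bool)
    if not 0 <= region.slice_index < grid.n_slices:
        warnings.warn(
            f"region {region.label!r} slice {region.slice_index} outside grid "
            f"({grid.n_slices} slices); empty mask",
            stacklevel=2,
        )
        return BinaryMask(flags)
    poly = region.polygon()
    rmin, cmin, rmax, cmax = poly.bounds
    n_rows, n_cols = grid.shape[1], grid.shape[2]
    r0 = max(0, int(np.ceil(rmin / grid.pixel_spacing_row - 1e-9)))
    r1 = min(n_rows - 1, int(np.floor(rmax / grid.pixel_spacing_row + 1e-9)))
    c0 = max(0, int(np.ceil(cmin / grid.pixel_spacing_col - 1e-9)))
    c1 = min(n_cols - 1, int(np.floor(cmax / grid.pixel_spacing_col + 1e-9)))
    if r0 > r1 or c0 > c1:
        warnings.warn(
            f"region {region.label!r} covers no voxel centers "
            "(outside the grid or between lattice points); empty mask",
            stacklevel=2,
        )
        return BinaryMask(flags)
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    rr, cc = np.meshgrid(rows * grid.pixel_spacing_row, cols * grid.pixel_spacing_col,
                         indexing="ij")
    shapely.prepare(poly)
    # intersects includes the boundary, realizing the on-edge-counts-inside rule
    inside = shapely.intersects_xy(poly, rr.ravel(), cc.ravel()).reshape(rr.shape)
    flags[region.slice_index, r0 : r1 + 1, c0 : c1 + 1] = inside
    return BinaryMask(flags)


def rasterize_union(regions: Iterable[RegionSpec], grid: VoxelGrid) -> BinaryMask:
    """Union of :func:`rasterize` over several regions."""
    flags = np.zeros(grid.shape, dtype=bool)
    for region in regions:
        flags |= rasterize(region, grid).flags
    return BinaryMask(flags)
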