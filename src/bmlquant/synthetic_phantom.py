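"""Synthetic STIR-like knee phantoms with known ground truth.

No clinical image set accompanies the method, so validation runs on phantoms:
a marrow background of approximately Gaussian signal intensity (default mean
185, SD 34 — the regime of a healthy lateral condyle reference region) with
optional hyperintense ellipsoidal lesions of known voxelized volume, plus
matching reference/target ROI polygon files.  Lesions get a smooth one-voxel
edge taper to emulate the ill-defined margins the segmentation methods were
designed for.  Geometry defaults follow the acquisition protocol: 266 x 512
in-plane matrix over a 20 cm field of view, 4.0 mm slices with a 0.4 mm gap.

Gaussian noise is the default; Rician (magnitude of a complex Gaussian) is
selectable since STIR magnitude noise is Rician, but phantom realism beyond
the signal-intensity statistics is not attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .image_model import (
    RegionSpec,
    VoxelGrid,
    rasterize_union,
    write_regions,
    write_stack,
)


@dataclass(frozen=True)
class Lesion:
    """Ellipsoidal lesion: center/semi-axes in mm (slice-axis, row, col);
    intensity offset in units of the background SD."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    offset_sd: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if not np.isfinite(self.offset_sd):
            raise ValueError("offset must be finite")


@dataclass
class PhantomSpec:
    """Recipe for a phantom stack, its ROI file, and its ground truth."""

    shape: tuple[int, int, int] = (8, 266, 512)
    pixel_spacing_row: float = 200.0 / 266
    pixel_spacing_col: float = 200.0 / 512
    slice_thickness: float = 4.0
    interslice_gap: float = 0.4
    background_mean: float = 185.0
    background_sd: float = 34.0
    lesions: tuple[Lesion, ...] = ()
    noise_model: str = "gaussian"
    seed: int = 0
    reference_slices: tuple[int, ...] = (1, 2)
    target_slices: tuple[int, ...] | None = None  # default: three central slices
    reference_rect_mm: tuple[float, float, float, float] | None = None  # (r0,c0,r1,c1)
    target_rect_mm: tuple[float, float, float, float] | None = None
    edge_taper_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.background_sd <= 0 or self.background_mean <= 0:
            raise ValueError("background mean and SD must be positive")
        if self.edge_taper_mm <= 0:
            raise ValueError("edge taper must be positive")
        self.lesions = tuple(self.lesions)

    @property
    def slice_pitch(self) -> float:
        return self.slice_thickness + self.interslice_gap

    def resolved_target_slices(self) -> tuple[int, ...]:
        if self.target_slices is not None:
            return tuple(self.target_slices)
        mid = self.shape[0] // 2
        return (mid - 1, mid, mid + 1)

    def resolved_target_rect(self) -> tuple[float, float, float, float]:
        if self.target_rect_mm is not None:
            return self.target_rect_mm
        extent_r = (self.shape[1] - 1) * self.pixel_spacing_row
        extent_c = (self.shape[2] - 1) * self.pixel_spacing_col
        return (0.2 * extent_r, 0.2 * extent_c, 0.8 * extent_r, 0.8 * extent_c)

    def resolved_reference_rect(self) -> tuple[float, float, float, float]:
        if self.reference_rect_mm is not None:
            return self.reference_rect_mm
        extent_r = (self.shape[1] - 1) * self.pixel_spacing_row
        extent_c = (self.shape[2] - 1) * self.pixel_spacing_col
        half_r = min(15.0, 0.3 * extent_r)
        half_c = min(12.5, 0.3 * extent_c)
        return (
            extent_r / 2 - half_r,
            extent_c / 2 - half_c,
            extent_r / 2 + half_r,
            extent_c / 2 + half_c,
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth: voxelized lesion volumes (voxel-center counting against
    the analytic ellipsoids), the target-region relative percent, and the
    noise-free background statistics behind the thresholds."""

    lesion_volumes_mm3: tuple[float, ...]
    region_relative_percent: float
    background_mean: float
    background_sd: float
    region_volume_mm3: float

    def to_dict(self) -> dict:
        return {
            "lesion_volumes_mm3": list(self.lesion_volumes_mm3),
            "region_relative_percent": self.region_relative_percent,
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
            "region_volume_mm3": self.region_volume_mm3,
        }


def _rect_polygon(rect: tuple[float, float, float, float]) -> np.ndarray:
    r0, c0, r1, c1 = rect
    return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], dtype=float)


def _check_lesion_containment(spec: PhantomSpec, lesion: Lesion) -> None:
    cz, cr, cc = lesion.center_mm
    az, ar, ac = lesion.semi_axes_mm
    pitch = spec.slice_pitch
    target_slices = set(spec.resolved_target_slices())
    covered = [s for s in range(spec.shape[0]) if abs(s * pitch - cz) <= az]
    if not covered or not set(covered) <= target_slices:
        raise ValueError(
            f"lesion at z={cz} mm spans slices {covered} outside target slices "
            f"{sorted(target_slices)}"
        )
    r0, c0, r1, c1 = spec.resolved_target_rect()
    if not (r0 <= cr - ar and cr + ar <= r1 and c0 <= cc - ac and cc + ac <= c1):
        raise ValueError("lesion extends outside the target region in-plane")


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, list[RegionSpec], PhantomTruth]:
    """Generate a phantom stack, its ROI polygons, and the ground truth.

    Same spec and seed give bit-identical output.  Each lesion raises the
    underlying signal by ``offset_sd * background_sd`` inside its ellipsoid,
    fading linearly to zero across a one-voxel-scale taper at the margin;
    overlapping lesions add (a negative-offset lesion inside a positive one
    builds a hypointense core).
    """
    overlap = set(spec.reference_slices) & set(spec.resolved_target_slices())
    if overlap:
        raise ValueError(
            f"reference slices {sorted(overlap)} overlap the target slices; "
            "the reference must stay lesion-free"
        )
    for lesion in spec.lesions:
        _check_lesion_containment(spec, lesion)
    rng = np.random.default_rng(spec.seed)
    n_s, n_r, n_c = spec.shape
    z = np.arange(n_s) * spec.slice_pitch
    r = np.arange(n_r) * spec.pixel_spacing_row
    c = np.arange(n_c) * spec.pixel_spacing_col

    signal = np.full(spec.shape, spec.background_mean, dtype=np.float64)
    lesion_volumes = []
    voxel_volume = spec.pixel_spacing_row * spec.pixel_spacing_col * spec.slice_pitch
    for lesion in spec.lesions:
        cz, cr, cc = lesion.center_mm
        az, ar, ac = lesion.semi_axes_mm
        d = np.sqrt(
            ((z[:, None, None] - cz) / az) ** 2
            + ((r[None, :, None] - cr) / ar) ** 2
            + ((c[None, None, :] - cc) / ac) ** 2
        )
        w = spec.edge_taper_mm / min(lesion.semi_axes_mm)
        taper = np.clip((1 + w / 2 - d) / w, 0.0, 1.0)
        signal += lesion.offset_sd * spec.background_sd * taper
        lesion_volumes.append(float((d <= 1).sum()) * voxel_volume)

    if spec.noise_model == "gaussian":
        intensities = signal + rng.normal(0.0, spec.background_sd, spec.shape)
    else:  # rician: magnitude of complex Gaussian around the signal
        g1 = rng.normal(0.0, spec.background_sd, spec.shape)
        g2 = rng.normal(0.0, spec.background_sd, spec.shape)
        intensities = np.sqrt((signal + g1) ** 2 + g2**2)
    intensities = np.clip(intensities, 0.0, None)

    grid = VoxelGrid(
        intensities,
        pixel_spacing_row=spec.pixel_spacing_row,
        pixel_spacing_col=spec.pixel_spacing_col,
        slice_thickness=spec.slice_thickness,
        interslice_gap=spec.interslice_gap,
    )

    regions: list[RegionSpec] = []
    ref_poly = _rect_polygon(spec.resolved_reference_rect())
    for s in spec.reference_slices:
        regions.append(
            RegionSpec(
                label=f"reference_slice{s}",
                role="reference_femur",
                slice_index=int(s),
                vertices_mm=ref_poly.copy(),
            )
        )
    target_poly = _rect_polygon(spec.resolved_target_rect())
    targets = [
        RegionSpec(
            label=f"target_slice{s}",
            role="target_femur_medial",
            slice_index=int(s),
            vertices_mm=target_poly.copy(),
        )
        for s in spec.resolved_target_slices()
    ]
    regions.extend(targets)

    region_volume = rasterize_union(targets, grid).count * voxel_volume
    total_lesion = float(sum(lesion_volumes))
    truth = PhantomTruth(
        lesion_volumes_mm3=tuple(lesion_volumes),
        region_relative_percent=100.0 * total_lesion / region_volume if region_volume else 0.0,
        background_mean=spec.background_mean,
        background_sd=spec.background_sd,
        region_volume_mm3=region_volume,
    )
    return grid, regions, truth


def two_reader_perturbation(
    regions: Sequence[RegionSpec], jitter_mm: float, seed: int
) -> list[RegionSpec]:
    """Emulate a second reader: jitter polygon vertices with truncated
    Gaussian noise (SD = jitter_mm, truncated at 2 SD), keeping each polygon
    simple (up to 10 redraws per polygon)."""
    if jitter_mm < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for region in regions:
        if jitter_mm == 0:
            out.append(replace(region, vertices_mm=region.vertices_mm.copy()))
            continue
        for _ in range(10):
            disp = rng.normal(0.0, jitter_mm, region.vertices_mm.shape)
            disp = np.clip(disp, -2 * jitter_mm, 2 * jitter_mm)
            try:
                out.append(replace(region, vertices_mm=region.vertices_mm + disp))
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                f"could not jitter polygon {region.label!r} without self-intersection"
            )
    return out


def write_phantom(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write stack.nii.gz, regions.json and truth.json into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid, regions, truth = generate_phantom(spec)
    stack_path = out_dir / "stack.nii.gz"
    roi_path = out_dir / "regions.json"
    truth_path = out_dir / "truth.json"
    write_stack(grid, stack_path)
    write_regions(regions, roi_path)
    with open(truth_path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return stack_path, roi_path, truth_path
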