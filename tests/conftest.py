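import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bmlquant as bq

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def raycast_inside(vertices: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Independent even-odd point-in-polygon oracle (numpy ray casting).

    Boundary points are not guaranteed a particular answer; tests using this
    oracle avoid putting probe points exactly on edges.
    """
    vertices = np.asarray(vertices, float)
    points = np.asarray(points, float)
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xint, np.inf))
    return inside


def flood_fill_components(flags: np.ndarray, offsets) -> list[set]:
    """Exhaustive BFS connected components, independent of scipy labelling."""
    flags = np.asarray(flags, bool)
    seen = np.zeros_like(flags)
    comps = []
    coords = list(zip(*np.nonzero(flags)))
    coord_set = set(coords)
    for start in coords:
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if nb in coord_set and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(comp)
    return comps


OFFSETS_26 = [
    (dz, dr, dc)
    for dz in (-1, 0, 1)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if (dz, dr, dc) != (0, 0, 0)
]
OFFSETS_8_IN_SLICE = [off for off in OFFSETS_26 if off[0] == 0]


@pytest.fixture
def unit_grid():
    """Small uniform grid at 1 mm pixels, protocol thickness/gap."""
    return bq.VoxelGrid(
        np.full((3, 40, 40), 100.0),
        pixel_spacing_row=1.0,
        pixel_spacing_col=1.0,
        slice_thickness=4.0,
        interslice_gap=0.4,
    )


@pytest.fixture
def lesion_phantom():
    """Phantom with one ~1390 mm^3 hyperintense lesion at +5 SD."""
    spec = bq.PhantomSpec(
        shape=(8, 160, 240),
        lesions=(bq.Lesion((4 * 4.4, 60.0, 45.0), (6.0, 8.0, 6.5), 5.0),),
        seed=42,
    )
    return spec, *bq.generate_phantom(spec)
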