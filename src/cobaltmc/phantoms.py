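"""Validation phantom generators and the DICOM CT reader.

The generators rebuild the validation geometries programmatically: the
31.8 x 48.4 x 30 cm water tank, the same tank with a two-bar aluminum
insert flanking a measurement plane at 3.0 cm depth, and a layered
soft-tissue/lung/bone slab phantom that stands in for an anthropomorphic
phantom (it reproduces the heterogeneity classes, not the anatomy).  All
generators are deterministic functions of their parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .materials import ALUMINUM, DensityModel
from .transport import VoxelGrid

__all__ = [
    "PhantomSpec", "make_water_phantom", "add_aluminum_insert",
    "make_layered_body", "read_ct_series",
    "WATER_TANK_DIMENSIONS", "ALUMINUM_DENSITY",
]

#: Water tank (x, y, z) outer dimensions in cm.
WATER_TANK_DIMENSIONS = (31.8, 48.4, 30.0)
#: Bulk density assigned to the aluminum insert (g/cm^3).
ALUMINUM_DENSITY = 2.70
#: Default voxel size (cm), matching the CT export resolution.
DEFAULT_VOXEL = (0.254, 0.254, 0.5)


@dataclass
class PhantomSpec:
    """Declarative phantom description (used by the CLI/config layer)."""

    kind: str = "water_tank"  # water_tank | water_tank_with_insert | layered_body
    dimensions: tuple = WATER_TANK_DIMENSIONS
    voxel_size: tuple = DEFAULT_VOXEL
    insert_bar_thickness: float = 0.95   # cm along depth
    insert_gap: float = 0.6              # cm between the two bars
    insert_depth: float = 3.0            # cm, measurement-plane depth
    insert_extent: tuple = (10.0, 10.0)  # cm lateral footprint
    layers: tuple = ()                   # (thickness_cm, hu) pairs, top down

    def build(self) -> VoxelGrid:
        if self.kind == "water_tank":
            return make_water_phantom(self.voxel_size, self.dimensions)
        if self.kind == "water_tank_with_insert":
            grid = make_water_phantom(self.voxel_size, self.dimensions)
            return add_aluminum_insert(
                grid, bar_thickness=self.insert_bar_thickness,
                gap=self.insert_gap, depth=self.insert_depth,
                extent=self.insert_extent)
        if self.kind == "layered_body":
            return make_layered_body(self.layers or None,
                                     voxel_size=self.voxel_size)
        raise ValueError(f"unknown phantom kind {self.kind!r}")


def make_water_phantom(voxel_size=DEFAULT_VOXEL,
                       dimensions=WATER_TANK_DIMENSIONS) -> VoxelGrid:
    """Uniform water tank, HU = 0 everywhere, base on the table top."""
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel size must be positive")
    shape = tuple(max(1, int(round(d / v)))
                  for d, v in zip(dimensions, voxel_size))
    hu = np.zeros(shape, dtype=np.float32)
    return VoxelGrid.from_hu(hu, voxel_size=voxel_size)


def add_aluminum_insert(grid: VoxelGrid, bar_thickness: float = 0.95,
                        gap: float = 0.6, depth: float = 3.0,
                        extent: tuple = (10.0, 10.0),
                        center: tuple = (0.0, 0.0)) -> VoxelGrid:
    """Place two parallel aluminum bars flanking a plane at ``depth``.

    The bars (default 9.5 mm thick along the beam) sit directly above and
    below a water gap centered at the given depth below the phantom
    surface, so a film-like measurement plane between them stays water.
    Aluminum is assigned by material override with the declared bulk
    density rather than through the HU calibration.
    """
    z_top = grid.z_top
    z_lo_bar_top = z_top - depth - gap / 2.0
    z_hi_bar_bot = z_top - depth + gap / 2.0
    spans = [(z_lo_bar_top - bar_thickness, z_lo_bar_top),
             (z_hi_bar_bot, z_hi_bar_bot + bar_thickness)]
    if spans[0][0] < grid.origin[2] or spans[1][1] > z_top:
        raise ValueError("insert extends outside the phantom")
    sx, sy, sz = grid.voxel_size
    x = grid.origin[0] + (np.arange(grid.shape[0]) + 0.5) * sx
    y = grid.origin[1] + (np.arange(grid.shape[1]) + 0.5) * sy
    z = grid.origin[2] + (np.arange(grid.shape[2]) + 0.5) * sz
    in_x = np.abs(x - center[0]) <= extent[0] / 2.0
    in_y = np.abs(y - center[1]) <= extent[1] / 2.0
    if not (in_x.any() and in_y.any()):
        raise ValueError("insert footprint misses the grid")
    density = grid.density.copy()
    material = grid.material.copy()
    for z0, z1 in spans:
        in_z = (z >= z0) & (z < z1)
        region = np.ix_(np.where(in_x)[0], np.where(in_y)[0],
                        np.where(in_z)[0])
        density[region] = ALUMINUM_DENSITY
        material[region] = ALUMINUM
    return VoxelGrid(hu=grid.hu.copy(), voxel_size=grid.voxel_size,
                     origin=grid.origin.copy(), density=density,
                     material=material,
                     table_top_height=grid.table_top_height)


#: Default chest-like layer stack, top down: soft tissue over lung over a
#: bone layer over soft tissue (thickness cm, HU).
DEFAULT_BODY_LAYERS = ((3.0, 0.0), (10.0, -700.0), (2.0, 800.0), (5.0, 0.0))


def make_layered_body(layers=None, lateral=(30.0, 30.0),
                      voxel_size=DEFAULT_VOXEL,
                      model: DensityModel | None = None) -> VoxelGrid:
    """Slab phantom with configurable HU layers stacked along the beam.

    ``layers`` is a top-down sequence of ``(thickness_cm, hu)`` pairs; the
    defaults emulate a thorax-like soft-tissue/lung/bone stack.  This is a
    heterogeneity test object, not an anatomical replica.
    """
    layers = tuple(layers) if layers is not None else DEFAULT_BODY_LAYERS
    if not layers or any(t <= 0 for t, _ in layers):
        raise ValueError("layers must have positive thicknesses")
    sz = voxel_size[2]
    height = sum(t for t, _ in layers)
    nz = max(1, int(round(height / sz)))
    shape = (max(1, int(round(lateral[0] / voxel_size[0]))),
             max(1, int(round(lateral[1] / voxel_size[1]))), nz)
    hu = np.zeros(shape, dtype=np.float32)
    z_centers_depth = (np.arange(nz)[::-1] + 0.5) * sz  # depth from top
    bounds = np.cumsum([t for t, _ in layers])
    layer_idx = np.searchsorted(bounds, z_centers_depth, side="right")
    layer_idx = np.clip(layer_idx, 0, len(layers) - 1)
    hu_per_layer = np.array([h for _, h in layers], dtype=np.float32)
    hu[:, :] = hu_per_layer[layer_idx][None, None, :]
    return VoxelGrid.from_hu(hu, voxel_size=voxel_size, model=model)


def read_ct_series(path) -> VoxelGrid:
    """Read a single-series axial DICOM CT directory into a VoxelGrid.

    Slices are ordered by table position; voxel size comes from the pixel
    spacing and slice spacing tags, HU from the rescale slope/intercept,
    and the grid is placed with its base on the 6.0 cm table top.
    """
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no files in {path}")
    slices = [pydicom.dcmread(f) for f in files]
    uids = {s.SeriesInstanceUID for s in slices}
    if len(uids) != 1:
        raise ValueError("directory holds more than one DICOM series")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    positions = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(slices) > 1:
        gaps = np.diff(positions)
        if np.ptp(gaps) > 1e-3 * abs(gaps.mean()) + 1e-6:
            raise ValueError("nonuniform slice spacing")
        dz_mm = float(abs(gaps.mean()))
    else:
        dz_mm = float(getattr(slices[0], "SliceThickness", 1.0))
    row_mm, col_mm = (float(v) for v in slices[0].PixelSpacing)
    hu = np.stack(
        [s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
         + float(getattr(s, "RescaleIntercept", 0.0)) for s in slices],
        axis=-1)  # (rows, cols, slices)
    voxel_size = (row_mm / 10.0, col_mm / 10.0, dz_mm / 10.0)
    return VoxelGrid.from_hu(hu.astype(np.float32), voxel_size=voxel_size)
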