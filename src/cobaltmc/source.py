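"""Co-60 source head and lead flattening-filter transport.

World frame: the treatment-room floor is z = 0 and the beam axis is the
vertical z axis.  The 2-cm-radius source disk sits 195.4 cm above the
floor and illuminates a 50 cm x 200 cm field at floor level (x across the
couch, y along it).  Six concentric round lead plates (0.3175 cm each)
form the flattening filter, stacked just below the source and clipped to
the 33 cm x 14 cm filter footprint, so thicker lead shadows the center of
the field than its periphery.

Filter transport keeps only zero- and single-scatter photons: a photon
either crosses its lead thickness untouched (probability ``exp(-mu t)``),
or undergoes exactly one interaction -- photoelectric absorption, Compton
scatter (recoil electron dismissed), or Rayleigh scatter -- after which it
must escape the remaining lead without further interaction or it is
dismissed.  Electrons set in motion in the filter never reach the patient
(an acrylic sheet removes electron contamination in the physical unit) and
are not tracked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel, materials, sampling
from .materials import LEAD
from .sampling import RandomStream, build_angle_table

__all__ = [
    "LEAD_DENSITY", "SourceModel", "FilterGeometry", "Photon",
    "emit_photon", "filter_path_thickness", "transport_through_filter",
    "project_to_entry_window",
]

#: Bulk density of the lead filter plates (g/cm^3).
LEAD_DENSITY = 11.35


@dataclass
class SourceModel:
    """Finite-disk Co-60 source collimated to the TBI floor field."""

    radius: float = 2.0            # cm
    height_above_floor: float = 195.4  # cm
    energy: float = 1.25           # MeV, single effective emission line
    field_width: float = 50.0      # cm at floor, x
    field_length: float = 200.0    # cm at floor, y


@dataclass
class FilterGeometry:
    """Stacked-plate lead flattening filter below the source."""

    plate_thickness: float = 0.3175  # cm per plate
    plate_diameters: tuple = (7.62, 12.7, 17.8, 22.9, 27.9, 33.0)  # cm
    source_to_bottom: float = 25.4   # cm from source to filter bottom
    length: float = 33.0             # cm footprint along y
    width: float = 14.0              # cm footprint along x

    @property
    def plate_count(self) -> int:
        return len(self.plate_diameters)

    @property
    def plate_radii(self) -> np.ndarray:
        return np.asarray(self.plate_diameters, dtype=float) / 2.0

    @property
    def stack_thickness(self) -> float:
        return self.plate_count * self.plate_thickness

    def mid_plane_height(self, source: SourceModel) -> float:
        """World z of the filter stack mid-plane (thin-stack approximation)."""
        z_bottom = source.height_above_floor - self.source_to_bottom
        return z_bottom + 0.5 * self.stack_thickness


@dataclass
class Photon:
    """A transported photon: position (cm), unit direction, energy (MeV)."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    scatter_count: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not math.isclose(n, 1.0, abs_tol=1e-9):
            self.direction = self.direction / n


def emit_photon(source: SourceModel, stream: RandomStream) -> Photon:
    """Emit a 1.25 MeV photon from the source disk toward the field.

    The emission point is uniform on the source disk; the direction is
    uniform in solid angle within the collimation limits, realized by
    sampling the floor-field rectangle uniformly and accepting with the
    cos^3 solid-angle weight of the target point.
    """
    z = source.height_above_floor
    fx = source.field_width / 2.0
    fy = source.field_length / 2.0
    while True:
        r = source.radius * math.sqrt(float(stream.uniform()))
        ang = 2.0 * math.pi * float(stream.uniform())
        x0, y0 = r * math.cos(ang), r * math.sin(ang)
        tx = fx * (2.0 * float(stream.uniform()) - 1.0)
        ty = fy * (2.0 * float(stream.uniform()) - 1.0)
        d = np.array([tx - x0, ty - y0, -z])
        norm = np.linalg.norm(d)
        cos_t = z / norm
        if float(stream.uniform()) < cos_t**3:
            break
    return Photon(position=np.array([x0, y0, z]), direction=d / norm,
                  energy=source.energy, scatter_count=0)


def filter_path_thickness(photon: Photon, filt: FilterGeometry,
                          source: SourceModel | None = None) -> float:
    """Lead thickness (cm) covering the photon ray at the filter plane.

    The thickness is the plate count at the ray's lateral position on the
    stack mid-plane times the per-plate thickness, with plates clipped to
    the filter footprint width; the central ray sees all six plates
    (1.905 cm) and rays beyond the largest plate see none.
    """
    if photon.direction[2] >= 0:
        raise ValueError("photon must be directed downward")
    source = source or SourceModel()
    z_mid = filt.mid_plane_height(source)
    s = (z_mid - photon.position[2]) / photon.direction[2]
    x = photon.position[0] + s * photon.direction[0]
    y = photon.position[1] + s * photon.direction[1]
    return float(_kernel.filter_thickness(
        x, y, filt.plate_radii, filt.width / 2.0, filt.plate_thickness))


def _lead_weights(energy: float) -> tuple[float, float, float]:
    pe, c, r = materials.mass_attenuation(LEAD, energy)
    tot = pe + c + r
    return float(pe / tot), float(c / tot), float(tot * LEAD_DENSITY)


def transport_through_filter(photon: Photon, filt: FilterGeometry,
                             stream: RandomStream,
                             source: SourceModel | None = None,
                             cutoff: float = 0.01) -> Photon | None:
    """Zero/single-scatter transport through the filter.

    Returns the surviving photon, advanced to the filter mid-plane, or
    ``None`` if it was absorbed or dismissed.  Surviving photons carry
    ``scatter_count`` 0 (unscattered) or 1 (single scatter) -- never more.
    """
    source = source or SourceModel()
    t = filter_path_thickness(photon, filt, source)
    z_mid = filt.mid_plane_height(source)
    s = (z_mid - photon.position[2]) / photon.direction[2]
    pos = photon.position + s * photon.direction
    out = Photon(position=pos, direction=photon.direction.copy(),
                 energy=photon.energy, scatter_count=photon.scatter_count)
    if t <= 0.0:
        return out
    w_pe, w_c, mu = _lead_weights(photon.energy)
    trans = math.exp(-mu * t)
    if float(stream.uniform()) < trans:
        return out
    depth = -math.log(1.0 - float(stream.uniform()) * (1.0 - trans)) / mu
    w = float(stream.uniform())
    if w < w_pe:
        return None  # photoelectric: absorbed, electron dismissed
    if w < w_pe + w_c:
        table = build_angle_table("compton")
        theta = sampling.sample_angle(table, photon.energy, stream)
        hvp = sampling.compton_scattered_energy(photon.energy, theta)
        if hvp < cutoff:
            return None
        out.energy = float(hvp)
    else:
        table = build_angle_table("rayleigh", LEAD)
        theta = sampling.sample_angle(table, photon.energy, stream)
    psi = sampling.sample_azimuth(stream)
    out.direction = sampling.rotate_direction(photon.direction, theta, psi)
    out.scatter_count = photon.scatter_count + 1
    # single-scatter rule: escape the remaining lead or be dismissed
    mu_out = _lead_weights(out.energy)[2]
    if float(stream.uniform()) >= math.exp(-mu_out * (t - depth)):
        return None
    return out


def project_to_entry_window(photon: Photon, grid) -> Photon | None:
    """Advance the photon in vacuum to the top plane of the voxel grid.

    Photons whose straight-line intersection with the entry plane falls
    outside the grid's lateral extent (or that travel upward) are
    dismissed; energy and direction are untouched by the projection.
    """
    if photon.direction[2] >= -1e-12:
        return None
    z_top = grid.origin[2] + grid.shape[2] * grid.voxel_size[2]
    s = (z_top - photon.position[2]) / photon.direction[2]
    if s < 0:
        return None
    pos = photon.position + s * photon.direction
    x_min, y_min = grid.origin[0], grid.origin[1]
    x_max = x_min + grid.shape[0] * grid.voxel_size[0]
    y_max = y_min + grid.shape[1] * grid.voxel_size[1]
    if not (x_min <= pos[0] < x_max and y_min <= pos[1] < y_max):
        return None
    return Photon(position=pos, direction=photon.direction.copy(),
                  energy=photon.energy, scatter_count=photon.scatter_count)
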