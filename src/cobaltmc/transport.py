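"""In-patient voxel Monte Carlo: stepping, interactions, dose scoring.

Photons are stepped through the CT-derived density grid by survival
probability: a flight draws one uniform surviving probability, then
accumulates transmission ``exp(-sum h / lambda_j)`` in fixed steps of
``h`` (default 1 mm) using the mean free path of the voxel at each step
midpoint, and interacts at the first step where the accumulated
transmission falls below the draw.  In tissue only photoelectric
absorption and Compton scattering compete (coherent scattering is
excluded); recoil and photo-electrons deposit energy along straight lines
in the continuous-slowing-down approximation with no angular scatter.
Photons and electrons below the 10 keV cutoff deposit their remaining
energy in the local voxel.

Dose to medium is the deposited energy per voxel mass; dose to water is
obtained at the end of a run by multiplying each voxel with the
water-to-medium collision stopping-power ratio at 0.3 MeV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import _kernel, materials, sampling
from .materials import LEAD, DensityModel, transport_grids
from .sampling import RandomStream, build_angle_table
from .source import (LEAD_DENSITY, FilterGeometry, Photon, SourceModel)

__all__ = [
    "VoxelGrid", "Electron", "DoseGrid", "TransportConfig",
    "step_photon_to_interaction", "choose_interaction", "do_photoelectric",
    "do_compton", "transport_electron_csda", "run_simulation",
    "dose_to_water",
]

#: Height of the patient support surface above the floor (cm).
TABLE_TOP_HEIGHT = 6.0


@dataclass
class VoxelGrid:
    """Voxelized patient/phantom: HU, density and material per voxel.

    Voxel ``(i, j, k)`` spans the half-open box ``origin + idx * size`` to
    ``origin + (idx + 1) * size``; ``origin`` is the minimum corner, so
    ``k`` increases upward and the beam enters through the top face.
    """

    hu: np.ndarray
    voxel_size: tuple
    origin: np.ndarray
    density: np.ndarray
    material: np.ndarray
    table_top_height: float = TABLE_TOP_HEIGHT

    def __post_init__(self) -> None:
        self.hu = np.ascontiguousarray(self.hu, dtype=np.float32)
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        self.material = np.ascontiguousarray(self.material, dtype=np.uint8)
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.density.shape != self.hu.shape \
                or self.material.shape != self.hu.shape:
            raise ValueError("density/material arrays must match the HU shape")
        if np.any(self.density <= 0):
            raise ValueError("densities must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @classmethod
    def from_hu(cls, hu: np.ndarray, voxel_size=(0.254, 0.254, 0.5),
                origin=None, model: DensityModel | None = None,
                table_top_height: float = TABLE_TOP_HEIGHT) -> "VoxelGrid":
        """Build a grid from a HU volume via the bilinear CT calibration.

        With no explicit ``origin`` the grid is centered laterally on the
        beam axis with its base resting on the patient support surface,
        ``table_top_height`` above the floor.
        """
        model = model or DensityModel()
        hu = np.asarray(hu)
        density = model.density(hu.astype(float))
        material = model.material(density)
        if origin is None:
            origin = np.array([
                -hu.shape[0] * voxel_size[0] / 2.0,
                -hu.shape[1] * voxel_size[1] / 2.0,
                table_top_height,
            ])
        return cls(hu=hu, voxel_size=voxel_size, origin=origin,
                   density=density, material=material,
                   table_top_height=table_top_height)

    @property
    def shape(self) -> tuple:
        return self.hu.shape

    @property
    def z_top(self) -> float:
        return float(self.origin[2] + self.shape[2] * self.voxel_size[2])

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.voxel_size
        return sx * sy * sz

    def voxel_index(self, position) -> tuple:
        idx = np.floor((np.asarray(position) - self.origin)
                       / np.asarray(self.voxel_size)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise IndexError("position outside grid")
        return tuple(idx)


@dataclass
class Electron:
    """A CSDA-transported electron."""

    position: np.ndarray
    direction: np.ndarray
    kinetic_energy: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.direction = self.direction / np.linalg.norm(self.direction)
        if self.kinetic_energy < 0:
            raise ValueError("kinetic energy must be nonnegative")


@dataclass
class TransportConfig:
    """Run parameters for the voxel Monte Carlo."""

    n_histories: int = 1_000_000
    seed: int = 0
    step_h: float = 0.1        # cm; stepping resolution for photons/electrons
    cutoff: float = 0.01       # MeV; local absorption below this energy
    literal_recoil: bool = False  # flip the recoil-angle sign (see docs)

    def __post_init__(self) -> None:
        if self.step_h <= 0 or self.cutoff <= 0:
            raise ValueError("step size and cutoff must be positive")
        if self.n_histories <= 0:
            raise ValueError("history count must be positive")


@dataclass
class DoseGrid:
    """Scored energy deposition and derived dose arrays."""

    energy_deposited: np.ndarray  # MeV per voxel
    grid: VoxelGrid
    histories: int
    counters: dict = field(default_factory=dict)

    @property
    def dose_medium(self) -> np.ndarray:
        """Dose to the voxel medium (MeV/g)."""
        return self.energy_deposited / (self.grid.voxel_volume
                                        * self.grid.density)

    @property
    def dose_water(self) -> np.ndarray:
        """Dose to water (MeV/g), via Bragg-Gray stopping-power ratios."""
        return dose_to_water(self)

    @property
    def energy_entered(self) -> float:
        return self.counters.get("energy_entered", math.nan)

    @property
    def energy_exited(self) -> float:
        return self.counters.get("energy_exited", math.nan)


@lru_cache(maxsize=4)
def _kernel_tables(literal_rayleigh: bool = False):
    """Assemble the flat lookup arrays consumed by the numba kernels."""
    g = transport_grids()
    att_nc = np.ascontiguousarray(g["pe"] + g["compton"])
    frac_pe = np.ascontiguousarray(g["pe"] / att_nc)
    stop = np.ascontiguousarray(g["stop"])
    mu_pb_lin = np.ascontiguousarray(
        (g["pe"][LEAD] + g["compton"][LEAD] + g["rayleigh"][LEAD])
        * LEAD_DENSITY)
    compton_tab = np.ascontiguousarray(build_angle_table("compton").angles_rad)
    ray_tab = build_angle_table(
        "rayleigh", LEAD, literal_rayleigh=literal_rayleigh)
    rayleigh_row = np.ascontiguousarray(ray_tab.angles_rad[-1])
    pe, c, r = (g["pe"][LEAD, -1], g["compton"][LEAD, -1],
                g["rayleigh"][LEAD, -1])
    tot = pe + c + r
    return {
        "att_nc": att_nc, "frac_pe": frac_pe, "stop": stop,
        "spr": np.ascontiguousarray(g["spr"]),
        "mu_pb_lin": mu_pb_lin, "compton_tab": compton_tab,
        "rayleigh_row": rayleigh_row,
        "w_pe": float(pe / tot), "w_pec": float((pe + c) / tot),
    }


def step_photon_to_interaction(photon: Photon, grid: VoxelGrid,
                               cfg: TransportConfig,
                               stream: RandomStream):
    """Step a photon to its next interaction site inside the grid.

    Draws the surviving probability once, then accumulates transmission in
    steps of ``cfg.step_h``; returns ``(site, voxel_index)`` at the
    interaction, or ``None`` if the photon leaves the grid first.
    """
    if photon.energy <= cfg.cutoff:
        raise ValueError("photon below cutoff should have been absorbed")
    t = _kernel_tables()
    tau_target = -math.log(1.0 - float(stream.uniform()))
    erow = _kernel.energy_row(photon.energy, t["att_nc"].shape[1] - 1)
    hit, x, y, z = _kernel.step_to_interaction(
        photon.position[0], photon.position[1], photon.position[2],
        photon.direction[0], photon.direction[1], photon.direction[2],
        tau_target, erow, grid.density, grid.material, t["att_nc"],
        grid.origin, np.asarray(grid.voxel_size), cfg.step_h)
    if not hit:
        return None
    site = np.array([x, y, z])
    try:
        idx = grid.voxel_index(site)
    except IndexError:
        return None  # stepped past the boundary on the final step
    return site, idx


def choose_interaction(photon: Photon, voxel_material: int,
                       stream: RandomStream) -> str:
    """Draw photoelectric vs Compton from their attenuation shares."""
    pe, c, _ = materials.mass_attenuation(voxel_material, photon.energy)
    return "photoelectric" if float(stream.uniform()) < pe / (pe + c) \
        else "compton"


def do_photoelectric(photon: Photon, site, grid: VoxelGrid,
                     dose: np.ndarray) -> None:
    """Absorb the photon, depositing its full energy in the local voxel.

    The ejected photoelectron is not transported: its range at the
    energies where photoelectric absorption matters is below the voxel
    size, so local deposition is exact to within the grid resolution.
    """
    idx = grid.voxel_index(site)
    dose[idx] += photon.energy
    photon.energy = 0.0


def do_compton(photon: Photon, site, cfg: TransportConfig,
               stream: RandomStream):
    """Sample a Compton event; returns (scattered photon, recoil electron).

    The scattered photon's angle comes from the pre-inverted table at the
    snapped energy row and its energy from the Compton relation, so photon
    plus electron energy is conserved exactly.  Either particle may come
    back below the cutoff; the caller deposits such energies locally (a
    ``None`` electron stands for a zero-energy recoil at theta = 0).
    """
    table = build_angle_table("compton")
    theta = sampling.sample_angle(table, photon.energy, stream)
    psi = sampling.sample_azimuth(stream)
    hvp = float(sampling.compton_scattered_energy(photon.energy, theta))
    te = photon.energy - hvp
    scattered = Photon(
        position=np.asarray(site, dtype=float),
        direction=sampling.rotate_direction(photon.direction, theta, psi),
        energy=hvp, scatter_count=photon.scatter_count + 1)
    if theta <= 0.0 or te <= 0.0:
        return scattered, None
    phi, psi_e = sampling.recoil_electron_direction(
        photon.energy, theta, psi, literal=cfg.literal_recoil)
    electron = Electron(
        position=np.asarray(site, dtype=float),
        direction=sampling.rotate_direction(photon.direction, phi, psi_e),
        kinetic_energy=te)
    return scattered, electron


def transport_electron_csda(electron: Electron, grid: VoxelGrid,
                            cfg: TransportConfig,
                            dose: np.ndarray) -> float:
    """Deposit an electron's energy along a straight CSDA track.

    Each step of ``cfg.step_h`` deposits ``S/rho * rho * h`` of the
    remaining kinetic energy into the midpoint voxel; the sub-cutoff
    remainder is deposited locally.  Returns the energy carried out of the
    grid (zero for fully contained tracks).
    """
    t = _kernel_tables()
    escaped = _kernel.deposit_electron(
        electron.position[0], electron.position[1], electron.position[2],
        electron.direction[0], electron.direction[1], electron.direction[2],
        electron.kinetic_energy, grid.density, grid.material, t["stop"],
        grid.origin, np.asarray(grid.voxel_size), cfg.step_h, cfg.cutoff,
        dose)
    return float(escaped)


def dose_to_water(dose: DoseGrid) -> np.ndarray:
    """Convert dose-to-medium to dose-to-water (applied post-simulation).

    Multiplies each voxel by the water-to-medium mass collision
    stopping-power ratio at 0.3 MeV; water voxels are unchanged, so the
    conversion is idempotent there.
    """
    spr = _kernel_tables()["spr"]
    return dose.dose_medium * spr[dose.grid.material]


def run_simulation(grid: VoxelGrid, cfg: TransportConfig,
                   source: SourceModel | None = None,
                   filt: FilterGeometry | None = None) -> DoseGrid:
    """Run the full source -> filter -> patient cascade.

    Emits ``cfg.n_histories`` primaries, transports them through the
    flattening filter and, for those crossing the entry window, through
    the voxel grid with all secondary electrons, and returns the scored
    :class:`DoseGrid`.  Identical seeds give bit-identical dose arrays.
    """
    source = source or SourceModel()
    filt = filt or FilterGeometry()
    t = _kernel_tables()
    src_params = np.array([source.radius, source.height_above_floor,
                           source.field_width / 2.0,
                           source.field_length / 2.0])
    filt_params = np.array([filt.mid_plane_height(source), filt.width / 2.0,
                            filt.plate_thickness, t["w_pe"], t["w_pec"]])
    dose = np.zeros(grid.shape, dtype=np.float64)
    counters = np.zeros(_kernel.N_COUNTERS, dtype=np.float64)
    _kernel.run_histories(
        int(cfg.n_histories), int(cfg.seed) & 0x7FFFFFFF,
        src_params, filt_params, filt.plate_radii,
        t["mu_pb_lin"], t["compton_tab"], t["rayleigh_row"],
        grid.density, grid.material, grid.origin,
        np.asarray(grid.voxel_size),
        t["att_nc"], t["frac_pe"], t["stop"],
        cfg.step_h, cfg.cutoff,
        -1.0 if cfg.literal_recoil else 1.0,
        dose, counters)
    names = ["n_emitted", "n_filter_pass", "n_filter_scattered",
             "n_filter_lost", "n_window_dismissed", "n_entered",
             "energy_entered", "energy_exited", "n_interactions",
             "n_photoelectric", "n_compton"]
    return DoseGrid(energy_deposited=dose, grid=grid,
                    histories=int(cfg.n_histories),
                    counters=dict(zip(names, counters.tolist())))
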