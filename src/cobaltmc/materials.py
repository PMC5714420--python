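"""Material physics data: CT calibration, attenuation, stopping powers.

All quantities are mass coefficients so that the voxel transport can scale
them by the CT-derived density.  Tables are shipped as plain-text CSV files
(one per material) covering 10 keV to 1.33 MeV and are interpolated
log-log between nodes, the standard practice for attenuation data.

The CT number to density calibration is the bilinear fit used clinically::

    rho = 0.001  * HU + 1.034   (HU <= 0)
    rho = 0.0006 * HU + 1.034   (HU > 0)

so water-equivalent tissue (HU = 0) is assigned 1.034 g/cm^3, and air
(HU = -1000) 0.034 g/cm^3.  A voxel's material class is then chosen from
its density via conventional CT segmentation bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "MATERIALS",
    "AIR", "LUNG", "WATER", "SOFT_TISSUE", "BONE", "ALUMINUM", "LEAD",
    "MaterialTable", "DensityModel",
    "hu_to_density", "density_to_material", "material_table",
    "mass_attenuation", "mean_free_path", "collision_stopping_power",
    "water_spr", "lead_form_factor",
]

# Material identifiers. Lead appears only in the flattening filter; the
# patient material set is AIR..ALUMINUM.
AIR, LUNG, WATER, BONE, ALUMINUM, LEAD = 0, 1, 2, 3, 4, 5
SOFT_TISSUE = WATER  # soft tissue is treated as water-equivalent

MATERIALS = {
    AIR: "air",
    LUNG: "lung",
    WATER: "water",
    BONE: "bone",
    ALUMINUM: "aluminum",
    LEAD: "lead",
}

#: Reference energy (MeV) for Bragg-Gray stopping-power ratios.
SPR_ENERGY = 0.3

#: Densities below this floor are clamped (g/cm^3); keeps the mean free
#: path finite for HU values at or below -1034.
DENSITY_FLOOR = 0.001

_ENERGY_MIN = 0.010
_ENERGY_MAX = 1.330


@dataclass(frozen=True)
class MaterialTable:
    """Per-material physics table on an ascending energy grid.

    Attenuation components are mass coefficients in cm^2/g; the collision
    stopping power is in MeV cm^2/g.
    """

    material_id: int
    name: str
    energy_grid: np.ndarray
    mu_over_rho_pe: np.ndarray
    mu_over_rho_compton: np.ndarray
    mu_over_rho_rayleigh: np.ndarray
    stopping_power_collision: np.ndarray

    def __post_init__(self) -> None:
        e = self.energy_grid
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if e[0] > _ENERGY_MIN or e[-1] < _ENERGY_MAX:
            raise ValueError("energy grid must cover [10 keV, 1.33 MeV]")
        for arr in (self.mu_over_rho_pe, self.mu_over_rho_compton,
                    self.mu_over_rho_rayleigh, self.stopping_power_collision):
            if np.any(arr <= 0):
                raise ValueError("coefficients must be strictly positive")

    @property
    def total(self) -> np.ndarray:
        return (self.mu_over_rho_pe + self.mu_over_rho_compton
                + self.mu_over_rho_rayleigh)

    @property
    def spr_water_over_medium(self) -> float:
        return water_spr(self.material_id)

    def _interp(self, values: np.ndarray, energy) -> np.ndarray:
        energy = np.asarray(energy, dtype=float)
        if np.any(~np.isfinite(energy)):
            raise ValueError("energy must be finite")
        if np.any(energy < _ENERGY_MIN) or np.any(energy > _ENERGY_MAX):
            raise ValueError(
                f"energy outside table range [{_ENERGY_MIN}, {_ENERGY_MAX}] MeV"
            )
        out = np.exp(np.interp(np.log(energy), np.log(self.energy_grid),
                               np.log(values)))
        return out


@dataclass(frozen=True)
class DensityModel:
    """Bilinear HU-to-density calibration plus density-to-material bins."""

    slope_neg: float = 0.001    # g/cm^3 per HU, HU <= 0
    slope_pos: float = 0.0006   # g/cm^3 per HU, HU > 0
    intercept: float = 1.034    # g/cm^3 at HU = 0
    #: Upper density edges (g/cm^3) for air, lung, soft tissue, bone; above
    #: the last edge the voxel is classed as metal (aluminum).
    material_bin_edges: tuple = (0.05, 0.6, 1.1, 2.0)
    _bin_materials: tuple = field(
        default=(AIR, LUNG, WATER, BONE, ALUMINUM), repr=False)

    def density(self, hu):
        hu = np.asarray(hu, dtype=float)
        if np.any(~np.isfinite(hu)):
            raise ValueError("HU must be finite")
        slope = np.where(hu <= 0, self.slope_neg, self.slope_pos)
        rho = slope * hu + self.intercept
        out = np.maximum(rho, DENSITY_FLOOR)
        return out if out.ndim else float(out)

    def material(self, density):
        density = np.asarray(density, dtype=float)
        if np.any(density <= 0):
            raise ValueError("density must be positive")
        idx = np.searchsorted(np.asarray(self.material_bin_edges), density,
                              side="left")
        out = np.asarray(self._bin_materials, dtype=np.uint8)[idx]
        return out if out.ndim else int(out)


_DEFAULT_DENSITY_MODEL = DensityModel()


def hu_to_density(hu, model: DensityModel | None = None):
    """Convert CT numbers to mass density (g/cm^3), clamped positive."""
    return (model or _DEFAULT_DENSITY_MODEL).density(hu)


def density_to_material(density, model: DensityModel | None = None):
    """Bin a density into a material id (air/lung/soft tissue/bone/metal)."""
    return (model or _DEFAULT_DENSITY_MODEL).material(density)


@lru_cache(maxsize=None)
def material_table(material_id: int) -> MaterialTable:
    """Load the embedded :class:`MaterialTable` for a material id."""
    try:
        name = MATERIALS[material_id]
    except KeyError:
        raise ValueError(f"unknown material id {material_id}") from None
    ref = resources.files("cobaltmc.data") / f"material_{name}.csv"
    with resources.as_file(ref) as path:
        raw = np.loadtxt(path, delimiter=",")
    return MaterialTable(
        material_id=material_id,
        name=name,
        energy_grid=raw[:, 0],
        mu_over_rho_pe=raw[:, 1],
        mu_over_rho_compton=raw[:, 2],
        mu_over_rho_rayleigh=raw[:, 3],
        stopping_power_collision=raw[:, 5],
    )


def mass_attenuation(material_id: int, energy):
    """Mass attenuation components ``(pe, compton, rayleigh)`` in cm^2/g."""
    t = material_table(material_id)
    return (t._interp(t.mu_over_rho_pe, energy),
            t._interp(t.mu_over_rho_compton, energy),
            t._interp(t.mu_over_rho_rayleigh, energy))


def mean_free_path(material_id: int, density: float, energy,
                   include_rayleigh: bool = True):
    """Photon mean free path (cm) at the given density.

    In-patient transport excludes the Rayleigh component (coherent
    scattering is negligible in tissue at these energies); pass
    ``include_rayleigh=False`` for that convention.
    """
    if np.any(np.asarray(density) <= 0):
        raise ValueError("density must be positive")
    pe, c, r = mass_attenuation(material_id, energy)
    mu = pe + c + (r if include_rayleigh else 0.0)
    return 1.0 / (mu * density)


def collision_stopping_power(material_id: int, energy):
    """Mass collision stopping power (MeV cm^2/g), log-log interpolated."""
    t = material_table(material_id)
    energy = np.asarray(energy, dtype=float)
    if np.any(energy < _ENERGY_MIN) or np.any(energy > 1.25 + 1e-12):
        raise ValueError("energy outside stopping-power range [0.01, 1.25] MeV")
    return t._interp(t.stopping_power_collision, energy)


def water_spr(material_id: int) -> float:
    """Water-to-medium mass collision stopping-power ratio at 0.3 MeV.

    This is the Bragg-Gray factor applied at the end of a simulation to
    convert dose-to-medium into dose-to-water; identically 1 for water.
    """
    if material_id == WATER:
        return 1.0
    s_w = float(collision_stopping_power(WATER, SPR_ENERGY))
    s_m = float(collision_stopping_power(material_id, SPR_ENERGY))
    return s_w / s_m


@lru_cache(maxsize=1)
def lead_form_factor() -> tuple:
    """Lead atomic form factor table ``(x, F)``, x in 1/Angstrom."""
    ref = resources.files("cobaltmc.data") / "form_factor_lead.csv"
    with resources.as_file(ref) as path:
        raw = np.loadtxt(path, delimiter=",")
    return raw[:, 0], raw[:, 1]


def transport_grids(energy_step: float = 0.01, n_rows: int = 125):
    """Resample material data onto the uniform lookup grid used in transport.

    Returns a dict of ``(n_materials, n_rows + 1)`` arrays indexed by
    ``round(E / energy_step)`` (row 0 is a copy of row 1 and is never used;
    particles below the 10 keV cutoff are absorbed locally).
    """
    n_mat = len(MATERIALS)
    shape = (n_mat, n_rows + 1)
    pe = np.empty(shape)
    compton = np.empty(shape)
    rayleigh = np.empty(shape)
    stop = np.empty(shape)
    energies = np.arange(1, n_rows + 1) * energy_step
    for mid in MATERIALS:
        p, c, r = mass_attenuation(mid, energies)
        pe[mid, 1:], compton[mid, 1:], rayleigh[mid, 1:] = p, c, r
        stop[mid, 1:] = collision_stopping_power(
            mid, np.minimum(energies, 1.25))
    pe[:, 0], compton[:, 0] = pe[:, 1], compton[:, 1]
    rayleigh[:, 0], stop[:, 0] = rayleigh[:, 1], stop[:, 1]
    spr = np.array([water_spr(mid) for mid in sorted(MATERIALS)])
    return {"pe": pe, "compton": compton, "rayleigh": rayleigh,
            "stop": stop, "spr": spr, "energy_step": energy_step}
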