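"""Scattering kinematics and discretized inverse-CDF angle sampling.

The engine never inverts a cross section at run time.  For each process the
differential cross section is discretized at 1 degree resolution, summed
into a CDF, and quantized into 1000 slots: slot ``round(u * 1000)`` of a
uniform deviate ``u`` directly holds the sampled polar angle.  Tables are
built for every 10 keV photon energy up to 1.25 MeV, and an event's energy
is snapped to the nearest table row, so a sample costs one lookup.

Conventions:

* ``theta`` is the photon polar deflection, sampled over [0, pi] with the
  solid-angle Jacobian ``sin(theta)`` applied to the Klein-Nishina cross
  section before discretization.
* The Compton recoil electron leaves at ``cot(phi) = (1 + hv/m0c^2) *
  tan(theta/2)`` (always forward of the incoming photon) with azimuth
  opposite the scattered photon.  A ``literal`` switch evaluates the same
  relation with a minus sign for comparison; that variant sends recoil
  electrons backward and is provided only as a sensitivity study.
* Rayleigh scattering uses Thomson angular dependence ``(1 + cos^2 theta)``
  times the squared atomic form factor; a ``literal`` switch substitutes
  ``(1 - cos^2 theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .materials import LEAD, lead_form_factor

__all__ = [
    "R0_CM", "MEC2", "RandomStream", "AngleTable",
    "klein_nishina_dcs", "compton_scattered_energy", "rayleigh_dcs",
    "build_angle_table", "sample_angle", "sample_azimuth",
    "rotate_direction", "recoil_electron_direction",
]

#: Classical electron radius (cm), from e^2 / (4 pi eps0 m0 c^2).
R0_CM = 2.8179403262e-13
#: Electron rest energy (MeV).
MEC2 = 0.51099895

_N_BINS = 1000
_ENERGY_STEP = 0.01
_N_ROWS = 125  # rows at 10 keV .. 1.25 MeV


class RandomStream:
    """Seeded Mersenne-twister uniform deviate stream.

    Identical seeds yield identical sequences, which makes every sampling
    operation in the package reproducible run to run.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self._state = np.random.RandomState(self.seed)

    def uniform(self, size=None):
        """Uniform deviates in [0, 1)."""
        u = self._state.random_sample(size)
        return u


def compton_scattered_energy(hv, theta):
    """Scattered photon energy (MeV) after Compton deflection ``theta``."""
    hv = np.asarray(hv, dtype=float)
    if np.any(hv <= 0):
        raise ValueError("photon energy must be positive")
    out = hv / (1.0 + hv / MEC2 * (1.0 - np.cos(theta)))
    return out if out.ndim or np.ndim(theta) else float(out)


def klein_nishina_dcs(hv, theta):
    """Klein-Nishina differential cross section per electron (cm^2/sr)."""
    hv = np.asarray(hv, dtype=float)
    if np.any(hv <= 0):
        raise ValueError("photon energy must be positive")
    hvp = compton_scattered_energy(hv, theta)
    ratio = hvp / hv
    out = 0.5 * R0_CM**2 * ratio**2 * (1.0 / ratio + ratio
                                       - np.sin(theta) ** 2)
    return out if np.ndim(out) else float(out)


def rayleigh_dcs(hv, theta, material: int = LEAD, literal: bool = False):
    """Unnormalized Rayleigh polar-angle density at ``theta`` (radians).

    Thomson angular factor times the squared atomic form factor times the
    ``sin(theta)`` Jacobian; zero at both endpoints.  Only the lead filter
    uses coherent scattering, so only the lead form factor is shipped.
    """
    if material != LEAD:
        raise ValueError("Rayleigh sampling is only supported for lead")
    theta = np.asarray(theta, dtype=float)
    x_grid, f_grid = lead_form_factor()
    # momentum-transfer variable x = sin(theta/2)/lambda in 1/Angstrom
    x = np.sin(theta / 2.0) * np.asarray(hv, dtype=float) / 1.23984193e-2
    f = np.interp(x, x_grid, f_grid)
    c2 = np.cos(theta) ** 2
    angular = (1.0 - c2) if literal else (1.0 + c2)
    out = angular * np.sin(theta) * f**2
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AngleTable:
    """Pre-inverted polar-angle sampling table.

    ``angles_deg[i, j]`` holds the angle (integer degrees, 0..180) drawn by
    deviate slot ``j = round(u * 1000)`` at energy row ``i`` (row energy
    ``i * 10 keV``; row 0 is unused padding below the transport cutoff).
    """

    process: str
    material: int | None
    energy_step: float
    angles_deg: np.ndarray  # (n_rows + 1, 1001) int16

    def __post_init__(self) -> None:
        if self.angles_deg.min() < 0 or self.angles_deg.max() > 180:
            raise ValueError("stored angles must lie in [0, 180] degrees")

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg.astype(np.float64))

    def row_for(self, energy: float) -> int:
        row = int(round(energy / self.energy_step))
        if row < 1:
            raise ValueError(
                "energy below the transport cutoff has no sampling row")
        return min(row, self.angles_deg.shape[0] - 1)


def _invert_density(weights: np.ndarray) -> np.ndarray:
    """Quantize a discrete angular density into 1001 lookup slots."""
    total = weights.sum()
    if total <= 0:
        raise ValueError("angular density must have positive mass")
    cdf = np.cumsum(weights) / total
    u = np.arange(_N_BINS + 1) / _N_BINS
    return np.searchsorted(cdf, u, side="left").clip(0, len(weights) - 1)


@lru_cache(maxsize=None)
def build_angle_table(process: str, material: int | None = None,
                      literal_rayleigh: bool = False) -> AngleTable:
    """Build the inverse-CDF table for ``compton`` or ``rayleigh``.

    Compton tables are per-electron (Klein-Nishina) and therefore material
    independent; Rayleigh tables require the material form factor (lead).
    """
    deg = np.arange(181)
    theta = np.deg2rad(deg)
    table = np.empty((_N_ROWS + 1, _N_BINS + 1), dtype=np.int16)
    for row in range(1, _N_ROWS + 1):
        hv = row * _ENERGY_STEP
        if process == "compton":
            w = klein_nishina_dcs(hv, theta) * np.sin(theta)
        elif process == "rayleigh":
            w = rayleigh_dcs(hv, theta, LEAD if material is None else material,
                             literal=literal_rayleigh)
        else:
            raise ValueError(f"unknown process {process!r}")
        table[row] = _invert_density(w)
    table[0] = table[1]
    return AngleTable(process=process, material=material,
                      energy_step=_ENERGY_STEP, angles_deg=table)


def sample_angle(table: AngleTable, energy: float,
                 stream: RandomStream) -> float:
    """Draw a polar angle (radians) from the table row nearest ``energy``."""
    row = table.row_for(energy)
    j = int(round(float(stream.uniform()) * _N_BINS))
    return float(np.deg2rad(table.angles_deg[row, j]))


def sample_azimuth(stream: RandomStream) -> float:
    """Uniform azimuthal angle in [0, 2 pi)."""
    return float(2.0 * np.pi * stream.uniform())


def rotate_direction(u, theta: float, psi: float) -> np.ndarray:
    """Deflect unit vector ``u`` by polar ``theta`` and azimuth ``psi``.

    The rotation is carried out in a local orthonormal frame built from
    ``u`` so that near-vertical directions are handled without gimbal
    degeneracy; the deviation angle between input and output is exactly
    ``theta`` and the norm is preserved.
    """
    u = np.asarray(u, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("direction must be a nonzero vector")
    u = u / n
    # local frame: e1, e2 perpendicular to u
    if abs(u[2]) < 0.99:
        a = np.array([0.0, 0.0, 1.0])
    else:
        a = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(a, u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    st, ct = np.sin(theta), np.cos(theta)
    out = ct * u + st * (np.cos(psi) * e1 + np.sin(psi) * e2)
    return out / np.linalg.norm(out)


def recoil_electron_direction(hv: float, theta_photon: float,
                              psi_photon: float,
                              literal: bool = False) -> tuple[float, float]:
    """Polar and azimuthal emission angles of the Compton recoil electron.

    Angles are measured from the incoming photon direction.  ``theta_photon``
    must be positive: a photon that is not deflected transfers no energy and
    produces no recoil electron.
    """
    if theta_photon <= 0:
        raise ValueError("no recoil electron for an undeflected photon")
    factor = (1.0 - hv / MEC2) if literal else (1.0 + hv / MEC2)
    cot_phi = factor * np.tan(theta_photon / 2.0)
    phi = float(np.arctan2(1.0, cot_phi))
    psi_e = float((psi_photon + np.pi) % (2.0 * np.pi))
    return phi, psi_e
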