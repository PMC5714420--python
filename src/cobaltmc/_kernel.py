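"""Numba transport kernels.

Single source of truth for the per-event math: the public operation-level
API wraps these helpers one event at a time, and :func:`run_histories`
fuses them into the full source -> filter -> voxel cascade loop.

Units: cm, MeV, g/cm^3.  Energy lookup rows are ``round(E / 10 keV)`` into
``(n_materials, 126)`` tables; row 0 sits below the transport cutoff and is
never used.  All randomness inside :func:`run_histories` comes from numba's
Mersenne-twister state seeded once per call, so a fixed seed reproduces the
dose array bit for bit.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MEC2 = 0.51099895
TWO_PI = 2.0 * math.pi

# counter indices for run_histories
N_EMITTED = 0
N_FILTER_PASS = 1
N_FILTER_SCATTERED = 2
N_FILTER_LOST = 3
N_WINDOW_DISMISSED = 4
N_ENTERED = 5
E_ENTERED = 6
E_EXITED = 7
N_INTERACTIONS = 8
N_PHOTOELECTRIC = 9
N_COMPTON = 10
N_COUNTERS = 11


@njit(cache=True)
def compton_energy(hv, theta):
    return hv / (1.0 + hv / MEC2 * (1.0 - math.cos(theta)))


@njit(cache=True)
def rotate(ux, uy, uz, theta, psi):
    """Deflect the unit vector (ux,uy,uz) by polar theta, azimuth psi."""
    if abs(uz) < 0.99:
        ax, ay, az = 0.0, 0.0, 1.0
    else:
        ax, ay, az = 1.0, 0.0, 0.0
    # e1 = a x u, normalized
    e1x = ay * uz - az * uy
    e1y = az * ux - ax * uz
    e1z = ax * uy - ay * ux
    n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= n1
    e1y /= n1
    e1z /= n1
    # e2 = u x e1
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x
    st = math.sin(theta)
    ct = math.cos(theta)
    cp = math.cos(psi)
    sp = math.sin(psi)
    ox = ct * ux + st * (cp * e1x + sp * e2x)
    oy = ct * uy + st * (cp * e1y + sp * e2y)
    oz = ct * uz + st * (cp * e1z + sp * e2z)
    n = math.sqrt(ox * ox + oy * oy + oz * oz)
    return ox / n, oy / n, oz / n


@njit(cache=True)
def filter_thickness(x, y, plate_radii, half_width, plate_t):
    """Lead thickness (cm) at lateral filter-plane position (x, y)."""
    if abs(x) > half_width:
        return 0.0
    r = math.sqrt(x * x + y * y)
    n = 0
    for i in range(plate_radii.shape[0]):
        if r <= plate_radii[i]:
            n += 1
    return n * plate_t


@njit(cache=True)
def energy_row(energy, n_rows):
    row = int(energy * 100.0 + 0.5)
    if row < 1:
        row = 1
    if row > n_rows:
        row = n_rows
    return row


@njit(cache=True)
def step_to_interaction(px, py, pz, dx, dy, dz, tau_target, erow,
                        density, material, att, origin, vox, h):
    """Survival-probability stepping to the next interaction site.

    Accumulates optical depth in steps of ``h`` using the voxel at each
    step midpoint until it reaches ``tau_target`` (drawn once per flight)
    or the photon leaves the grid.  Returns ``(hit, x, y, z)``.
    """
    nx, ny, nz = density.shape
    ox, oy, oz = origin[0], origin[1], origin[2]
    sx, sy, sz = vox[0], vox[1], vox[2]
    tau = 0.0
    x, y, z = px, py, pz
    hx, hy, hz = h * dx, h * dy, h * dz
    while True:
        mx = x + 0.5 * hx
        my = y + 0.5 * hy
        mz = z + 0.5 * hz
        i = int(math.floor((mx - ox) / sx))
        j = int(math.floor((my - oy) / sy))
        k = int(math.floor((mz - oz) / sz))
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            return False, x, y, z
        tau += density[i, j, k] * att[material[i, j, k], erow] * h
        x += hx
        y += hy
        z += hz
        if tau >= tau_target:
            return True, x, y, z


@njit(cache=True)
def deposit_electron(px, py, pz, dx, dy, dz, t_kin, density, material,
                     stop, origin, vox, h, cutoff, dose):
    """Straight-line CSDA electron deposition; returns escaped energy."""
    nx, ny, nz = density.shape
    ox, oy, oz = origin[0], origin[1], origin[2]
    sx, sy, sz = vox[0], vox[1], vox[2]
    n_rows = stop.shape[1] - 1
    x, y, z = px, py, pz
    hx, hy, hz = h * dx, h * dy, h * dz
    while t_kin >= cutoff:
        mx = x + 0.5 * hx
        my = y + 0.5 * hy
        mz = z + 0.5 * hz
        i = int(math.floor((mx - ox) / sx))
        j = int(math.floor((my - oy) / sy))
        k = int(math.floor((mz - oz) / sz))
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            return t_kin
        row = energy_row(t_kin, n_rows)
        de = stop[material[i, j, k], row] * density[i, j, k] * h
        if de > t_kin:
            de = t_kin
        dose[i, j, k] += de
        t_kin -= de
        x += hx
        y += hy
        z += hz
    if t_kin > 0.0:
        i = int(math.floor((x - ox) / sx))
        j = int(math.floor((y - oy) / sy))
        k = int(math.floor((z - oz) / sz))
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            return t_kin
        dose[i, j, k] += t_kin
    return 0.0


@njit(cache=True)
def run_histories(n_histories, seed,
                  src_params,     # radius, z_source, field_half_x, field_half_y
                  filt_params,    # z_mid, half_width_x, plate_t, w_pe, w_pe+c
                  plate_radii,
                  mu_pb_lin,      # (126,) linear attenuation of lead per row
                  compton_tab,    # (126, 1001) polar angles, radians
                  rayleigh_row,   # (1001,) lead Rayleigh angles at 1.25 MeV
                  density, material, origin, vox,
                  att_nc,         # (nmat, 126) pe+compton mass coefficient
                  frac_pe,        # (nmat, 126) photoelectric share
                  stop,           # (nmat, 126) collision stopping power
                  h, cutoff, recoil_sign,
                  dose, counters):
    """Full Co-60 TBI cascade for ``n_histories`` primaries."""
    np.random.seed(seed)
    src_r = src_params[0]
    z_src = src_params[1]
    fx = src_params[2]
    fy = src_params[3]
    z_mid = filt_params[0]
    half_w = filt_params[1]
    plate_t = filt_params[2]
    w_pe = filt_params[3]
    w_pec = filt_params[4]
    nx, ny, nz = density.shape
    z_top = origin[2] + nz * vox[2]
    x_max = origin[0] + nx * vox[0]
    y_max = origin[1] + ny * vox[1]
    n_rows = mu_pb_lin.shape[0] - 1
    mu_pb_125 = mu_pb_lin[n_rows]

    for _ in range(n_histories):
        counters[N_EMITTED] += 1.0
        # --- emission: uniform over the source disk, direction uniform in
        # solid angle within the collimated field (cos^3 rejection on a
        # uniformly sampled floor target).
        while True:
            r = src_r * math.sqrt(np.random.random())
            ang = TWO_PI * np.random.random()
            x0 = r * math.cos(ang)
            y0 = r * math.sin(ang)
            tx = fx * (2.0 * np.random.random() - 1.0)
            ty = fy * (2.0 * np.random.random() - 1.0)
            ddx = tx - x0
            ddy = ty - y0
            ddz = -z_src
            norm = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            cos_t = z_src / norm
            if np.random.random() < cos_t * cos_t * cos_t:
                break
        dx, dy, dz = ddx / norm, ddy / norm, ddz / norm
        energy = 1.25
        erow = n_rows

        # --- flattening filter (zero- or single-scatter transport)
        s = (z_mid - z_src) / dz
        x = x0 + s * dx
        y = y0 + s * dy
        z = z_mid
        t_f = filter_thickness(x, y, plate_radii, half_w, plate_t)
        if t_f > 0.0:
            trans = math.exp(-mu_pb_125 * t_f)
            if np.random.random() >= trans:
                # interaction inside the lead at sampled depth
                depth = -math.log(1.0 - np.random.random()
                                  * (1.0 - trans)) / mu_pb_125
                w = np.random.random()
                if w < w_pe:
                    counters[N_FILTER_LOST] += 1.0
                    continue  # photoelectric: photon absorbed
                if w < w_pec:
                    # Compton scatter in lead
                    j = int(np.random.random() * 1000.0 + 0.5)
                    theta = compton_tab[erow, j]
                    psi = TWO_PI * np.random.random()
                    hvp = compton_energy(energy, theta)
                    if hvp < cutoff:
                        counters[N_FILTER_LOST] += 1.0
                        continue
                    dx, dy, dz = rotate(dx, dy, dz, theta, psi)
                    energy = hvp
                    erow = energy_row(energy, n_rows)
                else:
                    # Rayleigh scatter: direction change only
                    j = int(np.random.random() * 1000.0 + 0.5)
                    theta = rayleigh_row[j]
                    psi = TWO_PI * np.random.random()
                    dx, dy, dz = rotate(dx, dy, dz, theta, psi)
                # single-scatter rule: must escape the remaining lead
                esc = math.exp(-mu_pb_lin[erow] * (t_f - depth))
                if np.random.random() >= esc:
                    counters[N_FILTER_LOST] += 1.0
                    continue
                counters[N_FILTER_SCATTERED] += 1.0
            else:
                counters[N_FILTER_PASS] += 1.0
        else:
            counters[N_FILTER_PASS] += 1.0

        # --- project to the patient entry window (vacuum flight)
        if dz >= -1e-12:
            counters[N_WINDOW_DISMISSED] += 1.0
            continue
        s = (z_top - z) / dz
        x += s * dx
        y += s * dy
        z = z_top
        if x < origin[0] or x >= x_max or y < origin[1] or y >= y_max:
            counters[N_WINDOW_DISMISSED] += 1.0
            continue
        counters[N_ENTERED] += 1.0
        counters[E_ENTERED] += energy

        # --- in-patient cascade
        while True:
            tau_target = -math.log(1.0 - np.random.random())
            hit, x, y, z = step_to_interaction(
                x, y, z, dx, dy, dz, tau_target, erow,
                density, material, att_nc, origin, vox, h)
            if not hit:
                counters[E_EXITED] += energy
                break
            i = int(math.floor((x - origin[0]) / vox[0]))
            j = int(math.floor((y - origin[1]) / vox[1]))
            k = int(math.floor((z - origin[2]) / vox[2]))
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                counters[E_EXITED] += energy
                break
            counters[N_INTERACTIONS] += 1.0
            mat = material[i, j, k]
            if np.random.random() < frac_pe[mat, erow]:
                # photoelectric: local absorption of the full photon energy
                counters[N_PHOTOELECTRIC] += 1.0
                dose[i, j, k] += energy
                break
            counters[N_COMPTON] += 1.0
            jj = int(np.random.random() * 1000.0 + 0.5)
            theta = compton_tab[erow, jj]
            psi = TWO_PI * np.random.random()
            hvp = compton_energy(energy, theta)
            t_e = energy - hvp
            if theta > 0.0 and t_e > 0.0:
                if t_e < cutoff:
                    dose[i, j, k] += t_e
                else:
                    cot_phi = (1.0 + recoil_sign * energy / MEC2) \
                        * math.tan(0.5 * theta)
                    phi = math.atan2(1.0, cot_phi)
                    psi_e = psi + math.pi
                    ex, ey, ez = rotate(dx, dy, dz, phi, psi_e)
                    esc = deposit_electron(x, y, z, ex, ey, ez, t_e,
                                           density, material, stop,
                                           origin, vox, h, cutoff, dose)
                    counters[E_EXITED] += esc
            dx, dy, dz = rotate(dx, dy, dz, theta, psi)
            if hvp < cutoff:
                dose[i, j, k] += hvp
                break
            energy = hvp
            erow = energy_row(energy, n_rows)
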