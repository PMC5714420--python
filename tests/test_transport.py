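"""Voxel transport: stepping, interactions, electrons, full runs."""

import math

import numpy as np
import pytest

import cobaltmc as cm
from cobaltmc import materials


@pytest.fixture
def cfg():
    return cm.TransportConfig(n_histories=1000, seed=1)


class TestVoxelGrid:
    def test_from_hu_builds_density_and_material(self):
        hu = np.full((4, 4, 4), -700.0, dtype=np.float32)
        grid = cm.VoxelGrid.from_hu(hu, voxel_size=(1, 1, 1))
        assert np.allclose(grid.density, 0.334)
        assert np.all(grid.material == materials.LUNG)
        assert grid.origin[2] == 6.0  # base on the table top

    def test_half_open_indexing(self):
        grid = cm.VoxelGrid.from_hu(np.zeros((4, 4, 4), dtype=np.float32),
                                    voxel_size=(1, 1, 1))
        assert grid.voxel_index(grid.origin + 1e-9) == (0, 0, 0)
        assert grid.voxel_index(grid.origin + [1.0, 0.5, 0.5]) == (1, 0, 0)
        with pytest.raises(IndexError):
            grid.voxel_index(grid.origin + [4.0, 0.5, 0.5])

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            cm.VoxelGrid(hu=np.zeros((2, 2, 2)), voxel_size=(1, 1, 1),
                         origin=[0, 0, 0], density=np.zeros((2, 2, 2)),
                         material=np.zeros((2, 2, 2)))


class TestStepping:
    def test_free_path_distribution_in_water(self, water_column,
                                             pencil_photon, cfg):
        """Interaction depths over many photons are exponential with the
        water mean free path at 1.25 MeV (within the 1 mm step scale)."""
        stream = cm.RandomStream(42)
        depths = []
        n = 30_000
        for _ in range(n):
            hit = cm.step_photon_to_interaction(pencil_photon, water_column,
                                                cfg, stream)
            if hit is not None:
                depths.append(water_column.z_top - hit[0][2])
        depths = np.array(depths)
        lam = cm.mean_free_path(materials.WATER, 1.034, 1.25,
                                include_rayleigh=False)
        depth_max = water_column.z_top - water_column.origin[2]
        # censored-exponential mean over [0, depth_max]
        expected = lam - depth_max * math.exp(-depth_max / lam) \
            / (1 - math.exp(-depth_max / lam))
        assert np.mean(depths) == pytest.approx(expected, rel=0.02)

    def test_vacuum_like_grid_everything_exits(self, cfg):
        hu = np.full((6, 6, 40), -1100.0, dtype=np.float32)
        grid = cm.VoxelGrid.from_hu(hu, voxel_size=(2.0, 2.0, 0.5))
        ph = cm.Photon([0, 0, grid.z_top], [0, 0, -1], 1.25)
        stream = cm.RandomStream(0)
        hits = sum(cm.step_photon_to_interaction(ph, grid, cfg, stream)
                   is not None for _ in range(2000))
        assert hits < 5

    def test_two_layer_interface_break(self, cfg):
        """Water-over-lung grid: interaction depths follow the piecewise
        exponential with a break at the interface."""
        hu = np.zeros((8, 8, 120), dtype=np.float32)
        hu[:, :, :60] = -700.0  # lower half lung (k=0 is the bottom)
        grid = cm.VoxelGrid.from_hu(hu, voxel_size=(2.0, 2.0, 0.25))
        ph = cm.Photon([0, 0, grid.z_top], [0, 0, -1], 1.25)
        stream = cm.RandomStream(9)
        depths = []
        for _ in range(40_000):
            hit = cm.step_photon_to_interaction(ph, grid, cfg, stream)
            if hit is not None:
                depths.append(grid.z_top - hit[0][2])
        depths = np.array(depths)
        lam_w = cm.mean_free_path(materials.WATER, 1.034, 1.25,
                                  include_rayleigh=False)
        lam_l = cm.mean_free_path(materials.LUNG, 0.334, 1.25,
                                  include_rayleigh=False)
        t_int = 15.0  # interface depth (cm)
        # fraction interacting before the interface vs closed form
        p_first = 1 - math.exp(-t_int / lam_w)
        p_total = 1 - math.exp(-t_int / lam_w - 15.0 / lam_l)
        frac = np.mean(depths < t_int) * np.mean(
            np.array(depths) < np.inf)  # depths already conditioned on hit
        n_hit = len(depths)
        se = math.sqrt(p_first / p_total * (1 - p_first / p_total) / n_hit)
        assert np.mean(depths < t_int) == pytest.approx(
            p_first / p_total, abs=4 * se + 0.01)

    def test_photon_below_cutoff_rejected(self, water_column, cfg):
        ph = cm.Photon([0, 0, water_column.z_top], [0, 0, -1], 0.005)
        with pytest.raises(ValueError):
            cm.step_photon_to_interaction(ph, water_column, cfg,
                                          cm.RandomStream(0))


class TestChooseInteraction:
    def test_compton_dominates_at_co60_energy(self):
        stream = cm.RandomStream(1)
        ph = cm.Photon([0, 0, 0], [0, 0, -1], 1.25)
        n = 20_000
        pe = sum(cm.choose_interaction(ph, materials.WATER, stream)
                 == "photoelectric" for _ in range(n))
        assert pe / n < 0.01

    def test_frequencies_match_coefficient_ratio(self):
        stream = cm.RandomStream(2)
        ph = cm.Photon([0, 0, 0], [0, 0, -1], 0.02)
        pe_c, c_c, _ = cm.mass_attenuation(materials.WATER, 0.02)
        p = pe_c / (pe_c + c_c)
        assert p > 0.5  # photoelectric dominates at 20 keV
        n = 20_000
        pe = sum(cm.choose_interaction(ph, materials.WATER, stream)
                 == "photoelectric" for _ in range(n))
        assert abs(pe / n - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestPhotoelectric:
    def test_local_deposition_bookkeeping(self, small_water_grid):
        dose = np.zeros(small_water_grid.shape)
        site = small_water_grid.origin + np.array([1.0, 1.0, 1.0])
        total = 0.0
        for e in np.linspace(0.02, 1.0, 50):
            ph = cm.Photon(site, [0, 0, -1], float(e))
            cm.do_photoelectric(ph, site, small_water_grid, dose)
            assert ph.energy == 0.0
            total += e
        assert dose.sum() == pytest.approx(total, rel=1e-12)
        assert np.count_nonzero(dose) == 1


class TestCompton:
    def test_energy_conservation_every_event(self, cfg):
        stream = cm.RandomStream(3)
        site = np.zeros(3)
        for _ in range(500):
            ph = cm.Photon(site, [0, 0, -1], 1.25)
            scattered, electron = cm.do_compton(ph, site, cfg, stream)
            te = electron.kinetic_energy if electron is not None else 0.0
            assert scattered.energy + te == pytest.approx(1.25, abs=1e-15)
            assert scattered.energy >= 1.25 / (1 + 2 * 1.25 / 0.51099895) \
                - 1e-9
            assert scattered.scatter_count == 1

    def test_mean_scattered_energy_matches_quadrature(self, cfg):
        from scipy.integrate import quad
        f = lambda t: cm.klein_nishina_dcs(1.25, t) * np.sin(t)
        norm = quad(f, 0, np.pi)[0]
        mean = quad(lambda t: cm.compton_scattered_energy(1.25, t) * f(t),
                    0, np.pi)[0] / norm
        var = quad(lambda t: cm.compton_scattered_energy(1.25, t) ** 2
                   * f(t), 0, np.pi)[0] / norm - mean**2
        stream = cm.RandomStream(4)
        site = np.zeros(3)
        n = 30_000
        es = [cm.do_compton(cm.Photon(site, [0, 0, -1], 1.25), site, cfg,
                            stream)[0].energy for _ in range(n)]
        tol = 3 * math.sqrt(var / n) + 2e-3  # + table discretization
        assert abs(np.mean(es) - mean) < tol


class TestElectronTransport:
    def test_energy_conserved_in_grid(self, small_water_grid):
        cfg = cm.TransportConfig(n_histories=1, seed=0, step_h=0.1)
        dose = np.zeros(small_water_grid.shape)
        center = small_water_grid.origin + np.array([10.0, 10.0, 10.0])
        e = cm.Electron(center, [0.3, 0.2, -0.93], 1.0)
        escaped = cm.transport_electron_csda(e, small_water_grid, cfg, dose)
        assert escaped == 0.0
        assert dose.sum() == pytest.approx(1.0, rel=1e-12)

    def test_csda_range_with_fine_steps(self):
        """0.3 MeV electron in unit-density water stops after ~0.084 cm
        (ESTAR CSDA range) when stepped finely."""
        hu = np.full((40, 40, 40), -34.0, dtype=np.float32)  # rho = 1.000
        grid = cm.VoxelGrid.from_hu(hu, voxel_size=(0.05, 0.05, 0.05))
        cfg = cm.TransportConfig(n_histories=1, seed=0, step_h=0.002)
        dose = np.zeros(grid.shape)
        start = grid.origin + np.array([1.0, 1.0, 1.0])
        e = cm.Electron(start, [0, 0, 1.0], 0.3)
        cm.transport_electron_csda(e, grid, cfg, dose)
        ks = np.nonzero(dose.sum(axis=(0, 1)))[0]
        track_length = (ks.max() - ks.min() + 1) * 0.05
        assert track_length == pytest.approx(0.084, abs=0.02)

    def test_higher_density_deposits_more_per_step(self):
        # thin water entrance layer (2 mm) over bone: the same electron
        # deposits more per step once it crosses into the denser medium
        hu = np.zeros((10, 10, 40), dtype=np.float32)
        hu[:, :, :38] = 800.0  # bone below the top two voxels
        grid = cm.VoxelGrid.from_hu(hu, voxel_size=(1.0, 1.0, 0.1))
        cfg = cm.TransportConfig(n_histories=1, seed=0, step_h=0.1)
        dose = np.zeros(grid.shape)
        start = np.array([grid.origin[0] + 5.0, grid.origin[1] + 5.0,
                          grid.z_top - 1e-6])
        e = cm.Electron(start, [0, 0, -1.0], 1.2)
        cm.transport_electron_csda(e, grid, cfg, dose)
        z_profile = dose.sum(axis=(0, 1))
        water_first_step = z_profile[39]
        bone_first_step = z_profile[37]
        assert bone_first_step > water_first_step


class TestRunSimulation:
    def test_seed_determinism_bit_identical(self, small_water_grid):
        cfg = cm.TransportConfig(n_histories=50_000, seed=77)
        a = cm.run_simulation(small_water_grid, cfg)
        b = cm.run_simulation(small_water_grid, cfg)
        assert np.array_equal(a.energy_deposited, b.energy_deposited)
        c = cm.run_simulation(small_water_grid,
                              cm.TransportConfig(n_histories=50_000, seed=78))
        assert not np.array_equal(a.energy_deposited, c.energy_deposited)

    def test_energy_conservation(self, small_water_grid):
        cfg = cm.TransportConfig(n_histories=100_000, seed=5)
        dose = cm.run_simulation(small_water_grid, cfg)
        deposited = dose.energy_deposited.sum()
        assert deposited + dose.energy_exited == pytest.approx(
            dose.energy_entered, rel=1e-9)
        assert deposited <= dose.energy_entered

    def test_error_scaling_with_histories(self, small_water_grid):
        """Relative standard error of the central-voxel dose falls as
        1/sqrt(N)."""
        center = (small_water_grid.shape[0] // 2,
                  small_water_grid.shape[1] // 2,
                  small_water_grid.shape[2] - 6)  # ~3 cm deep
        box = (slice(center[0] - 4, center[0] + 5),
               slice(center[1] - 4, center[1] + 5),
               slice(center[2] - 2, center[2] + 3))

        def spread(n, seeds):
            vals = [cm.run_simulation(
                small_water_grid,
                cm.TransportConfig(n_histories=n, seed=s)
            ).energy_deposited[box].sum() / n for s in seeds]
            return np.std(vals) / np.mean(vals)

        r1 = spread(20_000, range(10))
        r4 = spread(80_000, range(10, 20))
        assert r4 < r1  # must shrink
        assert r4 / r1 == pytest.approx(0.5, abs=0.25)

    def test_invalid_inputs(self, small_water_grid):
        with pytest.raises(ValueError):
            cm.TransportConfig(n_histories=0)
        with pytest.raises(ValueError):
            cm.TransportConfig(step_h=-1.0)


class TestDoseToWater:
    def test_water_grid_identity(self, small_water_grid):
        cfg = cm.TransportConfig(n_histories=30_000, seed=2)
        dose = cm.run_simulation(small_water_grid, cfg)
        assert np.array_equal(dose.dose_water, dose.dose_medium)

    def test_bone_scaling_and_zeros(self):
        hu = np.zeros((6, 6, 10), dtype=np.float32)
        hu[:, :, 4:6] = 800.0
        grid = cm.VoxelGrid.from_hu(hu, voxel_size=(2.0, 2.0, 1.0))
        dose = cm.DoseGrid(energy_deposited=np.ones(grid.shape), grid=grid,
                           histories=1)
        ratio = dose.dose_water / dose.dose_medium
        assert np.allclose(ratio[:, :, 4:6], cm.water_spr(materials.BONE))
        assert np.allclose(ratio[:, :, :4], 1.0)
        dose.energy_deposited[0, 0, 0] = 0.0
        assert dose.dose_water[0, 0, 0] == 0.0
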