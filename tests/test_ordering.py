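import math

import numpy as np
import pytest

from dmsopore import ordering as o
from dmsopore import synthetic as syn
from dmsopore.model_io import BilayerFrame, Trajectory

from conftest import chain_frame, point_dopc_frame, straight_chain, zigzag_chain

MAGIC = math.degrees(math.acos(1.0 / math.sqrt(3.0)))  # 54.7356...


class TestScd:
    def test_all_trans_vertical_chain_gives_half(self):
        """Chain along z: every reconstructed C-H is in-plane, -S_CD = 0.5."""
        f = chain_frame([zigzag_chain([1, 1, 1], [0, 0, 1])], [5, 5, 9])
        prof = o.scd_profile(Trajectory([f]))
        np.testing.assert_allclose(prof.minus_scd, 0.5, atol=1e-12)
        assert prof.mean_minus_scd == pytest.approx(0.5)

    def test_magic_angle_gives_zero(self):
        """Directors at the magic angle with uniform azimuth average to
        -S_CD = 0 (within 1e-3)."""
        s, c = math.sin(math.radians(MAGIC)), math.cos(math.radians(MAGIC))
        u = [s * math.cos(0.3), s * math.sin(0.3), c]
        chains = [zigzag_chain([10, 10, 10], u, azimuth=2 * np.pi * k / 12)
                  for k in range(12)]
        f = chain_frame(chains, [40, 40, 40])
        prof = o.scd_profile(Trajectory([f]))
        assert abs(prof.mean_minus_scd) < 1e-3

    def test_isotropic_directors_average_to_zero(self):
        rng = np.random.default_rng(42)
        chains = []
        for _ in range(800):
            c = rng.uniform(-1, 1)
            phi = rng.uniform(0, 2 * np.pi)
            s = math.sqrt(1 - c * c)
            chains.append(zigzag_chain(
                rng.uniform(5, 25, 3),
                [s * math.cos(phi), s * math.sin(phi), c],
                azimuth=rng.uniform(0, 2 * np.pi)))
        prof = o.scd_profile(Trajectory([chain_frame(chains, [60, 60, 60])]))
        assert abs(prof.mean_minus_scd) < 0.02

    def test_bounds_respected(self, lipid_traj):
        prof = o.scd_profile(lipid_traj)
        assert np.all(prof.minus_scd >= -1.0) and np.all(prof.minus_scd <= 0.5)

    def test_generator_target_recovered(self, lipid_traj):
        prof = o.scd_profile(lipid_traj)
        assert prof.mean_minus_scd == pytest.approx(0.1528, abs=0.005)

    def test_short_chain_skipped_with_warning(self):
        f = chain_frame([zigzag_chain([1, 1, 1], [0, 0, 1], n_carbons=2),
                         zigzag_chain([3, 3, 1], [0, 0, 1])], [6, 6, 9])
        with pytest.warns(UserWarning, match="shorter"):
            prof = o.scd_profile(Trajectory([f]))
        assert prof.mean_minus_scd == pytest.approx(0.5)


class TestTilt:
    def _two_leaflet_frame(self, upper_dir, lower_dir):
        up = straight_chain([2, 2, 6.0], upper_dir)
        lo = straight_chain([4, 4, 2.0], lower_dir)
        return chain_frame([up, lo], [8, 8, 10])

    def test_chains_along_outward_normals_zero_tilt(self):
        # chains grow toward the core: upper chain points down (-z)
        f = self._two_leaflet_frame([0, 0, -1], [0, 0, 1])
        t = o.tilt_angles(Trajectory([f]))
        assert t.tail_tilt_deg == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_chains_ninety_degrees(self):
        f = self._two_leaflet_frame([1, 0, 0], [0, 1, 0])
        t = o.tilt_angles(Trajectory([f]))
        assert t.tail_tilt_deg == pytest.approx(90.0, abs=1e-9)

    def test_generator_targets_recovered(self, lipid_traj):
        t = o.tilt_angles(lipid_traj)
        assert t.tail_tilt_deg == pytest.approx(28.26, abs=0.5)
        assert t.chol_tilt_deg == pytest.approx(30.88, abs=0.7)

    def test_mirror_invariance(self, lipid_traj):
        f = lipid_traj.frames[0]
        mirrored = BilayerFrame(
            f.topology,
            np.column_stack([f.positions[:, 0], f.positions[:, 1],
                             f.box[2] - f.positions[:, 2]]),
            f.box)
        t1 = o.tilt_angles(Trajectory([f]))
        t2 = o.tilt_angles(Trajectory([mirrored]))
        assert t2.tail_tilt_deg == pytest.approx(t1.tail_tilt_deg, abs=1e-9)
        assert t2.chol_tilt_deg == pytest.approx(t1.chol_tilt_deg, abs=1e-9)

    def test_scd_mirror_invariance(self, lipid_traj):
        f = lipid_traj.frames[0]
        mirrored = BilayerFrame(
            f.topology,
            np.column_stack([f.positions[:, 0], f.positions[:, 1],
                             f.box[2] - f.positions[:, 2]]),
            f.box)
        p1 = o.scd_profile(Trajectory([f]))
        p2 = o.scd_profile(Trajectory([mirrored]))
        np.testing.assert_allclose(p1.minus_scd, p2.minus_scd, atol=1e-12)


class TestLateralCorrelation:
    def test_poisson_points_give_unity(self):
        rng = np.random.default_rng(0)
        box = [6.4, 6.4, 8.0]
        frames = [point_dopc_frame(rng.uniform(0, 6.4, (200, 2)),
                                   rng.uniform(0, 6.4, (200, 2)), box,
                                   time=float(k)) for k in range(20)]
        c = o.lateral_correlation(Trajectory(frames), bin_width=0.1,
                                  r_max=3.0)
        sel = c.r_bins > 0.15
        # 3 sigma of the Poisson pair count per bin
        expected_pairs = np.where(c.c_value[sel] > 0,
                                  c.pair_counts[sel] / np.maximum(
                                      c.c_value[sel], 1e-12), np.inf)
        sigma = 3.0 / np.sqrt(np.maximum(c.pair_counts[sel], 1.0))
        assert np.all(np.abs(c.c_value[sel] - 1.0) <= sigma + 0.02)

    def test_square_lattice_first_peak_at_spacing(self):
        a = 0.8
        g = np.arange(8) * a + 0.4
        xy = np.stack(np.meshgrid(g, g), -1).reshape(-1, 2)
        f = point_dopc_frame(xy, xy + 0.05, [6.4, 6.4, 8.0])
        c = o.lateral_correlation(Trajectory([f]), bin_width=0.05, r_max=3.0)
        first = np.flatnonzero(c.pair_counts)[0]
        assert abs(c.r_bins[first] - a) <= c.r_edges[1]  # within one bin
        assert c.pair_counts[c.r_edges[1:] <= a - 0.03].sum() == 0

    def test_matches_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(7)
        box = np.array([4.0, 4.0, 8.0])
        up = rng.uniform(0, 4.0, (40, 2))
        lo = rng.uniform(0, 4.0, (40, 2))
        f = point_dopc_frame(up, lo, box)
        c = o.lateral_correlation(Trajectory([f]), bin_width=0.1, r_max=2.0)
        # oracle: brute-force ordered-pair histogram per leaflet
        counts = np.zeros_like(c.pair_counts)
        for pts in (up, lo):
            for i in range(len(pts)):
                for j in range(len(pts)):
                    if i == j:
                        continue
                    d = pts[i] - pts[j]
                    d -= box[:2] * np.round(d / box[:2])
                    r = np.hypot(*d)
                    k = int(r // 0.1)
                    if k < len(counts):
                        counts[k] += 1
        np.testing.assert_array_equal(c.pair_counts, counts)

    def test_normalization_sum_rule(self):
        rng = np.random.default_rng(3)
        box = [5.0, 5.0, 8.0]
        f = point_dopc_frame(rng.uniform(0, 5, (30, 2)),
                             rng.uniform(0, 5, (30, 2)), box)
        c = o.lateral_correlation(Trajectory([f]), bin_width=0.1, r_max=2.5)
        areas = np.pi * (c.r_edges[1:] ** 2 - c.r_edges[:-1] ** 2)
        n, rho = 30, 29 / 25.0
        lhs = np.sum(c.c_value * areas * rho * n) * 2  # both leaflets
        assert lhs == pytest.approx(c.pair_counts.sum())

    def test_single_molecule_per_leaflet_is_error(self):
        f = point_dopc_frame([[1.0, 1.0]], [[2.0, 2.0]], [5, 5, 8])
        with pytest.raises(ValueError, match=">= 2"):
            o.lateral_correlation(Trajectory([f]), bin_width=0.1, r_max=2.0)

    def test_oversized_rmax_rejected(self):
        f = point_dopc_frame([[1, 1], [2, 2]], [[1, 2], [2, 1]], [5, 5, 8])
        with pytest.raises(ValueError, match="r_max"):
            o.lateral_correlation(Trajectory([f]), r_max=4.0)


class TestDipoleOrientation:
    def test_isotropic_mean_ninety(self):
        frame = syn.isotropic_dmso_box(120_000, (20, 20, 20), seed=3)
        prof = o.dipole_orientation_profile(Trajectory([frame]), "DMSO",
                                            bin_width=2.0)
        w = prof.n_samples.sum()
        mean = float(np.nansum(prof.mean_angle_deg * prof.n_samples) / w)
        assert w >= 1e5
        assert mean == pytest.approx(90.0, abs=0.5)

    def test_aligned_dipoles_zero_everywhere(self):
        # all O->S along +z in the upper half (outward normal +z)
        n = 100
        rng = np.random.default_rng(1)
        frame = syn.isotropic_dmso_box(n, (5, 5, 4), seed=1)
        pos = frame.positions.copy()
        s = pos[0::4]
        s[:, 2] = rng.uniform(2.2, 3.8, n)  # strictly upper half
        pos[0::4] = s
        pos[1::4] = s - [0, 0, 0.153]
        pos[2::4] = s + [0.15, 0, 0.09]
        pos[3::4] = s + [-0.15, 0, 0.09]
        f = syn.BilayerFrame(frame.topology, pos, frame.box)
        prof = o.dipole_orientation_profile(Trajectory([f]), "DMSO",
                                            bin_width=0.5)
        assert np.nanmax(prof.mean_angle_deg[prof.n_samples > 0]) < 1e-6

    def test_interfacial_dmso_bias_recovered(self, solvated_traj):
        prof = o.dipole_orientation_profile(solvated_traj, "DMSO",
                                            bin_width=0.2)
        m = (np.abs(np.abs(prof.bin_centers) - 0.9) < 0.3) \
            & (prof.n_samples > 50)
        mean = float(np.nansum(prof.mean_angle_deg[m] * prof.n_samples[m])
                     / prof.n_samples[m].sum())
        assert mean == pytest.approx(110.0, abs=2.0)
        # both leaflets above 90 degrees
        for side in (1, -1):
            ms = m & (np.sign(prof.bin_centers) == side)
            sm = float(np.nansum(prof.mean_angle_deg[ms] * prof.n_samples[ms])
                       / prof.n_samples[ms].sum())
            assert sm > 90.0

    def test_interfacial_water_h_toward_membrane(self, solvated_traj):
        prof = o.dipole_orientation_profile(solvated_traj, "WATER",
                                            bin_width=0.2)
        m = (np.abs(np.abs(prof.bin_centers) - 1.0) < 0.25) \
            & (prof.n_samples > 50)
        mean = float(np.nansum(prof.mean_angle_deg[m] * prof.n_samples[m])
                     / prof.n_samples[m].sum())
        assert mean > 90.0

    def test_mirrored_frame_mirrors_profile(self, solvated_traj):
        f = solvated_traj.frames[0]
        mirrored = syn.BilayerFrame(
            f.topology,
            np.column_stack([f.positions[:, 0], f.positions[:, 1],
                             f.box[2] - f.positions[:, 2]]),
            f.box)
        p1 = o.dipole_orientation_profile(Trajectory([f]), "DMSO",
                                          bin_width=0.25)
        p2 = o.dipole_orientation_profile(Trajectory([mirrored]), "DMSO",
                                          bin_width=0.25)
        v1 = p1.mean_angle_deg[p1.n_samples > 0]
        v2 = p2.mean_angle_deg[p2.n_samples > 0]
        np.testing.assert_allclose(v1, v2[::-1], atol=0.6)
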