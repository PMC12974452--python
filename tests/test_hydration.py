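"""Water density grids, smoothing, and hydration-site detection."""

import numpy as np
import pytest

from hydroshell.config import AnalysisConfig
from hydroshell.hydration import (A3_TO_L, WATER_MASS_KG, DensityGrid,
                                  accumulate_density, assign_site_residue,
                                  density_from_count, detect_sites,
                                  merge_window_sites, smooth_density,
                                  HydrationSite)
from hydroshell.synth import (PlantedSite, auto_site_positions,
                              generate_trajectory, toy_protein)
from hydroshell.trajectory import (Trajectory, TrajectoryError, align_window,
                                   sample_windows)


@pytest.fixture(scope="module")
def aligned_windows(site_trajectory):
    traj, truth = site_trajectory
    windows = sample_windows(traj, 500, 1.0)
    ref = windows[0].coords[0][windows[0].protein_indices]
    return [align_window(w, ref) for w in windows], truth


class TestSampleWindows:
    def test_scaled_ten_window_sampling(self, small_scaffold):
        """A 100-ns trajectory cut into 1-ns windows at 10-ns intervals yields
        10 windows (here scaled: 10 ns at 1-ns intervals, 500-frame windows)."""
        traj, _ = generate_trajectory(None, n_frames=5000, n_sites=0,
                                      bulk_density=0.0, scaffold=small_scaffold,
                                      seed=1)
        assert len(sample_windows(traj, 500, 1.0)) == 10

    def test_shorter_trajectory_arithmetic(self, small_scaffold):
        traj, _ = generate_trajectory(None, n_frames=1500, n_sites=0,
                                      bulk_density=0.0, scaffold=small_scaffold,
                                      seed=1)
        assert len(sample_windows(traj, 500, 1.0)) == 3

    def test_too_short_trajectory_errors(self, small_scaffold):
        traj, _ = generate_trajectory(None, n_frames=250, n_sites=0,
                                      bulk_density=0.0, scaffold=small_scaffold,
                                      seed=1)
        with pytest.raises(TrajectoryError, match="500"):
            sample_windows(traj, 500, 1.0)


class TestAlignWindow:
    def test_identity_when_already_aligned(self, small_scaffold):
        traj, _ = generate_trajectory(None, n_frames=100, n_sites=1,
                                      bulk_density=0.0, scaffold=small_scaffold,
                                      seed=2)
        w = sample_windows(traj, 100, 0.2)[0]
        aligned = align_window(w)
        assert np.abs(aligned.coords - w.coords).max() <= 1e-6

    def test_per_frame_rigid_rotation_removed(self, small_scaffold):
        traj, _ = generate_trajectory(None, n_frames=50, n_sites=1,
                                      bulk_density=0.0, scaffold=small_scaffold,
                                      seed=3)
        w = sample_windows(traj, 50, 0.1)[0]
        rng = np.random.default_rng(4)
        coords = w.coords.copy()
        for f in range(1, w.n_frames):
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta), 0],
                          [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
            coords[f] = coords[f] @ R.T + rng.uniform(-5, 5, 3)
        from hydroshell.trajectory import TrajectoryWindow
        moved = TrajectoryWindow(topology=w.topology, coords=coords,
                                 frame_interval_ps=w.frame_interval_ps,
                                 start_time_ns=0.0)
        aligned = align_window(moved, w.coords[0][w.protein_indices])
        prot = aligned.protein_indices
        for f in range(aligned.n_frames):
            dev = aligned.coords[f][prot] - w.coords[0][prot]
            assert np.sqrt((dev ** 2).sum(1).mean()) <= 1e-6


class TestAccumulateDensity:
    def test_no_waters_all_zero(self, small_scaffold, config):
        traj, _ = generate_trajectory(None, n_frames=20, n_sites=0,
                                      bulk_density=0.0, scaffold=small_scaffold,
                                      seed=5)
        w = align_window(sample_windows(traj, 20, 0.04)[0])
        grid = accumulate_density(w, config)
        assert grid.values.sum() == 0.0

    def test_stationary_water_analytic_density(self, small_scaffold, config):
        """One stationary water in one 0.5 Å voxel: 18.015 u / (0.5 Å)³
        = 2.9915e-26 kg / 1.25e-28 L ≈ 239.3 kg/L."""
        pos = auto_site_positions(small_scaffold, 1)[0]
        traj, _ = generate_trajectory(
            None, n_frames=50, sites=[PlantedSite(pos, 1.0, 10.0)],
            site_jitter=0.0, bulk_density=0.0, scaffold=small_scaffold, seed=6)
        w = align_window(sample_windows(traj, 50, 0.1)[0])
        grid = accumulate_density(w, config)
        expected = 18.015 * 1.66053906660e-27 / (0.125 * 1e-27)
        assert expected == pytest.approx(239.3, abs=0.1)
        assert grid.values.max() == pytest.approx(expected, rel=1e-9)

    def test_bulk_density_expectation(self, small_scaffold, config):
        """Uniform bulk at 1 kg/L (0.0334 Å⁻³): mean in-shell voxel density
        1.00 kg/L within 2% (closed-form expectation)."""
        traj, _ = generate_trajectory(None, n_frames=1000, n_sites=0,
                                      bulk_density=1.0, scaffold=small_scaffold,
                                      seed=7)
        w = align_window(sample_windows(traj, 1000, 2.0)[0])
        grid = accumulate_density(w, config)
        assert grid.values[grid.shell_mask].mean() == pytest.approx(1.0, rel=0.02)

    def test_mass_conservation_before_masking(self, small_scaffold, config):
        traj, _ = generate_trajectory(None, n_frames=200, n_sites=4,
                                      bulk_density=0.0, scaffold=small_scaffold,
                                      seed=8)
        w = align_window(sample_windows(traj, 200, 0.4)[0])
        grid = accumulate_density(w, config, apply_shell_mask=False)
        n_waters = len(w.water_indices)
        # all planted waters bound within the grid → total mass = n × m_water
        waters = w.water_coords().reshape(-1, 3)
        inside = np.all((waters >= grid.origin) &
                        (waters < grid.origin + np.array(grid.values.shape)
                         * grid.spacing), axis=1)
        expected = inside.mean() * n_waters * WATER_MASS_KG
        assert grid.total_mass_kg() == pytest.approx(expected, rel=1e-9)


class TestSmoothDensity:
    def _grid(self, values):
        v = np.asarray(values, float)
        return DensityGrid(origin=np.zeros(3), spacing=0.5, values=v,
                           shell_mask=np.ones_like(v, bool))

    def test_uniform_grid_unchanged(self):
        g = self._grid(np.full((5, 5, 5), 3.7))
        assert np.allclose(smooth_density(g).values, 3.7)

    def test_single_interior_voxel_seven_point_stencil(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 7.0
        s = smooth_density(self._grid(v)).values
        assert s[2, 2, 2] == pytest.approx(1.0)
        for off in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)]:
            assert s[2 + off[0], 2 + off[1], 2 + off[2]] == pytest.approx(1.0)
        assert s[1, 1, 2] == 0.0   # edge-diagonal untouched in 6-neighbor mode

    def test_all_zero_stays_zero(self):
        g = self._grid(np.zeros((4, 4, 4)))
        assert smooth_density(g).values.sum() == 0.0

    def test_interior_mass_conserved(self):
        """Mass at least two voxels from the boundary is conserved by the
        boundary-corrected stencil."""
        rng = np.random.default_rng(11)
        v = np.zeros((9, 9, 9))
        v[2:7, 2:7, 2:7] = rng.uniform(0, 5, (5, 5, 5))
        s = smooth_density(self._grid(v)).values
        assert s.sum() == pytest.approx(v.sum(), rel=1e-12)

    def test_18_neighbor_mode(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 19.0
        s = smooth_density(self._grid(v), neighbors=18).values
        assert s[2, 2, 2] == pytest.approx(1.0)
        assert s[1, 1, 2] == pytest.approx(1.0)


class TestDetectSites:
    def _grid_with_peaks(self, peaks, shape=(20, 20, 20), spacing=0.5):
        v = np.zeros(shape)
        for (i, j, k), dens in peaks:
            v[i, j, k] = dens
        return DensityGrid(origin=np.zeros(3), spacing=spacing, values=v,
                           shell_mask=np.ones(shape, bool))

    def test_below_threshold_no_sites(self, config):
        g = self._grid_with_peaks([((5, 5, 5), 5.9)])
        assert detect_sites(g, config) == []

    def test_merge_below_separation_above(self, config):
        # 0.7 Å apart (indices differ by 1 in two axes: sqrt(2)*0.5 ≈ 0.707 Å);
        # within the 26-neighborhood both survive only as an equal plateau
        g = self._grid_with_peaks([((5, 5, 5), 10.0), ((6, 6, 5), 10.0)])
        sites = detect_sites(g, config)
        assert len(sites) == 1
        expected = (np.array([2.75, 2.75, 2.75]) + np.array([3.25, 3.25, 2.75])) / 2
        assert np.allclose(sites[0].position, expected)
        assert sites[0].smoothed_density == 10.0
        # 1.5 Å apart → two sites
        g2 = self._grid_with_peaks([((5, 5, 5), 10.0), ((8, 5, 5), 8.0)])
        assert len(detect_sites(g2, config)) == 2

    def test_threshold_monotonicity(self, aligned_windows, config):
        w = aligned_windows[0][0]
        sgrid = smooth_density(accumulate_density(w, config))
        counts = []
        for thr in (4.0, 6.0, 10.0):
            cfg = AnalysisConfig(density_threshold=thr)
            counts.append(len(detect_sites(sgrid, cfg)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_merge_distance_monotonicity(self, aligned_windows, config):
        w = aligned_windows[0][0]
        sgrid = smooth_density(accumulate_density(w, config))
        counts = [len(detect_sites(sgrid, AnalysisConfig(merge_distance=md)))
                  for md in (0.5, 1.0, 2.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_planted_sites_recovered(self, aligned_windows, config):
        """12 planted bound-water sites recovered with ≤0.5 Å positional error
        from each window; merging across windows is order-independent."""
        windows, truth = aligned_windows
        per_window = []
        for w in windows:
            sgrid = smooth_density(accumulate_density(w, config))
            per_window.append(detect_sites(sgrid, config, window=w))
        merged = merge_window_sites(per_window, config.merge_distance)
        planted = np.array([s["position"] for s in truth.payload["sites"]])
        assert len(merged) == len(planted)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(np.array([s.position for s in merged])).query(planted)
        assert d.max() <= 0.5
        reversed_merge = merge_window_sites(per_window[::-1], config.merge_distance)
        assert np.allclose(
            sorted(tuple(s.position) for s in merged),
            sorted(tuple(s.position) for s in reversed_merge))


class TestAssignSiteResidue:
    def test_static_protein_full_vote(self, small_scaffold, config):
        pos = auto_site_positions(small_scaffold, 1)[0]
        traj, _ = generate_trajectory(
            None, n_frames=50, sites=[PlantedSite(pos, 1.0, 10.0)],
            bulk_density=0.0, scaffold=small_scaffold, seed=12)
        w = align_window(sample_windows(traj, 50, 0.1)[0])
        site = HydrationSite(position=pos, smoothed_density=10.0)
        res = assign_site_residue(site, w, config)
        heavy = small_scaffold.protein_atoms(heavy_only=True)
        d = [np.linalg.norm(a.position - pos) for a in heavy]
        expected = heavy[int(np.argmin(d))]
        assert res == (expected.residue_name, expected.residue_id,
                       expected.chain_id)

    def test_majority_vote_and_tie_break(self, small_scaffold, config):
        """A site equidistant over time votes: 300/500 frames wins; an exact
        tie goes to the lower residue_id."""
        from hydroshell.trajectory import TrajectoryWindow
        from hydroshell.core import AtomRecord, StructureModel
        a1 = AtomRecord("C", "CA", "ALA", 1, "A", np.array([0.0, 0, 0]))
        a2 = AtomRecord("C", "CA", "GLY", 2, "A", np.array([10.0, 0, 0]))
        topo = StructureModel([a1, a2])
        coords = np.zeros((500, 2, 3))
        coords[:, 1, 0] = 10.0
        # site at x=5; move atom 1 away for 200 frames so atom 2 is closer
        coords[300:, 0, 0] = -20.0
        w = TrajectoryWindow(topology=topo, coords=coords, frame_interval_ps=2.0,
                             start_time_ns=0.0, aligned=True)
        site = HydrationSite(position=np.array([4.9, 0, 0]), smoothed_density=10.0)
        assert assign_site_residue(site, w, config)[1] == 1
        coords[250:, 0, 0] = -20.0
        site_tie = HydrationSite(position=np.array([4.9, 0, 0]), smoothed_density=10.0)
        w2 = TrajectoryWindow(topology=topo, coords=coords, frame_interval_ps=2.0,
                              start_time_ns=0.0, aligned=True)
        assert assign_site_residue(site_tie, w2, config)[1] == 1
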