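"""Binding-mode geometry: ionic lock, membrane frame, d/alpha, densities,
dynamics metric, RMSF."""

import numpy as np
import pytest

from arrbind import geometry, synth
from arrbind.core import AnalysisWindows, Trajectory, make_windows
from arrbind.geometry import (BindingModeReference, BindingModeSeries,
                              MembraneFrame)

from conftest import make_structure, small_system_spec


def _toy_reference(toy):
    s = toy.structure
    tm = s.select(synth.SELECTIONS["tm_bundle"])
    nlobe = s.select(synth.SELECTIONS["nlobe"])
    clobe = s.select(synth.SELECTIONS["clobe"])
    mf = MembraneFrame(np.array([0.0, 0.0, 1.0]), 0.0)
    return BindingModeReference(s, tm, nlobe, clobe, mf, "toy"), tm, nlobe, \
        clobe


class TestIonicLock:
    def test_coincident_zero(self):
        s = make_structure([[0, 0, 0], [0, 0, 0]], resids=[131, 268])
        assert geometry.ionic_lock_distance(s) == 0.0

    def test_axis_separation(self):
        s = make_structure([[0, 0, 0], [0, 0, 1.5]], resids=[131, 268])
        assert geometry.ionic_lock_distance(s) == pytest.approx(1.5)

    def test_missing_calpha_names_residue(self):
        s = make_structure([[0, 0, 0]], resids=[131])
        with pytest.raises(ValueError, match="268"):
            geometry.ionic_lock_distance(s)


class TestMembraneFrame:
    def test_flat_bilayer_normal_and_midplane(self):
        coords = [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (3.0, 7.0)]
        s = make_structure(coords, names=["P"] * 8, elements=["P"] * 8,
                           resnames=["PCX"] * 8)
        mf = geometry.membrane_frame(None, membrane=s.atom_group(range(8)))
        np.testing.assert_allclose(mf.normal, [0, 0, 1])
        assert mf.midplane == pytest.approx(5.0)

    def test_bundle_axis_recovers_rotated_normal(self):
        rng = np.random.default_rng(1)
        axis_pts = np.array([[0.1 * np.cos(k), 0.1 * np.sin(k), z]
                             for k, z in zip(range(40),
                                             np.linspace(-2, 2, 40))])
        theta = np.radians(30.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        rotated = axis_pts @ rot.T
        s = make_structure(rotated)
        below = make_structure(np.array([[0, 0, -5.0]]) @ rot.T)
        mf = geometry.membrane_frame(None, bundle=s.atom_group(range(40)),
                                     below=None)
        expected = rot @ np.array([0, 0, 1.0])
        angle = np.degrees(np.arccos(abs(np.dot(mf.normal, expected))))
        assert angle < 2.0


class TestInsertionDepth:
    def test_equal_heights_zero(self):
        s = make_structure([[0, 0, 1.0], [5, 5, 1.0]])
        mf = MembraneFrame(np.array([0, 0, 1.0]), 0.0)
        assert geometry.insertion_depth(None, s.atom_group([0]),
                                        s.atom_group([1]), mf) == 0.0

    def test_projection_arithmetic(self):
        s = make_structure([[0, 0, 5.0], [3, 1, 0.7]])
        mf = MembraneFrame(np.array([0, 0, 1.0]), 0.0)
        assert geometry.insertion_depth(
            None, s.atom_group([0]), s.atom_group([1]), mf
        ) == pytest.approx(4.3)

    def test_rigid_motion_invariance(self, small_toy):
        ref, tm, nlobe, _ = _toy_reference(small_toy)
        s = small_toy.structure
        mf = ref.mframe
        d0 = geometry.insertion_depth(None, tm, nlobe, mf)
        shifted = s.coords + np.array([1.0, -2.0, 3.0])
        assert geometry.insertion_depth(shifted, tm, nlobe, mf) == \
            pytest.approx(d0, abs=1e-9)
        rotated = geometry.rotate_about_normal(s.coords, np.array([4, 4, 0.0]),
                                               37.0, (0, 0, 1))
        assert geometry.insertion_depth(rotated, tm, nlobe, mf) == \
            pytest.approx(d0, abs=1e-9)


class TestRotationAngle:
    def test_reference_against_itself_is_zero(self, small_toy):
        ref, tm, nlobe, clobe = _toy_reference(small_toy)
        a = geometry.rotation_angle(small_toy.structure.coords, tm, nlobe,
                                    clobe, ref)
        assert a == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("delta", [-90.0, -10.0, 10.0, 25.0, 90.0, 180.0])
    def test_equivariance_under_applied_rotation(self, small_toy, delta):
        ref, tm, nlobe, clobe = _toy_reference(small_toy)
        s = small_toy.structure
        xyz = s.coords.copy()
        arrestin = s.select("chain A").indices
        center = np.array([s.coords[tm.indices, 0].mean(),
                           s.coords[tm.indices, 1].mean(), 0.0])
        xyz[arrestin] = geometry.rotate_about_normal(
            xyz[arrestin], center, delta, ref.mframe.normal)
        a = geometry.rotation_angle(xyz, tm, nlobe, clobe, ref)
        assert a == pytest.approx(geometry.wrap_angle(delta), abs=1e-6)

    def test_full_turn_is_zero(self, small_toy):
        ref, tm, nlobe, clobe = _toy_reference(small_toy)
        s = small_toy.structure
        xyz = s.coords.copy()
        arrestin = s.select("chain A").indices
        xyz[arrestin] = geometry.rotate_about_normal(
            xyz[arrestin], np.zeros(3), 360.0, (0, 0, 1))
        a = geometry.rotation_angle(xyz, tm, nlobe, clobe, ref)
        assert a == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_in_plane_projection(self):
        s = make_structure([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                            [0.5, 0.5, -1.0], [0.5, 0.5, -3.0]])
        mf = MembraneFrame(np.array([0, 0, 1.0]), 0.0)
        fit = s.atom_group([0, 1, 2])
        ref = BindingModeReference(s, fit, s.atom_group([3]),
                                   s.atom_group([4]), mf)
        with pytest.raises(ValueError, match="degenerate"):
            ref.in_plane_direction()


class TestEngagement:
    def _series(self, d):
        d = np.asarray(d, dtype=float)
        return BindingModeSeries(np.arange(len(d), dtype=float), d,
                                 np.zeros(len(d)))

    def test_constant_engaged(self):
        labels, frac, _ = geometry.classify_engagement(self._series([4.5] * 7))
        assert set(labels) == {"core-engaged"} and frac == 0.0

    def test_constant_disengaged(self):
        labels, frac, _ = geometry.classify_engagement(self._series([5.4] * 7))
        assert set(labels) == {"core-disengaged"} and frac == 1.0

    def test_threshold_is_strict(self):
        labels, frac, _ = geometry.classify_engagement(
            self._series([5.3, 5.3 + 1e-9]))
        assert list(labels) == ["core-engaged", "core-disengaged"]

    def test_scripted_crossing_fraction(self):
        d = np.where(np.arange(50) % 5 == 0, 5.5, 4.5)
        _, frac, _ = geometry.classify_engagement(self._series(d))
        assert frac == pytest.approx(0.2)


class TestBindingModeSeries:
    def test_static_trajectory_constant_series(self, small_toy):
        dyn = synth.DynamicsSpec(
            ou_d=synth.OUSpec(4.5, 0.0, 1.0), ou_alpha=synth.OUSpec(10.0, 0.0, 1.0),
            contacts={}, default_jitter=0.0, icl2_p_helical=None,
            n_frames=5, seed=0)
        bundle = synth.simulate_trajectory(small_toy, dyn)
        ref, tm, nlobe, clobe = _toy_reference(small_toy)
        w = AnalysisWindows([(0.0, 0.5)])
        series = geometry.binding_mode_series(
            bundle.trajectory, tm, nlobe, tm, nlobe, clobe, ref, w)
        np.testing.assert_allclose(series.d, 4.5, atol=1e-9)
        np.testing.assert_allclose(series.alpha, 10.0, atol=1e-9)

    def test_empty_windows_error(self, small_toy):
        dyn = synth.DynamicsSpec(contacts={}, icl2_p_helical=None,
                                 n_frames=3, seed=0)
        bundle = synth.simulate_trajectory(small_toy, dyn)
        ref, tm, nlobe, clobe = _toy_reference(small_toy)
        with pytest.raises(ValueError):
            geometry.binding_mode_series(bundle.trajectory, tm, nlobe, tm,
                                         nlobe, clobe, ref,
                                         AnalysisWindows([]))


class TestDensity2D:
    def _series(self, d, a):
        return BindingModeSeries(np.arange(len(d), dtype=float),
                                 np.asarray(d, float), np.asarray(a, float))

    def test_single_cell_gets_all_mass(self):
        g = geometry.density2d(self._series([4.5] * 9, [10.0] * 9),
                               [4.4, 4.6], [5.0, 15.0])
        assert g.weights[0, 0] == 1.0

    def test_uniform_four_cells(self):
        d = [4.1, 4.1, 4.3, 4.3]
        a = [1.0, 3.0, 1.0, 3.0]
        g = geometry.density2d(self._series(d, a), [4.0, 4.2, 4.4],
                               [0.0, 2.0, 4.0])
        np.testing.assert_allclose(g.weights, 0.25)

    def test_matches_manual_binning_and_reorder_invariance(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(4.0, 5.0, 500)
        a = rng.uniform(-30, 30, 500)
        d_edges = np.linspace(4.0, 5.0, 11)
        a_edges = np.linspace(-30, 30, 13)
        g = geometry.density2d(self._series(d, a), d_edges, a_edges)
        manual = np.zeros((10, 12))
        for x, y in zip(d, a):
            i = min(int((x - 4.0) / 0.1), 9)
            j = min(int((y + 30.0) / 5.0), 11)
            manual[i, j] += 1
        np.testing.assert_allclose(g.weights, manual / manual.sum())
        assert g.weights.sum() == pytest.approx(1.0)
        perm = rng.permutation(500)
        g2 = geometry.density2d(self._series(d[perm], a[perm]), d_edges,
                                a_edges)
        np.testing.assert_allclose(g.weights, g2.weights)

    def test_outliers_clamped_and_reported(self):
        with pytest.warns(UserWarning, match="clamped"):
            g = geometry.density2d(self._series([3.0, 4.5], [0.0, 0.0]),
                                   [4.4, 4.6], [-1.0, 1.0])
        assert g.n_clamped == 1
        assert g.weights.sum() == pytest.approx(1.0)


class TestDynamicsMetric:
    def test_constant_series_zero(self):
        s = BindingModeSeries(np.arange(100.0), np.full(100, 4.5),
                              np.full(100, 3.0))
        m = geometry.dynamics_metric(s, AnalysisWindows([(0, 50), (50, 100)]))
        assert m.d_sd_mean == 0.0 and m.alpha_sd_mean == 0.0

    def test_alternating_two_level_sd(self):
        d = np.where(np.arange(400) % 2 == 0, 4.4, 4.6)
        s = BindingModeSeries(np.arange(400.0), d, np.zeros(400))
        m = geometry.dynamics_metric(s, AnalysisWindows([(0, 400)]))
        assert m.d_sd_mean == pytest.approx(0.1, rel=5e-3)

    def test_alpha_unwrapped_within_window(self):
        # angles hovering around the +-180 seam: wrapped SD would be huge
        a = np.where(np.arange(200) % 2 == 0, 179.0, -179.0)
        s = BindingModeSeries(np.arange(200.0), np.full(200, 4.5), a)
        m = geometry.dynamics_metric(s, AnalysisWindows([(0, 200)]))
        assert m.alpha_sd_mean == pytest.approx(1.0, rel=2e-2)

    def test_ou_stationary_sd_recovery(self, small_toy):
        dyn = synth.DynamicsSpec(
            ou_d=synth.OUSpec(4.48, 0.065, 1.0),
            ou_alpha=synth.OUSpec(0.0, 3.5, 1.0),
            contacts={}, icl2_p_helical=None, n_frames=6000, seed=29)
        bundle = synth.simulate_trajectory(small_toy, dyn)
        ref, tm, nlobe, clobe = _toy_reference(small_toy)
        w = make_windows(bundle.trajectory, length=100.0)  # 100x tau
        series = geometry.binding_mode_series(
            bundle.trajectory, tm, nlobe, tm, nlobe, clobe, ref, w)
        m = geometry.dynamics_metric(series, w)
        assert m.d_sd_mean == pytest.approx(0.065, rel=0.10)
        assert m.alpha_sd_mean == pytest.approx(3.5, rel=0.10)


class TestRmsf:
    def test_static_trajectory_zero(self, small_toy):
        dyn = synth.DynamicsSpec(ou_d=synth.OUSpec(4.48, 0.0, 1.0),
                                 ou_alpha=synth.OUSpec(0.0, 0.0, 1.0),
                                 contacts={}, default_jitter=0.0,
                                 icl2_p_helical=None, n_frames=4, seed=0)
        bundle = synth.simulate_trajectory(small_toy, dyn)
        s = small_toy.structure
        fit = s.select(synth.SELECTIONS["tm_bundle"])
        residues = s.select(synth.SELECTIONS["cterm"]).split_by_residue()
        prof = geometry.rmsf_profile(bundle.trajectory, residues,
                                     AnalysisWindows([(0.0, 0.4)]), fit)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_two_frame_displacement(self):
        base = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5.0, 5.0, 5.0]])
        s = make_structure(base)
        frames = np.stack([base, base])
        frames[1, 3] += np.array([0.4, 0.0, 0.0])   # |delta| = 0.4
        traj = Trajectory(s, np.array([0.0, 1.0]), frames)
        prof = geometry.rmsf_profile(traj, [s.atom_group([3])],
                                     AnalysisWindows([(0.0, 2.0)]),
                                     s.atom_group([0, 1, 2]))
        assert prof.rmsf[0] == pytest.approx(0.2, abs=1e-9)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self, small_toy):
        sigma = 0.12
        jitter = {("R", r): sigma for r in synth.CTERM_RESIDS}
        dyn = synth.DynamicsSpec(contacts={}, jitter=jitter,
                                 icl2_p_helical=None, n_frames=4000, seed=31)
        bundle = synth.simulate_trajectory(small_toy, dyn)
        s = small_toy.structure
        fit = s.select(synth.SELECTIONS["tm_bundle"])
        residues = s.select(synth.SELECTIONS["cterm"]).split_by_residue()
        w = make_windows(bundle.trajectory, length=200.0)
        prof = geometry.rmsf_profile(bundle.trajectory, residues, w, fit)
        np.testing.assert_allclose(prof.rmsf, sigma * np.sqrt(3), rtol=0.05)
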