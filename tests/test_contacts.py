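"""Contact probabilities, anchoring, bound-lipid counts, salt bridges."""

import numpy as np
import pytest

from arrbind import contacts, synth
from arrbind.core import AnalysisWindows, Trajectory, distance_array, make_windows

from conftest import make_structure, small_system_spec


def _two_group_structure(res_z, lipid_xy, box=None):
    """One single-atom residue per entry of res_z plus lipid atoms at z=0."""
    coords = [[0.0, 0.0, z] for z in res_z] + \
             [[x, y, 0.0] for x, y in lipid_xy]
    n_res = len(res_z)
    return make_structure(
        coords,
        chains=["R"] * n_res + ["M"] * len(lipid_xy),
        resids=list(range(1, n_res + 1)) + [100 + i for i in
                                            range(len(lipid_xy))],
        resnames=["ALA"] * n_res + ["PCX"] * len(lipid_xy),
        box=box,
    )


def _scripted_trajectory(structure, z_series, atom_index=0, dt=1.0):
    """Move one atom along z according to a scripted series."""
    frames = np.repeat(structure.coords[None], len(z_series), axis=0)
    frames[:, atom_index, 2] = z_series
    return Trajectory(structure, dt * np.arange(len(z_series)), frames)


class TestMinDistance:
    def test_coincident_atoms_give_zero(self):
        s = _two_group_structure([0.0], [(0.0, 0.0)])
        d = contacts.min_distance_residue_to_group(
            s.coords, s.atom_group([0]), s.atom_group([1]))
        assert d == 0.0

    def test_constructed_nearest_atom(self):
        s = _two_group_structure([0.45], [(0.0, 0.0), (3.0, 0.0), (0.0, 4.0)])
        d = contacts.min_distance_residue_to_group(
            s.coords, s.atom_group([0]), s.atom_group([1, 2, 3]))
        assert d == pytest.approx(0.45)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        box = np.diag([5.0, 5.0, 5.0])
        coords = rng.uniform(0, 5, (60, 3))
        s = make_structure(coords, box=box)
        a, b = s.atom_group(range(25)), s.atom_group(range(25, 60))
        got = contacts.min_distance_residue_to_group(coords, a, b, box)
        from arrbind.core import minimum_image_distance
        brute = min(minimum_image_distance(coords[i], coords[j], box)
                    for i in range(25) for j in range(25, 60))
        assert got == pytest.approx(brute, abs=1e-12)


class TestContactProfile:
    def test_counting_fraction(self):
        s = _two_group_structure([2.0], [(0.0, 0.0)])
        z = np.where(np.arange(100) < 60, 0.3, 2.0)   # 60 contact frames
        traj = _scripted_trajectory(s, z)
        w = AnalysisWindows([(0.0, 100.0)])
        prof = contacts.contact_probability_profile(
            traj, [s.atom_group([0])], s.atom_group([1]), w, cutoff=0.5)
        assert prof.probabilities[0] == pytest.approx(0.60)

    def test_always_in_contact_sem_zero(self):
        s = _two_group_structure([0.3], [(0.0, 0.0)])
        traj = _scripted_trajectory(s, np.full(40, 0.3))
        w = AnalysisWindows([(0, 10), (10, 20), (20, 30), (30, 40)])
        prof = contacts.contact_probability_profile(
            traj, [s.atom_group([0])], s.atom_group([1]), w)
        assert prof.probabilities[0] == 1.0
        assert prof.sems[0] == 0.0
        assert prof.n_windows == 4

    def test_pooled_equals_frame_weighted_window_mean(self):
        s = _two_group_structure([2.0], [(0.0, 0.0)])
        rng = np.random.default_rng(0)
        z = np.where(rng.random(90) < 0.5, 0.2, 2.0)
        traj = _scripted_trajectory(s, z)
        w = AnalysisWindows([(0, 50), (50, 90)])
        prof = contacts.contact_probability_profile(
            traj, [s.atom_group([0])], s.atom_group([1]), w)
        weights = [50, 40]
        manual = np.average(prof.window_means[:, 0], weights=weights)
        assert prof.probabilities[0] == pytest.approx(manual)

    def test_cutoff_limits(self):
        s = _two_group_structure([2.0], [(0.0, 0.0)])
        traj = _scripted_trajectory(s, np.full(10, 2.0))
        w = AnalysisWindows([(0.0, 10.0)])
        hi = contacts.contact_probability_profile(
            traj, [s.atom_group([0])], s.atom_group([1]), w, cutoff=1e6)
        lo = contacts.contact_probability_profile(
            traj, [s.atom_group([0])], s.atom_group([1]), w, cutoff=1e-9)
        assert hi.probabilities[0] == 1.0
        assert lo.probabilities[0] == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.4, 0.8])
    def test_markov_process_recovery(self, p):
        """Stationary contact probability recovered within 3 SE, with the
        effective sample size corrected for chain autocorrelation."""
        toy = synth.build_toy_complex(small_system_spec(), seed=4)
        proc = synth.ContactProcess(p=p, dwell_contact_ns=2.0)
        dyn = synth.DynamicsSpec(contacts={("R", 261): proc},
                                 icl2_p_helical=None, n_frames=5000, seed=17)
        bundle = synth.simulate_trajectory(toy, dyn)
        traj = bundle.trajectory
        s = toy.structure
        w = make_windows(traj, length=100.0)
        res = s.select("chain R and resid 261")
        mem = s.select("resname PCX PGX CHX")
        prof = contacts.contact_probability_profile(traj, [res], mem, w)
        n_eff = synth.markov_effective_sample_size(proc, dyn.n_frames, dyn.dt)
        se = np.sqrt(p * (1 - p) / n_eff)
        assert abs(prof.probabilities[0] - p) < 3 * se


class TestAnchoring:
    def test_buried_loop_is_always_attached(self):
        s = _two_group_structure([0.1], [(0.0, 0.0)])
        traj = _scripted_trajectory(s, np.full(20, 0.1))
        w = make_windows(traj, length=10.0)
        occ = contacts.anchoring_fraction(traj, s.atom_group([0]),
                                          s.atom_group([1]), w)
        assert occ.pooled == 1.0

    def test_solvated_loop_never_attached(self):
        s = _two_group_structure([3.0], [(0.0, 0.0)])
        traj = _scripted_trajectory(s, np.full(20, 3.0))
        w = make_windows(traj, length=10.0)
        occ = contacts.anchoring_fraction(traj, s.atom_group([0]),
                                          s.atom_group([1]), w)
        assert occ.pooled == 0.0

    def test_cedge_dwell_fixture_exceeds_90_percent(self, small_toy):
        dyn = synth.DynamicsSpec(
            contacts={("A", r): synth.ContactProcess(0.95, 20.0)
                      for r in synth.CEDGE_RESIDS},
            icl2_p_helical=None, n_frames=2000, seed=23)
        bundle = synth.simulate_trajectory(small_toy, dyn)
        s = small_toy.structure
        w = make_windows(bundle.trajectory, length=50.0)
        occ = contacts.anchoring_fraction(
            bundle.trajectory, s.select(synth.SELECTIONS["cedge"]),
            s.select(synth.SELECTIONS["membrane"]), w)
        assert occ.pooled > 0.9


class TestBoundLipids:
    def _membrane_structure(self):
        # site of 2 atoms + 4 lipid molecules of 3 atoms each
        coords = [[0, 0, 0], [0.3, 0, 0]]
        lipid_centers = [(0.4, 0.0), (0.0, 0.45), (2.5, 2.5), (3.5, 0.0)]
        resids, resnames, chains = [1, 1], ["SIT", "SIT"], ["R", "R"]
        for i, (x, y) in enumerate(lipid_centers):
            for k in range(3):
                coords.append([x, y, 0.2 * k])
                resids.append(10 + i)
                resnames.append("PGX")
                chains.append("M")
        return make_structure(coords, resids=resids, resnames=resnames,
                              chains=chains, box=np.diag([6.0, 6.0, 6.0]))

    def test_counts_constructed_molecules(self):
        s = self._membrane_structure()
        site = s.atom_group([0, 1])
        lipids = [g for g in s.select("resname PGX").split_by_residue()]
        n = contacts.count_bound_lipids(s.coords, site, lipids, cutoff=0.5,
                                        box=s.box)
        assert n == 2    # molecules at (0.4,0) and (0,0.45); others too far

    def test_no_lipids_within_cutoff(self):
        s = self._membrane_structure()
        site = s.atom_group([0, 1])
        lipids = [g for g in s.select("resname PGX").split_by_residue()]
        n = contacts.count_bound_lipids(s.coords, site, lipids, cutoff=0.01,
                                        box=s.box)
        assert n == 0

    def test_overlapping_molecules_rejected(self):
        s = self._membrane_structure()
        site = s.atom_group([0])
        lipids = [s.atom_group([2, 3]), s.atom_group([3, 4])]
        with pytest.raises(ValueError, match="overlap"):
            contacts.count_bound_lipids(s.coords, site, lipids)

    def test_matches_brute_force_and_invariances(self):
        rng = np.random.default_rng(9)
        box = np.diag([5.0, 5.0, 5.0])
        coords = rng.uniform(0, 5, (62, 3))
        resids = [1, 1] + [10 + i // 4 for i in range(60)]
        s = make_structure(coords, resids=resids,
                           resnames=["SIT"] * 2 + ["PGX"] * 60,
                           chains=["R"] * 2 + ["M"] * 60, box=box)
        site = s.atom_group([0, 1])
        lipids = s.select("resname PGX").split_by_residue()
        n = contacts.count_bound_lipids(coords, site, lipids, 0.7, box)
        brute = 0
        for g in lipids:
            hit = any(
                np.linalg.norm(
                    (coords[i] - coords[j] + 2.5) % 5.0 - 2.5) < 0.7
                for i in g.indices for j in (0, 1))
            brute += hit
        assert n == brute
        # relabeling and rigid translation (with PBC) leave the count alone
        n_rev = contacts.count_bound_lipids(coords, site, lipids[::-1], 0.7,
                                            box)
        shifted = coords + np.array([1.3, -2.2, 0.7])
        n_shift = contacts.count_bound_lipids(shifted, site, lipids, 0.7, box)
        assert n == n_rev == n_shift


class TestPairMatrixAndSaltBridge:
    def test_permanent_and_absent_contacts(self):
        s = _two_group_structure([0.2, 4.0], [(0.0, 0.0)],
                                 box=np.diag([10.0, 10.0, 10.0]))
        traj = _scripted_trajectory(s, np.full(10, 0.2))
        w = AnalysisWindows([(0.0, 10.0)])
        m = contacts.pair_contact_matrix(
            traj, [s.atom_group([0]), s.atom_group([1])],
            [s.atom_group([2])], w, cutoff=0.5)
        assert m.probabilities[0, 0] == 1.0
        assert m.probabilities[1, 0] == 0.0

    def test_scripted_intermittent_contact(self):
        s = _two_group_structure([2.0], [(0.0, 0.0)])
        z = np.where(np.arange(50) % 5 < 2, 0.2, 2.0)   # 40% duty cycle
        traj = _scripted_trajectory(s, z)
        w = AnalysisWindows([(0.0, 50.0)])
        m = contacts.pair_contact_matrix(traj, [s.atom_group([0])],
                                         [s.atom_group([1])], w, cutoff=0.5)
        assert m.probabilities[0, 0] == pytest.approx(0.4)

    def test_salt_bridge_distances_and_duty_cycle(self):
        s = make_structure([[0, 0, 0], [0, 0, 0.3]],
                           names=["OE1", "NZ"], elements=["O", "N"])
        traj = _scripted_trajectory(s, np.full(10, 0.30), atom_index=1)
        w = AnalysisWindows([(0.0, 10.0)])
        occ = contacts.salt_bridge_occupancy(traj, s.atom_group([0]),
                                             s.atom_group([1]), w)
        assert occ.pooled == 1.0
        traj = _scripted_trajectory(s, np.full(10, 0.60), atom_index=1)
        occ = contacts.salt_bridge_occupancy(traj, s.atom_group([0]),
                                             s.atom_group([1]),
                                             AnalysisWindows([(0.0, 10.0)]))
        assert occ.pooled == 0.0
        z = np.where(np.arange(20) % 2 == 0, 0.30, 0.60)
        traj = _scripted_trajectory(s, z, atom_index=1)
        occ = contacts.salt_bridge_occupancy(traj, s.atom_group([0]),
                                             s.atom_group([1]),
                                             AnalysisWindows([(0.0, 20.0)]))
        assert occ.pooled == pytest.approx(0.5)

    def test_empty_window_is_an_error(self):
        s = _two_group_structure([0.2], [(0.0, 0.0)])
        traj = _scripted_trajectory(s, np.full(10, 0.2))
        w = AnalysisWindows([(0, 5), (100, 200)])
        with pytest.raises(ValueError, match="no frames"):
            contacts.contact_probability_profile(
                traj, [s.atom_group([0])], s.atom_group([1]), w)
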