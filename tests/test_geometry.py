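"""Ring detection, centroids, contact criteria; rigid-motion invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fluorocage.geometry import (RingSystem, cation_ring_distance, centroid,
                                 closest_methyl_carbon_distance, contact_series,
                                 detect_indole_rings)
from fluorocage.io import AtomRecord, Structure, Trajectory


def _rigid(coords, rot, trans):
    return coords @ rot.T + trans


class TestDetection:
    def test_two_indoles_detected_with_shared_fusion_atoms(self, cage_runs):
        for variant, (structure, _, _) in cage_runs.items():
            rings = detect_indole_rings(structure)
            assert len(rings) == 2
            assert [r.label for r in rings] == ["Trp18-like", "Trp28-like"]
            for r in rings:
                fusion = set(r.five_ring) & set(r.six_ring)
                names = {structure.atoms[i].name for i in fusion}
                assert names == {"CD2", "CE2"}
                assert len(r.all_heavy) == 9
                expected_f = {"WT": 0, "5F": 1, "6F": 1, "56diF": 2}[variant]
                assert len(r.fluorines) == expected_f

    def test_template_planarity(self, wt_run):
        structure, _, _ = wt_run
        for r in detect_indole_rings(structure):
            pts = structure.coordinates[list(r.all_heavy)]
            pts = pts - pts.mean(axis=0)
            # smallest singular value = max out-of-plane deviation scale
            assert np.linalg.svd(pts, compute_uv=False)[-1] < 0.2

    def test_non_indole_residue_is_an_error(self):
        atoms = [AtomRecord(0, "CA", "C", "ALA", 7, (0.0, 0.0, 0.0)),
                 AtomRecord(1, "CB", "C", "ALA", 7, (1.5, 0.0, 0.0))]
        s = Structure(atoms=atoms)
        with pytest.raises(ValueError, match="residue 7"):
            detect_indole_rings(s, residue_ids=[7])


class TestCentroid:
    def test_regular_hexagon_centroid_is_origin(self):
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        pts = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        assert np.allclose(centroid(pts, np.arange(6)), 0.0, atol=1e-12)

    def test_translation_equivariance_and_mean_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        t = np.array([1.0, -2.0, 0.5])
        c0 = centroid(pts, np.arange(6))
        assert np.allclose(centroid(pts + t, np.arange(6)), c0 + t, atol=1e-12)
        assert np.allclose(c0, sum(pts[i] for i in range(6)) / 6, atol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            centroid(np.zeros((3, 3)), [])


def _toy_ring_frame():
    """A planar 9-atom indole-like frame centered at the origin, plus a
    cation N directly above it."""
    ang = np.linspace(0, 2 * np.pi, 10)[:-1]
    ring_pts = np.column_stack([1.3 * np.cos(ang), 1.3 * np.sin(ang), np.zeros(9)])
    n_pos = np.array([[0.0, 0.0, 3.0]])
    frame = np.vstack([n_pos, ring_pts])
    ring = RingSystem(residue_id=1, five_ring=tuple(range(1, 6)),
                      six_ring=(4, 5, 6, 7, 8, 9), all_heavy=tuple(range(1, 10)))
    return frame, ring


class TestDistances:
    def test_axial_cation_distance(self):
        frame, ring = _toy_ring_frame()
        assert cation_ring_distance(frame[0], ring, "whole", frame) == pytest.approx(3.0)

    def test_unknown_substructure_rejected(self):
        frame, ring = _toy_ring_frame()
        with pytest.raises(ValueError, match="substructure"):
            cation_ring_distance(frame[0], ring, "7MR", frame)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance(self, seed):
        """Distances are unchanged by any global rotation + translation."""
        frame, ring = _toy_ring_frame()
        rng = np.random.default_rng(seed)
        rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        trans = rng.normal(scale=10, size=3)
        moved = _rigid(frame, rot, trans)
        for sub in ("5MR", "6MR", "whole"):
            d0 = cation_ring_distance(frame[0], ring, sub, frame)
            d1 = cation_ring_distance(moved[0], ring, sub, moved)
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_distance_equals_norm_oracle_over_frames(self, wt_run):
        structure, traj, _ = wt_run
        ring = detect_indole_rings(structure)[1]
        n_idx = int(structure.select(residue_id=1, names=["N"])[0])
        for f in range(0, traj.n_frames, 37):
            frame = traj.coordinates[f]
            d = cation_ring_distance(frame[n_idx], ring, "6MR", frame)
            oracle = np.linalg.norm(frame[n_idx] - frame[list(ring.six_ring)].mean(axis=0))
            assert d == pytest.approx(oracle, abs=1e-12)


class TestContactSeries:
    def _static(self, distance):
        frame, ring = _toy_ring_frame()
        frame[0] = [0.0, 0.0, distance]
        traj = Trajectory(times_ps=[0.0, 20.0],
                          coordinates=np.stack([frame, frame]))
        return traj, ring

    def test_static_within_cutoff(self):
        traj, ring = self._static(4.0)
        assert contact_series(traj, [0], ring).fraction == 1.0

    def test_static_beyond_cutoff(self):
        traj, ring = self._static(7.0)
        assert contact_series(traj, [0], ring).fraction == 0.0

    def test_histogram_mass_equals_frame_count(self, wt_run):
        structure, traj, _ = wt_run
        ring = detect_indole_rings(structure)[0]
        n_idx = structure.select(residue_id=1, names=["N"])
        cs = contact_series(traj, n_idx, ring, hist_range=(3.5, 4.5))
        assert cs.hist_counts.sum() == traj.n_frames

    def test_cutoff_monotonicity(self, wt_run):
        structure, traj, _ = wt_run
        ring = detect_indole_rings(structure)[0]
        n_idx = structure.select(residue_id=1, names=["N"])
        fracs = [contact_series(traj, n_idx, ring, cutoff=c).fraction
                 for c in (3.0, 4.0, 5.0, 6.0, 8.0)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_cutoff_rejected(self):
        traj, ring = self._static(4.0)
        with pytest.raises(ValueError, match="cutoff"):
            contact_series(traj, [0], ring, cutoff=0.0)


class TestClosestPair:
    def test_single_hydrogen_distance(self):
        frame, ring = _toy_ring_frame()
        # put one "methyl H" 2.5 A above a known ring atom
        h = frame[list(ring.all_heavy)[3]] + np.array([0.0, 0.0, 2.5])
        frame2 = np.vstack([frame, h])
        d, pair = closest_methyl_carbon_distance(frame2, [len(frame2) - 1], ring)
        assert d == pytest.approx(2.5)
        assert pair[0] == len(frame2) - 1

    def test_matches_exhaustive_double_loop(self, wt_run):
        structure, traj, _ = wt_run
        ring = detect_indole_rings(structure)[0]
        h_idx = structure.select(residue_id=1, element="H")
        for f in (0, 100, 500):
            frame = traj.coordinates[f]
            d, _ = closest_methyl_carbon_distance(frame, h_idx, ring)
            oracle = min(np.linalg.norm(frame[h] - frame[c])
                         for h in h_idx for c in ring.all_heavy)
            assert d == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_tie_is_deterministic(self):
        frame, ring = _toy_ring_frame()
        target = frame[list(ring.all_heavy)[0]]
        h1 = target + np.array([0.0, 0.0, 2.0])
        h2 = target + np.array([0.0, 0.0, -2.0])
        frame2 = np.vstack([frame, h1, h2])
        hs = [len(frame2) - 2, len(frame2) - 1]
        d, pair = closest_methyl_carbon_distance(frame2, hs, ring)
        assert d == pytest.approx(2.0)
        assert pair[0] == hs[0]  # lowest H index wins the tie

    def test_no_hydrogens_rejected(self):
        frame, ring = _toy_ring_frame()
        with pytest.raises(ValueError, match="methyl hydrogens"):
            closest_methyl_carbon_distance(frame, [], ring)
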