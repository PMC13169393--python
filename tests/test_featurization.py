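"""Native-contact featurization and trajectory-analysis correctness."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdsom._geom import rotation_about_axis
from mdsom.featurization import (FeatureSpec, backbone_rmsd_series,
                                 compute_features, concat_features,
                                 contact_count_series,
                                 find_native_contact_pairs, rmsf_per_residue)
from mdsom.structure_io import TrajectoryHandle
from mdsom.synthetic_data import build_helix_peptide
from tests.conftest import make_model


def beads_model(positions):
    rows = []
    for i, p in enumerate(positions, start=1):
        rows.append(("CA", "C", i, "GLY", tuple(p)))
    return make_model(rows)


def make_traj(model, coords_list, times=None):
    coords = np.asarray(coords_list, dtype=float)
    if times is None:
        times = (np.arange(len(coords)) + 1) * 100.0
    return TrajectoryHandle(model, coords, times, system_label="S", replica_id=1)


class TestNativeContacts:
    def test_collinear_beads_give_seven_pairs(self):
        """5 beads spaced 4 A: pairs at 4, 8 A are contacts, 12/16 A not."""
        m = beads_model([(4.0 * i, 0, 0) for i in range(5)])
        ps = find_native_contact_pairs(m, FeatureSpec(contact_cutoff=11.0))
        assert ps.n_pairs == 7
        assert set(ps.pairs) == {(1, 2), (2, 3), (3, 4), (4, 5),
                                 (1, 3), (2, 4), (3, 5)}

    def test_single_residue_gives_zero_pairs(self):
        m = beads_model([(0, 0, 0)])
        ps = find_native_contact_pairs(m)
        assert ps.n_pairs == 0

    def test_reference_distances_below_cutoff(self, helix12):
        ps = find_native_contact_pairs(helix12)
        assert np.all(ps.reference_distances < 11.0)
        assert all(i < j for i, j in ps.pairs)

    def test_independent_of_atom_order(self, helix12, rng):
        from mdsom.structure_io import StructureModel
        ps1 = find_native_contact_pairs(helix12)
        shuffled = list(helix12.atoms)
        rng.shuffle(shuffled)
        ps2 = find_native_contact_pairs(StructureModel(shuffled))
        assert ps1.pairs == ps2.pairs
        np.testing.assert_allclose(ps1.reference_distances,
                                   ps2.reference_distances)

    def test_min_sequence_separation_filter(self):
        m = beads_model([(4.0 * i, 0, 0) for i in range(5)])
        ps = find_native_contact_pairs(
            m, FeatureSpec(contact_cutoff=11.0, min_sequence_separation=2))
        assert set(ps.pairs) == {(1, 3), (2, 4), (3, 5)}


class TestComputeFeatures:
    def test_reference_frame_reproduces_reference_distances(self, helix12):
        ps = find_native_contact_pairs(helix12)
        traj = make_traj(helix12, [helix12.coords()])
        fm = compute_features(traj, ps)
        np.testing.assert_allclose(fm.values[0], ps.reference_distances,
                                   atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        helix = build_helix_peptide(12)
        ps = find_native_contact_pairs(helix)
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        R = rotation_about_axis(axis, rng.uniform(0, 2 * np.pi))
        t = rng.uniform(-50, 50, size=3)
        moved = helix.coords() @ R.T + t
        traj = make_traj(helix, [helix.coords(), moved])
        fm = compute_features(traj, ps)
        np.testing.assert_allclose(fm.values[0], fm.values[1], atol=1e-6)

    def test_stride_retains_multiples_and_row_count(self, helix12):
        ps = find_native_contact_pairs(helix12)
        # 2 ns at 50 ps spacing -> 40 frames; 100 ps stride keeps 20
        n = 40
        coords = np.stack([helix12.coords()] * n)
        times = (np.arange(n) + 1) * 50.0
        traj = make_traj(helix12, coords, times)
        fm100 = compute_features(traj, ps, FeatureSpec(stride=100.0))
        fm50 = compute_features(traj, ps, FeatureSpec(stride=50.0))
        assert fm100.n_frames == 20
        assert fm50.n_frames == 40
        assert set(fm100.frame_meta["time_ps"]) <= set(fm50.frame_meta["time_ps"])

    def test_csv_round_trip(self, tmp_path, helix12):
        from mdsom.featurization import FeatureMatrix
        ps = find_native_contact_pairs(helix12)
        traj = make_traj(helix12, [helix12.coords()] * 3)
        fm = compute_features(traj, ps)
        p = tmp_path / "f.csv"
        fm.to_csv(p)
        back = FeatureMatrix.from_csv(p)
        np.testing.assert_allclose(back.values, fm.values)
        assert back.pair_index.pairs == fm.pair_index.pairs

    def test_concat_requires_same_pairs(self, helix12):
        ps = find_native_contact_pairs(helix12)
        traj = make_traj(helix12, [helix12.coords()])
        fm = compute_features(traj, ps)
        other = build_helix_peptide(16)
        ps2 = find_native_contact_pairs(other)
        fm2 = compute_features(make_traj(other, [other.coords()]), ps2)
        with pytest.raises(ValueError):
            concat_features([fm, fm2])


class TestRmsd:
    def test_identity_trajectory_gives_zero(self, helix12):
        traj = make_traj(helix12, [helix12.coords()] * 3)
        out = backbone_rmsd_series(traj, helix12)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_rigid_translation_removed_by_superposition(self, helix12):
        traj = make_traj(helix12, [helix12.coords() + np.array([3.0, 4.0, 0.0])])
        out = backbone_rmsd_series(traj, helix12)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_two_atom_displacement_without_superposition(self):
        """One of two atoms displaced 1 A -> RMSD = 1/sqrt(2)."""
        m = make_model([("N", "N", 1, "ALA", (0, 0, 0)),
                        ("CA", "C", 1, "ALA", (3, 0, 0))])
        moved = np.array([[0.0, 0.0, 0.0], [3.0, 1.0, 0.0]])
        traj = make_traj(m, [moved])
        out = backbone_rmsd_series(traj, m, superpose=False)
        np.testing.assert_allclose(out, [1.0 / np.sqrt(2.0)], atol=1e-12)


class TestRmsf:
    def test_static_trajectory_has_zero_rmsf(self, helix12):
        traj = make_traj(helix12, [helix12.coords()] * 5)
        df = rmsf_per_residue([traj])
        np.testing.assert_allclose(df["rmsf_mean_A"], 0.0, atol=1e-10)

    def test_two_frame_oscillation_closed_form(self):
        """Central atom oscillating +/- a between two frames.

        With n atoms, superposition removes the net translation a/n and
        (for an atom at the anchor centroid) gains nothing by rotation, so
        the closed form is RMSF = a(n-1)/n for the mover and a/n for each
        anchor.
        """
        a = 0.7
        s = 1000.0  # large anchors suppress any rotational absorption
        base = np.array([[-s, -s, 0], [s, -s, 0], [s, s, 0], [-s, s, 0],
                         [0, 0, 0]], dtype=float)
        rows = [("CA", "C", i + 1, "ALA", tuple(base[i])) for i in range(5)]
        m = make_model(rows)
        up = base.copy()
        up[4, 2] += a
        dn = base.copy()
        dn[4, 2] -= a
        traj = make_traj(m, [up, dn])
        df = rmsf_per_residue([traj])
        n = 5
        assert df["rmsf_mean_A"].iloc[4] == pytest.approx(a * (n - 1) / n,
                                                          abs=1e-6)
        np.testing.assert_allclose(df["rmsf_mean_A"].iloc[:4], a / n,
                                   atol=1e-6)

    def test_identical_replicas_have_zero_sem(self, helix12, rng):
        coords = np.stack([helix12.coords() + rng.normal(0, 0.2,
                          helix12.coords().shape) for _ in range(4)])
        t1 = make_traj(helix12, coords)
        t2 = make_traj(helix12, coords.copy())
        df = rmsf_per_residue([t1, t2])
        np.testing.assert_allclose(df["rmsf_sem_A"], 0.0, atol=1e-12)

    def test_single_frame_replica_rejected(self, helix12):
        traj = make_traj(helix12, [helix12.coords()])
        with pytest.raises(ValueError):
            rmsf_per_residue([traj])


class TestContactCount:
    def test_matches_brute_force_double_loop(self, rng):
        n_res = 8
        rows = []
        pos = rng.uniform(0, 12, size=(n_res * 2, 3))
        k = 0
        for r in range(1, n_res + 1):
            for name in ("CA", "CB"):
                rows.append((name, "C", r, "ALA", tuple(pos[k])))
                k += 1
        m = make_model(rows)
        traj = make_traj(m, [pos, pos + 0.5])
        counts = contact_count_series(traj, cutoff=4.5)
        # brute-force oracle
        resid = np.repeat(np.arange(1, n_res + 1), 2)
        expected = 0
        seen = set()
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                if abs(resid[i] - resid[j]) < 3:
                    continue
                if np.linalg.norm(pos[i] - pos[j]) < 4.5:
                    seen.add((min(resid[i], resid[j]), max(resid[i], resid[j])))
        assert counts[0] == len(seen)
        assert counts[1] == len(seen)  # rigid shift preserves contacts

    def test_dispersed_atoms_have_zero_contacts(self):
        m = beads_model([(100.0 * i, 0, 0) for i in range(5)])
        traj = make_traj(m, [m.coords()])
        assert contact_count_series(traj)[0] == 0
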