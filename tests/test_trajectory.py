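"""Coordinate I/O, replica concatenation, Kabsch superposition, matrix layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from essdyn.exceptions import (
    ConsistencyError,
    FormatOverflowError,
    InsufficientPointsError,
    StructuralError,
)
from essdyn.trajectory import (
    Frame,
    Trajectory,
    build_coordinate_matrix,
    concatenate_replicas,
    coordinate_matrix_from_csv,
    coordinate_matrix_to_csv,
    kabsch_fit,
    read_multimodel_pdb,
    superpose_trajectory,
    write_multimodel_pdb,
)
from tests.conftest import make_ca_trajectory


# ---------------------------------------------------------------------------
# PDB round trips
# ---------------------------------------------------------------------------

class TestPdbIO:
    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        coords = 30.0 * rng.standard_normal((3, 2, 3))
        traj = make_ca_trajectory(coords)
        path = tmp_path / "t.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.ca_array(), coords, atol=1e-3)

    def test_one_frame_per_model(self, tmp_path, rng):
        traj = make_ca_trajectory(rng.standard_normal((101, 4, 3)))
        path = tmp_path / "t.pdb"
        write_multimodel_pdb(traj, path)
        assert read_multimodel_pdb(path).n_frames == 101

    def test_missing_ca_names_model_and_residue(self, tmp_path):
        lines = []
        for model in (1, 2):
            lines.append(f"MODEL     {model}")
            for res in range(1, 7):
                name = " CB " if (model == 2 and res == 5) else " CA "
                lines.append(
                    f"ATOM  {res:>5}{name} ALA A{res:>4}    "
                    f"{res * 3.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        path = tmp_path / "broken.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructuralError, match=r"model 2.*residue 5"):
            read_multimodel_pdb(path)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ConsistencyError):
            Trajectory(frames=[], n_residues=0)

    def test_coordinate_overflow_rejected(self, tmp_path):
        traj = make_ca_trajectory([[[10500.0, 0, 0], [1, 2, 3], [4, 5, 6]]])
        with pytest.raises(FormatOverflowError):
            write_multimodel_pdb(traj, tmp_path / "t.pdb")


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

class TestConcatenation:
    def test_three_replicas_of_101_frames_give_303(self, rng):
        reps = [
            make_ca_trajectory(rng.standard_normal((101, 5, 3)))
            for _ in range(3)
        ]
        cat = concatenate_replicas(reps)
        assert cat.n_frames == 303
        # 0 ns frames of each replica land at global indices 0, 101, 202
        for gidx, rid in ((0, 0), (101, 1), (202, 2)):
            assert cat.frame_labels[gidx] == (rid, 0.0)

    def test_single_replica_identity(self, rng):
        coords = rng.standard_normal((4, 5, 3))
        cat = concatenate_replicas([make_ca_trajectory(coords)])
        np.testing.assert_array_equal(cat.ca_array(), coords)

    def test_count_additivity_and_boundaries(self, rng):
        reps = [
            make_ca_trajectory(rng.standard_normal((50, 5, 3))),
            make_ca_trajectory(rng.standard_normal((51, 5, 3))),
        ]
        cat = concatenate_replicas(reps)
        assert cat.n_frames == 101
        assert [r for r, _ in cat.frame_labels] == [0] * 50 + [1] * 51

    def test_mismatched_residue_counts_rejected(self, rng):
        reps = [
            make_ca_trajectory(rng.standard_normal((2, 5, 3))),
            make_ca_trajectory(rng.standard_normal((2, 6, 3))),
        ]
        with pytest.raises(ConsistencyError):
            concatenate_replicas(reps)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def brute_force_rmsd(mobile, reference):
    """Independent oracle: minimize RMSD over Euler angles + translation.

    The translation optimum is analytic (match centroids of rotated mobile);
    the rotation is found numerically from many restarts, with no SVD.
    """
    mobile = np.asarray(mobile)
    reference = np.asarray(reference)
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((m @ R.T - r) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(0)
    for _ in range(40):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity_fit(self, rng):
        pts = rng.standard_normal((10, 3))
        fit = kabsch_fit(pts, pts)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(fit.translation, 0.0, atol=1e-10)
        assert fit.rmsd < 1e-12

    def test_recovers_planted_rigid_transform(self, rng):
        ref = rng.standard_normal((12, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ R.T + np.array([1.0, 2.0, 3.0])
        fit = kabsch_fit(mobile, ref)
        assert fit.rmsd < 1e-10
        np.testing.assert_allclose(fit.apply(mobile), ref, atol=1e-8)

    def test_rmsd_matches_brute_force_oracle(self, rng):
        ref = np.array(
            [[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 2.0, 3.0]]
        )
        mobile = ref + rng.normal(0, 0.5, ref.shape)
        fit = kabsch_fit(mobile, ref)
        assert fit.rmsd == pytest.approx(brute_force_rmsd(mobile, ref), abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_warns_but_fits(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.warns(RuntimeWarning, match="collinear"):
            fit = kabsch_fit(line, line)
        assert fit.rmsd < 1e-10

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(float, (6, 3), elements=st.floats(-50, 50)),
        arrays(float, (6, 3), elements=st.floats(-50, 50)),
    )
    def test_rotation_always_proper_orthonormal(self, mobile, reference):
        fit = kabsch_fit(mobile, reference)
        np.testing.assert_allclose(
            fit.rotation.T @ fit.rotation, np.eye(3), atol=1e-8
        )
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-8)


class TestSuperposeTrajectory:
    def test_rigid_copies_collapse_onto_reference(self, rng):
        ref = 10 * rng.standard_normal((20, 3))
        frames = [ref]
        for _ in range(9):
            q = rng.standard_normal(4)
            R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
            frames.append(ref @ R.T + rng.normal(0, 15, 3))
        traj = make_ca_trajectory(np.stack(frames))
        aligned = superpose_trajectory(traj)
        assert aligned.aligned
        for f in aligned.frames:
            np.testing.assert_allclose(f.ca_coords, ref, atol=1e-8)

    def test_idempotent_on_aligned_input(self, rng):
        traj = make_ca_trajectory(10 * rng.standard_normal((5, 8, 3)))
        once = superpose_trajectory(traj)
        twice = superpose_trajectory(once)
        np.testing.assert_allclose(twice.ca_array(), once.ca_array(), atol=1e-10)

    def test_never_increases_rmsd_to_reference(self, rng):
        coords = 5 * rng.standard_normal((15, 10, 3))
        traj = make_ca_trajectory(coords)
        ref = traj.frames[0].ca_coords
        aligned = superpose_trajectory(traj)
        for before, after in zip(traj.frames, aligned.frames):
            rmsd_before = np.sqrt(np.mean(np.sum((before.ca_coords - ref) ** 2, 1)))
            rmsd_after = np.sqrt(np.mean(np.sum((after.ca_coords - ref) ** 2, 1)))
            assert rmsd_after <= rmsd_before + 1e-12


# ---------------------------------------------------------------------------
# Coordinate matrix
# ---------------------------------------------------------------------------

class TestCoordinateMatrix:
    def test_449_residues_give_1347_columns(self, rng):
        traj = make_ca_trajectory(rng.standard_normal((2, 449, 3)), aligned=True)
        m = build_coordinate_matrix(traj)
        assert m.n_columns == 1347
        assert m.column_labels[:3] == [(1, "x"), (1, "y"), (1, "z")]

    def test_minimal_matrix(self):
        traj = make_ca_trajectory(np.ones((1, 1, 3)), aligned=True)
        assert build_coordinate_matrix(traj).values.shape == (1, 3)

    def test_row_reshape_recovers_frame(self, rng):
        coords = rng.standard_normal((10, 6, 3))
        m = build_coordinate_matrix(make_ca_trajectory(coords, aligned=True))
        np.testing.assert_array_equal(m.frame_coords(7), coords[7])

    def test_unaligned_warns(self, rng):
        traj = make_ca_trajectory(rng.standard_normal((2, 3, 3)))
        with pytest.warns(UserWarning, match="alignment"):
            build_coordinate_matrix(traj)

    def test_csv_round_trip(self, tmp_path, rng):
        coords = rng.standard_normal((4, 3, 3))
        m = build_coordinate_matrix(make_ca_trajectory(coords, aligned=True))
        path = tmp_path / "m.csv"
        coordinate_matrix_to_csv(m, path)
        back = coordinate_matrix_from_csv(path)
        np.testing.assert_array_equal(back.values, m.values)
        assert back.column_labels == m.column_labels
        assert back.frame_labels == m.frame_labels
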