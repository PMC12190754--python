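"""DCCM correctness and block summarization; porcupine fields and exports."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from essdyn.essential_dynamics import pca
from essdyn.exceptions import DataError
from essdyn.motion import (
    arrow_difference_table,
    dccm,
    dccm_blocks,
    export_arrows,
    porcupine_field,
    read_arrows_csv,
)
from essdyn.synthetic import make_modes, make_reference_chain
from essdyn.trajectory import CoordinateMatrix, Frame, superpose_trajectory
from tests.conftest import make_ca_trajectory


def brute_force_dccm(coords):
    """Double-loop reference implementation of the correlation matrix."""
    F, N, _ = coords.shape
    mean = coords.mean(axis=0)
    C = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            num = sum((coords[t, i] - mean[i]) @ (coords[t, j] - mean[j])
                      for t in range(F)) / F
            vi = sum((coords[t, i] - mean[i]) @ (coords[t, i] - mean[i])
                     for t in range(F)) / F
            vj = sum((coords[t, j] - mean[j]) @ (coords[t, j] - mean[j])
                     for t in range(F)) / F
            C[i, j] = num / np.sqrt(vi * vj)
    return C


class TestDccm:
    def test_diagonal_is_one(self, rng):
        d = dccm(rng.standard_normal((30, 8, 3)))
        np.testing.assert_allclose(np.diag(d.values), 1.0, atol=1e-9)

    def test_identical_and_negated_series(self, rng):
        disp = rng.standard_normal((50, 1, 3))
        base = np.zeros((50, 3, 3))
        base[:, 0] = disp[:, 0]
        base[:, 1] = disp[:, 0]          # identical displacement series
        base[:, 2] = -disp[:, 0]         # exactly negated
        d = dccm(base)
        assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert d.values[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        coords = rng.standard_normal((50, 20, 3))
        d = dccm(coords)
        np.testing.assert_allclose(d.values, brute_force_dccm(coords), atol=1e-12)

    def test_independent_noise_has_small_offdiagonal(self, rng):
        d = dccm(rng.standard_normal((10_000, 12, 3)))
        off = d.values[~np.eye(12, dtype=bool)]
        # sampling bound: |C| < 0.05 with probability >= 0.99 per entry
        assert np.mean(np.abs(off) < 0.05) >= 0.99

    def test_symmetry_and_range(self, rng):
        d = dccm(rng.standard_normal((40, 10, 3)))
        np.testing.assert_allclose(d.values, d.values.T, atol=1e-12)
        assert d.values.min() >= -1.0 - 1e-9
        assert d.values.max() <= 1.0 + 1e-9

    def test_zero_variance_residue_flagged(self, rng):
        coords = rng.standard_normal((20, 4, 3))
        coords[:, 2] = [1.0, 2.0, 3.0]
        d = dccm(coords)
        assert d.zero_variance_residues == [3]
        assert np.all(d.values[2, [0, 1, 3]] == 0.0)
        assert d.values[2, 2] == 1.0

    def test_invariant_under_global_rotation(self, rng):
        coords = 5 * rng.standard_normal((40, 10, 3))
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        rotated = coords @ R.T
        a = dccm(superpose_trajectory(make_ca_trajectory(coords)))
        b = dccm(superpose_trajectory(make_ca_trajectory(rotated)))
        np.testing.assert_allclose(b.values, a.values, atol=1e-8)

    def test_equals_block_trace_of_3n_covariance(self, rng):
        coords = rng.standard_normal((60, 7, 3))
        d = dccm(coords)
        flat = coords.reshape(60, -1)
        cov = np.cov(flat.T, ddof=0)
        N = 7
        C = np.zeros((N, N))
        for i in range(N):
            for j in range(N):
                tij = np.trace(cov[3 * i : 3 * i + 3, 3 * j : 3 * j + 3])
                tii = np.trace(cov[3 * i : 3 * i + 3, 3 * i : 3 * i + 3])
                tjj = np.trace(cov[3 * j : 3 * j + 3, 3 * j : 3 * j + 3])
                C[i, j] = tij / np.sqrt(tii * tjj)
        np.testing.assert_allclose(d.values, C, atol=1e-10)


class TestDccmBlocks:
    def test_planted_anticorrelated_blocks(self, rng):
        # single anti-phase mode over two halves -> +1 within, -1 between
        ref = make_reference_chain(20, seed=0)
        modes = make_modes(
            ref, (4.0,), blocks=[[(0, 10, +1), (10, 20, -1)]], seed=1
        )
        amps = rng.standard_normal(60) * 2.0
        coords = (ref.ca_coords.ravel() + np.outer(amps, modes[0])).reshape(60, 20, 3)
        d = dccm(coords)
        blocks = dccm_blocks(d, threshold=0.9)
        positives = [b for b in blocks if b["sign"] > 0]
        negatives = [b for b in blocks if b["sign"] < 0]
        assert len(positives) == 2 and len(negatives) == 1
        assert negatives[0]["range_a"] == (1, 10)
        assert negatives[0]["range_b"] == (11, 20)
        for b in blocks:
            assert b["mean_abs_correlation"] == pytest.approx(1.0, abs=1e-9)

    def test_identity_matrix_yields_nothing(self):
        from essdyn.motion import DCCMatrix

        d = DCCMatrix(np.eye(15), list(range(1, 16)), [])
        assert dccm_blocks(d, threshold=0.5) == []

    def test_high_threshold_on_noise_is_empty(self, rng):
        d = dccm(rng.standard_normal((200, 10, 3)))
        assert dccm_blocks(d, threshold=0.99) == []


def pca_result_with_loadings(loadings):
    """Minimal essential-dynamics result wrapping given unit loadings."""
    from essdyn.essential_dynamics import EssentialDynamicsResult

    loadings = np.asarray(loadings, dtype=float)
    k = loadings.shape[1]
    return EssentialDynamicsResult(
        eigenvalues=np.ones(k),
        variance_proportion=np.full(k, 1 / k),
        cumulative_proportion=np.linspace(1 / k, 1, k),
        scores=np.zeros((2, k)),
        loadings=loadings,
        k_retained=k,
        standardized=False,
    )


class TestPorcupine:
    def test_zero_eigenvector_gives_zero_arrows(self, rng):
        ref = Frame.from_ca_coords(rng.standard_normal((5, 3)))
        res = pca_result_with_loadings(np.zeros((15, 1)))
        field = porcupine_field(res, 1, ref, scale=2.0)
        np.testing.assert_array_equal(field.arrows, 0.0)

    def test_unit_loading_single_residue(self, rng):
        ref = Frame.from_ca_coords(rng.standard_normal((6, 3)))
        vec = np.zeros((18, 1))
        vec[3 * 4 + 0] = 1.0  # residue 5, x axis
        field = porcupine_field(pca_result_with_loadings(vec), 1, ref, scale=10.0)
        np.testing.assert_array_equal(field.arrows[4], [10.0, 0.0, 0.0])
        assert np.all(field.arrows[[0, 1, 2, 3, 5]] == 0.0)

    def test_magnitudes_equal_scaled_norms(self, rng):
        ref = Frame.from_ca_coords(rng.standard_normal((8, 3)))
        vec = rng.standard_normal((24, 1))
        vec /= np.linalg.norm(vec)
        field = porcupine_field(pca_result_with_loadings(vec), 1, ref, scale=3.5)
        expected = 3.5 * np.linalg.norm(vec.reshape(8, 3), axis=1)
        np.testing.assert_allclose(field.magnitudes, expected, atol=1e-12)

    def test_default_scale_longest_arrow_10A(self, rng):
        ref = Frame.from_ca_coords(rng.standard_normal((8, 3)))
        vec = rng.standard_normal((24, 1))
        field = porcupine_field(pca_result_with_loadings(vec), 1, ref)
        assert field.magnitudes.max() == pytest.approx(10.0, abs=1e-9)

    def test_component_out_of_range(self, rng):
        ref = Frame.from_ca_coords(rng.standard_normal((4, 3)))
        res = pca_result_with_loadings(rng.standard_normal((12, 2)))
        with pytest.raises(ValueError):
            porcupine_field(res, 3, ref)


class TestArrowExport:
    def _field(self, rng, n=6):
        ref = Frame.from_ca_coords(rng.standard_normal((n, 3)))
        vec = rng.standard_normal((3 * n, 1))
        return porcupine_field(pca_result_with_loadings(vec), 1, ref, scale=1.0)

    def test_csv_round_trip(self, tmp_path, rng):
        field = self._field(rng)
        path = tmp_path / "a.csv"
        export_arrows(field, path, "csv")
        df = read_arrows_csv(path)
        assert len(df) == 6
        tips = df[["tip_x", "tip_y", "tip_z"]].to_numpy()
        np.testing.assert_allclose(tips, field.base + field.arrows, atol=1e-12)
        np.testing.assert_allclose(df["magnitude"], field.magnitudes, atol=1e-12)

    def test_bild_arrows_parse_back(self, tmp_path, rng):
        field = self._field(rng)
        path = tmp_path / "a.bild"
        export_arrows(field, path, "bild")
        records = [
            line.split()[1:] for line in path.read_text().splitlines()
            if line.startswith(".arrow")
        ]
        assert len(records) == 6
        for rec, base, arrow in zip(records, field.base, field.arrows):
            vals = np.asarray(rec, dtype=float)
            np.testing.assert_allclose(vals[:3], base, atol=1e-4)
            np.testing.assert_allclose(vals[3:6], base + arrow, atol=1e-4)

    def test_unknown_format_rejected(self, tmp_path, rng):
        with pytest.raises(ValueError):
            export_arrows(self._field(rng), tmp_path / "x", "xml")

    def test_difference_table(self, rng):
        a = self._field(rng)
        b = self._field(rng)
        table = arrow_difference_table(a, b)
        np.testing.assert_allclose(
            table[["dx", "dy", "dz"]].to_numpy(), b.arrows - a.arrows, atol=1e-12
        )
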