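"""Block partition, zigzag expansion, measurement, DCT basis, StOMP."""

import numpy as np
import pytest
from scipy.fft import dct

from leafcs import (
    HyperCube,
    StompParams,
    compose_sensing,
    expand_block,
    inverse_expand_block,
    make_dct_basis,
    make_gaussian_matrix,
    measure,
    measurements_count,
    partition_roi_blocks,
    stomp_recover,
)

from conftest import random_cube


class TestPartition:
    def test_aligned_2x2_roi_is_one_full_block(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[2:4, 2:4] = 1
        blocks = partition_roi_blocks(labels, 1)
        assert blocks.n_blocks == 1
        np.testing.assert_array_equal(blocks.anchors, [[2, 2]])
        assert blocks.valid.all()

    def test_3x3_roi_block_valid_counts(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[1:4, 1:4] = 1
        blocks = partition_roi_blocks(labels, 1)
        counts = sorted(blocks.valid.sum(axis=1))
        assert counts == [1, 2, 2, 4]

    def test_l_shape_covered_exactly_once(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:7, 3] = 1
        labels[6, 3:8] = 1
        blocks = partition_roi_blocks(labels, 1)
        covered = np.zeros_like(labels)
        for (ar, ac), flags in zip(blocks.anchors, blocks.valid):
            for slot, (dr, dc) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
                if flags[slot]:
                    covered[ar + dr, ac + dc] += 1
        np.testing.assert_array_equal(covered, labels)

    def test_roi_at_image_edge_blocks_clipped(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[4, 4] = 1  # bounding box is the corner pixel
        blocks = partition_roi_blocks(labels, 1)
        assert blocks.n_blocks == 1
        assert blocks.valid.sum() == 1

    def test_unknown_roi_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            partition_roi_blocks(np.zeros((4, 4), dtype=int), 3)


class TestExpansion:
    def _cube(self, values):
        values = np.asarray(values)
        return HyperCube(
            data=values.astype(np.uint16),
            wavelengths=np.linspace(500, 600, values.shape[2]),
        )

    def test_single_band_zigzag_order(self):
        cube = self._cube(np.array([[[1], [2]], [[3], [4]]]))
        vec = expand_block(cube, (0, 0), np.ones(4, bool))
        np.testing.assert_array_equal(vec, [1, 2, 3, 4])

    def test_band_major_layout(self):
        data = np.zeros((2, 2, 2), dtype=int)
        data[:, :, 0] = [[1, 2], [3, 4]]
        data[:, :, 1] = [[5, 6], [7, 8]]
        vec = expand_block(self._cube(data), (0, 0), np.ones(4, bool))
        np.testing.assert_array_equal(vec, [1, 2, 3, 4, 5, 6, 7, 8])

    def test_mean_fill_of_invalid_slot(self):
        data = np.array([[[10], [20]], [[30], [99]]])
        valid = np.array([True, True, True, False])
        vec = expand_block(self._cube(data), (0, 0), valid)
        np.testing.assert_array_equal(vec, [10, 20, 30, 20])

    def test_zero_fill_rule(self):
        data = np.array([[[10], [20]], [[30], [99]]])
        valid = np.array([True, True, True, False])
        vec = expand_block(self._cube(data), (0, 0), valid, fill_rule="zero")
        np.testing.assert_array_equal(vec, [10, 20, 30, 0])

    def test_roundtrip_identity_on_valid_pixels(self, rng):
        cube = random_cube(rng, 4, 4, 6)
        out = HyperCube(
            data=np.zeros_like(cube.data), wavelengths=cube.wavelengths
        )
        valid = np.array([True, False, True, True])
        vec = expand_block(cube, (2, 0), valid)
        inverse_expand_block(vec, (2, 0), valid, out)
        for slot, (dr, dc) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            if valid[slot]:
                np.testing.assert_array_equal(
                    out.data[2 + dr, 0 + dc], cube.data[2 + dr, 0 + dc]
                )
            else:
                assert np.all(out.data[2 + dr, 0 + dc] == 0)

    @pytest.mark.parametrize("bit_depth", [12, 16])
    def test_roundtrip_many_random_blocks(self, bit_depth):
        rng = np.random.default_rng(11)
        full = (1 << bit_depth) - 1
        for _ in range(250):
            cube = HyperCube(
                data=rng.integers(0, full + 1, size=(2, 2, 3), dtype=np.uint16),
                wavelengths=np.array([500.0, 600.0, 700.0]),
                bit_depth=bit_depth,
            )
            valid = rng.random(4) < 0.7
            if not valid.any():
                valid[0] = True
            out = HyperCube(
                data=np.zeros_like(cube.data),
                wavelengths=cube.wavelengths,
                bit_depth=bit_depth,
            )
            vec = expand_block(cube, (0, 0), valid)
            inverse_expand_block(vec, (0, 0), valid, out)
            np.testing.assert_array_equal(out.data[valid.reshape(2, 2)],
                                          cube.data[valid.reshape(2, 2)])

    def test_clipping_negative_and_overflow(self):
        out = HyperCube(
            data=np.zeros((2, 2, 1), dtype=np.uint16),
            wavelengths=np.array([500.0]),
        )
        vec = np.array([-3.4, 65535.6, 12.5, 7.0])
        inverse_expand_block(vec, (0, 0), np.ones(4, bool), out)
        np.testing.assert_array_equal(
            out.data[:, :, 0], [[0, 65535], [12, 7]]
        )

    def test_length_mismatch_rejected(self):
        out = HyperCube(
            data=np.zeros((2, 2, 2), dtype=np.uint16),
            wavelengths=np.array([500.0, 600.0]),
        )
        with pytest.raises(ValueError, match="length"):
            inverse_expand_block(np.zeros(7), (0, 0), np.ones(4, bool), out)


class TestMeasurement:
    def test_same_seed_identical(self):
        a = make_gaussian_matrix(10, 40, seed=5)
        b = make_gaussian_matrix(10, 40, seed=5)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_entry_variance(self):
        op = make_gaussian_matrix(100, 1000, seed=1)
        assert np.var(op.phi) == pytest.approx(1 / 100, rel=0.10)

    @pytest.mark.parametrize("m,n", [(0, 5), (5, 5), (6, 5)])
    def test_bad_shapes_rejected(self, m, n):
        with pytest.raises(ValueError):
            make_gaussian_matrix(m, n, seed=0)

    @pytest.mark.parametrize(
        "rate,n,expected",
        [(0.05, 2384, 120), (0.5, 8, 4), (0.001, 8, 1)],
    )
    def test_measurements_count(self, rate, n, expected):
        assert measurements_count(rate, n) == expected

    @pytest.mark.parametrize("rate", [0.0, 1.0, -0.1, 1.5])
    def test_rate_out_of_range(self, rate):
        with pytest.raises(ValueError, match="rate"):
            measurements_count(rate, 100)

    def test_measure_is_matrix_vector_product(self, rng):
        phi = make_gaussian_matrix(3, 6, seed=2)
        x = rng.standard_normal(6)
        y = measure(phi, x)
        oracle = np.array([phi.phi[i] @ x for i in range(3)])
        np.testing.assert_allclose(y, oracle)
        np.testing.assert_allclose(measure(phi, np.zeros(6)), 0.0)

    def test_identity_selection(self):
        phi = make_gaussian_matrix(3, 8, seed=0)
        phi.phi = np.eye(8)[:3]
        x = np.arange(8.0)
        np.testing.assert_allclose(measure(phi, x), [0, 1, 2])


class TestDctBasis:
    def test_degenerate_n1(self):
        np.testing.assert_allclose(make_dct_basis(1), [[1.0]])

    def test_n2_closed_form(self):
        expected = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        np.testing.assert_allclose(make_dct_basis(2), expected, atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 4, 64, 1476, 2384])
    def test_orthonormality(self, n):
        psi = make_dct_basis(n)
        err = np.abs(psi.T @ psi - np.eye(n)).max()
        assert err < 1e-9

    def test_matches_scipy_dct(self):
        n = 33
        np.testing.assert_allclose(
            make_dct_basis(n), dct(np.eye(n), axis=0, norm="ortho"), atol=1e-12
        )

    def test_bad_size_rejected(self):
        with pytest.raises(ValueError):
            make_dct_basis(0)


class TestComposeSensing:
    def test_identity_selection_rows_of_psi(self):
        psi = make_dct_basis(8)
        phi = np.eye(8)[:3]
        np.testing.assert_allclose(compose_sensing(phi, psi), psi[:3])

    def test_hand_product(self):
        phi = np.array([[1.0, 0, 2], [0, 1, -1]])
        psi = np.array([[1.0, 2, 0], [0, 1, 1], [1, 0, 1]])
        expected = np.array([[3.0, 2, 2], [-1, 1, 0]])
        np.testing.assert_allclose(compose_sensing(phi, psi), expected)

    def test_shape_and_mismatch(self):
        a = compose_sensing(np.zeros((3, 6)), np.eye(6))
        assert a.shape == (3, 6)
        with pytest.raises(ValueError, match="compose"):
            compose_sensing(np.zeros((3, 5)), np.eye(6))


class TestStomp:
    def test_zero_measurements_give_zero(self):
        a = make_gaussian_matrix(8, 32, seed=0).phi
        s, y_hat = stomp_recover(a, np.zeros(8))
        assert np.all(s == 0) and np.all(y_hat == 0)

    def test_1_sparse_exact_vs_exhaustive_oracle(self):
        n, m = 64, 16
        psi = make_dct_basis(n).T
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = compose_sensing(make_gaussian_matrix(m, n, seed), psi)
            j = int(rng.integers(n))
            s0 = np.zeros(n)
            s0[j] = rng.uniform(1, 10)
            y = a @ s0
            s, _ = stomp_recover(a, y)
            # oracle: exhaustive single-atom least squares
            resid = [
                np.linalg.norm(y - a[:, k] * (a[:, k] @ y) / (a[:, k] @ a[:, k]))
                for k in range(n)
            ]
            assert int(np.argmin(resid)) == j
            assert set(np.flatnonzero(s)) == {j}
            assert np.linalg.norm(s - s0) / np.linalg.norm(s0) < 1e-8

    def test_8_sparse_high_success_rate(self):
        n, m, k = 256, 96, 8
        psi = make_dct_basis(n).T
        successes = 0
        for trial in range(50):
            rng = np.random.default_rng(1000 + trial)
            a = compose_sensing(make_gaussian_matrix(m, n, 2000 + trial), psi)
            s0 = np.zeros(n)
            s0[rng.choice(n, k, replace=False)] = rng.standard_normal(k) * 5
            y = a @ s0
            s, _ = stomp_recover(a, y)
            if np.linalg.norm(s - s0) / np.linalg.norm(s0) < 1e-4:
                successes += 1
        assert successes >= 45

    def test_error_non_increasing_in_m(self):
        """Average recovery error shrinks as measurements grow."""
        n, k = 128, 6
        psi = make_dct_basis(n).T
        mean_err = []
        for m in (24, 48, 96):
            errs = []
            for trial in range(15):
                rng = np.random.default_rng(300 + trial)
                a = compose_sensing(make_gaussian_matrix(m, n, 400 + trial), psi)
                s0 = np.zeros(n)
                s0[rng.choice(n, k, replace=False)] = rng.standard_normal(k) * 3
                s, _ = stomp_recover(a, a @ s0)
                errs.append(np.linalg.norm(s - s0) / np.linalg.norm(s0))
            mean_err.append(np.mean(errs))
        assert mean_err[0] >= mean_err[1] >= mean_err[2]

    def test_noiseless_recovery_rate_m_over_4k(self):
        """k-sparse signals with M >= 4k measurements (here M = 6k) recover
        in >= 90% of seeded trials."""
        n = 128
        psi = make_dct_basis(n).T
        for k in (4, 8, 12):
            good = 0
            m = 6 * k
            for trial in range(20):
                rng = np.random.default_rng(7000 + 100 * k + trial)
                a = compose_sensing(
                    make_gaussian_matrix(m, n, 8000 + 100 * k + trial), psi
                )
                s0 = np.zeros(n)
                s0[rng.choice(n, k, replace=False)] = rng.standard_normal(k) * 4
                s, _ = stomp_recover(a, a @ s0)
                good += np.linalg.norm(s - s0) / np.linalg.norm(s0) < 1e-6
            assert good >= 18

    def test_support_capped_at_m(self):
        n, m = 64, 10
        a = compose_sensing(make_gaussian_matrix(m, n, 3), make_dct_basis(n).T)
        rng = np.random.default_rng(9)
        y = rng.standard_normal(m) * 100  # generic, not sparse
        s, _ = stomp_recover(a, y, StompParams(threshold=0.5, max_stages=50))
        assert np.count_nonzero(s) <= m

    def test_bad_lengths_rejected(self):
        a = np.zeros((4, 8))
        with pytest.raises(ValueError, match="measurement length"):
            stomp_recover(a, np.zeros(5))
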