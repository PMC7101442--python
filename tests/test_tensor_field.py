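"""Sliding-window covariance tensors: hand values, oracle, equivariance."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import fmtensor as fm


def naive_tensor_field(dset, window, stride, min_count):
    """Independent per-window double loop with exact (fsum) accumulation."""
    lo, hi = dset.bounding_box
    stride3 = np.broadcast_to(np.asarray(stride, float), (3,))
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / stride3[k])) + 1 for k in range(3))
    mats = np.zeros(shape + (3, 3))
    counts = np.zeros(shape, dtype=int)
    half = window / 2.0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                c = lo + np.array([i, j, k]) * stride3
                pts = []
                for m in range(len(dset)):
                    mid = dset.midpoints[m]
                    if ((mid >= c - half) & (mid < c + half)).all():
                        pts.append(dset.vectors[m] / 2.0)
                        pts.append(-dset.vectors[m] / 2.0)
                n = len(pts) // 2
                counts[i, j, k] = n
                if n:
                    for a in range(3):
                        for b in range(3):
                            mats[i, j, k, a, b] = math.fsum(
                                p[a] * p[b] for p in pts
                            ) / (2 * n)
    return mats, counts


class TestHandValues:
    def test_single_descriptor(self):
        d = fm.DescriptorSet(np.array([[1.0, 0, 0]]), np.array([[2.0, 0, 0]]))
        f = fm.compute_tensor_field(d, window=10, stride=10, min_count=1)
        assert np.allclose(f.matrices[0, 0, 0], np.diag([1.0, 0, 0]))
        assert f.counts[0, 0, 0] == 1

    def test_two_orthogonal_descriptors(self):
        d = fm.DescriptorSet(
            np.zeros((2, 3)), np.array([[2.0, 0, 0], [0.0, 2, 0]])
        )
        f = fm.compute_tensor_field(d, window=10, stride=10, min_count=1)
        assert np.allclose(f.matrices[0, 0, 0], np.diag([0.5, 0.5, 0.0]))
        e = fm.eigendecompose(f)
        lam = e.eigenvalues[0, 0, 0]
        assert lam[0] == pytest.approx(lam[1])

    def test_empty_window_invalid(self):
        d = fm.DescriptorSet(np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]]))
        f = fm.compute_tensor_field(d, window=10, stride=10, min_count=2)
        assert not f.valid.any() and f.counts[0, 0, 0] == 1

    def test_empty_descriptor_set_all_invalid(self):
        d = fm.DescriptorSet(np.zeros((0, 3)), np.zeros((0, 3)))
        f = fm.compute_tensor_field(d, window=10, stride=10)
        assert not f.valid.any()

    def test_sample_normalization_flag(self):
        d = fm.DescriptorSet(np.zeros((2, 3)), np.array([[2.0, 0, 0], [0.0, 2, 0]]))
        f = fm.compute_tensor_field(d, 10, 10, 1, sample_normalization=True)
        # divisor 2N-1 = 3 instead of 2N = 4
        assert np.allclose(f.matrices[0, 0, 0], np.diag([2 / 3, 2 / 3, 0.0]))

    def test_window_smaller_than_stride_rejected(self):
        d = fm.DescriptorSet(np.zeros((1, 3)), np.ones((1, 3)))
        with pytest.raises(ValueError):
            fm.compute_tensor_field(d, window=5, stride=10)


class TestOracleEquivalence:
    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(1, 200)
            mids = rng.uniform(0, 100, (n, 3))
            vecs = rng.normal(0, 1.0, (n, 3))
            vecs[np.linalg.norm(vecs, axis=1) == 0] = [1, 0, 0]
            dset = fm.DescriptorSet(mids, vecs)
            window = rng.uniform(20, 60)
            stride = rng.uniform(10, window)
            f = fm.compute_tensor_field(dset, window, stride, 1)
            mats, counts = naive_tensor_field(dset, window, stride, 1)
            assert np.array_equal(f.counts, counts)
            assert np.abs(f.matrices - mats).max() <= 1e-12

    def test_midpoint_membership_is_half_open(self):
        # a midpoint exactly on the boundary between two abutting windows
        # belongs to the upper one only — nothing is double-counted
        d = fm.DescriptorSet(
            np.array([[0.0, 0, 0], [5.0, 0, 0], [15.0, 0, 0]]),
            np.ones((3, 3)),
        )
        f = fm.compute_tensor_field(d, window=10, stride=10, min_count=1)
        assert f.counts[:, 0, 0].tolist() == [1, 1, 1]
        assert f.counts.sum() == len(d)


class TestInvariants:
    def test_rotation_conjugates_tensor(self):
        rng = np.random.default_rng(3)
        mids = rng.uniform(-10, 10, (50, 3))
        vecs = rng.normal(size=(50, 3))
        dset = fm.DescriptorSet(mids, vecs)
        # one giant window holds everything
        f = fm.compute_tensor_field(dset, 1000, 1000, 1, origin=(0, 0, 0), shape=(1, 1, 1))
        R = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        dset_r = fm.DescriptorSet(mids @ R.T, vecs @ R.T)
        f_r = fm.compute_tensor_field(dset_r, 1000, 1000, 1, origin=(0, 0, 0), shape=(1, 1, 1))
        expect = R @ f.matrices[0, 0, 0] @ R.T
        assert np.abs(f_r.matrices[0, 0, 0] - expect).max() < 1e-9

    def test_axis_permutation_permutes_field(self):
        rng = np.random.default_rng(4)
        mids = rng.uniform(0, 80, (200, 3))
        vecs = rng.normal(size=(200, 3))
        f = fm.compute_tensor_field(fm.DescriptorSet(mids, vecs), 40, 20, 1)
        perm = [2, 0, 1]
        fp = fm.compute_tensor_field(
            fm.DescriptorSet(mids[:, perm], vecs[:, perm]), 40, 20, 1
        )
        P = np.eye(3)[perm]
        expect = np.einsum("ab,...bc,dc->...ad", P, f.matrices, P)
        assert np.abs(fp.matrices.transpose(1, 2, 0, 3, 4) - expect).max() < 1e-12
        assert np.array_equal(fp.counts.transpose(1, 2, 0), f.counts)

    def test_uniform_phantom_rank_one(self):
        spec = fm.UniformCloudSpec(n=500, direction=(0, 1, 0), jitter_deg=0)
        dset, _ = fm.make_segment_cloud("uniform", spec, seed=5)
        f = fm.compute_tensor_field(dset, 90, 20, 2)
        e = fm.eigendecompose(f)
        lam = e.eigenvalues[e.valid]
        assert np.abs(lam[:, 1:]).max() <= 1e-9
        v1 = e.eigenvectors[e.valid][:, :, 0]
        assert np.allclose(np.abs(v1[:, 1]), 1.0, atol=1e-9)

    def test_isotropic_phantom_low_fa(self):
        dset, _ = fm.make_segment_cloud("isotropic", fm.IsotropicCloudSpec(n=10_000), seed=6)
        f = fm.compute_tensor_field(dset, 90, 20, 2)
        fa = fm.fractional_anisotropy(fm.eigendecompose(f))
        assert np.nanmedian(fa.values) < 0.15

    def test_growing_window_never_loses_members(self):
        rng = np.random.default_rng(7)
        dset = fm.DescriptorSet(rng.uniform(0, 100, (300, 3)), rng.normal(size=(300, 3)))
        f_small = fm.compute_tensor_field(dset, 30, 20, 1)
        f_large = fm.compute_tensor_field(dset, 90, 20, 1)
        assert (f_large.counts >= f_small.counts).all()


class TestEigendecompose:
    def test_diagonal_tensor(self):
        d = fm.DescriptorSet(np.zeros((1, 3)), np.array([[1.0, 0, 0]]))
        f = fm.compute_tensor_field(d, 10, 10, 1)
        f.matrices[0, 0, 0] = np.diag([3.0, 2.0, 1.0])
        e = fm.eigendecompose(f)
        assert np.allclose(e.eigenvalues[0, 0, 0], [3, 2, 1])
        assert np.allclose(e.eigenvectors[0, 0, 0, :, 0], [1, 0, 0])  # sign-normalized +x

    def test_conjugation_invariance(self):
        rng = np.random.default_rng(8)
        base = np.diag([3.0, 2.0, 1.0])
        for _ in range(10):
            R = Rotation.random(rng=rng).as_matrix()
            f = _single_tensor(R @ base @ R.T)
            e = fm.eigendecompose(f)
            assert np.allclose(e.eigenvalues[0, 0, 0], [3, 2, 1], atol=1e-9)
            v1 = e.eigenvectors[0, 0, 0, :, 0]
            assert abs(abs(v1 @ R[:, 0]) - 1) < 1e-9  # axial match

    def test_orthonormality_and_order(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(3, 3))
        f = _single_tensor(A @ A.T)
        e = fm.eigendecompose(f)
        V = e.eigenvectors[0, 0, 0]
        assert np.abs(V.T @ V - np.eye(3)).max() < 1e-9
        lam = e.eigenvalues[0, 0, 0]
        assert lam[0] >= lam[1] >= lam[2] >= 0

    def test_nan_matrix_marked_invalid(self):
        f = _single_tensor(np.full((3, 3), np.nan))
        e = fm.eigendecompose(f)
        assert not e.valid.any()

    def test_slightly_negative_eigenvalue_clamped(self):
        f = _single_tensor(np.diag([1.0, 1e-12, -1e-12]))
        e = fm.eigendecompose(f)
        assert (e.eigenvalues[0, 0, 0] >= 0).all()


def _single_tensor(M):
    from fmtensor.tensor_field import TensorField

    return TensorField(
        np.zeros(3), np.full(3, 20.0), 90.0,
        np.asarray(M, float)[None, None, None], np.array([[[5]]]), 2,
    )


class TestPrincipalVectorField:
    def test_index_selection_and_scaling(self):
        f = _single_tensor(np.diag([3.0, 2.0, 1.0]))
        e = fm.eigendecompose(f)
        v1 = fm.principal_vector_field(e, 1)
        v3 = fm.principal_vector_field(e, 3)
        assert np.allclose(v1.vectors[0, 0, 0], [1, 0, 0])
        assert np.allclose(v3.vectors[0, 0, 0], [0, 0, 1])
        scaled = fm.principal_vector_field(e, 1, scale_by_sqrt_eigenvalue=True)
        assert np.linalg.norm(scaled.vectors[0, 0, 0]) == pytest.approx(np.sqrt(3))

    def test_invalid_center_zero_vector(self):
        f = _single_tensor(np.diag([3.0, 2.0, 1.0]))
        f.counts[0, 0, 0] = 0
        e = fm.eigendecompose(f)
        assert np.allclose(fm.principal_vector_field(e, 1).vectors, 0)

    def test_bad_index_rejected(self):
        e = fm.eigendecompose(_single_tensor(np.eye(3)))
        with pytest.raises(ValueError):
            fm.principal_vector_field(e, 4)
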