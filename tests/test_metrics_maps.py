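"""FA, Westin, DEC maps, wall frames and the transmural helix-angle profile."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import fmtensor as fm
from fmtensor.tensor_field import TensorField

from conftest import make_eigen_field


def eigen_from_lambdas(l1, l2, l3, R=None):
    M = np.diag([float(l1), float(l2), float(l3)])
    if R is not None:
        M = R @ M @ R.T
    tf = TensorField(
        np.zeros(3), np.full(3, 20.0), 90.0, M[None, None, None], np.array([[[5]]]), 2
    )
    return fm.eigendecompose(tf)


class TestFractionalAnisotropy:
    @pytest.mark.parametrize(
        "lams,expected",
        [((1, 1, 1), 0.0), ((1, 0, 0), 1.0), ((2, 1, 1), 0.4082)],
    )
    def test_closed_forms(self, lams, expected):
        fa = fm.fractional_anisotropy(eigen_from_lambdas(*lams))
        assert fa.values[0, 0, 0] == pytest.approx(expected, abs=1e-3)

    def test_zero_tensor_is_nan(self):
        fa = fm.fractional_anisotropy(eigen_from_lambdas(0, 0, 0))
        assert np.isnan(fa.values[0, 0, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.floats(0, 10)] * 3))
    def test_range(self, lams):
        lams = tuple(sorted(lams, reverse=True))
        fa = fm.fractional_anisotropy(eigen_from_lambdas(*lams)).values[0, 0, 0]
        assert np.isnan(fa) or 0.0 <= fa <= 1.0

    def test_rotation_invariant(self):
        R = Rotation.from_rotvec([0.4, 0.2, -0.7]).as_matrix()
        a = fm.fractional_anisotropy(eigen_from_lambdas(3, 2, 1)).values[0, 0, 0]
        b = fm.fractional_anisotropy(eigen_from_lambdas(3, 2, 1, R)).values[0, 0, 0]
        assert a == pytest.approx(b, abs=1e-9)


class TestWestin:
    @pytest.mark.parametrize(
        "lams,expected",
        [
            ((1, 0, 0), (1, 0, 0)),
            ((1, 1, 1), (0, 0, 1)),
            ((3, 2, 1), (1 / 6, 1 / 3, 1 / 2)),
        ],
    )
    def test_closed_forms(self, lams, expected):
        cl, cp, cs = fm.westin_coefficients(eigen_from_lambdas(*lams))
        got = (cl.values[0, 0, 0], cp.values[0, 0, 0], cs.values[0, 0, 0])
        assert got == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.floats(1e-3, 10)] * 3))
    def test_partition_of_unity(self, lams):
        lams = tuple(sorted(lams, reverse=True))
        cl, cp, cs = fm.westin_coefficients(eigen_from_lambdas(*lams))
        vals = np.array([m.values[0, 0, 0] for m in (cl, cp, cs)])
        assert ((0 <= vals) & (vals <= 1)).all()
        assert vals.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_sum_is_nan(self):
        cl, _, _ = fm.westin_coefficients(eigen_from_lambdas(0, 0, 0))
        assert np.isnan(cl.values[0, 0, 0])

    def test_lambda1_variant(self):
        cl, cp, cs = fm.westin_coefficients(
            eigen_from_lambdas(4, 2, 1), variant="lambda1"
        )
        assert cl.values[0, 0, 0] == pytest.approx(0.5)
        assert cp.values[0, 0, 0] == pytest.approx(0.25)
        assert cs.values[0, 0, 0] == pytest.approx(0.25)


class TestDecMap:
    def test_axis_aligned_primary_colors(self):
        # v1 = x -> red; v1 = z -> blue (X red, Y green, Z blue)
        m = fm.dec_map(eigen_from_lambdas(3, 2, 1), 1)
        assert np.allclose(m.values[0, 0, 0], [1, 0, 0])
        Rz = np.array([[0.0, 0, 1], [0, 1, 0], [-1, 0, 0]])  # x -> -z axis
        m2 = fm.dec_map(eigen_from_lambdas(3, 2, 1, Rz), 1)
        assert np.allclose(m2.values[0, 0, 0], [0, 0, 1], atol=1e-12)

    def test_oblique_equal_channels(self):
        u1 = np.ones(3) / np.sqrt(3)
        u2 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        R = np.column_stack([u1, u2, np.cross(u1, u2)])
        m = fm.dec_map(eigen_from_lambdas(3, 2, 1, R), 1)
        assert np.allclose(m.values[0, 0, 0], 1 / np.sqrt(3), atol=1e-9)

    def test_channels_permute_with_axes(self):
        R = Rotation.from_rotvec([0.3, 0.1, 0.8]).as_matrix()
        m = fm.dec_map(eigen_from_lambdas(3, 2, 1, R), 1).values[0, 0, 0]
        perm = [1, 2, 0]
        P = np.eye(3)[perm]
        m_p = fm.dec_map(eigen_from_lambdas(3, 2, 1, P @ R), 1).values[0, 0, 0]
        assert np.allclose(m_p, P @ m, atol=1e-12)

    def test_fa_weighting_darkens_isotropic(self):
        m = fm.dec_map(eigen_from_lambdas(1, 1, 1), 1, weight="fa")
        assert np.allclose(m.values[0, 0, 0], 0.0)


class TestWallFrame:
    def _grid(self):
        return eigen_from_lambdas(3, 2, 1)  # single centre at the origin

    def test_geometry_example(self):
        eig = make_eigen_field((10, 0, 0), (1, 1, 1), (1, 1, 1), lambda c: c * 0 + [1.0, 0, 0])
        frame = fm.build_wall_frame(eig, (0, 0, 0), (0, 0, 1), 20.0, 5.0)
        assert np.allclose(frame.r_hat[0, 0, 0], [1, 0, 0])
        assert np.allclose(frame.l_hat[0, 0, 0], [0, 0, 1])
        assert np.allclose(np.abs(frame.c_hat[0, 0, 0]), [0, 1, 0])

    @pytest.mark.parametrize("radius,expected_d", [(20.0, 0.0), (5.0, 1.0), (12.5, 0.5)])
    def test_depth_mapping(self, radius, expected_d):
        eig = make_eigen_field((radius, 0, 0), (1, 1, 1), (1, 1, 1), lambda c: c * 0 + [1.0, 0, 0])
        frame = fm.build_wall_frame(eig, (0, 0, 0), (0, 0, 1), 20.0, 5.0)
        assert frame.depth[0, 0, 0] == pytest.approx(expected_d)

    def test_triad_orthonormal(self):
        eig = make_eigen_field((-40, 0, 0), (7, 11, 13), (5, 5, 3), lambda c: c * 0 + [1.0, 0, 0])
        frame = fm.build_wall_frame(eig, (1, 2, 3), (1, 1, 1), 60.0, 10.0)
        for a, b in [("c_hat", "l_hat"), ("c_hat", "r_hat"), ("l_hat", "r_hat")]:
            dots = np.einsum("...k,...k->...", getattr(frame, a), getattr(frame, b))
            assert np.abs(dots[frame.valid]).max() < 1e-9

    def test_center_on_axis_invalid(self):
        eig = make_eigen_field((0, 0, 5), (1, 1, 1), (1, 1, 1), lambda c: c * 0 + [1.0, 0, 0])
        frame = fm.build_wall_frame(eig, (0, 0, 0), (0, 0, 1), 20.0, 5.0)
        assert not frame.valid[0, 0, 0]


class TestHelixTransverseAngles:
    def _setup(self, v1):
        eig = make_eigen_field((10, 0, 0), (1, 1, 1), (1, 1, 1), lambda c: c * 0 + v1)
        frame = fm.build_wall_frame(eig, (0, 0, 0), (0, 0, 1), 20.0, 5.0)
        ha, ta = fm.helix_transverse_angles(eig, frame)
        return ha.values[0, 0, 0], ta.values[0, 0, 0]

    def test_circumferential_zero(self):
        ha, ta = self._setup([0.0, 1.0, 0.0])  # = ±c_hat at (10,0,0)
        assert ha == pytest.approx(0.0, abs=1e-9)
        assert ta == pytest.approx(0.0, abs=1e-9)

    def test_longitudinal_ninety(self):
        ha, ta = self._setup([0.0, 0.0, 1.0])
        assert abs(ha) == pytest.approx(90.0)
        assert ta == pytest.approx(0.0, abs=1e-9)

    def test_forty_five(self):
        ha, ta = self._setup(np.array([0, 1.0, 1.0]) / np.sqrt(2))
        assert abs(ha) == pytest.approx(45.0)
        assert ta == pytest.approx(0.0, abs=1e-9)

    def test_radial_vector_undefined_ha(self):
        ha, ta = self._setup([1.0, 0.0, 0.0])  # parallel to r_hat
        assert np.isnan(ha)
        assert abs(ta) == pytest.approx(90.0)

    def test_axial_symmetry(self):
        v = np.array([0.2, 0.7, 0.4])
        ha1, ta1 = self._setup(v / np.linalg.norm(v))
        ha2, ta2 = self._setup(-v / np.linalg.norm(v))
        assert ha1 == pytest.approx(ha2) and ta1 == pytest.approx(ta2)


class TestTransmuralProfile:
    def test_helical_phantom_recovery(self, helical_recovery):
        prof = helical_recovery["profile"]
        spec = helical_recovery["spec"]
        assert prof.span_deg == pytest.approx(
            spec.alpha_epi + spec.alpha_endo, abs=5.0
        )
        true = spec.helix_angle(prof.bin_centers)
        filled = prof.counts >= 10
        assert filled.sum() >= 4
        assert np.abs(prof.mean_ha_deg[filled] - true[filled]).max() < 5.0

    def test_constant_direction_flat_profile(self):
        # circumferential field everywhere -> HA == 0, span ~ 0
        def circ(c):
            t = np.stack([-c[..., 1], c[..., 0], np.zeros(c.shape[:-1])], axis=-1)
            n = np.linalg.norm(t, axis=-1, keepdims=True)
            return t / np.where(n == 0, 1, n)

        eig = make_eigen_field((-100, -100, -20), (20, 20, 20), (11, 11, 3), circ)
        frame = fm.build_wall_frame(eig, (0, 0, 0), (0, 0, 1), 120.0, 20.0)
        ha, _ = fm.helix_transverse_angles(eig, frame)
        prof = fm.transmural_profile(ha, frame, n_bins=5)
        assert np.nanmax(np.abs(prof.mean_ha_deg)) < 1e-6
        assert abs(prof.span_deg) < 1e-6

    def test_single_bin_aggregates_everything(self, helical_recovery):
        prof = fm.transmural_profile(
            helical_recovery["ha"], helical_recovery["frame"], n_bins=1
        )
        assert prof.counts.size == 1 and prof.counts[0] > 0

    def test_bins_cover_unit_interval(self, helical_recovery):
        prof = helical_recovery["profile"]
        assert prof.bin_centers[0] == pytest.approx(0.05)
        assert prof.bin_centers[-1] == pytest.approx(0.95)
        assert (prof.counts >= 0).all()

    def test_empty_input_rejected(self):
        eig = make_eigen_field((0, 0, 5), (1, 1, 1), (1, 1, 1), lambda c: c * 0 + [1.0, 0, 0])
        frame = fm.build_wall_frame(eig, (0, 0, 0), (0, 0, 1), 20.0, 5.0)
        ha = fm.ScalarMap(eig.origin, eig.stride, np.full((1, 1, 1), np.nan))
        with pytest.raises(ValueError):
            fm.transmural_profile(ha, frame)
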