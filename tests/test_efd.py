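"""Chain codes and elliptical Fourier descriptors."""

from dataclasses import replace

import numpy as np
import pytest

from leafscape.efd import (
    ChainCode,
    chain_code,
    decode_chain,
    drop_asymmetric,
    efd_coefficients,
    efd_feature_matrix,
    normalize_efd,
    reconstruct,
)
from leafscape.errors import ParameterError, ShapeError
from leafscape.measure import extract_contour
from leafscape.synthetic import LeafParams, generate_leaf_outline, rasterize_outline


def _rotate(points, degrees):
    th = np.deg2rad(degrees)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return points @ R.T


class TestChainCode:
    def test_horizontal_run_is_all_zeros(self):
        run = np.column_stack([np.arange(6), np.zeros(6, int)])
        assert chain_code(run, closed=False).codes.tolist() == [0] * 5

    def test_2x2_square_roundtrip(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]])
        chain = chain_code(square)
        assert chain.codes.tolist() == [0, 2, 4, 6]
        np.testing.assert_array_equal(decode_chain(chain), square)

    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_on_raster_leaves(self, seed):
        params = LeafParams(
            aspect_ratio=1.4 + 0.15 * seed,
            blade_scale=200.0,
            serration_amplitude=0.02 * (seed % 4),
            serration_count=20,
            petiole_length=0.1,
            seed=seed,
        )
        img = rasterize_outline(generate_leaf_outline(params, 256))
        contour = extract_contour(img)
        np.testing.assert_array_equal(decode_chain(chain_code(contour)), contour)

    def test_non_adjacent_points_rejected(self):
        with pytest.raises(ShapeError, match="8-adjacent"):
            chain_code(np.array([[0, 0], [3, 0]]), closed=False)


class TestEFDCoefficients:
    def test_analytic_ellipse_recovery(self, dense_ellipse):
        coef = efd_coefficients(dense_ellipse, 5, parameterization="uniform")
        assert coef.a[0] == pytest.approx(2.0, abs=2e-3)
        assert coef.d[0] == pytest.approx(1.0, abs=2e-3)
        assert abs(coef.b[0]) < 2e-3 and abs(coef.c[0]) < 2e-3
        higher = np.concatenate([coef.a[1:], coef.b[1:], coef.c[1:], coef.d[1:]])
        assert np.abs(higher).max() < 2e-3

    def test_circle_first_harmonic_axes(self):
        t = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        circle = np.column_stack([5 * np.cos(t), 5 * np.sin(t)])
        coef = efd_coefficients(circle, 3)
        assert coef.a[0] == pytest.approx(5.0, rel=1e-3)
        assert coef.d[0] == pytest.approx(5.0, rel=1e-3)

    def test_dc_terms_recover_centroid(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        circle = np.column_stack([3 + np.cos(t), -7 + np.sin(t)])
        coef = efd_coefficients(circle, 2)
        assert coef.a0 == pytest.approx(3.0, abs=1e-3)
        assert coef.c0 == pytest.approx(-7.0, abs=1e-3)

    def test_zero_harmonics_rejected(self):
        with pytest.raises(ParameterError):
            efd_coefficients(np.eye(2), 0)


class TestNormalization:
    @pytest.fixture(scope="class")
    def base(self, generic_leaf_outline):
        return normalize_efd(efd_coefficients(generic_leaf_outline, 20))

    def _diff(self, a, b):
        return max(
            np.abs(a.a - b.a).max(),
            np.abs(a.b - b.b).max(),
            np.abs(a.c - b.c).max(),
            np.abs(a.d - b.d).max(),
        )

    def test_convention_a1_one_b1_c1_zero(self, base):
        assert base.a[0] == pytest.approx(1.0)
        assert abs(base.b[0]) < 1e-12 and abs(base.c[0]) < 1e-12
        assert 0 < base.d[0] <= 1.0

    def test_rotation_invariance(self, base, generic_leaf_outline):
        rotated = _rotate(generic_leaf_outline, 37.0) + [120.0, -40.0]
        other = normalize_efd(efd_coefficients(rotated, 20))
        assert self._diff(base, other) < 1e-6

    def test_scale_invariance(self, base, generic_leaf_outline):
        other = normalize_efd(efd_coefficients(generic_leaf_outline * 3.0, 20))
        assert self._diff(base, other) < 1e-6

    def test_start_point_invariance(self, base, generic_leaf_outline):
        shifted = np.roll(generic_leaf_outline, len(generic_leaf_outline) // 4, axis=0)
        other = normalize_efd(efd_coefficients(shifted, 20))
        assert self._diff(base, other) < 1e-6


class TestDropAsymmetric:
    def test_symmetric_outline_nearly_unchanged(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        # bilaterally symmetric ovate: y even in x, symmetric about y=0
        x = 2.0 * np.cos(t)
        y = np.sin(t) * (1 + 0.3 * np.cos(t))
        coef = normalize_efd(efd_coefficients(np.column_stack([x, y]), 15))
        sym = drop_asymmetric(coef)
        delta = np.sqrt(np.sum((coef.quadruples() - sym.quadruples()) ** 2))
        assert delta < 1e-3

    def test_reconstruction_is_mirror_symmetric(self, generic_leaf_outline):
        from scipy.spatial.distance import cdist

        coef = drop_asymmetric(
            normalize_efd(efd_coefficients(generic_leaf_outline, 20))
        )
        rec = reconstruct(coef, 400)
        mirrored = rec * [1.0, -1.0]
        hausdorff = max(
            cdist(rec, mirrored).min(axis=1).max(),
            cdist(mirrored, rec).min(axis=1).max(),
        )
        size = np.ptp(rec[:, 0])
        assert hausdorff < 1e-3 * size

    def test_b_c_zeroed_a_d_untouched(self, generic_leaf_outline):
        coef = normalize_efd(efd_coefficients(generic_leaf_outline, 20))
        sym = drop_asymmetric(coef)
        assert np.all(sym.b == 0) and np.all(sym.c == 0)
        np.testing.assert_array_equal(sym.a, coef.a)
        np.testing.assert_array_equal(sym.d, coef.d)

    def test_energy_non_increasing(self, generic_leaf_outline):
        coef = normalize_efd(efd_coefficients(generic_leaf_outline, 20))
        sym = drop_asymmetric(coef)
        assert np.sum(sym.quadruples() ** 2) <= np.sum(coef.quadruples() ** 2)


class TestReconstruct:
    @pytest.fixture(scope="class")
    def coef(self, generic_leaf_outline):
        return normalize_efd(efd_coefficients(generic_leaf_outline, 10))

    def test_unit_factors_match_plain_inverse(self, coef):
        np.testing.assert_allclose(
            reconstruct(coef, 200),
            reconstruct(coef, 200, amplification=np.ones(10)),
            atol=1e-12,
        )

    def test_zero_factor_equals_harmonic_deletion(self, coef):
        amp = np.ones(10)
        amp[3] = 0.0
        deleted = replace(
            coef,
            a=np.where(np.arange(10) == 3, 0, coef.a),
            b=np.where(np.arange(10) == 3, 0, coef.b),
            c=np.where(np.arange(10) == 3, 0, coef.c),
            d=np.where(np.arange(10) == 3, 0, coef.d),
        )
        np.testing.assert_allclose(
            reconstruct(coef, 200, amplification=amp),
            reconstruct(deleted, 200),
            atol=1e-12,
        )

    def test_amplification_scales_pure_harmonic_deviation(self):
        from leafscape.efd import EFDCoefficients

        # pure harmonic-2 deviation on top of a circle
        coef = EFDCoefficients(
            a=np.array([1.0, 0.05]),
            b=np.zeros(2),
            c=np.zeros(2),
            d=np.array([1.0, 0.05]),
        )
        base = reconstruct(replace(coef, a=np.array([1.0, 0.0]), d=np.array([1.0, 0.0])), 100)
        r1 = reconstruct(coef, 100) - base
        r3 = reconstruct(coef, 100, amplification=np.array([1.0, 3.0])) - base
        np.testing.assert_allclose(r3, 3.0 * r1, atol=1e-12)

    def test_negative_factor_rejected(self, coef):
        with pytest.raises(ParameterError):
            reconstruct(coef, 200, amplification=np.r_[-1.0, np.ones(9)])

    def test_roundtrip_error_decreases_with_harmonics(self, generic_leaf_outline):
        from scipy.spatial.distance import cdist

        target = generic_leaf_outline - generic_leaf_outline.mean(axis=0)
        errs = []
        for H in (2, 5, 10, 20):
            coef = efd_coefficients(target, H)
            rec = reconstruct(coef, 512)
            errs.append(cdist(target, rec).min(axis=1).max())
        assert all(e2 <= e1 * 1.05 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] < errs[0]


class TestFeatureMatrix:
    def test_single_tree_identical_leaves(self, generic_leaf_outline):
        coef = drop_asymmetric(
            normalize_efd(efd_coefficients(generic_leaf_outline, 20))
        )
        X = efd_feature_matrix([[coef, coef]])
        assert X.shape == (1, 40)
        np.testing.assert_allclose(X[0], coef.symmetric_features())

    def test_two_leaves_average_elementwise(self, generic_leaf_outline):
        c1 = normalize_efd(efd_coefficients(generic_leaf_outline, 5))
        c2 = normalize_efd(efd_coefficients(_rotate(generic_leaf_outline, 90.0) * 2, 5))
        X = efd_feature_matrix([[c1, c2]])
        np.testing.assert_allclose(
            X[0], (c1.symmetric_features() + c2.symmetric_features()) / 2
        )

    def test_ragged_harmonics_rejected(self, generic_leaf_outline):
        c1 = efd_coefficients(generic_leaf_outline, 5)
        c2 = efd_coefficients(generic_leaf_outline, 6)
        with pytest.raises(ParameterError, match="ragged"):
            efd_feature_matrix([[c1], [c2]])
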