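"""Contour tracing, chain codes and elliptical Fourier descriptors."""

import numpy as np
import pytest
from skimage import draw

from leafmass._errors import ValidationError
from leafmass.outline_efd import (
    _FREEMAN,
    ChainCode,
    Contour,
    contour_to_chain_code,
    efd_feature_matrix,
    efd_fit,
    efd_fit_points,
    mean_outline,
    normalize_efd,
    reconstruct_outline,
    trace_boundary,
)


def _square_mask(side: int, pad: int = 2) -> np.ndarray:
    m = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    m[pad:pad + side, pad:pad + side] = True
    return m


def _disc_mask(radius: int) -> np.ndarray:
    m = np.zeros((2 * radius + 10, 2 * radius + 10), dtype=bool)
    rr, cc = draw.disk((radius + 5, radius + 5), radius)
    m[rr, cc] = True
    return m


class TestTraceBoundary:
    def test_two_by_two_square_four_points(self):
        contour = trace_boundary(_square_mask(2))
        assert len(contour) == 4

    def test_ten_by_ten_square_perimeter_pixels(self):
        contour = trace_boundary(_square_mask(10))
        assert len(contour) == 36
        # every contour pixel is a foreground pixel with a background 4-neighbor
        mask = _square_mask(10)
        for x, y in contour.points:
            assert mask[y, x]

    def test_disc_boundary_count_matches_enumeration(self):
        mask = _disc_mask(30)
        contour = trace_boundary(mask)
        # independent oracle: boundary pixels = foreground with a background
        # 4-neighbor (the outer boundary of a filled disc)
        from scipy import ndimage as ndi

        eroded = ndi.binary_erosion(mask)
        boundary_count = int((mask & ~eroded).sum())
        assert len(contour) == pytest.approx(boundary_count, rel=0.05)

    def test_touching_border_rejected(self):
        m = np.ones((5, 5), dtype=bool)
        with pytest.raises(ValidationError, match="border"):
            trace_boundary(m)

    def test_tiny_mask_rejected(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        with pytest.raises(ValidationError):
            trace_boundary(m)


class TestChainCode:
    def test_unit_square_canonical_codes(self):
        # counter-clockwise in math convention: right, up, left, down
        contour = Contour(np.array([(0, 1), (1, 1), (1, 0), (0, 0)]))
        chain = contour_to_chain_code(contour)
        assert chain.codes.tolist() == [0, 2, 4, 6]

    @pytest.mark.parametrize("shape", ["square", "disc"])
    def test_closure_of_traced_shapes(self, shape):
        mask = _square_mask(9) if shape == "square" else _disc_mask(20)
        chain = contour_to_chain_code(trace_boundary(mask))
        disp = _FREEMAN[chain.codes].sum(axis=0)
        assert disp.tolist() == [0, 0]

    def test_reversal_identity(self):
        mask = _disc_mask(15)
        contour = trace_boundary(mask)
        chain = contour_to_chain_code(contour)
        reversed_contour = Contour(contour.points[::-1])
        rev_chain = contour_to_chain_code(reversed_contour)
        expected = ((chain.codes[::-1] + 4) % 8)
        # reversal shifts which step leaves the (new) start point
        assert rev_chain.codes.tolist() == np.roll(expected, -1).tolist() or \
            rev_chain.codes.tolist() == expected.tolist()

    def test_nonadjacent_points_rejected(self):
        with pytest.raises(ValidationError):
            Contour(np.array([(0, 0), (5, 5), (0, 5)]))

    def test_open_chain_rejected(self):
        with pytest.raises(ValidationError, match="closed"):
            ChainCode(start=(0, 0), codes=[0, 0, 2])


class TestEfdFit:
    def test_circle_first_harmonic_dominates(self):
        chain = contour_to_chain_code(trace_boundary(_disc_mask(40)))
        efd = efd_fit(chain, 10)
        a1, b1, c1, d1 = efd.coefficients[0]
        assert np.hypot(a1, b1) == pytest.approx(40, rel=0.02)
        assert np.hypot(c1, d1) == pytest.approx(40, rel=0.02)
        first = (efd.coefficients[0] ** 2).sum()
        rest = (efd.coefficients[1:] ** 2).sum()
        assert rest < 0.01 * first

    def test_fifteen_harmonics_sixty_coefficients(self, blob_contour):
        efd = efd_fit_points(blob_contour, 15)
        assert efd.coefficients.size == 60

    def test_translation_changes_only_offset(self, blob_contour):
        efd = efd_fit_points(blob_contour, 8)
        shifted = efd_fit_points(blob_contour + [17.0, -6.5], 8)
        np.testing.assert_allclose(
            shifted.coefficients, efd.coefficients, atol=1e-10
        )
        assert shifted.offset[0] == pytest.approx(efd.offset[0] + 17.0)
        assert shifted.offset[1] == pytest.approx(efd.offset[1] - 6.5)

    def test_invalid_harmonic_count_rejected(self, blob_contour):
        with pytest.raises(ValidationError):
            efd_fit_points(blob_contour, 0)


def _rot(deg):
    th = np.deg2rad(deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


class TestNormalization:
    def test_similarity_transform_invariance(self, blob_contour):
        base = normalize_efd(efd_fit_points(blob_contour, 12)).coefficients
        moved = (np.roll(blob_contour, 123, axis=0) @ _rot(37).T) * 2.5 + [8, -3]
        other = normalize_efd(efd_fit_points(moved, 12)).coefficients
        np.testing.assert_allclose(other, base, atol=1e-6)

    def test_semi_major_fixed_to_half(self, blob_contour):
        norm = normalize_efd(efd_fit_points(blob_contour, 12))
        a1, b1, c1, d1 = norm.coefficients[0]
        semi_major = np.hypot(a1, c1)
        assert semi_major == pytest.approx(0.5, abs=1e-9)
        assert norm.offset == (0.0, 0.0)

    def test_idempotent(self, blob_contour):
        once = normalize_efd(efd_fit_points(blob_contour, 12))
        twice = normalize_efd(once)
        np.testing.assert_allclose(
            twice.coefficients, once.coefficients, atol=1e-9
        )

    def test_mirror_image_not_identified(self, blob_contour):
        base = normalize_efd(efd_fit_points(blob_contour, 12)).coefficients
        mirrored = (blob_contour * [-1, 1])[::-1]
        other = normalize_efd(efd_fit_points(mirrored, 12)).coefficients
        assert np.abs(other - base).max() > 1e-3


class TestReconstruction:
    def test_circle_reconstruction(self):
        chain = contour_to_chain_code(trace_boundary(_disc_mask(40)))
        for n in (1, 3, 8):
            pts = reconstruct_outline(efd_fit(chain, n), 200)
            radii = np.hypot(*(pts - pts.mean(axis=0)).T)
            assert np.abs(radii - 40).max() < 0.02 * 40 + 1.0

    def test_error_non_increasing_in_harmonics(self, blob_contour):
        errors = []
        for n in (1, 2, 5, 10, 15, 25):
            efd = efd_fit_points(blob_contour, n)
            recon = reconstruct_outline(efd, 500)
            target = _resample_closed(blob_contour, 500)
            errors.append(np.sqrt(np.mean((recon - target) ** 2)))
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_high_harmonics_reach_subpercent_error(self, blob_contour):
        efd = efd_fit_points(blob_contour, 40)
        recon = reconstruct_outline(efd, 720)
        target = _resample_closed(blob_contour, 720)
        height = np.ptp(blob_contour[:, 1])
        rms = np.sqrt(np.mean((recon - target) ** 2))
        assert rms < 0.01 * height

    def test_too_few_points_rejected(self, blob_contour):
        with pytest.raises(ValidationError):
            reconstruct_outline(efd_fit_points(blob_contour, 5), 2)


def _resample_closed(points: np.ndarray, m: int) -> np.ndarray:
    """Resample a closed polygon at m uniform arc-length positions."""
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, t[-1], m, endpoint=False)
    x = np.interp(targets, t, closed[:, 0])
    y = np.interp(targets, t, closed[:, 1])
    return np.column_stack([x, y])


class TestMeanOutline:
    def test_mean_of_identical_outlines_is_the_outline(self, blob_contour):
        efd = normalize_efd(efd_fit_points(blob_contour, 10))
        mean = mean_outline([efd] * 5, 100)
        np.testing.assert_allclose(mean, reconstruct_outline(efd, 100), atol=1e-12)

    def test_concentric_circles_average_to_middle_radius(self):
        t = np.linspace(0, 2 * np.pi, 600, endpoint=False)
        c1 = np.column_stack([np.cos(t), np.sin(t)])
        efd1 = efd_fit_points(c1, 5)
        efd3 = efd_fit_points(3 * c1, 5)
        mean = mean_outline([efd1, efd3], 300, require_normalized=False)
        radii = np.hypot(*mean.T)
        np.testing.assert_allclose(radii, 2.0, atol=0.01)

    def test_linearity_identity_exact(self, blob_contour):
        efds = [
            normalize_efd(efd_fit_points(np.roll(blob_contour, k, axis=0), 8))
            for k in (0, 50, 100)
        ]
        coeff_mean = mean_outline(efds, 64)
        point_mean = np.mean([reconstruct_outline(e, 64) for e in efds], axis=0)
        np.testing.assert_allclose(coeff_mean, point_mean, atol=1e-12)

    def test_mixed_harmonics_rejected(self, blob_contour):
        e1 = normalize_efd(efd_fit_points(blob_contour, 5))
        e2 = normalize_efd(efd_fit_points(blob_contour, 6))
        with pytest.raises(ValidationError):
            mean_outline([e1, e2])

    def test_unnormalized_input_rejected_by_default(self, blob_contour):
        with pytest.raises(ValidationError):
            mean_outline([efd_fit_points(blob_contour, 5)] * 2)


class TestFeatureMatrix:
    def test_shape_and_ordering(self, blob_contour):
        efds = [
            normalize_efd(efd_fit_points(blob_contour * s, 15)) for s in (1, 2, 3)
        ]
        X = efd_feature_matrix(efds)
        assert X.shape == (3, 60)
        np.testing.assert_allclose(X[0, :4], efds[0].coefficients[0])

    def test_duplicated_leaves_give_identical_rows(self, blob_contour):
        efd = normalize_efd(efd_fit_points(blob_contour, 7))
        X = efd_feature_matrix([efd, efd])
        np.testing.assert_array_equal(X[0], X[1])

    def test_single_leaf_row(self, blob_contour):
        efd = normalize_efd(efd_fit_points(blob_contour, 7))
        assert efd_feature_matrix([efd]).shape == (1, 28)
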