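"""Curvature, circularity, and brightness feature oracles.

Closed-form oracles: a circle of radius r has curvature 1/r everywhere; an
axis-aligned ellipse has maximum curvature a/b^2 at the ends of its major
axis; total turning of a convex closed curve is 2*pi; a disk attains the
isoperimetric bound (circularity 1) and a square attains sqrt(pi)/2.
"""

import numpy as np
import pytest

from spherovia.features import (
    brightness_ratio,
    circularity,
    contour_curvature,
    extract_features,
    features_from_image,
)
from spherovia.segmentation import Contour, extract_contour
from spherovia.synth import (
    MorphologyParams,
    render_spheroid,
    viability_to_morphology,
)


def _closed(points):
    return Contour(np.vstack([points, points[:1]]))


def _circle(radius, n=256, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return _closed(np.column_stack([center[0] + radius * np.cos(t),
                                    center[1] + radius * np.sin(t)]))


class TestCurvature:
    def test_circle_curvature_is_one_over_radius(self):
        k = contour_curvature(_circle(50))
        assert np.all(np.abs(k - 0.02) <= 0.05 * 0.02)

    def test_ellipse_max_curvature_closed_form(self):
        a, b, n = 60.0, 30.0, 1024
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        k = contour_curvature(_closed(
            np.column_stack([a * np.cos(t), b * np.sin(t)])))
        assert k.max() == pytest.approx(a / b**2, rel=0.05)

    def test_straight_segment_has_near_zero_curvature(self):
        # rounded square: long straight edges joined by quarter-circles
        edge = np.linspace(-40, 40, 60)
        arc = np.linspace(0, np.pi / 2, 20, endpoint=False)
        r, half = 10.0, 50.0
        pts = []
        pts += [(x, -half) for x in edge]
        pts += [(40 + r * np.sin(t), -half + r * (1 - np.cos(t))) for t in arc]
        pts += [(half, y) for y in edge]
        pts += [(half - r * (1 - np.cos(t)), 40 + r * np.sin(t)) for t in arc]
        pts += [(-x, half) for x in edge]
        pts += [(-40 - r * np.sin(t), half - r * (1 - np.cos(t))) for t in arc]
        pts += [(-half, -y) for y in edge]
        pts += [(-half + r * (1 - np.cos(t)), -40 - r * np.sin(t)) for t in arc]
        k = contour_curvature(_closed(np.array(pts)))
        mid_edge = np.argmin(np.abs(np.array(pts)[:, 0]))  # middle of bottom edge
        assert k[mid_edge] < 1e-6

    def test_total_turning_of_convex_contours_is_two_pi(self):
        for contour in (_circle(30), _circle(75, n=512)):
            k = contour_curvature(contour)
            seg = np.linalg.norm(np.diff(contour.points, axis=0), axis=1)
            assert float((k * seg).sum()) == pytest.approx(2 * np.pi, rel=0.05)

    def test_needs_enough_points(self):
        with pytest.raises(ValueError):
            contour_curvature(np.zeros((8, 2)))


class TestCircularity:
    def test_disk_attains_isoperimetric_bound(self, disk_mask):
        mask = disk_mask(40)
        assert circularity(mask, extract_contour(mask)) == pytest.approx(
            1.0, abs=0.02)

    def test_square_closed_form(self):
        mask = np.zeros((120, 120), dtype=bool)
        mask[10:110, 10:110] = True
        c = circularity(mask, extract_contour(mask, smoothing_window=1))
        assert c == pytest.approx(np.sqrt(np.pi) / 2, abs=0.02)

    def test_lobed_shape_strictly_below_disk(self, disk_mask):
        params = MorphologyParams(
            radius=25, irregularity_amplitude=0.3,
            irregularity_harmonics=((5, 0.0, 1.0),), core_darkness=0.0,
            fragment_count=0, noise_sd=0.0)
        _, lobed = render_spheroid(params, 128, seed=0)
        disk = disk_mask(25)
        c_disk = circularity(disk, extract_contour(disk))
        c_lobed = circularity(lobed, extract_contour(lobed))
        assert c_lobed < c_disk - 0.05

    def test_isoperimetric_inequality_on_random_shapes(self, render_batch):
        for v, img, mask in render_batch(50, seed0=8100):
            c = circularity(mask, extract_contour(mask))
            assert c <= 1.02


class TestBrightnessRatio:
    def test_uniform_image_gives_exactly_one(self, disk_mask):
        mask = disk_mask(20, frame=96)
        assert brightness_ratio(np.full((96, 96), 0.6), mask) == pytest.approx(
            1.0, abs=1e-12)

    def test_synthetic_interior_background_ratio(self, disk_mask):
        mask = disk_mask(20, frame=96)
        img = np.full((96, 96), 0.8)
        img[mask] = 0.4
        assert brightness_ratio(img, mask) == pytest.approx(0.5, abs=0.01)

    def test_darker_core_lowers_ratio(self):
        kw = dict(radius=20, irregularity_amplitude=0.0,
                  irregularity_harmonics=(), fragment_count=0, noise_sd=0.0)
        img_h, m = render_spheroid(
            MorphologyParams(core_darkness=0.0, **kw), 96, 0)
        img_d, _ = render_spheroid(
            MorphologyParams(core_darkness=0.5, **kw), 96, 0)
        assert brightness_ratio(img_d, m) < brightness_ratio(img_h, m)

    def test_whole_frame_mask_has_no_background(self):
        with pytest.raises(ValueError, match="background"):
            brightness_ratio(np.ones((32, 32)), np.ones((32, 32), dtype=bool))


class TestFeatureVector:
    def test_healthy_render_is_nearly_circular(self):
        params = viability_to_morphology(1.0, seed=21)
        img, mask = render_spheroid(params, 96, seed=22)
        fv = features_from_image(img)
        assert fv.circularity > 0.97
        # interior attenuation ~25% plus rim: ratio well below 1, above 0.5
        assert 0.5 < fv.brightness_ratio < 0.9

    def test_damaged_contour_raises_curvature_spread(self):
        wins = 0
        for i in range(20):
            f_low = features_from_image(
                render_spheroid(viability_to_morphology(0.1, 500 + i),
                                96, 900 + i)[0])
            f_high = features_from_image(
                render_spheroid(viability_to_morphology(1.0, 500 + i),
                                96, 900 + i)[0])
            wins += f_low.curvature_sd_norm > f_high.curvature_sd_norm
        assert wins >= 16

    def test_extraction_is_deterministic(self, render_batch):
        (_, img, _), = render_batch(1, seed0=64)
        a = features_from_image(img)
        b = features_from_image(img)
        assert a == b

    def test_scale_normalized_curvature_is_scale_invariant(self):
        from skimage.transform import rescale

        kw = dict(irregularity_amplitude=0.15,
                  irregularity_harmonics=((4, 0.2, 0.5), (6, 2.0, 0.5)),
                  core_darkness=0.2, fragment_count=0, noise_sd=0.0)
        img1, _ = render_spheroid(MorphologyParams(radius=18, **kw), 96, 0)
        img2 = rescale(img1, 2.0, order=1)
        f1 = features_from_image(img1)
        f2 = features_from_image(img2)
        assert f2.curvature_mean_norm == pytest.approx(
            f1.curvature_mean_norm, rel=0.03)
        # un-normalized curvature roughly halves when the image is upscaled
        # 2x (looser: raw curvature also absorbs boundary-placement shifts)
        assert f2.curvature_mean == pytest.approx(f1.curvature_mean / 2,
                                                  rel=0.08)
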