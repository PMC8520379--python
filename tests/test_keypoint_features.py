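import math

import numpy as np
import pytest

from endostitch.keypoint_features import (
    Keypoint,
    assign_orientations,
    compute_descriptor,
    detect_and_describe,
    detect_extrema,
)
from endostitch.scale_space import build_scale_space


def circdiff(a, b):
    """Smallest absolute angular difference in degrees."""
    d = (math.degrees(a - b) + 180.0) % 360.0 - 180.0
    return abs(d)


def blob_image(size=64, centre=(32.0, 32.0), sigma=4.0, amp=0.6, bg=0.1):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx, cy = centre
    return bg + amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestDetectExtrema:
    def test_constant_image_yields_nothing(self):
        ss = build_scale_space(np.full((64, 64), 0.5), 3, 3, 1.6)
        assert detect_extrema(ss) == []

    def test_bright_blob_found_at_centre_and_scale(self):
        img = blob_image(sigma=4.0)
        ss = build_scale_space(img, 3, 3, 1.6)
        kps = detect_extrema(ss)
        near = [k for k in kps if math.hypot(k.x - 32, k.y - 32) < 2.0]
        assert near
        expected = 4.0 * math.sqrt(2.0)
        assert any(expected / 1.6 <= k.sigma <= expected * 1.6 for k in near)

    def test_step_edge_suppressed_by_curvature_ratio(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        ss = build_scale_space(img, 3, 3, 1.6)
        kps = detect_extrema(ss, contrast_thresh=0.03, edge_ratio=10.0)
        # edge responses have one large and one ~zero principal curvature
        assert all(abs(k.x - 32) > 3.0 for k in kps)

    def test_keypoints_reverify_as_26_neighbour_extrema(self, textured_image):
        ss = build_scale_space(textured_image, 4, 3, 1.6)
        kps = detect_extrema(ss)
        assert kps
        for kp in kps:
            scale = ss.octave_scale(kp.octave)
            l = kp.level
            r = int(round(kp.y / scale))
            c = int(round(kp.x / scale))
            cube = ss.dogs[kp.octave][l - 1 : l + 2, r - 1 : r + 2, c - 1 : c + 2]
            centre = cube[1, 1, 1]
            rest = np.delete(cube.ravel(), 13)
            assert centre > rest.max() or centre < rest.min()


class TestOrientations:
    def test_ramp_gradient_direction_recovered(self):
        img = np.tile(np.linspace(0.0, 1.0, 64), (64, 1))
        ss = build_scale_space(img, 1, 3, 1.6)
        kp = Keypoint(x=32.0, y=32.0, sigma=2.0, octave=0, level=1)
        oriented = assign_orientations(kp, ss)
        assert oriented
        assert min(circdiff(o.orientation, 0.0) for o in oriented) < 5.0

    def test_isotropic_blob_returns_at_least_one_orientation(self):
        img = blob_image()
        ss = build_scale_space(img, 1, 3, 1.6)
        kp = Keypoint(x=32.0, y=32.0, sigma=4.0, octave=0, level=1)
        assert len(assign_orientations(kp, ss)) >= 1


@pytest.fixture(scope="module")
def detections(textured_image):
    img = textured_image
    rot = np.rot90(img, 1)
    ss_a = build_scale_space(img, 4, 3, 1.6)
    ss_b = build_scale_space(rot, 4, 3, 1.6)
    kps_a, desc_a = detect_and_describe(ss_a)
    kps_b, desc_b = detect_and_describe(ss_b)
    return img.shape[1], kps_a, desc_a, kps_b, desc_b


class TestRotationEquivariance:
    @staticmethod
    def _map_point(x, y, width):
        # np.rot90(img, 1): (x, y) -> (y, width - 1 - x)
        return y, width - 1.0 - x

    def test_keypoint_locations_survive_rotation(self, detections):
        width, kps_a, _, kps_b, _ = detections
        pts_b = np.array([[k.x, k.y] for k in kps_b])
        hits = 0
        for k in kps_a:
            mx, my = self._map_point(k.x, k.y, width)
            d = np.hypot(pts_b[:, 0] - mx, pts_b[:, 1] - my)
            hits += bool(d.min() < 2.0)
        assert hits / len(kps_a) >= 0.7

    def test_orientations_rotate_with_the_image(self, detections):
        width, kps_a, _, kps_b, _ = detections
        pts_b = np.array([[k.x, k.y] for k in kps_b])
        diffs = []
        for k in kps_a:
            mx, my = self._map_point(k.x, k.y, width)
            d = np.hypot(pts_b[:, 0] - mx, pts_b[:, 1] - my)
            j = int(np.argmin(d))
            if d[j] < 2.0:
                # gradient frame rotates by -90 deg under this mapping
                diffs.append(circdiff(k.orientation - kps_b[j].orientation, math.pi / 2))
        assert diffs
        assert np.mean(np.asarray(diffs) < 5.0) >= 0.7

    def test_descriptor_closer_to_counterpart_than_random(self, detections):
        width, kps_a, desc_a, kps_b, desc_b = detections
        pts_b = np.array([[k.x, k.y] for k in kps_b])
        wins = trials = 0
        for i, k in enumerate(kps_a):
            mx, my = self._map_point(k.x, k.y, width)
            d = np.hypot(pts_b[:, 0] - mx, pts_b[:, 1] - my)
            j = int(np.argmin(d))
            if d[j] >= 2.0:
                continue
            dist_pair = np.linalg.norm(desc_a[i] - desc_b[j])
            dist_all = np.linalg.norm(desc_b - desc_a[i], axis=1)
            trials += 1
            wins += bool(dist_pair < np.percentile(dist_all, 5))
        assert trials >= 20
        assert wins / trials >= 0.7


class TestDescriptor:
    def test_flat_patch_gives_flagged_zero_descriptor(self):
        ss = build_scale_space(np.full((64, 64), 0.4), 1, 3, 1.6)
        kp = Keypoint(x=32.0, y=32.0, sigma=2.0, octave=0, level=1)
        d = compute_descriptor(kp, ss)
        assert d.shape == (128,)
        assert not d.any()

    def test_descriptors_have_unit_norm(self, textured_image):
        ss = build_scale_space(textured_image, 4, 3, 1.6)
        _, descs = detect_and_describe(ss)
        assert len(descs) > 0
        norms = np.linalg.norm(descs, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_descriptor_invariant_to_global_brightening(self, textured_image):
        img = 0.6 * textured_image  # keep 1.5x within [0, 1)
        ss1 = build_scale_space(img, 2, 3, 1.6)
        ss2 = build_scale_space(1.5 * img, 2, 3, 1.6)
        kps = detect_extrema(ss1)
        assert kps
        checked = 0
        for kp in kps[:20]:
            for okp in assign_orientations(kp, ss1):
                d1 = compute_descriptor(okp, ss1)
                d2 = compute_descriptor(okp, ss2)
                if d1.any():
                    np.testing.assert_allclose(d1, d2, atol=1e-3)
                    checked += 1
        assert checked > 0

    def test_window_outside_image_degenerates(self, textured_image):
        ss = build_scale_space(textured_image, 1, 3, 1.6)
        kp = Keypoint(x=-500.0, y=-500.0, sigma=2.0, octave=0, level=1)
        assert not compute_descriptor(kp, ss).any()
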