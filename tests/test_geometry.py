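"""Marker detection, homography estimation, warping, cropping."""

import numpy as np
import pytest
from skimage.draw import disk

import phenotray as pt
from phenotray import geometry, traysim


def _distorted_tray(params, rng, strength=0.04, day=8.0, seed=1):
    d = traysim.random_distortion(rng, params.canvas_shape, strength)
    p = traysim.replace(params, distortion=d)
    return pt.generate_tray(p, day=day, seed=seed)


class TestDetectMarkers:
    def test_detects_four_centers_within_1px(self, small_params):
        img, truth = pt.generate_tray(small_params, day=8, seed=4)
        markers = pt.detect_markers(img)
        assert set(markers.centers) == {"TL", "TR", "BL", "BR"}
        for role, (x, y) in truth.marker_centers_ideal.items():
            mx, my = markers.centers[role]
            assert np.hypot(mx - x, my - y) < 1.0

    def test_subthreshold_distractors_ignored(self, small_params):
        """Red blobs under the 150-px area filter do not become markers."""
        img, _ = pt.generate_tray(small_params, day=8, seed=4)
        img = img.copy()
        # three distractor blobs of ~100 px (r=5.6 disk), away from markers
        for cy, cx in [(8, 200), (180, 60), (100, 320)]:
            rr, cc = disk((cy, cx), 5.65, shape=img.shape[:2])
            assert 95 <= len(rr) <= 105
            img[rr, cc] = (205, 30, 35)
        markers = pt.detect_markers(img)
        assert len(markers.centers) == 4

    def test_no_red_pixels_raises_with_empty_partial(self):
        img = np.full((100, 200, 3), 80, dtype=np.uint8)
        with pytest.raises(geometry.MarkerDetectionError) as err:
            pt.detect_markers(img)
        assert err.value.n_candidates == 0

    def test_area_filter_monotonicity(self, small_params):
        """Raising the area threshold never increases the candidate count."""
        img, _ = pt.generate_tray(small_params, day=8, seed=4)
        counts = []
        for thr in (50, 150, 400):
            try:
                ms = pt.detect_markers(
                    img, geometry.MarkerConfig(area_threshold=thr))
                counts.append(len(ms.centers))
            except geometry.MarkerDetectionError as e:
                counts.append(e.n_candidates)
        assert counts == sorted(counts, reverse=True)


class TestRecovery:
    def test_missing_role_filled_from_prev(self):
        partial = geometry.MarkerSet(centers={
            "TR": (600.0, 250.0), "BL": (410.0, 700.0), "BR": (600.0, 700.0)})
        prev = geometry.MarkerSet(centers={
            "TL": (410.0, 250.0), "TR": (601.0, 251.0),
            "BL": (411.0, 699.0), "BR": (601.0, 701.0)})
        out = geometry.recover_missing_markers(partial, prev=prev)
        assert out.centers["TL"] == (410.0, 250.0)
        assert out.provenance["TL"] == "recovered"
        assert out.provenance["TR"] == "detected"

    def test_no_gaps_is_identity(self):
        full = geometry.MarkerSet(centers={
            "TL": (1.0, 1.0), "TR": (9.0, 1.0),
            "BL": (1.0, 9.0), "BR": (9.0, 9.0)})
        out = geometry.recover_missing_markers(full)
        assert out.centers == full.centers
        assert all(v == "detected" for v in out.provenance.values())

    def test_prev_wins_over_next(self):
        partial = geometry.MarkerSet(centers={
            "TR": (9.0, 1.0), "BL": (1.0, 9.0), "BR": (9.0, 9.0)})
        prev = geometry.MarkerSet(centers={"TL": (1.0, 1.0)})
        nxt = geometry.MarkerSet(centers={"TL": (2.0, 2.0)})
        out = geometry.recover_missing_markers(partial, prev=prev, next=nxt)
        assert out.centers["TL"] == (1.0, 1.0)

    def test_unrecoverable_without_neighbors(self):
        partial = geometry.MarkerSet(centers={"TR": (9.0, 1.0)})
        with pytest.raises(ValueError):
            geometry.recover_missing_markers(partial)


class TestTargets:
    def test_deployment_geometry(self):
        tp = pt.target_points(pt.TrayGeometry(pot_w=224, pot_h=224))
        assert tp.centers["TL"] == (448.0, 224.0)
        assert tp.centers["TR"] == (1344.0, 224.0)
        assert tp.centers["BL"] == (448.0, 672.0)
        assert tp.centers["BR"] == (1344.0, 672.0)

    def test_unit_geometry(self):
        tp = pt.target_points(pt.TrayGeometry(pot_w=1, pot_h=1))
        assert tp.centers["TL"] == (2.0, 1.0)
        assert tp.centers["TR"] == (6.0, 1.0)
        assert tp.centers["BL"] == (2.0, 3.0)
        assert tp.centers["BR"] == (6.0, 3.0)

    @pytest.mark.parametrize("pw,ph", [(224, 224), (100, 50), (17, 31)])
    def test_marker_span_is_4pw_by_2ph(self, pw, ph):
        tp = pt.target_points(pt.TrayGeometry(pot_w=pw, pot_h=ph)).centers
        assert tp["TR"][0] - tp["TL"][0] == 4 * pw
        assert tp["BL"][1] - tp["TL"][1] == 2 * ph


class TestHomography:
    def _square(self, offset=(0.0, 0.0)):
        ox, oy = offset
        return geometry.MarkerSet(centers={
            "TL": (10.0 + ox, 10.0 + oy), "TR": (90.0 + ox, 10.0 + oy),
            "BL": (10.0 + ox, 90.0 + oy), "BR": (90.0 + ox, 90.0 + oy)})

    def test_identity(self):
        s = self._square()
        h = pt.estimate_homography(s, s)
        assert np.allclose(h, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        src = self._square(offset=(10.0, 5.0))
        dst = self._square()
        h = pt.estimate_homography(src, dst)
        expected = np.array([[1, 0, -10], [0, 1, -5], [0, 0, 1]], float)
        assert np.allclose(h, expected, atol=1e-9)

    def test_inverts_known_projective(self):
        p = np.array([[1.05, 0.02, 3.0],
                      [-0.01, 0.98, -2.0],
                      [1e-4, -5e-5, 1.0]])
        dst = self._square()
        src_pts = geometry.apply_homography(p, dst.as_array())
        src = geometry.MarkerSet(centers={
            r: tuple(src_pts[i]) for i, r in enumerate(geometry.ROLES)})
        h = pt.estimate_homography(src, dst)
        composed = h @ p
        composed /= composed[2, 2]
        assert np.linalg.norm(composed - np.eye(3)) < 1e-6

    def test_collinear_sources_rejected(self):
        src = geometry.MarkerSet(centers={
            "TL": (0.0, 0.0), "TR": (1.0, 0.0),
            "BL": (2.0, 0.0), "BR": (3.0, 0.0)})
        dst = self._square()
        with pytest.raises(ValueError):
            pt.estimate_homography(src, dst)


class TestWarpAndCrop:
    def test_warped_markers_land_on_targets(self, small_params, small_geom,
                                            rng):
        img, _ = _distorted_tray(small_params, rng)
        corrected, _, _ = geometry.rectify(img, small_geom)
        assert corrected.shape[:2] == small_geom.canvas_shape
        redetected = pt.detect_markers(corrected)
        targets = pt.target_points(small_geom)
        for role in geometry.ROLES:
            dx = redetected.centers[role][0] - targets.centers[role][0]
            dy = redetected.centers[role][1] - targets.centers[role][1]
            assert np.hypot(dx, dy) < 1.0, role

    def test_roundtrip_residual_over_random_distortions(self, small_params,
                                                        small_geom):
        """Detect -> homography -> warp -> re-detect stays within 1.5 px."""
        rng = np.random.default_rng(20)
        worst = 0.0
        for trial in range(20):
            img, _ = _distorted_tray(small_params, rng,
                                     strength=rng.uniform(0.01, 0.06),
                                     seed=100 + trial)
            corrected, _, _ = geometry.rectify(img, small_geom)
            redetected = pt.detect_markers(corrected)
            targets = pt.target_points(small_geom)
            for role in geometry.ROLES:
                dx = redetected.centers[role][0] - targets.centers[role][0]
                dy = redetected.centers[role][1] - targets.centers[role][1]
                worst = max(worst, float(np.hypot(dx, dy)))
        assert worst < 1.5

    def test_crop_grid_and_partition(self, small_geom):
        canvas = np.arange(np.prod(small_geom.canvas_shape),
                           dtype=np.int64).reshape(small_geom.canvas_shape)
        crops = pt.crop_pots(canvas, small_geom)
        assert len(crops) == 32
        assert all(c.shape == (48, 48) for c in crops)
        # disjoint + exhaustive: every canvas value appears exactly once
        assert np.array_equal(
            np.sort(np.concatenate([c.ravel() for c in crops])),
            np.arange(canvas.size))

    def test_single_pot_crop_is_whole_canvas(self):
        geom = pt.TrayGeometry(pot_w=30, pot_h=20, n_rows=1, n_cols=1)
        canvas = np.zeros((20, 30, 3), dtype=np.uint8)
        crops = pt.crop_pots(canvas, geom)
        assert len(crops) == 1 and crops[0].shape == (20, 30, 3)

    def test_canvas_size_mismatch(self, small_geom):
        with pytest.raises(ValueError):
            pt.crop_pots(np.zeros((10, 10, 3)), small_geom)
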