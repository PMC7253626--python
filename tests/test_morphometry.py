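"""Outline, landmark and trait geometry."""

import numpy as np
import pytest
from scipy import ndimage

from phenoseg.errors import MissingTargetError
from phenoseg.morphometry import (LANDMARK_NAMES, TRAIT_NAMES,
                                  TRAIT_REQUIREMENTS, compute_traits,
                                  extract_landmarks, extract_outline,
                                  orient_right)
from phenoseg.synthetic import SilhouetteSpec, make_silhouette_image


def _landmark_errors(truth, landmarks):
    errs = {}
    for name in LANDMARK_NAMES:
        gt, est = truth.landmarks[name], landmarks[name]
        errs[name] = (np.inf if est is None
                      else float(np.hypot(est[0] - gt[0], est[1] - gt[1])))
    return errs


class TestExtractOutline:
    def test_rectangle_perimeter(self):
        mask = np.zeros((80, 100), dtype=bool)
        mask[30:40, 20:40] = True  # 20x10 rectangle
        outline = extract_outline(mask)
        edge_count = outline.edge.sum()
        assert edge_count == 2 * 20 + 2 * 10 - 4
        assert len(outline.points) == edge_count
        # ordered ring: successive points 8-connected, closed
        d = np.abs(np.diff(np.vstack([outline.points, outline.points[:1]]),
                           axis=0))
        assert (d.max(axis=1) == 1).all()

    def test_speck_removed(self):
        mask = np.zeros((80, 100), dtype=bool)
        mask[30:40, 20:40] = True
        mask[60, 60] = True
        outline = extract_outline(mask, min_object=5)
        assert not outline.edge[60, 60]

    def test_empty_mask_raises(self):
        with pytest.raises(MissingTargetError):
            extract_outline(np.zeros((10, 10), dtype=bool))
        with pytest.raises(MissingTargetError):
            extract_outline(np.eye(3, dtype=bool), min_object=50)

    def test_fixture_outline_hugs_ground_truth(self):
        _, truth = make_silhouette_image(SilhouetteSpec(), seed=31)
        outline = extract_outline(truth.mask)
        gt_boundary = truth.mask & ~ndimage.binary_erosion(truth.mask)
        dist = ndimage.distance_transform_edt(~gt_boundary)
        assert dist[outline.points[:, 1], outline.points[:, 0]].max() <= 1.0


class TestExtractLandmarks:
    def test_rectangle_rear_hoof_is_bottom_left_corner(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[20:61, 10:91] = True  # x in [10, 90], y in [20, 60]
        lm = extract_landmarks(extract_outline(mask))
        assert lm["rear_hoof"] == (10, 60)
        assert lm["front_hoof"] == (90, 60)

    def test_all_landmarks_close_to_truth_on_fixture(self):
        _, truth = make_silhouette_image(
            SilhouetteSpec(background="flat"), seed=32)
        lm = extract_landmarks(extract_outline(truth.mask))
        errs = _landmark_errors(truth, lm)
        assert max(errs.values()) <= 3.0, errs

    def test_head_erased_marks_head_landmarks_missing(self):
        _, truth = make_silhouette_image(SilhouetteSpec(), seed=33)
        beheaded = truth.mask & ~truth.parts["head"]
        lm_full = extract_landmarks(extract_outline(truth.mask))
        lm = extract_landmarks(extract_outline(beheaded))
        for name in ("nose_tip", "poll", "muzzle_top", "jaw"):
            assert lm[name] is None, name
        for name in set(LANDMARK_NAMES) - {"nose_tip", "poll", "muzzle_top",
                                           "jaw"}:
            a, b = lm[name], lm_full[name]
            assert a is not None
            assert np.hypot(a[0] - b[0], a[1] - b[1]) <= 3.0, name

    def test_present_landmarks_lie_on_outline(self):
        _, truth = make_silhouette_image(SilhouetteSpec(), seed=34)
        outline = extract_outline(truth.mask)
        lm = extract_landmarks(outline)
        ptset = {tuple(p) for p in outline.points}
        for name, pt in lm.items():
            assert pt in ptset, name


class TestComputeTraits:
    def _full_lm(self):
        _, truth = make_silhouette_image(SilhouetteSpec(), seed=35)
        return truth, extract_outline(truth.mask)

    def test_closed_form_geometry(self):
        truth, outline = self._full_lm()
        lm = dict(truth.landmarks)
        lm.update({"withers": (0, 0), "tail_head": (1, 0), "brisket": (0, 1)})
        tv = compute_traits(lm, outline)
        assert tv.values["body_area_triangle"] == pytest.approx(0.5)
        lm.update({"tail_head": (0, 0), "back_top": (0, 1), "withers": (1, 1),
                   "brisket": (1, 0), "belly_rear": (0, 0)})
        tv = compute_traits(lm, outline)
        assert tv.values["body_area_polygon"] == pytest.approx(1.0)
        lm.update({"nose_tip": (3, 4), "poll": (0, 0)})
        assert compute_traits(lm, outline).values["face_length"] == pytest.approx(5.0)

    def test_collinear_back_gives_zero_deviation(self):
        mask = np.zeros((60, 100), dtype=bool)
        mask[20:40, 10:90] = True  # rectangle: flat top
        outline = extract_outline(mask)
        lm = extract_landmarks(outline)
        lm["withers"] = (60, 20)
        lm["tail_head"] = (10, 20)
        tv = compute_traits(lm, outline)
        assert tv.values["back_deviation"] == 0.0

    def test_missingness_propagates_exactly(self):
        truth, outline = self._full_lm()
        lm = dict(truth.landmarks)
        lm["nose_tip"] = None
        lm["brisket"] = None
        tv = compute_traits(lm, outline)
        expected = {t for t, req in TRAIT_REQUIREMENTS.items()
                    if "nose_tip" in req or "brisket" in req}
        assert tv.missing == expected
        for t in TRAIT_NAMES:
            if t in expected:
                assert np.isnan(tv.as_row()[t])
            else:
                assert np.isfinite(tv.as_row()[t])

    def test_translation_equivariance(self):
        _, truth = make_silhouette_image(SilhouetteSpec(), seed=36)
        dx, dy = 9, 5
        big = np.zeros((truth.mask.shape[0] + 20, truth.mask.shape[1] + 20),
                       dtype=bool)
        big[dy:dy + truth.mask.shape[0], dx:dx + truth.mask.shape[1]] = truth.mask
        lm0 = extract_landmarks(extract_outline(truth.mask))
        lm1 = extract_landmarks(extract_outline(big))
        for name in LANDMARK_NAMES:
            # corner-anchored hoof rules move with the frame; compare shifted
            if name in ("rear_hoof", "front_hoof"):
                continue
            x0, y0 = lm0[name]
            assert lm1[name] == (x0 + dx, y0 + dy), name
        t0 = compute_traits(lm0, extract_outline(truth.mask))
        t1 = compute_traits(lm1, extract_outline(big))
        for t in TRAIT_NAMES:
            assert t1.values[t] == pytest.approx(t0.values[t], abs=1e-9), t

    def test_scale_covariance(self):
        _, truth = make_silhouette_image(SilhouetteSpec(), seed=37)
        mask2 = np.kron(truth.mask, np.ones((2, 2), dtype=bool))
        t1 = compute_traits(extract_landmarks(extract_outline(truth.mask)),
                            extract_outline(truth.mask))
        t2 = compute_traits(extract_landmarks(extract_outline(mask2)),
                            extract_outline(mask2))
        for t in TRAIT_NAMES:
            factor = 4.0 if t.startswith("body_area") else 2.0
            assert t2.values[t] == pytest.approx(factor * t1.values[t],
                                                 rel=0.02, abs=2.5), t


class TestOrientRight:
    def test_flip_is_an_involution(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, size=(20, 30, 3), dtype=np.uint8)
        mask = rng.random((20, 30)) < 0.5
        img1, mask1, flipped = orient_right(img, mask, mode="flip")
        assert flipped
        img2, mask2, _ = orient_right(img1, mask1, mode="flip")
        assert (img2 == img).all() and (mask2 == mask).all()

    def test_auto_keeps_right_facing_fixture(self):
        img, truth = make_silhouette_image(SilhouetteSpec(), seed=38)
        _, _, flipped = orient_right(img, truth.mask, mode="auto")
        assert not flipped

    def test_auto_flips_mirrored_fixture(self):
        img, truth = make_silhouette_image(SilhouetteSpec(), seed=38)
        _, _, flipped = orient_right(img[:, ::-1], truth.mask[:, ::-1],
                                     mode="auto")
        assert flipped

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            orient_right(np.zeros((5, 5, 3)), np.zeros((5, 5), bool), "sideways")
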