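"""Haar feature evaluation, boosted detector, geometric filter, cropping."""

import numpy as np
import pytest

from grimace.detection import (
    BoundingBox,
    FaceHypothesis,
    GeometricRules,
    HaarStumpDetector,
    _eval_features_windows,
    _pad_integral,
    crop_to_hypothesis,
    detect_whole_face,
    detection_report,
    enumerate_features,
    extract_crop_features,
    geometric_filter,
    iou,
    laplacian_energy,
    train_detector,
    two_stage_detect,
)


class TestHaarFeatures:
    def test_matches_skimage_oracle(self):
        """My vectorized rectangle-sum evaluator reproduces scikit-image's
        haar_like_feature values for every feature type."""
        from skimage.feature import haar_like_feature, haar_like_feature_coord
        from skimage.transform import integral_image

        rng = np.random.default_rng(0)
        img = rng.random((12, 12))
        ii_sk = integral_image(img)
        for ft in ("type-2-x", "type-2-y", "type-3-x", "type-3-y", "type-4"):
            coords, types = haar_like_feature_coord(12, 12, ft)
            pick = rng.choice(len(coords), size=min(20, len(coords)),
                              replace=False)
            expected = haar_like_feature(
                ii_sk, 0, 0, 12, 12, feature_type=types[pick],
                feature_coord=coords[pick])
            from grimace.detection import HaarFeature

            feats = [HaarFeature.from_skimage(ft, coords[i]) for i in pick]
            mine = extract_crop_features(img[None], feats, 12)[0]
            np.testing.assert_allclose(mine, expected, atol=1e-9)

    def test_window_offsets(self):
        """Features evaluated at a window origin equal features of the
        corresponding crop."""
        rng = np.random.default_rng(1)
        img = rng.random((20, 20))
        feats = enumerate_features(8, rng, 30)
        ii2 = _pad_integral(img)
        x, ys, xs = _eval_features_windows(ii2, feats, 8, stride=4)
        for wi, (r, c) in enumerate((r, c) for r in ys for c in xs):
            crop = img[r:r + 8, c:c + 8]
            np.testing.assert_allclose(
                x[wi], extract_crop_features(crop[None], feats, 8)[0],
                atol=1e-9)


@pytest.fixture(scope="module")
def toy_detector():
    """Bright-square-on-dark detector trained from toy crops."""
    rng = np.random.default_rng(2)
    pos, neg = [], []
    for _ in range(30):
        p = rng.normal(0.1, 0.03, (16, 16))
        p[1:15, 1:15] += 0.8          # square nearly fills the window
        pos.append(p)
        neg.append(rng.normal(0.3, 0.1, (16, 16)))
    return train_detector(pos, neg, window=16, n_features=60,
                          n_estimators=15, seed=0)


class TestDetector:
    def test_blank_image_yields_nothing(self, toy_detector):
        assert detect_whole_face(np.full((48, 48), 0.3), toy_detector) == []

    def test_detects_planted_square(self, toy_detector):
        rng = np.random.default_rng(3)
        img = rng.normal(0.1, 0.03, (48, 48))
        img[12:32, 10:30] += 0.8
        boxes = detect_whole_face(img, toy_detector,
                                  scales=[16 / 18.0, 16 / 22.0],
                                  threshold=0.0)
        assert boxes
        assert iou(boxes[0], (10, 12, 30, 32)) >= 0.5

    def test_deterministic(self, toy_detector):
        rng = np.random.default_rng(4)
        img = rng.normal(0.1, 0.03, (40, 40))
        img[10:26, 10:26] += 0.8
        a = detect_whole_face(img, toy_detector)
        b = detect_whole_face(img, toy_detector)
        assert a == b

    def test_boxes_sorted_by_score(self, toy_detector):
        rng = np.random.default_rng(5)
        img = rng.normal(0.1, 0.03, (64, 64))
        img[8:24, 8:24] += 0.8
        img[40:56, 36:52] += 0.6
        boxes = detect_whole_face(img, toy_detector, threshold=-np.inf)
        scores = [b.score for b in boxes]
        assert scores == sorted(scores, reverse=True)

    def test_json_roundtrip_preserves_scores(self, toy_detector, tmp_path):
        toy_detector.save(tmp_path / "det.json")
        loaded = HaarStumpDetector.load(tmp_path / "det.json")
        rng = np.random.default_rng(6)
        crops = rng.random((5, 16, 16))
        x = extract_crop_features(crops, toy_detector.features, 16)
        x2 = extract_crop_features(crops, loaded.features, 16)
        np.testing.assert_allclose(loaded.decision_scores(x2),
                                   toy_detector.decision_scores(x))

    def test_missing_model_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.json"):
            HaarStumpDetector.load(tmp_path / "nope.json")

    def test_scores_match_sklearn_decision_function(self):
        """The serialized stump ensemble reproduces the fitted booster's
        decision function exactly (dual-route check)."""
        from sklearn.ensemble import GradientBoostingClassifier

        rng = np.random.default_rng(7)
        x = rng.random((80, 12))
        y = (x[:, 3] + 0.2 * rng.random(80) > 0.6).astype(int)
        gb = GradientBoostingClassifier(n_estimators=12, max_depth=1,
                                        learning_rate=0.3, random_state=0)
        gb.fit(x, y)
        p1 = float(np.ravel(gb.init_.predict_proba(x[:1]))[1])
        det = HaarStumpDetector(
            window=1, features=[],
            stumps=[(int(e.tree_.feature[0]), float(e.tree_.threshold[0]),
                     float(e.tree_.value[1].ravel()[0]),
                     float(e.tree_.value[2].ravel()[0]))
                    for e in gb.estimators_[:, 0]],
            bias=float(np.log(p1 / (1 - p1))), learning_rate=0.3)
        np.testing.assert_allclose(det.decision_scores(x),
                                   gb.decision_function(x), atol=1e-10)


def box_at(cx, cy, half=3, score=1.0):
    return BoundingBox(int(cx - half), int(cy - half),
                       int(cx + half), int(cy + half), score)


class TestGeometricFilter:
    RULES = GeometricRules(d_min=0.05, d_max=0.6, tol=0.15)
    H = 100

    def brute_force(self, eyes, ears):
        """Literal re-statement of rules R1-R3."""
        if not eyes and not ears:
            return False, "no parts"
        if not eyes or not ears:
            return False, "R1"
        eye_cy = [(b.y0 + b.y1) / 2 for b in eyes]
        ear_cy = [(b.y0 + b.y1) / 2 for b in ears]
        if not min(ear_cy) < min(eye_cy):
            return False, "R1"
        ec = np.mean([[(b.x0 + b.x1) / 2, (b.y0 + b.y1) / 2] for b in eyes], axis=0)
        ac = np.mean([[(b.x0 + b.x1) / 2, (b.y0 + b.y1) / 2] for b in ears], axis=0)
        d = float(np.hypot(*(ec - ac)))
        if not self.RULES.d_min * self.H <= d <= self.RULES.d_max * self.H:
            return False, "R2"
        if len(eyes) >= 2 and max(eye_cy) - min(eye_cy) > self.RULES.tol * self.H:
            return False, "R3"
        return True, None

    def test_plausible_group_accepted(self):
        eyes = [box_at(40, 50), box_at(60, 50)]
        ears = [box_at(35, 25), box_at(65, 25)]
        grp = geometric_filter(eyes, ears, self.RULES, self.H)
        assert grp.accepted

    def test_ears_below_eyes_rejected_r1(self):
        grp = geometric_filter([box_at(50, 30)], [box_at(50, 70)],
                               self.RULES, self.H)
        assert not grp.accepted
        assert grp.reason == "R1"

    def test_no_parts(self):
        grp = geometric_filter([], [], self.RULES, self.H)
        assert grp.reason == "no parts"

    def test_exhaustive_grid_matches_brute_force(self):
        """One eye x one ear over a coordinate grid: decisions and reasons
        match the literal rule statement everywhere."""
        coords = range(5, 100, 7)
        for ex in coords:
            for ey in coords:
                for ax in (20, 50, 80):
                    for ay in coords:
                        eyes, ears = [box_at(ex, ey)], [box_at(ax, ay)]
                        grp = geometric_filter(eyes, ears, self.RULES, self.H)
                        expected = self.brute_force(eyes, ears)
                        assert (grp.accepted, grp.reason) == expected, (
                            (ex, ey, ax, ay))

    def test_two_eye_grid_with_r3(self):
        for dy in range(0, 60, 5):
            eyes = [box_at(40, 50), box_at(60, 50 + dy)]
            ears = [box_at(50, 20)]
            grp = geometric_filter(eyes, ears, self.RULES, self.H)
            assert (grp.accepted, grp.reason) == self.brute_force(eyes, ears)

    def test_mirror_invariance(self):
        """Horizontally mirroring all boxes never changes the decision."""
        rng = np.random.default_rng(8)
        for _ in range(300):
            eyes = [box_at(rng.integers(10, 90), rng.integers(10, 90))
                    for _ in range(rng.integers(1, 3))]
            ears = [box_at(rng.integers(10, 90), rng.integers(10, 90))
                    for _ in range(rng.integers(1, 3))]

            def mirror(b):
                return BoundingBox(100 - b.x1, b.y0, 100 - b.x0, b.y1, b.score)

            a = geometric_filter(eyes, ears, self.RULES, self.H)
            m = geometric_filter([mirror(b) for b in eyes],
                                 [mirror(b) for b in ears], self.RULES, self.H)
            assert (a.accepted, a.reason) == (m.accepted, m.reason)


class TestTwoStage:
    def _stub_models(self, stage1_fires):
        class Stub(HaarStumpDetector):
            def __init__(self):
                super().__init__(window=8, features=[], stumps=[], threshold=0.0)

        stub = Stub()
        return stub, stage1_fires

    def test_stage1_short_circuit(self, monkeypatch):
        """When stage 1 returns a box, part detectors never run."""
        import grimace.detection as det

        face_box = BoundingBox(10, 10, 30, 30, 2.0)
        monkeypatch.setattr(det, "detect_whole_face",
                            lambda *a, **k: [face_box])

        def boom(*a, **k):
            raise AssertionError("stage 2 must not run")

        monkeypatch.setattr(det, "detect_parts", boom)
        stub, _ = self._stub_models(True)
        hyp = det.two_stage_detect(np.zeros((50, 50)), stub, stub, stub)
        assert hyp.accepted and hyp.source == "whole_face"
        assert hyp.face_box == face_box

    def test_fallback_used_when_stage1_empty(self, monkeypatch):
        import grimace.detection as det

        monkeypatch.setattr(det, "detect_whole_face", lambda *a, **k: [])
        eyes = [box_at(20, 30, score=0.5), box_at(32, 30, score=0.5)]
        ears = [box_at(18, 14, score=0.5), box_at(34, 14, score=0.5)]
        monkeypatch.setattr(det, "detect_parts", lambda *a, **k: (eyes, ears))
        stub, _ = self._stub_models(False)
        hyp = det.two_stage_detect(np.zeros((50, 50)), stub, stub, stub)
        assert hyp.accepted and hyp.source == "parts_fallback"
        assert hyp.face_box is not None

    def test_blank_image_not_accepted(self):
        stub, _ = self._stub_models(False)
        stub.threshold = np.inf
        hyp = two_stage_detect(np.full((40, 40), 0.5), stub, None, None)
        assert not hyp.accepted


class TestCrop:
    def test_zero_margin_full_box_identity(self):
        img = np.random.default_rng(9).random((20, 30))
        hyp = FaceHypothesis(face_box=BoundingBox(0, 0, 30, 20), accepted=True)
        np.testing.assert_array_equal(crop_to_hypothesis(img, hyp, 0.0), img)

    def test_corner_box_clipped(self):
        img = np.random.default_rng(10).random((20, 20))
        hyp = FaceHypothesis(face_box=BoundingBox(0, 0, 6, 6), accepted=True)
        crop = crop_to_hypothesis(img, hyp, 0.5)
        assert crop.shape == (9, 9)  # expansion clipped at the origin

    def test_margin_monotonicity(self):
        img = np.random.default_rng(11).random((40, 40))
        hyp = FaceHypothesis(face_box=BoundingBox(10, 10, 25, 25), accepted=True)
        sizes = [crop_to_hypothesis(img, hyp, m).size for m in (0.0, 0.1, 0.3)]
        assert sizes == sorted(sizes)

    def test_unaccepted_hypothesis_errors(self):
        hyp = FaceHypothesis(face_box=None, accepted=False)
        with pytest.raises(ValueError, match="no face"):
            crop_to_hypothesis(np.zeros((10, 10)), hyp)


class TestReport:
    def _hyp(self, source, accepted):
        return FaceHypothesis(face_box=BoundingBox(0, 0, 1, 1) if accepted else None,
                              source=source, accepted=accepted)

    def test_eight_of_ten(self):
        hyps = [self._hyp("whole_face", True)] * 8 + [
            self._hyp("parts_fallback", False)] * 2
        rep = detection_report(hyps)
        assert rep[rep["stage"] == "overall"]["rate"].iloc[0] == pytest.approx(0.8)

    def test_all_stage1(self):
        hyps = [self._hyp("whole_face", True)] * 5
        rep = detection_report(hyps)
        assert rep[rep["stage"] == "overall"]["rate"].iloc[0] == 1.0
        assert np.isnan(rep[rep["stage"] == "parts_fallback"]["rate"].iloc[0])

    def test_random_pattern_matches_recount(self):
        rng = np.random.default_rng(12)
        hyps = [self._hyp(rng.choice(["whole_face", "parts_fallback"]),
                          bool(rng.integers(0, 2))) for _ in range(67)]
        rep = detection_report(hyps)
        overall = rep[rep["stage"] == "overall"].iloc[0]
        assert overall["accepted"] == sum(h.accepted for h in hyps)
        assert overall["rate"] == pytest.approx(
            sum(h.accepted for h in hyps) / 67)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            detection_report([])


class TestQualityGate:
    def test_blurry_scores_below_sharp(self):
        rng = np.random.default_rng(13)
        sharp = rng.random((32, 32))
        from scipy import ndimage

        blurry = ndimage.gaussian_filter(sharp, 3.0)
        assert laplacian_energy(blurry) < laplacian_energy(sharp)

    def test_gate_rejects_flat_crop_when_enabled(self, monkeypatch):
        import grimace.detection as det

        monkeypatch.setattr(det, "detect_whole_face",
                            lambda *a, **k: [BoundingBox(5, 5, 25, 25, 1.0)])
        stub = HaarStumpDetector(window=8, features=[], stumps=[])
        flat = np.full((40, 40), 0.5)
        default = det.two_stage_detect(flat, stub)
        assert default.accepted                  # gate is off by default
        gated = det.two_stage_detect(flat, stub, min_quality=1e-6)
        assert not gated.accepted
        assert gated.rejection_reason == "low quality"


class TestIoU:
    def test_identity(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_disjoint(self):
        assert iou((0, 0, 5, 5), (10, 10, 15, 15)) == 0.0

    def test_half_overlap(self):
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)
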