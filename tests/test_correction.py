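import numpy as np
import pytest
from scipy import ndimage

from amyseg.correction import (
    FEATURE_NAMES,
    BoostModel,
    Standardizer,
    Stump,
    correct_segmentation,
    detect_bias_region,
    extract_features,
    mask_to_offsets,
    train_adaboost,
    train_structure_corrector,
)
from amyseg.fusion import VoteMap
from amyseg.volumes import LabelMap, ValidationError, Volume


def lm(mask):
    return LabelMap(np.asarray(mask, dtype=np.int16))


class TestDetectBiasRegion:
    def test_perfect_segmentation_empty_mask(self):
        seg = lm(np.zeros((6, 6, 6)))
        mask = detect_bias_region([seg], [seg.copy()])
        assert (mask.labels == 0).all()

    def test_single_voxel_ball_dilation_oracle(self):
        init = np.zeros((11, 11, 11))
        truth = np.zeros((11, 11, 11))
        init[5, 5, 5] = 1
        mask = detect_bias_region([lm(init)], [lm(truth)], dilation_mm=2.0)
        # oracle: all voxels within euclidean distance 2 of (5,5,5)
        grids = np.meshgrid(*[np.arange(11)] * 3, indexing="ij")
        dist2 = sum((g - 5) ** 2 for g in grids)
        expected = dist2 <= 4.0 + 1e-9
        assert np.array_equal(mask.labels > 0, expected)

    def test_contains_all_disagreements(self, rng):
        inits = [lm(rng.integers(0, 2, (8, 8, 8))) for _ in range(3)]
        truths = [lm(rng.integers(0, 2, (8, 8, 8))) for _ in range(3)]
        mask = detect_bias_region(inits, truths, dilation_mm=1.0)
        for i, t in zip(inits, truths):
            assert (mask.labels[(i.labels != t.labels)] > 0).all()


class TestExtractFeatures:
    def _inputs(self, rng, shape=(10, 10, 10)):
        img = Volume(rng.random(shape) * 100)
        initial = lm(rng.integers(0, 2, shape))
        votes = VoteMap(Volume(rng.random(shape)), 1)
        box = ((2, 2, 2), (8, 8, 8))
        return img, initial, votes, box

    def test_center_voxel_zero_offsets(self, rng):
        img, initial, votes, box = self._inputs(rng)
        center = np.array([4, 4, 4])  # (lo + hi - 1)/2 = 4.5... use offsets directly
        offsets = np.array([[2, 2, 2]])  # voxel (4,4,4); center is (4.5,4.5,4.5)
        X = extract_features(img, initial, votes, box, 1, offsets)
        off = X[0, -3:]
        assert np.allclose(off, [-0.5, -0.5, -0.5])

    def test_interior_structure_count_27(self):
        initial = np.zeros((10, 10, 10))
        initial[3:8, 3:8, 3:8] = 1
        img = Volume(np.random.default_rng(0).random((10, 10, 10)))
        votes = VoteMap(Volume(np.zeros((10, 10, 10))), 1)
        offsets = np.array([[3, 3, 3]])  # voxel (5,5,5), fully inside
        X = extract_features(img, lm(initial), votes, ((2, 2, 2), (9, 9, 9)), 1, offsets)
        i3 = FEATURE_NAMES.index("count_3cube")
        i5 = FEATURE_NAMES.index("count_5cube")
        assert X[0, i3] == 27
        assert X[0, i5] == 125

    def test_constant_image_zero_variance_dropped(self, rng, caplog):
        img = Volume(np.full((10, 10, 10), 5.0))
        initial = lm(rng.integers(0, 2, (10, 10, 10)))
        votes = VoteMap(Volume(rng.random((10, 10, 10))), 1)
        offsets = np.argwhere(np.ones((6, 6, 6), dtype=bool))
        X = extract_features(img, initial, votes, ((2, 2, 2), (8, 8, 8)), 1, offsets)
        std = Standardizer().fit(X)
        for name in ("intensity", "gradient_magnitude"):
            assert FEATURE_NAMES.index(name) not in std.kept
        Xt = std.transform(X)
        assert np.isfinite(Xt).all()

    def test_deterministic_row_order(self, rng):
        img, initial, votes, box = self._inputs(rng)
        mask = lm(rng.integers(0, 2, (10, 10, 10)))
        offsets = mask_to_offsets(mask, box)
        assert np.array_equal(offsets, np.array(sorted(map(tuple, offsets))))


class TestAdaBoost:
    def test_alpha_closed_form(self):
        # eps = 0.1 -> alpha = 0.5 ln 9
        assert 0.5 * np.log(9.0) == pytest.approx(1.0986, abs=1e-4)
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0], [6.0], [7.0], [8.0], [9.0]])
        y = np.array([-1, -1, -1, -1, -1, 1, 1, 1, 1, -1.0])  # one inseparable point
        stumps, eps = train_adaboost(X, y, T=1)
        assert eps[0] == pytest.approx(0.1)
        assert stumps[0].alpha == pytest.approx(0.5 * np.log(9.0), abs=1e-12)

    def test_eps_half_halts_without_stump(self):
        # constant feature, balanced classes: every stump has error exactly 0.5
        X = np.ones((4, 1))
        y = np.array([1.0, 1.0, -1.0, -1.0])
        stumps, eps = train_adaboost(X, y, T=10)
        assert len(stumps) == 0  # alpha = 0.5 ln(1) = 0 -> halt

    def test_separable_perfect_after_one_round(self, rng):
        X = np.concatenate([rng.normal(-5, 0.5, 50), rng.normal(5, 0.5, 50)])[:, None]
        y = np.concatenate([-np.ones(50), np.ones(50)])
        stumps, eps = train_adaboost(X, y, T=10)
        assert len(stumps) == 1
        assert eps[0] == 0.0
        pred = stumps[0].predict(X)
        assert (pred == y).all()

    def test_exponential_bound(self, rng):
        X = rng.normal(size=(200, 5))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=0.8, size=200) > 0, 1.0, -1.0)
        stumps, eps = train_adaboost(X, y, T=30)
        score = np.zeros(200)
        for s in stumps:
            score += s.alpha * s.predict(X)
        train_err = np.mean(np.where(score >= 0, 1.0, -1.0) != y)
        bound = np.prod([2.0 * np.sqrt(e * (1.0 - e)) for e in eps])
        assert train_err <= bound + 1e-12

    def test_training_error_nonincreasing_in_rounds(self, rng):
        X = rng.normal(size=(150, 4))
        y = np.where(X[:, 0] - X[:, 2] + rng.normal(scale=0.5, size=150) > 0, 1.0, -1.0)
        stumps, _ = train_adaboost(X, y, T=25)
        errs = []
        score = np.zeros(150)
        for s in stumps:
            score += s.alpha * s.predict(X)
            errs.append(np.mean(np.where(score >= 0, 1.0, -1.0) != y))
        # exponential bound decays; allow small non-monotone jitter of 0-1 loss
        assert errs[-1] <= errs[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train_adaboost(np.zeros((5, 2)), np.ones(5), T=5)


class TestModelRoundtrip:
    def _toy_model(self, rng):
        X = rng.normal(size=(80, len(FEATURE_NAMES)))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        std = Standardizer().fit(X)
        stumps, _ = train_adaboost(std.transform(X), y, T=10)
        return BoostModel(
            stumps=stumps, standardizer=std, structure_label=1,
            roi_box=((1, 2, 3), (9, 10, 11)),
            mask_offsets=rng.integers(0, 8, size=(20, 3)),
            rounds=10,
        ), X

    def test_serialization_identical_predictions(self, rng, tmp_path):
        model, X = self._toy_model(rng)
        model.save(tmp_path / "m.json")
        back = BoostModel.load(tmp_path / "m.json")
        Xt = model.standardizer.transform(X)
        assert np.array_equal(model.predict(Xt), back.predict(back.standardizer.transform(X)))
        assert back.roi_box == model.roi_box
        assert np.array_equal(back.mask_offsets, model.mask_offsets)


def _dilated(truth_labels, structure):
    mask = truth_labels == structure
    dil = ndimage.binary_dilation(mask, iterations=1)
    out = np.where(dil, structure, 0).astype(np.int16)
    return out


class TestCorrectSegmentation:
    def test_identity_when_empty_mask(self, rng):
        img = Volume(rng.random((8, 8, 8)))
        initial = lm(rng.integers(0, 2, (8, 8, 8)))
        votes = VoteMap(Volume(rng.random((8, 8, 8))), 1)
        model = BoostModel(
            stumps=[], standardizer=Standardizer().fit(rng.normal(size=(5, len(FEATURE_NAMES)))),
            structure_label=1, roi_box=((0, 0, 0), (8, 8, 8)),
            mask_offsets=np.zeros((0, 3), dtype=int), rounds=5,
        )
        out = correct_segmentation(initial, model, img, votes)
        assert np.array_equal(out.labels, initial.labels)

    def test_flip_is_involutive(self, rng):
        initial = lm(rng.integers(0, 2, (6, 6, 6)))
        flip = rng.integers(0, 2, (6, 6, 6)).astype(bool)
        flipped = initial.labels.copy()
        flipped[flip] = np.where(flipped[flip] == 1, 0, 1)
        twice = flipped.copy()
        twice[flip] = np.where(twice[flip] == 1, 0, 1)
        assert np.array_equal(twice, initial.labels)

    def test_never_edits_outside_working_roi(self, rng, base_small, small_params):
        # systematic dilation bias: corrector must leave everything outside
        # the mask untouched
        from amyseg.phantom import simulate_subject

        cases = [simulate_subject(base_small, small_params, seed=s) for s in range(6)]
        box = ((4, 14, 10), (18, 26, 24))
        imgs = [c.image for c in cases]
        initials = [LabelMap(_dilated(c.truth.labels, 1), c.truth.spacing) for c in cases]
        votes = [VoteMap(Volume(ndimage.gaussian_filter(
            (c.truth.labels == 1).astype(float), 1.0)), 1) for c in cases]
        truths = [LabelMap((c.truth.labels == 1).astype(np.int16) , c.truth.spacing)
                  for c in cases]
        model = train_structure_corrector(
            imgs[:5], initials[:5], votes[:5], truths[:5], box, 1, rounds=20
        )
        out = correct_segmentation(initials[5], model, imgs[5], votes[5])
        mask = np.zeros((32, 32, 32), dtype=bool)
        lo = model.roi_box[0]
        mask[model.mask_offsets[:, 0] + lo[0],
             model.mask_offsets[:, 1] + lo[1],
             model.mask_offsets[:, 2] + lo[2]] = True
        assert np.array_equal(out.labels[~mask], initials[5].labels[~mask])

    def test_systematic_dilation_corrected(self, base_small, small_params):
        # fused segmentations systematically dilate truth by one voxel;
        # held-out Dice must improve after correction in >= 4 of 5 seeds
        from amyseg.metrics import dice
        from amyseg.phantom import simulate_subject

        wins = 0
        for seed in range(5):
            cases = [simulate_subject(base_small, small_params, seed=100 * seed + i)
                     for i in range(7)]
            sup = np.zeros((32, 32, 32), dtype=bool)
            for c in cases:
                sup |= c.truth.labels == 1
            idx = np.argwhere(sup)
            lo = np.maximum(idx.min(0) - 4, 0)
            hi = np.minimum(idx.max(0) + 5, 32)
            box = (tuple(lo), tuple(hi))
            initials = [LabelMap(_dilated(c.truth.labels, 1), c.truth.spacing) for c in cases]
            votes = [VoteMap(Volume(ndimage.gaussian_filter(
                (l.labels == 1).astype(float), 1.0)), 1) for l in initials]
            truths = [LabelMap((c.truth.labels == 1).astype(np.int16), c.truth.spacing)
                      for c in cases]
            model = train_structure_corrector(
                [c.image for c in cases[:6]], initials[:6], votes[:6], truths[:6],
                box, 1, rounds=30,
            )
            held = 6
            corrected = correct_segmentation(
                initials[held], model, cases[held].image, votes[held]
            )
            d_before = dice(initials[held], truths[held], 1)
            d_after = dice(corrected, truths[held], 1)
            if d_after > d_before:
                wins += 1
        assert wins >= 4
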