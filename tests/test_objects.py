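"""Feature extraction, forest training, evaluation and serialization."""

import numpy as np
import pytest

from carfind.objects import (
    CLASSES,
    FEATURE_NAMES,
    evaluate,
    load_model,
    save_model,
    train_classifier,
    classify,
    extract_features,
)
from carfind.prefilter import Candidate


def _disc_candidate(radius=10, value=100.0, crop_value=None, elongation=1.0):
    side = int(4 * radius * max(elongation, 1)) + 5
    yy, xx = np.mgrid[0:side, 0:side]
    c = side // 2
    mask = ((yy - c) / elongation) ** 2 + (xx - c) ** 2 <= radius**2
    crop = np.full((side, side), value if crop_value is None else crop_value)
    return Candidate(
        center=(float(c), float(c)),
        radius_px=float(radius),
        crop=crop,
        mask=mask,
        peak_score=0.5,
    )


class TestExtractFeatures:
    def test_vector_length_and_order_is_frozen(self):
        feats = extract_features(_disc_candidate())
        assert feats.shape == (len(FEATURE_NAMES),)

    def test_perfect_disc_on_constant_crop(self):
        feats = extract_features(_disc_candidate(radius=10))
        named = dict(zip(FEATURE_NAMES, feats))
        assert named["circularity"] == pytest.approx(1.0, rel=0.10)
        assert named["sd_intensity"] == 0.0
        assert named["mean_intensity"] == named["median_intensity"] == 100.0
        assert named["equivalent_radius_px"] == pytest.approx(10.0, rel=0.1)

    def test_elongated_mask_has_high_eccentricity(self):
        feats = extract_features(_disc_candidate(radius=8, elongation=2.0))
        named = dict(zip(FEATURE_NAMES, feats))
        assert named["eccentricity"] > 0.8

    def test_median_matches_sort_oracle(self, rng):
        cand = _disc_candidate(radius=7)
        cand.crop = rng.uniform(0, 500, cand.crop.shape)
        feats = extract_features(cand)
        named = dict(zip(FEATURE_NAMES, feats))
        vals = np.sort(cand.crop[cand.mask])
        n = len(vals)
        oracle = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
        assert named["median_intensity"] == pytest.approx(oracle, abs=1e-12)
        assert named["intensity_q50"] == pytest.approx(oracle, abs=1e-9)

    def test_empty_mask_rejected(self):
        cand = _disc_candidate()
        cand.mask = np.zeros_like(cand.mask)
        with pytest.raises(ValueError):
            extract_features(cand)


def _cluster_data(rng, n_per_class, spread=0.5):
    """Linearly separable synthetic clusters, one per category."""
    data = []
    for k, cls in enumerate(CLASSES):
        center = np.zeros(len(FEATURE_NAMES))
        center[k % len(FEATURE_NAMES)] = 10.0 * (k + 1)
        for _ in range(n_per_class):
            data.append((center + rng.normal(0, spread, len(center)), cls))
    return data


class TestTrainClassifier:
    def test_separable_clusters_classified_accurately(self, rng):
        train = _cluster_data(rng, 100)
        test = _cluster_data(rng, 50)
        model = train_classifier(train, seed=7)
        report = evaluate(model, test, n_train=len(train))
        assert report.accuracy >= 0.95
        assert report.n_test == 200

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        train = _cluster_data(rng, 100)
        labels = [cls for _, cls in train]
        rng.shuffle(labels)
        shuffled = [(f, c) for (f, _), c in zip(train, labels)]
        model = train_classifier(shuffled, seed=7)
        test = _cluster_data(rng, 50)
        report = evaluate(model, test)
        # 4 balanced classes: binomial(200, 1/4), 3 SD band
        sd = np.sqrt(0.25 * 0.75 / 200)
        assert abs(report.accuracy - 0.25) <= 3 * sd + 1e-9

    def test_same_seed_and_data_identical_predictions(self, rng):
        train = _cluster_data(rng, 30)
        X = np.array([f for f, _ in _cluster_data(rng, 10)])
        p1 = train_classifier(train, seed=3).predict(X)
        p2 = train_classifier(train, seed=3).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        data = [(rng.normal(0, 1, len(FEATURE_NAMES)), "CART") for _ in range(20)]
        with pytest.raises(ValueError):
            train_classifier(data, seed=0)

    def test_tiny_class_rejected(self, rng):
        data = _cluster_data(rng, 10) + [(rng.normal(0, 1, len(FEATURE_NAMES)), "CART")]
        data = [d for d in data if d[1] != "RBC"][:31] + [
            (np.zeros(len(FEATURE_NAMES)), "RBC")
        ]
        with pytest.raises(ValueError):
            train_classifier(data, seed=0)


class _StubModel:
    """Duck-typed model with fixed predictions, for metric arithmetic."""

    classes = CLASSES
    feature_names = FEATURE_NAMES

    def __init__(self, predictions):
        self._pred = np.asarray(predictions)

    def predict(self, X):
        return self._pred[: len(X)]


class TestEvaluate:
    def _fixed_outcome(self, tp, fn, tn, fp):
        """A CART-vs-rest outcome with the given confusion counts."""
        truths, preds = [], []
        truths += ["CART"] * tp + ["CART"] * fn
        preds += ["CART"] * tp + ["OTHER"] * fn
        truths += ["OTHER"] * tn + ["OTHER"] * fp
        preds += ["OTHER"] * tn + ["CART"] * fp
        test = [(np.zeros(len(FEATURE_NAMES)), t) for t in truths]
        return _StubModel(preds), test

    def test_perfect_predictions(self):
        model, test = self._fixed_outcome(tp=50, fn=0, tn=150, fp=0)
        report = evaluate(model, test)
        assert report.sensitivity["CART"] == 1.0
        assert report.specificity["CART"] == 1.0

    def test_operating_point_arithmetic(self):
        # 50 positives / 150 negatives split with TP=44, FN=6, TN=144, FP=6
        model, test = self._fixed_outcome(tp=44, fn=6, tn=144, fp=6)
        report = evaluate(model, test)
        assert report.sensitivity["CART"] == pytest.approx(0.88)
        assert report.specificity["CART"] == pytest.approx(0.96)

    def test_all_negative_predictions(self):
        model, test = self._fixed_outcome(tp=0, fn=50, tn=150, fp=0)
        report = evaluate(model, test)
        assert report.sensitivity["CART"] == 0.0
        assert report.specificity["CART"] == 1.0

    def test_confusion_sums_to_test_size(self, rng):
        test = _cluster_data(rng, 25)
        model = train_classifier(_cluster_data(rng, 50), seed=1)
        report = evaluate(model, test)
        assert report.confusion.sum() == len(test)

    def test_permutation_invariance(self, rng):
        train = _cluster_data(rng, 50)
        test = _cluster_data(rng, 25)
        model = train_classifier(train, seed=1)
        r1 = evaluate(model, test)
        order = rng.permutation(len(test))
        r2 = evaluate(model, [test[i] for i in order])
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.accuracy == r2.accuracy


class TestClassify:
    def test_empty_list_gives_zero_counts(self, trained_model):
        labeled, counts = classify(trained_model, [])
        assert labeled == []
        assert sum(counts.values()) == 0

    def test_counts_conserved_and_all_labeled(self, trained_model, small_library):
        _, test = small_library
        cands = [cand for cand, _ in test[:40]]
        labeled, counts = classify(trained_model, cands)
        assert sum(counts.values()) == len(cands)
        assert all(c.label in CLASSES for c in labeled)

    def test_library_cart_crops_mostly_labeled_cart(self, trained_model, small_library):
        _, test = small_library
        cart = [cand for cand, cls in test if cls == "CART"]
        _, counts = classify(trained_model, cart)
        assert counts["CART"] / len(cart) >= 0.85

    def test_feature_length_mismatch_rejected(self, trained_model):
        with pytest.raises(ValueError):
            trained_model.predict(np.zeros((1, 3)))


class TestSerialization:
    def test_roundtrip_predictions_identical(self, tmp_path, trained_model, small_library):
        _, test = small_library
        X = np.array([cand.features for cand, _ in test])
        path = tmp_path / "model.bin"
        save_model(trained_model, path)
        back = load_model(path)
        assert back.feature_names == trained_model.feature_names
        assert np.array_equal(back.predict(X), trained_model.predict(X))
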