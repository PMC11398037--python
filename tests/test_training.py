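"""Training loop, splits and evaluation metrics vs independent oracles."""

import numpy as np
import pytest

from pathgait.nn.model import ModelConfig, build_model
from pathgait.training import (ConfusionMatrix, TrainConfig,
                               confusion_from_predictions, metrics_from_confusion,
                               split_indices, train)

CLASSES5 = ["a", "b", "c", "d", "e"]


def metrics_oracle(y_true, y_pred, n_classes):
    """Per-sample brute-force evaluation of the five metrics (percent)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    n = len(y_true)
    acc = 100.0 * np.mean(y_true == y_pred)
    prec, sens, spec, f1 = [], [], [], []
    for c in range(n_classes):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = n - tp - fp - fn
        p_c = tp / (tp + fp) if tp + fp else 0.0
        s_c = tp / (tp + fn) if tp + fn else 0.0
        sp_c = tn / (tn + fp) if tn + fp else 0.0
        f_c = 2 * p_c * s_c / (p_c + s_c) if p_c + s_c else 0.0
        prec.append(p_c), sens.append(s_c), spec.append(sp_c), f1.append(f_c)
    return (acc, 100 * np.mean(prec), 100 * np.mean(sens),
            100 * np.mean(spec), 100 * np.mean(f1))


def test_split_is_stratified_and_exhaustive():
    labels = np.repeat(np.arange(5), 20)
    tr, te = split_indices(labels, 0.2, seed=0)
    assert len(tr) == 80 and len(te) == 20
    for c in range(5):
        assert (labels[te] == c).sum() == 4
        assert (labels[tr] == c).sum() == 16
    assert np.array_equal(np.sort(np.concatenate([tr, te])), np.arange(100))


def test_split_seeded_determinism_and_disjointness():
    labels = np.repeat(np.arange(3), 11)
    a = split_indices(labels, 0.2, seed=42)
    b = split_indices(labels, 0.2, seed=42)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    assert not set(a[0]) & set(a[1])


def test_split_rejects_tiny_class():
    with pytest.raises(ValueError, match="fewer than 2"):
        split_indices(np.array([0, 0, 1]), 0.2, seed=0)


def test_confusion_matrix_examples():
    perfect = confusion_from_predictions([0, 1, 2, 3, 4], [0, 1, 2, 3, 4], CLASSES5)
    assert np.array_equal(perfect.counts, np.eye(5, dtype=int))
    constant = confusion_from_predictions([0, 1, 2, 3, 4], [2] * 5, CLASSES5)
    assert constant.counts[:, 2].sum() == 5
    assert constant.counts.sum() == 5


def test_confusion_matches_per_sample_loop(rng):
    y_true = rng.integers(0, 5, size=20)
    y_pred = rng.integers(0, 5, size=20)
    cm = confusion_from_predictions(y_true, y_pred, CLASSES5)
    for i in range(5):
        for j in range(5):
            expected = sum(1 for t, p in zip(y_true, y_pred) if t == i and p == j)
            assert cm.counts[i, j] == expected


def test_perfect_predictor_scores_100_everywhere():
    cm = ConfusionMatrix(np.eye(5, dtype=int) * 7, CLASSES5)
    rep = metrics_from_confusion(cm)
    for v in (rep.accuracy, rep.macro_precision, rep.macro_sensitivity,
              rep.macro_specificity, rep.macro_f1):
        assert v == 100.0


def test_all_wrong_predictor_scores_0_accuracy():
    counts = np.zeros((3, 3), dtype=int)
    counts[0, 1] = counts[1, 2] = counts[2, 0] = 5
    rep = metrics_from_confusion(ConfusionMatrix(counts, ["a", "b", "c"]))
    assert rep.accuracy == 0.0


def test_two_class_hand_computed_metrics():
    """[[8,2],[1,9]]: accuracy 85%, class-0 precision 8/9, sensitivity 8/10."""
    cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ["pos", "neg"])
    rep = metrics_from_confusion(cm)
    assert rep.accuracy == pytest.approx(85.0)
    assert rep.per_class["pos"]["precision"] == pytest.approx(100 * 8 / 9)
    assert rep.per_class["pos"]["sensitivity"] == pytest.approx(80.0)
    assert rep.per_class["pos"]["specificity"] == pytest.approx(90.0)
    p0, s0 = 8 / 9, 8 / 10
    p1, s1 = 9 / 11, 9 / 10
    assert rep.macro_precision == pytest.approx(100 * (p0 + p1) / 2)
    assert rep.macro_f1 == pytest.approx(
        100 * (2 * p0 * s0 / (p0 + s0) + 2 * p1 * s1 / (p1 + s1)) / 2)


def test_metrics_match_brute_force_on_random_vectors(rng):
    for _ in range(5):
        n = int(rng.integers(10, 100))
        y_true = rng.integers(0, 5, size=n)
        y_pred = rng.integers(0, 5, size=n)
        cm = confusion_from_predictions(y_true, y_pred, CLASSES5)
        rep = metrics_from_confusion(cm)
        acc, prec, sens, spec, f1 = metrics_oracle(y_true, y_pred, 5)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.macro_precision == pytest.approx(prec)
        assert rep.macro_sensitivity == pytest.approx(sens)
        assert rep.macro_specificity == pytest.approx(spec)
        assert rep.macro_f1 == pytest.approx(f1)


def test_metrics_agree_with_sklearn(rng):
    from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                                 recall_score)
    y_true = rng.integers(0, 5, size=60)
    y_pred = rng.integers(0, 5, size=60)
    cm = confusion_from_predictions(y_true, y_pred, CLASSES5)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = metrics_from_confusion(cm)
        assert rep.accuracy == pytest.approx(100 * accuracy_score(y_true, y_pred))
        assert rep.macro_precision == pytest.approx(
            100 * precision_score(y_true, y_pred, average="macro", zero_division=0))
        assert rep.macro_sensitivity == pytest.approx(
            100 * recall_score(y_true, y_pred, average="macro", zero_division=0))
        assert rep.macro_f1 == pytest.approx(
            100 * f1_score(y_true, y_pred, average="macro"), abs=1e-6)


def test_zero_denominator_class_warns():
    counts = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
    with pytest.warns(UserWarning, match="zero denominator"):
        rep = metrics_from_confusion(ConfusionMatrix(counts, ["a", "b", "c"]))
    assert rep.per_class["c"]["sensitivity"] == 0.0


def test_empty_confusion_matrix_rejected():
    with pytest.raises(ValueError, match="empty"):
        metrics_from_confusion(ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"]))


@pytest.fixture(scope="module")
def tiny_model():
    """Smallest legal input (32x32 -> 1x1 features) keeps training tests fast."""
    return build_model(ModelConfig(input_size=32, freeze_backbone=True, seed=0))


def test_zero_learning_rate_changes_nothing(tiny_model, rng):
    X = rng.random((8, 1, 32, 32))
    y = rng.integers(0, 5, size=8)
    before = [p.data.copy() for p in tiny_model.parameters()]
    train(tiny_model, (X, y), TrainConfig(learning_rate=0.0, epochs=1, seed=0))
    for b, p in zip(before, tiny_model.parameters()):
        assert np.array_equal(b, p.data)


def test_loss_decreases_on_single_class_batch(rng):
    model = build_model(ModelConfig(input_size=32, freeze_backbone=True, seed=1))
    X = np.repeat(rng.random((1, 1, 32, 32)), 32, axis=0)
    y = np.zeros(32, dtype=int)
    hist = train(model, (X, y), TrainConfig(learning_rate=1e-3, epochs=5, seed=1))
    assert hist.loss[-1] < hist.loss[0]


def test_training_is_reproducible(rng):
    X = rng.random((10, 1, 32, 32))
    y = rng.integers(0, 5, size=10)
    histories = []
    for _ in range(2):
        model = build_model(ModelConfig(input_size=32, freeze_backbone=True, seed=9))
        histories.append(train(model, (X, y),
                               TrainConfig(learning_rate=1e-3, epochs=3, seed=9)))
    assert histories[0].loss == histories[1].loss
    assert histories[0].accuracy == histories[1].accuracy


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(test_fraction=0.0)
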