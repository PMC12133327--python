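"""Tests for the block classifier: taps, training contract, persistence."""

from __future__ import annotations

import numpy as np
import pytest

from judicam.models import (
    ClassifierConfig,
    TrainedClassifier,
    _build_net,
    extract_activations,
    load_classifier,
    predict_scores,
    save_classifier,
    train_classifier,
)
from judicam.synthetic_data import generate_dataset, split_dataset


@pytest.fixture(scope="module")
def tiny_splits():
    samples = generate_dataset(12, 12, side=32, difficulty="easy", seed=1)
    return split_dataset(samples, fractions=(0.5, 0.25, 0.25), seed=1)


@pytest.fixture(scope="module")
def tiny_model(tiny_splits):
    return train_classifier(tiny_splits, ClassifierConfig(epochs=2, batch_size=4, seed=1))


def test_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(n_blocks=3, channels=(8, 16, 32))
    with pytest.raises(ValueError):
        ClassifierConfig(channels=(8, 16, 32))  # wrong length
    with pytest.raises(ValueError):
        ClassifierConfig(objective="f1")
    with pytest.raises(ValueError):
        ClassifierConfig(class_weights=(-1.0, 1.0))


def test_tap_shapes_and_gradient(tiny_model):
    image = np.random.default_rng(0).uniform(size=(32, 32))
    acts3, grad3 = tiny_model.activations_and_gradient(image, "AM3", 1)
    acts4, grad4 = tiny_model.activations_and_gradient(image, "AM4", 1)
    assert acts3.shape == grad3.shape == (32, 4, 4)
    assert acts4.shape == grad4.shape == (32, 2, 2)
    with pytest.raises(ValueError):
        tiny_model.activations_and_gradient(image, "AM5", 1)


def test_gradient_matches_finite_differences_of_class_score(tiny_model):
    image = np.random.default_rng(1).uniform(size=(32, 32))
    acts, grad = tiny_model.activations_and_gradient(image, "AM4", 1)
    rng = np.random.default_rng(2)
    for _ in range(5):
        idx = tuple(rng.integers(0, s) for s in acts.shape)
        eps = 1e-6
        up, down = acts.copy(), acts.copy()
        up[idx] += eps
        down[idx] -= eps
        num = (tiny_model.forward_from("AM4", up)[1] - tiny_model.forward_from("AM4", down)[1]) / (2 * eps)
        assert np.isclose(grad[idx], num, atol=1e-6)


def test_gap_head_gradient_is_spatially_constant(tiny_model):
    """ds_c/dA at the head-feeding block equals W[c, k] / (h*w) per channel."""
    image = np.random.default_rng(3).uniform(size=(32, 32))
    _, grad = tiny_model.activations_and_gradient(image, "AM4", 1)
    per_channel_std = grad.std(axis=(1, 2))
    assert np.all(per_channel_std < 1e-12)


def test_forward_from_composes_with_tap(tiny_model):
    image = np.random.default_rng(4).uniform(size=(32, 32))
    full = tiny_model.logits(image[None])[0]
    acts, _ = tiny_model.activations_and_gradient(image, "AM3", 0)
    assert np.allclose(tiny_model.forward_from("AM3", acts), full, atol=1e-10)


def test_predict_scores_and_extract_activations(tiny_model):
    image = np.random.default_rng(5).uniform(size=(32, 32))
    scores, conf = predict_scores(tiny_model, image)
    assert scores.shape == (2,) and np.isclose(conf.sum(), 1.0)
    acts, gradient_hook = extract_activations(tiny_model, image, "AM4")
    grad = gradient_hook(1)
    assert acts.shape == grad.shape


def test_image_validation(tiny_model):
    with pytest.raises(ValueError):
        tiny_model.activations_and_gradient(np.zeros((8, 8)), "AM4", 1)  # too small
    bad = np.zeros((32, 32))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        predict_scores(tiny_model, bad)


def test_training_is_deterministic_and_requires_both_classes(tiny_splits):
    cfg = ClassifierConfig(epochs=1, batch_size=4, seed=3)
    m1 = train_classifier(tiny_splits, cfg)
    m2 = train_classifier(tiny_splits, cfg)
    for p1, p2 in zip(m1.net.params, m2.net.params):
        assert np.array_equal(p1, p2)
    only_pos = {k: [s for s in v if s.label == 1] for k, v in tiny_splits.items()}
    with pytest.raises(ValueError):
        train_classifier(only_pos, cfg)


def test_checkpoint_selection_maximises_objective(tiny_splits):
    model = train_classifier(tiny_splits, ClassifierConfig(epochs=3, batch_size=4, seed=5, objective="sensitivity"))
    best = model.training_report[model.selected_epoch]
    for row in model.training_report:
        assert row["val_sensitivity"] <= best["val_sensitivity"] + 1e-12


def test_save_load_roundtrip(tmp_path, tiny_model):
    path = tmp_path / "model.pkl"
    save_classifier(tiny_model, path)
    loaded = load_classifier(path)
    image = np.random.default_rng(6).uniform(size=(32, 32))
    assert np.allclose(loaded.logits(image[None]), tiny_model.logits(image[None]))
    assert loaded.selected_epoch == tiny_model.selected_epoch


def test_untrained_net_has_expected_tap_indices():
    config = ClassifierConfig()
    model = TrainedClassifier(_build_net(config), config)
    assert model.tap_index == {"AM3": 9, "AM4": 12}
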