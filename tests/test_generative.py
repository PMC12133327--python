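"""Tests for the map-generating autoencoders and their training losses."""

from __future__ import annotations

import numpy as np
import pytest

from judicam.cam_algorithms import postprocess
from judicam.generative import (
    AutoencoderConfig,
    MapAutoencoder,
    _direction_gradient,
    _normalize_backward,
    _normalize_forward,
    ae_predict,
    load_autoencoder,
    save_autoencoder,
    train_autoencoder,
)


def _toy_problem(n=12, c=4, side=8, seed=0):
    """Feature tensors plus teacher maps that are a fixed projection of them."""
    rng = np.random.default_rng(seed)
    feats, teachers = [], []
    w = rng.uniform(0.5, 1.0, size=c)
    for _ in range(n):
        f = np.abs(rng.normal(size=(c, side, side)))
        raw = np.tensordot(w, f, axes=1)
        teachers.append(postprocess(raw, (side * 8, side * 8), polarity="positive", level="AM3", algorithm="hirescam"))
        feats.append(f)
    return feats, teachers


def test_config_validation():
    with pytest.raises(ValueError):
        AutoencoderConfig(level="AM5")
    with pytest.raises(ValueError):
        AutoencoderConfig(polarity="both")
    with pytest.raises(ValueError):
        AutoencoderConfig(epochs=0)
    with pytest.raises(ValueError):
        AutoencoderConfig(polish_fraction=1.5)


def test_normalized_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(7)
    out = rng.normal(size=(3, 5, 5))
    y = np.maximum(rng.normal(size=(3, 5, 5)), 0)
    y /= y.reshape(3, -1).max(axis=1)[:, None, None]

    def loss(o):
        norm, _ = _normalize_forward(o)
        return float(((norm - y) ** 2).mean())

    norm, cache = _normalize_forward(out)
    resid = norm - y
    grad = _normalize_backward(2.0 * resid / resid.size, cache)
    eps = 1e-6
    rng2 = np.random.default_rng(8)
    for _ in range(20):
        idx = tuple(rng2.integers(0, s) for s in out.shape)
        if abs(out[idx]) < 1e-4:
            continue  # skip the ReLU kink
        up, down = out.copy(), out.copy()
        up[idx] += eps
        down[idx] -= eps
        assert np.isclose(grad[idx], (loss(up) - loss(down)) / (2 * eps), atol=1e-6)


def test_direction_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(9)
    out = rng.normal(size=(2, 6, 6))
    y = np.maximum(rng.normal(size=(2, 6, 6)), 0)
    yu = y / np.linalg.norm(y.reshape(2, -1), axis=1)[:, None, None]
    _, grad = _direction_gradient(out, yu)
    eps = 1e-6
    rng2 = np.random.default_rng(10)
    for _ in range(20):
        idx = tuple(rng2.integers(0, s) for s in out.shape)
        if abs(out[idx]) < 1e-4:
            continue
        up, down = out.copy(), out.copy()
        up[idx] += eps
        down[idx] -= eps
        num = (_direction_gradient(up, yu)[0] - _direction_gradient(down, yu)[0]) / (2 * eps) / out.size
        assert np.isclose(grad[idx], num, atol=1e-6)


def test_direction_loss_is_scale_invariant():
    rng = np.random.default_rng(11)
    out = np.abs(rng.normal(size=(2, 4, 4)))
    yu = out / np.linalg.norm(out.reshape(2, -1), axis=1)[:, None, None]
    sse, _ = _direction_gradient(5.0 * out, yu)
    assert sse < 1e-20  # any positive rescaling of a perfect map has zero loss


def test_training_fits_an_easy_linear_teacher():
    feats, teachers = _toy_problem()
    config = AutoencoderConfig(level="AM3", polarity="positive", epochs=120, batch_size=6, seed=0)
    ae, report = train_autoencoder(feats, teachers, config)
    assert report.train_mse < 1e-2
    assert report.epoch_mse[-1] < report.epoch_mse[0]


def test_training_is_deterministic():
    feats, teachers = _toy_problem()
    config = AutoencoderConfig(level="AM3", polarity="positive", epochs=5, batch_size=6, seed=4)
    ae1, r1 = train_autoencoder(feats, teachers, config)
    ae2, r2 = train_autoencoder(feats, teachers, config)
    assert r1.epoch_mse == r2.epoch_mse
    for p1, p2 in zip(ae1.params, ae2.params):
        assert np.array_equal(p1, p2)


def test_training_validates_inputs():
    feats, teachers = _toy_problem()
    config = AutoencoderConfig(level="AM3", polarity="positive", epochs=1)
    with pytest.raises(ValueError):
        train_autoencoder([], [], config)
    with pytest.raises(ValueError):
        train_autoencoder(feats, teachers[:-1], config)
    wrong = AutoencoderConfig(level="AM3", polarity="negative", epochs=1)
    with pytest.raises(ValueError):
        train_autoencoder(feats, teachers, wrong)  # polarity mismatch with teachers


def test_full_resolution_loss_requires_power_of_two_factor():
    feats, teachers = _toy_problem(side=8)
    config = AutoencoderConfig(level="AM3", polarity="positive", epochs=1, full_resolution_loss=True)
    ae, report = train_autoencoder(feats, teachers, config)  # 64 = 8 * 2^3: fine
    assert np.isfinite(report.train_mse)


def test_predict_and_postprocessing_shapes():
    feats, teachers = _toy_problem()
    config = AutoencoderConfig(level="AM3", polarity="positive", epochs=2, seed=1)
    ae, _ = train_autoencoder(feats, teachers, config)
    smap = ae_predict(ae, feats[0], target_shape=(64, 64))
    assert smap.values.shape == (64, 64)
    assert smap.polarity == "positive" and smap.level == "AM3" and smap.algorithm == "generative"
    assert 0.0 <= smap.values.min() and smap.values.max() <= 1.0
    with pytest.raises(ValueError):
        ae.predict_raw(np.zeros((2, 8, 8)))  # wrong channel count


def test_save_load_roundtrip_preserves_standardization(tmp_path):
    feats, teachers = _toy_problem()
    config = AutoencoderConfig(level="AM3", polarity="positive", epochs=2, seed=2)
    ae, _ = train_autoencoder(feats, teachers, config)
    path = tmp_path / "ae.pkl"
    save_autoencoder(ae, path)
    loaded = load_autoencoder(path)
    assert np.array_equal(loaded.feature_mean, ae.feature_mean)
    assert np.allclose(loaded.predict_raw(feats[0]), ae.predict_raw(feats[0]))


def test_autoencoder_rejects_tiny_feature_maps():
    with pytest.raises(ValueError):
        MapAutoencoder(4, (2, 2), AutoencoderConfig())
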