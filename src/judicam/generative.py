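"""Autoencoders that generate class activation maps from feature tensors.

Each autoencoder is trained, one per (polarity, level) pair, by supervised
regression: given the classifier's activation tensor at a level, predict
the saliency map that the single-model pipeline would produce for that
image, with mean squared error as the loss. The loss is computed against
the teacher map at its native (pre-upsampling) resolution by default, so
that interpolation artifacts do not dominate; a config flag switches to
full-resolution targets.

Architecture: feature tensors are standardised per channel (training-set
statistics, stored with the model); a two-conv full-resolution stem
extracts local detail; a pool-conv encoder compresses to a bottleneck
carrying global context (CAMs are normalised per image); a resize-conv
decoder (nearest upsample + conv) expands back and is summed with the
stem before a 1-channel head.

Optimisation: teacher maps are max-normalised, so the fit only has to be
right up to a positive scale. Training therefore uses a scale-invariant
loss in two phases: a smooth L2-direction loss (MSE between the
L2-normalised prediction and the L2-normalised teacher) for most epochs,
then a short polish phase on the max-normalised MSE, which is the
reported metric. The direction loss avoids the sharp argmax subgradient
of max normalisation, which otherwise traps a noticeable fraction of
random initialisations in poor basins.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import SGD, Adam, AvgPool2, Conv3x3, LeakyReLU, Sequential, Upsample2
from .cam_algorithms import SaliencyMap, postprocess

__all__ = [
    "AutoencoderConfig",
    "AeTrainingReport",
    "MapAutoencoder",
    "train_autoencoder",
    "ae_predict",
    "save_autoencoder",
    "load_autoencoder",
]


@dataclass
class AutoencoderConfig:
    """Configuration for one map-generating autoencoder."""

    level: str = "AM4"  # "AM3" | "AM4"
    polarity: str = "positive"  # "positive" | "negative"
    latent_width: int = 48
    epochs: int = 500
    batch_size: int = 32
    learning_rate: float = 3e-3
    final_lr_fraction: float = 0.02  # linear per-epoch decay to this fraction
    polish_fraction: float = 0.2  # trailing fraction of epochs on the max-normalised loss
    optimizer: str = "adam"  # "adam" | "sgd"
    full_resolution_loss: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.level not in ("AM3", "AM4"):
            raise ValueError(f"unknown level: {self.level!r}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity: {self.polarity!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer: {self.optimizer!r}")
        if not 0.0 <= self.polish_fraction <= 1.0:
            raise ValueError("polish_fraction must be in [0, 1]")


@dataclass
class AeTrainingReport:
    """Per-epoch training loss plus final three-split MSEs.

    ``epoch_mse`` follows the loss in use that epoch (direction loss, then
    max-normalised MSE in the polish phase); the three split MSEs are always
    measured on the max-normalised scale.
    """

    epoch_mse: list[float] = field(default_factory=list)
    train_mse: float = float("nan")
    validation_mse: float = float("nan")
    test_mse: float = float("nan")


class MapAutoencoder:
    """Encoder/decoder mapping a (C, h, w) feature tensor to an (h, w) map.

    Inputs are standardised with stored per-channel statistics. A
    full-resolution two-conv stem extracts local detail; a two-stage
    pool-conv encoder compresses to a bottleneck that carries global
    context (needed because CAMs are normalised per image); the
    resize-conv decoder expands back and is summed with the stem before
    the 1-channel head.
    """

    def __init__(self, in_channels: int, in_shape: tuple[int, int], config: AutoencoderConfig):
        if min(in_shape) < 4:
            raise ValueError("feature maps must be at least 4x4 for two pooling stages")
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
        mid = max(8, config.latent_width // 2)
        latent = config.latent_width
        self.feature_mean = np.zeros(in_channels)
        self.feature_std = np.ones(in_channels)
        self.stem = Sequential([Conv3x3(in_channels, mid, rng), LeakyReLU(), Conv3x3(mid, mid, rng), LeakyReLU()])
        self.down_up = Sequential(
            [
                AvgPool2(),
                Conv3x3(mid, latent, rng),
                LeakyReLU(),
                AvgPool2(),
                Conv3x3(latent, latent, rng),
                LeakyReLU(),
                Upsample2(),
                Conv3x3(latent, mid, rng),
                LeakyReLU(),
                Upsample2(),
            ]
        )
        self.head = Sequential([Conv3x3(mid, 1, rng)])
        self.in_channels = in_channels
        self.in_shape = tuple(in_shape)
        self.config = config

    @property
    def params(self) -> list[np.ndarray]:
        return self.stem.params + self.down_up.params + self.head.params

    def set_params(self, values: list[np.ndarray]) -> None:
        n1 = len(self.stem.params)
        n2 = len(self.down_up.params)
        self.stem.set_params(values[:n1])
        self.down_up.set_params(values[n1 : n1 + n2])
        self.head.set_params(values[n1 + n2 :])

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_mean[None, :, None, None]) / self.feature_std[None, :, None, None]

    def forward(self, x: np.ndarray):
        s, c_stem = self.stem.forward(x)
        d, c_down = self.down_up.forward(s)
        out, c_head = self.head.forward(s + d)
        return out, (c_stem, c_down, c_head)

    def backward(self, dout: np.ndarray, caches):
        c_stem, c_down, c_head = caches
        dsum, g_head = self.head.backward(dout, c_head)
        ds_branch, g_down = self.down_up.backward(dsum, c_down)
        _, g_stem = self.stem.backward(dsum + ds_branch, c_stem)
        return g_stem + g_down + g_head

    def predict_raw(self, features: np.ndarray) -> np.ndarray:
        """Raw (unnormalised) map for one feature tensor."""
        features = np.asarray(features, dtype=float)
        if features.shape != (self.in_channels, *self.in_shape):
            raise ValueError(
                f"feature tensor shape {features.shape} does not match the "
                f"trained level ({(self.in_channels, *self.in_shape)})"
            )
        out, _ = self.forward(self.standardize(features[None]))
        return out[0, 0]


def _normalize_forward(out: np.ndarray) -> tuple[np.ndarray, tuple]:
    """ReLU + divide by the per-sample spatial maximum, like a CAM.

    The loss compares maps on the same [0, 1] scale the teacher uses, so
    the decoder only has to learn the map's shape up to a positive scale.
    Returns the normalised batch and a cache for the exact backward pass.
    """
    r = np.maximum(out, 0.0)
    n = r.shape[0]
    flat = r.reshape(n, -1)
    m = flat.max(axis=1)
    safe = m > 1e-12
    denom = np.where(safe, m, 1.0)
    norm = r / denom[:, None, None]
    return norm, (out, r, flat.argmax(axis=1), m, safe)


def _normalize_backward(dnorm: np.ndarray, cache: tuple) -> np.ndarray:
    out, r, imax, m, safe = cache
    n = r.shape[0]
    denom = np.where(safe, m, 1.0)
    dr = dnorm / denom[:, None, None]
    # subgradient through the per-sample maximum (first-argmax convention)
    dot = (dnorm * r).reshape(n, -1).sum(axis=1)
    dr_flat = dr.reshape(n, -1)
    rows = np.arange(n)[safe]
    dr_flat[rows, imax[safe]] -= dot[safe] / (m[safe] ** 2)
    dout = dr_flat.reshape(r.shape) * (out > 0.0)
    # a sample whose map is entirely rectified away would otherwise send no
    # gradient at all (dead output); fall back to the raw residual there
    dout[~safe] = dnorm[~safe]
    return dout


def _direction_gradient(out: np.ndarray, unit_targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Sum of squared errors between L2-normalised output and unit targets,
    plus the exact gradient with respect to the raw output.

    Smooth everywhere the rectified output is non-zero (unlike the
    max-normalised loss, whose argmax pivot has a sharp subgradient).
    """
    r = np.maximum(out, 0.0)
    n = r.shape[0]
    norms = np.linalg.norm(r.reshape(n, -1), axis=1)
    safe = norms > 1e-12
    denom = np.where(safe, norms, 1.0)
    u = r / denom[:, None, None]
    resid = u - unit_targets
    dresid = 2.0 * resid / resid.size
    # d(u)/d(r) = (I - u u^T) / ||r||
    dot = (dresid * u).reshape(n, -1).sum(axis=1)
    dr = (dresid - u * dot[:, None, None]) / denom[:, None, None]
    dout = dr * (out > 0.0)
    # dead samples fall back to the raw residual so they recover gradient
    dout[~safe] = dresid[~safe]
    return float((resid**2).sum()), dout


def _teacher_targets(teacher_maps: list[SaliencyMap], config: AutoencoderConfig, feature_shape: tuple[int, int]) -> np.ndarray:
    targets = []
    for tm in teacher_maps:
        if tm.polarity != config.polarity or tm.level != config.level:
            raise ValueError("teacher map polarity/level does not match the autoencoder config")
        if config.full_resolution_loss or tm.native_values is None:
            targets.append(tm.values)
        else:
            targets.append(tm.native_values)
    targets = np.stack(targets).astype(float)
    if not config.full_resolution_loss and targets.shape[1:] != feature_shape:
        raise ValueError("teacher native resolution does not match the feature level")
    return targets


def train_autoencoder(
    features: list[np.ndarray],
    teacher_maps: list[SaliencyMap],
    config: AutoencoderConfig,
    validation: tuple[list[np.ndarray], list[SaliencyMap]] | None = None,
    test: tuple[list[np.ndarray], list[SaliencyMap]] | None = None,
) -> tuple[MapAutoencoder, AeTrainingReport]:
    """Fit an autoencoder to reproduce teacher maps from feature tensors.

    Deterministic under a fixed config seed. The report carries the
    per-epoch training MSE and the final MSE on each provided split.
    """
    if len(features) == 0:
        raise ValueError("empty training set")
    if len(features) != len(teacher_maps):
        raise ValueError("one teacher map per feature tensor required")
    x = np.stack([np.asarray(f, dtype=float) for f in features])
    ae = MapAutoencoder(x.shape[1], x.shape[2:], config)
    ae.feature_mean = x.mean(axis=(0, 2, 3))
    ae.feature_std = np.maximum(x.std(axis=(0, 2, 3)), 1e-8)
    x = ae.standardize(x)
    y = _teacher_targets(teacher_maps, config, x.shape[2:])
    y_unit = y / np.maximum(np.linalg.norm(y.reshape(len(y), -1), axis=1), 1e-12)[:, None, None]
    # with full-resolution loss the decoder output is expanded to the
    # teacher resolution by stateless nearest-neighbour doubling layers
    up = Sequential([])
    if config.full_resolution_loss:
        factor = y.shape[1] // x.shape[2]
        if factor < 1 or factor & (factor - 1) or y.shape[1:] != (x.shape[2] * factor, x.shape[3] * factor):
            raise ValueError("full-resolution loss requires the teacher shape to be a power-of-two multiple of the feature shape")
        up = Sequential([Upsample2() for _ in range(factor.bit_length() - 1)])

    opt_cls = Adam if config.optimizer == "adam" else SGD
    opt = opt_cls(ae.params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    n = len(x)
    polish_start = int(round(config.epochs * (1.0 - config.polish_fraction)))
    report = AeTrainingReport()
    for epoch in range(config.epochs):
        frac = epoch / max(1, config.epochs - 1)
        opt.lr = config.learning_rate * (1.0 - (1.0 - config.final_lr_fraction) * frac)
        order = rng.permutation(n)
        sse = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x[idx]
            out, caches = ae.forward(xb)
            out, up_caches = up.forward(out)
            if epoch < polish_start:
                batch_sse, dout = _direction_gradient(out[:, 0], y_unit[idx])
            else:
                norm, norm_cache = _normalize_forward(out[:, 0])
                resid = norm - y[idx]
                batch_sse = float((resid**2).sum())
                dout = _normalize_backward(2.0 * resid / resid.size, norm_cache)
            sse += batch_sse
            dout, _ = up.backward(dout[:, None], up_caches)
            grads = ae.backward(dout, caches)
            opt.step(grads)
        report.epoch_mse.append(sse / y.size)

    def split_mse(feats: list[np.ndarray], teachers: list[SaliencyMap]) -> float:
        xt = ae.standardize(np.stack([np.asarray(f, dtype=float) for f in feats]))
        yt = _teacher_targets(teachers, config, xt.shape[2:])
        out, _ = ae.forward(xt)
        out, _ = up.forward(out)
        norm, _ = _normalize_forward(out[:, 0])
        return float(((norm - yt) ** 2).mean())

    report.train_mse = split_mse(features, teacher_maps)
    if validation is not None:
        report.validation_mse = split_mse(*validation)
    if test is not None:
        report.test_mse = split_mse(*test)
    return ae, report


def ae_predict(ae: MapAutoencoder, features: np.ndarray, target_shape: tuple[int, int] | None = None) -> SaliencyMap:
    """Generate a saliency map from a feature tensor with a trained AE.

    The raw decoder output is post-processed exactly like a CAM (ReLU,
    bilinear upsample to ``target_shape``, min-max normalisation).
    """
    raw = ae.predict_raw(features)
    if target_shape is None:
        scale = 8 if ae.config.level == "AM3" else 16
        target_shape = (raw.shape[0] * scale, raw.shape[1] * scale)
    return postprocess(raw, target_shape, polarity=ae.config.polarity, level=ae.config.level, algorithm="generative")


def save_autoencoder(ae: MapAutoencoder, path: str | Path) -> None:
    payload = {
        "config": ae.config,
        "in_channels": ae.in_channels,
        "in_shape": ae.in_shape,
        "feature_mean": ae.feature_mean.copy(),
        "feature_std": ae.feature_std.copy(),
        "params": [p.copy() for p in ae.params],
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_autoencoder(path: str | Path) -> MapAutoencoder:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    ae = MapAutoencoder(payload["in_channels"], payload["in_shape"], payload["config"])
    ae.set_params(payload["params"])
    ae.feature_mean = payload["feature_mean"]
    ae.feature_std = payload["feature_std"]
    return ae
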