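"""Block-structured binary classifier with exposed intermediate feature levels.

A miniature stand-in for the large residual backbones used in fracture
detection: four convolution blocks (conv3x3 -> ReLU -> 2x2 max pool),
global average pooling and a two-neuron linear head. The outputs of the
third and fourth blocks are exposed as the AM3 (fine-grained) and AM4
(high-level) feature levels from which class activation maps are computed.

Training uses class-weighted cross-entropy; the returned checkpoint is the
epoch whose validation metric (accuracy, sensitivity or specificity —
whichever the config names as the objective) is highest, with ties broken
by higher accuracy and then by the earlier epoch. Sensitivity- and
specificity-optimised variants are obtained by combining class weights
that favour one class with objective-based checkpoint selection.
"""

from __future__ import annotations

import copy
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import SGD, Adam, Conv3x3, GlobalAvgPool, Linear, MaxPool2, ReLU, Sequential, softmax

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "train_classifier",
    "predict_scores",
    "extract_activations",
    "save_classifier",
    "load_classifier",
]

LEVELS = ("AM3", "AM4")


@dataclass
class ClassifierConfig:
    """Training configuration for the miniature block classifier."""

    n_blocks: int = 4
    channels: tuple[int, ...] = (8, 16, 32, 32)
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 3e-3
    optimizer: str = "adam"  # "adam" | "sgd"
    objective: str = "accuracy"  # "accuracy" | "sensitivity" | "specificity"
    class_weights: tuple[float, float] = (1.0, 1.0)  # (negative, positive)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 4:
            raise ValueError("n_blocks must be >= 4 (AM3/AM4 need blocks 3 and 4)")
        if len(self.channels) != self.n_blocks:
            raise ValueError("one channel count per block required")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.objective not in ("accuracy", "sensitivity", "specificity"):
            raise ValueError(f"unknown objective: {self.objective!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer: {self.optimizer!r}")
        if min(self.class_weights) < 0:
            raise ValueError("class weights must be non-negative")


class TrainedClassifier:
    """A trained block CNN with named access to block outputs ("taps").

    ``net`` is the full layer stack; ``tap_index[level]`` is the number of
    leading layers whose output is that level's activation tensor.
    """

    def __init__(self, net: Sequential, config: ClassifierConfig, training_report: list[dict] | None = None, selected_epoch: int | None = None):
        self.net = net
        self.config = config
        self.training_report = training_report or []
        self.selected_epoch = selected_epoch
        # blocks are (conv, relu, pool) triples followed by GAP and the head
        self.tap_index = {"AM3": 9, "AM4": 3 * config.n_blocks}

    # -- forward passes ------------------------------------------------
    def _check_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("expected a single 2-D grayscale image")
        if not np.all(np.isfinite(image)):
            raise ValueError("image contains non-finite pixels")
        min_side = 2 ** self.config.n_blocks
        if min(image.shape) < min_side:
            raise ValueError(f"image smaller than the model minimum ({min_side})")
        return image

    def logits(self, images: np.ndarray) -> np.ndarray:
        """Class scores for a batch shaped (N, H, W)."""
        x = np.asarray(images, dtype=float)[:, None]
        out, _ = self.net.forward(x)
        return out

    def forward_from(self, level: str, activations: np.ndarray) -> np.ndarray:
        """Class scores computed from a tap activation tensor (C, h, w)."""
        if level not in self.tap_index:
            raise ValueError(f"unknown level: {level!r}")
        out, _ = self.net.forward(activations[None], start=self.tap_index[level])
        return out[0]

    def activations_and_gradient(self, image: np.ndarray, level: str, class_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Tap activations A (C, h, w) and the gradient ds_c/dA."""
        if level not in self.tap_index:
            raise ValueError(f"unknown level: {level!r}")
        image = self._check_image(image)
        idx = self.tap_index[level]
        x = image[None, None]
        acts, _ = self.net.forward(x, stop=idx)
        out, caches = self.net.forward(acts, start=idx)
        dy = np.zeros_like(out)
        dy[0, class_index] = 1.0
        dacts, _ = self.net.backward(dy, caches, start=idx)
        return acts[0], dacts[0]


def predict_scores(model: TrainedClassifier, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw class scores and softmax confidences (sum to 1) for one image."""
    image = model._check_image(image)
    scores = model.logits(image[None])[0]
    return scores, softmax(scores)


def extract_activations(model: TrainedClassifier, image: np.ndarray, level: str):
    """Tap activations at ``level`` plus a hook giving ds_c/dA for class c."""
    image = model._check_image(image)
    if level not in model.tap_index:
        raise ValueError(f"unknown level: {level!r}")
    acts, _ = model.net.forward(image[None, None], stop=model.tap_index[level])

    def gradient(class_index: int) -> np.ndarray:
        _, grad = model.activations_and_gradient(image, level, class_index)
        return grad

    return acts[0], gradient


def _build_net(config: ClassifierConfig) -> Sequential:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    layers: list = []
    c_in = 1
    for c_out in config.channels:
        layers += [Conv3x3(c_in, c_out, rng), ReLU(), MaxPool2()]
        c_in = c_out
    layers += [GlobalAvgPool(), Linear(c_in, 2, rng)]
    return Sequential(layers)


def _split_metrics(model_net: Sequential, images: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    out, _ = model_net.forward(images[:, None])
    pred = out.argmax(axis=1)
    pos = labels == 1
    neg = labels == 0
    sens = float((pred[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((pred[neg] == 0).mean()) if neg.any() else float("nan")
    return {
        "accuracy": float((pred == labels).mean()),
        "sensitivity": sens,
        "specificity": spec,
    }


def train_classifier(data: dict[str, list], config: ClassifierConfig) -> TrainedClassifier:
    """Train the block classifier with class-weighted cross-entropy.

    ``data`` maps split names to lists of samples with ``image`` and
    ``label`` attributes; "train" and "validation" must be non-empty and
    contain both classes. Deterministic for fixed (data, config).
    """
    for split in ("train", "validation"):
        labels = {s.label for s in data.get(split, [])}
        if labels != {0, 1}:
            raise ValueError(f"{split} split must be non-empty and contain both classes")

    x_train = np.stack([s.image for s in data["train"]]).astype(float)
    y_train = np.array([s.label for s in data["train"]])
    x_val = np.stack([s.image for s in data["validation"]]).astype(float)
    y_val = np.array([s.label for s in data["validation"]])

    net = _build_net(config)
    opt_cls = Adam if config.optimizer == "adam" else SGD
    opt = opt_cls(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    w = np.asarray(config.class_weights, dtype=float)

    report: list[dict] = []
    best: tuple | None = None
    best_params: list[np.ndarray] | None = None
    best_epoch = -1

    n = len(x_train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx][:, None]
            yb = y_train[idx]
            out, caches = net.forward(xb)
            p = softmax(out)
            wb = w[yb]
            eps = 1e-12
            loss = float(np.mean(wb * -np.log(p[np.arange(len(yb)), yb] + eps)))
            epoch_loss += loss * len(yb)
            dout = p.copy()
            dout[np.arange(len(yb)), yb] -= 1.0
            dout *= wb[:, None] / len(yb)
            _, grads = net.backward(dout, caches)
            opt.step(grads)
        metrics = _split_metrics(net, x_val, y_val)
        report.append({"epoch": epoch, "train_loss": epoch_loss / n, **{f"val_{k}": v for k, v in metrics.items()}})
        # higher objective wins; ties -> higher accuracy -> earlier epoch
        key = (metrics[config.objective], metrics["accuracy"], -epoch)
        if best is None or key > best:
            best = key
            best_params = [p.copy() for p in net.params]
            best_epoch = epoch

    net.set_params(best_params)
    return TrainedClassifier(net, config, training_report=report, selected_epoch=best_epoch)


def save_classifier(model: TrainedClassifier, path: str | Path) -> None:
    """Serialize a checkpoint (config, parameters, report) to one file."""
    payload = {
        "config": model.config,
        "params": [p.copy() for p in model.net.params],
        "report": model.training_report,
        "selected_epoch": model.selected_epoch,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_classifier(path: str | Path) -> TrainedClassifier:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    net = _build_net(payload["config"])
    net.set_params(payload["params"])
    return TrainedClassifier(net, payload["config"], payload["report"], payload["selected_epoch"])
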