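"""The three juxtaposed-evidence pipelines.

Each pipeline yields, for one image, the four-map bundle
{positive, negative} x {AM3, AM4} that a judicial decision-support
protocol presents to the reader:

* *single-model* — one classifier; the CAM algorithm is applied to both
  output neurons (positive = "fracture" neuron 1, negative = neuron 0).
* *dual-model*   — positive maps from a sensitivity-optimised classifier's
  fracture neuron, negative maps from a specificity-optimised
  classifier's no-fracture neuron.
* *generative*   — four autoencoders (one per polarity/level) map the
  feature tensors of a shared feature-extractor classifier directly to
  saliency maps, having been trained to imitate the single-model maps.

The default CAM algorithm is HiResCAM; any supported algorithm may be
requested for the first two pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import softmax
from .cam_algorithms import ALL_ALGORITHMS, SaliencyMap, compute_raw_map, postprocess
from .generative import MapAutoencoder, ae_predict
from .models import TrainedClassifier

__all__ = ["JuxtaposedEvidence", "single_model_evidence", "dual_model_evidence", "generative_evidence"]

POLARITY_CLASS = {"positive": 1, "negative": 0}
LEVELS = ("AM3", "AM4")


@dataclass
class JuxtaposedEvidence:
    """The 4-map bundle for one image."""

    maps: dict[tuple[str, str], SaliencyMap]  # (polarity, level) -> map
    approach: str  # "single" | "dual" | "generative"
    image_id: str = ""
    confidences: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {(p, l) for p in POLARITY_CLASS for l in LEVELS}
        if set(self.maps) != expected:
            raise ValueError("evidence bundle must contain exactly the 4 (polarity, level) maps")
        shapes = {m.values.shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError("all maps in a bundle must share the image shape")
        for (polarity, level), m in self.maps.items():
            if m.polarity != polarity or m.level != level:
                raise ValueError("map tags must match their bundle slot")

    def map(self, polarity: str, level: str) -> SaliencyMap:
        return self.maps[(polarity, level)]


def _check_algorithm(algorithm: str) -> None:
    if algorithm not in ALL_ALGORITHMS:
        raise ValueError(f"unsupported algorithm: {algorithm!r}")


def _cam_for(model: TrainedClassifier, image: np.ndarray, polarity: str, level: str, algorithm: str, seed: int = 0) -> SaliencyMap:
    acts, grad = model.activations_and_gradient(image, level, POLARITY_CLASS[polarity])
    raw = compute_raw_map(algorithm, acts, grad, seed=seed)
    return postprocess(raw, np.asarray(image).shape, polarity=polarity, level=level, algorithm=algorithm)


def _confidences(model: TrainedClassifier, image: np.ndarray) -> dict[str, float]:
    conf = softmax(model.logits(np.asarray(image, dtype=float)[None])[0])
    return {"negative": float(conf[0]), "positive": float(conf[1])}


def single_model_evidence(model: TrainedClassifier, image: np.ndarray, algorithm: str = "hirescam", image_id: str = "", seed: int = 0) -> JuxtaposedEvidence:
    """Four maps from one classifier by explaining both output neurons."""
    _check_algorithm(algorithm)
    maps = {(p, l): _cam_for(model, image, p, l, algorithm, seed=seed) for p in POLARITY_CLASS for l in LEVELS}
    return JuxtaposedEvidence(maps=maps, approach="single", image_id=image_id, confidences=_confidences(model, image))


def dual_model_evidence(
    sens_model: TrainedClassifier,
    spec_model: TrainedClassifier,
    image: np.ndarray,
    algorithm: str = "hirescam",
    image_id: str = "",
    seed: int = 0,
) -> JuxtaposedEvidence:
    """Positive maps from the sensitivity-optimised model's fracture
    neuron; negative maps from the specificity-optimised model's
    no-fracture neuron."""
    _check_algorithm(algorithm)
    if sens_model.config.n_blocks != spec_model.config.n_blocks:
        raise ValueError("models have incompatible architectures")
    maps = {}
    for level in LEVELS:
        maps[("positive", level)] = _cam_for(sens_model, image, "positive", level, algorithm, seed=seed)
        maps[("negative", level)] = _cam_for(spec_model, image, "negative", level, algorithm, seed=seed)
    conf = {
        "positive": _confidences(sens_model, image)["positive"],
        "negative": _confidences(spec_model, image)["negative"],
    }
    return JuxtaposedEvidence(maps=maps, approach="dual", image_id=image_id, confidences=conf)


def generative_evidence(
    feature_model: TrainedClassifier,
    autoencoders: dict[tuple[str, str], MapAutoencoder],
    image: np.ndarray,
    image_id: str = "",
) -> JuxtaposedEvidence:
    """Four maps decoded by the (polarity, level)-specific autoencoders
    from the feature extractor's activation tensors."""
    expected = {(p, l) for p in POLARITY_CLASS for l in LEVELS}
    if set(autoencoders) != expected:
        raise ValueError("one autoencoder per (polarity, level) pair required")
    image = np.asarray(image, dtype=float)
    maps = {}
    for (polarity, level), ae in autoencoders.items():
        if (ae.config.polarity, ae.config.level) != (polarity, level):
            raise ValueError(f"autoencoder at slot {(polarity, level)} was trained for {(ae.config.polarity, ae.config.level)}")
        acts, _ = feature_model.net.forward(image[None, None], stop=feature_model.tap_index[level])
        maps[(polarity, level)] = ae_predict(ae, acts[0], target_shape=image.shape)
    return JuxtaposedEvidence(maps=maps, approach="generative", image_id=image_id, confidences=_confidences(feature_model, image))
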