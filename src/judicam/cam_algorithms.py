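"""Class activation map algorithms and shared post-processing.

Raw maps are computed from a tap's activation tensor A (K, h, w) and the
gradient of the explained class score with respect to it, G = ds_c/dA:

* Grad-CAM      — per-channel weight a_k = spatial mean of G_k; map = sum_k a_k A_k.
* HiResCAM      — map = sum_k (G_k ⊙ A_k), keeping spatial gradient detail.
* Grad-CAM++    — weights from second/third-order gradient terms of exp(s).
* XGrad-CAM     — activation-normalised weights sum_ij (G_k ⊙ A_k) / sum(A_k).
* LayerCAM      — map = sum_k ReLU(G_k) ⊙ A_k.
* RandomCAM     — i.i.d. uniform noise, the sanity-check reference.

Rectification (ReLU) happens in :func:`postprocess`, not in the raw
formulas, so positive- and negative-class raw maps can be inspected with a
uniform sign convention before normalisation. Post-processing upsamples
bilinearly (corner-aligned) to the image resolution and min-max normalises
to [0, 1]; a constant non-zero raw map maps to all ones and an identically
zero map stays zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "SaliencyMap",
    "grad_cam",
    "hirescam",
    "cam_variant",
    "random_cam",
    "postprocess",
    "compute_raw_map",
    "CAM_VARIANTS",
    "ALL_ALGORITHMS",
]

CAM_VARIANTS = ("gradcam_pp", "xgradcam", "layercam")
ALL_ALGORITHMS = ("gradcam", "hirescam", "gradcam_pp", "xgradcam", "layercam", "randomcam")


@dataclass
class SaliencyMap:
    """A normalised 2-D relevance map with provenance tags.

    ``values`` lies in [0, 1] at the explained image's resolution;
    ``native_values`` is the same map normalised at the tap's native
    (pre-upsampling) resolution, used as the regression target when
    training map-generating autoencoders.
    """

    values: np.ndarray
    polarity: str = "positive"  # "positive" (fracture) | "negative"
    level: str = "AM4"  # "AM3" | "AM4"
    algorithm: str = ""
    native_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("saliency values must lie in [0, 1]")


def _check_shapes(activations: np.ndarray, gradients: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(activations, dtype=float)
    g = np.asarray(gradients, dtype=float)
    if a.ndim != 3 or a.shape != g.shape:
        raise ValueError("activations and gradients must be 3-D tensors of one shape")
    return a, g


def grad_cam(activations: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Channel weights = spatial mean gradient; raw map = weighted activation sum."""
    a, g = _check_shapes(activations, gradients)
    alpha = g.mean(axis=(1, 2))
    return np.tensordot(alpha, a, axes=1)


def hirescam(activations: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Element-wise (Hadamard) gradient-activation product summed over channels."""
    a, g = _check_shapes(activations, gradients)
    return (g * a).sum(axis=0)


def _gradcam_pp(a: np.ndarray, g: np.ndarray) -> np.ndarray:
    # closed form with s replaced by exp(s): grad2 = g^2, grad3 = g^3
    if a.min() < -1e-9:
        raise ValueError("gradcam_pp expects non-negative (post-ReLU) activations")
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + a.sum(axis=(1, 2), keepdims=True) * g3
    alpha = np.where(g != 0.0, g2 / np.where(denom != 0.0, denom, 1.0), 0.0)
    weights = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))
    return np.tensordot(weights, a, axes=1)


def _xgradcam(a: np.ndarray, g: np.ndarray) -> np.ndarray:
    denom = a.sum(axis=(1, 2))
    weights = (g * a).sum(axis=(1, 2)) / (denom + 1e-12)
    return np.tensordot(weights, a, axes=1)


def _layercam(a: np.ndarray, g: np.ndarray) -> np.ndarray:
    return (np.maximum(g, 0.0) * a).sum(axis=0)


def cam_variant(name: str, activations: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Dispatch to one of the optimised Grad-CAM family variants."""
    a, g = _check_shapes(activations, gradients)
    if name == "gradcam_pp":
        return _gradcam_pp(a, g)
    if name == "xgradcam":
        return _xgradcam(a, g)
    if name == "layercam":
        return _layercam(a, g)
    raise ValueError(f"unknown CAM variant: {name!r}")


def random_cam(shape: tuple[int, int], seed: int = 0) -> np.ndarray:
    """I.i.d. uniform [0, 1] map — the sanity-check reference."""
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("shape dimensions must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, h, w]))
    return rng.uniform(size=(h, w))


def compute_raw_map(algorithm: str, activations: np.ndarray, gradients: np.ndarray, seed: int = 0) -> np.ndarray:
    """Raw (unrectified, unnormalised) map for any supported algorithm name."""
    if algorithm == "gradcam":
        return grad_cam(activations, gradients)
    if algorithm == "hirescam":
        return hirescam(activations, gradients)
    if algorithm in CAM_VARIANTS:
        return cam_variant(algorithm, activations, gradients)
    if algorithm == "randomcam":
        return random_cam(np.asarray(activations).shape[1:], seed=seed)
    raise ValueError(f"unsupported CAM algorithm: {algorithm!r}")


def _normalize(raw: np.ndarray) -> np.ndarray:
    rectified = np.maximum(raw, 0.0)
    lo, hi = rectified.min(), rectified.max()
    if hi == 0.0:
        return np.zeros_like(rectified)
    if hi - lo <= 1e-12 * hi:
        # constant non-zero maps (up to float jitter, e.g. after resizing)
        # normalise to all ones by convention
        return np.ones_like(rectified)
    return (rectified - lo) / (hi - lo)


def _bilinear_resize(arr: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Corner-aligned bilinear upsampling."""
    h, w = arr.shape
    th, tw = target_shape
    if (h, w) == (th, tw):
        return arr.copy()
    interp = RegularGridInterpolator(
        (np.linspace(0.0, 1.0, h) if h > 1 else np.array([0.0]), np.linspace(0.0, 1.0, w) if w > 1 else np.array([0.0])),
        arr,
        method="linear",
        bounds_error=False,
        fill_value=None,
    )
    yy = np.linspace(0.0, 1.0, th)
    xx = np.linspace(0.0, 1.0, tw)
    pts = np.stack(np.meshgrid(yy, xx, indexing="ij"), axis=-1)
    return interp(pts)


def postprocess(raw: np.ndarray, target_shape: tuple[int, int], polarity: str = "positive", level: str = "AM4", algorithm: str = "") -> SaliencyMap:
    """ReLU, bilinear upsample to the image shape, min-max normalise to [0, 1]."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw map contains non-finite values")
    native = _normalize(raw)
    up = np.clip(_bilinear_resize(np.maximum(raw, 0.0), target_shape), 0.0, None)
    values = _normalize(up)
    return SaliencyMap(values=values, polarity=polarity, level=level, algorithm=algorithm, native_values=native)


def save_saliency(map_: SaliencyMap, path: str | Path) -> None:
    """Persist the float32 map plus an 8-bit PNG heatmap preview."""
    from PIL import Image

    path = Path(path)
    np.save(path.with_suffix(".npy"), map_.values.astype(np.float32))
    Image.fromarray(np.round(map_.values * 255).astype(np.uint8), mode="L").save(path.with_suffix(".png"))
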