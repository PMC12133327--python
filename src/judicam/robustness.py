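"""CAM-selection metrics: drop/increase in confidence, ROAD, sanity check.

*Drop / increase in confidence* mask the input by its saliency map
(Hadamard product) and compare the explained class's softmax confidence
before (Y) and after (O): drop = mean max(0, Y-O)/Y, increase = fraction
of images with O > Y.

*ROAD* (remove-and-debias style perturbation) removes the most relevant
(MoRF) and least relevant (LeRF) fraction p of pixels by map value,
imputes the removed pixels with a noisy linear (discrete-harmonic)
infill, and scores mean_p (conf_LeRF - conf_MoRF)/2 per image, averaged
over images. A faithful map scores high; a random map scores near zero.
Pixel ranking ties are broken by row-major index (stable sort), which
keeps constant maps well defined.

The *sanity check* passes when a candidate algorithm's ROAD strictly
exceeds a poor reference's (RandomCAM) under the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from ._nn import softmax
from .cam_algorithms import SaliencyMap
from .models import TrainedClassifier

__all__ = [
    "CamRobustnessReport",
    "drop_increase",
    "noisy_linear_impute",
    "road_score",
    "sanity_check",
    "evaluate_algorithms",
]

DEFAULT_PERCENTILES = (0.2, 0.4, 0.6, 0.8)


@dataclass
class CamRobustnessReport:
    """Per-algorithm robustness rows for one (model, dataset, class) setting."""

    rows: pd.DataFrame  # columns: Algorithm, Drop, Increase, ROAD
    dataset_tag: str = ""
    model_tag: str = ""
    class_explained: int = 1

    def row(self, algorithm: str) -> pd.Series:
        match = self.rows[self.rows["Algorithm"] == algorithm]
        if match.empty:
            raise KeyError(f"no row for algorithm {algorithm!r}")
        return match.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dataset": self.dataset_tag,
            "model": self.model_tag,
            "class_explained": self.class_explained,
            "rows": self.rows.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _confidence(model: TrainedClassifier, image: np.ndarray, class_index: int) -> float:
    scores = model.logits(np.asarray(image, dtype=float)[None])[0]
    return float(softmax(scores)[class_index])


def drop_increase(model: TrainedClassifier, samples: list[np.ndarray], maps: list[SaliencyMap], class_index: int) -> tuple[float, float]:
    """Mean relative confidence drop and fraction of confidence increases
    after masking each image by its saliency map."""
    if len(samples) == 0:
        raise ValueError("empty sample list")
    if len(samples) != len(maps):
        raise ValueError("one map per image required")
    drops, increases = [], []
    for image, smap in zip(samples, maps):
        image = np.asarray(image, dtype=float)
        if smap.values.shape != image.shape:
            raise ValueError("map shape must match image shape")
        y = _confidence(model, image, class_index)
        o = _confidence(model, image * smap.values, class_index)
        drops.append(max(0.0, y - o) / y)
        increases.append(1.0 if o > y else 0.0)
    return float(np.mean(drops)), float(np.mean(increases))


def noisy_linear_impute(image: np.ndarray, removal_mask: np.ndarray, sigma: float = 0.01, seed: int = 0) -> np.ndarray:
    """Replace masked pixels by the discrete-harmonic infill plus noise.

    Each removed pixel is constrained to equal the mean of its in-grid
    4-neighbours; retained pixels act as Dirichlet boundary values. The
    sparse linear system is solved exactly, then zero-mean Gaussian noise
    of standard deviation ``sigma`` is added to the imputed pixels only.
    """
    image = np.asarray(image, dtype=float)
    removal_mask = np.asarray(removal_mask).astype(bool)
    if removal_mask.shape != image.shape:
        raise ValueError("removal_mask shape must match image shape")
    if removal_mask.all():
        raise ValueError("cannot impute a fully-removed image")
    if not removal_mask.any():
        return image.copy()

    h, w = image.shape
    idx_grid = -np.ones((h, w), dtype=int)
    rr, cc = np.nonzero(removal_mask)
    n_unknown = len(rr)
    idx_grid[rr, cc] = np.arange(n_unknown)

    rows_list, cols_list, vals_list = [], [], []
    b = np.zeros(n_unknown)
    degree = np.zeros(n_unknown)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nr, nc = rr + dr, cc + dc
        in_grid = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        degree += in_grid
        kk = np.nonzero(in_grid)[0]
        nb_removed = removal_mask[nr[kk], nc[kk]]
        unk = kk[nb_removed]
        rows_list.append(unk)
        cols_list.append(idx_grid[nr[unk], nc[unk]])
        vals_list.append(np.full(len(unk), -1.0))
        known = kk[~nb_removed]
        np.add.at(b, known, image[nr[known], nc[known]])
    rows_list.append(np.arange(n_unknown))
    cols_list.append(np.arange(n_unknown))
    vals_list.append(degree)
    a = csr_matrix(
        (np.concatenate(vals_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
        shape=(n_unknown, n_unknown),
    )
    x = spsolve(a, b)
    if n_unknown == 1:
        x = np.atleast_1d(x)
    out = image.copy()
    out[rr, cc] = x
    if sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, n_unknown]))
        out[rr, cc] += rng.normal(0.0, sigma, size=n_unknown)
    return out


def _removal_masks(values: np.ndarray, p: float) -> tuple[np.ndarray, np.ndarray]:
    """MoRF (top-p by value) and LeRF (bottom-p) removal masks; stable
    row-major tie-breaking."""
    flat = values.ravel()
    k = int(round(p * flat.size))
    k = max(1, min(k, flat.size - 1))
    desc = np.argsort(-flat, kind="stable")
    asc = np.argsort(flat, kind="stable")
    morf = np.zeros(flat.size, dtype=bool)
    lerf = np.zeros(flat.size, dtype=bool)
    morf[desc[:k]] = True
    lerf[asc[:k]] = True
    return morf.reshape(values.shape), lerf.reshape(values.shape)


def road_score(
    model: TrainedClassifier,
    samples: list[np.ndarray],
    maps: list[SaliencyMap],
    class_index: int,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    sigma: float = 0.01,
    seed: int = 0,
) -> float:
    """Combined MoRF/LeRF perturbation score, averaged over percentiles
    and images; higher means the map ranks informative pixels better."""
    if len(percentiles) == 0:
        raise ValueError("empty percentile list")
    if any(not (0.0 < p < 1.0) for p in percentiles):
        raise ValueError("percentiles must lie in (0, 1)")
    if len(samples) == 0:
        raise ValueError("empty sample list")
    if len(samples) != len(maps):
        raise ValueError("one map per image required")

    per_image = []
    for i, (image, smap) in enumerate(zip(samples, maps)):
        image = np.asarray(image, dtype=float)
        diffs = []
        for p in percentiles:
            morf, lerf = _removal_masks(smap.values, p)
            conf_morf = _confidence(model, noisy_linear_impute(image, morf, sigma=sigma, seed=seed * 7919 + i), class_index)
            conf_lerf = _confidence(model, noisy_linear_impute(image, lerf, sigma=sigma, seed=seed * 7919 + i + 1), class_index)
            diffs.append((conf_lerf - conf_morf) / 2.0)
        per_image.append(float(np.mean(diffs)))
    return float(np.mean(per_image))


def sanity_check(candidate: pd.Series | dict, reference: pd.Series | dict, candidate_tags: dict | None = None, reference_tags: dict | None = None) -> bool:
    """Pass iff the candidate's ROAD strictly exceeds the reference's.

    When tag dicts (model/dataset/percentiles) are supplied they must
    match; comparing rows from different configurations is an error.
    """
    if candidate_tags is not None or reference_tags is not None:
        if (candidate_tags or {}) != (reference_tags or {}):
            raise ValueError("candidate and reference come from different configurations")
    return float(candidate["ROAD"]) > float(reference["ROAD"])


def evaluate_algorithms(
    model: TrainedClassifier,
    samples: list[np.ndarray],
    algorithms: tuple[str, ...],
    class_index: int = 1,
    level: str = "AM4",
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    sigma: float = 0.01,
    seed: int = 0,
    model_tag: str = "",
    dataset_tag: str = "",
) -> CamRobustnessReport:
    """Compute one Drop/Increase/ROAD row per algorithm (RandomCAM included)."""
    from .cam_algorithms import compute_raw_map, postprocess

    records = []
    for algorithm in algorithms:
        maps = []
        for i, image in enumerate(samples):
            image = np.asarray(image, dtype=float)
            acts, grad = model.activations_and_gradient(image, level, class_index)
            raw = compute_raw_map(algorithm, acts, grad, seed=seed * 131 + i)
            maps.append(postprocess(raw, image.shape, level=level, algorithm=algorithm))
        drop, increase = drop_increase(model, samples, maps, class_index)
        road = road_score(model, samples, maps, class_index, percentiles=percentiles, sigma=sigma, seed=seed)
        records.append({"Algorithm": algorithm, "Drop": drop, "Increase": increase, "ROAD": road})
    return CamRobustnessReport(rows=pd.DataFrame.from_records(records), dataset_tag=dataset_tag, model_tag=model_tag, class_explained=class_index)
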