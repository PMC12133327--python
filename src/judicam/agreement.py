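"""Consensus ground truth and human/AI overlap scoring.

Implements the validation-study computations: fill-holes preprocessing of
annotator masks, STAPLE consensus fusion (EM estimation of a latent truth
together with each rater's sensitivity/specificity), mean-plus-std
binarization of saliency maps, IoU / IoGT overlap indices, and
chance-corrected inter-annotator agreement (Fleiss' kappa across all
raters, Cohen's kappa between two masks, e.g. the specialists' and the
residents' consensus).

Conventions: masks are row-major boolean arrays, origin top-left, aligned
pixel grids (no registration). On disk, 0 is background and any non-zero
value is foreground. STAPLE uses a spatially uniform prior equal to the
mean rater foreground fraction, initialises every rater at
sensitivity = specificity = 0.99999, and binarizes the posterior at 0.5
(ties count as foreground).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cam_algorithms import SaliencyMap
from .synthetic_data import RaterMaskSet

__all__ = [
    "StapleResult",
    "AgreementReport",
    "OverlapReport",
    "fill_holes",
    "staple",
    "binarize_map",
    "iou",
    "iogt",
    "fleiss_kappa",
    "cohen_kappa",
    "overlap_study",
]


@dataclass
class StapleResult:
    """Consensus probability map plus per-rater EM performance estimates."""

    consensus_prob: np.ndarray  # (H, W) in [0, 1]
    consensus_mask: np.ndarray  # (H, W) bool, posterior >= 0.5
    sensitivities: np.ndarray  # p_j per rater
    specificities: np.ndarray  # q_j per rater
    iterations: int
    converged: bool


@dataclass
class AgreementReport:
    fleiss_kappa: float
    cohen_kappa_specialists_vs_residents: float
    n_pixels: int
    n_raters: int
    per_image_fleiss: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))


@dataclass
class OverlapReport:
    """Mean IoU / IoGT per (approach, level, polarity) row."""

    rows: pd.DataFrame  # columns: approach, level, polarity, IoU, IoGT, n_images

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)

    def value(self, approach: str, level: str, polarity: str, metric: str) -> float:
        sel = self.rows[
            (self.rows["approach"] == approach) & (self.rows["level"] == level) & (self.rows["polarity"] == polarity)
        ]
        if sel.empty:
            raise KeyError((approach, level, polarity))
        return float(sel.iloc[0][metric])


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Flip every background component not touching the border (4-connectivity)."""
    return ndimage.binary_fill_holes(np.asarray(mask).astype(bool))


def staple(masks: RaterMaskSet | list[np.ndarray], tol: float = 1e-7, max_iter: int = 100) -> StapleResult:
    """Simultaneous truth and performance level estimation by EM.

    E-step: posterior truth probability per pixel given the current rater
    sensitivities p_j and specificities q_j and a scalar prior (the mean
    rater foreground fraction). M-step: re-estimate p_j, q_j from the
    posterior. Stops when the largest parameter change falls below
    ``tol`` or after ``max_iter`` iterations.
    """
    mask_list = masks.masks if isinstance(masks, RaterMaskSet) else list(masks)
    if len(mask_list) < 2:
        raise ValueError("STAPLE requires at least 2 raters")
    d = np.stack([np.asarray(m).astype(bool) for m in mask_list]).reshape(len(mask_list), -1)
    shape = np.asarray(mask_list[0]).shape
    n_raters, n_pix = d.shape

    prior = float(d.mean())
    # degenerate unanimity: the EM fixed point is the common mask itself
    if prior in (0.0, 1.0):
        w = np.full(n_pix, prior)
        return StapleResult(
            consensus_prob=w.reshape(shape),
            consensus_mask=(w >= 0.5).reshape(shape),
            sensitivities=np.ones(n_raters),
            specificities=np.ones(n_raters),
            iterations=0,
            converged=True,
        )

    p = np.full(n_raters, 0.99999)
    q = np.full(n_raters, 0.99999)
    eps = 1e-12
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for numerical stability
        log_a = np.log(prior + eps) + (d * np.log(p[:, None] + eps) + (~d) * np.log(1 - p[:, None] + eps)).sum(axis=0)
        log_b = np.log(1 - prior + eps) + ((~d) * np.log(q[:, None] + eps) + d * np.log(1 - q[:, None] + eps)).sum(axis=0)
        m = np.maximum(log_a, log_b)
        w = np.exp(log_a - m) / (np.exp(log_a - m) + np.exp(log_b - m))
        # M-step
        sw = w.sum()
        p_new = (d * w).sum(axis=1) / (sw + eps)
        q_new = ((~d) * (1 - w)).sum(axis=1) / (n_pix - sw + eps)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    return StapleResult(
        consensus_prob=w.reshape(shape),
        consensus_mask=(w >= 0.5).reshape(shape),
        sensitivities=p,
        specificities=q,
        iterations=it,
        converged=converged,
    )


def binarize_map(map_: SaliencyMap | np.ndarray) -> np.ndarray:
    """Foreground where the map exceeds its own mean plus one (population)
    standard deviation; a constant map yields an empty mask."""
    values = map_.values if isinstance(map_, SaliencyMap) else np.asarray(map_, dtype=float)
    return values > values.mean() + values.std()


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union; 0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return float((a & b).sum() / union)


def iogt(cam_mask: np.ndarray, gt: np.ndarray) -> float:
    """Fraction of the ground-truth mask covered by the CAM mask."""
    cam_mask = np.asarray(cam_mask).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if cam_mask.shape != gt.shape:
        raise ValueError("mask shapes must match")
    n_gt = gt.sum()
    if n_gt == 0:
        raise ValueError("IoGT is undefined for an empty ground-truth mask")
    return float((cam_mask & gt).sum() / n_gt)


def _rating_table(masks: list[np.ndarray]) -> np.ndarray:
    """(n_items, 2) counts of raters voting (background, foreground) per pixel."""
    d = np.stack([np.asarray(m).astype(bool).ravel() for m in masks])
    fg = d.sum(axis=0)
    return np.stack([d.shape[0] - fg, fg], axis=1)


def fleiss_kappa(masks: RaterMaskSet | list[np.ndarray]) -> float:
    """Fleiss' kappa over items = pixels, categories = {background, foreground}."""
    mask_list = masks.masks if isinstance(masks, RaterMaskSet) else list(masks)
    if len(mask_list) < 2:
        raise ValueError("Fleiss' kappa requires at least 2 raters")
    table = _rating_table(mask_list)
    n_items, _ = table.shape
    if n_items < 2:
        raise ValueError("Fleiss' kappa requires at least 2 pixels")
    n = table.sum(axis=1)[0]
    pj = table.sum(axis=0) / (n_items * n)
    if pj.min() == 0.0:
        raise ValueError("kappa undefined: only one category present in the data")
    p_i = ((table**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_e = float((pj**2).sum())
    if p_e == 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return float((p_bar - p_e) / (1 - p_e))


def cohen_kappa(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Cohen's kappa on the pixel-wise 2x2 confusion table of two masks."""
    a = np.asarray(mask_a).astype(bool).ravel()
    b = np.asarray(mask_b).astype(bool).ravel()
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    n = a.size
    n11 = float((a & b).sum())
    n00 = float((~a & ~b).sum())
    pa = float(a.mean())
    pb = float(b.mean())
    po = (n11 + n00) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        raise ValueError("Cohen's kappa undefined: both raters assign a single identical category")
    return float((po - pe) / (1 - pe))


def overlap_study(evidence: list, gts: dict[str, np.ndarray]) -> OverlapReport:
    """Mean IoU and IoGT of binarized maps vs consensus ground truth.

    ``evidence`` is a list of 4-map bundles (positive-labeled images
    only); ``gts`` maps image ids to consensus masks. Averaging is per
    image, then across images, for every (approach, level, polarity).
    """
    if not evidence:
        raise ValueError("no evidence bundles supplied")
    acc: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    for bundle in evidence:
        if bundle.image_id not in gts:
            raise ValueError(f"missing ground truth for image {bundle.image_id!r}")
        gt = np.asarray(gts[bundle.image_id]).astype(bool)
        for (polarity, level), smap in bundle.maps.items():
            mask = binarize_map(smap)
            key = (bundle.approach, level, polarity)
            acc.setdefault(key, []).append((iou(mask, gt), iogt(mask, gt)))
    records = [
        {
            "approach": approach,
            "level": level,
            "polarity": polarity,
            "IoU": float(np.mean([v[0] for v in vals])),
            "IoGT": float(np.mean([v[1] for v in vals])),
            "n_images": len(vals),
        }
        for (approach, level, polarity), vals in sorted(acc.items())
    ]
    return OverlapReport(rows=pd.DataFrame.from_records(records))
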