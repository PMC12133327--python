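"""Seeded synthetic radiograph-like images and simulated annotator masks.

The generator emulates the statistical structure of cropped spine X-rays
used by the evidence pipelines: each image shows a bright, textured,
convex quadrilateral ("vertebral body") over a noisy background, with
per-sample nuisances (scale, gamma, blur, occasional occluding bright
bar). Positive samples additionally carry a wedge-shaped intensity
defect crossing the body's cortical margin — the appearance of a
compression fracture — recorded as a ground-truth binary mask.

Simulated raters produce sensitivity/specificity-degraded copies of a
true defect mask, optionally smoothed so they resemble hand-drawn
regions. All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "LabeledSample",
    "RaterMaskSet",
    "generate_dataset",
    "simulate_raters",
    "split_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass
class LabeledSample:
    """A grayscale image with a binary class label and ground-truth defect mask.

    ``defect_mask`` is all-background for negatives and marks the wedge
    defect for positives.
    """

    image: np.ndarray  # (H, W) float64 in [0, 1]
    label: int  # 0 = no defect, 1 = defect
    defect_mask: np.ndarray  # (H, W) bool, empty when label == 0
    sample_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image contains non-finite values")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        if self.defect_mask.shape != self.image.shape:
            raise ValueError("defect_mask shape must equal image shape")
        if self.label == 1 and not self.defect_mask.any():
            raise ValueError("positive sample requires a non-empty defect mask")
        if self.label == 0 and self.defect_mask.any():
            raise ValueError("negative sample must have an empty defect mask")


@dataclass
class RaterMaskSet:
    """Ordered per-rater binary masks for one image."""

    masks: list[np.ndarray]  # each (H, W) bool
    roles: list[str] = field(default_factory=list)  # "specialist" | "resident"
    image_id: str = ""

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise ValueError("all rater masks must share one shape")
        if not self.roles:
            self.roles = ["specialist"] * len(self.masks)
        if len(self.roles) != len(self.masks):
            raise ValueError("one role per rater required")

    @property
    def n_raters(self) -> int:
        return len(self.masks)


def _convex_quad(rng: np.random.Generator, side: int, scale: float) -> np.ndarray:
    """Corner coordinates (4, 2) of a jittered convex quadrilateral."""
    cx = side / 2 + rng.uniform(-0.06, 0.06) * side
    cy = side / 2 + rng.uniform(-0.06, 0.06) * side
    base = np.array([45.0, 135.0, 225.0, 315.0])
    angles = np.deg2rad(base + rng.uniform(-12, 12, size=4) + rng.uniform(-15, 15))
    radii = scale * side / 2 * rng.uniform(0.85, 1.1, size=4)
    return np.stack([cy + radii * np.sin(angles), cx + radii * np.cos(angles)], axis=1)


def _fill_convex(corners: np.ndarray, side: int) -> np.ndarray:
    """Rasterize a convex polygon: a pixel is inside iff every edge cross
    product has the same sign (pixel-centre convention)."""
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    inside = np.ones((side, side), dtype=bool)
    n = len(corners)
    for i in range(n):
        y0, x0 = corners[i]
        y1, x1 = corners[(i + 1) % n]
        cross = (x1 - x0) * (yy - y0) - (y1 - y0) * (xx - x0)
        inside &= cross >= 0
    return inside


def _wedge_mask(rng: np.random.Generator, corners: np.ndarray, body: np.ndarray, side: int) -> np.ndarray:
    """Triangular wedge crossing one edge of the body, clipped to the body."""
    for _ in range(20):
        i = rng.integers(0, 4)
        a, b = corners[i], corners[(i + 1) % 4]
        t = rng.uniform(0.3, 0.7)
        apex_edge = a + t * (b - a)  # point on the cortical margin
        centroid = corners.mean(axis=0)
        depth = rng.uniform(0.5, 0.75)
        tip = apex_edge + depth * (centroid - apex_edge)
        half = rng.uniform(0.12, 0.2) * side
        edge_dir = (b - a) / (np.linalg.norm(b - a) + 1e-12)
        p1 = apex_edge - half * edge_dir
        p2 = apex_edge + half * edge_dir
        wedge = _fill_convex(_orient_ccw(np.array([p1, p2, tip])), side) & body
        if wedge.sum() >= 8:
            return wedge
    # fall back: small block at the body centroid (degenerate geometry draw)
    cy, cx = np.clip(corners.mean(axis=0).astype(int), 2, side - 3)
    block = np.zeros((side, side), dtype=bool)
    block[cy - 2 : cy + 3, cx - 2 : cx + 3] = True
    return block & body if (block & body).sum() >= 1 else block


def _orient_ccw(pts: np.ndarray) -> np.ndarray:
    area = 0.0
    n = len(pts)
    for i in range(n):
        y0, x0 = pts[i]
        y1, x1 = pts[(i + 1) % n]
        area += x0 * y1 - x1 * y0
    return pts if area > 0 else pts[::-1]


def _render_sample(ss: np.random.SeedSequence, side: int, positive: bool, difficulty: str, sample_id: str) -> LabeledSample:
    rng = np.random.default_rng(ss)
    easy = difficulty == "easy"

    # noisy background with mild large-scale structure
    bg = 0.15 + 0.05 * rng.standard_normal((side, side))
    bg += ndimage.gaussian_filter(rng.standard_normal((side, side)), side / 8) * 0.05

    # vertebral body: bright textured convex quadrilateral
    scale = rng.uniform(0.55, 0.8)
    corners = _orient_ccw(_convex_quad(rng, side, scale))
    body = _fill_convex(corners, side)
    body_soft = ndimage.gaussian_filter(body.astype(float), 1.0)
    level = rng.uniform(0.55, 0.75)
    texture = 1.0 + 0.08 * ndimage.gaussian_filter(rng.standard_normal((side, side)), 1.5)
    img = bg + body_soft * level * texture

    defect = np.zeros((side, side), dtype=bool)
    if positive:
        defect = _wedge_mask(rng, corners, body, side)
        contrast = rng.uniform(0.4, 0.55) if easy else rng.uniform(0.12, 0.22)
        soft_defect = ndimage.gaussian_filter(defect.astype(float), 0.7)
        img -= contrast * soft_defect  # dark cleft at the cortical margin

    # nuisances shared by both classes
    if rng.uniform() < 0.15:
        col = rng.integers(0, side - 3)
        img[:, col : col + 3] += rng.uniform(0.2, 0.4)  # occluding bright bar
    blur = rng.uniform(0.0, 0.35) if easy else rng.uniform(0.4, 1.4)
    if blur > 0.05:
        img = ndimage.gaussian_filter(img, blur)
    img = np.clip(img, 0.0, 1.0)
    gamma = rng.uniform(0.9, 1.1) if easy else rng.uniform(0.7, 1.4)
    img = img**gamma

    return LabeledSample(image=img, label=int(positive), defect_mask=defect, sample_id=sample_id)


def generate_dataset(n_pos: int, n_neg: int, side: int = 64, difficulty: str = "easy", seed: int = 0) -> list[LabeledSample]:
    """Generate ``n_pos`` positive and ``n_neg`` negative seeded samples.

    ``difficulty`` controls defect contrast and nuisance strength
    (``"easy"`` or ``"hard"``). Identical arguments give bit-identical
    output. ``side`` must be at least 32 so that two pooling stages leave
    usable activation maps.
    """
    if side < 32:
        raise ValueError("side must be >= 32 (activation maps degenerate below)")
    if difficulty not in ("easy", "hard"):
        raise ValueError(f"unknown difficulty: {difficulty!r}")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("sample counts must be non-negative")
    samples = []
    for i in range(n_pos):
        ss = np.random.SeedSequence([seed, 1, i])
        samples.append(_render_sample(ss, side, True, difficulty, f"pos_{i:04d}"))
    for i in range(n_neg):
        ss = np.random.SeedSequence([seed, 0, i])
        samples.append(_render_sample(ss, side, False, difficulty, f"neg_{i:04d}"))
    return samples


def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def simulate_raters(
    truth: np.ndarray,
    n_raters: int,
    sens: float,
    spec: float,
    smooth_radius: int = 0,
    seed: int = 0,
    roles: list[str] | None = None,
    image_id: str = "",
) -> RaterMaskSet:
    """Draw independent rater masks as noisy copies of ``truth``.

    Each rater keeps a true foreground pixel with probability ``sens`` and
    flips a background pixel on with probability ``1 - spec``; the result
    is then smoothed by morphological closing followed by opening with a
    disk of ``smooth_radius`` (0 disables smoothing, preserving the exact
    Bernoulli statistics needed by calibration tests).
    """
    truth = np.asarray(truth).astype(bool)
    if not truth.any() or truth.all():
        raise ValueError("truth mask must contain both foreground and background")
    if not (0 < sens <= 1 and 0 < spec <= 1):
        raise ValueError("sens and spec must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, truth.shape[0], truth.shape[1]]))
    masks = []
    for _ in range(n_raters):
        u = rng.uniform(size=truth.shape)
        mask = np.where(truth, u < sens, u < (1.0 - spec))
        if smooth_radius > 0:
            disk = _disk(smooth_radius)
            mask = ndimage.binary_opening(ndimage.binary_closing(mask, disk), disk)
        masks.append(mask)
    return RaterMaskSet(masks=masks, roles=roles or [], image_id=image_id)


def split_dataset(samples: list[LabeledSample], fractions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0) -> dict[str, list[LabeledSample]]:
    """Stratified train/validation/test split (default 80/10/10)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    splits: dict[str, list[LabeledSample]] = {"train": [], "validation": [], "test": []}
    for label in (0, 1):
        group = [s for s in samples if s.label == label]
        order = rng.permutation(len(group))
        n = len(group)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        for k, idx in enumerate(order):
            if k < n_train:
                splits["train"].append(group[idx])
            elif k < n_train + n_val:
                splits["validation"].append(group[idx])
            else:
                splits["test"].append(group[idx])
    return splits


def _to_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8), mode="L").save(path)


def write_dataset(splits: dict[str, list[LabeledSample]], out_dir: str | Path) -> Path:
    """Write images and masks as 8-bit grayscale PNGs plus a CSV manifest."""
    out = Path(out_dir)
    manifest_rows = []
    for split, samples in splits.items():
        img_dir = out / split / "images"
        mask_dir = out / split / "masks"
        img_dir.mkdir(parents=True, exist_ok=True)
        mask_dir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            _to_png(s.image, img_dir / f"{s.sample_id}.png")
            _to_png(s.defect_mask.astype(float), mask_dir / f"{s.sample_id}.png")
            manifest_rows.append((s.sample_id, s.label, split))
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label", "split"])
        writer.writerows(manifest_rows)
    return manifest


def read_dataset(root: str | Path) -> dict[str, list[LabeledSample]]:
    """Load a dataset written by :func:`write_dataset`."""
    root = Path(root)
    splits: dict[str, list[LabeledSample]] = {"train": [], "validation": [], "test": []}
    with open(root / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            split = row["split"]
            sid = row["sample_id"]
            img = np.asarray(Image.open(root / split / "images" / f"{sid}.png"), dtype=float) / 255.0
            mask_path = root / split / "masks" / f"{sid}.png"
            if mask_path.exists():
                mask = np.asarray(Image.open(mask_path)) > 0
            else:
                mask = np.zeros_like(img, dtype=bool)
            splits[split].append(LabeledSample(image=img, label=int(row["label"]), defect_mask=mask, sample_id=sid))
    return splits
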