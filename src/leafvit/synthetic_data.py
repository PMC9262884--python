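"""Seeded generator of leaf-disease-like RGB image datasets.

The generator emulates the statistical structure of wheat-rust leaf imagery:
a textured green background for every class, no lesions for "healthy",
yellow dots whose centres fall approximately on a random line for
"yellow_rust" (stripe rust forms roughly linear pustule rows), and brown
dots scattered uniformly for "brown_rust" (leaf rust has no particular
pattern).  Class names outside these three get a deterministic per-class dot
colour and pattern, which supports many-class imbalanced datasets of the
Plant-Village kind.

Every pixel is a pure function of the seed; images are side x side x 3
floats in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "ImageDataset", "generate_dataset",
           "generate_imbalanced", "skewed_counts", "write_image_folder",
           "WRCD_CLASS_COUNTS"]

#: Per-class image counts of the wheat-rust benchmark this generator mirrors.
WRCD_CLASS_COUNTS = {"brown_rust": 1128, "yellow_rust": 1156,
                     "healthy": 1395}

_BASE_GREEN = np.array([0.20, 0.52, 0.17])
_DOT_COLORS = {"yellow_rust": np.array([0.85, 0.75, 0.20]),
               "brown_rust": np.array([0.45, 0.25, 0.10])}
_COLOR_JITTER = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator.

    ``class_counts`` maps class name to the exact number of images;
    ``dot_count_range`` / ``dot_radius_range`` bound the lesions per diseased
    image; ``alignment_jitter`` is the perpendicular scatter (pixels) of the
    aligned class's dot row; ``background_noise`` scales the low-frequency
    multiplicative texture of the leaf-green background.
    """

    side: int = 50
    class_counts: dict[str, int] = field(default_factory=lambda: {
        "brown_rust": 30, "healthy": 30, "yellow_rust": 30})
    dot_count_range: tuple[int, int] = (5, 12)
    dot_radius_range: tuple[float, float] = (2.0, 4.5)
    alignment_jitter: float = 1.5
    background_noise: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 16:
            raise ValueError("side must be >= 16")
        if not self.class_counts:
            raise ValueError("class_counts must be nonempty")
        if any(c < 1 for c in self.class_counts.values()):
            raise ValueError("all class counts must be >= 1")
        if self.alignment_jitter < 0:
            raise ValueError("alignment_jitter must be >= 0")
        if self.dot_radius_range[1] >= self.side / 2:
            raise ValueError(
                f"max dot radius {self.dot_radius_range[1]} must be smaller "
                f"than side/2 = {self.side / 2}")


@dataclass
class ImageDataset:
    """Labelled RGB images: (n, side, side, 3) floats in [0, 1], integer
    labels indexing the ordered ``class_names``."""

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if self.labels.size and not (
                0 <= self.labels.min()
                and self.labels.max() < len(self.class_names)):
            raise ValueError("labels out of range for class_names")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "ImageDataset":
        return ImageDataset(self.images[idx], self.labels[idx],
                            self.class_names)

    def class_frequency(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=len(self.class_names))
        return {name: int(c) for name, c in zip(self.class_names, counts)}


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _background(side: int, noise: float, rng: np.random.Generator
                ) -> np.ndarray:
    # per-image base-colour jitter is kept well below the mean-channel shift
    # a handful of lesions produces, so classes stay separable by colour
    # statistics by construction
    base = _BASE_GREEN + rng.uniform(-0.015, 0.015, size=3)
    img = np.broadcast_to(base, (side, side, 3)).copy()
    # low-frequency multiplicative texture: coarse noise upsampled bilinearly
    coarse_side = max(side // 8, 2)
    coarse = rng.uniform(1.0 - noise, 1.0 + noise,
                         size=(coarse_side, coarse_side))
    tex = ndimage.zoom(coarse, side / coarse_side, order=1,
                       grid_mode=True, mode="nearest")[:side, :side]
    img *= tex[..., None]
    return np.clip(img, 0.0, 1.0)


def _draw_dot(img: np.ndarray, cy: float, cx: float, radius: float,
              color: np.ndarray) -> None:
    side = img.shape[0]
    yy, xx = np.ogrid[:side, :side]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)  # anti-aliased edge
    img += alpha[..., None] * (color - img)


def _dot_centers(kind: str, n_dots: int, side: int, jitter: float,
                 rng: np.random.Generator) -> np.ndarray:
    margin = 3.0
    lo, hi = margin, side - margin
    if kind == "aligned":
        # centres approximately on a random line through the image
        cy, cx = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0.0, np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        span = 0.45 * side
        t = np.linspace(-span, span, n_dots) + rng.normal(0, 1.0, n_dots)
        centers = np.stack([cy + t * d[0], cx + t * d[1]], axis=1)
        perp = np.array([d[1], -d[0]])
        centers += rng.normal(0.0, jitter, size=(n_dots, 1)) * perp
        return np.clip(centers, lo, hi)
    return rng.uniform(lo, hi, size=(n_dots, 2))


def _class_recipe(name: str, index: int) -> tuple[str, np.ndarray | None]:
    """(pattern, dot colour) for a class name; None colour means no dots."""
    if "healthy" in name:
        return "none", None
    if name in _DOT_COLORS:
        pattern = "aligned" if name == "yellow_rust" else "scattered"
        return pattern, _DOT_COLORS[name]
    # generic class: deterministic colour off a hue wheel, alternating pattern
    hue = (index * 0.37) % 1.0
    color = np.array([0.5 + 0.45 * np.cos(2 * np.pi * hue),
                      0.5 + 0.45 * np.cos(2 * np.pi * (hue + 1 / 3)),
                      0.5 + 0.45 * np.cos(2 * np.pi * (hue + 2 / 3))])
    return ("aligned" if index % 2 else "scattered"), np.clip(color, 0, 1)


def _render_image(pattern: str, color: np.ndarray | None,
                  cfg: SyntheticConfig, rng: np.random.Generator
                  ) -> np.ndarray:
    img = _background(cfg.side, cfg.background_noise, rng)
    if color is not None:
        n_dots = int(rng.integers(cfg.dot_count_range[0],
                                  cfg.dot_count_range[1] + 1))
        centers = _dot_centers(pattern, n_dots, cfg.side,
                               cfg.alignment_jitter, rng)
        for cy, cx in centers:
            radius = rng.uniform(*cfg.dot_radius_range)
            c = np.clip(color + rng.uniform(-_COLOR_JITTER, _COLOR_JITTER,
                                            size=3), 0, 1)
            _draw_dot(img, cy, cx, radius, c)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Dataset-level operations
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SyntheticConfig) -> ImageDataset:
    """Render the configured number of images per class, seeded.

    Classes are ordered lexicographically (matching the image-folder
    reader's convention), so labels are stable across write/read round
    trips.
    """
    class_names = tuple(sorted(cfg.class_counts))
    rng = np.random.default_rng(cfg.seed)
    images, labels = [], []
    for ci, name in enumerate(class_names):
        pattern, color = _class_recipe(name, ci)
        for _ in range(cfg.class_counts[name]):
            images.append(_render_image(pattern, color, cfg, rng))
            labels.append(ci)
    return ImageDataset(np.stack(images), np.array(labels, dtype=np.int64),
                        class_names)


def skewed_counts(n_classes: int, min_count: int, ratio: float
                  ) -> dict[str, int]:
    """Geometrically interpolated class counts from ``min_count`` up to
    ``min_count * ratio`` (imbalance of the Plant-Village kind)."""
    if n_classes < 2:
        raise ValueError("need >= 2 classes")
    t = np.linspace(0.0, 1.0, n_classes)
    counts = np.round(min_count * ratio ** t).astype(int)
    return {f"class_{i:02d}": int(c) for i, c in enumerate(counts)}


def generate_imbalanced(cfg: SyntheticConfig) -> ImageDataset:
    """As :func:`generate_dataset` for many-class skewed configurations;
    logs a class-frequency summary."""
    if len(cfg.class_counts) < 2:
        raise ValueError("imbalanced generation needs >= 2 classes")
    ds = generate_dataset(cfg)
    freq = ds.class_frequency()
    lo, hi = min(freq.values()), max(freq.values())
    logger.info("generated %d classes, %d images, count range %d..%d "
                "(ratio %.1f)", len(freq), len(ds), lo, hi, hi / max(lo, 1))
    return ds


def write_image_folder(dataset: ImageDataset, root, *,
                       overwrite: bool = False) -> Path:
    """Write the dataset as one PNG subdirectory per class.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Pixels are quantised to 8 bits, so a read-back
    differs from the source by at most 1/255 per channel.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{root} exists and is not empty (pass overwrite=True)")
    counters = {name: 0 for name in dataset.class_names}
    for name in dataset.class_names:
        (root / name).mkdir(parents=True, exist_ok=True)
    for img, lab in zip(dataset.images, dataset.labels):
        name = dataset.class_names[int(lab)]
        i = counters[name]
        counters[name] += 1
        arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(root / name / f"{name}_{i:05d}.png")
    return root
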