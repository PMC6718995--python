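"""Fundus-style image preparation: resize, central crop, splits, statistics.

Raw retinal photographs come in thousands-by-thousands resolutions; training
resolutions here are 64x64 or 224x224.  Preparation is deliberately minimal:
scale so the shorter edge hits the target (preserving the eyeball's aspect
ratio), crop the central square, and stop — no flipping, no contrast
enhancement, no other post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DR_CLASS_NAMES",
    "LabeledImageSet",
    "ClassDistribution",
    "resize_shorter_edge",
    "center_crop_square",
    "class_distribution",
    "distribution_from_counts",
    "split_dataset",
    "prep_directory",
    "load_image",
    "save_image",
    "FundusPreprocessor",
]

#: severity phases 0..4 of diabetic retinopathy
DR_CLASS_NAMES = ("Normal", "Mild NPDR", "Moderate NPDR", "Severe NPDR", "Proliferative DR")


@dataclass(frozen=True)
class LabeledImageSet:
    """Image paths with class indices 0-4."""

    records: tuple[tuple[str, int], ...]
    class_names: tuple[str, ...] = DR_CLASS_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple((str(p), int(l)) for p, l in self.records))
        n_classes = len(self.class_names)
        for p, l in self.records:
            if not 0 <= l < n_classes:
                raise ValueError(f"label {l} for {p!r} outside 0..{n_classes - 1}")
        paths = [p for p, _ in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("image paths must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([l for _, l in self.records], dtype=int)

    @classmethod
    def from_csv(cls, path, class_names: tuple[str, ...] = DR_CLASS_NAMES) -> "LabeledImageSet":
        df = pd.read_csv(path)
        return cls(tuple(zip(df["filename"].astype(str), df["label"].astype(int))), class_names)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.records, columns=["filename", "label"]).to_csv(path, index=False)


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class counts and percentages (two decimals, round half-up)."""

    counts: tuple[int, ...]
    percentages: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")
        if abs(sum(self.percentages) - 100.0) > 0.05:
            raise ValueError("percentages must sum to 100 within rounding slack")

    @property
    def total(self) -> int:
        return sum(self.counts)


def _round2_half_up(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def distribution_from_counts(counts: Sequence[int]) -> ClassDistribution:
    counts = tuple(int(c) for c in counts)
    total = sum(counts)
    if total == 0:
        raise ValueError("empty class counts")
    pct = tuple(_round2_half_up(100.0 * c / total) for c in counts)
    return ClassDistribution(counts, pct)


def class_distribution(image_set: LabeledImageSet) -> ClassDistribution:
    """Count images per class and report percentages of the total."""
    if len(image_set) == 0:
        raise ValueError("empty image set")
    n_classes = len(image_set.class_names)
    counts = np.bincount(image_set.labels, minlength=n_classes)
    return distribution_from_counts(counts)


def resize_shorter_edge(image: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize so the shorter edge equals ``target``.

    The longer edge scales proportionally (rounded), so aspect ratio is
    preserved.  ``image`` is (H, W) or (H, W, C).
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    if h <= w:
        nh, nw = target, int(round(w * target / h))
    else:
        nh, nw = int(round(h * target / w)), target
    if (nh, nw) == (h, w):
        return image.copy()
    pil = Image.fromarray(image)
    return np.asarray(pil.resize((nw, nh), resample=Image.BILINEAR))


def center_crop_square(image: np.ndarray) -> np.ndarray:
    """Crop the central SxS window, S the shorter edge; offsets floor-divide."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    s = min(h, w)
    top = (h - s) // 2
    left = (w - s) // 2
    return image[top:top + s, left:left + s].copy()


def split_dataset(
    image_set: LabeledImageSet, ratio: float, seed: int
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Uniform random disjoint split; train gets floor(ratio * n) records."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = len(image_set)
    if n < 2:
        raise ValueError("need at least two records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    take = lambda idx: LabeledImageSet(
        tuple(image_set.records[i] for i in sorted(idx)), image_set.class_names
    )
    return take(order[:n_train]), take(order[n_train:])


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image)).save(path)


def prep_directory(in_dir, labels_csv, out_dir, size: int) -> LabeledImageSet:
    """Resize + crop every labeled image from ``in_dir`` into ``out_dir``."""
    image_set = LabeledImageSet.from_csv(labels_csv)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for fname, label in image_set.records:
        img = load_image(Path(in_dir) / fname)
        img = center_crop_square(resize_shorter_edge(img, size))
        save_image(img, out / fname)
        records.append((fname, label))
    prepped = LabeledImageSet(tuple(records), image_set.class_names)
    prepped.to_csv(out / "labels.csv")
    return prepped


class FundusPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer: shorter-edge resize + center crop.

    ``transform`` accepts a list of (H, W[, C]) arrays of arbitrary sizes and
    returns one stacked (n, size, size[, C]) array.
    """

    def __init__(self, size: int = 64):
        self.size = size

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        out = [center_crop_square(resize_shorter_edge(img, self.size)) for img in X]
        return np.stack(out)
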