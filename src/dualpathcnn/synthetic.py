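"""Synthetic fixtures: sensor specimen clusters and toy retina-like images.

The real apparatus measurements behind the five-parameter pollutant data are
not published, so the sensor generator emulates their statistical premise:
five well-separated classes in a five-parameter space with minimal internal
correlation, sampled as Gaussian clusters around per-class means.  The toy
retina generator emulates only the coarse structure of graded fundus
photographs — a bright disk on a dark background whose count of small bright
"lesion" spots grows with severity class — enough for pipelines and
classifiers to have real signal to find, and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .imageprep import LabeledImageSet
from .sensor import PressureRange, SensorSpecimen

__all__ = [
    "SensorGenConfig",
    "ToyFundusConfig",
    "DEFAULT_CLASS_MEANS",
    "gen_sensor_specimens",
    "gen_toy_fundus",
    "write_toy_fundus",
]

#: per-class means for (doping_code, angle [deg], force [a.u.], pressure [Pa],
#: current [a.u.]) — five distinct pollutant signatures
DEFAULT_CLASS_MEANS = (
    (1.0, 15.0, 1.0, 20000.0, 1.0),
    (2.0, 30.0, 2.0, 40000.0, 3.0),
    (3.0, 45.0, 3.0, 60000.0, 5.0),
    (4.0, 60.0, 4.0, 80000.0, 7.0),
    (5.0, 75.0, 5.0, 100000.0, 9.0),
)


@dataclass(frozen=True)
class SensorGenConfig:
    """Gaussian-cluster generator for five-parameter specimens.

    ``noise_sd`` is a fraction of each parameter's scale (the maximum class
    mean of that parameter).  ``pressure_ranges``, when given, is a cycle of
    ``(span, increment)`` pairs in Pascal: specimen *i* then carries a
    :class:`PressureRange` from its sampled pressure up to sampled + span.
    """

    n_classes: int = 5
    class_means: tuple[tuple[float, ...], ...] = DEFAULT_CLASS_MEANS
    noise_sd: float = 0.05
    pressure_ranges: Optional[tuple[tuple[float, float], ...]] = None
    n_specimens: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.class_means) != self.n_classes:
            raise ValueError("need one mean vector per class")
        if len(set(self.class_means)) != self.n_classes:
            raise ValueError("class means must be pairwise distinct")


def gen_sensor_specimens(cfg: SensorGenConfig = SensorGenConfig()) -> list[SensorSpecimen]:
    """Draw ``n_specimens`` specimens, labels assigned round-robin over classes.

    Parameter j of a class-k specimen is ``mean[k][j] + N(0, noise_sd *
    scale_j)`` clipped to be nonnegative, ``scale_j`` the largest class mean
    of parameter j.  Deterministic given the seed.
    """
    means = np.asarray(cfg.class_means, dtype=float)
    scales = means.max(axis=0)
    rng = np.random.default_rng(cfg.seed)
    out: list[SensorSpecimen] = []
    for i in range(cfg.n_specimens):
        label = i % cfg.n_classes
        vals = means[label] + rng.normal(0.0, cfg.noise_sd * scales, size=means.shape[1])
        vals = np.clip(vals, 0.0, None)
        pressure: object = float(vals[3])
        if cfg.pressure_ranges is not None:
            span, inc = cfg.pressure_ranges[i % len(cfg.pressure_ranges)]
            pressure = PressureRange(float(vals[3]), float(vals[3]) + span, inc)
        out.append(SensorSpecimen(
            doping_code=float(vals[0]), angle=float(vals[1]), force=float(vals[2]),
            pressure=pressure, current=float(vals[4]), label=label,
        ))
    return out


@dataclass(frozen=True)
class ToyFundusConfig:
    """Toy retina-image generator.

    ``lesion_density`` gives the exact number of bright spots per image for
    each severity class; counts must be nondecreasing from class 0 to 4.
    Images are generated slightly wider than tall (4:3) so the shorter-edge
    resize and central crop have real work to do.
    """

    size: int = 64
    n_per_class: int = 10
    lesion_density: tuple[int, ...] = (0, 2, 5, 9, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if any(b < a for a, b in zip(self.lesion_density, self.lesion_density[1:])):
            raise ValueError("lesion_density must be nondecreasing over classes")


def _toy_image(rng: np.random.Generator, cfg: ToyFundusConfig, n_spots: int) -> np.ndarray:
    h = cfg.size
    w = round(cfg.size * 4 / 3)
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[...] = (12, 8, 8)  # dark surround
    yy, xx = np.mgrid[:h, :w]
    cy, cx = h / 2, w / 2
    radius = 0.45 * h
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    img[disk] = (176, 96, 64)  # retina-colored disk
    spot_r = max(1, h // 32)
    for _ in range(n_spots):
        # rejection-free placement: polar sample inside the disk
        ang = rng.uniform(0, 2 * np.pi)
        rad = (radius - spot_r - 1) * np.sqrt(rng.uniform())
        sy, sx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        spot = (yy - sy) ** 2 + (xx - sx) ** 2 <= spot_r ** 2
        img[spot] = (240, 220, 120)
    return img


def gen_toy_fundus(cfg: ToyFundusConfig = ToyFundusConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Images (n, H, W, 3) and labels (n,); class order 0..4 repeated."""
    rng = np.random.default_rng(cfg.seed)
    n_classes = len(cfg.lesion_density)
    images, labels = [], []
    for label in range(n_classes):
        for _ in range(cfg.n_per_class):
            images.append(_toy_image(rng, cfg, cfg.lesion_density[label]))
            labels.append(label)
    return np.stack(images), np.asarray(labels, dtype=int)


def write_toy_fundus(cfg: ToyFundusConfig, out_dir) -> LabeledImageSet:
    """Write the generated set as PNGs plus a labels.csv; returns the label set."""
    images, labels = gen_toy_fundus(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, label) in enumerate(zip(images, labels)):
        fname = f"fundus_{i:05d}.png"
        Image.fromarray(img).save(out / fname)
        records.append((fname, int(label)))
    image_set = LabeledImageSet(tuple(records))
    image_set.to_csv(out / "labels.csv")
    return image_set
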