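"""Five-zone encoding of multi-parameter sensor specimens into images.

Each specimen of air-quality apparatus data carries five parameters — doping
material (as a numeric code), measurement angle, force, air pressure, and the
"in air current" through the doped sensing material — plus a pollutant class
label (0=acetone, 1=ethanol, 2=chloroform, 3=toluene, 4=methanol).  A
specimen is rendered as a 64x64 grayscale image holding five disjoint square
zones, one per parameter; the gray level of zone *i* is the normalized value
of parameter *i* scaled to 0..255.  Because a convolutional network sees
spatial position, identical gray values in different zones carry different
information — this is what lets a CNN classify what is originally tabular
data.

Air pressure may be recorded as a range; :func:`expand_pressure_range`
augments such a specimen into one specimen per pressure step, which is how a
handful of measured specimens becomes a trainable image set.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PressureRange",
    "SensorSpecimen",
    "ZoneLayout",
    "DEFAULT_LAYOUT",
    "PARAMETER_NAMES",
    "normalize_parameters",
    "expand_pressure_range",
    "encode_specimen",
    "encode_dataset",
    "read_specimens",
    "write_specimens",
    "SensorImageEncoder",
]

#: zone order: zone i (1-based) encodes PARAMETER_NAMES[i-1]
PARAMETER_NAMES = ("doping_code", "angle", "force", "pressure", "current")


@dataclass(frozen=True)
class PressureRange:
    """An air-pressure interval measured as a range, in Pascal."""

    low: float
    high: float
    increment: float = 295.0

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError(f"increment must be > 0, got {self.increment}")
        if self.high < self.low:
            raise ValueError(f"range requires high >= low, got [{self.low}, {self.high}]")


@dataclass(frozen=True)
class SensorSpecimen:
    """One specimen: five parameters and a class label 0-4."""

    doping_code: float
    angle: float
    force: float
    pressure: Union[float, PressureRange]
    current: float
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2, 3, 4):
            raise ValueError(f"label must be in 0..4, got {self.label}")

    @property
    def has_range(self) -> bool:
        return isinstance(self.pressure, PressureRange)

    def values(self) -> np.ndarray:
        """The five scalar parameter values (pressure must be scalar)."""
        if self.has_range:
            raise ValueError("specimen carries a pressure range; expand it first")
        return np.array(
            [self.doping_code, self.angle, self.force, self.pressure, self.current],
            dtype=float,
        )


@dataclass(frozen=True)
class ZoneLayout:
    """Pixel geometry of the five encoding zones on the canvas.

    ``zones`` is a tuple of five ``(row, col, height, width)`` rectangles, in
    parameter order.  Zones must be pairwise disjoint and inside the canvas.
    """

    canvas: tuple[int, int] = (64, 64)
    zones: tuple[tuple[int, int, int, int], ...] = (
        (2, 2, 20, 20),    # zone 1: doping material code (top-left)
        (2, 42, 20, 20),   # zone 2: angle (top-right)
        (42, 2, 20, 20),   # zone 3: force (bottom-left)
        (42, 42, 20, 20),  # zone 4: air pressure (bottom-right)
        (22, 22, 20, 20),  # zone 5: in-air current (center, most decisive)
    )

    def __post_init__(self) -> None:
        if len(self.zones) != 5:
            raise ValueError("a layout needs exactly five zones")
        h, w = self.canvas
        occupancy = np.zeros((h, w), dtype=bool)
        for r, c, zh, zw in self.zones:
            if r < 0 or c < 0 or r + zh > h or c + zw > w:
                raise ValueError(f"zone ({r},{c},{zh},{zw}) exceeds the {h}x{w} canvas")
            block = occupancy[r:r + zh, c:c + zw]
            if block.any():
                raise ValueError("zones overlap")
            occupancy[r:r + zh, c:c + zw] = True

    def masks(self) -> list[np.ndarray]:
        """Boolean mask per zone on the canvas."""
        h, w = self.canvas
        out = []
        for r, c, zh, zw in self.zones:
            m = np.zeros((h, w), dtype=bool)
            m[r:r + zh, c:c + zw] = True
            out.append(m)
        return out


DEFAULT_LAYOUT = ZoneLayout()


def normalize_parameters(specimens: Sequence[SensorSpecimen]) -> list[SensorSpecimen]:
    """Scale each of the five parameters by its maximum over all specimens.

    Max-scaling (divide by the column maximum of absolute values) maps every
    value into [0, 1] while preserving zero.  Labels are unchanged.  A
    parameter that is zero for every specimen is left at zero with a warning.
    Specimens must carry scalar pressures — expand ranges first.
    """
    if len(specimens) == 0:
        raise ValueError("need at least one specimen")
    table = np.stack([s.values() for s in specimens])
    maxima = np.abs(table).max(axis=0)
    for j, m in enumerate(maxima):
        if m == 0:
            warnings.warn(
                f"parameter {PARAMETER_NAMES[j]!r} is zero for all specimens; left as zeros",
                stacklevel=2,
            )
    scale = np.where(maxima > 0, maxima, 1.0)
    scaled = table / scale
    return [
        replace(
            s,
            doping_code=row[0], angle=row[1], force=row[2],
            pressure=row[3], current=row[4],
        )
        for s, row in zip(specimens, scaled)
    ]


def expand_pressure_range(s: SensorSpecimen) -> list[SensorSpecimen]:
    """Expand a range-bearing specimen into one specimen per pressure step.

    Produces ``floor((high - low) / increment) + 1`` specimens at pressures
    ``low, low + increment, ...``; all other fields are copied.
    """
    if not isinstance(s.pressure, PressureRange):
        raise ValueError("specimen does not carry a pressure range")
    rng = s.pressure
    n = int(np.floor((rng.high - rng.low) / rng.increment)) + 1
    return [replace(s, pressure=rng.low + i * rng.increment) for i in range(n)]


def _as_gray(value: float) -> int:
    # round half-up onto the 0..255 gray scale
    return int(np.floor(value * 255.0 + 0.5))


def encode_specimen(s: SensorSpecimen, layout: ZoneLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Render one normalized specimen as an 8-bit grayscale image.

    Zone *i* is filled with ``round(value_i * 255)``; the background stays
    black.  Values must already be in [0, 1] (see :func:`normalize_parameters`).
    """
    vals = s.values()
    if (vals < 0).any() or (vals > 1).any():
        bad = {PARAMETER_NAMES[j]: vals[j] for j in np.flatnonzero((vals < 0) | (vals > 1))}
        raise ValueError(f"parameter values outside [0, 1]: {bad}; normalize first")
    img = np.zeros(layout.canvas, dtype=np.uint8)
    for (r, c, zh, zw), v in zip(layout.zones, vals):
        img[r:r + zh, c:c + zw] = _as_gray(v)
    return img


def encode_dataset(
    specimens: Sequence[SensorSpecimen],
    layout: ZoneLayout = DEFAULT_LAYOUT,
    out_dir: Union[str, Path, None] = None,
) -> pd.DataFrame:
    """Encode a normalized specimen list; optionally write PNGs + a label table.

    Returns a DataFrame with columns ``filename`` and ``label``.  With
    ``out_dir`` set, writes ``specimen_00000.png`` ... plus ``labels.csv``
    there; naming is positional, so re-running is byte-identical.
    """
    records = []
    images = [encode_specimen(s, layout) for s in specimens]
    for i, (s, img) in enumerate(zip(specimens, images)):
        records.append({"filename": f"specimen_{i:05d}.png", "label": s.label})
    table = pd.DataFrame(records, columns=["filename", "label"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, img in zip(records, images):
            Image.fromarray(img, mode="L").save(out / rec["filename"])
        table.to_csv(out / "labels.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# CSV interchange

def read_specimens(path) -> list[SensorSpecimen]:
    """Read specimens from CSV.

    Required columns: doping_code, angle, force, pressure, current, label.
    Optional columns pressure_high and pressure_increment turn ``pressure``
    into the low end of a :class:`PressureRange`.
    """
    df = pd.read_csv(path)
    missing = set(PARAMETER_NAMES + ("label",)) - set(df.columns)
    if missing:
        raise ValueError(f"specimen table {path} lacks columns: {sorted(missing)}")
    has_range_cols = "pressure_high" in df.columns
    out = []
    for _, row in df.iterrows():
        pressure: Union[float, PressureRange] = float(row["pressure"])
        if has_range_cols and pd.notna(row.get("pressure_high")):
            inc = float(row.get("pressure_increment", 295.0))
            pressure = PressureRange(float(row["pressure"]), float(row["pressure_high"]), inc)
        out.append(
            SensorSpecimen(
                doping_code=float(row["doping_code"]),
                angle=float(row["angle"]),
                force=float(row["force"]),
                pressure=pressure,
                current=float(row["current"]),
                label=int(row["label"]),
            )
        )
    return out


def write_specimens(specimens: Sequence[SensorSpecimen], path) -> None:
    rows = []
    for s in specimens:
        row = {
            "doping_code": s.doping_code, "angle": s.angle, "force": s.force,
            "pressure": s.pressure.low if s.has_range else s.pressure,
            "pressure_high": s.pressure.high if s.has_range else np.nan,
            "pressure_increment": s.pressure.increment if s.has_range else np.nan,
            "current": s.current, "label": s.label,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


class SensorImageEncoder(BaseEstimator, TransformerMixin):
    """Tabular-to-image transformer for five-parameter specimens.

    ``fit`` learns the per-parameter maxima from the training table;
    ``transform`` max-scales each column by the learned maxima, clips at 1
    (values beyond the training maximum render as white), and renders each
    row as a five-zone grayscale image.

    Parameters
    ----------
    layout : ZoneLayout
        Pixel geometry of the five zones (64x64 canvas by default).

    Attributes
    ----------
    scale_ : ndarray of shape (5,)
        Per-parameter absolute maxima learned during ``fit``.
    """

    def __init__(self, layout: ZoneLayout = DEFAULT_LAYOUT):
        self.layout = layout

    @staticmethod
    def _to_table(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(PARAMETER_NAMES)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 5:
            raise ValueError(f"expected a (n_samples, 5) parameter table, got shape {X.shape}")
        return X

    def fit(self, X, y=None):
        table = self._to_table(X)
        maxima = np.abs(table).max(axis=0)
        if (maxima == 0).any():
            warnings.warn("all-zero parameter column(s); they will encode as black", stacklevel=2)
        self.scale_ = np.where(maxima > 0, maxima, 1.0)
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scale_")
        table = np.clip(self._to_table(X) / self.scale_, 0.0, 1.0)
        images = np.zeros((len(table), *self.layout.canvas), dtype=np.uint8)
        for (r, c, zh, zw), col in zip(self.layout.zones, table.T):
            gray = np.floor(col * 255.0 + 0.5).astype(np.uint8)
            images[:, r:r + zh, c:c + zw] = gray[:, None, None]
        return images
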