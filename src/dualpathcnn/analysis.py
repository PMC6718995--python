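"""Activation-space analysis: pooled features, dead units, 3-D embedding.

After global average pooling, each sample is a nonnegative feature vector
(336 or 416 entries depending on the architecture).  A *dead unit* is a
feature column that is exactly zero on every evaluated sample — its ReLU
never activated, so the averaged map is identically zero.  The census of
dead units diagnoses how many kernels in the last modules failed to learn
anything from their (small) input maps.  For visualization the feature table
is projected to three dimensions with t-SNE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .network import TrainedModel, prepare_images
from .nn.model import Network

__all__ = [
    "ActivationTable",
    "extract_activations",
    "count_dead_units",
    "embed_3d",
]


@dataclass(frozen=True)
class ActivationTable:
    """Pooled feature vectors per sample, with labels and sample ids."""

    rows: np.ndarray          # (n_samples, n_features), nonnegative
    labels: np.ndarray        # (n_samples,)
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if rows.ndim != 2:
            raise ValueError("rows must be a 2-D table")
        if (rows < 0).any():
            raise ValueError("pooled post-ReLU activations must be nonnegative")
        if not (len(rows) == len(self.labels) == len(self.sample_ids)):
            raise ValueError("rows, labels and sample_ids must have equal length")

    @property
    def width(self) -> int:
        return self.rows.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.rows, columns=[f"f{i + 1}" for i in range(self.width)])
        df["label"] = self.labels
        df["id"] = list(self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ActivationTable":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        return cls(df[feat_cols].to_numpy(float), df["label"].to_numpy(int),
                   tuple(df["id"].astype(str)))


def extract_activations(model: Union[TrainedModel, Network], images: np.ndarray,
                        labels: Sequence[int],
                        sample_ids: Optional[Sequence[str]] = None,
                        batch_size: int = 64) -> ActivationTable:
    """Global-average-pooled feature vectors (the fully-connected input) per sample."""
    network = model.network if isinstance(model, TrainedModel) else model
    x = prepare_images(images, network.spec)
    labels = np.asarray(labels, dtype=int)
    if len(x) != len(labels):
        raise ValueError("images and labels must have equal length")
    if sample_ids is None:
        sample_ids = tuple(f"sample_{i:05d}" for i in range(len(x)))
    feats = [network.features(x[s:s + batch_size]) for s in range(0, len(x), batch_size)]
    rows = np.concatenate(feats) if feats else np.zeros((0, network.feature_dim))
    return ActivationTable(rows, labels, tuple(sample_ids))


def count_dead_units(table: Union[ActivationTable, np.ndarray]) -> tuple[int, int]:
    """(dead, alive): columns that are exactly zero everywhere vs the rest.

    Exact zero is the right test — a pooled post-ReLU average is zero iff
    every contributing activation was non-positive.
    """
    rows = table.rows if isinstance(table, ActivationTable) else np.asarray(table)
    if rows.size == 0:
        raise ValueError("empty activation table")
    dead = int((~rows.any(axis=0)).sum())
    return dead, rows.shape[1] - dead


def embed_3d(table: ActivationTable, seed: int = 0,
             perplexity: Optional[float] = None) -> pd.DataFrame:
    """t-SNE projection of the feature rows to 3-D, seeded for determinism.

    Perplexity defaults to min(30, n/4) and must stay below the sample count.
    Returns a DataFrame with columns x, y, z, label, id.
    """
    n = len(table.rows)
    if n < 2:
        raise ValueError("need at least two samples to embed")
    if perplexity is None:
        perplexity = min(30.0, max(1.0, n / 4.0))
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < sample count {n}")
    # method="exact": robust on degenerate inputs (e.g. duplicated rows) and
    # exactly reproducible; fine at the table sizes this package handles
    tsne = TSNE(n_components=3, perplexity=perplexity, random_state=seed,
                init="random", method="exact")
    coords = tsne.fit_transform(table.rows.astype(np.float32))
    return pd.DataFrame({
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "label": table.labels, "id": list(table.sample_ids),
    })
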