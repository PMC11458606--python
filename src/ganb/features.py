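"""Feature vectors from an intermediate discriminator layer.

A trained discriminator is a stack of K addressable blocks; the feature
map of any prefix of that stack is a usable image representation.  The
default is the penultimate block (the last one is a single saturating
probability).  Feature tables can be augmented with class-conditional
synthetic rows: each class's generator draws images that are pushed
through the same discriminator prefix and labeled by the class that
generated them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gan import DiscriminatorNet, GeneratorNet, sample_noise, generator_forward

__all__ = ["FeatureTable", "extract_features", "augment_with_synthetic", "resolve_layer"]

# above this width, spatial maps are global-average-pooled before flattening
# to keep downstream naive-Bayes estimates well conditioned
_POOL_THRESHOLD = 512


@dataclass
class FeatureTable:
    matrix: np.ndarray  # (n, d)
    labels: list | None  # per-row label or None for unlabeled tables
    layer_index: int
    source: list = field(default_factory=list)  # "real" | "synthetic" per row

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if self.d != other.d:
            raise ValueError(f"feature width mismatch: {self.d} vs {other.d}")
        labels = None
        if self.labels is not None and other.labels is not None:
            labels = list(self.labels) + list(other.labels)
        return FeatureTable(
            matrix=np.vstack([self.matrix, other.matrix]),
            labels=labels,
            layer_index=self.layer_index,
            source=list(self.source) + list(other.source),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=[f"f{j}" for j in range(self.d)])
        df.insert(0, "source", self.source)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, layer_index: int = 0) -> "FeatureTable":
        df = pd.read_csv(path)
        labels = df.pop("label").tolist() if "label" in df.columns else None
        source = df.pop("source").tolist() if "source" in df.columns else []
        return cls(matrix=df.to_numpy(dtype=float), labels=labels,
                   layer_index=layer_index, source=source)


def resolve_layer(i: int, K: int) -> int:
    """Map a possibly negative block index onto 1..K (-1 = last, -2 = penultimate)."""
    idx = K + 1 + i if i < 0 else i
    if not 1 <= idx <= K:
        raise ValueError(f"layer index {i} out of range; valid range is 1..{K} (or -{K}..-1)")
    return idx


def extract_features(D: DiscriminatorNet, images: np.ndarray, layer_index: int | None = None,
                     labels: list | None = None) -> FeatureTable:
    """Run images through discriminator blocks 1..i and flatten each output.

    Spatial maps wider than 512 values are global-average-pooled over their
    spatial dimensions first.  Row order equals input order.
    """
    i = D.feature_layer_default if layer_index is None else resolve_layer(layer_index, D.n_layers)
    out = D.forward(np.asarray(images, dtype=float), upto=i)
    if out.ndim == 4 and out[0].size > _POOL_THRESHOLD:
        out = out.mean(axis=(2, 3))
    mat = out.reshape(out.shape[0], -1)
    return FeatureTable(matrix=mat, labels=None if labels is None else list(labels),
                        layer_index=i, source=["real"] * mat.shape[0])


def augment_with_synthetic(class_gans: dict, D: DiscriminatorNet, n_per_class: int,
                           layer_index: int | None = None, seed: int = 0) -> FeatureTable:
    """Class-conditional synthetic feature rows, n_per_class per class.

    ``class_gans`` maps class label -> trained :class:`GeneratorNet`; rows
    carry the label of the generator that produced them and source
    'synthetic'.  Classes are processed in sorted order for reproducibility.
    """
    i = D.feature_layer_default if layer_index is None else resolve_layer(layer_index, D.n_layers)
    rng = np.random.default_rng(seed)
    mats, labels = [], []
    for cls in sorted(class_gans):
        G: GeneratorNet = class_gans[cls]
        if n_per_class == 0:
            continue
        z = sample_noise(n_per_class, G.latent_dim, rng)
        imgs = generator_forward(z, G)
        tab = extract_features(D, imgs[:, 0], layer_index=i)
        mats.append(tab.matrix)
        labels.extend([cls] * n_per_class)
    if not mats:
        d = extract_features(D, np.zeros((1,) + D.input_shape), layer_index=i).d
        return FeatureTable(matrix=np.empty((0, d)), labels=[], layer_index=i, source=[])
    return FeatureTable(matrix=np.vstack(mats), labels=labels, layer_index=i,
                        source=["synthetic"] * len(labels))
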