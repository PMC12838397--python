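"""Patch encoding and slide-level embedding.

Each patch is mapped to a d-dimensional feature vector by a pluggable
encoder; a slide with P patches is then summarized by concatenating the
element-wise mean, sample standard deviation, minimum and maximum of its
patch-feature matrix:

    x_s = [mean_p(z_sp) | std_p(z_sp) | min_p(z_sp) | max_p(z_sp)]

giving a 4d-length vector (4096 for d = 1024). The mean captures global
morphology; std/min/max capture within-slide heterogeneity, which is where
degradation signal often lives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .preprocess import Patch

__all__ = [
    "PatchEncoder",
    "SyntheticEncoder",
    "SlideEmbedding",
    "encode_patches",
    "aggregate_slide",
    "feature_names",
    "STAT_BLOCKS",
]

STAT_BLOCKS = ("mean", "std", "min", "max")


@runtime_checkable
class PatchEncoder(Protocol):
    """Contract for patch encoders: a name, an output dimension ``dim`` and a
    deterministic ``encode`` mapping a :class:`Patch` to a length-``dim``
    float vector."""

    name: str
    dim: int

    def encode(self, patch: Patch) -> np.ndarray: ...


class SyntheticEncoder:
    """Deterministic image-statistics encoder of configurable dimension.

    The first up-to-12 features are interpretable pixel statistics: the three
    channel means, then channel standard deviations, minima and maxima (all
    on the 0-255 scale, population SD). Higher dimensions are filled with
    fixed smooth nonlinear transforms of those base statistics so that any
    requested ``dim`` yields a deterministic, non-degenerate feature vector.

    This encoder stands in for heavyweight pretrained vision encoders: the
    pipeline only assumes the encoder contract, not any particular model.
    """

    def __init__(self, dim: int = 64):
        if dim < 1:
            raise ValueError("dim must be positive")
        self.name = "synthetic"
        self.dim = dim

    def _base_stats(self, pixels: np.ndarray) -> np.ndarray:
        px = pixels.reshape(-1, 3).astype(float)
        return np.concatenate(
            [px.mean(axis=0), px.std(axis=0), px.min(axis=0), px.max(axis=0)]
        )

    def encode(self, patch: Patch) -> np.ndarray:
        base = self._base_stats(patch.pixels)
        if self.dim <= base.size:
            return base[: self.dim]
        out = np.empty(self.dim)
        out[: base.size] = base
        scaled = base / 255.0
        for k in range(base.size, self.dim):
            # fixed phase/frequency per index keeps features distinct
            out[k] = np.cos((1 + k % base.size) * np.pi * scaled[k % base.size] + 0.1 * k)
        return out


def encode_patches(patches: Sequence[Patch], encoder: PatchEncoder) -> np.ndarray:
    """Encode patches into a (P, d) feature matrix, preserving patch order."""
    if len(patches) < 1:
        raise ValueError("need at least one patch to encode")
    rows = []
    for patch in patches:
        try:
            vec = np.asarray(encoder.encode(patch), dtype=float)
        except Exception as exc:  # noqa: BLE001 - re-raise with patch identity
            raise RuntimeError(
                f"encoder '{encoder.name}' failed on patch "
                f"{patch.slide_id}({patch.row},{patch.col}): {exc}"
            ) from exc
        if vec.shape != (encoder.dim,):
            raise ValueError(
                f"encoder '{encoder.name}' returned shape {vec.shape} for patch "
                f"{patch.slide_id}({patch.row},{patch.col}); expected ({encoder.dim},)"
            )
        rows.append(vec)
    return np.vstack(rows)


@dataclass
class SlideEmbedding:
    """Aggregated slide-level feature vector.

    ``vector`` has length 4d, ordered [mean | std | min | max];
    ``n_patches`` is the number of patches aggregated.
    """

    slide_id: str
    vector: np.ndarray
    n_patches: int


def aggregate_slide(patch_matrix: np.ndarray, slide_id: str = "") -> SlideEmbedding:
    """Aggregate a (P, d) patch-feature matrix into the 4d slide embedding.

    Statistics are taken element-wise over patches (rows): mean, sample
    standard deviation (divisor P - 1), min, max, concatenated in that
    order. Requires P >= 2 (guaranteed upstream by the slide filter), which
    also makes the sample SD well-defined.
    """
    m = np.asarray(patch_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("patch_matrix must be 2-dimensional (P x d)")
    if m.shape[0] < 2:
        raise ValueError("slide excluded: insufficient patches (need P >= 2)")
    vector = np.concatenate(
        [m.mean(axis=0), m.std(axis=0, ddof=1), m.min(axis=0), m.max(axis=0)]
    )
    return SlideEmbedding(slide_id=slide_id, vector=vector, n_patches=m.shape[0])


def feature_names(d: int) -> list[str]:
    """Column names for a 4d embedding: mean_0001..max_{d:04d}."""
    return [f"{block}_{j + 1:04d}" for block in STAT_BLOCKS for j in range(d)]
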