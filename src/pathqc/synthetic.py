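"""Synthetic histology tiles and slide-embedding datasets.

Two generators provide ground-truthed inputs for every pipeline stage:

* :func:`generate_tiles` renders H&E-like RGB images — a white background
  with elliptical "tissue" blobs whose color comes from a two-stain
  optical-density mixing model (known hematoxylin/eosin vectors, smooth
  concentration fields) — along with the exact tissue mask.

* :func:`generate_embedding_dataset` draws per-slide patch-feature matrices
  from tissue-specific Gaussian signatures, aggregates them with the same
  mean/std/min/max rule the pipeline uses, and plants a linear link from a
  known subset of feature coordinates to RIN (continuous, clipped to
  [1, 10]) plus an anti-correlated discretized autolysis score (0-3),
  optionally confounded by a Hardy-scale proxy.

Both are deterministic for a fixed seed (NumPy PCG64 via
``np.random.default_rng``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .embed import aggregate_slide
from .preprocess import DEFAULT_STAIN_PROFILE
from .tissue_models import SlideRecord

__all__ = ["SyntheticSpec", "generate_tiles", "generate_embedding_dataset"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults describe the reference simulation used throughout the test
    suite: 5 tissues x 100 slides, 64-dimensional patch features, 5 planted
    signal coordinates and residual noise at half the signal SD. See the
    methods note for the rationale behind each value.
    """

    n_tissues: int = 5
    slides_per_tissue: int = 100
    d: int = 64
    patches_per_slide: tuple[int, int] = (8, 16)
    n_signal_features: int = 5
    rin_coefficients: tuple[float, ...] | None = None
    noise_sd: float = 0.5  # as a multiple of the planted signal SD
    tissue_signature_separation: float = 3.0
    rin_range: tuple[float, float] = (1.0, 10.0)
    rin_center: float = 6.5
    rin_scale: float = 1.5
    confounder_strength: float = 0.0
    autolysis_noise_sd: float = 0.5
    seed: int = 0
    # tile generator controls
    image_size: int = 256
    n_blobs: int = 4
    tissue_fraction: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_tissues, self.slides_per_tissue, self.d,
               self.n_signal_features, self.image_size) < 1:
            raise ValueError("all counts must be positive")
        if self.n_signal_features > self.d:
            raise ValueError("n_signal_features cannot exceed d")
        if self.noise_sd < 0 or self.autolysis_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        payload = json.loads(Path(path).read_text())
        for key in ("patches_per_slide", "rin_range", "rin_coefficients"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


# ---------------------------------------------------------------------------
# image tiles


def _render_tile(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """One RGB tile plus its exact tissue mask."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    mask = np.zeros((s, s), dtype=bool)
    if spec.tissue_fraction > 0:
        # add ellipses until the rendered fraction reaches the request;
        # each blob is sized to (a share of) the remaining deficit, so
        # overlap between blobs cannot leave the mask short
        for attempt in range(8 * spec.n_blobs):
            deficit = spec.tissue_fraction - mask.mean()
            if deficit <= 0.01:
                break
            area = min(deficit, spec.tissue_fraction / spec.n_blobs) * s * s
            aspect = rng.uniform(0.6, 1.6)
            a = min(np.sqrt(area / np.pi * aspect), s / 2 - 1)
            b = min(area / np.pi / a, s / 2 - 1)
            cy = rng.uniform(a, s - a)
            cx = rng.uniform(b, s - b)
            theta = rng.uniform(0, np.pi)
            dy, dx = yy - cy, xx - cx
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0

    image = np.full((s, s, 3), 255, dtype=np.uint8)
    if mask.any():
        n = int(mask.sum())
        # smooth positive concentration fields for the two stains
        base = rng.uniform(0.3, 1.2, size=2)
        grad = rng.normal(0, 0.3 / s, size=(2, 2))
        conc = np.stack(
            [base[k] + grad[k, 0] * yy[mask] + grad[k, 1] * xx[mask] for k in range(2)],
            axis=1,
        )
        conc = np.clip(conc + rng.normal(0, 0.05, size=conc.shape), 0.05, None)
        od = conc @ DEFAULT_STAIN_PROFILE.stain_matrix.T
        intensity = np.clip(np.rint(256.0 * 10.0 ** (-od) - 1.0), 0, 255)
        image[mask] = intensity.astype(np.uint8)
    return image, mask


def generate_tiles(spec: SyntheticSpec, out_dir: str | Path) -> "pd.DataFrame":
    """Write synthetic slide images, ground-truth masks, and a manifest.

    Produces ``{slide_id}.png`` and ``{slide_id}_mask.png`` per slide plus a
    tab-delimited ``manifest.tsv`` (slide_id, tissue, tissue_fraction).
    Images are byte-identical across runs for a fixed seed.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for t in range(spec.n_tissues):
        tissue = f"tissue_{t:02d}"
        for i in range(spec.slides_per_tissue):
            slide_id = f"{tissue}_s{i:04d}"
            image, mask = _render_tile(rng, spec)
            Image.fromarray(image).save(out / f"{slide_id}.png")
            Image.fromarray((mask * 255).astype(np.uint8)).save(
                out / f"{slide_id}_mask.png"
            )
            rows.append(
                {"slide_id": slide_id, "tissue": tissue,
                 "tissue_fraction": float(mask.mean())}
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# embedding datasets


@dataclass
class EmbeddingDataset:
    """A generated cohort: embeddings, manifest, and the planted truth."""

    X: np.ndarray
    records: list[SlideRecord]
    signal_features: np.ndarray  # coordinate indices in patch-feature space
    rin_coefficients: np.ndarray
    tissue_signatures: np.ndarray  # (n_tissues, d)
    rin_latent: np.ndarray  # noiseless standardized latent per slide


def generate_embedding_dataset(spec: SyntheticSpec) -> EmbeddingDataset:
    """Simulate slide embeddings with planted quality signal.

    Per slide, P ~ Uniform{patches_per_slide} patch vectors are drawn from
    N(mu_tissue, I); slides are aggregated with the pipeline's own
    mean/std/min/max rule. The RIN latent is a fixed linear combination of
    the designated signal coordinates of the slide's mean patch vector,
    standardized across the cohort; then

        RIN = rin_center + rin_scale * latent + confounder + noise,

    clipped to ``rin_range``. Autolysis discretizes a negatively loaded
    copy of the same latent (plus independent noise) through fixed quantile
    thresholds, skewing mass toward the 0-1 classes and guaranteeing a
    negative RIN-autolysis coupling.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_tissues * spec.slides_per_tissue
    d = spec.d

    signatures = (
        rng.normal(0.0, 1.0, size=(spec.n_tissues, d))
        * spec.tissue_signature_separation
    )
    signal_features = rng.choice(d, size=spec.n_signal_features, replace=False)
    signal_features.sort()
    if spec.rin_coefficients is not None:
        coefs = np.asarray(spec.rin_coefficients, dtype=float)
        if coefs.size != spec.n_signal_features:
            raise ValueError("rin_coefficients length must equal n_signal_features")
    else:
        coefs = rng.uniform(0.5, 1.5, size=spec.n_signal_features) * rng.choice(
            [-1.0, 1.0], size=spec.n_signal_features
        )

    lo, hi = spec.patches_per_slide
    X = np.empty((n, 4 * d))
    mean_signal = np.empty((n, spec.n_signal_features))
    tissues = np.empty(n, dtype=object)
    n_patches = np.empty(n, dtype=int)
    for t in range(spec.n_tissues):
        for i in range(spec.slides_per_tissue):
            idx = t * spec.slides_per_tissue + i
            P = int(rng.integers(lo, hi + 1))
            patches = rng.normal(0.0, 1.0, size=(P, d)) + signatures[t]
            emb = aggregate_slide(patches)
            X[idx] = emb.vector
            mean_signal[idx] = patches.mean(axis=0)[signal_features]
            tissues[idx] = f"tissue_{t:02d}"
            n_patches[idx] = P

    raw_latent = mean_signal @ coefs
    latent = (raw_latent - raw_latent.mean()) / raw_latent.std()

    hardy = rng.integers(0, 5, size=n)
    confound = spec.confounder_strength * (2.0 - hardy) / 2.0
    rin = (
        spec.rin_center
        + spec.rin_scale * latent
        + confound
        + rng.normal(0.0, spec.noise_sd * spec.rin_scale, size=n)
    )
    rin = np.clip(rin, *spec.rin_range)

    auto_latent = -latent + rng.normal(0.0, spec.autolysis_noise_sd, size=n)
    cuts = np.quantile(auto_latent, [0.5, 0.8, 0.95])
    autolysis = np.searchsorted(cuts, auto_latent, side="right")

    ages = rng.uniform(21, 70, size=n)
    sexes = rng.choice(["F", "M"], size=n)
    records = [
        SlideRecord(
            slide_id=f"{tissues[i]}_s{i:05d}",
            donor_id=f"donor_{i // 2:05d}",
            tissue=str(tissues[i]),
            rin=float(np.round(rin[i], 2)),
            autolysis=int(autolysis[i]),
            hardy=int(hardy[i]),
            age=float(np.round(ages[i], 1)),
            sex=str(sexes[i]),
        )
        for i in range(n)
    ]
    return EmbeddingDataset(
        X=X,
        records=records,
        signal_features=signal_features,
        rin_coefficients=coefs,
        tissue_signatures=signatures,
        rin_latent=latent,
    )
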