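import numpy as np
import pytest

from pathqc.preprocess import DEFAULT_STAIN_PROFILE, Patch
from pathqc.synthetic import SyntheticSpec, generate_embedding_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """3 tissues x 40 slides, d=16: enough structure for model tests,
    small enough to refit repeatedly."""
    spec = SyntheticSpec(n_tissues=3, slides_per_tissue=40, d=16, seed=7)
    return generate_embedding_dataset(spec)


def render_stain_image(concentrations: np.ndarray, stain_matrix: np.ndarray,
                       shape: tuple[int, int]) -> np.ndarray:
    """Render an RGB image from per-pixel stain concentrations through a
    two-stain Beer-Lambert mixing model (the oracle construction for the
    stain-normalization tests)."""
    od = concentrations @ stain_matrix.T
    intensity = np.clip(np.rint(256.0 * 10.0 ** (-od) - 1.0), 0, 255)
    return intensity.astype(np.uint8).reshape(*shape, 3)


def two_stain_concentrations(rng: np.random.Generator, n: int,
                             pure_fraction: float = 0.1) -> np.ndarray:
    """Random positive concentration field including near-pure pixels of each
    stain, so the percentile-extreme angles land on the true stain vectors."""
    conc = rng.uniform(0.2, 1.5, size=(n, 2))
    k = int(n * pure_fraction)
    conc[:k, 1] = 0.0
    conc[:k, 0] = rng.uniform(0.7, 1.5, size=k)
    conc[k:2 * k, 0] = 0.0
    conc[k:2 * k, 1] = rng.uniform(0.7, 1.5, size=k)
    return conc


def make_patch(pixels: np.ndarray, slide_id: str = "s", row: int = 0,
               col: int = 0, tissue_fraction: float = 1.0) -> Patch:
    return Patch(slide_id, row, col, pixels, tissue_fraction)
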