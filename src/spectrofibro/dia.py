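"""Digital image analysis of Masson's-trichrome sections.

The reference fibrosis measurement: the RGB histology image is binarized to
remove the near-white paraffin background, unmixed into collagen (green),
cytoplasm (pink) and nuclei (black) concentration maps by Beer-Lambert
optical-density color deconvolution (Ruifrok-Johnston convention), and the
collagen area fraction of the tissue is reported as the fibrosis percentage.

Optical density per channel is ``-log10((pixel + 1) / I0)`` (the +1 offset
keeps 8-bit zeros finite); a pixel's OD vector is the concentration-weighted
sum of unit stain OD vectors, so concentrations are recovered with the
inverse stain matrix and clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .io import RGBImage

__all__ = [
    "StainVectors",
    "FibrosisMask",
    "deconvolve_stains",
    "segment_fibrosis",
    "fibrosis_percent_dia",
]

BACKGROUND_OD_DEFAULT = 0.15  # summed OD below this is bare background

STAIN_NAMES = ("collagen", "cytoplasm", "nuclei")


@dataclass(frozen=True)
class StainVectors:
    """Unit OD vectors (rows: collagen, cytoplasm, nuclei) and background I0."""

    od_matrix: np.ndarray  # 3 x 3, rows unit norm
    background: np.ndarray = None  # per-channel I0

    def __post_init__(self) -> None:
        m = np.asarray(self.od_matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3 x 3")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be nonzero")
        m = m / norms[:, None]
        if np.linalg.cond(m) > 1e6:
            raise ValueError("stain matrix is (near-)singular")
        object.__setattr__(self, "od_matrix", m)
        bg = self.background
        bg = np.full(3, 255.0) if bg is None else np.asarray(bg, dtype=np.float64)
        object.__setattr__(self, "background", bg)

    @classmethod
    def masson_default(cls) -> "StainVectors":
        """Package-default Masson-trichrome vectors.

        Green collagen absorbs red and blue, pink cytoplasm mostly green,
        black nuclei absorb all channels evenly.  Overridable wherever stain
        vectors are accepted.
        """
        return cls(np.array([
            [0.65, 0.10, 0.75],   # collagen (green stain)
            [0.10, 0.90, 0.42],   # cytoplasm (pink)
            [0.577, 0.577, 0.577],  # nuclei (black)
        ]))


@dataclass
class FibrosisMask:
    """Tissue and collagen boolean masks; collagen is a subset of tissue."""

    tissue: np.ndarray
    collagen: np.ndarray

    def __post_init__(self) -> None:
        if self.tissue.shape != self.collagen.shape:
            raise ValueError("masks must share one shape")
        if np.any(self.collagen & ~self.tissue):
            raise ValueError("collagen mask must be a subset of tissue")


def optical_density(rgb: RGBImage, vectors: StainVectors) -> np.ndarray:
    """Per-channel OD = -log10((pixel + 1) / I0), shape H x W x 3."""
    pix = rgb.pixels.astype(np.float64)
    return -np.log10((pix + 1.0) / vectors.background)


def deconvolve_stains(rgb: RGBImage, vectors: StainVectors) -> np.ndarray:
    """Concentration maps (H x W x 3: collagen, cytoplasm, nuclei).

    Negative concentrations (noise outside the stain simplex) are clipped
    to zero.
    """
    od = optical_density(rgb, vectors)
    conc = od @ np.linalg.inv(vectors.od_matrix)
    return np.clip(conc, 0.0, None)


def segment_fibrosis(
    rgb: RGBImage,
    vectors: StainVectors | None = None,
    background_od: float = BACKGROUND_OD_DEFAULT,
) -> FibrosisMask:
    """Binarize background, then segment collagen within the tissue.

    Tissue pixels have summed OD above ``background_od``.  A tissue pixel
    counts as collagen when the collagen concentration dominates both other
    stains and exceeds an Otsu threshold computed on collagen concentrations
    within tissue (skipped when the collagen distribution is flat, e.g. a
    uniformly stained section).
    """
    if background_od < 0:
        raise ValueError("background OD threshold must be >= 0")
    vectors = vectors or StainVectors.masson_default()
    od = optical_density(rgb, vectors)
    tissue = od.sum(axis=2) > background_od
    if not tissue.any():
        raise ValueError("no tissue pixels above the background OD threshold")
    conc = deconvolve_stains(rgb, vectors)
    coll = conc[:, :, 0]
    dominant = (coll >= conc[:, :, 1]) & (coll >= conc[:, :, 2])
    vals = coll[tissue]
    if np.ptp(vals) < 1e-6:
        thr = vals.min() - 1.0  # uniform staining: no split
    else:
        thr = threshold_otsu(vals)
    collagen = tissue & dominant & (coll > thr)
    return FibrosisMask(tissue, collagen)


def fibrosis_percent_dia(mask: FibrosisMask) -> float:
    """100 * collagen pixels / tissue pixels."""
    n_tissue = int(mask.tissue.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    return 100.0 * int(mask.collagen.sum()) / n_tissue
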