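"""K-means segmentation of spectral images and fibrosis-area quantification.

Per-image k-means partitions the dewaxed spectra of one sample into k
spectral classes; common k-means fits a single centroid set on spectra pooled
from many images so that class identities (and pseudo-colors) are comparable
across samples.  Classes are annotated as fibrosis / nodule / other by
correlating their centroid spectra against reference templates (or by an
explicit manual mapping), and the fibrosis area percentage is the share of
valid pixels whose class is annotated as fibrosis.

Conventions:

* best-of-``n_init`` restart by inertia, k-means++ by default; an
  ``init="random"`` mode seeds centroids with randomly chosen spectra;
* after convergence classes are re-ordered canonically by descending size
  (ties: original label), so seeds and pooling order yield stable ids;
* centroids are recomputed as exact class means of the final assignment;
* pseudo-colors come from a fixed palette indexed by class id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .io import SpectralImage, WavenumberAxis

__all__ = [
    "KMeansModel",
    "LabelImage",
    "ClusterAnnotation",
    "PALETTE",
    "fit_kmeans",
    "fit_common_kmeans",
    "annotate_clusters",
    "area_percent",
]

# fixed pseudo-color palette (RGB), indexed by class id
PALETTE = (
    (31, 119, 180),   # dark blue
    (214, 39, 40),    # red
    (44, 160, 44),    # green
    (148, 103, 189),  # purple
    (255, 127, 14),   # orange
    (140, 86, 75),    # brown
    (23, 190, 207),   # cyan
    (227, 119, 194),  # pink
)

TISSUE_LABELS = ("fibrosis", "nodule", "other")


@dataclass
class KMeansModel:
    """Fitted spectral k-means: centroids, axis, colors, fit diagnostics."""

    k: int
    centroids: np.ndarray  # k x B
    axis: WavenumberAxis
    seed: int
    inertia: float
    colors: tuple = ()

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid row count must equal k")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")
        if not self.colors:
            self.colors = tuple(PALETTE[i % len(PALETTE)] for i in range(self.k))

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean) labels; ties go to the lowest id."""
        d2 = ((spectra[:, None, :] - self.centroids[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)


@dataclass
class LabelImage:
    """Per-pixel class labels; -1 marks masked pixels."""

    labels: np.ndarray  # H x W int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def valid(self) -> np.ndarray:
        return self.labels >= 0

    def class_counts(self, k: int) -> np.ndarray:
        return np.bincount(self.labels[self.valid], minlength=k)


@dataclass
class ClusterAnnotation:
    """Mapping class id -> tissue label (fibrosis / nodule / other)."""

    mapping: dict[int, str]

    def __post_init__(self) -> None:
        for cid, lab in self.mapping.items():
            if lab not in TISSUE_LABELS:
                raise ValueError(f"unknown tissue label {lab!r} for class {cid}")

    def classes_for(self, target: str) -> list[int]:
        return [cid for cid, lab in self.mapping.items() if lab == target]


def _canonical_order(labels: np.ndarray, centroids: np.ndarray):
    """Relabel classes by descending size, ties broken by original id."""
    k = centroids.shape[0]
    counts = np.bincount(labels, minlength=k)
    order = np.lexsort((np.arange(k), -counts))  # size desc, then id asc
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    return remap[labels], centroids[order]


def _fit_pooled(spectra: np.ndarray, k: int, seed: int, n_init: int,
                init: str, axis: WavenumberAxis) -> tuple[KMeansModel, np.ndarray]:
    n = spectra.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"only {n} valid spectra for k = {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed,
                init="k-means++" if init == "k-means++" else "random",
                tol=1e-6, max_iter=300, algorithm="lloyd")
    labels = km.fit_predict(spectra)
    labels, _ = _canonical_order(labels, km.cluster_centers_)
    # exact class means of the final assignment
    centroids = np.vstack([spectra[labels == i].mean(axis=0) for i in range(k)])
    inertia = float(((spectra - centroids[labels]) ** 2).sum())
    model = KMeansModel(k, centroids, axis, seed, inertia)
    return model, labels


def _label_image(image: SpectralImage, labels_flat: np.ndarray) -> LabelImage:
    lab = np.full(image.cube.shape[:2], -1, dtype=np.int32)
    lab[image.mask] = labels_flat
    return LabelImage(lab, image.sample_id)


def fit_kmeans(
    image: SpectralImage,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    init: str = "k-means++",
) -> tuple[KMeansModel, LabelImage]:
    """Partition one dewaxed image into k spectral classes."""
    model, labels = _fit_pooled(image.valid_spectra(), k, seed, n_init,
                                init, image.axis)
    return model, _label_image(image, labels)


def fit_common_kmeans(
    images: list[SpectralImage],
    k: int,
    seed: int = 0,
    n_init: int = 10,
    init: str = "k-means++",
) -> tuple[KMeansModel, list[LabelImage]]:
    """Fit one centroid set on pooled spectra; label every image against it.

    Class ids and colors are therefore identical across all images.
    """
    if not images:
        raise ValueError("need at least one image")
    axis0 = images[0].axis
    for img in images[1:]:
        if len(img.axis) != len(axis0) or not np.allclose(
            img.axis.values, axis0.values
        ):
            raise ValueError(
                f"axis of image {img.sample_id!r} differs from the first image"
            )
    pooled = np.vstack([img.valid_spectra() for img in images])
    model, labels = _fit_pooled(pooled, k, seed, n_init, init, axis0)
    out = []
    start = 0
    for img in images:
        n = img.n_valid
        out.append(_label_image(img, labels[start:start + n]))
        start += n
    return model, out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return 0.0
    return float(x @ y / denom)


def annotate_clusters(
    model: KMeansModel,
    templates: dict[str, np.ndarray] | None = None,
    manual: dict[int, str] | None = None,
) -> ClusterAnnotation:
    """Assign each class a tissue label.

    A manual mapping wins outright (it must cover every class).  Otherwise
    each centroid takes the tissue label of the best-correlated template;
    ``templates`` maps tissue label -> spectrum (B,) or stacked spectra
    (n, B), all evaluated on the model axis.
    """
    if manual is not None:
        if set(manual) != set(range(model.k)):
            raise ValueError("manual mapping must cover every class id exactly once")
        return ClusterAnnotation(dict(manual))
    if not templates or not {"fibrosis", "nodule"} <= set(templates):
        raise ValueError("templates must cover 'fibrosis' and 'nodule', "
                         "or a manual mapping must be supplied")
    mapping: dict[int, str] = {}
    for cid in range(model.k):
        centroid = model.centroids[cid]
        scores = {}
        for label, spec in templates.items():
            spec = np.atleast_2d(np.asarray(spec, float))
            scores[label] = max(_pearson(centroid, row) for row in spec)
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < 1e-12:
            raise ValueError(
                f"class {cid}: correlation tie between {ranked[0][0]!r} and "
                f"{ranked[1][0]!r}; supply a manual mapping"
            )
        mapping[cid] = ranked[0][0]
    return ClusterAnnotation(mapping)


def default_templates(axis: WavenumberAxis) -> dict[str, np.ndarray]:
    """Annotation templates from the built-in endmember library."""
    from .synth import default_endmembers, synth_spectrum

    ems = default_endmembers()
    return {
        "fibrosis": np.vstack([
            synth_spectrum(ems["collagen_a"], axis),
            synth_spectrum(ems["collagen_b"], axis),
        ]),
        "nodule": synth_spectrum(ems["glycogen_nodule"], axis)[None, :],
    }


def area_percent(
    labels: LabelImage,
    annotation: ClusterAnnotation,
    target: str = "fibrosis",
) -> float:
    """Percentage of valid pixels whose class is annotated as ``target``."""
    valid = labels.valid
    n = int(valid.sum())
    if n == 0:
        raise ValueError("label image has no valid pixels")
    ids = annotation.classes_for(target)
    hit = np.isin(labels.labels, ids) & valid
    return 100.0 * hit.sum() / n
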