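"""Synthetic cirrhotic-liver phantoms: paired FTIR cubes and trichrome images.

The phantom emulates the two histological compartments of cirrhosis:
regeneration nodules (glycogen-rich hepatocyte spectra) separated by a
connected network of fibrous septa (collagen-rich spectra, in two sub-variants
that differ in their amide III profile).  On top of the clean class spectra
the cube model adds the nuisance terms a paraffin-embedded FTIR measurement
actually shows: an additive paraffin contribution, a smooth polynomial
baseline, a multiplicative scatter factor, and white noise:

    s(pixel) = scatter * (endmember + baseline + amp * paraffin) + noise

A matched pure-paraffin cube (as recorded at the tissue periphery) and a
Masson's-trichrome rendering of the same class map (green collagen / pink
cytoplasm / black nuclei / white background) are generated alongside, so the
dewaxing, clustering and stain-deconvolution stages can all be validated
against the same planted ground truth.

All stochastic draws descend from a single seed via ``np.random.SeedSequence``
spawn keys, so every artifact is reproducible from (config, seed) and the
label map, cube and trichrome draws are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import RGBImage, SpectralImage, WavenumberAxis

__all__ = [
    "BandSpec",
    "Endmember",
    "PhantomTruth",
    "PhantomConfig",
    "default_endmembers",
    "synth_spectrum",
    "synth_label_map",
    "synth_cube",
    "synth_trichrome",
    "make_phantom",
]

# class-map codes
BACKGROUND, NODULE, FIBROSIS_A, FIBROSIS_B = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", NODULE: "nodule",
               FIBROSIS_A: "fibrosis_a", FIBROSIS_B: "fibrosis_b"}


@dataclass(frozen=True)
class BandSpec:
    """A single Gaussian absorption band."""

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: float  # AU

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")


@dataclass(frozen=True)
class Endmember:
    """A named pure-component spectrum as a sum of Gaussian bands."""

    name: str
    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("endmember needs at least one band")


def _em(name: str, centers_amps: list[tuple[float, float]],
        sigma: float = 8.0) -> Endmember:
    return Endmember(name, tuple(BandSpec(c, sigma, a) for c, a in centers_amps))


MEAN_ABSORBANCE = 0.25  # AU, common tissue mean over the fingerprint region

# protein backbone bands shared by every tissue class: (center, sigma, amp).
# Amide I/II dominate any protein-containing tissue spectrum; class identity
# lives in the fingerprint bands riding on top of this common backbone.
_BACKBONE = ((1655.0, 25.0, 1.00), (1548.0, 22.0, 0.65))


def _mean_absorbance(bands: list[BandSpec], span: float = 900.0) -> float:
    """Analytic mean of a sum-of-Gaussians spectrum over the fingerprint."""
    area = sum(b.amplitude * b.width for b in bands) * np.sqrt(2 * np.pi)
    return area / span


def default_endmembers(sigma: float = 8.0) -> dict[str, Endmember]:
    """Built-in endmember library.

    Band centers follow the published infrared assignments for glycogenated
    hepatocytes and hepatic collagen; the relative amplitudes are free
    modelling parameters.  All tissue endmembers share the amide I/II
    backbone and are scaled to one common mean absorbance over the
    fingerprint region — adjacent compartments of one section differ in band
    profile, not in bulk absorbance.  ``collagen_b`` represents the more
    advanced, crosslinked fibrosis variant: relative to collagen_a its amide
    III bands (1204/1234/1284 cm^-1) are intensified 1.3x and the 1250 and
    1340 cm^-1 features are downshifted to 1244 and 1342 cm^-1.
    """
    def tissue(name: str, fingerprint: list[tuple[float, float]],
               scale: float | None = None) -> tuple[Endmember, float]:
        bands = [BandSpec(c, s, a) for c, s, a in _BACKBONE]
        bands += [BandSpec(c, sigma, a) for c, a in fingerprint]
        if scale is None:
            scale = MEAN_ABSORBANCE / _mean_absorbance(bands)
        em = Endmember(name, tuple(
            BandSpec(b.center, b.width, b.amplitude * scale) for b in bands))
        return em, scale

    gly = [(1022, 0.70), (1045, 1.00), (1080, 0.80), (1155, 0.60)]
    col_a = [(1050, 0.30), (1064, 0.30), (1084, 0.28),
             (1174, 0.45), (1202, 0.60), (1230, 0.80), (1250, 0.55),
             (1278, 0.65), (1304, 0.60), (1340, 0.50), (1404, 0.45)]
    col_b = [(1050, 0.30), (1064, 0.30), (1084, 0.28),
             (1174, 0.45), (1204, 0.78), (1234, 1.04), (1244, 0.55),
             (1284, 0.845), (1306, 0.60), (1342, 0.50), (1404, 0.45)]
    glycogen, _ = tissue("glycogen_nodule", gly)
    collagen_a, a_scale = tissue("collagen_a", col_a)
    # collagen_b keeps collagen_a's scale so it stays a band-level perturbation
    collagen_b, _ = tissue("collagen_b", col_b, scale=a_scale)
    paraffin = _em("paraffin", [(1378, 0.80), (1462, 1.00)], sigma)
    return {e.name: e for e in (glycogen, collagen_a, collagen_b, paraffin)}


def synth_spectrum(endmember: Endmember, axis: WavenumberAxis) -> np.ndarray:
    """Evaluate an endmember on a wavenumber axis (sum of Gaussians, AU)."""
    nu = axis.values
    out = np.zeros_like(nu)
    for band in endmember.bands:
        out += band.amplitude * np.exp(
            -((nu - band.center) ** 2) / (2.0 * band.width**2)
        )
    return out


@dataclass
class PhantomTruth:
    """Planted ground truth of one phantom."""

    class_map: np.ndarray  # H x W int codes (BACKGROUND..FIBROSIS_B)
    abundance: dict[str, np.ndarray]  # class name -> H x W weight
    fibrosis_fraction: float  # % of valid (tissue) pixels
    seed: int

    @property
    def tissue(self) -> np.ndarray:
        return self.class_map != BACKGROUND

    @property
    def fibrosis(self) -> np.ndarray:
        return (self.class_map == FIBROSIS_A) | (self.class_map == FIBROSIS_B)

    def recompute_fraction(self) -> float:
        return 100.0 * self.fibrosis.sum() / self.tissue.sum()


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom.

    Defaults model a 64 x 64 whole-sample image on a 900-1800 cm^-1 axis at
    2 cm^-1 point spacing, ~30% fibrosis, per-pixel paraffin amplitudes in
    [0.3, 0.7] AU, a degree-2 random baseline, scatter multipliers in
    [0.7, 1.3] and 0.01 AU white noise.
    """

    height: int = 64
    width: int = 64
    wn_lo: float = 900.0
    wn_hi: float = 1800.0
    wn_step: float = 2.0
    fibrosis_percent: float = 30.0
    paraffin_amp: tuple[float, float] = (0.3, 0.7)
    baseline_degree: int = 2
    baseline_coeff: tuple[float, float] = (-0.05, 0.05)
    scatter: tuple[float, float] = (0.7, 1.3)
    noise_sigma: float = 0.01
    bio_sigma: float = 0.08  # relative within-class band-amplitude variability
    n_bio_modes: int = 3
    fibrosis_b_fraction: float = 0.3
    septa_smoothness: float = 6.0  # px, Gaussian sigma of the septa field
    nuclei_fraction: float = 0.06  # nodule pixels rendered as nuclei
    pixel_size: float = 25.0  # µm
    paraffin_shape: tuple[int, int] = (16, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("paraffin_amp", "baseline_coeff", "scatter"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is not well-ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.wn_lo >= self.wn_hi or self.wn_step <= 0:
            raise ValueError("wavenumber grid is not well-ordered")

    def make_axis(self) -> WavenumberAxis:
        n = int(round((self.wn_hi - self.wn_lo) / self.wn_step)) + 1
        return WavenumberAxis(self.wn_lo + self.wn_step * np.arange(n))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def synth_label_map(config: PhantomConfig) -> PhantomTruth:
    """Plant a nodule/septa geometry hitting the target fibrosis fraction.

    The septa are the near-zero level set of a smoothed Gaussian random
    field: the zero contour of a smooth field forms connected, ribbon-like
    curves that partition the plane into blobs, which is exactly the
    nodule-and-septa morphology of cirrhotic tissue.  The band half-width is
    set by the empirical quantile of |field| among tissue pixels, so the
    achieved fibrosis fraction matches the target to pixel resolution.
    """
    if not 0.0 < config.fibrosis_percent < 100.0:
        raise ValueError("target fibrosis fraction must be in (0, 100)%")
    h, w = config.height, config.width
    rng = _rng(config.seed, 0)

    # elliptical tissue blob with a background margin
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    tissue = ((yy - cy) / (0.46 * h)) ** 2 + ((xx - cx) / (0.46 * w)) ** 2 <= 1.0

    fld = gaussian_filter(rng.standard_normal((h, w)), config.septa_smoothness)
    absfld = np.abs(fld)
    thr = np.quantile(absfld[tissue], config.fibrosis_percent / 100.0)
    fibrosis = tissue & (absfld <= thr)
    achieved = 100.0 * fibrosis.sum() / tissue.sum()
    if abs(achieved - config.fibrosis_percent) > 1.0:
        raise RuntimeError(
            f"could not reach target fraction: got {achieved:.2f}% "
            f"for target {config.fibrosis_percent:.2f}%"
        )

    # split septa into the two collagen sub-variants with a second smooth field
    sub = gaussian_filter(rng.standard_normal((h, w)), config.septa_smoothness)
    class_map = np.full((h, w), BACKGROUND, dtype=np.int8)
    class_map[tissue] = NODULE
    class_map[fibrosis] = FIBROSIS_A
    if config.fibrosis_b_fraction > 0 and fibrosis.any():
        cut = np.quantile(sub[fibrosis], 1.0 - config.fibrosis_b_fraction)
        class_map[fibrosis & (sub > cut)] = FIBROSIS_B

    abundance = {
        name: (class_map == code).astype(np.float64)
        for code, name in CLASS_NAMES.items()
        if code != BACKGROUND
    }
    return PhantomTruth(class_map, abundance, achieved, config.seed)


_CLASS_TO_ENDMEMBER = {
    NODULE: "glycogen_nodule",
    FIBROSIS_A: "collagen_a",
    FIBROSIS_B: "collagen_b",
}


def _random_baseline(rng, poly_basis: np.ndarray, coeff_range, n: int) -> np.ndarray:
    """n random smooth baselines as rows (n, B)."""
    lo, hi = coeff_range
    coeffs = rng.uniform(lo, hi, size=(n, poly_basis.shape[1]))
    return coeffs @ poly_basis.T


def _poly_basis(axis: WavenumberAxis, degree: int) -> np.ndarray:
    x = np.linspace(-1.0, 1.0, len(axis))
    return np.vander(x, degree + 1, increasing=True)


def synth_cube(
    truth: PhantomTruth,
    endmembers: dict[str, Endmember],
    config: PhantomConfig,
) -> tuple[SpectralImage, SpectralImage]:
    """Render (tissue cube, pure-paraffin cube) from a planted class map."""
    present = {_CLASS_TO_ENDMEMBER[c] for c in _CLASS_TO_ENDMEMBER
               if (truth.class_map == c).any()}
    missing = (present | {"paraffin"}) - set(endmembers)
    if missing:
        raise ValueError(f"missing endmembers for classes: {sorted(missing)}")

    axis = config.make_axis()
    h, w = truth.class_map.shape
    spectra = {name: synth_spectrum(em, axis) for name, em in endmembers.items()}
    paraffin = spectra["paraffin"]
    rng = _rng(truth.seed, 1)
    poly = _poly_basis(axis, config.baseline_degree)

    n_px = h * w
    flat_class = truth.class_map.ravel()
    pure = np.zeros((n_px, len(axis)))
    for code, em_name in _CLASS_TO_ENDMEMBER.items():
        sel = flat_class == code
        if not sel.any():
            continue
        pure[sel] = spectra[em_name]
        if config.bio_sigma > 0 and config.n_bio_modes > 0:
            # within-class biochemical variability: a few random
            # band-amplitude perturbation modes per class, i.i.d. per pixel
            em = endmembers[em_name]
            scale = config.bio_sigma / np.sqrt(config.n_bio_modes)
            modes = np.zeros((config.n_bio_modes, len(axis)))
            for j in range(config.n_bio_modes):
                delta = rng.normal(0.0, scale, size=len(em.bands))
                for d, band in zip(delta, em.bands):
                    modes[j] += d * band.amplitude * np.exp(
                        -((axis.values - band.center) ** 2)
                        / (2.0 * band.width**2))
            z = rng.standard_normal((int(sel.sum()), config.n_bio_modes))
            pure[sel] += z @ modes

    amp = rng.uniform(*config.paraffin_amp, size=n_px)
    scatter = rng.uniform(*config.scatter, size=n_px)
    baseline = _random_baseline(rng, poly, config.baseline_coeff, n_px)
    noise = rng.normal(0.0, config.noise_sigma, size=(n_px, len(axis))) \
        if config.noise_sigma > 0 else 0.0
    cube = scatter[:, None] * (pure + baseline + amp[:, None] * paraffin) + noise
    image = SpectralImage(
        cube.reshape(h, w, len(axis)), axis, config.pixel_size,
        truth.tissue, sample_id=f"phantom{truth.seed:04d}",
    )

    # pure-paraffin reference cube from the slide periphery
    ph, pw = config.paraffin_shape
    n_ref = ph * pw
    ref_amp = rng.uniform(0.8, 1.2, size=n_ref)
    ref_base = _random_baseline(rng, poly, config.baseline_coeff, n_ref)
    ref_noise = rng.normal(0.0, config.noise_sigma, size=(n_ref, len(axis))) \
        if config.noise_sigma > 0 else 0.0
    ref = ref_amp[:, None] * paraffin + ref_base + ref_noise
    paraffin_img = SpectralImage(
        ref.reshape(ph, pw, len(axis)), axis, config.pixel_size,
        sample_id=f"phantom{truth.seed:04d}_paraffin",
    )
    return image, paraffin_img


# -- trichrome rendering -----------------------------------------------------

# per-class stain concentrations (collagen, cytoplasm, nuclei)
_STAIN_LEVELS = {
    NODULE: (0.0, 0.6, 0.0),
    FIBROSIS_A: (0.85, 0.05, 0.0),
    FIBROSIS_B: (0.85, 0.05, 0.0),
}
_NUCLEUS = (0.0, 0.1, 1.2)


def synth_trichrome(truth: PhantomTruth, scale: float = 1.0,
                    nuclei_fraction: float = 0.06) -> RGBImage:
    """Render a Masson's-trichrome image of the planted class map.

    Fibrosis pixels carry the green collagen stain, nodules pink cytoplasm
    with scattered black nuclei, background stays white.  Pixel values follow
    the Beer-Lambert optical-density model used by the stain-deconvolution
    module, so deconvolution inverts the rendering.
    """
    from .dia import StainVectors  # local import to avoid a cycle

    rng = _rng(truth.seed, 2)
    h, w = truth.class_map.shape
    conc = np.zeros((h, w, 3))
    for code, levels in _STAIN_LEVELS.items():
        sel = truth.class_map == code
        conc[sel] = levels
    nodule = truth.class_map == NODULE
    if nodule.any():
        u = rng.random(int(nodule.sum()))
        nuc = np.zeros((h, w), dtype=bool)
        nuc[nodule] = u < nuclei_fraction
        conc[nuc] = _NUCLEUS
    # mild seeded intensity variation so stain maps are not flat
    jitter = 1.0 + 0.05 * gaussian_filter(rng.standard_normal((h, w)), 2.0)
    conc *= jitter[:, :, None]

    vectors = StainVectors.masson_default()
    od = conc @ vectors.od_matrix  # H x W x 3 optical densities per channel
    pixels = np.rint(vectors.background * np.power(10.0, -od) - 1.0)
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)
    return RGBImage(pixels, scale)


def make_phantom(
    config: PhantomConfig,
    endmembers: dict[str, Endmember] | None = None,
) -> tuple[PhantomTruth, SpectralImage, SpectralImage, RGBImage]:
    """Generate the full paired artifact set for one phantom."""
    endmembers = endmembers or default_endmembers()
    truth = synth_label_map(config)
    cube, paraffin = synth_cube(truth, endmembers, config)
    trichrome = synth_trichrome(truth, scale=config.pixel_size,
                                nuclei_fraction=config.nuclei_fraction)
    return truth, cube, paraffin, trichrome
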