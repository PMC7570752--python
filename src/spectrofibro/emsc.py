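"""Extended multiplicative signal correction (EMSC) digital dewaxing.

Each pixel spectrum ``s`` of a paraffin-embedded FTIR image is modelled by
ordinary least squares as

    s  =  a * m  +  P @ b  +  T @ c  +  e

where ``m`` is a reference tissue spectrum, the columns of ``P`` span the
paraffin interference (mean paraffin spectrum plus principal components of a
pure-paraffin cube recorded on the same slide), ``T`` holds polynomial
baseline columns on the axis rescaled to [-1, 1], and ``a`` is a
multiplicative scatter/thickness factor.  The corrected spectrum

    (s - P @ b - T @ c) / a

is simultaneously dewaxed, baseline-corrected and normalized.  Pixels whose
scale ``a`` is inadmissible relative to the image median (bare substrate,
holes) are flagged as outliers and dropped from the mask; a residual-based
rule is available opt-in.

The reference ``m`` is estimated from the image itself in two passes (mean
spectrum, then mean of corrected spectra) and finally purged of the mean
paraffin level, which is common to every pixel and therefore invisible to
an in-image reference estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import SpectralImage, WavenumberAxis

__all__ = [
    "EMSCBasis",
    "EMSCFit",
    "build_poly_basis",
    "build_paraffin_basis",
    "reduce_interference",
    "estimate_reference",
    "fit_emsc",
    "apply_correction",
    "flag_outliers",
    "dewax",
    "dewax_common",
]

A_BOUNDS_DEFAULT = (0.2, 5.0)
KAPPA_DEFAULT = 5.0
_RMSE_FLOOR = 1e-10  # AU, guards the MAD rule on noise-free data


class ModelError(ValueError):
    """Ill-posed EMSC design (rank deficiency, dimension mismatch)."""


@dataclass
class EMSCBasis:
    """Design components of the EMSC model on a fixed wavenumber axis."""

    reference: np.ndarray  # (B,)
    interference: np.ndarray  # (B, J)
    poly: np.ndarray  # (B, D+1)
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        b = len(self.axis)
        self.reference = np.asarray(self.reference, dtype=np.float64).reshape(b)
        self.interference = np.atleast_2d(np.asarray(self.interference, float))
        if self.interference.shape[0] != b:
            self.interference = self.interference.T
        self.poly = np.asarray(self.poly, dtype=np.float64)
        if self.poly.shape[0] != b:
            raise ModelError("polynomial basis rows must match axis length")
        for name, arr in (("reference", self.reference),
                          ("interference", self.interference),
                          ("poly", self.poly)):
            if not np.all(np.isfinite(arr)):
                raise ModelError(f"non-finite values in {name}")

    @property
    def design(self) -> np.ndarray:
        """Full design matrix [m | P | T], shape (B, 1 + J + D + 1)."""
        return np.column_stack([self.reference, self.interference, self.poly])


@dataclass
class EMSCFit:
    """Per-pixel EMSC coefficients and residual diagnostics."""

    a: np.ndarray  # H x W
    b: np.ndarray  # H x W x J
    c: np.ndarray  # H x W x (D+1)
    rmse: np.ndarray  # H x W
    outlier: np.ndarray  # H x W bool
    valid: np.ndarray  # H x W bool, pixels the fit covers


def build_poly_basis(axis: WavenumberAxis, degree: int) -> np.ndarray:
    """Monomial columns 1, x, .., x^degree on the axis rescaled to [-1, 1]."""
    nu = axis.values
    x = 2.0 * (nu - nu[0]) / (nu[-1] - nu[0]) - 1.0
    return np.vander(x, degree + 1, increasing=True)


def build_paraffin_basis(paraffin: SpectralImage, n_components: int) -> np.ndarray:
    """Paraffin interference matrix: mean spectrum + PCA loadings.

    Column 0 is the mean valid paraffin spectrum; the remaining
    ``n_components - 1`` columns are the leading principal-component loadings
    of the mean-centered paraffin spectra, unit norm, with the sign fixed so
    the largest-magnitude element is positive.
    """
    return paraffin_basis_from_spectra(paraffin.valid_spectra(), n_components)


def paraffin_basis_from_spectra(spectra: np.ndarray,
                                n_components: int) -> np.ndarray:
    """Array-level variant of :func:`build_paraffin_basis` for pooled cubes."""
    n, b = spectra.shape
    if n < n_components:
        raise ModelError(
            f"paraffin cube has {n} valid pixels < {n_components} components"
        )
    mean = spectra.mean(axis=0)
    cols = [mean]
    n_pc = n_components - 1
    if n_pc > 0:
        centered = spectra - mean
        # economy SVD: right singular vectors are the loadings
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
        if n_pc > rank:
            raise ModelError(
                f"requested {n_pc} principal components but paraffin "
                f"variation has rank {rank}"
            )
        for j in range(n_pc):
            v = vt[j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            cols.append(v)
    return np.column_stack(cols)


def _correct_matrix(spectra: np.ndarray, design: np.ndarray) -> np.ndarray:
    """EMSC-correct rows of (N, B) against a given design; helper for the
    reference estimate."""
    coef, *_ = np.linalg.lstsq(design, spectra.T, rcond=None)
    a = coef[0]
    nuisance = design[:, 1:] @ coef[1:]
    a = np.where(np.abs(a) < 1e-6, 1.0, a)
    return (spectra - nuisance.T) / a[:, None]


def reduce_interference(interference: np.ndarray, poly: np.ndarray,
                        tol: float = 1e-8) -> np.ndarray:
    """Remove interference directions already representable by the baseline.

    Paraffin cubes recorded on a real slide carry their own baselines, so
    principal components of the paraffin variation can duplicate polynomial
    columns and make the joint design singular.  This projects every
    interference column onto the orthogonal complement of the polynomial
    block, drops columns that (almost) vanish, and re-orthonormalizes the
    trailing principal-component columns.
    """
    interference = np.atleast_2d(np.asarray(interference, float))
    qt, _ = np.linalg.qr(poly)
    proj = interference - qt @ (qt.T @ interference)
    col0 = proj[:, 0]
    if np.linalg.norm(col0) < tol * max(np.linalg.norm(interference[:, 0]), 1.0):
        raise ModelError("paraffin mean spectrum lies in the baseline span")
    cols = [col0]
    if proj.shape[1] > 1:
        rest = proj[:, 1:]
        u0 = col0 / np.linalg.norm(col0)
        rest = rest - np.outer(u0, u0 @ rest)
        u, s, _ = np.linalg.svd(rest, full_matrices=False)
        keep = s > tol * max(s[0], 1.0) if s.size else np.array([], bool)
        for j in np.nonzero(keep)[0]:
            v = u[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            cols.append(v)
    return np.column_stack(cols)


def estimate_reference(
    image: SpectralImage,
    interference: np.ndarray,
    poly: np.ndarray,
) -> np.ndarray:
    """Two-pass in-image reference estimate, paraffin-purged.

    Pass 1 uses the mean valid spectrum as a provisional reference; pass 2
    averages the spectra corrected against it.  The image-wide mean paraffin
    level survives both passes (it is common to every pixel, so correcting
    against an in-image reference cannot see it), so it is removed
    explicitly: each interference column's coefficient in the average is
    estimated from its narrow-band structure — the high-pass residual after
    Gaussian smoothing, which is spatially localized, so tissue bands at
    other wavenumbers cannot couple into it — and the *full* column (bands
    plus smooth part) is subtracted.  The result is rescaled to unit mean
    absorbance.
    """
    return reference_from_spectra(image.valid_spectra(), interference, poly)


def _narrowband(x: np.ndarray, sigma_points: float) -> np.ndarray:
    """High-pass: remove structure broader than ~sigma_points grid steps."""
    from scipy.ndimage import gaussian_filter1d

    return x - gaussian_filter1d(x, sigma_points, axis=0, mode="nearest")


def reference_from_spectra(spectra: np.ndarray, interference: np.ndarray,
                           poly: np.ndarray,
                           purge_sigma_points: float = 15.0) -> np.ndarray:
    """Array-level variant of :func:`estimate_reference` for pooled cubes."""
    if spectra.shape[0] == 0:
        raise ValueError("image has no valid pixels")
    interference = np.atleast_2d(np.asarray(interference, float))
    if interference.shape[0] != spectra.shape[1]:
        interference = interference.T
    m0 = spectra.mean(axis=0)
    design = np.column_stack([m0, interference, poly])
    corrected = _correct_matrix(spectra, design)
    m = corrected.mean(axis=0)
    p_band = _narrowband(interference, purge_sigma_points)
    # generous cutoff: columns with almost no narrow-band structure are
    # baseline look-alikes; estimating their coefficient from what little
    # remains would amplify noise into the reference
    beta = np.linalg.pinv(p_band, rcond=5e-2) @ _narrowband(
        m[:, None], purge_sigma_points)[:, 0]
    m = m - interference @ beta
    mean_abs = m.mean()
    if abs(mean_abs) < 1e-12:
        raise ValueError("estimated reference has ~zero mean absorbance")
    return m / mean_abs


def fit_emsc(
    image: SpectralImage,
    basis: EMSCBasis,
    a_bounds: tuple[float, float] = A_BOUNDS_DEFAULT,
    kappa: float | None = None,
    flag: bool = True,
) -> EMSCFit:
    """Per-pixel OLS fit of the EMSC model; optionally flags outliers."""
    if len(basis.axis) != image.cube.shape[2]:
        raise ModelError("basis axis length does not match image")
    if not np.allclose(basis.axis.values, image.axis.values):
        raise ModelError("basis axis differs from image axis")
    design = basis.design
    b_len, n_col = design.shape
    if np.linalg.matrix_rank(design) < n_col:
        # identify which columns are collinear for the error message
        names = (["reference"]
                 + [f"interference[{j}]" for j in range(basis.interference.shape[1])]
                 + [f"poly[{d}]" for d in range(basis.poly.shape[1])])
        _, r = np.linalg.qr(design)
        bad = [names[i] for i in range(n_col)
               if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
        raise ModelError(f"design matrix rank-deficient; collinear: {bad}")

    h, w, _ = image.cube.shape
    j = basis.interference.shape[1]
    d1 = basis.poly.shape[1]
    spectra = image.valid_spectra()
    coef, *_ = np.linalg.lstsq(design, spectra.T, rcond=None)
    resid = spectra.T - design @ coef
    rmse_valid = np.sqrt(np.mean(resid**2, axis=0))

    a = np.zeros((h, w))
    b = np.zeros((h, w, j))
    c = np.zeros((h, w, d1))
    rmse = np.zeros((h, w))
    a[image.mask] = coef[0]
    b[image.mask] = coef[1:1 + j].T
    c[image.mask] = coef[1 + j:].T
    rmse[image.mask] = rmse_valid
    fit = EMSCFit(a, b, c, rmse, np.zeros((h, w), dtype=bool),
                  image.mask.copy())
    if flag:
        fit = flag_outliers(fit, a_bounds, kappa)
    return fit


def flag_outliers(
    fit: EMSCFit,
    a_bounds: tuple[float, float] = A_BOUNDS_DEFAULT,
    kappa: float | None = KAPPA_DEFAULT,
) -> EMSCFit:
    """Flag pixels with inadmissible scale or anomalous residual.

    A pixel is an outlier when its scale ``a`` falls outside ``a_bounds``
    *relative to the image median scale* (so the rule is invariant to an
    overall intensity rescaling of the data), or when its residual RMS
    exceeds ``median + kappa * MAD`` over valid pixels (MAD in robust-sigma
    units, with a tiny absolute floor so numerically-zero residuals never
    trip the rule).  Larger ``kappa`` always flags fewer pixels;
    ``kappa=None`` disables the residual component entirely.

    Note that on heterogeneous tissue the residual against a single global
    reference confounds junk with spectrally distinct minority tissue, so
    the quantification pipeline flags on the scale alone by default and
    leaves the residual rule opt-in.
    """
    valid = fit.valid
    med_a = float(np.median(fit.a[valid]))
    lo, hi = a_bounds[0] * med_a, a_bounds[1] * med_a
    out = np.zeros_like(fit.outlier)
    out[valid] = (fit.a[valid] < lo) | (fit.a[valid] > hi)
    if kappa is not None:
        rmse_v = fit.rmse[valid]
        med = np.median(rmse_v)
        mad = 1.4826 * np.median(np.abs(rmse_v - med))  # robust sigma
        thr = med + kappa * mad + _RMSE_FLOOR
        out[valid] |= fit.rmse[valid] > thr
    return replace(fit, outlier=out)


def apply_correction(
    image: SpectralImage,
    fit: EMSCFit,
    basis: EMSCBasis,
) -> SpectralImage:
    """Subtract interference and baseline, divide by the scale.

    Outlier pixels are removed from the returned mask; their cube values are
    left untouched.
    """
    h, w, b_len = image.cube.shape
    corrected = image.cube.copy()
    keep = fit.valid & ~fit.outlier
    a = fit.a[keep]
    if np.any(np.abs(a) < 1e-8):
        raise FloatingPointError(
            "scale coefficient ~0 at a non-outlier pixel; tighten a_bounds"
        )
    nuisance = (fit.b[keep] @ basis.interference.T
                + fit.c[keep] @ basis.poly.T)
    corrected[keep] = (image.cube[keep] - nuisance) / a[:, None]
    return SpectralImage(corrected, image.axis, image.pixel_size,
                         keep, image.sample_id, image.group)


def _shared_basis(
    tissue_spectra: np.ndarray,
    paraffin_spectra: np.ndarray,
    axis: WavenumberAxis,
    n_interference: int,
    poly_degree: int,
) -> EMSCBasis:
    """Basis from pooled tissue and paraffin spectra (rank-adaptive)."""
    try:
        interference = paraffin_basis_from_spectra(paraffin_spectra,
                                                   n_interference)
    except ModelError:
        # fall back to however many components the paraffin cube supports
        mean = paraffin_spectra.mean(axis=0)
        s = np.linalg.svd(paraffin_spectra - mean, compute_uv=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
        interference = paraffin_basis_from_spectra(
            paraffin_spectra, max(1, min(n_interference, rank + 1)))
    poly = build_poly_basis(axis, poly_degree)
    # reference purge uses the full columns; the fit design the reduced ones
    reference = reference_from_spectra(tissue_spectra, interference, poly)
    interference = reduce_interference(interference, poly)
    return EMSCBasis(reference, interference, poly, axis)


def dewax(
    image: SpectralImage,
    paraffin: SpectralImage,
    n_interference: int = 10,
    poly_degree: int = 4,
    a_bounds: tuple[float, float] = A_BOUNDS_DEFAULT,
    kappa: float | None = None,
) -> tuple[SpectralImage, EMSCFit, EMSCBasis]:
    """One-call digital dewaxing: basis, reference, fit, correction.

    ``n_interference`` counts the paraffin columns (mean + PCs); it is
    reduced automatically if the paraffin cube has lower rank.
    """
    basis = _shared_basis(image.valid_spectra(), paraffin.valid_spectra(),
                          image.axis, n_interference, poly_degree)
    fit = fit_emsc(image, basis, a_bounds=a_bounds, kappa=kappa)
    corrected = apply_correction(image, fit, basis)
    return corrected, fit, basis


def dewax_common(
    images: list[SpectralImage],
    paraffins: list[SpectralImage],
    n_interference: int = 10,
    poly_degree: int = 4,
    a_bounds: tuple[float, float] = A_BOUNDS_DEFAULT,
    kappa: float | None = None,
) -> tuple[list[SpectralImage], list[EMSCFit], EMSCBasis]:
    """Dewax many images against one shared basis and reference.

    For analyses that pool spectra across images (common k-means), a
    per-image reference would imprint each image's own composition on its
    corrected spectra and the pooled classes would sort by image rather than
    by tissue.  Here one paraffin model and one reference are estimated from
    all images together; every image is then fitted and corrected against
    that shared basis.
    """
    if len(images) != len(paraffins) or not images:
        raise ValueError("need equally many images and paraffin cubes (>= 1)")
    axis0 = images[0].axis
    for img in images[1:] + paraffins:
        if not np.allclose(img.axis.values, axis0.values):
            raise ValueError("all cubes must share one wavenumber axis")
    pooled_tissue = np.vstack([img.valid_spectra() for img in images])
    pooled_paraffin = np.vstack([p.valid_spectra() for p in paraffins])
    basis = _shared_basis(pooled_tissue, pooled_paraffin, axis0,
                          n_interference, poly_degree)
    corrected, fits = [], []
    for img in images:
        fit = fit_emsc(img, basis, a_bounds=a_bounds, kappa=kappa)
        corrected.append(apply_correction(img, fit, basis))
        fits.append(fit)
    return corrected, fits, basis
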