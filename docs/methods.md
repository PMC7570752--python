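# Methods

This note documents the models implemented in `spectrofibro`, their
assumptions, the defaults that matter, and the design decisions taken where
the methodology was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A `SpectralImage` is an H×W grid of absorbance spectra on a common,
strictly ascending, uniformly spaced wavenumber axis (cm⁻¹), with a boolean
validity mask and a pixel size in µm. FTIR files conventionally store the
axis descending; readers normalize on load so all in-memory math can assume
ascending order. HDF5 is the canonical interchange format; ENVI (text
header + raw BSQ float32) and a long-format CSV (`row, col, wavenumber,
absorbance`, valid pixels only — which is also how the mask round-trips)
are supported for interoperability and human-inspectable fixtures. Spectral
windows are closed intervals on both ends: `crop_range(x, 900, 1800)`
keeps every grid point ν with 900 ≤ ν ≤ 1800.

Analysis windows: whole-sample work uses the 900–1800 cm⁻¹ fingerprint
region; the fibrosis-focus analysis uses 1040–1425 cm⁻¹, which contains
most collagen bands while excluding the strong 1462 cm⁻¹ paraffin band.
The EMSC fit is restricted to the same window as the downstream analysis.

## EMSC digital dewaxing

Per valid pixel, ordinary least squares of

    s = a·m + P·b + T·c + e

* `m` — reference tissue spectrum (below);
* `P` — interference matrix: column 0 is the mean spectrum of the
  pure-paraffin cube recorded at the tissue periphery; the remaining
  columns are the leading PCA loadings of the mean-centered paraffin
  spectra (unit norm, sign fixed so the largest-magnitude element is
  positive). Default J = 10 columns, reduced automatically when the
  paraffin cube has lower rank.
* `T` — monomials of degree 0…D on the axis rescaled to [−1, 1];
  default D = 4.

The corrected spectrum is `(s − P·b − T·c)/a`: dewaxed, baseline-corrected
and normalized by the multiplicative scale in one step. No separate vector
normalization is applied.

Three refinements proved necessary in practice:

**Interference reduction.** A paraffin cube recorded on a real slide has
its own baselines, so paraffin PCA loadings can duplicate polynomial
columns and make the joint design `[m | P | T]` singular. Interference
columns are therefore projected onto the orthogonal complement of the
polynomial block; columns that (almost) vanish are dropped and the rest
re-orthonormalized. An exactly rank-deficient design (e.g. an interference
column passed in that *is* a polynomial) still raises an error naming the
collinear columns.

**Reference estimation with paraffin purge.** The reference is estimated
from the image itself in two passes (the mean valid spectrum, then the mean
of spectra corrected against it) because no external reference exists for
FFPE tissue. A subtlety: the image-wide *mean* paraffin level survives both
passes — it is common to every pixel, so correcting against an in-image
reference cannot see it, and it would re-enter every corrected spectrum
through `a·m`. The purge estimates each interference column's coefficient
in the two-pass mean from its narrow-band structure (the high-pass residual
after Gaussian smoothing with σ = 15 grid points ≈ 30 cm⁻¹; high-pass
residuals are spatially localized, so tissue bands at other wavenumbers
cannot couple into the coefficient) and subtracts the full column.
Columns with almost no narrow-band structure are baseline look-alikes and
are excluded from the purge (pseudo-inverse cutoff 5 × 10⁻²) — estimating
their coefficient from what little remains would amplify noise into the
reference. The purged reference is rescaled to unit mean absorbance over
the fitting window.

**Outlier flagging.** A pixel is flagged when its scale `a` falls outside
`a_bounds = [0.2, 5]` *relative to the image-median scale*. Relative bounds
keep the rule invariant to an overall intensity rescaling of the data
(scaling every spectrum by λ scales every `a` by λ and leaves corrected
spectra and flags unchanged) and remain meaningful when the unit-mean
reference puts the typical scale far from 1. An additional residual rule —
flag `rmse > median + κ·MAD` (MAD in robust-σ units, κ = 5) — is
implemented and available, but the pipelines do not enable it by default:
on heterogeneous tissue the residual against a single global reference
confounds junk with spectrally distinct minority tissue. On phantoms with
5% fibrosis the fibrosis pixels' residuals sit 6–7× above the image median,
indistinguishable by magnitude from moderate junk, and any threshold that
keeps them passes order-of-magnitude garbage. The scale rule, by contrast,
catches the practically relevant junk (bare substrate, holes, tears — all
with `a ≈ 0` or wildly off) without touching minority tissue. Users who
want the residual rule opt in via `kappa`.

For analyses that pool spectra across images (common k-means),
`dewax_common` estimates **one** paraffin model and **one** reference from
all images together and corrects every image against that shared basis. A
per-image reference would imprint each image's own composition on its
corrected spectra, and pooled classes would sort by image rather than by
tissue — this failure mode is directly observable on phantoms.

## Clustering and quantification

K-means uses Euclidean distance, k-means++ initialization with 10 restarts
(keeping the lowest inertia), convergence at relative inertia change
< 10⁻⁶ or 300 iterations; a `random` initialization mode reproduces the
historical choice of random spectra as initial centroids. After
convergence, classes are relabeled canonically by descending size (ties:
original label) so seeds and pooling order give stable ids, and centroids
are recomputed as exact class means of the final assignment. Pseudo-colors
come from a fixed palette indexed by class id, so the same class keeps the
same color across images of a common model.

Annotation correlates each centroid with reference templates (the built-in
collagen and glycogen endmembers by default) over the analysis window and
assigns the tissue label of the best-correlated template; a manual mapping
always wins; correlation ties (< 10⁻¹²) raise rather than guess. The
fibrosis-area percentage is 100 × (pixels in fibrosis-annotated classes) /
(valid pixels); percentages over all tissue labels sum to 100 exactly.

## Second-derivative band analysis

Savitzky–Golay second derivatives (window 9 points, polyorder 3 — the
method's usual sweet spot at 2 cm⁻¹ point spacing; both exposed) divided by
the grid spacing squared, so units are AU/cm⁻². Absorption bands are minima
of the second derivative. Band picking reports local minima deeper than a
prominence floor and attaches the nearest tabulated assignment within
±6 cm⁻¹ — the tolerance absorbs the range notation of published
assignments (e.g. 1202–1204 cm⁻¹). Hierarchical clustering of centroid
spectra uses Ward linkage on Euclidean distances (configurable); the
two-group cut is taken at the root merge, which is well defined even with
tied or zero distances.

## Trichrome digital image analysis

Beer–Lambert color deconvolution in the Ruifrok–Johnston convention:
per-channel optical density `OD = −log₁₀((pixel + 1)/I₀)` (the +1 keeps
8-bit zeros finite), concentrations = OD row-vector × inverse stain matrix,
negatives clipped. The default Masson vectors (rows: collagen/green
(0.65, 0.10, 0.75), cytoplasm/pink (0.10, 0.90, 0.42), nuclei/black
(0.577, 0.577, 0.577), each normalized) are package constants and fully
overridable — published stain vectors vary by scanner and batch. Tissue is
binarized at summed OD > 0.15 (near-white paraffin background falls well
below); collagen pixels must dominate both other channels *and* exceed an
Otsu threshold computed on collagen concentrations within tissue. When the
collagen distribution is flat (uniformly stained section) the Otsu split
would be meaningless and is skipped. The fibrosis percentage is
100 × collagen / tissue pixels.

## Statistics

Pearson's r by the product-moment formula; two-sided p from
`t = r·√(n−2)/√(1−r²)` with n−2 degrees of freedom — the exact
transformation appropriate at n ≤ 10, where permutation adds nothing.
Outlier exclusion is an explicit caller-supplied id list, logged in the
result, never automatic: a reader must be able to audit exactly which
points an analysis dropped. Group summaries are descriptive only (mean,
SD); no between-group test is offered at n = 5 per group. The
fibrosis-subclass proportion table pools, within each group, all pixels of
fibrosis-annotated classes and reports each class's share of that pool;
columns sum to 100 by construction.

## Synthetic phantoms

The generator emulates the study conditions: cirrhotic tissue as nodules
separated by a connected septa network, imaged at 25 µm (whole sample,
64×64 px default) or 2.7 µm (fibrosis regions), on a 900–1800 cm⁻¹ axis at
2 cm⁻¹ spacing (the optical resolution of such instruments is 4 cm⁻¹; the
digitized point spacing is finer and configurable).

* **Geometry.** The septa are the near-zero level set of a
  Gaussian-smoothed random field inside an elliptical tissue blob: the zero
  contour of a smooth field forms connected ribbons partitioning the plane
  into blobs — precisely the nodule/septa morphology. The band half-width
  is an empirical quantile of |field|, so the achieved fibrosis fraction
  matches the target to pixel resolution (±1 point guaranteed, usually
  ±0.05). A second smooth field splits the septa into the two collagen
  sub-variants at a planted share.
* **Endmembers.** Sums of Gaussian bands (σ = 8 cm⁻¹ for fingerprint
  bands). All tissue endmembers share an amide I/II protein backbone
  (1655 cm⁻¹, σ 25; 1548 cm⁻¹, σ 22) and are scaled to one common mean
  absorbance (0.25 AU over the fingerprint): adjacent compartments of one
  section differ in band profile, not in bulk absorbance, and without the
  shared backbone a single-reference EMSC scale would be class-dependent
  and meaningless. Glycogen nodules: 1022/1045/1080/1155 cm⁻¹. Collagen A:
  carbohydrate 1050/1064/1084, then 1174/1202/1230/1250/1278/1304/1340/
  1404 cm⁻¹. Collagen B (advanced, crosslinked fibrosis): amide III bands
  (1204/1234/1284) intensified 1.3×, the 1250 and 1340 cm⁻¹ features
  downshifted to 1244 and 1342 cm⁻¹. Paraffin: 1378 and 1462 cm⁻¹ (CH₃/CH₂
  deformation). Relative amplitudes are free modelling parameters, not
  claims about real tissue.
* **Pixel model.** `s = scatter·(endmember + Δ_bio + baseline +
  amp·paraffin) + noise`, with scatter uniform in [0.7, 1.3], per-pixel
  paraffin amplitude uniform in [0.3, 0.7] AU, a random polynomial baseline
  (degree ≤ 2, coefficients ±0.05), white noise σ = 0.01 AU, and Δ_bio a
  low-rank within-class variability term (3 random band-amplitude
  perturbation modes per class, 8% relative scale, i.i.d. pixel
  coefficients). The variability term matters: identical per-class pixel
  copies are unrealistic and make any residual-based QC rule degenerate.
  The paired pure-paraffin cube gets its own amplitude variation (0.8–1.2),
  baselines and noise, so its PCA yields genuine interference components.
* **Trichrome rendering.** Per-class stain concentrations (fibrosis:
  collagen 0.85; nodules: cytoplasm 0.6 with 6% scattered nuclei;
  background: zero) with mild smooth intensity jitter, pushed through the
  same Beer–Lambert model the DIA module inverts, quantized to 8 bits.
  Deconvolution therefore recovers concentrations up to quantization
  (≲0.05), and DIA recovers planted fibrosis fractions to well under a
  percentage point.
* **Reproducibility.** All draws descend from a single seed through
  `SeedSequence` spawn keys (label map / cube / trichrome use separate
  streams), so every artifact is reproducible from (config, seed) and the
  streams are mutually independent.

What the phantoms do *not* emulate: resonant Mie scattering and other
wavelength-dependent scatter, atmospheric vapor lines, partial-volume
mixing at class boundaries, instrument drift, real nuclei morphology, and
the full biochemical continuum of tissue. Passing tests on phantoms
demonstrate that the pipeline inverts its own (deliberately faithful)
forward model and recovers planted structure under realistic nuisance
terms — not that it would achieve the same accuracy on real FFPE cubes.

## Problem sizes and numerical choices

Tests and the acceptance script run whole-sample phantoms at 64×64 px
(2 716 tissue pixels) and fibrosis regions at 32×32 px, 6 regions per
group — sizes chosen so the full suite completes in well under a minute
while every pixel count stays large enough for stable quantiles and PCA.
The exhaustive bipartition oracle for k-means optimality runs at n = 12
spectra (2 047 bipartitions). Convergence and tolerance defaults: k-means
tol 10⁻⁶, 300 iterations; EMSC least squares via LAPACK `gelsd`;
equidistant-centroid ties resolve to the lowest class id; empty clusters
are reseeded by scikit-learn's standard mechanism.

## Known limitations

* The EMSC reference is image-internal; two images of the same sample can
  converge to slightly different references unless `dewax_common` is used.
* The residual-based outlier rule is opt-in for the reason given above;
  datasets with junk whose scale coefficient is plausible (e.g. smeared
  tissue) need the κ rule or manual masking.
* Band assignment is nearest-match within ±6 cm⁻¹ against a fixed table;
  shifts smaller than the grid spacing (2 cm⁻¹ default) are not resolvable,
  so distinguishing e.g. 1244 from 1250 cm⁻¹ requires spacing ≤ 2 cm⁻¹.
* Stain vectors are fixed constants, not estimated from the image; real
  slides may need per-batch vectors for accurate deconvolution.
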