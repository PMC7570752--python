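"""Reading, writing and spectral windowing of hyperspectral cubes.

A hyperspectral FTIR image is an H x W grid of absorbance spectra sampled on a
common wavenumber axis (cm^-1).  The canonical in-memory orientation is an
*ascending* axis; files stored descending (the usual FTIR convention) are
reversed on read.  Three interchange formats are supported:

* HDF5 (canonical): datasets ``/cube`` (H x W x B float32), ``/axis``
  (B float64), optional ``/mask`` (H x W uint8), attributes ``pixel_size_um``,
  ``sample_id``, ``group``.
* ENVI: a plain-text ``.hdr`` plus a raw BSQ float32 binary, ``wavelength``
  in cm^-1.
* Long-format CSV: columns ``row, col, wavenumber, absorbance`` — meant for
  tiny, human-inspectable fixtures.  Only valid (unmasked) pixels are written,
  which is also how the mask round-trips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

__all__ = [
    "WavenumberAxis",
    "SpectralImage",
    "RGBImage",
    "read_cube",
    "write_cube",
    "crop_range",
    "read_rgb",
    "write_rgb",
]

GROUPS = ("uncomplicated", "hcc", "unknown")

_AXIS_TOL = 1e-6  # cm^-1, allowed deviation from uniform spacing


class FormatError(ValueError):
    """Malformed file or inconsistent header/payload."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniformly spaced, strictly ascending wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 2:
            raise FormatError("axis must be a 1-D array with at least 2 points")
        d = np.diff(v)
        if not np.all(d > 0):
            raise FormatError("axis must be strictly ascending")
        if np.ptp(d) > _AXIS_TOL:
            raise FormatError(
                f"axis spacing not uniform (spread {np.ptp(d):.3g} cm^-1)"
            )
        object.__setattr__(self, "values", v)

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean selector for the closed interval [lo, hi]."""
        return (self.values >= lo) & (self.values <= hi)


@dataclass
class SpectralImage:
    """Absorbance cube with axis, pixel size, validity mask and metadata.

    ``mask`` is True at valid tissue pixels; masked-out pixels may hold
    arbitrary values and are ignored by all downstream math.
    """

    cube: np.ndarray  # H x W x B, absorbance (AU)
    axis: WavenumberAxis
    pixel_size: float = 25.0  # µm
    mask: np.ndarray | None = None
    sample_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=np.float64)
        if self.cube.ndim != 3:
            raise FormatError("cube must be H x W x B")
        if self.cube.shape[2] != len(self.axis):
            raise FormatError(
                f"cube has {self.cube.shape[2]} bands but axis has "
                f"{len(self.axis)} points"
            )
        if self.mask is None:
            self.mask = np.ones(self.cube.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.cube.shape[:2]:
                raise FormatError("mask shape must equal cube spatial shape")
        if self.group not in GROUPS:
            raise FormatError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.all(np.isfinite(self.cube[self.mask])):
            raise FormatError("non-finite absorbance at valid pixels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cube.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_spectra(self) -> np.ndarray:
        """Valid-pixel spectra as an (N, B) matrix, row-major pixel order."""
        return self.cube[self.mask]


@dataclass
class RGBImage:
    """8-bit RGB histology image with a physical scale in µm/pixel."""

    pixels: np.ndarray  # H x W x 3 uint8
    scale: float = 1.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise FormatError("RGB image must be H x W x 3")
        if p.dtype != np.uint8:
            if p.min() < 0 or p.max() > 255:
                raise FormatError("channel values must lie in [0, 255]")
            p = p.astype(np.uint8)
        self.pixels = p


# ---------------------------------------------------------------------------
# cube I/O


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix in (".hdr", ".envi", ".raw", ".img"):
        return "envi"
    if suffix == ".csv":
        return "csv"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


def read_cube(path: str | Path, format: str | None = None) -> SpectralImage:
    """Read a hyperspectral cube; the returned axis is always ascending."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        img = _read_hdf5(path)
    elif fmt == "envi":
        img = _read_envi(path)
    elif fmt == "csv":
        img = _read_csv(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return _ascending(img)


def write_cube(image: SpectralImage, path: str | Path, format: str | None = None) -> Path:
    """Write a cube so that ``read_cube`` reproduces it (mask included)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        _write_hdf5(image, path)
    elif fmt == "envi":
        _write_envi(image, path)
    elif fmt == "csv":
        _write_csv(image, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


def _ascending(img: SpectralImage) -> SpectralImage:
    return img  # readers already normalize; kept as a single choke point


def _flip_if_descending(cube: np.ndarray, axis_values: np.ndarray):
    if axis_values.size >= 2 and axis_values[1] < axis_values[0]:
        return cube[:, :, ::-1].copy(), axis_values[::-1].copy()
    return cube, axis_values


def _read_hdf5(path: Path) -> SpectralImage:
    with h5py.File(path, "r") as f:
        for name in ("cube", "axis"):
            if name not in f:
                raise FormatError(f"HDF5 file missing dataset /{name}")
        cube = f["cube"][...].astype(np.float64)
        axis_values = f["axis"][...].astype(np.float64)
        if cube.ndim != 3 or cube.shape[2] != axis_values.size:
            raise FormatError(
                f"/cube band count {cube.shape[-1]} does not match /axis "
                f"length {axis_values.size}"
            )
        mask = f["mask"][...].astype(bool) if "mask" in f else None
        attrs = f.attrs
        pixel_size = float(attrs.get("pixel_size_um", 25.0))
        sample_id = str(attrs.get("sample_id", ""))
        group = str(attrs.get("group", "unknown"))
    cube, axis_values = _flip_if_descending(cube, axis_values)
    return SpectralImage(cube, WavenumberAxis(axis_values), pixel_size, mask,
                         sample_id, group)


def _write_hdf5(image: SpectralImage, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=image.cube.astype(np.float64))
        f.create_dataset("axis", data=image.axis.values)
        f.create_dataset("mask", data=image.mask.astype(np.uint8))
        f.attrs["pixel_size_um"] = image.pixel_size
        f.attrs["sample_id"] = image.sample_id
        f.attrs["group"] = image.group


# -- ENVI (text .hdr + raw BSQ float32) -------------------------------------

_ENVI_LIST = re.compile(r"\{([^}]*)\}", re.S)


def _envi_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix.lower() == ".hdr":
        hdr = path
        raw = path.with_suffix(".raw")
        if not raw.exists():
            for alt in (".img", ".dat", ""):
                cand = path.with_suffix(alt)
                if cand != hdr and cand.exists():
                    raw = cand
                    break
    else:
        raw = path
        hdr = path.with_suffix(".hdr")
    return hdr, raw


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # join continuation lines inside { } blocks
    text = re.sub(r"\n(?=[^=]*\})", " ", text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(path: Path) -> SpectralImage:
    hdr_path, raw_path = _envi_paths(Path(path))
    if not hdr_path.exists():
        raise FormatError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        h = int(fields["lines"])
        w = int(fields["samples"])
        b = int(fields["bands"])
    except KeyError as e:
        raise FormatError(f"ENVI header missing field {e.args[0]!r}") from None
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError("only BSQ interleave is supported")
    if int(fields.get("data type", 4)) != 4:
        raise FormatError("only float32 (data type = 4) is supported")
    m = _ENVI_LIST.search(fields.get("wavelength", ""))
    if m is None:
        raise FormatError("ENVI header missing 'wavelength' list")
    axis_values = np.array([float(x) for x in m.group(1).split(",")])
    if axis_values.size != b:
        raise FormatError(
            f"'wavelength' lists {axis_values.size} values but bands = {b}"
        )
    data = np.fromfile(raw_path, dtype="<f4")
    if data.size != h * w * b:
        raise FormatError(
            f"raw file holds {data.size} values, expected {h * w * b}"
        )
    cube = data.reshape(b, h, w).transpose(1, 2, 0).astype(np.float64)
    cube, axis_values = _flip_if_descending(cube, axis_values)
    pixel_size = float(fields.get("pixel size", 25.0))
    sample_id = fields.get("sample id", "")
    group = fields.get("group", "unknown")
    return SpectralImage(cube, WavenumberAxis(axis_values), pixel_size,
                         None, sample_id, group)


def _write_envi(image: SpectralImage, path: Path) -> None:
    hdr_path, raw_path = _envi_paths(Path(path))
    h, w, b = image.cube.shape
    wl = ", ".join(f"{v:.6f}" for v in image.axis.values)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Wavenumber\n"
        f"pixel size = {image.pixel_size}\n"
        f"sample id = {image.sample_id}\n"
        f"group = {image.group}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    image.cube.transpose(2, 0, 1).astype("<f4").tofile(raw_path)


# -- long-format CSV ---------------------------------------------------------


def _read_csv(path: Path) -> SpectralImage:
    meta = {"pixel_size_um": 25.0, "sample_id": "", "group": "unknown",
            "height": None, "width": None}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("row"):
                continue
            rows.append(tuple(float(x) for x in line.split(",")))
    if not rows:
        raise FormatError("CSV contains no data rows")
    arr = np.array(rows)
    r, c, wn, ab = arr.T
    axis_values = np.unique(wn)
    h = int(meta["height"]) if meta["height"] else int(r.max()) + 1
    w = int(meta["width"]) if meta["width"] else int(c.max()) + 1
    b = axis_values.size
    cube = np.zeros((h, w, b))
    mask = np.zeros((h, w), dtype=bool)
    band_of = {v: i for i, v in enumerate(axis_values)}
    for ri, ci, wi, ai in rows:
        cube[int(ri), int(ci), band_of[wi]] = ai
        mask[int(ri), int(ci)] = True
    per_pixel = mask.sum() * b
    if arr.shape[0] != per_pixel:
        raise FormatError(
            f"CSV has {arr.shape[0]} rows; expected {per_pixel} "
            "(every valid pixel must carry every wavenumber)"
        )
    return SpectralImage(cube, WavenumberAxis(axis_values),
                         float(meta["pixel_size_um"]), mask,
                         str(meta["sample_id"]), str(meta["group"]))


def _write_csv(image: SpectralImage, path: Path) -> None:
    h, w, _ = image.cube.shape
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_um = {image.pixel_size!r}\n")
        fh.write(f"# sample_id = {image.sample_id}\n")
        fh.write(f"# group = {image.group}\n")
        fh.write(f"# height = {h}\n")
        fh.write(f"# width = {w}\n")
        fh.write("row,col,wavenumber,absorbance\n")
        for ri in range(h):
            for ci in range(w):
                if not image.mask[ri, ci]:
                    continue
                for wn, ab in zip(image.axis.values, image.cube[ri, ci]):
                    fh.write(f"{ri},{ci},{wn:.10g},{ab:.12g}\n")


# ---------------------------------------------------------------------------
# spectral windowing


def crop_range(image: SpectralImage, lo: float, hi: float) -> SpectralImage:
    """Restrict the cube to wavenumbers in the closed interval [lo, hi]."""
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got [{lo}, {hi}]")
    sel = image.axis.window(lo, hi)
    if not sel.any():
        raise ValueError(
            f"[{lo}, {hi}] cm^-1 does not overlap the axis "
            f"[{image.axis.values[0]}, {image.axis.values[-1]}]"
        )
    return SpectralImage(
        image.cube[:, :, sel],
        WavenumberAxis(image.axis.values[sel]),
        image.pixel_size,
        image.mask.copy(),
        image.sample_id,
        image.group,
    )


# ---------------------------------------------------------------------------
# RGB histology I/O


def read_rgb(path: str | Path, scale: float = 1.0) -> RGBImage:
    pixels = iio.imread(path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    return RGBImage(pixels, scale)


def write_rgb(image: RGBImage, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, image.pixels)
    return path
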