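"""End-to-end orchestration of the two analyses.

``run_whole_sample`` reproduces the whole-biopsy workflow: crop to the
900-1800 cm^-1 fingerprint region, EMSC dewax against the slide's paraffin
cube, k-means at each requested k, annotate classes against the endmember
templates, read off the fibrosis-area percentage, quantify the paired
trichrome image by color deconvolution, and correlate the two measurements
across samples.

``run_fibrosis_focus`` reproduces the high-resolution fibrosis study: dewax
each fibrosis-region cube on the 1040-1425 cm^-1 window, pool all regions
into one common k-means (k = 4), analyze the centroids by second derivative
and hierarchical clustering, and tabulate the per-group proportions of the
fibrosis subclasses.

Every stage is deterministic given (inputs, config, seed); per-sample
failures are recorded and do not halt the remaining samples.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bands as bands_mod
from . import dia as dia_mod
from .cluster import (ClusterAnnotation, KMeansModel, LabelImage, area_percent,
                      annotate_clusters, default_templates, fit_common_kmeans,
                      fit_kmeans)
from .emsc import dewax, dewax_common
from .io import RGBImage, SpectralImage, crop_range, read_cube, read_rgb
from .stats import class_proportions, compare_methods

__all__ = [
    "SampleSpec",
    "PipelineConfig",
    "WholeSampleReport",
    "FocusReport",
    "run_whole_sample",
    "run_fibrosis_focus",
]

WHOLE_RANGE = (900.0, 1800.0)
FOCUS_RANGE = (1040.0, 1425.0)


@dataclass
class SampleSpec:
    """One manifest entry; cube/paraffin/trichrome may be paths or objects."""

    sample_id: str
    cube: SpectralImage | str | Path
    paraffin: SpectralImage | str | Path
    trichrome: RGBImage | str | Path | None = None
    group: str = "unknown"


@dataclass
class PipelineConfig:
    samples: list[SampleSpec]
    wn_range: tuple[float, float] = WHOLE_RANGE
    ks: tuple[int, ...] = (2, 3, 4, 5)
    seed: int = 0
    n_interference: int = 10
    poly_degree: int = 4
    a_bounds: tuple[float, float] = (0.2, 5.0)
    kappa: float | None = None
    n_init: int = 10
    background_od: float = dia_mod.BACKGROUND_OD_DEFAULT
    prominence: float = 5e-4
    exclude: tuple[str, ...] = ()
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.ks):
            raise ValueError("k values must be >= 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        samples = [SampleSpec(s["sample_id"], s["cube"], s["paraffin"],
                              s.get("trichrome"), s.get("group", "unknown"))
                   for s in raw.pop("samples")]
        if "wn_range" in raw:
            raw["wn_range"] = tuple(raw["wn_range"])
        if "ks" in raw:
            raw["ks"] = tuple(raw["ks"])
        if "a_bounds" in raw:
            raw["a_bounds"] = tuple(raw["a_bounds"])
        if "exclude" in raw:
            raw["exclude"] = tuple(raw["exclude"])
        if "out_dir" in raw:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(samples=samples, **raw)

    def params(self) -> dict:
        return {
            "wn_range": list(self.wn_range), "ks": list(self.ks),
            "seed": self.seed, "n_interference": self.n_interference,
            "poly_degree": self.poly_degree, "a_bounds": list(self.a_bounds),
            "kappa": self.kappa, "n_init": self.n_init,
            "background_od": self.background_od,
            "prominence": self.prominence, "exclude": list(self.exclude),
        }


def _load_cube(src) -> SpectralImage:
    return src if isinstance(src, SpectralImage) else read_cube(src)


def _load_rgb(src) -> RGBImage:
    return src if isinstance(src, RGBImage) else read_rgb(src)


def _dewax_sample(spec: SampleSpec, config: PipelineConfig):
    cube = crop_range(_load_cube(spec.cube), *config.wn_range)
    paraffin = crop_range(_load_cube(spec.paraffin), *config.wn_range)
    corrected, fit, basis = dewax(
        cube, paraffin,
        n_interference=config.n_interference,
        poly_degree=config.poly_degree,
        a_bounds=config.a_bounds,
        kappa=config.kappa,
    )
    qc = {
        "sample_id": spec.sample_id,
        "group": spec.group,
        "n_valid": int(fit.valid.sum()),
        "n_outliers": int(fit.outlier.sum()),
        "rmse_median": float(np.median(fit.rmse[fit.valid])),
        "a_median": float(np.median(fit.a[fit.valid])),
    }
    return corrected, qc


@dataclass
class WholeSampleReport:
    paired_table: pd.DataFrame
    correlations: dict
    group_means: pd.DataFrame
    qc: pd.DataFrame
    params: dict
    errors: list = field(default_factory=list)

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        self.paired_table.to_csv(out / "paired.csv", index=False)
        rows = [{"k": k, "r": c.r, "p": c.p, "n": c.n,
                 "excluded": ";".join(c.excluded)}
                for k, c in sorted(self.correlations.items())]
        pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
        self.group_means.to_csv(out / "group_means.csv")
        self.qc.to_csv(out / "emsc_qc.csv", index=False)


def run_whole_sample(config: PipelineConfig) -> WholeSampleReport:
    """Whole-sample analysis: dewax -> per-k k-means -> fibrosis % -> DIA."""
    rows, qc_rows, errors = [], [], []
    for spec in config.samples:
        try:
            corrected, qc = _dewax_sample(spec, config)
            templates = default_templates(corrected.axis)
            row = {"sample_id": spec.sample_id, "group": spec.group}
            for k in config.ks:
                model, labels = fit_kmeans(corrected, k, seed=config.seed,
                                           n_init=config.n_init)
                annotation = annotate_clusters(model, templates)
                row[f"spectral_k{k}"] = area_percent(labels, annotation,
                                                     "fibrosis")
            if spec.trichrome is None:
                raise ValueError("whole-sample analysis needs a trichrome image")
            mask = dia_mod.segment_fibrosis(
                _load_rgb(spec.trichrome), background_od=config.background_od)
            row["dia_percent"] = dia_mod.fibrosis_percent_dia(mask)
            rows.append(row)
            qc_rows.append(qc)
        except Exception as exc:  # record and continue with other samples
            errors.append({"sample_id": spec.sample_id, "stage": "whole_sample",
                           "error": f"{type(exc).__name__}: {exc}"})
    if not rows:
        raise RuntimeError(f"every sample failed: {errors}")
    table = pd.DataFrame(rows)
    try:
        corr, means = compare_methods(table,
                                      exclude=list(config.exclude) or None)
    except ValueError:
        # fewer than 3 usable pairs: report descriptives, no correlation
        corr = {}
        pct_cols = [c for c in table.columns
                    if c == "dia_percent" or c.startswith("spectral_k")]
        means = table.groupby("group")[pct_cols].agg(["mean", "std"])
    report = WholeSampleReport(table, corr, means, pd.DataFrame(qc_rows),
                               config.params(), errors)
    if config.out_dir is not None:
        report.to_dir(config.out_dir)
    return report


@dataclass
class FocusReport:
    model: KMeansModel
    labels: list[LabelImage]
    annotation: ClusterAnnotation
    dendrogram: bands_mod.CentroidDendrogram
    band_tables: list[bands_mod.BandTable]
    proportions: pd.DataFrame
    qc: pd.DataFrame
    params: dict
    errors: list = field(default_factory=list)

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        self.proportions.to_csv(out / "proportions.csv")
        axis = self.model.axis.values
        cent = pd.DataFrame(
            self.model.centroids.T, index=axis,
            columns=[f"class_{i}" for i in range(self.model.k)])
        cent.index.name = "wavenumber"
        cent.to_csv(out / "centroids.csv")
        pd.concat(
            [bt.to_frame().assign(class_id=i)
             for i, bt in enumerate(self.band_tables)]
        ).to_csv(out / "bands.csv", index=False)
        self.qc.to_csv(out / "emsc_qc.csv", index=False)


def run_fibrosis_focus(config: PipelineConfig, k: int = 4) -> FocusReport:
    """Fibrosis-focus analysis: common k-means over pooled region cubes."""
    config = replace(config, wn_range=config.wn_range
                     if config.wn_range != WHOLE_RANGE else FOCUS_RANGE)
    cubes, paraffins, groups, ids, errors = [], [], [], [], []
    for spec in config.samples:
        try:
            cubes.append(crop_range(_load_cube(spec.cube), *config.wn_range))
            paraffins.append(
                crop_range(_load_cube(spec.paraffin), *config.wn_range))
            groups.append(spec.group)
            ids.append(spec.sample_id)
        except Exception as exc:
            errors.append({"sample_id": spec.sample_id, "stage": "load",
                           "error": f"{type(exc).__name__}: {exc}"})
    if not cubes:
        raise RuntimeError(f"every region failed: {errors}")
    # one shared basis so pooled classes compare across regions
    corrected_list, fits, _ = dewax_common(
        cubes, paraffins,
        n_interference=config.n_interference,
        poly_degree=config.poly_degree,
        a_bounds=config.a_bounds,
        kappa=config.kappa,
    )
    qc_rows = [
        {"sample_id": sid, "group": grp,
         "n_valid": int(fit.valid.sum()),
         "n_outliers": int(fit.outlier.sum()),
         "rmse_median": float(np.median(fit.rmse[fit.valid])),
         "a_median": float(np.median(fit.a[fit.valid]))}
        for sid, grp, fit in zip(ids, groups, fits)
    ]
    model, labels = fit_common_kmeans(corrected_list, k, seed=config.seed,
                                      n_init=config.n_init)
    templates = default_templates(model.axis)
    annotation = annotate_clusters(model, templates)
    band_tables = []
    for centroid in model.centroids:
        deriv = bands_mod.second_derivative(centroid, model.axis)
        band_tables.append(bands_mod.pick_bands(deriv, config.prominence))
    dendro = bands_mod.cluster_centroids(model.centroids)
    proportions = class_proportions(labels, annotation, groups)
    report = FocusReport(model, labels, annotation, dendro, band_tables,
                         proportions, pd.DataFrame(qc_rows), config.params(),
                         errors)
    if config.out_dir is not None:
        report.to_dir(config.out_dir)
    return report
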