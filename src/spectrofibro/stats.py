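"""Method-comparison statistics for the two fibrosis measurements.

Pearson correlation between the histology-derived (DIA) and spectral-cluster
fibrosis percentages, per-group descriptive summaries, and the per-group
proportion table of the fibrosis spectral subclasses.

Two deliberate conventions:

* outlier exclusion is an explicit, caller-supplied list of sample ids —
  never automatic — so every excluded point is auditable;
* group comparison stays descriptive (mean and SD); no between-group
  significance test is attempted at n = 5 per group.

P-values use the exact t transformation ``t = r * sqrt(n-2) / sqrt(1-r^2)``
with n-2 degrees of freedom, the standard inference for Pearson's r at small
n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .cluster import ClusterAnnotation, LabelImage

__all__ = [
    "CorrelationResult",
    "pearson_corr",
    "pearson_p_from_r",
    "compare_methods",
    "class_proportions",
    "PAIRED_COLUMNS",
]

PAIRED_COLUMNS = ("sample_id", "group", "dia_percent",
                  "spectral_k2", "spectral_k3", "spectral_k4", "spectral_k5")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with two-sided t-based p-value."""

    r: float
    p: float
    n: int
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")
        if self.n < 3:
            raise ValueError("need at least 3 pairs")


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a given Pearson r and sample size."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * t_dist.sf(abs(t), df))


def pearson_corr(
    x: np.ndarray,
    y: np.ndarray,
    ids: list[str] | None = None,
    exclude: list[str] | None = None,
) -> CorrelationResult:
    """Product-moment correlation with explicit, logged exclusions.

    ``exclude`` names sample ids (requires ``ids``); excluded pairs are
    dropped from both vectors before computing r.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    excluded: tuple[str, ...] = ()
    if exclude:
        if ids is None:
            raise ValueError("exclusion by id requires ids")
        keep = ~np.isin(np.asarray(ids), list(exclude))
        excluded = tuple(i for i in ids if i in set(exclude))
        x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"only {n} pairs after exclusion; need >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(xd @ yd / denom)
    return CorrelationResult(r, pearson_p_from_r(r, n), n, excluded)


def validate_paired_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample_id", "group", "dia_percent")
               if c not in table.columns]
    if missing:
        raise ValueError(f"paired table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    pct_cols = [c for c in table.columns
                if c == "dia_percent" or c.startswith("spectral_k")]
    vals = table[pct_cols].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    return table


def compare_methods(
    table: pd.DataFrame,
    exclude: list[str] | None = None,
) -> tuple[dict[int, CorrelationResult], pd.DataFrame]:
    """Per-k DIA-vs-spectral correlations and per-group mean/SD summaries.

    ``table`` follows the paired layout (sample_id, group, dia_percent,
    spectral_k{2..5}); exclusions apply uniformly to every k.
    """
    table = validate_paired_table(table)
    if len(table) == 0:
        raise ValueError("paired table is empty")
    ids = table["sample_id"].tolist()
    ks = sorted(int(c.removeprefix("spectral_k")) for c in table.columns
                if c.startswith("spectral_k"))
    if not ks:
        raise ValueError("paired table has no spectral_k columns")
    corr = {
        k: pearson_corr(table["dia_percent"].to_numpy(),
                        table[f"spectral_k{k}"].to_numpy(),
                        ids=ids, exclude=exclude)
        for k in ks
    }
    keep = table if not exclude else table[~table["sample_id"].isin(exclude)]
    if len(keep) == 0:
        raise ValueError("all rows excluded")
    pct_cols = ["dia_percent"] + [f"spectral_k{k}" for k in ks]
    means = keep.groupby("group")[pct_cols].agg(["mean", "std"])
    return corr, means


def class_proportions(
    labels: list[LabelImage],
    annotation: ClusterAnnotation,
    groups: list[str],
) -> pd.DataFrame:
    """Share of each fibrosis-annotated class within each group's fibrosis pool.

    Pixels of all fibrosis-annotated classes are pooled per group; each
    class's percentage of that pool is reported.  Columns sum to 100.
    """
    if len(labels) != len(groups):
        raise ValueError("one group label per label image required")
    fib_ids = sorted(annotation.classes_for("fibrosis"))
    if len(fib_ids) < 2:
        raise ValueError("need at least two fibrosis-annotated classes")
    out = {}
    for grp in dict.fromkeys(groups):  # preserve first-seen order
        counts = np.zeros(len(fib_ids))
        for lab, g in zip(labels, groups):
            if g != grp:
                continue
            for j, cid in enumerate(fib_ids):
                counts[j] += int((lab.labels == cid).sum())
        total = counts.sum()
        if total == 0:
            raise ValueError(f"group {grp!r} has no fibrosis-class pixels")
        out[grp] = 100.0 * counts / total
    return pd.DataFrame(out, index=[f"cluster_{cid}" for cid in fib_ids])
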