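"""Binary maps, five-model ensemble maps, and point-exposure summaries.

Each fitted form's continuous suitability surface is thresholded at its
minimum-training-presence value into a 0/1 map; the ensemble map is the
per-pixel average of the binary maps, so with five contributing forms
every pixel takes a value in {0, 0.2, 0.4, 0.6, 0.8, 1.0} — the
fraction of forms calling the pixel suitable.  Exposure summaries
extract the ensemble value at point locations (e.g., wind turbines) and
report the mean, range, histogram, and skewness of those values; a
left-skewed histogram indicates points concentrated in habitat most
forms call suitable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .grids import RasterLayer, check_aligned
from .occurrences import SubsetKey


class Point(NamedTuple):
    id: str
    x_km: float
    y_km: float


def binarize(surface: RasterLayer, threshold: float) -> RasterLayer:
    """0/1 map: 1 where suitability >= threshold; nodata propagates."""
    vals = np.where(surface.values >= threshold, 1.0, 0.0)
    vals[surface.nodata_mask] = np.nan
    return RasterLayer(surface.grid, f"{surface.name}_binary", vals)


@dataclass
class EnsembleMap:
    """Per-pixel mean of the contributing forms' binary maps."""

    subset: SubsetKey | None
    layer: RasterLayer
    contributing_forms: list[str]

    @property
    def values(self) -> np.ndarray:
        return self.layer.values


def ensemble(
    binary_maps: list[RasterLayer],
    subset: SubsetKey | None = None,
    forms: list[str] | None = None,
) -> EnsembleMap:
    """Average grid-aligned binary maps; nodata where any contributor is."""
    grid = check_aligned(binary_maps)
    stackvals = np.stack([m.values for m in binary_maps])
    finite = stackvals[~np.isnan(stackvals)]
    if not np.isin(finite, (0.0, 1.0)).all():
        raise ValueError("ensemble inputs must be binary (0/1) maps")
    vals = stackvals.mean(axis=0)  # NaN in any contributor propagates
    layer = RasterLayer(grid, "ensemble", vals)
    return EnsembleMap(subset, layer, forms or [m.name for m in binary_maps])


def extract_at_points(
    emap: EnsembleMap, points: list[Point]
) -> tuple[np.ndarray, int]:
    """Ensemble value of the pixel containing each point.

    Points outside the grid or on nodata pixels are excluded; the count
    of exclusions is returned alongside the values.  Two points in one
    pixel yield two (identical) values.
    """
    if not points:
        raise ValueError("empty point list")
    grid = emap.layer.grid
    values = []
    n_excluded = 0
    for pt in points:
        if not grid.contains(pt.x_km, pt.y_km):
            n_excluded += 1
            continue
        r, c = grid.pixel_of(pt.x_km, pt.y_km)
        v = emap.values[r, c]
        if np.isnan(v):
            n_excluded += 1
        else:
            values.append(float(v))
    return np.array(values), n_excluded


@dataclass
class ExposureSummary:
    subset: SubsetKey | None
    n_points: int
    mean: float
    min: float
    max: float
    bin_edges: np.ndarray
    counts: np.ndarray
    skewness: float | None  # None when fewer than 2 values


def exposure_summary(
    values, n_bins: int = 10, subset: SubsetKey | None = None
) -> ExposureSummary:
    """Summarize point-exposure values on [0, 1].

    Histogram uses equal-width bins over [0, 1] with the last bin
    right-closed; skewness is the adjusted (bias-corrected)
    Fisher–Pearson sample coefficient, undefined for fewer than two
    values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    if v.size >= 2 and v.std() > 0:
        skew = float(stats.skew(v, bias=False))
    elif v.size >= 2:
        skew = 0.0
    else:
        skew = None
    return ExposureSummary(
        subset=subset,
        n_points=int(v.size),
        mean=float(v.mean()),
        min=float(v.min()),
        max=float(v.max()),
        bin_edges=edges,
        counts=counts,
        skewness=skew,
    )
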