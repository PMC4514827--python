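"""Seasonal covariate stacks: construction, correlation screening,
background sampling, and training-table assembly.

Each season's candidate covariates follow the common SDM recipe:
seasonal mean temperature (mean of that season's monthly means, °C),
an adjacent-season mean temperature (prior season for winter/spring/
summer, next season for autumn), seasonal temperature range (mean of
monthly range values, supplied in the WorldClim °C×10 convention and
rescaled on ingest), precipitation seasonality (BIO15), growing-season
length (days), and tree cover (%).  Strongly correlated pairs
(|Pearson| or |Spearman| r > 0.70 on a fixed-seed pixel sample) are
resolved by a deterministic drop rule before modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import GridSpec, RasterLayer, check_aligned
from .occurrences import NEXT_SEASON, PRIOR_SEASON, SEASON_MONTHS, OccupiedPixelSet, SubsetKey

#: Pairwise-correlation threshold above which one covariate is dropped.
CORRELATION_THRESHOLD = 0.70

#: Number of unmasked pixels sampled for the correlation screen.
SCREEN_SAMPLE_PIXELS = 50_000

#: Variables dropped preferentially when flagged against anything else
#: (ordered; earlier entries are dropped first).  Encodes the usual
#: choices for this covariate family: temperature beats elevation,
#: season length beats diurnal range and raw precipitation totals.
DEFAULT_DROP_PRIORITY = (
    "elevation",
    "mean_diurnal_range",
    "annual_precipitation",
    "seasonal_precipitation",
)


@dataclass
class PredictorStack:
    """Grid-aligned, named covariate layers for one season."""

    season: str
    layers: dict[str, RasterLayer]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_aligned(self.layers.values())

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def valid_mask(self) -> np.ndarray:
        """Pixels with data in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for lyr in self.layers.values():
            mask &= ~lyr.nodata_mask
        return mask

    def matrix(self, pixels) -> np.ndarray:
        """Covariate matrix (len(pixels) × n_layers) at (row, col) pixels."""
        rows = np.array([p[0] for p in pixels], dtype=int)
        cols = np.array([p[1] for p in pixels], dtype=int)
        return np.column_stack([
            lyr.values[rows, cols] for lyr in self.layers.values()
        ])

    def subset(self, names) -> "PredictorStack":
        return PredictorStack(
            self.season,
            {n: self.layers[n] for n in names},
            {n: self.provenance.get(n, "") for n in names},
        )


def _seasonal_month_mean(
    monthly: list[RasterLayer], season: str, name: str, scale: float = 1.0
) -> RasterLayer:
    if len(monthly) != 12:
        raise ValueError("expected 12 monthly layers (January..December)")
    grid = check_aligned(monthly)
    months = SEASON_MONTHS[season]
    stackvals = np.stack([monthly[m - 1].values for m in months])
    # NaN (nodata) in any contributing month propagates to the output.
    vals = stackvals.mean(axis=0) * scale
    return RasterLayer(grid, name, vals, monthly[0].units)


def seasonal_mean_temperature(monthly_means: list[RasterLayer], season: str) -> RasterLayer:
    """Per-pixel mean of the season's monthly mean temperatures (°C).

    Season month sets mirror the occurrence bins: winter {Dec, Jan,
    Feb}, spring {Mar–May}, summer {Jun, Jul}, autumn {Aug–Nov}.
    """
    return _seasonal_month_mean(monthly_means, season, f"{season}_mean_temp")


def adjacent_season_temperature(
    monthly_means: list[RasterLayer], season: str, direction: str
) -> RasterLayer:
    """Mean temperature of the adjacent season.

    ``direction='prior'`` is allowed for winter, spring, and summer;
    autumn instead uses ``direction='next'`` (its next season being
    winter).  Other combinations are contract violations.
    """
    if direction == "prior":
        if season == "autumn":
            raise ValueError("autumn uses the next season, not the prior one")
        adj = PRIOR_SEASON[season]
    elif direction == "next":
        if season != "autumn":
            raise ValueError(f"direction='next' is only defined for autumn, got {season!r}")
        adj = NEXT_SEASON[season]
    else:
        raise ValueError(f"direction must be 'prior' or 'next', got {direction!r}")
    layer = seasonal_mean_temperature(monthly_means, adj)
    layer.name = f"{adj}_mean_temp"
    return layer


def seasonal_temperature_range(
    monthly_ranges: list[RasterLayer], season: str, input_scale: float = 0.1
) -> RasterLayer:
    """Per-pixel mean of the season's monthly temperature-range values.

    Monthly inputs are expected in the WorldClim °C×10 convention and
    are rescaled to °C via ``input_scale`` (set 1.0 for inputs already
    in °C).
    """
    lyr = _seasonal_month_mean(
        monthly_ranges, season, f"{season}_temp_range", scale=input_scale
    )
    lyr.units = "degC"
    return lyr


# --------------------------------------------------------------------------
# Correlation screening

@dataclass
class ScreenReport:
    retained: list[str]
    dropped: list[str]
    flagged_pairs: list[dict]  # name_a, name_b, pearson_r, spearman_r, dropped
    constant_layers: list[str]
    n_sample_pixels: int


def correlation_screen(
    candidate_layers: dict[str, RasterLayer],
    threshold: float = CORRELATION_THRESHOLD,
    sample_pixels: int = SCREEN_SAMPLE_PIXELS,
    seed: int = 0,
    drop_priority=DEFAULT_DROP_PRIORITY,
) -> tuple[list[str], ScreenReport]:
    """Drop one member of every strongly correlated covariate pair.

    A pair is flagged when |Pearson r| or |Spearman r| exceeds
    ``threshold`` on a fixed-seed random sample of jointly unmasked
    pixels.  Flagged pairs are resolved deterministically: a variable in
    ``drop_priority`` is dropped first; otherwise the member with the
    larger mean absolute correlation to all other candidates goes, with
    name order as final tie-break.  Zero-variance layers have undefined
    correlations; they are retained but flagged in the report.
    """
    names = list(candidate_layers)
    if len(names) < 2:
        raise ValueError("need at least two candidate layers to screen")
    check_aligned(candidate_layers.values())

    valid = np.ones(candidate_layers[names[0]].grid.shape, dtype=bool)
    for lyr in candidate_layers.values():
        valid &= ~lyr.nodata_mask
    idx = np.flatnonzero(valid.ravel())
    if idx.size == 0:
        raise ValueError("no jointly unmasked pixels to screen on")
    rng = np.random.default_rng(seed)
    if idx.size > sample_pixels:
        idx = rng.choice(idx, size=sample_pixels, replace=False)
        idx.sort()
    data = np.column_stack([
        candidate_layers[n].values.ravel()[idx] for n in names
    ])

    sds = data.std(axis=0)
    constant = [n for n, sd in zip(names, sds) if sd == 0]
    p = len(names)
    pear = np.eye(p)
    spear = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if sds[i] == 0 or sds[j] == 0:
                pear[i, j] = pear[j, i] = np.nan
                spear[i, j] = spear[j, i] = np.nan
                continue
            pear[i, j] = pear[j, i] = stats.pearsonr(data[:, i], data[:, j])[0]
            spear[i, j] = spear[j, i] = stats.spearmanr(data[:, i], data[:, j])[0]

    with np.errstate(invalid="ignore"):
        strength = np.fmax(np.abs(pear), np.abs(spear))
    np.fill_diagonal(strength, 0.0)
    mean_abs = {
        n: float(np.nanmean(np.abs(np.delete(pear[i], i))))
        if not np.all(np.isnan(np.delete(pear[i], i))) else 0.0
        for i, n in enumerate(names)
    }
    prio = {n: k for k, n in enumerate(drop_priority)}

    def choose_drop(a: str, b: str) -> str:
        pa, pb = prio.get(a), prio.get(b)
        if pa is not None or pb is not None:
            if pb is None or (pa is not None and pa < pb):
                return a
            return b
        if mean_abs[a] != mean_abs[b]:
            return a if mean_abs[a] > mean_abs[b] else b
        return max(a, b)

    retained = set(names)
    flagged: list[dict] = []
    while True:
        best = None
        for i in range(p):
            if names[i] not in retained:
                continue
            for j in range(i + 1, p):
                if names[j] not in retained:
                    continue
                s = strength[i, j]
                if np.isnan(s) or s <= threshold:
                    continue
                key = (s, names[i], names[j])
                if best is None or key > best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        drop = choose_drop(names[i], names[j])
        retained.discard(drop)
        flagged.append({
            "name_a": names[i],
            "name_b": names[j],
            "pearson_r": float(pear[i, j]),
            "spearman_r": float(spear[i, j]),
            "dropped": drop,
        })
    retained_ordered = [n for n in names if n in retained]
    report = ScreenReport(
        retained=retained_ordered,
        dropped=[n for n in names if n not in retained],
        flagged_pairs=flagged,
        constant_layers=constant,
        n_sample_pixels=int(idx.size),
    )
    return retained_ordered, report


# --------------------------------------------------------------------------
# Background sampling and training-table assembly

def sample_background(
    grid: GridSpec,
    n: int,
    seed: int,
    exclude_mask: np.ndarray | None = None,
) -> set[tuple[int, int]]:
    """Uniform sample of ``n`` distinct available pixels, seeded.

    ``exclude_mask`` (True = unavailable) removes pixels from the pool;
    asking for more pixels than are available is an error.
    """
    if exclude_mask is not None:
        available = np.flatnonzero(~exclude_mask.ravel())
    else:
        available = np.arange(grid.n_pixels)
    if n > available.size:
        raise ValueError(
            f"requested {n} background pixels but only {available.size} available"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(available, size=n, replace=False)
    return {(int(f // grid.n_cols), int(f % grid.n_cols)) for f in flat}


@dataclass
class TrainingTable:
    """Labeled pixel rows (presence=1, background=0) with covariates."""

    frame: pd.DataFrame  # columns: row, col, label, then covariates
    covariate_names: list[str]
    subset: SubsetKey | None = None
    n_dropped_nodata: int = 0

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.covariate_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def n_presence(self) -> int:
        return int(self.frame["label"].sum())

    @property
    def n_background(self) -> int:
        return int((self.frame["label"] == 0).sum())

    def presence_X(self) -> np.ndarray:
        return self.frame.loc[self.frame["label"] == 1, self.covariate_names].to_numpy(float)


def assemble_training_table(
    occupied: OccupiedPixelSet,
    background_ids: set[tuple[int, int]],
    stack: PredictorStack,
) -> TrainingTable:
    """Join occupied and background pixels to the covariate stack.

    A background pixel that coincides with an occupied pixel appears
    once, labeled presence.  Rows with nodata in any covariate are
    dropped and tallied.
    """
    if not occupied.pixel_ids:
        raise ValueError("empty presence set: no occupied pixels")
    presence = sorted(occupied.pixel_ids)
    background = sorted(set(background_ids) - occupied.pixel_ids)
    pixels = presence + background
    labels = np.r_[np.ones(len(presence), int), np.zeros(len(background), int)]
    X = stack.matrix(pixels)
    frame = pd.DataFrame(X, columns=stack.names)
    frame.insert(0, "label", labels)
    frame.insert(0, "col", [p[1] for p in pixels])
    frame.insert(0, "row", [p[0] for p in pixels])
    ok = ~frame[stack.names].isna().any(axis=1)
    n_dropped = int((~ok).sum())
    frame = frame.loc[ok].reset_index(drop=True)
    if not (frame["label"] == 1).any():
        raise ValueError("all presence rows were dropped for nodata covariates")
    return TrainingTable(frame, stack.names, occupied.subset, n_dropped)
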