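"""Synthetic landscapes with known structure for end-to-end testing.

Real continental covariate rasters (climate normals, phenology, tree
cover) and digitized museum records are multi-gigabyte downloads, so
this module builds planar stand-ins with the statistical features the
pipeline assumes: spatially autocorrelated covariates on realistic
scales, a known logistic true-suitability surface, presence-only
records drawn proportional to that surface (with optional sampling
bias), and turbine-like point sets.  Because the truth is known,
downstream stages can be tested for parameter recovery, importance
ranking, and calibration rather than just for plumbing.

Randomness is organized as one master seed per scenario plus a stable
per-operation label, so regenerating one artifact never perturbs the
others.
"""

from __future__ import annotations

import calendar
import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date as Date
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .ensemble import Point
from .grids import GridSpec, RasterLayer, write_ascii_grid
from .occurrences import (
    SEASON_MONTHS,
    SUBSET_KEYS,
    OccurrenceRecord,
    SubsetKey,
    write_occurrence_csv,
)
from .predictors import PredictorStack

_EARTH_RADIUS_KM = 6371.0


def seed_for(master_seed: int, label: str) -> int:
    """Stable per-operation substream seed (below 2^31)."""
    h = hashlib.blake2b(
        label.encode(), key=str(master_seed).encode(), digest_size=4
    )
    return int.from_bytes(h.digest(), "big") % (2**31)


@dataclass(frozen=True)
class CovariateSpec:
    """Recipe for one autocorrelated covariate field."""

    name: str
    mean: float
    sd: float
    autocorrelation_length_km: float = 0.0
    value_bounds: tuple[float, float] | None = None
    units: str = ""


def generate_covariate_field(
    grid: GridSpec, spec: CovariateSpec, seed: int
) -> RasterLayer:
    """Gaussian-kernel-smoothed white noise rescaled to (mean, sd).

    ``autocorrelation_length_km`` sets the smoothing kernel's standard
    deviation in km; zero yields white noise.  Values are clipped to
    ``value_bounds`` after rescaling.  ``sd=0`` gives a constant field.
    """
    if spec.sd < 0:
        raise ValueError(f"covariate {spec.name!r}: sd must be non-negative")
    if spec.autocorrelation_length_km < 0:
        raise ValueError(f"covariate {spec.name!r}: autocorrelation length must be >= 0")
    rng = np.random.default_rng(seed)
    if spec.sd == 0:
        vals = np.full(grid.shape, float(spec.mean))
    else:
        noise = rng.standard_normal(grid.shape)
        if spec.autocorrelation_length_km > 0:
            sigma_px = spec.autocorrelation_length_km / grid.cell_size_km
            noise = gaussian_filter(noise, sigma=sigma_px, mode="reflect")
        sd = noise.std()
        if sd == 0:  # degenerate 1x1 grid
            vals = np.full(grid.shape, float(spec.mean))
        else:
            vals = (noise - noise.mean()) / sd * spec.sd + spec.mean
    if spec.value_bounds is not None:
        vals = np.clip(vals, *spec.value_bounds)
    return RasterLayer(grid, spec.name, vals, spec.units)


# --------------------------------------------------------------------------
# Scenario

#: Subset record counts emulating a realistic multi-decade museum
#: collection: strong seasonal and sex imbalance.
DEFAULT_SUBSET_COUNTS: dict[str, int] = {
    "winter_pooled": 130,
    "spring_females": 324,
    "spring_males": 353,
    "summer_females": 342,
    "summer_males": 999,
    "autumn_females": 240,
    "autumn_males": 365,
}


@dataclass
class SyntheticScenario:
    """Full recipe for a synthetic study region and its records."""

    grid: GridSpec
    covariate_specs: list[CovariateSpec]
    true_coefficients: dict[str, float]
    intercept: float
    n_presences_per_subset: dict[str, int]
    sampling_bias_strength: float = 0.0
    error_km_distribution: dict = field(
        default_factory=lambda: {"kind": "uniform", "low": 0.0, "high": 25.0}
    )
    n_turbines: int = 5000
    female_fraction: float = 0.5
    unknown_sex_fraction: float = 0.0
    year_range: tuple[int, int] = (1950, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [s.name for s in self.covariate_specs]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        valid = {k.label for k in SUBSET_KEYS}
        for label in self.n_presences_per_subset:
            if label not in valid:
                raise ValueError(f"unknown subset {label!r}")


def default_scenario(seed: int = 0, n_rows: int = 100, n_cols: int = 100) -> SyntheticScenario:
    """The reference scenario: six-covariate seasonal landscape.

    Elevation drives a lapse-rate temperature gradient (so the
    correlation screen has a genuinely collinear candidate to drop);
    seasonal temperature anomalies decorrelate adjacent seasons; season
    length is the dominant suitability driver with a quadratic optimum
    near 250 days, plus moderate temperature, tree-cover, and
    temperature-range effects.
    """
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size_km=1.0)
    specs = [
        CovariateSpec("elevation", 800, 500, 20, (0, 4500), "m"),
        CovariateSpec("temp_anomaly", 0, 2.0, 15, None, "degC"),
        CovariateSpec("trange_base", 14, 3.0, 15, (2, 40), "degC"),
        CovariateSpec("precip_seasonality", 45, 20, 15, (0, 150), "cv_percent"),
        CovariateSpec("season_length", 190, 55, 15, (0, 365), "days"),
        CovariateSpec("tree_cover", 35, 22, 10, (0, 100), "percent"),
    ]
    for season in SEASON_MONTHS:
        specs.append(CovariateSpec(f"temp_anom_{season}", 0, 3.5, 12, None, "degC"))
        specs.append(CovariateSpec(f"trange_anom_{season}", 0, 2.5, 12, None, "degC"))
    # Season length dominates with a quadratic optimum at 250 days;
    # temperature, tree cover and temperature range carry moderate
    # effects, jointly giving the strong spatial discrimination typical
    # of continental-scale presence-background analyses.
    coefficients = {
        "season_length": 0.16,
        "season_length^2": -3.2e-4,
        "mean_temp": 0.25,
        "tree_cover": 0.04,
        "temp_range": -0.20,
    }
    return SyntheticScenario(
        grid=grid,
        covariate_specs=specs,
        true_coefficients=coefficients,
        intercept=-27.0,
        n_presences_per_subset=dict(DEFAULT_SUBSET_COUNTS),
        seed=seed,
    )


_LAPSE_RATE = 0.0065  # degC per m
_SEA_LEVEL_TEMP = 18.0
_ANNUAL_CYCLE_AMPLITUDE = 10.0


def _month_season(month: int) -> str:
    for season, months in SEASON_MONTHS.items():
        if month in months:
            return season
    raise ValueError(month)


def generate_landscape(scenario: SyntheticScenario) -> dict[str, RasterLayer]:
    """All primitive fields plus derived monthly temperature layers.

    Monthly mean temperature is sea-level temperature minus a lapse-rate
    elevation term, plus an annual cycle, a local anomaly, and a
    season-specific anomaly; monthly temperature range is a base field
    plus seasonal anomalies, emitted in the conventional °C×10 integer
    scale of climate-normal products.
    """
    fields: dict[str, RasterLayer] = {}
    for spec in scenario.covariate_specs:
        fields[spec.name] = generate_covariate_field(
            scenario.grid, spec, seed_for(scenario.seed, f"field:{spec.name}")
        )
    temp_base = (
        _SEA_LEVEL_TEMP
        - _LAPSE_RATE * fields["elevation"].values
        + fields["temp_anomaly"].values
    )
    layers = {
        name: fields[name]
        for name in ("elevation", "precip_seasonality", "season_length", "tree_cover")
    }
    for m in range(1, 13):
        season = _month_season(m)
        cycle = _ANNUAL_CYCLE_AMPLITUDE * np.cos(2 * np.pi * (m - 6.5) / 12.0)
        tm = temp_base + cycle + fields[f"temp_anom_{season}"].values
        layers[f"tmean_{m:02d}"] = RasterLayer(
            scenario.grid, f"tmean_{m:02d}", tm, "degC"
        )
        tr = np.maximum(
            fields["trange_base"].values + fields[f"trange_anom_{season}"].values, 0.5
        )
        layers[f"trange_{m:02d}"] = RasterLayer(
            scenario.grid, f"trange_{m:02d}", np.round(tr * 10.0), "degC_x10"
        )
    return layers


def true_suitability(stack: PredictorStack, scenario: SyntheticScenario) -> RasterLayer:
    """Known logistic-linear (plus quadratic) suitability surface.

    Coefficient keys name stack layers; a trailing ``^2`` denotes a
    quadratic term on that layer.  Values are the inverse logit of the
    linear predictor, hence within (0, 1).
    """
    eta = np.full(stack.grid.shape, float(scenario.intercept))
    for key, coef in scenario.true_coefficients.items():
        base = key[:-2] if key.endswith("^2") else key
        if base not in stack.layers:
            raise ValueError(f"true-suitability covariate {base!r} missing from stack")
        v = stack.layers[base].values
        eta = eta + coef * (v**2 if key.endswith("^2") else v)
    return RasterLayer(stack.grid, "true_suitability", expit(eta))


# --------------------------------------------------------------------------
# Occurrence sampling

def _season_dates(season: str, year: int) -> list[Date]:
    dates = []
    for m in SEASON_MONTHS[season]:
        for d in range(1, calendar.monthrange(year, m)[1] + 1):
            dates.append(Date(year, m, d))
    return dates


def _draw_error_km(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    kind = dist.get("kind", "uniform")
    if kind == "uniform":
        return rng.uniform(dist.get("low", 0.0), dist.get("high", 25.0), size=n)
    if kind == "exponential":
        e = rng.exponential(dist.get("scale", 10.0), size=n)
        return np.minimum(e, dist.get("max", 50.0))
    raise ValueError(f"unknown error_km distribution kind {kind!r}")


def _planar_to_lonlat(x_km: float, y_km: float) -> tuple[float, float]:
    lat = np.degrees(y_km / _EARTH_RADIUS_KM)
    lon = np.degrees(x_km / (_EARTH_RADIUS_KM * np.cos(np.radians(lat))))
    return lon, lat


def sample_occurrences(
    suitability: RasterLayer,
    scenario: SyntheticScenario,
    subset: SubsetKey,
    seed: int,
    bias_layer: RasterLayer | None = None,
) -> list[OccurrenceRecord]:
    """Presence-only records for one subset, drawn from the truth surface.

    Pixels are drawn with replacement with probability proportional to
    suitability (times ``exp(bias_strength * standardized bias)`` when a
    bias field is supplied), so repeated records per pixel occur, as in
    real collections.  Each record gets a uniform coordinate within its
    pixel, a collection date uniform over the subset's season (February
    29 possible in winter of leap years), the subset's sex (winter
    pooled draws sexes from the scenario's sex mix), and a
    georeferencing error from the scenario's error distribution.
    """
    n = scenario.n_presences_per_subset.get(subset.label, 0)
    if n < 1:
        raise ValueError(f"subset {subset.label}: need at least one presence")
    w = np.array(suitability.values, dtype=float)
    w[np.isnan(w)] = 0.0
    if bias_layer is not None and scenario.sampling_bias_strength > 0:
        b = bias_layer.values
        z = (b - np.nanmean(b)) / (np.nanstd(b) or 1.0)
        w = w * np.exp(scenario.sampling_bias_strength * np.nan_to_num(z))
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability surface is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    grid = suitability.grid
    flat = rng.choice(grid.n_pixels, size=n, p=w.ravel() / total, replace=True)
    rows, cols = flat // grid.n_cols, flat % grid.n_cols
    ux = rng.uniform(0, 1, size=n)
    uy = rng.uniform(0, 1, size=n)
    years = rng.integers(scenario.year_range[0], scenario.year_range[1] + 1, size=n)
    errors = _draw_error_km(rng, scenario.error_km_distribution, n)

    records = []
    for i in range(n):
        x = grid.origin_x + (cols[i] + ux[i]) * grid.cell_size_km
        y = grid.origin_y + (rows[i] + uy[i]) * grid.cell_size_km
        days = _season_dates(subset.season, int(years[i]))
        d = days[int(rng.integers(len(days)))]
        if subset.sex_group == "females":
            sex = "F"
        elif subset.sex_group == "males":
            sex = "M"
        else:
            u = rng.uniform()
            if u < scenario.unknown_sex_fraction:
                sex = "U"
            elif u < scenario.unknown_sex_fraction + (
                1 - scenario.unknown_sex_fraction
            ) * scenario.female_fraction:
                sex = "F"
            else:
                sex = "M"
        lon, lat = _planar_to_lonlat(x, y)
        records.append(OccurrenceRecord(
            id=f"{subset.label}_{i:04d}",
            x_km=float(x),
            y_km=float(y),
            longitude=round(float(lon), 3),
            latitude=round(float(lat), 3),
            date=d,
            sex=sex,
            error_km=float(round(errors[i], 3)),
            locality_precision="point",
        ))
    return records


def generate_turbines(
    grid: GridSpec,
    n: int,
    bias_layer: RasterLayer | None = None,
    seed: int = 0,
) -> list[Point]:
    """n point locations inside the grid footprint.

    Uniform over the footprint by default; with a bias layer, pixels are
    drawn proportional to its (non-negative) values, with uniform
    placement within the pixel.
    """
    if n < 1:
        raise ValueError("need at least one point")
    rng = np.random.default_rng(seed)
    s = grid.cell_size_km
    if bias_layer is None:
        x = grid.origin_x + rng.uniform(0, grid.n_cols * s, size=n)
        y = grid.origin_y + rng.uniform(0, grid.n_rows * s, size=n)
    else:
        w = np.array(bias_layer.values, dtype=float)
        w[np.isnan(w)] = 0.0
        if w.min() < 0:
            raise ValueError("bias layer must be non-negative")
        if w.sum() <= 0:
            raise ValueError("bias layer sums to zero")
        flat = rng.choice(grid.n_pixels, size=n, p=w.ravel() / w.sum(), replace=True)
        rows, cols = flat // grid.n_cols, flat % grid.n_cols
        x = grid.origin_x + (cols + rng.uniform(0, 1, size=n)) * s
        y = grid.origin_y + (rows + rng.uniform(0, 1, size=n)) * s
    return [Point(f"t{i:06d}", float(x[i]), float(y[i])) for i in range(n)]


def make_presence_table(
    stack: PredictorStack,
    suitability: RasterLayer,
    n_presence: int,
    n_background: int,
    seed: int,
):
    """Training table with exactly ``n_presence`` presence pixels.

    Presence pixels are drawn without replacement with probability
    proportional to suitability; background pixels uniformly without
    replacement (a background pixel coinciding with a presence keeps
    the presence label).  A convenience for desk-scale model tests that
    need fixed row counts.
    """
    from .occurrences import OccupiedPixelSet
    from .predictors import assemble_training_table, sample_background

    grid = stack.grid
    w = np.array(suitability.values, dtype=float)
    w[np.isnan(w)] = 0.0
    rng = np.random.default_rng(seed)
    flat = rng.choice(grid.n_pixels, size=n_presence, p=w.ravel() / w.sum(), replace=False)
    occupied = OccupiedPixelSet(
        None,
        {(int(f // grid.n_cols), int(f % grid.n_cols)) for f in flat},
        n_presence,
    )
    background = sample_background(grid, n_background, seed=seed + 1)
    return assemble_training_table(occupied, background, stack)


def single_driver_scenario(
    seed: int,
    n_rows: int = 200,
    n_cols: int = 200,
    n_noise: int = 4,
    driver_coef: float = 3.0,
    intercept: float = -5.0,
    autocorr_km: float = 15.0,
):
    """A one-driver recovery landscape: (stack, true suitability).

    One standardized covariate (``driver``) carries the whole signal —
    a ``driver_coef``-logit effect per SD — alongside ``n_noise``
    autocorrelated covariates with zero true effect.  Used for
    importance-recovery and model-sanity checks where ground truth must
    be unambiguous.
    """
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols)
    names = ["driver"] + [f"noise_{i}" for i in range(1, n_noise + 1)]
    layers = {}
    for name in names:
        spec = CovariateSpec(name, 0.0, 1.0, autocorr_km)
        layers[name] = generate_covariate_field(grid, spec, seed_for(seed, f"field:{name}"))
    stack = PredictorStack("summer", layers)
    scenario = SyntheticScenario(
        grid=grid,
        covariate_specs=[CovariateSpec(n, 0.0, 1.0, autocorr_km) for n in names],
        true_coefficients={"driver": driver_coef},
        intercept=intercept,
        n_presences_per_subset={"summer_males": 300},
        seed=seed,
    )
    return stack, true_suitability(stack, scenario)


# --------------------------------------------------------------------------
# Fixture bundle

def write_fixture_bundle(scenario: SyntheticScenario, out_dir) -> dict:
    """Write the scenario's full input set to disk; return the manifest.

    Emits the occurrence CSV (all subsets), one ESRI ASCII raster per
    landscape layer, a per-season true-suitability raster, the turbine
    CSV, and a JSON manifest recording the seed and scenario
    parameters.  Re-running with the same scenario and seed reproduces
    the CSVs byte for byte.
    """
    out_dir = Path(out_dir)
    raster_dir = out_dir / "rasters"
    try:
        raster_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    from .pipeline import build_candidate_stack  # deferred: avoid import cycle

    landscape = generate_landscape(scenario)
    raster_files = {}
    for name, layer in sorted(landscape.items()):
        path = raster_dir / f"{name}.asc"
        write_ascii_grid(layer, path)
        raster_files[name] = str(path.relative_to(out_dir))

    truth_files = {}
    all_records = []
    for key in SUBSET_KEYS:
        if key.label not in scenario.n_presences_per_subset:
            continue
        stack = build_candidate_stack(landscape, key.season, include_elevation=False)
        truth = true_suitability(stack, scenario)
        if key.season not in truth_files:
            tpath = raster_dir / f"true_suitability_{key.season}.asc"
            write_ascii_grid(truth, tpath)
            truth_files[key.season] = str(tpath.relative_to(out_dir))
        all_records.extend(sample_occurrences(
            truth, scenario, key, seed_for(scenario.seed, f"occurrences:{key.label}")
        ))
    occ_path = out_dir / "occurrences.csv"
    write_occurrence_csv(all_records, occ_path)

    turbines = generate_turbines(
        scenario.grid, scenario.n_turbines, seed=seed_for(scenario.seed, "turbines")
    )
    turb_path = out_dir / "turbines.csv"
    with open(turb_path, "w", newline="") as fh:
        fh.write("id,x_km,y_km\n")
        for t in turbines:
            fh.write(f"{t.id},{t.x_km!r},{t.y_km!r}\n")

    manifest = {
        "seed": scenario.seed,
        "grid": asdict(scenario.grid),
        "covariates": [asdict(s) for s in scenario.covariate_specs],
        "true_coefficients": scenario.true_coefficients,
        "intercept": scenario.intercept,
        "n_presences_per_subset": scenario.n_presences_per_subset,
        "sampling_bias_strength": scenario.sampling_bias_strength,
        "error_km_distribution": scenario.error_km_distribution,
        "n_turbines": scenario.n_turbines,
        "files": {
            "occurrences": "occurrences.csv",
            "turbines": "turbines.csv",
            "rasters": raster_files,
            "true_suitability": truth_files,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
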