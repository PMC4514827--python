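"""Occurrence-record QC, seasonal binning, sex stratification, rasterization.

Presence-only records (museum/collection specimens) enter as CSV rows
with coordinates, a collection date, sex, and georeferencing-error
metadata.  They are quality-filtered (precise locality, spatial error
<= 50 km), split by calendar season — winter Dec 1–Feb 29, spring
Mar 1–May 31, summer Jun 1–Jul 31, autumn Aug 1–Nov 30 — and
sex-stratified into seven modeling subsets (winter pooled across sexes;
the other three seasons split females/males).  Each subset is then
reduced to its set of occupied 1-km² pixels: the pixel, not the record,
is the modeling unit, so multiple records in one pixel count as one
presence location.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

from .grids import GridSpec

# --------------------------------------------------------------------------
# Seasons

SEASON_NAMES = ("winter", "spring", "summer", "autumn")

#: Months composing each season (winter spans the year boundary).
SEASON_MONTHS: dict[str, tuple[int, ...]] = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7),
    "autumn": (8, 9, 10, 11),
}

PRIOR_SEASON = {"winter": "autumn", "spring": "winter",
                "summer": "spring", "autumn": "summer"}
NEXT_SEASON = {v: k for k, v in PRIOR_SEASON.items()}

_MONTH_TO_SEASON = {m: s for s, months in SEASON_MONTHS.items() for m in months}


def assign_season(d: Date) -> str:
    """Season of a calendar date (month–day only; the year is ignored).

    December belongs to the winter bin that spans the year boundary and
    February 29 falls in winter.
    """
    return _MONTH_TO_SEASON[d.month]


@dataclass(frozen=True)
class SubsetKey:
    """One of the seven season × sex modeling subsets."""

    season: str
    sex_group: str  # females | males | pooled

    def __post_init__(self) -> None:
        if self.season not in SEASON_NAMES:
            raise ValueError(f"unknown season {self.season!r}")
        if self.season == "winter":
            if self.sex_group != "pooled":
                raise ValueError("winter is modeled with sexes pooled")
        elif self.sex_group not in ("females", "males"):
            raise ValueError(
                f"non-winter subsets are sex-specific, got {self.sex_group!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.season}_{self.sex_group}"

    @classmethod
    def from_label(cls, label: str) -> "SubsetKey":
        season, _, sex_group = label.partition("_")
        return cls(season, sex_group)


#: The seven valid subsets, in season order.
SUBSET_KEYS: tuple[SubsetKey, ...] = (
    SubsetKey("winter", "pooled"),
    SubsetKey("spring", "females"),
    SubsetKey("spring", "males"),
    SubsetKey("summer", "females"),
    SubsetKey("summer", "males"),
    SubsetKey("autumn", "females"),
    SubsetKey("autumn", "males"),
)


# --------------------------------------------------------------------------
# Records

OCCURRENCE_COLUMNS = (
    "id", "longitude", "latitude", "x_km", "y_km",
    "date", "sex", "error_km", "locality_precision",
)

_EARTH_RADIUS_KM = 6371.0


def lonlat_to_planar(longitude: float, latitude: float) -> tuple[float, float]:
    """Sinusoidal equal-area projection of lon/lat (degrees) to km.

    A deliberately simple stand-in for a full projection engine: it is
    equal-area, so pixel densities stay meaningful, which is all the
    pipeline needs from planar coordinates.
    """
    lam, phi = math.radians(longitude), math.radians(latitude)
    return (_EARTH_RADIUS_KM * lam * math.cos(phi), _EARTH_RADIUS_KM * phi)


# Normalization of free-text sex entries to the canonical {F, M, U} codes.
_SEX_TABLE = {
    "f": "F", "female": "F", "fem": "F",
    "m": "M", "male": "M",
    "u": "U", "unk": "U", "unknown": "U", "": "U", "na": "U", "nd": "U",
}

_PRECISION_VALUES = ("point", "county", "state")


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single presence-only record with location and QC metadata."""

    id: str
    x_km: float
    y_km: float
    longitude: float
    latitude: float
    date: Date
    sex: str  # F | M | U
    error_km: float
    locality_precision: str  # point | county | state

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M", "U"):
            raise ValueError(f"record {self.id}: invalid sex {self.sex!r}")
        if self.error_km < 0:
            raise ValueError(f"record {self.id}: negative error_km")
        if self.locality_precision not in _PRECISION_VALUES:
            raise ValueError(
                f"record {self.id}: invalid locality_precision "
                f"{self.locality_precision!r}"
            )


@dataclass
class ParseResult:
    records: list[OccurrenceRecord]
    rejects: list[dict]  # row payload + "reject_reason"


def _parse_row(row: dict) -> OccurrenceRecord:
    sex_raw = row["sex"].strip().lower()
    if sex_raw not in _SEX_TABLE:
        raise ValueError(f"unrecognized sex value {row['sex']!r}")
    precision = row["locality_precision"].strip().lower()
    if precision not in _PRECISION_VALUES:
        raise ValueError(f"unrecognized locality_precision {row['locality_precision']!r}")
    d = Date.fromisoformat(row["date"].strip())
    lon = float(row["longitude"])
    lat = float(row["latitude"])
    x_raw, y_raw = row["x_km"].strip(), row["y_km"].strip()
    if x_raw == "" or y_raw == "":
        x, y = lonlat_to_planar(lon, lat)
    else:
        x, y = float(x_raw), float(y_raw)
    return OccurrenceRecord(
        id=row["id"].strip(),
        x_km=x,
        y_km=y,
        longitude=lon,
        latitude=lat,
        date=d,
        sex=_SEX_TABLE[sex_raw],
        error_km=float(row["error_km"]),
        locality_precision=precision,
    )


def parse_occurrences(csv_path) -> ParseResult:
    """Read an occurrence CSV; malformed rows go to a rejects report.

    The header must contain exactly the columns of
    :data:`OCCURRENCE_COLUMNS` (order-free).  A missing column rejects
    the whole file; a malformed row is recorded with its reason and does
    not abort the parse.
    """
    csv_path = Path(csv_path)
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in OCCURRENCE_COLUMNS if c not in header]
        if missing:
            raise ValueError(
                f"{csv_path}: missing required column(s) {', '.join(missing)}"
            )
        records: list[OccurrenceRecord] = []
        rejects: list[dict] = []
        for row in reader:
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError) as exc:
                bad = dict(row)
                bad["reject_reason"] = str(exc)
                rejects.append(bad)
    return ParseResult(records, rejects)


# --------------------------------------------------------------------------
# Filtering and subsetting

#: QC threshold on georeferencing error: records with error strictly
#: greater than this many km are dropped.
MAX_ERROR_KM = 50.0


def filter_records(
    records: list[OccurrenceRecord], max_error_km: float = MAX_ERROR_KM
) -> tuple[list[OccurrenceRecord], list[tuple[OccurrenceRecord, str]]]:
    """Apply the locality-precision and spatial-error QC filters.

    Keeps records georeferenced to a point locality with
    ``error_km <= max_error_km`` (a record at exactly the threshold is
    kept; only strictly larger errors are dropped).  Returns
    ``(kept, dropped)`` where each dropped record carries its first
    failing reason.
    """
    kept: list[OccurrenceRecord] = []
    dropped: list[tuple[OccurrenceRecord, str]] = []
    for rec in records:
        if rec.locality_precision != "point":
            dropped.append((rec, f"locality_precision={rec.locality_precision}"))
        elif rec.error_km > max_error_km:
            dropped.append((rec, f"error_km={rec.error_km:g} > {max_error_km:g}"))
        else:
            kept.append(rec)
    return kept, dropped


@dataclass
class SubsetResult:
    subsets: dict[SubsetKey, list[OccurrenceRecord]]
    n_unknown_sex_excluded: int


def make_subsets(records: list[OccurrenceRecord]) -> SubsetResult:
    """Split filtered records into the seven season × sex subsets.

    Winter pools all sexes (including unknown); outside winter, records
    of unknown sex belong to no subset and are tallied in the result's
    exclusion count.
    """
    subsets: dict[SubsetKey, list[OccurrenceRecord]] = {k: [] for k in SUBSET_KEYS}
    n_excluded = 0
    for rec in records:
        season = assign_season(rec.date)
        if season == "winter":
            subsets[SubsetKey("winter", "pooled")].append(rec)
        elif rec.sex == "F":
            subsets[SubsetKey(season, "females")].append(rec)
        elif rec.sex == "M":
            subsets[SubsetKey(season, "males")].append(rec)
        else:
            n_excluded += 1
    return SubsetResult(subsets, n_excluded)


@dataclass
class OccupiedPixelSet:
    """Distinct occupied pixels (presence locations) of one subset."""

    subset: SubsetKey | None
    pixel_ids: set[tuple[int, int]]
    n_records: int

    @property
    def n_locations(self) -> int:
        return len(self.pixel_ids)


def rasterize_occurrences(
    records: list[OccurrenceRecord],
    grid: GridSpec,
    subset: SubsetKey | None = None,
) -> OccupiedPixelSet:
    """Collapse records to the set of occupied pixels on ``grid``.

    Pixel membership uses the half-open (lower-left inclusive) square
    convention.  A record outside the grid footprint is an error naming
    the record id.
    """
    pixel_ids: set[tuple[int, int]] = set()
    for rec in records:
        try:
            pixel_ids.add(grid.pixel_of(rec.x_km, rec.y_km))
        except ValueError:
            raise ValueError(
                f"record {rec.id} at ({rec.x_km:g}, {rec.y_km:g}) km "
                "lies outside the grid"
            ) from None
    return OccupiedPixelSet(subset, pixel_ids, len(records))


def write_occurrence_csv(records: list[OccurrenceRecord], path) -> None:
    """Write records in the canonical occurrence CSV layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(OCCURRENCE_COLUMNS)
        for r in records:
            writer.writerow([
                r.id, f"{r.longitude:.3f}", f"{r.latitude:.3f}",
                repr(r.x_km), repr(r.y_km), r.date.isoformat(),
                r.sex, repr(r.error_km), r.locality_precision,
            ])
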