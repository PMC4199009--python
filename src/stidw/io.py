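"""CSV readers/writers for measurements, targets and surfaces; GeoJSON export.

The measurement schema follows the monitoring-data attribute list: ``id,
year, month, day, x, y, value`` with x/y as longitude/latitude in decimal
degrees and value a concentration in µg/m³.  Calendar dates are converted to
a 1-based continuous day index anchored at 1 January of the earliest year in
the file (a single-year file therefore uses ordinary day-of-year numbering,
and leap years simply yield index 366).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import Measurement, PredictionRecord, TargetSite
from .errors import InvalidDayError, RowError, SchemaError

__all__ = [
    "MeasurementTable", "SurfaceTable", "read_measurements", "read_targets",
    "write_targets", "write_measurements", "write_surface", "read_surface",
    "export_geojson", "day_index_to_date",
]

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ("id", "year", "month", "day", "x", "y", "value")
TARGET_COLUMNS = ("id", "x", "y")


def day_index_to_date(day: int, base_year: int) -> date:
    """Invert the continuous day index: day 1 -> 1 January of base_year."""
    return date(base_year, 1, 1) + timedelta(days=day - 1)


@dataclass(frozen=True)
class MeasurementTable:
    """Measurements plus the extent metadata the scale factor needs."""

    rows: tuple[Measurement, ...]
    base_year: int

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) enclosing all rows."""
        xs = [m.x for m in self.rows]
        ys = [m.y for m in self.rows]
        return (min(xs), max(xs), min(ys), max(ys))

    @property
    def day_span(self) -> tuple[int, int]:
        days = [m.day for m in self.rows]
        return (min(days), max(days))

    @property
    def n_days(self) -> int:
        """Length of the covered day span (both endpoints inclusive)."""
        lo, hi = self.day_span
        return hi - lo + 1


@dataclass(frozen=True)
class SurfaceTable:
    """Prediction records keyed by (target_id, day), in engine output order.

    ``target_coords`` maps target_id to (x, y) when known (engine output);
    surfaces re-read from CSV do not carry coordinates and need the target
    table again for GeoJSON export.
    """

    records: tuple[PredictionRecord, ...]
    base_year: int = 2009
    target_coords: dict | None = None

    def __post_init__(self):
        keys = [(r.target_id, r.day) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (target_id, day) keys in surface")

    @property
    def day_span(self) -> tuple[int, int]:
        days = [r.day for r in self.records]
        return (min(days), max(days))


def _require_columns(frame: pd.DataFrame, required: Sequence[str],
                     source) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {', '.join(missing)}")


def read_measurements(source) -> MeasurementTable:
    """Read a measurement CSV into a :class:`MeasurementTable`.

    The header row is required and columns are matched by name.  Rows with
    unparsable numbers or impossible calendar dates raise :class:`RowError`
    carrying the 1-based file line number (header = line 1).
    """
    frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if frame.empty:
        raise SchemaError(f"{source}: no data rows")
    frame.columns = [c.strip().lower() for c in frame.columns]
    _require_columns(frame, MEASUREMENT_COLUMNS, source)
    years = pd.to_numeric(frame["year"], errors="coerce")
    if years.isna().any():
        bad = int(years.index[years.isna()][0])
        raise RowError(bad + 2, f"unparsable year {frame['year'].iloc[bad]!r}")
    base_year = int(years.min())
    base = date(base_year, 1, 1)
    rows = []
    for idx, rec in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        try:
            year, month, day = int(rec.year), int(rec.month), int(rec.day)
            x, y, value = float(rec.x), float(rec.y), float(rec.value)
        except (TypeError, ValueError) as exc:
            raise RowError(line, f"unparsable numeric field ({exc})") from None
        try:
            when = date(year, month, day)
        except ValueError:
            raise RowError(line, f"invalid calendar date {year}-{month:02d}-{day:02d}") from None
        day_index = (when - base).days + 1
        try:
            rows.append(Measurement(rec.id, x, y, day_index, value))
        except ValueError as exc:
            raise RowError(line, str(exc)) from None
    log.info("read %d measurements from %s", len(rows), source)
    return MeasurementTable(tuple(rows), base_year)


def read_targets(source) -> list[TargetSite]:
    """Read a centroid CSV (id, x, y) preserving file order.

    Duplicate ids are kept (both rows) with a logged warning, since task
    order — and therefore output order — follows the file.
    """
    frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if frame.empty:
        raise SchemaError(f"{source}: no data rows")
    frame.columns = [c.strip().lower() for c in frame.columns]
    _require_columns(frame, TARGET_COLUMNS, source)
    targets = []
    seen = set()
    for idx, rec in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        try:
            targets.append(TargetSite(rec.id, float(rec.x), float(rec.y)))
        except (TypeError, ValueError) as exc:
            raise RowError(line, f"unparsable coordinate ({exc})") from None
        if rec.id in seen:
            log.warning("duplicated target id %r at line %d (kept)", rec.id, line)
        seen.add(rec.id)
    return targets


def write_targets(targets: Sequence[TargetSite], sink) -> None:
    """Write a centroid CSV (id, x, y) in list order."""
    with open(sink, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TARGET_COLUMNS)
        for t in targets:
            writer.writerow([t.target_id, f"{t.x:.12g}", f"{t.y:.12g}"])


def write_measurements(table: MeasurementTable, sink) -> None:
    """Write measurements back to the CSV schema (day index -> calendar date)."""
    with open(sink, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for m in table.rows:
            when = day_index_to_date(m.day, table.base_year)
            writer.writerow([m.site_id, when.year, when.month, when.day,
                             f"{m.x:.12g}", f"{m.y:.12g}", f"{m.value:.12g}"])


def write_surface(table: SurfaceTable, sink) -> None:
    """Write predictions as CSV: target_id, year, month, day, value, neighbors_used.

    Missing predictions serialize as an empty value field with
    neighbors_used 0; values round-trip to at least 10 significant digits.
    """
    with open(sink, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target_id", "year", "month", "day", "value",
                         "neighbors_used"])
        for r in table.records:
            when = day_index_to_date(r.day, table.base_year)
            value = "" if r.value is None else f"{r.value:.12g}"
            writer.writerow([r.target_id, when.year, when.month, when.day,
                             value, r.neighbors_used])


def read_surface(source) -> SurfaceTable:
    """Read a surface CSV back (inverse of :func:`write_surface`)."""
    frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if frame.empty:
        raise SchemaError(f"{source}: no data rows")
    frame.columns = [c.strip().lower() for c in frame.columns]
    _require_columns(frame, ("target_id", "year", "month", "day", "value",
                             "neighbors_used"), source)
    base_year = int(pd.to_numeric(frame["year"]).min())
    base = date(base_year, 1, 1)
    records = []
    for idx, rec in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        try:
            when = date(int(rec.year), int(rec.month), int(rec.day))
            missing = pd.isna(rec.value) or str(rec.value).strip() == ""
            value = None if missing else float(rec.value)
            used = int(rec.neighbors_used)
        except (TypeError, ValueError) as exc:
            raise RowError(line, f"unparsable field ({exc})") from None
        records.append(PredictionRecord(rec.target_id, (when - base).days + 1,
                                        value, used))
    return SurfaceTable(tuple(records), base_year)


# endpoint colors of the export ramp: light green (low) to red (high)
_LOW_RGB = (144, 238, 144)
_HIGH_RGB = (255, 0, 0)


def _ramp_color(fraction: float) -> str:
    rgb = [round(lo + fraction * (hi - lo)) for lo, hi in zip(_LOW_RGB, _HIGH_RGB)]
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def export_geojson(table: SurfaceTable, day: int, sink, bins: int = 10) -> None:
    """Export one day of a surface as a GeoJSON FeatureCollection of Points.

    Each feature carries {target_id, value, day} plus an equal-interval class
    over the day's value range: ``bin`` in [0, bins) and a ``color`` on a
    linear ramp from light green (lowest class) to red (highest).  Days on
    which every prediction is missing export as an empty collection with a
    ``count`` of 0.
    """
    lo, hi = table.day_span
    if not lo <= day <= hi:
        raise InvalidDayError(f"day {day} outside surface range [{lo}, {hi}]")
    if table.target_coords is None:
        raise ValueError("surface carries no target coordinates; "
                         "supply the target table when constructing it")
    present = [r for r in table.records if r.day == day and r.value is not None]
    values = [r.value for r in present]
    vmin = min(values) if values else 0.0
    vmax = max(values) if values else 0.0
    span = vmax - vmin
    features = []
    for r in present:
        x, y = table.target_coords[r.target_id]
        if span > 0:
            idx = min(int((r.value - vmin) / span * bins), bins - 1)
        else:
            idx = 0
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": {
                "target_id": str(r.target_id),
                "value": r.value,
                "day": day,
                "bin": idx,
                "color": _ramp_color(idx / (bins - 1) if bins > 1 else 1.0),
            },
        })
    document = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"day": day, "count": len(features)},
    }
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            json.dump(document, fh, indent=1)
    else:
        json.dump(document, sink, indent=1)
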