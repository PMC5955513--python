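"""Reading, validating, filtering, and projecting event records.

An *event table* is a pandas ``DataFrame`` with the canonical columns

======================  =========================================
``event_id``            opaque string identifier
``lon``, ``lat``        WGS84 degrees
``timestamp``           naive local date-time (minute precision)
``driver_age``          years, nullable float
``victim_age``          years, nullable float
``gender``, ``weather`` optional strings
======================  =========================================

Rows that survive :func:`read_events` always carry valid coordinates
(lon in [-180, 180], lat in [-90, 90]) and a parseable timestamp; invalid
rows are dropped and counted, never silently discarded.  Timestamps are
interpreted in a single fixed local clock (no daylight-saving arithmetic):
the analyses downstream only ever use the wall-clock hour and the calendar
month.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import parse_crs

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("event_id", "lon", "lat", "timestamp",
                     "driver_age", "victim_age", "gender", "weather")
REQUIRED = ("event_id", "lon", "lat", "timestamp")


@dataclass
class ReadReport:
    """Row accounting for one :func:`read_events` call."""

    n_rows_in: int = 0
    n_retained: int = 0
    n_dropped: int = 0
    reasons: dict = field(default_factory=dict)


@dataclass
class ProjectedPoints:
    """Planar coordinates (metres) for the retained events.

    ``index`` links each point back to the event-table row it came from.
    """

    x: np.ndarray
    y: np.ndarray
    crs_tag: str
    index: pd.Index

    @property
    def n(self) -> int:
        return len(self.x)


def read_events(path, schema: dict | None = None) -> tuple[pd.DataFrame, ReadReport]:
    """Read a CSV of event records into a canonical event table.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    schema : dict, optional
        Mapping from canonical field name to the column name in the file,
        e.g. ``{"lon": "longitude"}``.  Unmapped canonical fields default
        to their own names; optional fields absent from the file are
        filled with nulls.

    Returns
    -------
    (events, report)
        The validated event table (row order preserved) and a
        :class:`ReadReport` counting dropped rows by reason.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If a mapped column for a required field is missing, naming it.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = schema or {}
    colmap = {f: schema.get(f, f) for f in CANONICAL_COLUMNS}
    for f in REQUIRED:
        if colmap[f] not in raw.columns:
            raise ValueError(f"required column {colmap[f]!r} (field {f!r}) "
                             f"not found in {path}")
    report = ReadReport(n_rows_in=len(raw))

    out = pd.DataFrame(index=raw.index)
    out["event_id"] = raw[colmap["event_id"]].astype(str)
    lon = pd.to_numeric(raw[colmap["lon"]], errors="coerce")
    lat = pd.to_numeric(raw[colmap["lat"]], errors="coerce")
    ts = pd.to_datetime(raw[colmap["timestamp"]], errors="coerce", format="mixed")
    out["lon"], out["lat"], out["timestamp"] = lon, lat, ts
    for f in ("driver_age", "victim_age"):
        col = colmap[f]
        out[f] = pd.to_numeric(raw[col], errors="coerce") if col in raw.columns else np.nan
    for f in ("gender", "weather"):
        col = colmap[f]
        out[f] = raw[col].replace("", pd.NA) if col in raw.columns else pd.NA

    bad_coord = (lon.isna() | lat.isna()
                 | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90))
    bad_time = ts.isna()
    keep = ~(bad_coord | bad_time)
    report.reasons = {"invalid_coordinates": int(bad_coord.sum()),
                      "invalid_timestamp": int((bad_time & ~bad_coord).sum())}
    report.n_dropped = int((~keep).sum())
    report.n_retained = int(keep.sum())
    if report.n_dropped:
        logger.warning("read_events: dropped %d/%d rows (%s)",
                       report.n_dropped, report.n_rows_in, report.reasons)
    return out[keep].reset_index(drop=True), report


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table back to CSV in the canonical schema."""
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%d %H:%M")
    out.to_csv(path, index=False, columns=list(CANONICAL_COLUMNS))


def filter_elderly(events: pd.DataFrame, role: str, min_age: float = 65,
                   return_report: bool = False):
    """Keep events where the given role's age is ``min_age`` or older.

    ``role`` is ``"driver"`` or ``"victim"``.  Rows with a missing age for
    that role are excluded (and counted when ``return_report`` is true).
    Age exactly ``min_age`` is retained.
    """
    if role not in ("driver", "victim"):
        raise ValueError(f"unknown role {role!r}; expected 'driver' or 'victim'")
    age = events[f"{role}_age"]
    keep = age >= min_age  # NaN compares False -> excluded
    n_null = int(age.isna().sum())
    filtered = events[keep].reset_index(drop=True)
    if return_report:
        return filtered, {"n_retained": len(filtered),
                          "n_excluded": int((~keep).sum()),
                          "n_null_age": n_null}
    return filtered


def project_to_planar(events: pd.DataFrame, crs_tag: str) -> ProjectedPoints:
    """Project WGS84 event coordinates to planar metres.

    The inverse projection (``parse_crs(crs_tag).inverse``) recovers
    lon/lat to well below 1e-6 degrees.
    """
    proj = parse_crs(crs_tag)
    if len(events) == 0:
        return ProjectedPoints(np.empty(0), np.empty(0), crs_tag, events.index)
    x, y = proj.forward(events["lon"].to_numpy(), events["lat"].to_numpy())
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("projection produced non-finite coordinates")
    return ProjectedPoints(np.asarray(x, float), np.asarray(y, float),
                           crs_tag, events.index)


def events_to_geojson(events: pd.DataFrame, path) -> None:
    """Write events as a GeoJSON FeatureCollection of WGS84 points."""
    feats = []
    for _, row in events.iterrows():
        props = {"event_id": row["event_id"],
                 "timestamp": pd.Timestamp(row["timestamp"]).strftime("%Y-%m-%d %H:%M")}
        for f in ("driver_age", "victim_age", "gender", "weather"):
            v = row.get(f)
            props[f] = None if pd.isna(v) else (float(v) if "age" in f else str(v))
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point",
                                   "coordinates": [float(row["lon"]), float(row["lat"])]},
                      "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
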