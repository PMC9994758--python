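"""Readers and writers for the package's exchange formats.

All tabular interfaces are CSV with a leading schema comment line
(``# phenofcm schema_version=1.0``); readers reject files written by a
newer major schema.  Parcel geometries travel as GeoJSON in EPSG:4326.
Ground observations follow the field-campaign schema: one row per
visit with the primary stage and its prevalence percentage, and an
optional adjacent secondary stage with its own prevalence.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape

from .stages import Metaclass, PhenologyStage

SCHEMA_VERSION = "1.0"
_SCHEMA_PREFIX = "# phenofcm schema_version="

__all__ = [
    "GroundObservation",
    "read_observations",
    "write_observations",
    "read_bands",
    "write_bands",
    "read_weather",
    "write_weather",
    "read_predictions",
    "write_predictions",
    "write_fields_geojson",
    "read_fields_geojson",
    "make_field_geometries",
    "nearest_grid_cell",
    "dataset_descriptives",
    "date_to_doy",
]


@dataclass(frozen=True)
class GroundObservation:
    """One field visit from the ground-observation campaign."""

    field_id: str
    visit_doy: int
    primary_stage: PhenologyStage
    primary_prevalence: float
    secondary_stage: Optional[PhenologyStage] = None
    secondary_prevalence: Optional[float] = None
    sowing_doy: Optional[int] = None
    harvest_doy: Optional[int] = None
    photo_refs: str = ""

    @property
    def metaclass(self) -> Metaclass:
        return Metaclass(self.primary_stage, self.secondary_stage)


def date_to_doy(value: str) -> int:
    """ISO-8601 calendar date -> day of year of that date's year."""
    return _dt.date.fromisoformat(str(value)).timetuple().tm_yday


# -- low-level CSV plumbing -------------------------------------------------


def _write_csv(frame: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_SCHEMA_PREFIX}{SCHEMA_VERSION}\n")
        frame.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(_SCHEMA_PREFIX):
        version = first[len(_SCHEMA_PREFIX):].strip()
        major = int(version.split(".")[0])
        if major > int(SCHEMA_VERSION.split(".")[0]):
            raise ValueError(
                f"{path}: schema version {version} is newer than supported {SCHEMA_VERSION}"
            )
    return pd.read_csv(path, comment="#")


def write_bands(bands: pd.DataFrame, path) -> None:
    _write_csv(bands, path)


def read_bands(path) -> pd.DataFrame:
    return _read_csv(path)


def write_weather(weather: pd.DataFrame, path) -> None:
    _write_csv(weather, path)


def read_weather(path) -> pd.DataFrame:
    return _read_csv(path)


# -- ground observations ----------------------------------------------------

_MANDATORY_OBS_COLUMNS = ("field_id", "visit_doy", "primary_stage", "primary_prevalence")


def write_observations(observations: pd.DataFrame, path) -> None:
    _write_csv(observations, path)


def read_observations(
    path, column_map: Optional[Dict[str, str]] = None
) -> Tuple[List[GroundObservation], List[dict]]:
    """Parse a ground-observation table into validated records.

    ``column_map`` renames dataset-specific column names onto the
    canonical schema (e.g. ``{"visit_date": "visit_doy"}``; date-valued
    visit columns are converted to DoY).  Malformed rows — bad stage
    codes, prevalences outside (0, 100], or a non-adjacent secondary —
    are collected into the returned error report instead of raising.
    """
    frame = _read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = [c for c in _MANDATORY_OBS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    records: List[GroundObservation] = []
    errors: List[dict] = []
    for i, row in frame.iterrows():
        try:
            records.append(_parse_observation(row))
        except (ValueError, KeyError) as exc:
            errors.append({"row": int(i), "error": str(exc)})
    return records, errors


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    v = _opt_float(value)
    return int(v) if v is not None else None


def _parse_observation(row: pd.Series) -> GroundObservation:
    visit = row["visit_doy"]
    if isinstance(visit, str) and "-" in visit:
        visit_doy = date_to_doy(visit)
    else:
        visit_doy = int(visit)
    primary = PhenologyStage.from_code(str(row["primary_stage"]))
    p_prev = float(row["primary_prevalence"])
    if not 0.0 < p_prev <= 100.0:
        raise ValueError(f"primary prevalence {p_prev} outside (0, 100]")
    sec_raw = row.get("secondary_stage", "")
    secondary = None
    s_prev = None
    if isinstance(sec_raw, str) and sec_raw.strip():
        secondary = PhenologyStage.from_code(sec_raw)
        if not primary.is_adjacent(secondary):
            raise ValueError(
                f"secondary stage {secondary.code} not adjacent to primary {primary.code}"
            )
        s_prev = _opt_float(row.get("secondary_prevalence"))
        if s_prev is not None and not 0.0 < s_prev <= 100.0:
            raise ValueError(f"secondary prevalence {s_prev} outside (0, 100]")
    return GroundObservation(
        field_id=str(row["field_id"]),
        visit_doy=visit_doy,
        primary_stage=primary,
        primary_prevalence=p_prev,
        secondary_stage=secondary,
        secondary_prevalence=s_prev,
        sowing_doy=_opt_int(row.get("sowing_doy")),
        harvest_doy=_opt_int(row.get("harvest_doy")),
        photo_refs=str(row.get("photo_refs", "") or ""),
    )


def dataset_descriptives(observations: Sequence[GroundObservation]) -> dict:
    """Campaign summary: visit counts overall and with a secondary stage."""
    n = len(observations)
    n_secondary = sum(1 for o in observations if o.secondary_stage is not None)
    per_stage = {s.code: 0 for s in PhenologyStage}
    for o in observations:
        per_stage[o.primary_stage.code] += 1
    return {
        "n_visits": n,
        "n_secondary_visits": n_secondary,
        "primary_stage_counts": per_stage,
    }


# -- predictions ------------------------------------------------------------

_WEIGHT_COLUMNS = tuple(f"w_{s.code}" for s in PhenologyStage)


def write_predictions(predictions: pd.DataFrame, path) -> None:
    """Write the prediction table (field_id, doy, metaclass, w_RE..w_BO)."""
    cols = ["field_id", "doy", "metaclass", *_WEIGHT_COLUMNS]
    missing = [c for c in cols if c not in predictions.columns]
    if missing:
        raise ValueError(f"prediction table missing column(s) {missing}")
    _write_csv(predictions[cols], path)


def read_predictions(path) -> pd.DataFrame:
    """Read and validate predictions: weight rows sum to 1, metaclass legal."""
    frame = _read_csv(path)
    weights = frame[list(_WEIGHT_COLUMNS)].to_numpy(dtype=float)
    sums = weights.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"{path}: weight row {bad} sums to {sums[bad]!r}, not 1")
    frame["metaclass"].map(Metaclass.from_string)  # raises on malformed strings
    return frame


# -- parcel geometries ------------------------------------------------------


def make_field_geometries(
    field_ids: Sequence[str],
    origin: Tuple[float, float] = (22.95, 38.48),
    side_deg: float = 0.002,
    per_row: int = 8,
) -> Dict[str, Polygon]:
    """Synthetic square parcels laid out on a grid near Orchomenos, Greece."""
    geoms = {}
    for i, fid in enumerate(field_ids):
        x0 = origin[0] + (i % per_row) * 2 * side_deg
        y0 = origin[1] + (i // per_row) * 2 * side_deg
        geoms[fid] = Polygon(
            [(x0, y0), (x0 + side_deg, y0), (x0 + side_deg, y0 + side_deg), (x0, y0 + side_deg)]
        )
    return geoms


def write_fields_geojson(geometries: Dict[str, Polygon], path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"field_id": fid},
            "geometry": mapping(geom),
        }
        for fid, geom in geometries.items()
    ]
    payload = {
        "type": "FeatureCollection",
        "schema_version": SCHEMA_VERSION,
        "crs": {"type": "name", "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_fields_geojson(path) -> Dict[str, Polygon]:
    with open(path) as fh:
        payload = json.load(fh)
    version = str(payload.get("schema_version", SCHEMA_VERSION))
    if int(version.split(".")[0]) > int(SCHEMA_VERSION.split(".")[0]):
        raise ValueError(f"{path}: schema version {version} newer than supported")
    return {
        feat["properties"]["field_id"]: shape(feat["geometry"])
        for feat in payload["features"]
    }


def nearest_grid_cell(field_geometry, cell_centers: Sequence[Tuple[float, float]]) -> int:
    """Index of the weather grid cell nearest the parcel centroid.

    Exact distance ties resolve to the lowest cell index.
    """
    centroid = field_geometry.centroid
    dists = np.array([centroid.distance(Point(x, y)) for x, y in cell_centers])
    return int(np.argmin(dists))  # argmin takes the first (lowest) index on ties
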