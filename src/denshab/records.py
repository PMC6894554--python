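"""Tabular and vector record types shared across the pipeline.

Relocation tables ("LocationSets") are plain pandas DataFrames with the
columns in :data:`LOCATION_COLUMNS`; territory estimates are
:class:`TerritoryRecord` dataclasses.  GeoJSON I/O goes through shapely's
mapping/shape helpers so the files are readable by any GIS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

LOCATION_COLUMNS = ["pack_id", "year", "x_km", "y_km"]


def empty_locations() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="float64" if c.endswith("_km") else "object")
                         for c in LOCATION_COLUMNS})


def as_locations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOCATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"location table missing columns: {missing}")
    return df


def write_locations_csv(df: pd.DataFrame, path) -> None:
    as_locations(df).to_csv(path, index=False)


def read_locations_csv(path) -> pd.DataFrame:
    return as_locations(pd.read_csv(path))


@dataclass
class TerritoryRecord:
    """One pack-year territory: polygon, area and how it was estimated.

    ``method_tag`` follows the estimation cascade: "A-yearly" / "A-window"
    for single-year and 3-year moving-window kernel isopleths, "A" for a
    carried-forward earlier estimate, "B" for a pooled telemetry+track kernel
    estimate, "C" for a track-only minimum convex polygon, and "truth" for
    simulator-generated territories.
    """

    pack_id: str
    year: int
    polygon: BaseGeometry
    area_km2: float = field(default=None)
    method_tag: str = "truth"
    n_locations_used: int = 0
    size: float | None = None  # pack size when known (census / truth)

    def __post_init__(self) -> None:
        if self.area_km2 is None:
            self.area_km2 = float(self.polygon.area)

    @property
    def centroid(self):
        return self.polygon.centroid


def territories_to_geojson(records: list[TerritoryRecord], path) -> None:
    features = []
    for rec in records:
        features.append({
            "type": "Feature",
            "geometry": mapping(rec.polygon),
            "properties": {
                "pack_id": rec.pack_id,
                "year": int(rec.year),
                "area_km2": float(rec.area_km2),
                "method_tag": rec.method_tag,
                "n_locations_used": int(rec.n_locations_used),
                "size": None if rec.size is None else float(rec.size),
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def territories_from_geojson(path) -> list[TerritoryRecord]:
    with open(path) as fh:
        collection = json.load(fh)
    records = []
    for feat in collection["features"]:
        p = feat["properties"]
        records.append(TerritoryRecord(
            pack_id=p["pack_id"], year=int(p["year"]),
            polygon=shape(feat["geometry"]), area_km2=p.get("area_km2"),
            method_tag=p.get("method_tag", "truth"),
            n_locations_used=int(p.get("n_locations_used", 0)),
            size=p.get("size"),
        ))
    return records
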