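"""Readers and writers for the package's standard on-disk formats.

Gridded fields travel as NetCDF (classic format via the scipy backend),
vector data as GeoJSON feature collections, tables as CSV.  Coordinate
conventions are fixed package-wide: geographic rasters are regular
lat/lon grids (time × lat × lon); vector geometry files are GeoJSON in
geographic coordinates unless a ``crs`` property marks them as
equal-area metres; dates are calendar dates and intervals include both
endpoints.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

__all__ = [
    "read_weather",
    "write_dataset",
    "read_geojson",
    "write_geojson",
    "sha256_file",
]


def read_weather(path, rename: dict[str, str] | None = None) -> xr.Dataset:
    """Load a gridded daily weather file, optionally renaming variables.

    ``rename`` maps on-disk variable names to the package's canonical
    names (temp, tmax, rh, wind, precip).
    """
    ds = xr.load_dataset(path, engine="scipy")
    if rename:
        ds = ds.rename(rename)
    return ds


def write_dataset(ds: xr.Dataset, path) -> None:
    """Write a dataset as classic NetCDF (deterministic byte layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    enc = {}
    for name, var in ds.variables.items():
        if var.dtype == bool:
            enc[name] = {"dtype": "int8"}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_geojson(path) -> pd.DataFrame:
    """GeoJSON feature collection → DataFrame with a ``geometry`` column."""
    with open(path) as fh:
        data = json.load(fh)
    rows = []
    for feat in data.get("features", []):
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)


def write_geojson(df: pd.DataFrame, path, crs_note: str | None = None) -> None:
    """DataFrame with ``geometry`` column → GeoJSON feature collection."""
    features = []
    for _, row in df.iterrows():
        props = {
            k: (v.isoformat() if isinstance(v, pd.Timestamp) else v)
            for k, v in row.items()
            if k != "geometry"
        }
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(row["geometry"]),
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if crs_note:
        doc["crs_note"] = crs_note
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
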