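"""Map projection and grid-geometry helpers.

All areas and buffer operations in this package are carried out in a
spherical Albers equal-area conic projection over Canada (standard
parallels 50°N and 70°N, origin 40°N, central meridian 96°W), so that
metre-valued buffer radii and hectare areas are meaningful.  Grid-cell
areas on regular latitude/longitude meshes are computed analytically
from spherical geometry.
"""

from __future__ import annotations

import math

import numpy as np
import shapely

EARTH_RADIUS_M = 6_371_000.0

# Albers parameters (Canada Albers equal-area convention)
_PHI1 = math.radians(50.0)
_PHI2 = math.radians(70.0)
_PHI0 = math.radians(40.0)
_LON0 = math.radians(-96.0)

_N = (math.sin(_PHI1) + math.sin(_PHI2)) / 2.0
_C = math.cos(_PHI1) ** 2 + 2.0 * _N * math.sin(_PHI1)
_RHO0 = EARTH_RADIUS_M * math.sqrt(_C - 2.0 * _N * math.sin(_PHI0)) / _N


def albers_xy(lon, lat):
    """Forward-project geographic coordinates (degrees) to Albers metres.

    Accepts scalars or arrays; returns ``(x, y)`` of the same shape.
    """
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    rho = EARTH_RADIUS_M * np.sqrt(_C - 2.0 * _N * np.sin(phi)) / _N
    theta = _N * (lam - _LON0)
    x = rho * np.sin(theta)
    y = _RHO0 - rho * np.cos(theta)
    return x, y


def albers_lonlat(x, y):
    """Inverse Albers projection: metres back to (lon, lat) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, _RHO0 - y)
    theta = np.arctan2(x, _RHO0 - y)
    phi = np.arcsin((_C - (rho * _N / EARTH_RADIUS_M) ** 2) / (2.0 * _N))
    lam = _LON0 + theta / _N
    return np.degrees(lam), np.degrees(phi)


def project_geometry(geom):
    """Project a shapely geometry from lon/lat degrees to Albers metres."""
    return shapely.transform(
        geom, lambda pts: np.column_stack(albers_xy(pts[:, 0], pts[:, 1]))
    )


def unproject_geometry(geom):
    """Project a shapely geometry from Albers metres back to lon/lat."""
    return shapely.transform(
        geom, lambda pts: np.column_stack(albers_lonlat(pts[:, 0], pts[:, 1]))
    )


def cell_areas_km2(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Analytic areas (km²) of regular lat/lon grid cells.

    ``lat`` and ``lon`` are 1-D cell-centre coordinate arrays with uniform
    spacing.  Each cell spans half a step either side of its centre; the
    area is R²·Δλ·(sin φ₊ − sin φ₋) on the sphere.

    Returns an array of shape ``(len(lat), len(lon))``.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = abs(lat[1] - lat[0]) if lat.size > 1 else 1.0
    dlon = abs(lon[1] - lon[0]) if lon.size > 1 else 1.0
    phi_hi = np.radians(np.clip(lat + dlat / 2.0, -90.0, 90.0))
    phi_lo = np.radians(np.clip(lat - dlat / 2.0, -90.0, 90.0))
    band = (EARTH_RADIUS_M / 1000.0) ** 2 * math.radians(dlon) * (
        np.sin(phi_hi) - np.sin(phi_lo)
    )
    return np.repeat(band[:, None], lon.size, axis=1)


def solar_noon_offset_hours(lon) -> np.ndarray:
    """Whole-hour offset from UTC to local solar time, round(lon / 15°)."""
    return np.round(np.asarray(lon, dtype=float) / 15.0).astype(int)
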