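"""Great-circle geometry helpers (WGS84 coordinates, spherical Earth)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Great-circle distance in km; accepts scalars or broadcastable arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return float(d) if d.ndim == 0 else d


def pairwise_distance_km(coords: np.ndarray) -> np.ndarray:
    """Symmetric distance matrix for an ``(n, 2)`` array of (lat, lon)."""
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    return haversine_km(lat, lon, lat.T, lon.T)


def project_on_axis(coords: np.ndarray, axis_start: tuple[float, float],
                    axis_end: tuple[float, float]) -> np.ndarray:
    """Project points onto a geographic axis; distance from its start in km.

    Points and endpoints are mapped into a local equirectangular plane
    centred on the axis midpoint, projected orthogonally onto the segment
    (clamped to its ends), and the along-axis distance is returned.
    """
    a = np.asarray(axis_start, dtype=float)
    b = np.asarray(axis_end, dtype=float)
    if np.allclose(a, b):
        raise ValueError("axis endpoints must be distinct")
    lat0 = np.radians((a[0] + b[0]) / 2.0)

    def to_xy(latlon: np.ndarray) -> np.ndarray:
        latlon = np.atleast_2d(latlon)
        x = EARTH_RADIUS_KM * np.radians(latlon[:, 1]) * np.cos(lat0)
        y = EARTH_RADIUS_KM * np.radians(latlon[:, 0])
        return np.column_stack([x, y])

    p = to_xy(np.asarray(coords, dtype=float))
    s = to_xy(a)[0]
    e = to_xy(b)[0]
    v = e - s
    t = ((p - s) @ v) / (v @ v)
    t = np.clip(t, 0.0, 1.0)
    return t * np.linalg.norm(v)
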