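"""Haversine distances and spatial ordering of monitoring stations.

Spatial analysis with a windowed statistic needs a one-dimensional ordering of
the stations (a space-for-time substitution). Stations are ordered by their
great-circle (Haversine) distance from a reference corner — the coordinate-wise
minimum latitude and longitude of the dataset, generally not itself a station —
so the first window holds the stations closest to that corner and each
subsequent window advances one station outward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fisher import DataError

EARTH_RADIUS_KM = 6371.0

__all__ = ["EARTH_RADIUS_KM", "OrderedLandscape", "haversine_km", "order_stations"]


def _validate_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise DataError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise DataError("latitude outside [-90, 90] degrees")
    if np.any(np.abs(lon) > 180.0):
        raise DataError("longitude outside [-180, 180] degrees")


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points given in decimal degrees.

    d = 2 r asin( sqrt( sin^2(dphi/2) + cos(phi1) cos(phi2) sin^2(dlambda/2) ) )

    Vectorised over array inputs; symmetric; 0 <= d <= pi*r.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    _validate_coords(lat1, lon1)
    _validate_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class OrderedLandscape:
    """Stations sorted by Haversine distance from the dataset's SW corner."""

    reference: tuple[float, float]  # (min latitude, min longitude)
    frame: pd.DataFrame  # rank, station_id, lat, lon, [region], distance_km

    @property
    def station_ids(self) -> list[str]:
        return list(self.frame["station_id"])


def order_stations(
    stations: pd.DataFrame, radius_km: float = EARTH_RADIUS_KM
) -> OrderedLandscape:
    """Order stations by distance from the (min lat, min lon) reference corner.

    ``stations`` must have columns station_id, lat, lon (a ``region`` column is
    carried through when present). Distance ties are broken by lexicographic
    station id, making the ordering deterministic and invariant to input row
    order.
    """
    required = {"station_id", "lat", "lon"}
    missing = required - set(stations.columns)
    if missing:
        raise DataError(f"stations table missing columns: {sorted(missing)}")
    if len(stations) < 2:
        raise DataError("need at least 2 stations to order")
    df = stations.copy()
    df["station_id"] = df["station_id"].astype(str)
    if df["station_id"].duplicated().any():
        dupes = sorted(df.loc[df["station_id"].duplicated(), "station_id"].unique())
        raise DataError(f"duplicate station ids: {dupes}")
    _validate_coords(df["lat"], df["lon"])

    ref_lat = float(df["lat"].min())
    ref_lon = float(df["lon"].min())
    df["distance_km"] = haversine_km(
        df["lat"].to_numpy(), df["lon"].to_numpy(), ref_lat, ref_lon, radius_km
    )
    df = df.sort_values(
        ["distance_km", "station_id"], kind="mergesort", ignore_index=True
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    cols = ["rank", "station_id", "lat", "lon"]
    if "region" in df.columns:
        cols.append("region")
    cols.append("distance_km")
    return OrderedLandscape(reference=(ref_lat, ref_lon), frame=df[cols])
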