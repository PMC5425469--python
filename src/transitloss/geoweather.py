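"""Link slaughter plants to nearby weather stations and build plant-week weather.

Each plant is matched to its closest one to three stations within a fixed
search radius (default 100 statute miles) by great-circle distance, and the
daily station observations are pooled, unweighted, into weekly summaries of
average temperature, mean daily minimum temperature, and relative humidity.
Plants with no qualifying station are excluded downstream, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Mean Earth radius in statute miles; fixed so distances are reproducible.
EARTH_RADIUS_MILES = 3958.8

#: Plant processing-volume categories, smallest to largest weekly head count.
VOLUME_CATEGORIES = ("VS", "S", "M", "L", "VL")


@dataclass(frozen=True)
class Station:
    """A weather station with geographic coordinates in decimal degrees."""

    station_id: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        _check_coords(self.lat, self.lon)


@dataclass(frozen=True)
class Plant:
    """A slaughter establishment with location and volume category."""

    plant_id: str
    lat: float
    lon: float
    volume_category: str

    def __post_init__(self) -> None:
        _check_coords(self.lat, self.lon)
        if self.volume_category not in VOLUME_CATEGORIES:
            raise ValueError(
                f"volume_category {self.volume_category!r} not one of "
                f"{VOLUME_CATEGORIES}"
            )


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError(f"latitude out of [-90, 90]: {lat}")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError(f"longitude out of [-180, 180]: {lon}")


def haversine_miles(a, b) -> float:
    """Great-circle distance in statute miles between two (lat, lon) pairs.

    Uses the haversine formula on a sphere of radius ``EARTH_RADIUS_MILES``.
    Accepts scalars or broadcastable arrays of coordinate pairs.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_MILES * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def assign_stations(plant: Plant, catalog, max_miles: float = 100.0, k: int = 3):
    """Closest ``k`` stations within ``max_miles`` of a plant.

    Returns a list of ``(Station, distance)`` sorted by ascending distance.
    An empty list is a valid outcome (the plant is excluded downstream).
    """
    if not catalog:
        raise ValueError("station catalog is empty")
    pairs = []
    for st in catalog:
        d = haversine_miles((plant.lat, plant.lon), (st.lat, st.lon))
        if d <= max_miles:
            pairs.append((st, d))
    pairs.sort(key=lambda p: (p[1], p[0].station_id))
    return pairs[:k]


def weekly_weather(plant: Plant, assigned, daily: pd.DataFrame, week: str):
    """Pool daily observations from assigned stations into one plant-week row.

    ``daily`` must carry columns ``station_id, date, t_avg, t_min, rh`` with
    ``date`` parseable to datetimes.  Pooling is an unweighted mean over all
    (station, day) observations falling in the ISO week ``week`` (format
    ``YYYY-Www``).  Returns a dict (a ``PlantWeekWeather`` record) or ``None``
    when no observation falls in the week, in which case the plant-week is
    excluded from modelling.
    """
    if not assigned:
        return None
    ids = {st.station_id for st, _ in assigned}
    sub = daily[daily["station_id"].isin(ids)]
    if sub.empty:
        return None
    iso = pd.to_datetime(sub["date"]).dt.isocalendar()
    wk = iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)
    sub = sub[wk == week]
    sub = sub.dropna(subset=["t_avg", "t_min", "rh"])
    if sub.empty:
        return None
    n_days = sub.groupby("station_id")["date"].nunique().max()
    return {
        "plant_id": plant.plant_id,
        "week": week,
        "t_avg_week": float(sub["t_avg"].mean()),
        "t_min_week": float(sub["t_min"].mean()),
        "rh_week": float(sub["rh"].mean()),
        "n_stations_used": int(sub["station_id"].nunique()),
        "partial": bool(n_days < 7),
    }


def iso_week_label(dates) -> pd.Series:
    """ISO-8601 week labels ``YYYY-Www`` (Monday-start) for a date series."""
    iso = pd.to_datetime(pd.Series(dates)).dt.isocalendar()
    return iso["year"].astype(str) + "-W" + iso["week"].astype(str).str.zfill(2)


def weekly_weather_table(
    plants,
    stations,
    daily: pd.DataFrame,
    max_miles: float = 100.0,
    k: int = 3,
    min_days: int = 1,
):
    """Vectorised plant-week weather for a whole catalog.

    Assigns stations once per plant (fixed assignment; stations are not
    re-ranked week by week) and aggregates every ISO week present in the
    daily table.  Returns ``(table, excluded_plants)`` where ``table`` has
    one row per (plant_id, week) and ``excluded_plants`` lists plants with
    no station within ``max_miles``.
    """
    daily = daily.copy()
    daily["week"] = iso_week_label(daily["date"]).values
    rows = []
    excluded = []
    for plant in plants:
        assigned = assign_stations(plant, stations, max_miles=max_miles, k=k)
        if not assigned:
            excluded.append(plant.plant_id)
            continue
        ids = {st.station_id for st, _ in assigned}
        sub = daily[daily["station_id"].isin(ids)].dropna(
            subset=["t_avg", "t_min", "rh"]
        )
        if sub.empty:
            continue
        grp = sub.groupby("week")
        agg = grp.agg(
            t_avg_week=("t_avg", "mean"),
            t_min_week=("t_min", "mean"),
            rh_week=("rh", "mean"),
            n_stations_used=("station_id", "nunique"),
        )
        n_days = grp["date"].nunique()
        agg = agg[n_days >= min_days]
        agg = agg.reset_index()
        agg.insert(0, "plant_id", plant.plant_id)
        rows.append(agg)
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=[
                "plant_id",
                "week",
                "t_avg_week",
                "t_min_week",
                "rh_week",
                "n_stations_used",
            ]
        )
    return table, excluded
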