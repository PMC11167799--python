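"""Biological summaries derived from tracks and archives.

Distances and partial-migration strategy classes, quarterly space-use
kernel densities, daily vertical-behaviour metrics, spawning-candidate
flags, and population summaries mirroring the recovery table's columns.

Strategy thresholds follow the published scheme: short-distance migrators
(< 50 km), intermediate (50-200 km) and long-distance (> 200 km), assigned
only to fish at liberty more than 182 days (half a year).  Exact boundary
values go to the lower category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .archive import TagArchive

EARTH_RADIUS_KM = 6371.0
STRATEGY_SHORT_KM = 50.0
STRATEGY_LONG_KM = 200.0
MIN_LIBERTY_DAYS = 182
SPAWNING_TEMP_C = (8.5, 11.0)
SPAWNING_VSPEED_MS = 0.25

__all__ = [
    "haversine_km",
    "classify_strategy",
    "max_distance_from_release",
    "quarterly_density",
    "daily_metrics",
    "spawning_candidates",
    "summarize_population",
]


def haversine_km(p1, p2) -> float:
    """Great-circle distance between (lat, lon) points, R = 6371 km."""
    lat1, lon1 = np.radians(np.asarray(p1, dtype=float))
    lat2, lon2 = np.radians(np.asarray(p2, dtype=float))
    if abs(np.degrees(lat1)) > 90 or abs(np.degrees(lat2)) > 90:
        raise ValueError("latitude out of range")
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def classify_strategy(max_distance_km, liberty_days) -> str:
    """Partial-migration class from maximum displacement and time at liberty.

    ``unassigned`` when liberty <= 182 days or the distance is missing;
    otherwise short (< 50 km), intermediate (50-200 km) or long (> 200 km),
    with the boundary values 50 and 200 going to the lower category.
    """
    if max_distance_km is not None and not np.isnan(max_distance_km) and max_distance_km < 0:
        raise ValueError("distance must be nonnegative")
    if liberty_days is not None and not np.isnan(liberty_days) and liberty_days < 0:
        raise ValueError("liberty must be nonnegative")
    if (
        max_distance_km is None or liberty_days is None
        or np.isnan(max_distance_km) or np.isnan(liberty_days)
        or liberty_days <= MIN_LIBERTY_DAYS
    ):
        return "unassigned"
    if max_distance_km <= STRATEGY_SHORT_KM:
        return "short"
    if max_distance_km <= STRATEGY_LONG_KM:
        return "intermediate"
    return "long"


def max_distance_from_release(positions, release) -> float:
    """Straight-line (great-circle) distance from the release location to
    the farthest daily position.  ``positions`` is an iterable of (lat, lon)
    or a mode-positions structured array."""
    if hasattr(positions, "dtype") and positions.dtype.names:
        positions = np.column_stack([positions["lat"], positions["lon"]])
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("empty track")
    return max(haversine_km(release, p) for p in positions)


def assign_quarter(dates) -> np.ndarray:
    """Calendar quarter (1-4) of each date (Q1 = January-March)."""
    return pd.DatetimeIndex(dates).quarter.values


def quarterly_density(
    positions: pd.DataFrame,
    quarter: int,
    grid_lat: np.ndarray,
    grid_lon: np.ndarray,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Gaussian-kernel 2D density of the quarter's daily positions.

    ``positions`` needs ``date``, ``lat``, ``lon`` columns.  The surface is
    normalised to sum to 1 over the evaluation grid.  Daily positions are
    serially dependent, so this is a visualisation of space use rather than
    a probability model (carried as metadata by the caller).
    """
    q = assign_quarter(positions["date"])
    pts = positions.loc[q == quarter, ["lon", "lat"]].values
    if len(pts) < 10:
        raise ValueError(f"fewer than 10 positions in Q{quarter}")
    jitter = 1e-6 * np.random.default_rng(0).standard_normal(pts.shape)
    kde = stats.gaussian_kde((pts + jitter).T, bw_method=bandwidth or "silverman")
    lon_g, lat_g = np.meshgrid(grid_lon, grid_lat)
    dens = kde(np.vstack([lon_g.ravel(), lat_g.ravel()])).reshape(lat_g.shape)
    total = dens.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("evaluation grid does not resolve the density; refine it")
    return dens / total


def daily_metrics(archive: TagArchive) -> pd.DataFrame:
    """Per-day maximum depth, mean temperature and mean vertical speed.

    Vertical speed is the day's mean of |d depth| / dt over consecutive
    1-min samples (m/s).  Days with under 50% depth coverage are flagged.
    """
    depth = archive.depth
    temp = archive.data["temp_c"]
    day_key = depth.index.normalize()
    speed = depth.diff().abs() / 60.0  # m/s at 1-min sampling
    df = pd.DataFrame({
        "max_depth_m": depth.groupby(day_key).max(),
        "mean_temp_c": temp.groupby(day_key).mean(),
        "mean_vspeed_ms": speed.groupby(day_key).mean(),
        "coverage": depth.groupby(day_key).size() / 1440.0,
    })
    df["low_coverage"] = df["coverage"] < 0.5
    df.index.name = "date"
    return df


def spawning_candidates(
    track_positions,
    metrics: pd.DataFrame,
    env,
    temp_window_c: tuple[float, float] = SPAWNING_TEMP_C,
    vspeed_thresh_ms: float = SPAWNING_VSPEED_MS,
    quarters: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Flag days whose position, temperature and vertical activity are
    jointly compatible with spawning.

    A day is flagged when (a) the fish sits in the deepest quartile of the
    cells it visited, (b) the mean experienced temperature lies in the
    8.5-11 degC spawning window, and (c) mean vertical speed exceeds
    0.25 m/s; only days in the stated quarters (default Q1-Q2) are eligible.
    Missing temperature skips criterion (b) (noted in the output).
    """
    pos = pd.DataFrame(track_positions) if not isinstance(track_positions, pd.DataFrame) else track_positions
    metrics = metrics.reset_index()
    n = min(len(pos), len(metrics))
    pos, metrics = pos.iloc[:n], metrics.iloc[:n]
    dates = pd.DatetimeIndex(metrics["date"])
    visited_depths = env.bathy_m[pos["row"].values, pos["col"].values]
    deep_q = np.nanquantile(visited_depths, 0.75)

    in_quarter = np.isin(dates.quarter, quarters)
    deep = visited_depths >= deep_q
    temp = metrics["mean_temp_c"].values
    temp_missing = ~np.isfinite(temp)
    in_window = (temp >= temp_window_c[0]) & (temp <= temp_window_c[1])
    in_window = np.where(temp_missing, True, in_window)  # criterion skipped
    active = metrics["mean_vspeed_ms"].values > vspeed_thresh_ms

    flagged = in_quarter & deep & in_window & active
    return pd.DataFrame({
        "date": dates,
        "row": pos["row"].values,
        "col": pos["col"].values,
        "flagged": flagged,
        "deepest_quartile": deep,
        "temp_in_window": in_window,
        "temp_missing": temp_missing,
        "vspeed_above": active,
        "in_quarter_window": in_quarter,
    })


def summarize_population(table: pd.DataFrame) -> dict:
    """Counts, tallies and range statistics mirroring the published
    population summaries of the electronic-tag recovery table.

    Censored liberty values enter ranges/means at their stated bound and
    are counted in ``n_censored``.  Per-area maximum depth is reported both
    over all released fish and over "residents" (rows whose strategy
    annotation does not place the fish in another region).
    """
    if table.empty:
        raise ValueError("empty table")
    t = table
    areas = ["EC", "NS", "IS"]
    by_area = {a: t[t["release_area"] == a] for a in areas}

    fates = t["fate"].replace("", np.nan).dropna()
    strategy_counts = {
        a: by_area[a]["strategy"].replace("", np.nan).dropna().value_counts().to_dict()
        for a in areas
    }
    # "resident" = strategy annotation does not place the fish in another region
    dest = t["destination"].fillna("")
    resident = (dest == "") | (dest == t["release_area"])
    out = {
        "n_recovered": int(len(t)),
        "recovered_by_area": {a: int(len(by_area[a])) for a in areas},
        "fate_counts": fates.value_counts().to_dict(),
        "predated_by_area": {
            a: int((by_area[a]["fate"] == "Predated").sum()) for a in areas
        },
        "liberty_min": float(t["liberty_days"].min()),
        "liberty_max": float(t["liberty_days"].max()),
        "liberty_mean": float(t["liberty_days"].mean()),
        "liberty_sd": float(t["liberty_days"].std()),
        "n_censored": int(t["liberty_censored"].sum()),
        "distance_recovered_min": float(t["distance_recovered_km"].min()),
        "distance_recovered_max": float(t["distance_recovered_km"].max()),
        "distance_recovered_mean": float(t["distance_recovered_km"].mean()),
        "max_distance_by_area": {
            a: float(by_area[a]["max_distance_km"].max()) for a in areas
        },
        "strategy_counts": strategy_counts,
        "n_strategy_assigned_by_area": {
            a: int(by_area[a]["strategy"].ne("").sum()) for a in areas
        },
        "beach_pct_by_area": {
            a: 100.0 * (by_area[a]["recovery_method"] == "beached").mean() for a in areas
        },
        "max_depth_by_area": {
            a: float(by_area[a]["max_depth_m"].max()) for a in areas
        },
        "max_depth_resident_by_area": {
            a: float(by_area[a].loc[resident, "max_depth_m"].max()) for a in areas
        },
    }
    return out


def strategy_agreement(table: pd.DataFrame) -> pd.DataFrame:
    """Compare the distance-threshold strategy class with the printed label
    for every row carrying both; returns the disagreeing rows.

    The liberty gate is not applied here: the printed table itself labels
    two short-liberty fish, so agreement is defined on the distance
    thresholds alone.
    """
    rows = table[(table["strategy"] != "") & table["max_distance_km"].notna()]
    def dist_class(d):
        if d <= STRATEGY_SHORT_KM:
            return "short"
        if d <= STRATEGY_LONG_KM:
            return "intermediate"
        return "long"
    pred = rows["max_distance_km"].map(dist_class)
    return rows[pred != rows["strategy"]]


def track_to_geojson(positions, properties: dict | None = None) -> dict:
    """LineString geometry of a daily-position track for mapping.

    ``positions`` is a mode-positions structured array or an iterable of
    (lat, lon); coordinates are emitted (lon, lat) per GeoJSON convention.
    """
    if hasattr(positions, "dtype") and positions.dtype.names:
        coords = [[float(lon), float(lat)] for lat, lon in
                  zip(positions["lat"], positions["lon"])]
    else:
        coords = [[float(lon), float(lat)] for lat, lon in positions]
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": properties or {},
    }


def rolling_smoother(series: pd.Series, window_days: int = 15) -> pd.Series:
    """Plotting-only rolling-mean smoother for daily metric series."""
    return series.rolling(window_days, center=True, min_periods=1).mean()
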