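"""Synthetic fish tracks, tag archives and mortality/recovery events.

The generator realises the statistical structure the downstream analysis
assumes: a two-behaviour (resident/migratory) random walk on the grid,
diel vertical behaviour with seabed-resting intervals carrying the tidal
pressure signal of the occupied cell, temperature recorded at the
instantaneous depth, and post-event float-up with surface drift.

Conventions
-----------
Daily horizontal displacement is drawn from an isotropic Gaussian with
per-axis variance ``2 * D * dt`` (the Fokker-Planck spreading rate used by
the geolocation model), resampled until it lands on a sea cell.  "Day" is a
calendar day; within a day the fish occupies a single grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archive import Deployment, TagArchive
from .environment import M2_PERIOD_H, EnvironmentGrid

EVENT_KINDS = {"predation", "capture_discard", "premature_detachment", "fishery_recovery"}
RESIDENT, MIGRATORY = 0, 1

__all__ = ["TrueTrack", "EventSpec", "simulate_track", "record_tag", "inject_event"]


@dataclass
class TrueTrack:
    """Simulation ground truth: daily cells, behaviours and continuous
    positions (km east/north of the SW cell center)."""

    cells: np.ndarray       # (n_days, 2) int row/col
    behaviours: np.ndarray  # (n_days,) int, 0=resident 1=migratory
    positions_km: np.ndarray  # (n_days, 2) float (x_east, y_north)
    env: EnvironmentGrid

    @property
    def n_days(self) -> int:
        return len(self.behaviours)

    def latlon(self, day: int) -> tuple[float, float]:
        return self.env.cell_to_latlon(tuple(self.cells[day]))


@dataclass
class EventSpec:
    """A tag-ending event: what happened, when, and for how long."""

    kind: str
    event_day: int
    stomach_days: float | None = None
    drift_days: int = 0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if (self.stomach_days is not None) != (self.kind == "predation"):
            raise ValueError("stomach_days must be set iff kind is predation")
        if self.kind == "predation" and self.stomach_days <= 0:
            raise ValueError("stomach_days must be positive")
        if self.drift_days < 0:
            raise ValueError("drift_days must be nonnegative")


def _pos_to_cell(pos: np.ndarray, env: EnvironmentGrid) -> tuple[int, int]:
    cs = env.cell_size_km
    ny, nx = env.shape
    i = int(np.clip(np.round(pos[1] / cs), 0, ny - 1))
    j = int(np.clip(np.round(pos[0] / cs), 0, nx - 1))
    return i, j


def simulate_track(
    env: EnvironmentGrid,
    D_res: float,
    D_mig: float,
    switch_matrix: np.ndarray,
    n_days: int,
    release_cell: tuple[int, int],
    seed: int,
    start_behaviour: int = RESIDENT,
) -> TrueTrack:
    """Simulate a two-behaviour diffusive track on the sea cells of ``env``."""
    switch = np.asarray(switch_matrix, dtype=float)
    if switch.shape != (2, 2) or np.any(switch < 0):
        raise ValueError("switch_matrix must be a nonnegative 2x2 matrix")
    if np.any(switch.sum(axis=1) == 0):
        raise ValueError("degenerate switch_matrix: a row is all zero")
    if not np.allclose(switch.sum(axis=1), 1.0):
        raise ValueError("switch_matrix rows must sum to 1")
    if D_res > D_mig:
        raise ValueError("require D_res <= D_mig")
    if env.land[release_cell]:
        raise ValueError("release cell is on land")

    rng = np.random.default_rng(seed)
    cs = env.cell_size_km
    cells = np.empty((n_days, 2), dtype=int)
    behaviours = np.empty(n_days, dtype=int)
    positions = np.empty((n_days, 2), dtype=float)

    pos = np.array([release_cell[1] * cs, release_cell[0] * cs], dtype=float)
    b = int(start_behaviour)
    sd = {RESIDENT: np.sqrt(2.0 * D_res), MIGRATORY: np.sqrt(2.0 * D_mig)}
    xmax, ymax = (env.shape[1] - 1) * cs, (env.shape[0] - 1) * cs

    for d in range(n_days):
        cells[d] = _pos_to_cell(pos, env)
        behaviours[d] = b
        positions[d] = pos
        # next-day state: switch behaviour first, then displace
        b = int(rng.choice(2, p=switch[b]))
        for _ in range(200):
            cand = pos + rng.normal(0.0, sd[b], size=2)
            cand = np.clip(cand, [0.0, 0.0], [xmax, ymax])
            if not env.land[_pos_to_cell(cand, env)]:
                pos = cand
                break
        # if every candidate landed ashore, stay put
    return TrueTrack(cells=cells, behaviours=behaviours, positions_km=positions, env=env)


def _swim_depth(minutes: np.ndarray, bathy: float, period_min: float, phase: float) -> np.ndarray:
    """Smooth dive cycle between near-surface and near-seabed."""
    mid, amp = 0.5 * bathy, 0.45 * bathy
    return mid + amp * np.sin(2 * np.pi * minutes / period_min + phase)


def record_tag(
    track: TrueTrack,
    env: EnvironmentGrid,
    seed: int,
    release_date: str | pd.Timestamp = "2015-06-01",
    resting_fraction: float = 0.35,
    rest_window_h: float = 3.5,
    depth_noise_sd_m: float = 0.1,
    temp_noise_sd_c: float = 0.1,
    dive_period_min: float = 240.0,
    dive_period_by_day: np.ndarray | None = None,
    env_day0: int = 0,
    recovery_method: str = "fishery_rod",
) -> TagArchive:
    """Record a synthetic archive along ``track``: depth at 1-min and
    temperature at 10-min resolution.

    Each day contains at least one seabed-resting window (>= 3 h) during
    which recorded depth equals the occupied cell's seabed depth plus the
    M2 tidal elevation plus sensor noise; outside resting windows the fish
    performs dive cycles between near-surface and near-seabed.
    """
    if track.env.shape != env.shape:
        raise ValueError("track and environment grids do not match")
    rng = np.random.default_rng(seed)
    release_date = pd.Timestamp(release_date).normalize()
    n_days = track.n_days
    n_min = n_days * 1440
    minutes = np.arange(n_min)
    depth = np.empty(n_min)
    temp = np.full(n_min, np.nan)

    n_rest = max(1, int(round(resting_fraction * 24.0 / rest_window_h)))
    rest_len = int(round(rest_window_h * 60))

    for d in range(n_days):
        cell = tuple(track.cells[d])
        bathy = float(env.bathy_m[cell])
        day_min = np.arange(1440)
        sl = slice(d * 1440, (d + 1) * 1440)
        period = float(dive_period_by_day[d]) if dive_period_by_day is not None else dive_period_min
        dep = _swim_depth(day_min, bathy, period, phase=rng.uniform(0, 2 * np.pi))

        # resting windows: non-overlapping, seeded starts
        starts = np.sort(rng.choice(1440 - rest_len, size=n_rest, replace=False))
        prev_end = -rest_len
        t_hours_day0 = (env_day0 + d) * 24.0
        for s in starts:
            s = int(max(s, prev_end))
            if s + rest_len > 1440:
                break
            t_h = t_hours_day0 + (day_min[s : s + rest_len]) / 60.0
            dep[s : s + rest_len] = bathy + env.tide_elevation(cell, t_h)
            prev_end = s + rest_len

        dep = dep + rng.normal(0, depth_noise_sd_m, size=1440)
        depth[sl] = np.clip(dep, 0.0, None)

        # temperature at the instantaneous depth, every 10 min
        t_idx = day_min[::10]
        env_day = min(env_day0 + d, env.n_days - 1)
        tvals = env.temperature_at(env_day, cell, depth[sl][t_idx])
        temp[sl][t_idx] = tvals + rng.normal(0, temp_noise_sd_c, size=len(t_idx))

    index = release_date + pd.to_timedelta(minutes, unit="min")
    data = pd.DataFrame({"depth_m": depth, "temp_c": temp}, index=index)
    data.index.name = "timestamp"
    rel_lat, rel_lon = track.latlon(0)
    rec_lat, rec_lon = track.latlon(n_days - 1)
    dep_meta = Deployment(
        fish_id=f"SYN{seed:05d}",
        release_date=release_date,
        release_lat=rel_lat,
        release_lon=rel_lon,
        recovery_date=release_date + pd.Timedelta(days=n_days),
        recovery_lat=rec_lat,
        recovery_lon=rec_lon,
        recovery_method=recovery_method,
    )
    archive = TagArchive(dep_meta, data)
    archive.meta["env_day0"] = env_day0
    archive.meta["noise"] = {"depth_sd_m": depth_noise_sd_m, "temp_sd_c": temp_noise_sd_c}
    return archive


def _drift_cells(env: EnvironmentGrid, start_cell, n_days, speed_km_day, rng):
    """Post-mortem surface drift: random walk over sea cells."""
    cs = env.cell_size_km
    pos = np.array([start_cell[1] * cs, start_cell[0] * cs], dtype=float)
    xmax, ymax = (env.shape[1] - 1) * cs, (env.shape[0] - 1) * cs
    cells = []
    for _ in range(n_days):
        for _ in range(100):
            step = rng.normal(0.0, speed_km_day / np.sqrt(2), size=2)
            cand = np.clip(pos + step, [0.0, 0.0], [xmax, ymax])
            if not env.land[_pos_to_cell(cand, env)]:
                pos = cand
                break
        cells.append(_pos_to_cell(pos, env))
    return cells


def inject_event(
    archive: TagArchive,
    event: EventSpec,
    seed: int,
    env: EnvironmentGrid | None = None,
    track: TrueTrack | None = None,
    drift_speed_km_day: float = 15.0,
    event_hour: float = 10.0,
) -> TagArchive:
    """Overlay a tag-ending event on a recorded archive.

    All samples before the event are preserved exactly.  After the event the
    archive follows the event contract (predator stomach, air exposure, or
    immediate float-up) and ends at recovery.  Injected truth is stored in
    ``meta["event_truth"]`` for recovery tests.
    """
    n_days = len(archive.days)
    if not 0 <= event.event_day < n_days:
        raise ValueError("event_day outside archive span")
    rng = np.random.default_rng(seed)
    out = archive.copy()
    df = out.data
    noise = out.meta.get("noise", {"depth_sd_m": 0.1, "temp_sd_c": 0.1})
    d_sd, t_sd = noise["depth_sd_m"], noise["temp_sd_c"]

    t0 = df.index[0]
    ev_idx = event.event_day * 1440 + int(round(event_hour * 60))
    depth = df["depth_m"].values.copy()
    temp = df["temp_c"].values.copy()
    n_min_total = len(depth)

    if event.kind == "fishery_recovery":
        df = df.iloc[:ev_idx]
        out.data = df
        out.deployment.recovery_date = df.index[-1].normalize() + pd.Timedelta(days=1)
        out.meta["event_truth"] = {"kind": event.kind, "event_day": event.event_day,
                                   "floatup_day": None, "drift_days": 0}
        if track is not None:
            lat, lon = track.latlon(event.event_day)
            out.deployment.recovery_lat, out.deployment.recovery_lon = lat, lon
        return out

    if event.kind == "predation":
        stomach_min = int(round(event.stomach_days * 1440))
        float_idx = ev_idx + stomach_min
    elif event.kind == "capture_discard":
        # >= 8 degC air-exposure excursion lasting 30 min, then float-up
        air_len = 30
        base = np.nanmean(temp[max(0, ev_idx - 1440) : ev_idx])
        for k in range(ev_idx, min(ev_idx + air_len, n_min_total)):
            temp[k] = base + 10.0 + rng.normal(0, t_sd) if k % 10 == 0 else np.nan
        depth[ev_idx : ev_idx + air_len] = np.clip(
            rng.normal(0.3, d_sd, min(air_len, n_min_total - ev_idx)), 0.0, 0.9
        )
        float_idx = ev_idx + air_len
    else:  # premature_detachment
        float_idx = ev_idx

    if event.kind == "predation":
        # in-stomach phase: high temperature, frequent near-surface excursions
        sl = np.arange(ev_idx, min(float_idx, n_min_total))
        osc = 5.0 + 3.5 * np.sin(2 * np.pi * sl / 90.0)  # min 1.5 m: stays clear of the float-up depth band
        depth[sl] = np.clip(osc + rng.normal(0, d_sd, len(sl)), 0.0, None)
        sampled = ~np.isnan(temp[sl])
        temp[sl] = np.nan
        temp[sl[sampled]] = 36.5 + rng.normal(0, 0.3, int(sampled.sum()))

    # float phase: depth <= 1 m, temperature tracks SST of drifting cells
    float_day = min(float_idx // 1440, n_days - 1)
    end_day = float_day + event.drift_days
    end_idx = min((end_day + 1) * 1440, n_min_total)
    # extend the series if drift runs past the recorded span
    if (end_day + 1) * 1440 > n_min_total:
        extra = (end_day + 1) * 1440 - n_min_total
        depth = np.concatenate([depth, np.zeros(extra)])
        temp = np.concatenate([temp, np.full(extra, np.nan)])
        idx = t0 + pd.to_timedelta(np.arange(len(depth)), unit="min")
        end_idx = len(depth)
    else:
        idx = df.index
        depth = depth[:end_idx]
        temp = temp[:end_idx]
        idx = idx[:end_idx]

    fl = np.arange(float_idx, end_idx)
    depth[fl] = np.clip(rng.normal(0.4, min(d_sd, 0.15), len(fl)), 0.0, 0.95)
    start_cell = None
    if track is not None:
        start_cell = tuple(track.cells[min(float_day, track.n_days - 1)])
    if env is not None and start_cell is not None:
        cells = _drift_cells(env, start_cell, end_day - float_day + 1, drift_speed_km_day, rng)
        for k, cell in enumerate(cells):
            day = float_day + k
            day_sl = np.arange(max(day * 1440, float_idx), min((day + 1) * 1440, end_idx))
            sampled = day_sl[day_sl % 10 == 0]
            env_day = min(out.meta.get("env_day0", 0) + day, env.n_days - 1)
            temp[day_sl] = np.nan
            temp[sampled] = env.sst_c[env_day][cell] + rng.normal(0, t_sd, len(sampled))
        lat, lon = env.cell_to_latlon(cells[-1])
        out.deployment.recovery_lat, out.deployment.recovery_lon = lat, lon
        out.deployment.recovery_method = "beached"
    else:
        sampled = fl[fl % 10 == 0]
        base = np.nanmean(temp[:ev_idx][~np.isnan(temp[:ev_idx])][-144:]) if ev_idx else 12.0
        temp[fl] = np.nan
        temp[sampled] = base + rng.normal(0, t_sd, len(sampled))
        out.deployment.recovery_method = "beached"

    data = pd.DataFrame({"depth_m": depth, "temp_c": temp},
                        index=idx[: len(depth)])
    data.index.name = "timestamp"
    out.data = data
    out.deployment.recovery_date = data.index[-1].normalize() + pd.Timedelta(days=1)
    out.meta["event_truth"] = {
        "kind": event.kind,
        "event_day": event.event_day,
        "floatup_day": int(float_day),
        "drift_days": int(end_day - float_day),
        "stomach_days": event.stomach_days,
    }
    return out
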