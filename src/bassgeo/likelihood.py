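"""Daily observation likelihood surfaces for the geolocation HMM.

For each day at liberty the archive is summarised into a
:class:`DailyObservation` (maximum depth, tidal sinusoid fits from
seabed-resting windows, hourly temperature-at-depth samples) and converted
into a nonnegative weight surface over grid cells by combining:

1. a bathymetric mask — cells shallower than the maximum recorded depth
   (less a tolerance absorbing tidal range and sensor noise) are excluded;
2. a Gaussian tidal layer — cells whose M2 amplitude/phase match the fitted
   "wave" in the pressure record are up-weighted;
3. a Gaussian temperature layer — cells whose temperature at the sampled
   depths matches the recorded temperatures are up-weighted;
4. optional release/recovery anchors with confidence radii reflecting the
   recovery method (fishery < 5 km; beached > 200 km).

An all-zero product triggers a staged fallback (drop the tidal layer,
double the temperature width, relax the mask in 5 m steps) recorded in the
layer provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .archive import TagArchive
from .environment import M2_PERIOD_H, EnvironmentGrid

logger = logging.getLogger(__name__)

__all__ = [
    "TidalFit",
    "DailyObservation",
    "DailyLikelihood",
    "LikelihoodConfig",
    "detect_tidal_windows",
    "summarize_day",
    "bathymetry_mask",
    "tidal_likelihood",
    "temperature_likelihood",
    "endpoint_anchor",
    "build_daily_likelihood",
    "build_likelihood_stack",
]


@dataclass
class TidalFit:
    amplitude_m: float
    phase_rad: float  # in [0, 2*pi), same convention as the grid phase
    rmse_m: float
    start: pd.Timestamp | None = None
    n_min: int = 0


@dataclass
class DailyObservation:
    day: int
    max_depth_m: float | None
    tidal_fits: list[TidalFit] = field(default_factory=list)
    temp_samples: list[tuple[float, float]] = field(default_factory=list)  # (depth_m, temp_c)


@dataclass
class DailyLikelihood:
    day: int
    weights: np.ndarray  # (ny, nx), nonnegative, sums to 1
    layers: list[str] = field(default_factory=list)
    fallback: list[str] = field(default_factory=list)


@dataclass
class LikelihoodConfig:
    """Gaussian widths and mask tolerances (all config-exposed).

    The tidal phase width corresponds to a 30-minute timing error on the
    12.42 h constituent; the temperature width absorbs field error plus
    sensor error.  The mask tolerance absorbs the tidal range and sensor
    noise contained in the recorded maximum depth.
    """

    sigma_amp_m: float = 0.3
    sigma_phase_rad: float = 2 * np.pi * 0.5 / M2_PERIOD_H
    sigma_t_c: float = 0.7
    mask_tol_m: float = 5.0
    mask_relax_step_m: float = 5.0
    window_h: float = 3.0
    quiescence_sd_m: float = 0.3
    temp_thin_min: int = 60


def _fit_sinusoid(t_hours: np.ndarray, depth: np.ndarray) -> TidalFit:
    """Least-squares fit of ``c + a*cos(wt) + b*sin(wt)`` at the M2 period.

    Returns amplitude ``hypot(a, b)`` and phase such that the fitted signal
    is ``amp * cos(w t - phase)`` — directly comparable to the grid phase.
    """
    w = 2 * np.pi / M2_PERIOD_H
    X = np.column_stack([np.ones_like(t_hours), np.cos(w * t_hours), np.sin(w * t_hours)])
    coef, *_ = np.linalg.lstsq(X, depth, rcond=None)
    resid = depth - X @ coef
    amp = float(np.hypot(coef[1], coef[2]))
    phase = float(np.mod(np.arctan2(coef[2], coef[1]), 2 * np.pi))
    return TidalFit(amp, phase, rmse_m=float(np.sqrt(np.mean(resid**2))))


def detect_tidal_windows(
    depth: pd.Series,
    window_h: float = 3.0,
    quiescence_sd_m: float = 0.3,
    step_min: int = 30,
    t0: pd.Timestamp | None = None,
    env_day0: int = 0,
) -> list[TidalFit]:
    """Find seabed-resting windows carrying a clean M2 sinusoid.

    Slides a ``window_h``-hour window over the 1-min depth series; windows
    whose sinusoid-fit RMSE is at most ``quiescence_sd_m`` are accepted and
    overlapping accepted windows are merged and refitted.  Times are
    referenced to hours since the environment's day-0 midnight so that the
    fitted phase matches the grid convention.
    """
    if depth.empty:
        return []
    if t0 is None:
        t0 = depth.index[0].normalize()
    origin = t0 - pd.Timedelta(days=env_day0)
    t_hours = (depth.index - origin).total_seconds().values / 3600.0
    vals = depth.values
    n_win = int(window_h * 60)
    accepted: list[tuple[int, int]] = []
    for s in range(0, len(vals) - n_win + 1, step_min):
        seg = vals[s : s + n_win]
        if np.any(~np.isfinite(seg)):
            continue
        fit = _fit_sinusoid(t_hours[s : s + n_win], seg)
        if fit.rmse_m <= quiescence_sd_m:
            if accepted and s <= accepted[-1][1]:
                accepted[-1] = (accepted[-1][0], s + n_win)
            else:
                accepted.append((s, s + n_win))
    fits = []
    for s, e in accepted:
        fit = _fit_sinusoid(t_hours[s:e], vals[s:e])
        if fit.rmse_m <= quiescence_sd_m:
            fit.start = depth.index[s]
            fit.n_min = e - s
            fits.append(fit)
    return fits


def summarize_day(
    archive: TagArchive,
    day: int,
    config: LikelihoodConfig | None = None,
) -> DailyObservation:
    """Summarise one calendar day of an archive into the quantities the
    likelihood layers consume."""
    config = config or LikelihoodConfig()
    t0 = archive.data.index[0].normalize()
    date = t0 + pd.Timedelta(days=day)
    frame = archive.day_slice(date)
    if frame.empty:
        return DailyObservation(day=day, max_depth_m=None)
    depth = frame["depth_m"]
    env_day0 = archive.meta.get("env_day0", 0)
    fits = detect_tidal_windows(
        depth, config.window_h, config.quiescence_sd_m, t0=t0, env_day0=env_day0
    )
    temp = frame["temp_c"].dropna()
    # thin to limit within-day dependence double-counting
    temp = temp.resample(f"{config.temp_thin_min}min").first().dropna()
    samples = [(float(depth.asof(ts)), float(tv)) for ts, tv in temp.items()]
    return DailyObservation(
        day=day,
        max_depth_m=float(depth.max()),
        tidal_fits=fits,
        temp_samples=samples,
    )


def bathymetry_mask(
    obs: DailyObservation,
    env: EnvironmentGrid,
    tol_m: float = 5.0,
) -> np.ndarray:
    """Boolean mask of admissible cells: sea, and at least as deep as the
    maximum recorded depth less ``tol_m``.  If the constraint empties the
    mask it is relaxed in 5 m steps (logged)."""
    mask = env.sea.copy()
    if obs.max_depth_m is None:
        return mask
    need = obs.max_depth_m - tol_m
    cand = mask & (env.bathy_m >= need)
    while not cand.any():
        need -= 5.0
        logger.info("day %s: bathymetric mask empty, relaxing to %.1f m", obs.day, need)
        cand = mask & (env.bathy_m >= need)
        if need <= 0:
            return mask
    return cand


def tidal_likelihood(
    fits: TidalFit | list[TidalFit],
    env: EnvironmentGrid,
    sigma_amp_m: float = 0.3,
    sigma_phase_rad: float = 2 * np.pi * 0.5 / M2_PERIOD_H,
) -> np.ndarray:
    """Gaussian match of fitted tidal amplitude/phase to the grid fields;
    phase residuals are wrapped to [-pi, pi] and multiple fits multiply."""
    if sigma_amp_m <= 0 or sigma_phase_rad <= 0:
        raise ValueError("sigmas must be positive")
    if isinstance(fits, TidalFit):
        fits = [fits]
    log_w = np.zeros(env.shape)
    for fit in fits:
        damp = env.tide_amp_m - fit.amplitude_m
        dph = np.angle(np.exp(1j * (env.tide_phase_rad - fit.phase_rad)))
        log_w = log_w - 0.5 * (damp / sigma_amp_m) ** 2 - 0.5 * (dph / sigma_phase_rad) ** 2
    w = np.exp(log_w - log_w[env.sea].max())
    w[env.land] = 0.0
    return w


def temperature_likelihood(
    obs: DailyObservation,
    env: EnvironmentGrid,
    sigma_t_c: float = 0.7,
    env_day: int | None = None,
) -> np.ndarray:
    """Per-cell Gaussian product over (depth, temperature) samples.

    Cell temperature is interpolated between depth levels; samples deeper
    than a cell's seabed use the temperature at the seabed; samples
    shallower than 5 m match the SST field.
    """
    day = obs.day if env_day is None else env_day
    day = min(day, env.n_days - 1)
    if not obs.temp_samples:
        w = env.sea.astype(float)
        return w / w.sum()
    log_w = np.zeros(env.shape)
    levels = env.depth_levels_m
    profiles = env.tdep_c[day]  # (ny, nx, nlev)
    sst = env.sst_c[day]
    for depth_m, temp_c in obs.temp_samples:
        d = np.minimum(depth_m, env.bathy_m)
        d = np.where(env.sea, d, 0.0)
        upper = np.clip(np.searchsorted(levels, d, side="right") - 1, 0, len(levels) - 2)
        frac = np.clip((d - levels[upper]) / (levels[upper + 1] - levels[upper]), 0.0, 1.0)
        t_cell = np.take_along_axis(profiles, upper[..., None], axis=2)[..., 0] * (1 - frac)
        t_cell = t_cell + np.take_along_axis(profiles, (upper + 1)[..., None], axis=2)[..., 0] * frac
        t_cell = np.where(d < 5.0, sst, t_cell)
        log_w = log_w - 0.5 * ((temp_c - t_cell) / sigma_t_c) ** 2
    log_w = np.where(env.sea, log_w, -np.inf)
    w = np.exp(log_w - log_w[env.sea].max())
    w[~np.isfinite(w)] = 0.0
    return w


ANCHOR_SD_KM = {"release": 2.0, "fishery_recovery": 5.0, "beach_recovery": 200.0}


def endpoint_anchor(
    location: tuple[float, float],
    env: EnvironmentGrid,
    kind: str = "release",
) -> np.ndarray:
    """Gaussian bump at a known endpoint (lat, lon).

    Confidence radii: release ~ one cell; fishery recovery 5 km; beach
    recovery 200 km."""
    if kind not in ANCHOR_SD_KM:
        raise ValueError(f"unknown anchor kind {kind!r}")
    lat, lon = location
    if not env.contains(lat, lon, tol_cells=1.0) and kind != "beach_recovery":
        raise ValueError("anchor location off the grid")
    sd = ANCHOR_SD_KM[kind]
    coslat = np.cos(np.deg2rad(env.lat_centers.mean()))
    dy = (env.lat_centers[:, None] - lat) * 111.19
    dx = (env.lon_centers[None, :] - lon) * 111.19 * coslat
    w = np.exp(-0.5 * (dx**2 + dy**2) / sd**2)
    w[env.land] = 0.0
    return w


def build_daily_likelihood(
    obs: DailyObservation,
    env: EnvironmentGrid,
    anchors: list[np.ndarray] | None = None,
    config: LikelihoodConfig | None = None,
    env_day: int | None = None,
) -> DailyLikelihood:
    """Elementwise product of mask x tidal x temperature x anchor layers,
    renormalised to sum to 1, with a staged fallback on an empty product."""
    config = config or LikelihoodConfig()
    anchors = anchors or []

    def assemble(use_tidal: bool, sigma_t: float, mask_tol: float):
        layers = []
        mask = bathymetry_mask(obs, env, tol_m=mask_tol)
        if obs.max_depth_m is not None and not (
            env.sea & (env.bathy_m >= obs.max_depth_m - mask_tol)
        ).any():
            layers.append("bathymetry_mask(auto-relaxed)")
        w = mask.astype(float)
        layers.append("bathymetry_mask")
        if use_tidal and obs.tidal_fits:
            w = w * tidal_likelihood(obs.tidal_fits, env, config.sigma_amp_m, config.sigma_phase_rad)
            layers.append("tidal")
        if obs.temp_samples:
            w = w * temperature_likelihood(obs, env, sigma_t, env_day=env_day)
            layers.append("temperature")
        for a in anchors:
            w = w * a
            layers.append("anchor")
        return w, layers

    ladder = [
        ("", dict(use_tidal=True, sigma_t=config.sigma_t_c, mask_tol=config.mask_tol_m)),
        ("drop_tidal", dict(use_tidal=False, sigma_t=config.sigma_t_c, mask_tol=config.mask_tol_m)),
        ("widen_sigma_t", dict(use_tidal=False, sigma_t=2 * config.sigma_t_c, mask_tol=config.mask_tol_m)),
        ("relax_mask", dict(use_tidal=False, sigma_t=2 * config.sigma_t_c,
                            mask_tol=config.mask_tol_m + config.mask_relax_step_m)),
        ("relax_mask", dict(use_tidal=False, sigma_t=2 * config.sigma_t_c,
                            mask_tol=config.mask_tol_m + 2 * config.mask_relax_step_m)),
        ("uniform", None),
    ]
    fallback: list[str] = []
    for step, kw in ladder:
        if kw is None:
            w, layers = env.sea.astype(float), ["uniform"]
        else:
            w, layers = assemble(**kw)
        total = w.sum()
        if total > 0 and np.isfinite(total):
            if step:
                fallback.append(step)
                logger.info("day %s: likelihood fallback %s", obs.day, fallback)
            if "bathymetry_mask(auto-relaxed)" in layers:
                fallback.append("mask_auto_relaxed")
            return DailyLikelihood(day=obs.day, weights=w / total, layers=layers, fallback=fallback)
        fallback.append(step or "base_empty")
    raise RuntimeError("every sea cell is masked; inconsistent grid configuration")


def save_stack(stack: list[DailyLikelihood], env: EnvironmentGrid, path) -> None:
    """Persist a likelihood stack as a day x lat x lon array (NetCDF3)."""
    import xarray as xr

    arr = np.stack([dl.weights for dl in stack])
    ds = xr.Dataset(
        {"weights": (("day", "lat", "lon"), arr)},
        coords={"day": [dl.day for dl in stack],
                "lat": env.lat_centers, "lon": env.lon_centers},
    )
    ds.to_netcdf(path, engine="scipy")


def load_stack(path) -> np.ndarray:
    import xarray as xr

    return xr.load_dataset(path, engine="scipy")["weights"].values


def build_likelihood_stack(
    archive: TagArchive,
    env: EnvironmentGrid,
    config: LikelihoodConfig | None = None,
    last_day: int | None = None,
    release_anchor: bool = True,
    recovery_anchor: bool = True,
) -> list[DailyLikelihood]:
    """Per-day likelihoods for an archive, with endpoint anchors applied on
    the first and last day used for geolocation."""
    config = config or LikelihoodConfig()
    dep = archive.deployment
    env_day0 = archive.meta.get("env_day0", 0)
    n_days = len(archive.days) if last_day is None else last_day + 1
    out = []
    for day in range(n_days):
        obs = summarize_day(archive, day, config)
        anchors = []
        if day == 0 and release_anchor:
            anchors.append(endpoint_anchor((dep.release_lat, dep.release_lon), env, "release"))
        if day == n_days - 1 and recovery_anchor and dep.recovery_lat is not None:
            kind = "beach_recovery" if dep.recovery_method == "beached" else "fishery_recovery"
            anchors.append(endpoint_anchor((dep.recovery_lat, dep.recovery_lon), env, kind))
        out.append(build_daily_likelihood(obs, env, anchors, config, env_day=env_day0 + day))
    return out
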