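"""Gridded environmental fields used by the geolocation likelihoods.

An :class:`EnvironmentGrid` carries, on a regular ~5.2 km grid, the four
fields that the daily observation likelihoods are matched against:

* bathymetry (positive seabed depth, with land flagged),
* amplitude and phase of a single dominant semidiurnal tidal constituent
  (M2, period 12.42 h),
* daily sea-surface temperature, and
* daily temperature at a set of standard depth levels.

Synthetic grids generated by :func:`make_environment` emulate the broad
spatial structure of shelf-sea fields: depth increasing away from a coast,
tidal amplitude decaying offshore with phase propagating alongshore, and a
seasonally stratified water column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

M2_PERIOD_H = 12.42  # dominant semidiurnal constituent
KM_PER_DEG = 111.19  # 2*pi*6371/360

__all__ = ["EnvironmentGrid", "make_environment", "M2_PERIOD_H", "KM_PER_DEG"]


@dataclass
class EnvironmentGrid:
    """Regular grid of environmental fields (row-major from the SW corner).

    Arrays are indexed ``[row, col]`` = ``[lat, lon]``; daily fields carry a
    leading ``day`` axis and temperature-at-depth a trailing ``level`` axis.
    """

    cell_size_km: float
    lat_centers: np.ndarray  # (ny,)
    lon_centers: np.ndarray  # (nx,)
    bathy_m: np.ndarray      # (ny, nx), positive on sea, NaN on land
    tide_amp_m: np.ndarray   # (ny, nx)
    tide_phase_rad: np.ndarray  # (ny, nx), in [0, 2*pi)
    sst_c: np.ndarray        # (n_days, ny, nx)
    tdep_c: np.ndarray       # (n_days, ny, nx, n_levels)
    depth_levels_m: np.ndarray  # (n_levels,)
    land: np.ndarray = field(default=None)  # (ny, nx) bool

    def __post_init__(self) -> None:
        self.bathy_m = np.asarray(self.bathy_m, dtype=float)
        if self.land is None:
            self.land = ~np.isfinite(self.bathy_m)
        self.land = np.asarray(self.land, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        ny, nx = self.shape
        if self.lat_centers.shape != (ny,) or self.lon_centers.shape != (nx,):
            raise ValueError("coordinate arrays do not match grid shape")
        sea = self.sea
        if not np.all(self.bathy_m[sea] > 0):
            raise ValueError("bathymetry must be positive on sea cells")
        if np.any(self.tide_amp_m[sea] < 0):
            raise ValueError("tidal amplitude must be nonnegative")
        ph = self.tide_phase_rad[sea]
        if np.any(ph < 0) or np.any(ph >= 2 * np.pi):
            raise ValueError("tidal phase must lie in [0, 2*pi)")
        for name, arr in (("sst_c", self.sst_c), ("tdep_c", self.tdep_c)):
            if arr.shape[1:3] != (ny, nx):
                raise ValueError(f"{name} does not share the grid shape")
            if not np.all(np.isfinite(arr[:, sea])):
                raise ValueError(f"{name} must be finite on sea cells")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.bathy_m.shape

    @property
    def n_days(self) -> int:
        return self.sst_c.shape[0]

    @property
    def sea(self) -> np.ndarray:
        return ~self.land

    def cell_area_km2(self) -> float:
        return float(self.cell_size_km**2)

    def cell_to_latlon(self, cell: tuple[int, int]) -> tuple[float, float]:
        i, j = cell
        return float(self.lat_centers[i]), float(self.lon_centers[j])

    def latlon_to_cell(self, lat: float, lon: float) -> tuple[int, int]:
        i = int(np.argmin(np.abs(self.lat_centers - lat)))
        j = int(np.argmin(np.abs(self.lon_centers - lon)))
        return i, j

    def contains(self, lat: float, lon: float, tol_cells: float = 1.0) -> bool:
        dy = self.cell_size_km / KM_PER_DEG
        dx = dy / np.cos(np.deg2rad(self.lat_centers.mean()))
        return bool(
            self.lat_centers.min() - tol_cells * dy <= lat <= self.lat_centers.max() + tol_cells * dy
            and self.lon_centers.min() - tol_cells * dx <= lon <= self.lon_centers.max() + tol_cells * dx
        )

    # -- temperature lookup ----------------------------------------------
    def tide_elevation(self, cell: tuple[int, int], t_hours: np.ndarray) -> np.ndarray:
        """Sea-surface elevation (m) of the M2 signal at absolute hours."""
        amp = self.tide_amp_m[cell]
        phase = self.tide_phase_rad[cell]
        return amp * np.cos(2 * np.pi * np.asarray(t_hours, float) / M2_PERIOD_H - phase)

    def temperature_at(self, day: int, cell: tuple[int, int], depth_m: np.ndarray) -> np.ndarray:
        """Water temperature at given depths: SST above 5 m, interpolated
        temperature-at-depth below, clamped to the seabed."""
        depth = np.atleast_1d(np.asarray(depth_m, dtype=float))
        bathy = self.bathy_m[cell]
        d = np.minimum(depth, bathy)
        profile = self.tdep_c[day, cell[0], cell[1], :]
        temp = np.interp(d, self.depth_levels_m, profile)
        shallow = d < 5.0
        if np.any(shallow):
            temp = np.where(shallow, self.sst_c[day][cell], temp)
        return temp if np.ndim(depth_m) else float(temp[0])

    # -- persistence ------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "bathy_m": (("lat", "lon"), self.bathy_m),
                "tide_amp_m": (("lat", "lon"), self.tide_amp_m),
                "tide_phase_rad": (("lat", "lon"), self.tide_phase_rad),
                "sst_c": (("day", "lat", "lon"), self.sst_c),
                "tdep_c": (("day", "lat", "lon", "level"), self.tdep_c),
            },
            coords={
                "lat": self.lat_centers,
                "lon": self.lon_centers,
                "day": np.arange(self.n_days),
                "level": self.depth_levels_m,
            },
            attrs={"cell_size_km": self.cell_size_km},
        )

    def to_netcdf(self, path) -> None:
        # NetCDF3 via the scipy backend; land is encoded as NaN bathymetry
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvironmentGrid":
        ds = xr.load_dataset(path, engine="scipy")
        return cls(
            cell_size_km=float(ds.attrs["cell_size_km"]),
            lat_centers=ds["lat"].values,
            lon_centers=ds["lon"].values,
            bathy_m=ds["bathy_m"].values,
            tide_amp_m=ds["tide_amp_m"].values,
            tide_phase_rad=ds["tide_phase_rad"].values,
            sst_c=ds["sst_c"].values,
            tdep_c=ds["tdep_c"].values,
            depth_levels_m=ds["level"].values,
        )


def make_environment(
    ny: int = 30,
    nx: int = 30,
    n_days: int = 120,
    seed: int | None = None,
    bathymetry: str = "coastal_gradient",
    cell_size_km: float = 5.2,
    lat0: float = 51.0,
    lon0: float = 1.0,
    flat_depth_m: float = 40.0,
    min_depth_m: float = 5.0,
    max_depth_m: float = 120.0,
    depth_noise_m: float = 0.5,
    tide_amp_range_m: tuple[float, float] = (0.5, 3.0),
    tide_phase_span_rad: float = 1.5 * np.pi,
    sst_mean_c: float = 11.0,
    sst_seasonal_amp_c: float = 4.0,
    sst_lat_gradient_c: float = -2.5,
    sst_noise_c: float = 0.15,
    stratification_c: float = 3.0,
    depth_levels_m: np.ndarray | None = None,
    start_doy: int = 1,
) -> EnvironmentGrid:
    """Generate a synthetic :class:`EnvironmentGrid`.

    Parameters
    ----------
    bathymetry
        ``"flat"`` gives a constant ``flat_depth_m`` everywhere (all sea);
        ``"coastal_gradient"`` places a land "coast" along the southern row
        and increases depth monotonically with distance from it.
    sst_lat_gradient_c
        Total SST change (deg C) from the southern to the northern edge.
    stratification_c
        Maximum summer surface-to-bottom temperature difference (deg C);
        the column is fully mixed in winter.
    start_doy
        Day-of-year of day index 0, used for the seasonal cycle.
    """
    if ny < 3 or nx < 3:
        raise ValueError("grid dimensions must be at least 3x3")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)

    dlat = cell_size_km / KM_PER_DEG
    dlon = dlat / np.cos(np.deg2rad(lat0))
    lat_centers = lat0 + dlat * np.arange(ny)
    lon_centers = lon0 + dlon * np.arange(nx)

    rows = np.arange(ny)[:, None] * np.ones((1, nx))
    if bathymetry == "flat":
        bathy = np.full((ny, nx), float(flat_depth_m))
    elif bathymetry == "coastal_gradient":
        # coast along row 0 (land); depth increases monotonically northwards
        slope = (max_depth_m - min_depth_m) / max(ny - 1, 1)
        noise = rng.uniform(-0.4, 0.4, size=(ny, nx)) * min(depth_noise_m, 0.45 * slope)
        bathy = min_depth_m + slope * rows + noise
        bathy[0, :] = np.nan
    else:
        raise ValueError(f"unknown bathymetry style: {bathymetry!r}")

    frac_row = rows / max(ny - 1, 1)
    cols = np.arange(nx)[None, :] * np.ones((ny, 1))
    frac_col = cols / max(nx - 1, 1)
    amp = tide_amp_range_m[1] - (tide_amp_range_m[1] - tide_amp_range_m[0]) * frac_row
    amp = np.clip(amp + rng.normal(0, 0.02, size=amp.shape), 0.0, None)
    phase = np.mod(tide_phase_span_rad * frac_col + rng.normal(0, 0.01, size=amp.shape), 2 * np.pi)

    days = np.arange(n_days)
    doy = (start_doy + days) % 365.25
    seasonal = sst_seasonal_amp_c * np.sin(2 * np.pi * (doy - 120.0) / 365.25)
    lat_field = sst_lat_gradient_c * frac_row
    # day-to-day stochastic variability; a frozen spatial noise field would
    # make temperature-matching errors perfectly correlated across days
    daily_noise = rng.normal(0, sst_noise_c, size=(n_days, ny, nx)).astype(np.float32)
    sst = (sst_mean_c + seasonal[:, None, None] + lat_field[None, :, :] + daily_noise).astype(np.float32)

    if depth_levels_m is None:
        depth_levels_m = np.array([0.0, 10.0, 20.0, 30.0, 50.0, 75.0, 100.0, 150.0])
    depth_levels_m = np.asarray(depth_levels_m, dtype=float)
    # summer-only stratification: temperature non-increasing with depth
    season_w = np.clip(np.sin(2 * np.pi * (doy - 120.0) / 365.25), 0.0, 1.0)
    lvl = depth_levels_m / depth_levels_m.max()
    dT = stratification_c * season_w[:, None, None, None] * lvl[None, None, None, :]
    tdep = (sst[:, :, :, None] - dT).astype(np.float32)

    land = ~np.isfinite(bathy)
    bathy_filled = bathy.copy()
    sst[:, land] = np.nan
    tdep[:, land, :] = np.nan

    return EnvironmentGrid(
        cell_size_km=cell_size_km,
        lat_centers=lat_centers,
        lon_centers=lon_centers,
        bathy_m=bathy_filled,
        tide_amp_m=amp,
        tide_phase_rad=phase,
        sst_c=sst,
        tdep_c=tdep,
        depth_levels_m=depth_levels_m,
    )
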