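"""Tag archives: depth/temperature time series plus deployment metadata.

Archives are stored as a single delimited text table with one row per
1-minute depth sample; temperature (sampled every 10 minutes) is blank on
non-sampled minutes.  A small ``# key: value`` header carries the
deployment metadata.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECOVERY_METHODS = {
    "beached",
    "fishery_net",
    "fishery_rod",
    "fishery_trawl",
    "fishery_longline",
    "market",
    "unknown",
}

__all__ = ["Deployment", "TagArchive", "read_tag_archive", "write_tag_archive"]


@dataclass
class Deployment:
    """Release/recovery metadata for one tagged fish."""

    fish_id: str
    release_date: pd.Timestamp
    release_lat: float
    release_lon: float
    recovery_date: pd.Timestamp | None = None
    recovery_lat: float | None = None
    recovery_lon: float | None = None
    recovery_method: str = "unknown"
    length_cm: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        self.release_date = pd.Timestamp(self.release_date)
        if self.recovery_date is not None:
            self.recovery_date = pd.Timestamp(self.recovery_date)
            if not self.release_date < self.recovery_date:
                raise ValueError("release date must precede recovery date")
        if self.recovery_method not in RECOVERY_METHODS:
            raise ValueError(f"unknown recovery method {self.recovery_method!r}")


@dataclass
class TagArchive:
    """One fish's archive: a 1-min depth series and a 10-min temperature
    series on a shared minute-resolution time base."""

    deployment: Deployment
    data: pd.DataFrame  # index: UTC DatetimeIndex @ 1 min; columns depth_m, temp_c
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if (self.data["depth_m"].dropna() < -1e-9).any():
            bad = int(np.argmax(self.data["depth_m"].values < -1e-9))
            raise ValueError(f"negative depth at row {bad}")

    @property
    def depth(self) -> pd.Series:
        return self.data["depth_m"]

    @property
    def temperature(self) -> pd.Series:
        return self.data["temp_c"].dropna()

    @property
    def days(self) -> pd.DatetimeIndex:
        return self.data.index.normalize().unique()

    def day_slice(self, day) -> pd.DataFrame:
        day = pd.Timestamp(day).normalize()
        return self.data.loc[day : day + pd.Timedelta(days=1) - pd.Timedelta(minutes=1)]

    def day_index(self, ts) -> int:
        """Days elapsed since the first archive day (calendar days)."""
        t0 = self.data.index[0].normalize()
        return int((pd.Timestamp(ts).normalize() - t0).days)

    def sampling_intervals(self) -> dict:
        depth_dt = np.median(np.diff(self.data.index.asi8)) / 60e9
        tidx = self.data["temp_c"].dropna().index
        temp_dt = float(np.median(np.diff(tidx.asi8)) / 60e9) if len(tidx) > 1 else np.nan
        return {"depth_min": float(depth_dt), "temp_min": temp_dt}

    def copy(self) -> "TagArchive":
        return TagArchive(self.deployment, self.data.copy(), dict(self.meta))


def write_tag_archive(archive: TagArchive, path) -> None:
    buf = io.StringIO()
    d = asdict(archive.deployment)
    for key, value in d.items():
        if value is not None:
            buf.write(f"# {key}: {value}\n")
    df = archive.data.reset_index()
    df.columns = ["timestamp", "depth_m", "temp_c"]
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(buf, index=False, float_format="%.4f")
    Path(path).write_text(buf.getvalue())


def read_tag_archive(path) -> TagArchive:
    """Read a delimited-text archive; rows are sorted into time order (a
    reordering is logged) and sampling-interval metadata is attached."""
    path = Path(path)
    header: dict[str, str] = {}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition(":")
        header[key.strip()] = value.strip()
        n_header += 1
    body = "\n".join(lines[n_header:])
    df = pd.read_csv(io.StringIO(body))
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601").dt.tz_localize(None)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"malformed timestamp column in {path}: {exc}") from None
    df = df.drop(columns="timestamp").set_index(ts.rename("timestamp"))
    if not df.index.is_monotonic_increasing:
        logger.warning("archive %s rows out of order; sorting", path)
        df = df.sort_index()
    neg = df["depth_m"] < -1e-9
    if neg.any():
        raise ValueError(f"negative depth at row {int(np.argmax(neg.values))} of {path}")

    dep = Deployment(
        fish_id=header.get("fish_id", path.stem),
        release_date=header.get("release_date", df.index[0]),
        release_lat=float(header.get("release_lat", "nan")),
        release_lon=float(header.get("release_lon", "nan")),
        recovery_date=header.get("recovery_date") or None,
        recovery_lat=float(header["recovery_lat"]) if "recovery_lat" in header else None,
        recovery_lon=float(header["recovery_lon"]) if "recovery_lon" in header else None,
        recovery_method=header.get("recovery_method", "unknown"),
        length_cm=float(header["length_cm"]) if "length_cm" in header else None,
        sex=header.get("sex") or None,
    )
    archive = TagArchive(dep, df)
    archive.meta["sampling_intervals"] = archive.sampling_intervals()
    return archive
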