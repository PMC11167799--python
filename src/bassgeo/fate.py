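"""Tag-fate classification from depth/temperature archives.

Beached tags are classified by when they started floating and by the
behaviour recorded before float-up:

* **predation** — a pre-float window combining temperatures above 35 degC
  (mammalian stomach) with frequent near-surface depths; the duration of the
  supra-threshold span is reported as days in the predator's stomach;
* **capture and discard** — an air-exposure temperature excursion on the
  day the tag started floating;
* **premature detachment** — float-up with neither signature; evidence is
  reported as z-scores of the final week's seabed/surface time fractions
  against a "typical behaviour" baseline pooled over reference archives.

``FateClassifier`` follows the scikit-learn estimator protocol: ``fit`` on a
reference population of archives builds the baseline, ``predict`` labels new
archives, and ``report`` returns the full :class:`FateReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .archive import TagArchive

__all__ = [
    "FateReport",
    "BehaviourProfile",
    "behaviour_profile",
    "detect_floatup",
    "FateClassifier",
    "classify_fate",
]


@dataclass
class BehaviourProfile:
    """Per-day time fractions near the seabed and near the surface."""

    days: pd.DatetimeIndex
    seabed_fraction: np.ndarray   # within 20% of the day's maximum depth
    surface_fraction: np.ndarray  # within 5 m of the surface
    low_coverage: np.ndarray      # day has < 50% of expected samples

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seabed_fraction": self.seabed_fraction,
                "surface_fraction": self.surface_fraction,
                "low_coverage": self.low_coverage,
            },
            index=self.days,
        )


@dataclass
class FateReport:
    fish_id: str
    fate: str                     # predated | caught_discarded | premature_detachment | fishery | unknown
    floatup_day: int | None
    event_day: int | None
    drift_days: int | None
    stomach_days: float | None = None
    evidence: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def behaviour_profile(
    archive: TagArchive,
    seabed_tol: float = 0.2,
    surface_m: float = 5.0,
    depth_max_mode: str = "daily",
) -> BehaviourProfile:
    """Daily proportions of time near the assumed seabed (within
    ``seabed_tol`` of the maximum depth) and within ``surface_m`` of the
    surface, at native 1-min resolution.

    ``depth_max_mode`` selects the reference maximum: the day's own maximum
    (``"daily"``, the default, since the quantity is a daily proportion) or
    the deployment maximum (``"deployment"``).
    """
    depth = archive.depth
    if len(depth) < 1:
        raise ValueError("archive has no depth data")
    by_day = depth.groupby(depth.index.normalize())
    days = pd.DatetimeIndex(list(by_day.groups))
    dep_max = float(depth.max())
    seabed, surface, lowcov = [], [], []
    for _, series in by_day:
        ref = dep_max if depth_max_mode == "deployment" else float(series.max())
        n = len(series)
        seabed.append(float((series >= (1 - seabed_tol) * ref).sum() / n))
        surface.append(float((series <= surface_m).sum() / n))
        lowcov.append(n < 720)
    return BehaviourProfile(days, np.asarray(seabed), np.asarray(surface), np.asarray(lowcov))


def _terminal_surface_start(archive: TagArchive, depth_tol_m: float):
    """Index of the first sample of the terminal at-surface run, or None."""
    depth = archive.depth.values
    if len(depth) == 0:
        raise ValueError("archive is empty")
    deep = depth > depth_tol_m
    if not deep.any():
        return 0
    return int(np.flatnonzero(deep)[-1]) + 1


def detect_floatup(
    archive: TagArchive,
    depth_tol_m: float = 1.0,
    min_hours: float = 24.0,
) -> tuple[int | None, list[str]]:
    """Day index from which depth stays <= ``depth_tol_m`` until the series
    end for at least ``min_hours``; ``None`` if the fish was recovered at
    depth (fishery capture).  Returns ``(floatup_day, warnings)``."""
    warnings: list[str] = []
    start = _terminal_surface_start(archive, depth_tol_m)
    if start == 0 and not (archive.depth.values > depth_tol_m).any():
        warnings.append("never attached: whole archive at the surface")
        return 0, warnings
    n_float = len(archive.depth) - start
    if n_float < min_hours * 60:
        return None, warnings
    return archive.day_index(archive.data.index[start]), warnings


def _daily_temp_range(archive: TagArchive) -> pd.Series:
    temp = archive.temperature
    if temp.empty:
        return pd.Series(dtype=float)
    grouped = temp.groupby(temp.index.normalize())
    return grouped.max() - grouped.min()


class FateClassifier(BaseEstimator):
    """Classify archive fate against a typical-behaviour baseline.

    Parameters
    ----------
    temp_thresh_c : float
        Predator stomach temperature threshold (degC).
    air_margin_c : float
        Air-exposure margin: the float-day temperature range must exceed the
        archive's own high daily ranges by this many degC.
    min_spike_min : int
        Supra-threshold temperature spans shorter than this are ignored as
        sensor spikes.
    surface_quantile : float
        Predation additionally requires the pre-float surface fraction to
        exceed this baseline quantile.
    """

    def __init__(
        self,
        temp_thresh_c: float = 35.0,
        depth_tol_m: float = 1.0,
        min_hours: float = 24.0,
        air_margin_c: float = 8.0,
        min_spike_min: int = 30,
        surface_quantile: float = 0.95,
        z_thresh: float = 2.0,
    ):
        self.temp_thresh_c = temp_thresh_c
        self.depth_tol_m = depth_tol_m
        self.min_hours = min_hours
        self.air_margin_c = air_margin_c
        self.min_spike_min = min_spike_min
        self.surface_quantile = surface_quantile
        self.z_thresh = z_thresh

    # -- baseline -----------------------------------------------------------
    def fit(self, X, y=None):
        """Pool per-day seabed/surface fractions over reference archives."""
        seabed, surface = [], []
        for archive in X:
            prof = behaviour_profile(archive)
            ok = ~prof.low_coverage
            seabed.append(prof.seabed_fraction[ok])
            surface.append(prof.surface_fraction[ok])
        seabed = np.concatenate(seabed) if seabed else np.array([0.0])
        surface = np.concatenate(surface) if surface else np.array([0.0])
        self.baseline_ = {
            "seabed_mean": float(seabed.mean()),
            "seabed_sd": float(seabed.std() or 1e-6),
            "surface_mean": float(surface.mean()),
            "surface_sd": float(surface.std() or 1e-6),
            "surface_q": float(np.quantile(surface, self.surface_quantile)),
        }
        return self

    # -- classification -----------------------------------------------------
    def report(self, archive: TagArchive) -> FateReport:
        if not hasattr(self, "baseline_"):
            raise RuntimeError("fit the classifier on reference archives first")
        floatup_day, warns = detect_floatup(archive, self.depth_tol_m, self.min_hours)
        fish_id = archive.deployment.fish_id
        n_days = len(archive.days)
        if floatup_day is None:
            return FateReport(fish_id, "fishery", None, None, None, warnings=warns)

        drift_days = (n_days - 1) - floatup_day
        temp = archive.temperature
        if temp.empty:
            warns.append("missing temperature channel; label limited to float timing")
            return FateReport(fish_id, "unknown", floatup_day, None, drift_days, warnings=warns)

        t0 = archive.data.index[0].normalize()
        float_start = archive.data.index[_terminal_surface_start(archive, self.depth_tol_m)]
        pre = temp[temp.index < float_start]
        prof = behaviour_profile(archive)
        evidence = {"max_temp_c": float(temp.max())}

        # A: predation — sustained supra-threshold temperature before float-up
        stomach = self._stomach_span(pre)
        if stomach is not None:
            span_days, span_start = stomach
            surf = prof.surface_fraction[: floatup_day + 1]
            evidence["surface_fraction_before_float"] = float(surf.max() if len(surf) else 0.0)
            if evidence["surface_fraction_before_float"] >= self.baseline_["surface_q"]:
                event_day = archive.day_index(span_start)
                return FateReport(
                    fish_id, "predated", floatup_day, event_day, drift_days,
                    stomach_days=span_days, evidence=evidence, warnings=warns,
                )

        # B: capture & discard — air exposure on the float-start day
        ranges = _daily_temp_range(archive)
        float_date = t0 + pd.Timedelta(days=floatup_day)
        day_range = float(ranges.get(float_date, np.nan))
        typical = float(ranges.drop(float_date, errors="ignore").quantile(0.99)) if len(ranges) > 1 else 0.0
        evidence["air_exposure_range_c"] = day_range
        if np.isfinite(day_range) and day_range >= typical + self.air_margin_c:
            return FateReport(
                fish_id, "caught_discarded", floatup_day, floatup_day, drift_days,
                evidence=evidence, warnings=warns,
            )

        # C: premature detachment — z-scores of the final pre-float week
        week = slice(max(0, floatup_day - 7), max(floatup_day, 1))
        b = self.baseline_
        evidence["seabed_fraction_before_float"] = float(np.mean(prof.seabed_fraction[week]))
        evidence["surface_fraction_before_float"] = float(np.mean(prof.surface_fraction[week]))
        evidence["seabed_z"] = (evidence["seabed_fraction_before_float"] - b["seabed_mean"]) / b["seabed_sd"]
        evidence["surface_z"] = (evidence["surface_fraction_before_float"] - b["surface_mean"]) / b["surface_sd"]
        evidence["atypical_final_week"] = bool(
            abs(evidence["seabed_z"]) > self.z_thresh or abs(evidence["surface_z"]) > self.z_thresh
        )
        return FateReport(
            fish_id, "premature_detachment", floatup_day, floatup_day, drift_days,
            evidence=evidence, warnings=warns,
        )

    def _stomach_span(self, temp: pd.Series) -> tuple[float, pd.Timestamp] | None:
        """Duration (days) and start of the supra-threshold temperature span,
        ignoring spikes shorter than ``min_spike_min`` minutes."""
        hot = temp[temp > self.temp_thresh_c]
        if hot.empty:
            return None
        idx = hot.index
        gaps = np.flatnonzero(np.diff(idx.asi8) > 60 * 60e9)  # >1 h gap splits spans
        starts = np.r_[0, gaps + 1]
        ends = np.r_[gaps, len(idx) - 1]
        best = None
        for s, e in zip(starts, ends):
            dur_min = (idx[e] - idx[s]).total_seconds() / 60 + 10  # inclusive of last sample
            if dur_min >= self.min_spike_min and (best is None or dur_min > best[0] * 1440):
                best = (dur_min / 1440.0, idx[s])
        return best

    def predict(self, X) -> np.ndarray:
        return np.array([self.report(a).fate for a in X])


def classify_fate(
    archive: TagArchive,
    profile_baseline,
    temp_thresh_c: float = 35.0,
    **kwargs,
) -> FateReport:
    """Classify one archive.  ``profile_baseline`` is either a fitted
    :class:`FateClassifier` or a list of reference archives to fit on."""
    if isinstance(profile_baseline, FateClassifier):
        clf = profile_baseline
    else:
        clf = FateClassifier(temp_thresh_c=temp_thresh_c, **kwargs).fit(profile_baseline)
    return clf.report(archive)
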