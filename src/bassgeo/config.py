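"""Run configuration: thresholds, sigmas, grid spec and seeds.

Every biological threshold defaults to the published value (35 degC
predator stomach; 20% of daily maximum depth and 5 m surface bands;
50/200 km strategy thresholds at > 182 days liberty; 8.5-11 degC spawning
window; 0.25 m/s vertical-speed flag); the Gaussian likelihood widths are
package choices exposed here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .likelihood import LikelihoodConfig


@dataclass
class GridSpec:
    ny: int = 30
    nx: int = 30
    n_days: int = 120
    cell_size_km: float = 5.2
    bathymetry: str = "coastal_gradient"


@dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    n_fish: int = 3
    n_days: int = 90
    grid: GridSpec = field(default_factory=GridSpec)
    D_res: float = 5.0
    D_mig: float = 120.0
    p_stay: float = 0.9
    estimate: bool = False
    n_starts: int = 3
    maxfev: int = 150
    likelihood: LikelihoodConfig = field(default_factory=LikelihoodConfig)
    temp_thresh_c: float = 35.0
    seabed_tol: float = 0.2
    surface_m: float = 5.0
    strategy_short_km: float = 50.0
    strategy_long_km: float = 200.0
    min_liberty_days: int = 182
    spawning_temp_c: tuple = (8.5, 11.0)
    spawning_vspeed_ms: float = 0.25
    events: list = field(default_factory=list)  # per-fish event dicts or None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "grid" in raw and isinstance(raw["grid"], dict):
            raw = dict(raw)
            raw["grid"] = GridSpec(**raw["grid"])
        if "likelihood" in raw and isinstance(raw["likelihood"], dict):
            raw["likelihood"] = LikelihoodConfig(**raw["likelihood"])
        return cls(**raw)
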