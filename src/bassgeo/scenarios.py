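"""Standard synthetic study scenarios.

These fix the conditions under which the package validates itself:

* ``parameter_recovery`` — 20 fish, 300 days each, truth
  ``(D_res, D_mig) = (5, 120)`` km^2/day on a 60x60 coastal grid with tidal
  and temperature likelihood layers; diffusivities are re-estimated per
  fish.
* ``seasonal_migration`` — one fish on a 60x60 grid at 5.2 km for 180 days
  performing a scripted seasonal offshore migration (nearshore residency,
  offshore winter residency, return), used to score daily mode-position
  error against the known track.
* ``fate_batch`` — archives with separable predation / capture-discard /
  premature-detachment signatures plus injected drift, used to score fate
  classification against injected truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .archive import TagArchive
from .environment import EnvironmentGrid, make_environment
from .hmm import BehaviourModel
from .likelihood import LikelihoodConfig, build_likelihood_stack
from .simulate import (
    EventSpec,
    TrueTrack,
    _pos_to_cell,
    inject_event,
    record_tag,
    simulate_track,
)

TRUTH_D_RES = 5.0
TRUTH_D_MIG = 120.0
TRUTH_STAY = 0.9

__all__ = [
    "TRUTH_D_RES",
    "TRUTH_D_MIG",
    "parameter_recovery_env",
    "parameter_recovery_fish",
    "seasonal_migration_scenario",
    "fate_batch",
]


def parameter_recovery_env(seed: int, n_days: int = 320) -> EnvironmentGrid:
    return make_environment(60, 60, n_days=n_days, seed=seed)


def parameter_recovery_fish(env: EnvironmentGrid, seed: int, n_days: int = 300):
    """One simulated fish under the recovery-study truth; returns
    ``(track, archive, likelihood_stack)``."""
    switch = np.array([[TRUTH_STAY, 1 - TRUTH_STAY], [1 - TRUTH_STAY, TRUTH_STAY]])
    track = simulate_track(env, TRUTH_D_RES, TRUTH_D_MIG, switch, n_days,
                           (env.shape[0] // 2, env.shape[1] // 2), seed=seed)
    archive = record_tag(track, env, seed=seed)
    stack = build_likelihood_stack(archive, env)
    return track, archive, stack


def _scripted_seasonal_track(env: EnvironmentGrid, seed: int, n_days: int = 180) -> TrueTrack:
    """Nearshore residency -> offshore migration -> offshore residency ->
    return migration, with diffusive jitter around the script."""
    rng = np.random.default_rng(seed)
    cs = env.cell_size_km
    ny, nx = env.shape
    home = np.array([(nx // 2) * cs, 6 * cs])       # nearshore (shallow rows)
    winter = np.array([(nx // 2 + 8) * cs, (ny - 8) * cs])  # offshore, deep
    phases = [
        (0, 60, home, TRUTH_D_RES, 0),
        (60, 85, winter, TRUTH_D_MIG, 1),
        (85, 150, winter, TRUTH_D_RES, 0),
        (150, 175, home, TRUTH_D_MIG, 1),
        (175, n_days, home, TRUTH_D_RES, 0),
    ]
    cells = np.empty((n_days, 2), int)
    behaviours = np.empty(n_days, int)
    positions = np.empty((n_days, 2))
    pos = home.copy()
    xmax, ymax = (nx - 1) * cs, (ny - 1) * cs
    for start, end, target, D, beh in phases:
        for d in range(start, min(end, n_days)):
            cells[d] = _pos_to_cell(pos, env)
            behaviours[d] = beh
            positions[d] = pos
            drift = np.zeros(2)
            if beh == 1:
                gap = target - pos
                dist = np.hypot(*gap)
                if dist > 1e-9:
                    step = min(dist, np.sqrt(2 * D))
                    drift = gap / dist * step
            for _ in range(100):
                cand = pos + drift + rng.normal(0, np.sqrt(2 * TRUTH_D_RES), 2)
                cand = np.clip(cand, [0, 0], [xmax, ymax])
                if not env.land[_pos_to_cell(cand, env)]:
                    pos = cand
                    break
    return TrueTrack(cells=cells, behaviours=behaviours, positions_km=positions, env=env)


def seasonal_migration_scenario(seed: int, n_days: int = 180):
    """Standard track-recovery scenario; returns
    ``(env, track, archive, stack, uniform_stack)`` where ``uniform_stack``
    keeps only the endpoint anchors (the prior-only control)."""
    env = make_environment(60, 60, n_days=n_days + 20, seed=seed + 500)
    track = _scripted_seasonal_track(env, seed, n_days)
    archive = record_tag(track, env, seed=seed, recovery_method="fishery_rod")
    stack = build_likelihood_stack(archive, env)
    weights = np.stack([dl.weights for dl in stack])
    # prior-only control: uniform daily surfaces, endpoint anchors kept
    from .likelihood import endpoint_anchor

    dep = archive.deployment
    uniform = env.sea.astype(float) / env.sea.sum()
    control = np.broadcast_to(uniform, (n_days,) + env.shape).copy()
    rel = uniform * endpoint_anchor((dep.release_lat, dep.release_lon), env, "release")
    rec = uniform * endpoint_anchor((dep.recovery_lat, dep.recovery_lon), env, "fishery_recovery")
    control[0] = rel / rel.sum()
    control[-1] = rec / rec.sum()
    return env, track, archive, weights, control


@dataclass
class FateTruth:
    archive: TagArchive
    kind: str
    event_day: int
    floatup_day: int | None
    drift_days: int
    stomach_days: float | None


def fate_batch(n: int, seed: int, env: EnvironmentGrid | None = None):
    """Generate ``n`` archives with separable event parameters, balanced
    across predation, capture-discard and premature detachment (plus a few
    fishery recoveries), with injected truth attached."""
    rng = np.random.default_rng(seed)
    if env is None:
        env = make_environment(20, 20, n_days=80, seed=seed + 1, bathymetry="flat")
    switch = np.array([[0.95, 0.05], [0.05, 0.95]])
    kinds = ["predation", "capture_discard", "premature_detachment", "fishery_recovery"]
    out: list[FateTruth] = []
    for k in range(n):
        kind = kinds[k % 3] if k % 10 != 9 else "fishery_recovery"
        fish_seed = seed + 100 + k
        track = simulate_track(env, 3.0, 30.0, switch, 40, (10, 10), seed=fish_seed)
        archive = record_tag(track, env, seed=fish_seed)
        event_day = int(rng.integers(12, 30))
        if kind == "predation":
            stomach = float(np.round(rng.uniform(0.5, 3.0), 2))
            spec = EventSpec(kind, event_day, stomach_days=stomach,
                             drift_days=int(rng.integers(1, 5)))
        elif kind == "fishery_recovery":
            spec = EventSpec(kind, event_day)
        else:
            spec = EventSpec(kind, event_day, drift_days=int(rng.integers(1, 5)))
        archive = inject_event(archive, spec, seed=fish_seed + 5000, env=env, track=track)
        truth = archive.meta["event_truth"]
        out.append(FateTruth(
            archive=archive, kind=kind, event_day=truth["event_day"],
            floatup_day=truth["floatup_day"], drift_days=truth["drift_days"],
            stomach_days=truth.get("stomach_days"),
        ))
    return out


def reference_archives(seed: int, n: int = 4, env: EnvironmentGrid | None = None):
    """Clean (event-free) archives for fitting the fate baseline."""
    if env is None:
        env = make_environment(20, 20, n_days=80, seed=seed + 1, bathymetry="flat")
    switch = np.array([[0.95, 0.05], [0.05, 0.95]])
    return [
        record_tag(simulate_track(env, 3.0, 30.0, switch, 40, (10, 10), seed=seed + 50 + i),
                   env, seed=seed + 50 + i)
        for i in range(n)
    ]
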