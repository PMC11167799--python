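import numpy as np
import pandas as pd
import pytest

from bassgeo.environment import M2_PERIOD_H, make_environment
from bassgeo.likelihood import (
    DailyObservation,
    LikelihoodConfig,
    TidalFit,
    bathymetry_mask,
    build_daily_likelihood,
    build_likelihood_stack,
    detect_tidal_windows,
    endpoint_anchor,
    summarize_day,
    temperature_likelihood,
    tidal_likelihood,
)


def _sinusoid_series(amp, phase, hours=4.0, noise_sd=0.0, seed=0, offset=40.0):
    n = int(hours * 60)
    idx = pd.date_range("2020-01-01", periods=n, freq="min")
    t_h = np.arange(n) / 60.0
    rng = np.random.default_rng(seed)
    depth = offset + amp * np.cos(2 * np.pi * t_h / M2_PERIOD_H - phase)
    return pd.Series(depth + rng.normal(0, noise_sd, n), index=idx)


def _grid_search_fit(series, t0):
    """Independent exhaustive amplitude/phase grid search at the M2 period."""
    t_h = (series.index - t0).total_seconds().values / 3600.0
    best = (np.inf, None, None)
    for amp in np.arange(0.0, 4.0, 0.01):
        for phase in np.arange(0, 2 * np.pi, 0.02):
            pred = amp * np.cos(2 * np.pi * t_h / M2_PERIOD_H - phase)
            resid = series.values - pred
            resid = resid - resid.mean()
            rmse = np.sqrt((resid**2).mean())
            if rmse < best[0]:
                best = (rmse, amp, phase)
    return best


# -- tidal window detection --------------------------------------------------

def test_pure_sinusoid_window_recovered_exactly():
    series = _sinusoid_series(1.5, 1.0)
    fits = detect_tidal_windows(series, t0=series.index[0].normalize())
    assert fits
    assert fits[0].amplitude_m == pytest.approx(1.5, abs=1e-6)
    assert fits[0].phase_rad == pytest.approx(1.0, abs=1e-6)


def test_active_swimming_window_rejected():
    idx = pd.date_range("2020-01-01", periods=240, freq="min")
    rng = np.random.default_rng(1)
    swim = pd.Series(20 + 15 * np.sin(np.arange(240) / 8) + rng.normal(0, 2, 240), index=idx)
    assert detect_tidal_windows(swim, t0=idx[0].normalize()) == []


def test_noisy_window_matches_grid_search_oracle():
    series = _sinusoid_series(1.0, 2.5, hours=3.0, noise_sd=0.1, seed=3)
    t0 = series.index[0].normalize()
    fits = detect_tidal_windows(series, t0=t0)
    assert fits and fits[0].rmse_m <= 0.12
    rmse_o, amp_o, phase_o = _grid_search_fit(series, t0)
    assert fits[0].amplitude_m == pytest.approx(amp_o, abs=0.05)
    assert abs(np.angle(np.exp(1j * (fits[0].phase_rad - phase_o)))) < 0.1


def test_summarize_day_constant_day():
    idx = pd.date_range("2020-01-02", periods=1440, freq="min")
    temp = np.full(1440, np.nan)
    temp[::10] = 10.0
    df = pd.DataFrame({"depth_m": np.full(1440, 40.0), "temp_c": temp}, index=idx)
    from bassgeo.archive import Deployment, TagArchive

    arch = TagArchive(Deployment("X", "2020-01-01", 50, 1), df)
    obs = summarize_day(arch, 0)
    assert obs.max_depth_m == 40.0
    assert all(t == pytest.approx(10.0) for _, t in obs.temp_samples)
    assert all(d == pytest.approx(40.0) for d, _ in obs.temp_samples)


def test_summarize_day_recovers_generator_amplitude(flat_env, small_archive, small_track):
    cfg = LikelihoodConfig()
    obs = summarize_day(small_archive, 2, cfg)
    assert obs.tidal_fits
    cell = tuple(small_track.cells[2])
    amp = flat_env.tide_amp_m[cell]
    assert min(abs(f.amplitude_m - amp) for f in obs.tidal_fits) < 0.05


# -- masking -----------------------------------------------------------------

def test_mask_equals_per_cell_comparison(coastal_env):
    obs = DailyObservation(day=0, max_depth_m=60.0)
    mask = bathymetry_mask(obs, coastal_env, tol_m=5.0)
    expected = coastal_env.sea & (coastal_env.bathy_m >= 55.0)
    np.testing.assert_array_equal(mask, expected)


def test_mask_vacuous_when_no_depth(coastal_env):
    obs = DailyObservation(day=0, max_depth_m=0.0)
    mask = bathymetry_mask(obs, coastal_env)
    np.testing.assert_array_equal(mask, coastal_env.sea)


def test_mask_contradiction_relaxes(flat_env):
    obs = DailyObservation(day=0, max_depth_m=70.0)  # flat 40 m world
    mask = bathymetry_mask(obs, flat_env, tol_m=5.0)
    assert mask.any()


# -- tidal and temperature layers -------------------------------------------

def test_tidal_exact_match_is_argmax(flat_env):
    cell = (4, 7)
    fit = TidalFit(flat_env.tide_amp_m[cell], flat_env.tide_phase_rad[cell], 0.01)
    w = tidal_likelihood(fit, flat_env)
    assert np.unravel_index(np.argmax(w), w.shape) == cell


def test_tidal_phase_mismatch_suppression():
    # two cells with identical amplitude, phases pi apart: the mismatched
    # cell is suppressed by exp(-0.5 * (pi / sigma_p)^2) = exp(-18)
    env = make_environment(3, 3, n_days=2, seed=1, bathymetry="flat")
    env.tide_amp_m = np.full(env.shape, 1.0)
    env.tide_phase_rad = np.zeros(env.shape)
    env.tide_phase_rad[0, 1] = np.pi
    sigma_p = np.pi / 6
    fit = TidalFit(1.0, 0.0, 0.01)
    w = tidal_likelihood(fit, env, sigma_amp_m=0.3, sigma_phase_rad=sigma_p)
    assert w[0, 1] / w[0, 0] == pytest.approx(np.exp(-18), rel=1e-9)


def test_tidal_argmax_matches_brute_force():
    rng = np.random.default_rng(8)
    env = make_environment(10, 10, n_days=3, seed=8, bathymetry="flat")
    env.tide_amp_m = rng.uniform(0, 3, env.shape)
    env.tide_phase_rad = rng.uniform(0, 2 * np.pi, env.shape)
    fit = TidalFit(1.7, 2.0, 0.02)
    w = tidal_likelihood(fit, env, 0.3, 0.25)
    # exhaustive evaluation
    best, best_cell = -1, None
    for i in range(10):
        for j in range(10):
            dph = np.angle(np.exp(1j * (env.tide_phase_rad[i, j] - 2.0)))
            v = np.exp(-0.5 * ((env.tide_amp_m[i, j] - 1.7) / 0.3) ** 2
                       - 0.5 * (dph / 0.25) ** 2)
            if v > best:
                best, best_cell = v, (i, j)
    assert np.unravel_index(np.argmax(w), w.shape) == best_cell
    with pytest.raises(ValueError):
        tidal_likelihood(fit, env, 0.0, 0.25)


def test_temperature_uniform_field_is_flat(flat_env):
    env = flat_env
    obs = DailyObservation(day=0, max_depth_m=None, temp_samples=[(10.0, 11.0)])
    uniform = make_environment(6, 6, n_days=3, seed=1, bathymetry="flat",
                               sst_lat_gradient_c=0.0, sst_noise_c=0.0,
                               stratification_c=0.0)
    w = temperature_likelihood(obs, uniform)
    assert np.allclose(w[uniform.sea], w[uniform.sea][0])


def test_temperature_product_matches_brute_force(coastal_env):
    env = coastal_env
    day = 10
    samples = [(5.0, 11.0), (20.0, 10.5), (40.0, 10.0), (60.0, 9.8), (80.0, 9.6)]
    obs = DailyObservation(day=day, max_depth_m=None, temp_samples=samples)
    w = temperature_likelihood(obs, env, sigma_t_c=0.7, env_day=day)
    ny, nx = env.shape
    expected = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            if env.land[i, j]:
                continue
            logp = 0.0
            for d, tv in samples:
                t_env = env.temperature_at(day, (i, j), d)
                logp += -0.5 * ((tv - t_env) / 0.7) ** 2
            expected[i, j] = logp
    expected = np.where(env.sea, np.exp(expected - expected[env.sea].max()), 0.0)
    np.testing.assert_allclose(w, expected, atol=1e-12)


def test_temperature_unique_match_is_argmax(coastal_env):
    env = coastal_env
    cell = (12, 5)
    t_val = float(env.temperature_at(3, cell, 30.0))
    # offset the rest of the field so the match is unique
    obs = DailyObservation(day=3, max_depth_m=None, temp_samples=[(30.0, t_val)] * 3)
    w = temperature_likelihood(obs, env, sigma_t_c=0.05, env_day=3)
    assert w[cell] == pytest.approx(w.max())


# -- anchors -----------------------------------------------------------------

def test_release_anchor_is_near_delta(flat_env):
    lat, lon = flat_env.cell_to_latlon((6, 6))
    w = endpoint_anchor((lat, lon), flat_env, "release")
    w = w / w.sum()
    near = w[5:8, 5:8].sum()
    assert near >= 0.99


def test_fishery_anchor_mass_by_direct_summation():
    # fine grid so cell-center sampling approximates the continuous Gaussian:
    # a 2-D isotropic Gaussian holds 1 - exp(-2) = 86.5% within 2 sd and
    # 98.9% within 3 sd
    env = make_environment(41, 41, n_days=2, seed=1, bathymetry="flat", cell_size_km=1.0)
    lat, lon = env.cell_to_latlon((20, 20))
    w = endpoint_anchor((lat, lon), env, "fishery_recovery")
    w = w / w.sum()
    yy, xx = np.indices(env.shape)
    dist = np.hypot(yy - 20, xx - 20) * env.cell_size_km
    assert w[dist <= 10.0].sum() == pytest.approx(1 - np.exp(-2), abs=0.03)
    assert w[dist <= 15.0].sum() >= 0.95


def test_beach_anchor_sd_is_200km():
    from bassgeo.likelihood import ANCHOR_SD_KM

    assert ANCHOR_SD_KM["beach_recovery"] == 200.0


def test_anchor_off_grid_rejected(flat_env):
    with pytest.raises(ValueError):
        endpoint_anchor((20.0, -40.0), flat_env, "release")


# -- combined daily likelihood ----------------------------------------------

def test_only_mask_layer_gives_uniform(coastal_env):
    obs = DailyObservation(day=0, max_depth_m=60.0)
    dl = build_daily_likelihood(obs, coastal_env)
    mask = bathymetry_mask(obs, coastal_env)
    assert np.allclose(dl.weights[mask], dl.weights[mask][0])
    assert dl.weights[~mask].sum() == 0
    assert dl.weights.sum() == pytest.approx(1.0)


def test_all_uniform_layers_give_uniform(flat_env):
    obs = DailyObservation(day=0, max_depth_m=None)
    dl = build_daily_likelihood(obs, flat_env)
    sea = flat_env.sea
    assert np.allclose(dl.weights[sea], 1.0 / sea.sum())


def test_product_matches_brute_force(flat_env):
    rng = np.random.default_rng(3)
    env = make_environment(8, 8, n_days=3, seed=3, bathymetry="flat")
    anchors = [rng.uniform(0.1, 1, env.shape) for _ in range(2)]
    obs = DailyObservation(day=0, max_depth_m=30.0,
                           temp_samples=[(10.0, env.sst_c[0, 4, 4] + 0.1)])
    dl = build_daily_likelihood(obs, env, anchors=anchors)
    mask = bathymetry_mask(obs, env)
    expected = mask.astype(float) * temperature_likelihood(obs, env, 0.7, env_day=0)
    for a in anchors:
        expected = expected * a
    expected /= expected.sum()
    np.testing.assert_allclose(dl.weights, expected, atol=1e-12)


def test_layer_product_order_invariant(flat_env):
    rng = np.random.default_rng(4)
    layers = [rng.uniform(0, 1, flat_env.shape) for _ in range(3)]
    obs = DailyObservation(day=0, max_depth_m=20.0)
    a = build_daily_likelihood(obs, flat_env, anchors=layers)
    b = build_daily_likelihood(obs, flat_env, anchors=layers[::-1])
    np.testing.assert_allclose(a.weights, b.weights, atol=1e-14)


def test_fallback_ladder_on_contradiction(flat_env):
    # max depth impossible everywhere and an anchor wiping out the rest
    obs = DailyObservation(day=0, max_depth_m=200.0)
    anchor = np.zeros(flat_env.shape)
    anchor[0, 0] = 1.0
    dl = build_daily_likelihood(obs, flat_env, anchors=[anchor])
    assert dl.fallback
    assert dl.weights.sum() == pytest.approx(1.0)


def test_stack_round_trip(tmp_path, flat_env, small_archive):
    from bassgeo.likelihood import load_stack, save_stack

    stack = build_likelihood_stack(small_archive, flat_env)
    path = tmp_path / "stack.nc"
    save_stack(stack, flat_env, path)
    back = load_stack(path)
    np.testing.assert_allclose(back, np.stack([dl.weights for dl in stack]))


def test_stack_normalised_and_zero_on_land(coastal_env, small_archive):
    from bassgeo.simulate import record_tag, simulate_track

    switch = np.eye(2)
    tr = simulate_track(coastal_env, 2.0, 20.0, switch, 6, (10, 10), seed=6)
    arch = record_tag(tr, coastal_env, seed=6)
    stack = build_likelihood_stack(arch, coastal_env)
    for dl in stack:
        assert dl.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert dl.weights[coastal_env.land].sum() == 0.0
        assert (dl.weights >= 0).all()
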