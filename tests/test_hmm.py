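import numpy as np
import pytest

from bassgeo.environment import make_environment
from bassgeo.hmm import (
    BehaviourModel,
    DiffusionKernel,
    HMMGeolocator,
    _dense_transition,
    estimate_parameters,
    forward_backward,
    mode_positions,
    path_log_prob,
    viterbi,
)


def joint_transition(model, env):
    """Dense transition over the joint (cell, behaviour) state."""
    n = env.shape[0] * env.shape[1]
    P = [_dense_transition(DiffusionKernel(D, 1.0, env)) for D in model.diffusivities]
    S = model.switch_matrix
    M = np.zeros((2 * n, 2 * n))
    for b in range(2):
        for b2 in range(2):
            M[b * n : (b + 1) * n, b2 * n : (b2 + 1) * n] = S[b, b2] * P[b2]
    return M


def enumerate_paths(L, model, env, init=(0.5, 0.5)):
    """Exhaustive path enumeration oracle (vectorised over the path tensor).

    Returns total likelihood, per-day smoothed marginals and the MAP path.
    """
    T = L.shape[0]
    n = env.shape[0] * env.shape[1]
    M = joint_transition(model, env)
    e = [np.concatenate([L[t].ravel(), L[t].ravel()]) for t in range(T)]
    p0 = np.repeat(np.asarray(init), n) / 1.0
    p0 = np.concatenate([init[0] * L[0].ravel(), init[1] * L[0].ravel()])
    # joint tensor over all state sequences
    shape = (2 * n,) * T
    joint = p0.reshape((2 * n,) + (1,) * (T - 1)) * np.ones(shape)
    for t in range(1, T):
        trans_shape = [1] * T
        trans_shape[t - 1] = trans_shape[t] = 2 * n
        joint = joint * (M * e[t][None, :]).reshape(
            (1,) * (t - 1) + (2 * n, 2 * n) + (1,) * (T - t - 1)
        )
    tot = joint.sum()
    marg = np.empty((T, 2, n))
    for t in range(T):
        axes = tuple(a for a in range(T) if a != t)
        m = joint.sum(axis=axes)
        marg[t] = np.stack([m[:n], m[n:]]) / tot
    flat = np.unravel_index(np.argmax(joint), shape)
    best_lp = np.log(joint[flat])
    path = []
    for s in flat:
        b, cell = divmod(s, n)
        path.append((cell // env.shape[1], cell % env.shape[1], b))
    return tot, marg, best_lp, np.array(path)


# -- diffusion kernel --------------------------------------------------------

def test_zero_diffusivity_is_identity(flat_env):
    k = DiffusionKernel(0.0, 1.0, flat_env)
    rng = np.random.default_rng(0)
    x = rng.random(flat_env.shape) * flat_env.sea
    np.testing.assert_array_equal(k.apply(x), x)


def test_kernel_second_moment(flat_env):
    env = make_environment(41, 41, n_days=2, seed=1, bathymetry="flat")
    k = DiffusionKernel(50.0, 1.0, env)
    e = np.zeros(env.shape)
    e[20, 20] = 1.0
    out = k.apply(e)
    x = (np.arange(41) - 20) * env.cell_size_km
    for axis in (0, 1):
        m2 = (out.sum(axis=axis) * x**2).sum() / out.sum()
        assert m2 == pytest.approx(2 * 50.0, rel=0.05)


def test_kernel_mass_conserved_next_to_land(coastal_env):
    k = DiffusionKernel(80.0, 1.0, coastal_env)
    e = np.zeros(coastal_env.shape)
    e[2, 10] = 1.0  # beside the land row
    out = k.apply(e)
    # rows are renormalised, so total mass stays within numerical error of 1
    assert out[coastal_env.land].sum() == 0.0
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_negative_diffusivity_rejected(flat_env):
    with pytest.raises(ValueError):
        DiffusionKernel(-1.0, 1.0, flat_env)


# -- smoothing ---------------------------------------------------------------

def test_degenerate_bridge_stays_at_anchor(tiny_env):
    L = np.ones((5, 3, 3))
    anchor = np.zeros((3, 3))
    anchor[1, 1] = 1.0
    L[0] = anchor
    L[-1] = anchor
    model = BehaviourModel(0.0, 0.0)
    post = forward_backward(L, model, tiny_env)
    for t in range(5):
        assert post.spatial_marginals()[t][1, 1] == pytest.approx(1.0)


def test_smoother_matches_enumeration(tiny_env):
    rng = np.random.default_rng(1)
    L = rng.uniform(0.05, 1.0, size=(4, 3, 3))
    model = BehaviourModel(3.0, 45.0, np.array([[0.85, 0.15], [0.2, 0.8]]))
    tot, marg, _, _ = enumerate_paths(L, model, tiny_env)
    post = forward_backward(L, model, tiny_env)
    assert post.log_likelihood == pytest.approx(np.log(tot), rel=1e-12)
    np.testing.assert_allclose(post.smoothed.reshape(4, 2, 9), marg, rtol=1e-10, atol=1e-14)


def test_uninformative_day_ignored_in_full_mixing_limit(tiny_env):
    # with D large enough to mix the 3x3 grid in one step, inserting a
    # uniform day leaves the other days' marginals unchanged
    rng = np.random.default_rng(2)
    La = rng.uniform(0.2, 1.0, size=(3, 3, 3))
    Lb = np.insert(La, 1, np.ones((3, 3)), axis=0)
    model = BehaviourModel(1e6, 1e6)  # sd ~ 600 cells: essentially mixing
    pa = forward_backward(La, model, tiny_env).spatial_marginals()
    pb = forward_backward(Lb, model, tiny_env).spatial_marginals()
    # the truncated kernel is flat over a 3x3 grid only to ~(grid/sd)^2
    np.testing.assert_allclose(pa[0], pb[0], atol=1e-5)
    np.testing.assert_allclose(pa[1:], pb[2:], atol=1e-5)


def test_daily_normalization(coastal_env):
    rng = np.random.default_rng(3)
    L = rng.uniform(0, 1, size=(15,) + coastal_env.shape) * coastal_env.sea
    post = forward_backward(L, BehaviourModel(4.0, 90.0), coastal_env, keep_filtered=True)
    sums = post.smoothed.sum(axis=(1, 2, 3))
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    np.testing.assert_allclose(post.filtered.sum(axis=(1, 2, 3)), 1.0, atol=1e-9)
    assert post.smoothed[:, :, coastal_env.land].sum() == 0.0


# -- viterbi -----------------------------------------------------------------

def test_forced_path_followed(tiny_env):
    cells = [(0, 0), (0, 1), (1, 1), (2, 2)]
    L = np.zeros((4, 3, 3))
    for t, c in enumerate(cells):
        L[t][c] = 1.0
    path, _ = viterbi(L, BehaviourModel(10.0, 50.0), tiny_env)
    assert [tuple(r[:2]) for r in path] == cells


def test_viterbi_matches_enumeration(tiny_env):
    rng = np.random.default_rng(4)
    L = rng.uniform(0.05, 1.0, size=(4, 3, 3))
    model = BehaviourModel(2.0, 30.0, np.array([[0.7, 0.3], [0.25, 0.75]]))
    _, _, best_lp, best_path = enumerate_paths(L, model, tiny_env)
    path, lp = viterbi(L, model, tiny_env)
    np.testing.assert_array_equal(path, best_path)
    assert lp == pytest.approx(best_lp, rel=1e-10)


def test_viterbi_dominates_mode_sequence(tiny_env):
    rng = np.random.default_rng(5)
    model = BehaviourModel(2.0, 30.0)
    for _ in range(5):
        L = rng.uniform(0.05, 1.0, size=(5, 3, 3))
        post = forward_backward(L, model, tiny_env)
        path, lp = viterbi(L, model, tiny_env)
        modes = mode_positions(post)
        # most probable per-day cells with the more probable behaviour
        beh = post.smoothed.sum(axis=(2, 3)).argmax(axis=1)
        mode_path = np.column_stack([modes["row"], modes["col"], beh])
        lp_modes = path_log_prob(mode_path, L, model, tiny_env)
        assert lp >= lp_modes - 1e-12


# -- parameter estimation ----------------------------------------------------

def test_estimate_collapsed_model_flagged(flat_env):
    rng = np.random.default_rng(6)
    from bassgeo.simulate import record_tag, simulate_track
    from bassgeo.likelihood import build_likelihood_stack

    switch = np.array([[0.5, 0.5], [0.5, 0.5]])
    tr = simulate_track(flat_env, 20.0, 20.0, switch, 40, (6, 6), seed=7)
    arch = record_tag(tr, flat_env, seed=7)
    stack = build_likelihood_stack(arch, flat_env)
    model, diag = estimate_parameters(stack, flat_env, init=BehaviourModel(10.0, 40.0),
                                      n_starts=1, maxfev=60, seed=0)
    # equal-diffusivity truth: the two estimates collapse (ratio within 2)
    assert model.D_mig / max(model.D_res, 1e-6) <= 2.0
    assert diag["collapsed"]
    assert diag["log_likelihood"] >= diag["init_log_likelihood"] - 1e-9
    assert model.D_res <= model.D_mig


def test_estimate_rejects_nonfinite_init(tiny_env):
    L = np.zeros((3, 3, 3))  # no support anywhere
    with pytest.raises(ValueError):
        estimate_parameters(L, tiny_env, init=BehaviourModel(1.0, 10.0), n_starts=1)


# -- mode positions ----------------------------------------------------------

def test_mode_positions_delta(flat_env):
    T, (ny, nx) = 3, flat_env.shape
    sm = np.zeros((T, 2, ny, nx))
    sm[:, 0, 4, 5] = 1.0
    from bassgeo.hmm import PosteriorTrack

    post = PosteriorTrack(smoothed=sm, log_likelihood=0.0, env=flat_env)
    modes = mode_positions(post)
    assert (modes["row"] == 4).all() and (modes["col"] == 5).all()
    assert modes["hpd_area_km2"][0] == pytest.approx(5.2**2)


def test_mode_positions_uniform_hpd_counts_cells(flat_env):
    ny, nx = flat_env.shape
    n = ny * nx
    sm = np.full((1, 2, ny, nx), 1.0 / (2 * n))
    from bassgeo.hmm import PosteriorTrack

    post = PosteriorTrack(smoothed=sm, log_likelihood=0.0, env=flat_env)
    modes = mode_positions(post)
    assert modes["hpd_area_km2"][0] == pytest.approx(int(np.ceil(0.95 * n)) * 5.2**2)
    assert modes["tie"][0]


def test_mode_positions_pick_heavier_mode(flat_env):
    ny, nx = flat_env.shape
    sm = np.zeros((1, 2, ny, nx))
    sm[0, 0, 2, 2] = 0.45
    sm[0, 0, 9, 9] = 0.55
    from bassgeo.hmm import PosteriorTrack

    post = PosteriorTrack(smoothed=sm, log_likelihood=0.0, env=flat_env)
    modes = mode_positions(post)
    assert (modes["row"][0], modes["col"][0]) == (9, 9)


# -- estimator wrapper -------------------------------------------------------

def test_geolocator_sklearn_protocol(flat_env):
    from sklearn.base import clone
    from bassgeo.simulate import record_tag, simulate_track
    from bassgeo.likelihood import build_likelihood_stack

    geo = HMMGeolocator(env=flat_env, D_res=3.0, D_mig=30.0, estimate=False)
    params = geo.get_params()
    assert params["D_res"] == 3.0
    clone(geo)  # must be cloneable
    switch = np.array([[0.9, 0.1], [0.1, 0.9]])
    tr = simulate_track(flat_env, 3.0, 30.0, switch, 8, (6, 6), seed=8)
    arch = record_tag(tr, flat_env, seed=8)
    stack = build_likelihood_stack(arch, flat_env)
    geo.fit(stack)
    assert geo.model_.D_res == 3.0
    assert geo.posterior_.n_days == 8
    assert len(geo.mode_positions_) == 8
    path = geo.predict()
    assert path.shape == (8, 3)
    proba = geo.predict_proba()
    np.testing.assert_allclose(proba.sum(axis=(1, 2, 3)), 1.0, atol=1e-9)
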