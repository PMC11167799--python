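"""Grid-based hidden Markov model geolocation.

The hidden state is (grid cell, behaviour) with two behaviours, resident
and migratory, each with its own diffusivity ``D`` (km^2/day).  The daily
transition applies behaviour switching first, then spatial spreading by an
isotropic Gaussian with per-axis variance ``2*D*dt`` — the discrete-grid
realisation of Fokker-Planck diffusion — truncated at 4 standard
deviations, with land cells receiving zero mass and rows renormalised.

Inference is the standard scaled forward-backward smoother and Viterbi
decoder over the joint (cell x behaviour) state; diffusivities and
behaviour-switching probabilities are estimated by maximising the forward
log-likelihood with a bounded direct search on transformed parameters.

``HMMGeolocator`` packages the pieces as a scikit-learn style estimator:
``fit`` runs (optionally) parameter estimation plus smoothing, ``predict``
returns the Viterbi most-probable track, ``predict_proba`` the smoothed
daily marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.ndimage import convolve1d
from scipy.special import ndtr
from sklearn.base import BaseEstimator

from .environment import EnvironmentGrid
from .likelihood import DailyLikelihood

RESIDENT, MIGRATORY = 0, 1

__all__ = [
    "BehaviourModel",
    "PosteriorTrack",
    "DiffusionKernel",
    "diffusion_kernel",
    "forward_backward",
    "viterbi",
    "estimate_parameters",
    "mode_positions",
    "HMMGeolocator",
]


@dataclass
class BehaviourModel:
    """Two-behaviour movement model: diffusivities plus switch matrix."""

    D_res: float
    D_mig: float
    switch_matrix: np.ndarray = field(
        default_factory=lambda: np.array([[0.9, 0.1], [0.1, 0.9]])
    )

    def __post_init__(self) -> None:
        self.switch_matrix = np.asarray(self.switch_matrix, dtype=float)
        if not (0 <= self.D_res <= self.D_mig):
            raise ValueError("require 0 <= D_res <= D_mig")
        if self.switch_matrix.shape != (2, 2) or not np.allclose(
            self.switch_matrix.sum(axis=1), 1.0
        ):
            raise ValueError("switch matrix rows must sum to 1")

    @property
    def diffusivities(self) -> tuple[float, float]:
        return (self.D_res, self.D_mig)


class DiffusionKernel:
    """Daily spatial transition operator for one diffusivity.

    ``P(j | i) = K(j - i) * sea(j) / Z(i)`` with ``K`` the cell-integrated
    Gaussian (per-axis variance ``2*D*dt``) truncated at 4 sd and
    ``Z(i) = sum_j K(j - i) sea(j)``.  ``apply`` propagates a probability
    surface forward; ``apply_transpose`` is the backward-smoothing adjoint.
    ``D = 0`` is the identity on sea cells.
    """

    def __init__(self, D: float, dt_days: float, env: EnvironmentGrid):
        if D < 0:
            raise ValueError("diffusivity must be nonnegative")
        self.D = float(D)
        self.dt = float(dt_days)
        self.env = env
        self.sea = env.sea.astype(float)
        h = env.cell_size_km
        sigma_km = np.sqrt(2.0 * D * dt_days)
        self.sigma_cells = sigma_km / h
        if self.sigma_cells < 1e-6:
            self.kernel1d = np.array([1.0])
            self.kernel = np.array([[1.0]])
            self.radius = 0
        else:
            r = max(1, int(np.ceil(4.0 * self.sigma_cells)))
            edges = (np.arange(-r, r + 2) - 0.5) / self.sigma_cells
            cdf = ndtr(edges)
            k1 = np.diff(cdf)
            k1 /= k1.sum()
            self.kernel1d = k1
            self.kernel = np.outer(k1, k1)
            self.radius = r
        self.Z = self._conv(self.sea)
        self.Z[self.Z <= 0] = np.inf  # cells with no reachable sea mass

    def _conv(self, x: np.ndarray) -> np.ndarray:
        """Linear convolution with the truncated kernel (zero padding);
        the kernel is separable, so two 1-D passes suffice."""
        if self.radius == 0:
            return x.copy()
        out = convolve1d(x, self.kernel1d, axis=0, mode="constant")
        out = convolve1d(out, self.kernel1d, axis=1, mode="constant")
        return out

    def apply(self, surface: np.ndarray) -> np.ndarray:
        """alpha'(j) = sea(j) * sum_i K(j-i) alpha(i) / Z(i)."""
        if self.radius == 0:
            return surface * self.sea
        return self.sea * self._conv(surface / self.Z)

    def apply_transpose(self, surface: np.ndarray) -> np.ndarray:
        """beta(i) = sum_j P(j|i) v(j) = conv(sea*v)(i) / Z(i)."""
        if self.radius == 0:
            return surface * self.sea
        return self._conv(self.sea * surface) / self.Z

    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """(offset array (m, 2), log kernel weights (m,)) for max-product."""
        r = self.radius
        di, dj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
        w = self.kernel.ravel()
        keep = w > 0
        return np.column_stack([di.ravel()[keep], dj.ravel()[keep]]), np.log(w[keep])


def diffusion_kernel(D: float, dt_days: float, env: EnvironmentGrid) -> DiffusionKernel:
    return DiffusionKernel(D, dt_days, env)


class _KernelPair:
    """Both behaviours' transition operators applied in one batched FFT."""

    def __init__(self, model: BehaviourModel, env: EnvironmentGrid, dtype=np.float64):
        self.kernels = [DiffusionKernel(D, 1.0, env) for D in model.diffusivities]
        self.env = env
        self.dtype = dtype
        self.sea = env.sea.astype(dtype)
        self._k1 = [k.kernel1d.astype(dtype) for k in self.kernels]
        self.Z = np.stack([k.Z for k in self.kernels]).astype(dtype)

    def _conv(self, x: np.ndarray) -> np.ndarray:
        """Convolution of x[b] with behaviour b's separable kernel."""
        out = np.empty_like(x)
        for b, k1 in enumerate(self._k1):
            if len(k1) == 1:
                out[b] = x[b]
            else:
                tmp = convolve1d(x[b], k1, axis=0, mode="constant")
                out[b] = convolve1d(tmp, k1, axis=1, mode="constant")
        return out

    def apply(self, surfaces: np.ndarray) -> np.ndarray:
        """surfaces: (2, ny, nx) already behaviour-mixed; returns diffused."""
        return self.sea[None] * self._conv(surfaces / self.Z)

    def apply_transpose(self, surfaces: np.ndarray) -> np.ndarray:
        return self._conv(self.sea[None] * surfaces) / self.Z


@dataclass
class PosteriorTrack:
    """Smoothed daily state distributions plus decoded tracks."""

    smoothed: np.ndarray          # (T, 2, ny, nx); sums to 1 per day
    log_likelihood: float
    env: EnvironmentGrid
    filtered: np.ndarray | None = None
    viterbi_path: np.ndarray | None = None    # (T, 3): row, col, behaviour
    viterbi_log_prob: float | None = None

    @property
    def n_days(self) -> int:
        return self.smoothed.shape[0]

    def spatial_marginals(self) -> np.ndarray:
        return self.smoothed.sum(axis=1)

    def behaviour_marginals(self) -> np.ndarray:
        return self.smoothed.sum(axis=(2, 3))


def _as_stack(likelihoods) -> np.ndarray:
    if isinstance(likelihoods, np.ndarray):
        return likelihoods
    return np.stack([
        dl.weights if isinstance(dl, DailyLikelihood) else np.asarray(dl)
        for dl in likelihoods
    ])


def forward_backward(
    likelihoods,
    model: BehaviourModel,
    env: EnvironmentGrid,
    initial_behaviour: np.ndarray | None = None,
    keep_filtered: bool = False,
) -> PosteriorTrack:
    """Scaled filter/smoother over the joint (cell x behaviour) state.

    ``likelihoods`` is one surface per day at liberty (endpoint anchors are
    expected to be part of the first/last surfaces).  Per-day scaling
    constants accumulate into the total log-likelihood.
    """
    L = _as_stack(likelihoods)
    T = L.shape[0]
    if initial_behaviour is None:
        initial_behaviour = np.array([0.5, 0.5])
    pair = _KernelPair(model, env)
    S = model.switch_matrix

    alpha = np.empty((T, 2) + env.shape)
    loglik = 0.0
    a = initial_behaviour[:, None, None] * L[0][None] * env.sea[None]
    c = a.sum()
    if c <= 0:
        raise ValueError("day 0 likelihood has no support on sea cells")
    alpha[0] = a / c
    loglik += np.log(c)
    for t in range(1, T):
        mixed = np.tensordot(S.T, alpha[t - 1], axes=1)  # switch first
        a = pair.apply(mixed) * L[t][None]
        c = a.sum()
        if c <= 0 or not np.isfinite(c):
            raise ValueError(f"all-zero posterior support at day {t}")
        alpha[t] = a / c
        loglik += np.log(c)

    beta = np.ones((2,) + env.shape)
    smoothed = np.empty_like(alpha)
    smoothed[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        v = pair.apply_transpose(L[t + 1][None] * beta)
        beta = np.tensordot(S, v, axes=1)
        beta /= beta.max() or 1.0
        sm = alpha[t] * beta
        smoothed[t] = sm / sm.sum()

    return PosteriorTrack(
        smoothed=smoothed,
        log_likelihood=float(loglik),
        env=env,
        filtered=alpha if keep_filtered else None,
    )


def viterbi(
    likelihoods,
    model: BehaviourModel,
    env: EnvironmentGrid,
    initial_behaviour: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Joint-MAP (cell, behaviour) sequence by max-product dynamic
    programming; ties break toward the lower flat state index."""
    L = _as_stack(likelihoods)
    T, ny, nx = L.shape
    if initial_behaviour is None:
        initial_behaviour = np.array([0.5, 0.5])
    kernels = [DiffusionKernel(D, 1.0, env) for D in model.diffusivities]
    S = model.switch_matrix
    with np.errstate(divide="ignore"):
        logL = np.where(env.sea[None], np.log(np.clip(L, 1e-300, None)), -np.inf)
        logL[:, ~env.sea] = -np.inf
        logS = np.log(np.clip(S, 1e-300, None))
        log_init = np.log(np.clip(initial_behaviour, 1e-300, None))
        logZ = [np.log(k.Z) for k in kernels]

    delta = log_init[:, None, None] + logL[0][None]
    back = np.zeros((T, 2, ny, nx), dtype=np.int32)
    flat_prev = (np.arange(2)[:, None, None] * ny * nx
                 + np.arange(ny)[None, :, None] * nx
                 + np.arange(nx)[None, None, :]).astype(np.int32)

    for t in range(1, T):
        new_delta = np.full((2, ny, nx), -np.inf)
        new_back = np.zeros((2, ny, nx), dtype=np.int32)
        for b_new in range(2):
            offs, logK = kernels[b_new].offsets()
            for b_old in range(2):
                base = delta[b_old] - logZ[b_new] + logS[b_old, b_new]
                for (di, dj), lk in zip(offs, logK):
                    if abs(di) >= ny or abs(dj) >= nx:
                        continue
                    # candidate at (i, j) from predecessor (i-di, j-dj)
                    cand = np.full((ny, nx), -np.inf)
                    src_i = slice(max(0, -di), max(0, min(ny, ny - di)))
                    src_j = slice(max(0, -dj), max(0, min(nx, nx - dj)))
                    dst_i = slice(max(0, di), max(0, min(ny, ny + di)))
                    dst_j = slice(max(0, dj), max(0, min(nx, nx + dj)))
                    cand[dst_i, dst_j] = base[src_i, src_j] + lk
                    better = cand > new_delta[b_new]
                    new_delta[b_new][better] = cand[better]
                    src_flat = np.full((ny, nx), -1, dtype=np.int32)
                    src_flat[dst_i, dst_j] = flat_prev[b_old][src_i, src_j]
                    new_back[b_new][better] = src_flat[better]
        delta = new_delta + logL[t]
        back[t] = new_back

    path = np.empty((T, 3), dtype=int)
    flat = int(np.argmax(delta))
    log_prob = float(delta.ravel()[flat])
    b, rem = divmod(flat, ny * nx)
    i, j = divmod(rem, nx)
    path[T - 1] = (i, j, b)
    for t in range(T - 1, 0, -1):
        flat = int(back[t, b, i, j])
        b, rem = divmod(flat, ny * nx)
        i, j = divmod(rem, nx)
        path[t - 1] = (i, j, b)
    return path, log_prob


def path_log_prob(path: np.ndarray, likelihoods, model: BehaviourModel,
                  env: EnvironmentGrid,
                  initial_behaviour: np.ndarray | None = None) -> float:
    """Joint log probability of a given (cell, behaviour) sequence."""
    L = _as_stack(likelihoods)
    if initial_behaviour is None:
        initial_behaviour = np.array([0.5, 0.5])
    kernels = [DiffusionKernel(D, 1.0, env) for D in model.diffusivities]
    dense = {b: _dense_transition(kernels[b]) for b in range(2)}
    i, j, b = path[0]
    lp = np.log(initial_behaviour[b]) + np.log(L[0][i, j])
    ny, nx = env.shape
    for t in range(1, len(path)):
        i2, j2, b2 = path[t]
        trans = model.switch_matrix[b, b2] * dense[b2][i * nx + j, i2 * nx + j2]
        with np.errstate(divide="ignore"):
            lp += np.log(trans) + np.log(L[t][i2, j2])
        i, j, b = i2, j2, b2
    return float(lp)


def _dense_transition(kernel: DiffusionKernel) -> np.ndarray:
    """Materialise P(j|i) as a dense matrix (small grids only)."""
    ny, nx = kernel.env.shape
    n = ny * nx
    P = np.empty((n, n))
    for idx in range(n):
        e = np.zeros((ny, nx))
        e[divmod(idx, nx)] = 1.0
        P[idx] = kernel.apply(e).ravel()
    return P


# -- parameter estimation ----------------------------------------------------

def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _theta_to_model(theta, D_max) -> BehaviourModel:
    D1 = float(np.clip(np.exp(theta[0]), 1e-3, D_max))
    D2 = float(np.clip(np.exp(theta[1]), 1e-3, D_max))
    s11, s22 = _expit(theta[2]), _expit(theta[3])
    S = np.array([[s11, 1 - s11], [1 - s22, s22]])
    if D1 > D2:  # keep the resident label on the smaller diffusivity
        D1, D2 = D2, D1
        S = S[::-1, ::-1]
    return BehaviourModel(D1, D2, S)


def estimate_parameters(
    likelihoods,
    env: EnvironmentGrid,
    init: BehaviourModel | None = None,
    D_max: float = 500.0,
    n_starts: int = 3,
    seed: int = 0,
    maxfev: int = 200,
) -> tuple[BehaviourModel, dict]:
    """Maximise the forward log-likelihood over (D_res, D_mig, switch
    probabilities) by Nelder-Mead on log/logit-transformed parameters with
    deterministic multi-start.

    Returns ``(model, diagnostics)``; the returned model always satisfies
    ``D_res <= D_mig`` (labels are ordered) and a log-likelihood at least
    that of the initial model.
    """
    L = _as_stack(likelihoods).astype(np.float32)
    if init is None:
        init = BehaviourModel(10.0, 100.0)

    def negloglik(theta):
        try:
            model = _theta_to_model(theta, D_max)
            return -forward_backward_loglik(L, model, env)
        except (ValueError, FloatingPointError):
            return 1e12

    theta0 = np.array([
        np.log(max(init.D_res, 1e-3)),
        np.log(max(init.D_mig, 1e-3)),
        _logit(init.switch_matrix[0, 0]),
        _logit(init.switch_matrix[1, 1]),
    ])
    f0 = negloglik(theta0)
    if not np.isfinite(f0) or f0 >= 1e12:
        raise ValueError("non-finite likelihood at the initial model")

    rng = np.random.default_rng(seed)
    starts = [theta0] + [theta0 + rng.normal(0, [0.7, 0.7, 0.5, 0.5]) for _ in range(n_starts - 1)]
    best, best_f, n_eval = theta0, f0, 0
    results = []
    for s in starts:
        res = optimize.minimize(
            negloglik, s, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 0.02, "fatol": 0.05},
        )
        results.append(res)
        n_eval += res.nfev
        if res.fun < best_f:
            best, best_f = res.x, res.fun
    model = _theta_to_model(best, D_max)
    diag = {
        "log_likelihood": -best_f,
        "init_log_likelihood": -f0,
        "n_eval": n_eval,
        "converged": any(r.success for r in results),
        "collapsed": bool(model.D_mig < 2 * model.D_res),
    }
    return model, diag


def forward_backward_loglik(L, model, env) -> float:
    """Forward-pass log-likelihood only (no smoothing; used in fitting).

    Runs in single precision: per-day rescaling keeps the recursion well
    conditioned, and the direct-search optimiser only needs ~1e-3 accuracy.
    """
    pair = _KernelPair(model, env, dtype=np.float32)
    S = model.switch_matrix.astype(np.float32)
    L = L.astype(np.float32, copy=False)
    a = 0.5 * L[0][None] * pair.sea[None] * np.ones((2, 1, 1), np.float32)
    c = a.sum()
    if c <= 0:
        raise ValueError("no support at day 0")
    a = a / c
    loglik = np.log(c)
    for t in range(1, L.shape[0]):
        a = pair.apply(np.tensordot(S.T, a, axes=1)) * L[t][None]
        c = a.sum()
        if c <= 0 or not np.isfinite(c):
            raise ValueError(f"zero likelihood at day {t}")
        a = a / c
        loglik += np.log(c)
    return float(loglik)


def mode_positions(posterior: PosteriorTrack, hpd: float = 0.95):
    """Daily most-probable positions with an uncertainty area.

    Returns a structured array with fields day, lat, lon, row, col,
    posterior mass at the mode, and the area (km^2) of the smallest cell
    set holding ``hpd`` posterior mass.  Ties pick the northernmost, then
    westernmost cell (flagged).
    """
    env = posterior.env
    T = posterior.n_days
    marg = posterior.spatial_marginals()
    cell_area = env.cell_area_km2()
    out = np.zeros(T, dtype=[
        ("day", int), ("row", int), ("col", int), ("lat", float), ("lon", float),
        ("mode_mass", float), ("hpd_area_km2", float), ("tie", bool),
    ])
    for t in range(T):
        m = marg[t]
        best = m.max()
        ties = np.argwhere(m >= best * (1 - 1e-12))
        tie = len(ties) > 1
        # northernmost (max row: lat increases with row), then westernmost
        order = np.lexsort((ties[:, 1], -ties[:, 0]))
        i, j = ties[order[0]]
        flat = np.sort(m.ravel())[::-1]
        csum = np.cumsum(flat)
        n_hpd = int(np.searchsorted(csum, hpd * csum[-1]) + 1)
        lat, lon = env.cell_to_latlon((int(i), int(j)))
        out[t] = (t, i, j, lat, lon, best, n_hpd * cell_area, tie)
    return out


class HMMGeolocator(BaseEstimator):
    """Scikit-learn style wrapper for geolocation on a fixed grid.

    Parameters mirror :class:`BehaviourModel`; with ``estimate=True`` the
    diffusivities and switching probabilities are re-estimated from the
    data before smoothing.  ``fit`` expects a stack of daily likelihood
    surfaces (from :func:`bassgeo.likelihood.build_likelihood_stack`).

    Attributes (after fit): ``model_``, ``posterior_``, ``log_likelihood_``,
    ``mode_positions_``, ``diagnostics_``.
    """

    def __init__(
        self,
        env: EnvironmentGrid = None,
        D_res: float = 10.0,
        D_mig: float = 100.0,
        p_stay_res: float = 0.9,
        p_stay_mig: float = 0.9,
        estimate: bool = True,
        D_max: float = 500.0,
        n_starts: int = 3,
        maxfev: int = 200,
        seed: int = 0,
    ):
        self.env = env
        self.D_res = D_res
        self.D_mig = D_mig
        self.p_stay_res = p_stay_res
        self.p_stay_mig = p_stay_mig
        self.estimate = estimate
        self.D_max = D_max
        self.n_starts = n_starts
        self.maxfev = maxfev
        self.seed = seed

    def _init_model(self) -> BehaviourModel:
        S = np.array([
            [self.p_stay_res, 1 - self.p_stay_res],
            [1 - self.p_stay_mig, self.p_stay_mig],
        ])
        return BehaviourModel(self.D_res, self.D_mig, S)

    def fit(self, X, y=None):
        if self.env is None:
            raise ValueError("an EnvironmentGrid is required")
        L = _as_stack(X)
        model = self._init_model()
        if self.estimate:
            model, diag = estimate_parameters(
                L, self.env, init=model, D_max=self.D_max,
                n_starts=self.n_starts, seed=self.seed, maxfev=self.maxfev,
            )
            self.diagnostics_ = diag
        else:
            self.diagnostics_ = {}
        self.model_ = model
        self.posterior_ = forward_backward(L, model, self.env, keep_filtered=True)
        self.log_likelihood_ = self.posterior_.log_likelihood
        self.mode_positions_ = mode_positions(self.posterior_)
        self._L = L
        return self

    def predict(self, X=None) -> np.ndarray:
        """Viterbi most-probable track for the fitted (or given) data."""
        L = self._L if X is None else _as_stack(X)
        path, logp = viterbi(L, self.model_, self.env)
        if X is None:
            self.posterior_.viterbi_path = path
            self.posterior_.viterbi_log_prob = logp
        return path

    def predict_proba(self, X=None) -> np.ndarray:
        if X is None:
            return self.posterior_.smoothed
        return forward_backward(_as_stack(X), self.model_, self.env).smoothed
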