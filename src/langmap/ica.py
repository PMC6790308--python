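"""Spatial ICA of resting-state runs.

Orientation is fixed as *spatial* ICA: the voxels are the realisations, the
recovered sources are spatial maps that are mutually independent over
voxels, and each component has one associated time course (the mixing
column).  The decomposition pipeline is PCA dimensionality reduction with
whitening followed by (extended) Infomax unmixing by natural-gradient
ascent; component maps are z-scored over the brain mask and sign-fixed to
positive skewness so that "activation" is positive and a z = 2 threshold is
meaningful.

The component count defaults to 55 to match a full-length clinical run but
is validated against the temporal rank of the data; desk-scale synthetic
runs use 8-20 components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy import stats

from .grid import StatMap
from .simulate import BoldRun

__all__ = [
    "ICAConfig",
    "PCAWhitening",
    "ICADecomposition",
    "pca_whiten",
    "infomax_unmix",
    "decompose_rest",
    "threshold_component",
]


@dataclass(frozen=True)
class ICAConfig:
    n_components: int = 55
    learning_rate: float = 0.15  # step on the block-averaged natural gradient
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0
    extended: bool = True
    anneal_deg: float = 60.0
    anneal_scale: float = 0.9
    decay: float = 0.98  # per-pass learning-rate decay (shrinks the stochastic floor)
    ext_subsample: int = 10000  # voxels used per pass for kurtosis-sign estimation
    n_restarts: int = 3  # seeded restarts; the most non-Gaussian solution wins

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass(frozen=True)
class PCAWhitening:
    """Reduced, whitened data plus the back-projection to the original space."""

    whitened: np.ndarray  # (n_components, n_samples), unit variance, uncorrelated
    mixing: np.ndarray  # (n_observations, n_components): obs ~= mixing @ whitened
    mean: np.ndarray  # per-observation mean removed before reduction
    explained_variance_ratio: np.ndarray
    rank: int

    def back_project(self, sources: np.ndarray | None = None) -> np.ndarray:
        z = self.whitened if sources is None else sources
        return self.mixing @ z + self.mean[:, None]


def _as_series(run: BoldRun | np.ndarray) -> np.ndarray:
    if isinstance(run, BoldRun):
        return run.masked_series()
    return np.asarray(run, dtype=float)


def pca_whiten(run: BoldRun | np.ndarray, n_components: int) -> PCAWhitening:
    """Reduce the (time x voxels) data to ``n_components`` whitened series.

    Rows of the result are uncorrelated with unit variance over voxels;
    ``mixing`` maps them back to the retained-variance part of the data.
    """
    X = _as_series(run)  # (T, V)
    T, V = X.shape
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(T, V) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the data rank ({rank} achievable)"
        )
    scale = np.sqrt(V)
    whitened = Vt[:n_components] * scale
    mixing = U[:, :n_components] * (s[:n_components] / scale)
    var = s**2
    return PCAWhitening(
        whitened=whitened,
        mixing=mixing,
        mean=mean,
        explained_variance_ratio=var[:n_components] / var.sum(),
        rank=rank,
    )


def _infomax_once(
    Z: np.ndarray, config: "ICAConfig", W0: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """One Infomax run from the initial unmixing matrix ``W0``."""
    n, N = Z.shape
    lrate = config.learning_rate
    # block size: sqrt(N/3) (classic heuristic) but no more than 32 blocks
    # per pass, so very large voxel counts do not pay per-block overhead
    block = max(int(np.floor(np.sqrt(N / 3.0))), int(np.ceil(N / 32)))
    block = max(min(block, N), 8) if N >= 8 else N
    W = W0.copy()
    bias = np.zeros((n, 1))
    signs = np.ones(n)  # +1 super-Gaussian, -1 sub-Gaussian
    old_W = W.copy()
    old_delta = None
    change = np.inf
    n_iter = 0
    anneal_cos = np.cos(np.deg2rad(config.anneal_deg))
    sub_idx = rng.choice(N, size=min(N, config.ext_subsample), replace=False)
    for n_iter in range(1, config.max_iter + 1):
        if config.extended:
            k = stats.kurtosis(W @ Z[:, sub_idx], axis=1, fisher=True)
            signs = np.where(k >= 0, 1.0, -1.0)
        perm = rng.permutation(N)
        blown_up = False
        for start in range(0, N - block + 1, block):
            x = Z[:, perm[start : start + block]]
            u = W @ x + bias
            if config.extended:
                y = np.tanh(u)
                grad = block * np.eye(n) - (signs[:, None] * y) @ u.T - u @ u.T
                W = W + lrate / block * grad @ W
                # tanh is odd and the whitened sources are zero-mean: no bias
                # term is needed in the extended variant
            else:
                y = 1.0 / (1.0 + np.exp(-u))
                grad = block * np.eye(n) + (1.0 - 2.0 * y) @ u.T
                W = W + lrate / block * grad @ W
                bias = bias + lrate / block * (1.0 - 2.0 * y).sum(axis=1, keepdims=True)
            if not np.isfinite(W).all() or np.abs(W).max() > 1e8:
                blown_up = True
                break
        if blown_up:
            lrate *= 0.5
            W = W0.copy()
            bias = np.zeros((n, 1))
            old_W = W.copy()
            old_delta = None
            continue
        delta = W - old_W
        change = float(np.sqrt((delta**2).sum() / n**2))
        if old_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(old_delta)
            if denom > 0 and (delta * old_delta).sum() / denom < anneal_cos:
                lrate *= config.anneal_scale
        old_delta = delta
        old_W = W.copy()
        lrate *= config.decay
        if change < config.tol:
            break
    converged = change < config.tol
    sources = W @ Z
    sd = sources.std(axis=1)
    sd[sd == 0] = 1.0
    W = W / sd[:, None]
    kurt = stats.kurtosis(sources / sd[:, None], axis=1, fisher=True)
    diagnostics = {
        "iterations": n_iter,
        "final_weight_change": change,
        "converged": bool(converged),
        "learning_rate": lrate,
        "source_kurtosis": kurt,
        "near_gaussian": bool(np.abs(kurt).max() < 0.1),
        "signs": signs.copy(),
        # model-selection score: mean absolute excess kurtosis of the
        # unit-variance sources (higher = more non-Gaussian = better unmixing)
        "nongaussianity": float(np.abs(kurt).mean()),
    }
    return W, diagnostics


def _random_orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def infomax_unmix(
    whitened: np.ndarray, config: "ICAConfig"
) -> tuple[np.ndarray, dict]:
    """Infomax unmixing of whitened data by natural-gradient ascent.

    Standard Bell-Sejnowski rule with a logistic nonlinearity, or the
    extended (kurtosis-switching tanh) variant when ``config.extended``.
    Training is block-stochastic over a seeded sample permutation with
    learning-rate annealing; each run stops when the weight change per pass
    drops below ``tol`` or at ``max_iter`` passes (recorded in the
    diagnostics; a non-convergence warning is emitted for the selected
    run).  Because natural-gradient ascent can stall in a local optimum
    where two sources stay mixed, ``n_restarts`` seeded runs are performed
    from different orthogonal initialisations and the run whose
    unit-variance sources are most non-Gaussian (largest mean |excess
    kurtosis|) is kept.  Rows of the returned unmixing matrix are scaled so
    the recovered sources have unit variance.  Deterministic given the
    config seed.
    """
    Z = np.asarray(whitened, dtype=float)
    n, N = Z.shape
    if n != config.n_components:
        raise ValueError("whitened rows must equal config.n_components")
    rng = np.random.default_rng(config.seed)
    best: tuple[np.ndarray, dict] | None = None
    scores = []
    for restart in range(max(config.n_restarts, 1)):
        W0 = np.eye(n) if restart == 0 else _random_orthogonal(n, rng)
        W, diag = _infomax_once(Z, config, W0, rng)
        scores.append(diag["nongaussianity"])
        if best is None or diag["nongaussianity"] > best[1]["nongaussianity"]:
            best = (W, diag)
    W, diagnostics = best
    diagnostics["restart_scores"] = scores
    if not diagnostics["converged"]:
        warnings.warn(
            f"Infomax did not converge in {config.max_iter} iterations "
            f"(final weight change {diagnostics['final_weight_change']:.2e})",
            RuntimeWarning,
        )
    return W, diagnostics


@dataclass(frozen=True)
class ICADecomposition:
    """Spatial maps (z-scored, positive skewness), time courses, diagnostics."""

    spatial_maps: tuple[StatMap, ...]
    time_courses: np.ndarray  # (time, n_components)
    diagnostics: dict = field(repr=False)
    config: ICAConfig = field(default_factory=ICAConfig)

    @property
    def n_components(self) -> int:
        return len(self.spatial_maps)


def decompose_rest(run: BoldRun, config: ICAConfig) -> ICADecomposition:
    """Spatial ICA of a (preprocessed) resting run.

    Components are ordered by the variance their time course explains; each
    spatial map is z-scored over the mask and sign-fixed so its skewness is
    non-negative, with the time course flipped consistently.
    """
    white = pca_whiten(run, config.n_components)
    W, diagnostics = infomax_unmix(white.whitened, config)
    sources = W @ white.whitened  # (k, V) unit variance
    time_courses = white.mixing @ np.linalg.inv(W)  # (T, k)
    # sign convention: positive skewness of each spatial source
    skew = stats.skew(sources, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    sources = sources * flip[:, None]
    time_courses = time_courses * flip[None, :]
    # order components by explained temporal variance
    order = np.argsort(-(time_courses**2).sum(axis=0), kind="stable")
    sources = sources[order]
    time_courses = time_courses[:, order]
    grid = run.grid
    mask = grid.brain_mask
    maps = []
    for k in range(config.n_components):
        z = (sources[k] - sources[k].mean()) / sources[k].std()
        vol = np.zeros(grid.shape)
        vol[mask] = z
        maps.append(StatMap(grid=grid, values=vol, kind="z"))
    return ICADecomposition(
        spatial_maps=tuple(maps),
        time_courses=time_courses,
        diagnostics=diagnostics,
        config=config,
    )


def threshold_component(zmap: StatMap, z: float = 2.0) -> StatMap:
    """Set values <= z to background (zero); the mask is preserved."""
    if np.isnan(z):
        raise ValueError("z must not be NaN")
    out = np.where(zmap.values > z, zmap.values, 0.0)
    out = np.where(zmap.grid.brain_mask, out, np.nan)
    return StatMap(grid=zmap.grid, values=out, kind=zmap.kind)
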