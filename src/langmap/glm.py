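"""Task-fMRI analysis: block design matrix with the canonical HRF, 128-s
discrete-cosine high-pass, voxel-wise ordinary least squares, t-contrasts,
and multiple-comparison thresholding.

Family-wise error control is Bonferroni over in-mask voxels (conservative;
random-field theory is deliberately not implemented).  Cluster-level FDR
forms clusters at an uncorrected voxel p, computes cluster p-values against
a permutation null of the maximum cluster size, and applies
Benjamini-Hochberg across clusters.  No prewhitening is applied: noise is
modelled white, which matches the synthetic generator and is a documented
limitation for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import PeakSet, StatMap, VolumeGrid, local_maxima
from .simulate import BlockDesign, BoldRun

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "ThresholdSpec",
    "canonical_hrf",
    "discard_initial_volumes",
    "build_design",
    "fit_glm",
    "t_contrast",
    "apply_threshold",
    "max_cluster_null_glm",
]

HIGHPASS_DEFAULT_S = 128.0
HRF_LENGTH_S = 32.0
N_DISCARD_DEFAULT = 3


def canonical_hrf(tr_s: float, length_s: float = HRF_LENGTH_S) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR.

    Difference of two gamma densities (response peak 6 s, undershoot peak
    16 s, unit dispersions, undershoot ratio 1/6) over ``length_s`` seconds,
    peak-normalised to 1.  Kernel length is floor(length/tr) + 1 samples.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be > 0")
    t = np.arange(int(np.floor(length_s / tr_s)) + 1) * tr_s
    h = stats.gamma.pdf(t, a=6.0) - stats.gamma.pdf(t, a=16.0) / 6.0
    return h / h.max()


def smooth_run(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Volume-wise mask-aware Gaussian smoothing of a 4-D run."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return run
    grid = run.grid
    sigma = fwhm_mm / (np.sqrt(8.0 * np.log(2.0)) * grid.voxel_size_mm)
    mask = grid.brain_mask
    data = np.where(mask[..., None], run.data, 0.0)
    num = ndimage.gaussian_filter(data, sigma=tuple(sigma) + (0.0,), mode="constant")
    den = ndimage.gaussian_filter(mask.astype(float), sigma=tuple(sigma), mode="constant")
    out = np.zeros_like(num)
    out[mask] = num[mask] / den[mask, None]
    return replace(run, data=out)


def discard_initial_volumes(run: BoldRun, n: int = N_DISCARD_DEFAULT) -> BoldRun:
    """Drop the first ``n`` volumes (magnetisation stabilisation period)."""
    if not 0 <= n < run.n_volumes:
        raise ValueError(f"n must satisfy 0 <= n < {run.n_volumes}, got {n}")
    if n == 0:
        return run
    track = run.condition_track[n:] if run.condition_track is not None else None
    return replace(run, data=run.data[..., n:], condition_track=track)


@dataclass(frozen=True)
class DesignMatrix:
    """Named-regressor design: task regressors, DCT drift set, intercept."""

    names: tuple[str, ...]
    values: np.ndarray  # (time, regressors)
    tr_s: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(self.names):
            raise ValueError("values must be (time, len(names))")
        rank = np.linalg.matrix_rank(values)
        if rank < values.shape[1]:
            collinear = _collinear_columns(values, self.names)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "values", values)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def _collinear_columns(values: np.ndarray, names) -> list[str]:
    # pivoted QR: columns whose diagonal collapses are the dependent ones
    from scipy.linalg import qr

    _, r, piv = qr(values, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(values.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(names)) if i >= len(diag) or diag[i] <= tol]


def dct_drift_basis(n_timepoints: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift columns for all frequencies below 1/cutoff Hz.

    The number of columns is floor(2 * run duration / cutoff); basis k is
    cos(pi * k * (t + 1/2) / N), the standard DCT-II set excluding the
    constant term.
    """
    duration = n_timepoints * tr_s
    n_basis = int(np.floor(2.0 * duration / cutoff_s))
    t = np.arange(n_timepoints)
    cols = [
        np.sqrt(2.0 / n_timepoints) * np.cos(np.pi * k * (t + 0.5) / n_timepoints)
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.zeros((n_timepoints, 0))


def build_design(
    design: BlockDesign,
    hrf: np.ndarray,
    n_timepoints: int,
    tr_s: float,
    highpass_cutoff_s: float = HIGHPASS_DEFAULT_S,
) -> DesignMatrix:
    """Design matrix: per-condition boxcars convolved with the HRF, the DCT
    high-pass drift set, and an intercept.  No global-signal column."""
    duration = n_timepoints * tr_s
    for cond, onsets in design.onsets.items():
        for onset in onsets:
            if onset < -1e-9 or onset >= duration:
                raise ValueError(f"onset {onset} of condition {cond!r} outside the run")
    names: list[str] = []
    cols: list[np.ndarray] = []
    for cond in design.onsets:
        box = design.boxcar(cond, n_timepoints, tr_s)
        cols.append(np.convolve(box, hrf)[:n_timepoints])
        names.append(cond)
    drift = dct_drift_basis(n_timepoints, tr_s, highpass_cutoff_s)
    for k in range(drift.shape[1]):
        names.append(f"drift_{k + 1}")
        cols.append(drift[:, k])
    names.append("intercept")
    cols.append(np.ones(n_timepoints))
    return DesignMatrix(names=tuple(names), values=np.column_stack(cols), tr_s=tr_s)


@dataclass(frozen=True)
class GlmFit:
    """Voxel-wise OLS fit: beta maps, residual variance, degrees of freedom."""

    design: DesignMatrix
    beta: dict[str, StatMap]
    sigma2: StatMap
    dof: int
    residuals: np.ndarray = field(repr=False)  # (time, in-mask voxels)

    @property
    def grid(self) -> VolumeGrid:
        return self.sigma2.grid


def fit_glm(run: BoldRun, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares per in-mask voxel."""
    if run.n_volumes != design.n_timepoints:
        raise ValueError(
            f"run has {run.n_volumes} volumes but the design has "
            f"{design.n_timepoints} rows"
        )
    X = design.values
    Y = run.masked_series()  # (T, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    rank = np.linalg.matrix_rank(X)
    dof = X.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    grid = run.grid
    mask = grid.brain_mask

    def to_map(vec: np.ndarray, kind: str) -> StatMap:
        vol = np.zeros(grid.shape)
        vol[mask] = vec
        return StatMap(grid=grid, values=vol, kind=kind)

    beta_maps = {name: to_map(beta[i], "beta") for i, name in enumerate(design.names)}
    return GlmFit(
        design=design,
        beta=beta_maps,
        sigma2=to_map(sigma2, "amplitude"),
        dof=int(dof),
        residuals=resid,
    )


def t_contrast(fit: GlmFit, contrast: Mapping[str, float] | None = None) -> StatMap:
    """Voxel-wise t statistic for a named contrast (default SG - TL).

    t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c); voxels with zero residual
    variance have an undefined t and are removed from the output mask.
    """
    if contrast is None:
        contrast = {"SG": 1.0, "TL": -1.0}
    names = fit.design.names
    for name in contrast:
        if name not in names:
            raise ValueError(f"unknown regressor {name!r}; design has {names}")
    c = np.array([contrast.get(name, 0.0) for name in names])
    X = fit.design.values
    xtx_inv = np.linalg.pinv(X.T @ X)
    var_scale = float(c @ xtx_inv @ c)
    grid = fit.grid
    mask = grid.brain_mask
    eff = sum(contrast[name] * fit.beta[name].values for name in contrast)
    s2 = fit.sigma2.values
    defined = mask & (s2 > 0)
    tvals = np.zeros(grid.shape)
    tvals[defined] = eff[defined] / np.sqrt(s2[defined] * var_scale)
    tvals[~defined] = np.nan
    return StatMap(grid=grid.with_mask(defined), values=np.where(defined, tvals, np.nan), kind="t")


@dataclass(frozen=True)
class ThresholdSpec:
    """Multiple-comparison rule: voxel-level FWE or cluster-level FDR."""

    family: str = "FWE_voxel"
    alpha: float = 0.05
    cluster_forming_p: float = 0.001
    min_cluster_voxels: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("FWE_voxel", "FDR_cluster"):
            raise ValueError("family must be 'FWE_voxel' or 'FDR_cluster'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


_CONNECTIVITY_26 = np.ones((3, 3, 3), bool)


def _cluster_sizes(suprathreshold: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(suprathreshold, structure=_CONNECTIVITY_26)
    return labels, n


def _cluster_table(tmap: StatMap, keep: np.ndarray, labels: np.ndarray, which: list[int]) -> pd.DataFrame:
    rows = []
    grid = tmap.grid
    for lab in which:
        in_cluster = labels == lab
        size = int(in_cluster.sum())
        vals = np.where(in_cluster, tmap.values, -np.inf)
        peak_idx = np.unravel_index(np.nanargmax(vals), grid.shape)
        xyz = grid.affine[:3, :3] @ np.array(peak_idx, float) + grid.affine[:3, 3]
        rows.append(
            {
                "k": size,
                "t": float(tmap.values[peak_idx]),
                "x": float(xyz[0]),
                "y": float(xyz[1]),
                "z": float(xyz[2]),
            }
        )
    df = pd.DataFrame(rows, columns=["k", "t", "x", "y", "z"])
    return df.sort_values(["k", "t"], ascending=False, ignore_index=True) if len(df) else df


def apply_threshold(
    tmap: StatMap,
    spec: ThresholdSpec,
    dof: int,
    null_max_cluster_sizes: np.ndarray | None = None,
) -> tuple[StatMap, pd.DataFrame]:
    """Threshold a t map and tabulate the surviving clusters.

    FWE_voxel: Bonferroni over in-mask voxels on the Student t distribution.
    FDR_cluster: clusters formed at voxel p < ``cluster_forming_p``
    (26-connectivity); each cluster's p-value is the proportion of
    permutation-null maximum cluster sizes at least as large, and
    Benjamini-Hochberg at ``alpha`` is applied across clusters.  The null
    distribution must be supplied (see :func:`max_cluster_null_glm` and the
    paired-comparison helpers).
    """
    if tmap.kind != "t":
        raise ValueError("apply_threshold expects a t map")
    if dof <= 0:
        raise ValueError("dof must be > 0")
    grid = tmap.grid
    mask = grid.brain_mask
    vals = np.where(mask, tmap.values, -np.inf)
    if spec.family == "FWE_voxel":
        n_mask = int(mask.sum())
        t_crit = stats.t.isf(spec.alpha / n_mask, dof)
        keep = vals > t_crit
        labels, n = _cluster_sizes(keep)
        which = [
            lab
            for lab in range(1, n + 1)
            if (labels == lab).sum() >= max(spec.min_cluster_voxels, 1)
        ]
        keep = np.isin(labels, which)
    else:
        if null_max_cluster_sizes is None:
            raise ValueError(
                "FDR_cluster needs a permutation null of maximum cluster sizes"
            )
        null = np.asarray(null_max_cluster_sizes)
        t_form = stats.t.isf(spec.cluster_forming_p, dof)
        labels, n = _cluster_sizes(vals > t_form)
        sizes = np.array([(labels == lab).sum() for lab in range(1, n + 1)])
        if n == 0:
            keep = np.zeros(grid.shape, bool)
            which = []
        else:
            pvals = (1.0 + (null[None, :] >= sizes[:, None]).sum(axis=1)) / (1.0 + len(null))
            # Benjamini-Hochberg across clusters
            order = np.argsort(pvals)
            m = len(pvals)
            passed = pvals[order] <= spec.alpha * (np.arange(1, m + 1) / m)
            k_max = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
            selected = set(order[:k_max].tolist())
            which = [
                lab
                for lab in range(1, n + 1)
                if (lab - 1) in selected and sizes[lab - 1] >= max(spec.min_cluster_voxels, 1)
            ]
            keep = np.isin(labels, which)
    table = _cluster_table(tmap, keep, labels, which)
    out = np.where(keep, tmap.values, 0.0)
    out = np.where(mask, out, np.nan)
    return StatMap(grid=grid, values=out, kind="t"), table


def max_cluster_null_glm(
    fit: GlmFit,
    contrast: Mapping[str, float],
    cluster_forming_p: float = 0.001,
    n_permutations: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Permutation null of the maximum suprathreshold cluster size.

    Freedman-Lane style: residuals of the full fit are permuted in time,
    refit against the design, and the contrast t map is clustered at the
    forming threshold.  Returns one maximum cluster size per permutation.
    """
    rng = np.random.default_rng(seed)
    X = fit.design.values
    names = fit.design.names
    c = np.array([contrast.get(name, 0.0) for name in names])
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.pinv(X.T @ X)
    var_scale = float(c @ xtx_inv @ c)
    dof = fit.dof
    t_form = stats.t.isf(cluster_forming_p, dof)
    grid = fit.grid
    mask = grid.brain_mask
    maxima = np.zeros(n_permutations, dtype=int)
    T = X.shape[0]
    for p in range(n_permutations):
        perm = rng.permutation(T)
        Yp = fit.residuals[perm]
        beta = pinv @ Yp
        resid = Yp - X @ beta
        s2 = (resid**2).sum(axis=0) / dof
        eff = c @ beta
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = eff / np.sqrt(s2 * var_scale)
        vol = np.zeros(grid.shape)
        vol[mask] = np.nan_to_num(tv, nan=0.0)
        labels, n = _cluster_sizes(vol > t_form)
        maxima[p] = max(((labels == lab).sum() for lab in range(1, n + 1)), default=0)
    return maxima


def threshold_peaks(
    tmap: StatMap,
    spec: ThresholdSpec,
    dof: int,
    min_separation_mm: float = 8.0,
    source: str = "",
    null_max_cluster_sizes: np.ndarray | None = None,
) -> tuple[StatMap, pd.DataFrame, PeakSet]:
    """Convenience: threshold a t map and extract peaks of the survivors."""
    thr, table = apply_threshold(tmap, spec, dof, null_max_cluster_sizes)
    peaks = local_maxima(thr, threshold=0.0, min_separation_mm=min_separation_mm, source=source)
    return thr, table, peaks
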