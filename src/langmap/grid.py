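"""Volume data model shared by every analysis stage.

Scalar maps live on a fixed 3-D raster in MNI space (RAS+ millimetres,
0-based voxel indices, a voxel's coordinate is its centre, affine stored in
the NIfTI sform).  The default grid is a 3 mm isotropic box spanning
MNI [-78, 78] x [-112, 76] x [-50, 103] with an ellipsoidal brain mask; the
voxel size is configurable so desk-scale analyses can run the same box at a
coarser resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "StatMap",
    "Peak",
    "PeakSet",
    "default_grid",
    "mni_to_voxel",
    "voxel_to_mni",
    "gaussian_smooth",
    "local_maxima",
    "read_stat_map",
    "write_stat_map",
    "peaks_to_tsv",
]

#: MNI bounding box of the default grid, mm (lower corner, upper corner).
DEFAULT_BOX = ((-78.0, -112.0, -50.0), (78.0, 76.0, 103.0))

STAT_KINDS = ("t", "z", "beta", "amplitude")


@dataclass(frozen=True)
class VolumeGrid:
    """A raster in MNI space: shape, voxel size, affine, and brain mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        mask = np.asarray(self.brain_mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError(
                f"mask shape {mask.shape} != grid shape {tuple(self.shape)}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "brain_mask", mask)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_mask_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def coordinate_grid(self) -> np.ndarray:
        """MNI coordinates of every voxel centre, shape (3, *grid.shape)."""
        idx = np.indices(self.shape, dtype=float)
        homo = np.concatenate([idx, np.ones((1,) + self.shape)], axis=0)
        return np.einsum("ij,j...->i...", self.affine[:3], homo)

    def with_mask(self, mask: np.ndarray) -> "VolumeGrid":
        return replace(self, brain_mask=np.asarray(mask, dtype=bool))


@dataclass(frozen=True)
class StatMap:
    """A scalar map on a :class:`VolumeGrid`.

    ``kind`` records the units of the values: a t-score, a z-score, a
    regression coefficient, or an arbitrary amplitude.  Non-finite values
    are only permitted outside the brain mask.
    """

    grid: VolumeGrid
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in STAT_KINDS:
            raise ValueError(f"kind must be one of {STAT_KINDS}, got {self.kind!r}")
        if not np.isfinite(values[self.grid.brain_mask]).all():
            raise ValueError("non-finite values inside the brain mask")
        object.__setattr__(self, "values", values)

    def masked(self) -> np.ndarray:
        """Values at in-mask voxels, 1-D."""
        return self.values[self.grid.brain_mask]


@dataclass(frozen=True)
class Peak:
    mni_xyz: tuple[float, float, float]
    value: float
    rank: int


@dataclass(frozen=True)
class PeakSet:
    """Local maxima of one map, sorted by descending value, ranks unique."""

    peaks: tuple[Peak, ...]
    source: str = ""

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks)
        values = [p.value for p in peaks]
        if any(b > a for a, b in zip(values, values[1:])):
            raise ValueError("peaks must be sorted by descending value")
        ranks = [p.rank for p in peaks]
        if len(set(ranks)) != len(ranks):
            raise ValueError("peak ranks must be unique")
        object.__setattr__(self, "peaks", peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def coordinates(self) -> np.ndarray:
        """(n, 3) array of peak MNI coordinates."""
        if not self.peaks:
            return np.zeros((0, 3))
        return np.array([p.mni_xyz for p in self.peaks], dtype=float)


def default_grid(voxel_size_mm: float = 3.0, mask_scale: float = 1.05) -> VolumeGrid:
    """The default whole-brain MNI box at the requested isotropic resolution.

    The brain mask is the box-inscribed ellipsoid inflated by ``mask_scale``
    so that peripheral structures (cerebellum, orbitofrontal cortex) used as
    network nodes fall inside it.
    """
    lo, hi = (np.asarray(c, dtype=float) for c in DEFAULT_BOX)
    shape = tuple(int(np.floor(e / voxel_size_mm)) + 1 for e in hi - lo)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = lo
    grid = VolumeGrid(shape=shape, affine=affine, brain_mask=np.ones(shape, bool))
    xyz = grid.coordinate_grid()
    upper = lo + (np.array(shape) - 1) * voxel_size_mm
    center = (lo + upper) / 2.0
    semi = mask_scale * (upper - lo) / 2.0
    r2 = sum(((xyz[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return grid.with_mask(r2 <= 1.0)


def voxel_to_mni(grid: VolumeGrid, ijk: Sequence[float]) -> np.ndarray:
    """MNI mm coordinate of a (possibly fractional) voxel index."""
    ijk = np.asarray(ijk, dtype=float)
    return grid.affine[:3, :3] @ ijk + grid.affine[:3, 3]


def mni_to_voxel(grid: VolumeGrid, xyz_mm: Sequence[float]) -> tuple[int, int, int]:
    """Nearest voxel index to an MNI coordinate.

    Raises ``ValueError`` (naming the coordinate) when the point lies outside
    the grid's bounding box, i.e. more than half a voxel beyond any face.
    """
    xyz = np.asarray(xyz_mm, dtype=float)
    cont = np.linalg.solve(grid.affine[:3, :3], xyz - grid.affine[:3, 3])
    if np.any(cont < -0.5) or np.any(cont > np.array(grid.shape) - 0.5):
        raise ValueError(f"coordinate {tuple(xyz)} lies outside the grid bounding box")
    return tuple(int(i) for i in np.round(cont).astype(int))


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    return fwhm_mm / (np.sqrt(8.0 * np.log(2.0)) * voxel_size)


def gaussian_smooth(stat_map: StatMap, fwhm_mm: float) -> StatMap:
    """Mask-aware Gaussian smoothing with the given full width at half maximum.

    The kernel standard deviation per axis is fwhm / (sqrt(8 ln 2) * voxel
    size).  Convolution is renormalised by the smoothed mask so a constant
    map stays constant up to the mask edge; out-of-mask voxels are zero.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return stat_map
    grid = stat_map.grid
    sigma = _fwhm_to_sigma_vox(fwhm_mm, grid.voxel_size_mm)
    mask = grid.brain_mask.astype(float)
    data = np.where(grid.brain_mask, stat_map.values, 0.0)
    num = ndimage.gaussian_filter(data, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(mask, sigma=sigma, mode="constant")
    out = np.zeros_like(num)
    inside = grid.brain_mask
    out[inside] = num[inside] / den[inside]
    return StatMap(grid=grid, values=out, kind=stat_map.kind)


def local_maxima(
    stat_map: StatMap,
    threshold: float,
    min_separation_mm: float = 8.0,
    source: str = "",
) -> PeakSet:
    """Suprathreshold 26-connected local maxima with greedy peak suppression.

    A voxel is a candidate when its value exceeds ``threshold`` and is >= all
    of its 26 neighbours (out-of-mask neighbours count as background zero is
    not assumed: comparison uses -inf outside the mask).  Candidates are then
    visited in descending value order (ties broken by flat voxel index) and a
    candidate within ``min_separation_mm`` of an already accepted peak is
    suppressed.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    grid = stat_map.grid
    vals = np.where(grid.brain_mask, stat_map.values, -np.inf)
    footprint = np.ones((3, 3, 3), bool)
    neigh_max = ndimage.maximum_filter(vals, footprint=footprint, mode="constant", cval=-np.inf)
    cand = (vals > threshold) & (vals >= neigh_max) & grid.brain_mask
    idx = np.argwhere(cand)
    if idx.size == 0:
        return PeakSet(peaks=(), source=source)
    flat = np.ravel_multi_index(idx.T, grid.shape)
    values = vals[tuple(idx.T)]
    order = np.lexsort((flat, -values))
    coords_mm = (grid.affine[:3, :3] @ idx[order].T).T + grid.affine[:3, 3]
    kept: list[int] = []
    for i in range(len(order)):
        p = coords_mm[i]
        if all(np.linalg.norm(p - coords_mm[j]) >= min_separation_mm for j in kept):
            kept.append(i)
    peaks = tuple(
        Peak(mni_xyz=tuple(coords_mm[i]), value=float(values[order[i]]), rank=r + 1)
        for r, i in enumerate(kept)
    )
    return PeakSet(peaks=peaks, source=source)


def write_stat_map(stat_map: StatMap, path: str | Path) -> None:
    """Write a map as NIfTI-1; out-of-mask voxels are stored as NaN."""
    data = np.where(stat_map.grid.brain_mask, stat_map.values, np.nan)
    img = nib.Nifti1Image(data.astype(np.float64), stat_map.grid.affine)
    img.header.set_sform(stat_map.grid.affine, code=4)  # MNI space
    img.header.set_qform(stat_map.grid.affine, code=4)
    nib.save(img, str(path))


def read_stat_map(path: str | Path, kind: str = "amplitude") -> StatMap:
    """Read a NIfTI map; the mask is wherever the stored values are finite."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    mask = np.isfinite(data)
    grid = VolumeGrid(shape=data.shape, affine=img.affine, brain_mask=mask)
    return StatMap(grid=grid, values=np.where(mask, data, np.nan), kind=kind)


def peaks_to_tsv(peak_sets: Iterable[PeakSet], path: str | Path) -> pd.DataFrame:
    """Export peak sets as TSV with columns source, rank, x, y, z, value."""
    rows = [
        {
            "source": ps.source,
            "rank": p.rank,
            "x": p.mni_xyz[0],
            "y": p.mni_xyz[1],
            "z": p.mni_xyz[2],
            "value": p.value,
        }
        for ps in peak_sets
        for p in ps
    ]
    df = pd.DataFrame(rows, columns=["source", "rank", "x", "y", "z", "value"])
    df.to_csv(path, sep="\t", index=False)
    return df
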