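"""Synthetic BOLD runs in template space, with ground truth.

The study's raw imaging data are not shared, so this module generates
resting-state and task runs carrying the statistical structure the analysis
assumes: resting runs are sums of spatial network maps (each a mixture of
isotropic Gaussians at anatomical node coordinates) modulated by independent
band-limited (0.01-0.1 Hz) non-Gaussian time courses plus white noise; task
runs add a block design (16 s sentence-generation / tone-listening epochs)
convolved with the canonical haemodynamic response, a slow polynomial drift,
and white noise.  Every generator is a pure function of its arguments
including the seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .grid import StatMap, VolumeGrid, mni_to_voxel

__all__ = [
    "NetworkTemplate",
    "BlockDesign",
    "BoldRun",
    "default_network_templates",
    "render_network_map",
    "band_limited_series",
    "simulate_rest_run",
    "simulate_task_run",
]

TR_DEFAULT_S = 2.28
N_VOLUMES_DEFAULT = 270
BAND_DEFAULT_HZ = (0.01, 0.1)
EPOCH_DEFAULT_S = 16.0


@dataclass(frozen=True)
class NetworkTemplate:
    """A named network as a set of (MNI node, amplitude, spatial sigma) triples."""

    name: str
    nodes: tuple[tuple[tuple[float, float, float], float, float], ...]

    def __post_init__(self) -> None:
        nodes = tuple(
            (tuple(float(c) for c in xyz), float(a), float(s))
            for xyz, a, s in self.nodes
        )
        if not nodes:
            raise ValueError("template needs at least one node")
        for xyz, amp, sigma in nodes:
            if not np.isfinite(amp) or amp < 0:
                raise ValueError(f"node amplitude must be finite and >= 0, got {amp}")
            if sigma <= 0:
                raise ValueError(f"node sigma must be > 0, got {sigma}")
        object.__setattr__(self, "nodes", nodes)

    def node_coordinates(self) -> np.ndarray:
        return np.array([xyz for xyz, _, _ in self.nodes], dtype=float)


@dataclass(frozen=True)
class BlockDesign:
    """Non-overlapping task epochs tiling (part of) a run.

    ``onsets`` maps condition name -> onset times in seconds; every epoch
    lasts ``epoch_s`` seconds.  Remaining run time is implicit baseline.
    """

    epoch_s: float = EPOCH_DEFAULT_S
    onsets: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be > 0")
        onsets = {c: tuple(float(t) for t in ts) for c, ts in self.onsets.items()}
        starts = sorted(t for ts in onsets.values() for t in ts)
        for a, b in zip(starts, starts[1:]):
            if b < a + self.epoch_s - 1e-9:
                raise ValueError("epochs overlap")
        object.__setattr__(self, "onsets", onsets)

    @classmethod
    def alternating(
        cls,
        n_volumes: int,
        tr_s: float = TR_DEFAULT_S,
        epoch_s: float = EPOCH_DEFAULT_S,
        start_s: float = 0.0,
        conditions: Sequence[str] = ("SG", "TL"),
    ) -> "BlockDesign":
        """Alternating-condition design tiling the run; the tail that does
        not fit a whole epoch is left as baseline."""
        duration = n_volumes * tr_s
        n_epochs = int(np.floor((duration - start_s) / epoch_s))
        onsets: dict[str, list[float]] = {c: [] for c in conditions}
        for k in range(n_epochs):
            onsets[conditions[k % len(conditions)]].append(start_s + k * epoch_s)
        return cls(epoch_s=epoch_s, onsets={c: tuple(v) for c, v in onsets.items()})

    @property
    def n_epochs(self) -> int:
        return sum(len(ts) for ts in self.onsets.values())

    @property
    def end_s(self) -> float:
        ends = [t + self.epoch_s for ts in self.onsets.values() for t in ts]
        return max(ends) if ends else 0.0

    def shifted(self, dt_s: float) -> "BlockDesign":
        return BlockDesign(
            epoch_s=self.epoch_s,
            onsets={c: tuple(t + dt_s for t in ts) for c, ts in self.onsets.items()},
        )

    def boxcar(self, condition: str, n_volumes: int, tr_s: float) -> np.ndarray:
        """Condition indicator sampled at volume times i * tr."""
        t = np.arange(n_volumes) * tr_s
        box = np.zeros(n_volumes)
        for onset in self.onsets.get(condition, ()):
            box[(t >= onset - 1e-9) & (t < onset + self.epoch_s - 1e-9)] = 1.0
        return box

    def condition_track(self, n_volumes: int, tr_s: float) -> np.ndarray:
        track = np.full(n_volumes, "rest", dtype=object)
        for cond in self.onsets:
            track[self.boxcar(cond, n_volumes, tr_s) > 0] = cond
        return track.astype(str)


@dataclass(frozen=True)
class BoldRun:
    """A 4-D BOLD time series with acquisition metadata and ground truth."""

    grid: VolumeGrid
    data: np.ndarray  # (x, y, z, time)
    tr_s: float = TR_DEFAULT_S
    condition_track: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.shape[:3] != self.grid.shape:
            raise ValueError("data spatial shape must equal grid shape")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")
        if self.condition_track is not None and len(self.condition_track) != data.shape[3]:
            raise ValueError("condition_track length must equal n_volumes")
        object.__setattr__(self, "data", data)

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    def masked_series(self) -> np.ndarray:
        """In-mask data as (time, voxels)."""
        return self.data[self.grid.brain_mask].T


def default_network_templates() -> dict[str, NetworkTemplate]:
    """The shipped LANG/VAN/SN/DAN/lFPC/DMN/VIS template set."""
    ref = importlib.resources.files("langmap.data") / "templates.yaml"
    raw = yaml.safe_load(ref.read_text())
    return {
        name: NetworkTemplate(
            name=name,
            nodes=tuple(((x, y, z), amp, sigma) for x, y, z, amp, sigma in nodes),
        )
        for name, nodes in raw.items()
    }


def render_network_map(template: NetworkTemplate, grid: VolumeGrid) -> StatMap:
    """Spatialise a template as a sum of isotropic Gaussians at its nodes."""
    for xyz, _, _ in template.nodes:
        mni_to_voxel(grid, xyz)  # raises if a node is outside the grid box
    coords = grid.coordinate_grid()
    out = np.zeros(grid.shape)
    for xyz, amp, sigma in template.nodes:
        if amp == 0:
            continue
        d2 = sum((coords[a] - xyz[a]) ** 2 for a in range(3))
        out += amp * np.exp(-d2 / (2.0 * sigma**2))
    out[~grid.brain_mask] = 0.0
    return StatMap(grid=grid, values=out, kind="amplitude")


def band_limited_series(
    n_volumes: int,
    tr_s: float,
    band_hz: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance band-limited series with Laplacian (super-Gaussian)
    innovations, so its marginal keeps positive excess kurtosis."""
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 < low < high <= nyquist):
        raise ValueError(
            f"band {band_hz} must satisfy 0 < low < high <= Nyquist ({nyquist:.4f} Hz)"
        )
    e = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=n_volumes)
    spec = np.fft.rfft(e)
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    spec[(freqs < low) | (freqs > high)] = 0.0
    s = np.fft.irfft(spec, n=n_volumes)
    sd = s.std()
    if sd == 0:
        raise ValueError("band too narrow: no frequency bins fall inside it")
    return s / sd


def simulate_rest_run(
    templates: Sequence[NetworkTemplate],
    grid: VolumeGrid,
    n_volumes: int = N_VOLUMES_DEFAULT,
    tr_s: float = TR_DEFAULT_S,
    band_hz: tuple[float, float] = BAND_DEFAULT_HZ,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> BoldRun:
    """Resting-state run: sum over networks of (spatial map x band-limited
    time course) plus in-mask white Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mask = grid.brain_mask
    n_vox = int(mask.sum())
    series = np.zeros((n_volumes, n_vox))
    gt_maps: dict[str, StatMap] = {}
    gt_tc: dict[str, np.ndarray] = {}
    for tpl in templates:
        smap = render_network_map(tpl, grid)
        tc = band_limited_series(n_volumes, tr_s, band_hz, rng)
        series += np.outer(tc, smap.values[mask])
        gt_maps[tpl.name] = smap
        gt_tc[tpl.name] = tc
    if noise_sd > 0:
        series += noise_sd * rng.standard_normal(series.shape)
    data = np.zeros(grid.shape + (n_volumes,))
    data[mask] = series.T
    return BoldRun(
        grid=grid,
        data=data,
        tr_s=tr_s,
        ground_truth={"maps": gt_maps, "time_courses": gt_tc},
        seed=seed,
    )


def _polynomial_drift(
    n_volumes: int, order: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Slow trend as a random combination of Legendre polynomials 1..order
    with 1/k-weighted coefficients (a 1/f-ish drift)."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    drift = np.zeros(n_volumes)
    for k in range(1, order + 1):
        coeffs = np.zeros(k + 1)
        coeffs[k] = 1.0
        drift += rng.normal(0.0, 1.0 / k) * np.polynomial.legendre.legval(x, coeffs)
    sd = drift.std()
    return amplitude * drift / sd if sd > 0 else drift


def simulate_task_run(
    active_template: NetworkTemplate,
    design: BlockDesign,
    grid: VolumeGrid,
    n_volumes: int = N_VOLUMES_DEFAULT,
    tr_s: float = TR_DEFAULT_S,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    drift_amplitude: float = 1.0,
    drift_order: int = 3,
    hrf_kernel: np.ndarray | None = None,
    seed: int = 0,
) -> BoldRun:
    """Task run: active map x (SG boxcar convolved with the HRF), scaled by
    ``effect_size``, plus a global slow drift and in-mask white noise."""
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if design.end_s > n_volumes * tr_s + 1e-9:
        raise ValueError(
            f"design ends at {design.end_s:.2f} s but the run lasts {n_volumes * tr_s:.2f} s"
        )
    if hrf_kernel is None:
        from .glm import canonical_hrf

        hrf_kernel = canonical_hrf(tr_s)
    rng = np.random.default_rng(seed)
    mask = grid.brain_mask
    smap = render_network_map(active_template, grid)
    box = design.boxcar("SG", n_volumes, tr_s)
    regressor = np.convolve(box, hrf_kernel)[:n_volumes]
    series = effect_size * np.outer(regressor, smap.values[mask])
    if drift_amplitude > 0 and drift_order > 0:
        series += _polynomial_drift(n_volumes, drift_order, drift_amplitude, rng)[:, None]
    if noise_sd > 0:
        series += noise_sd * rng.standard_normal(series.shape)
    data = np.zeros(grid.shape + (n_volumes,))
    data[mask] = series.T
    return BoldRun(
        grid=grid,
        data=data,
        tr_s=tr_s,
        condition_track=design.condition_track(n_volumes, tr_s),
        ground_truth={"maps": {active_template.name: smap}, "regressor": regressor},
        seed=seed,
    )
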