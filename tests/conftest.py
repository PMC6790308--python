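"""Shared fixtures: compact synthetic grids, templates, and decompositions.

Heavy simulations are session-scoped so the suite pays for each once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from langmap import (
    ICAConfig,
    decompose_rest,
    default_grid,
    default_network_templates,
    discard_initial_volumes,
    gaussian_smooth,
    simulate_rest_run,
    smooth_run,
)
from langmap.grid import VolumeGrid
from langmap.simulate import NetworkTemplate, render_network_map

#: node sets for six mutually distinguishable compact networks in a
#: 60-mm box (pairwise spatial correlation < 0.1 after smoothing)
COMPACT_NODE_SETS = [
    [(9, 9, 9), (48, 48, 48)],
    [(48, 9, 9), (9, 48, 48)],
    [(9, 48, 9), (48, 9, 48)],
    [(9, 9, 48), (48, 48, 9)],
    [(28, 28, 9), (28, 9, 28)],
    [(9, 28, 28), (48, 28, 28)],
]


def make_compact_grid(n: int = 20, voxel_mm: float = 3.0) -> VolumeGrid:
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    shape = (n, n, n)
    return VolumeGrid(shape=shape, affine=affine, brain_mask=np.ones(shape, bool))


def make_compact_templates(amplitude: float = 1.0, sigma: float = 6.0):
    return [
        NetworkTemplate(
            name=f"N{i}",
            nodes=tuple(((x, y, z), amplitude, sigma) for x, y, z in nodes),
        )
        for i, nodes in enumerate(COMPACT_NODE_SETS)
    ]


def make_fitting_template(
    grid: VolumeGrid, name: str = "N0", amplitude: float = 1.0, sigma: float = 6.0
) -> NetworkTemplate:
    """A two-node template guaranteed to lie inside the given grid box."""
    upper = (np.array(grid.shape) - 1) * grid.voxel_size_mm
    a = tuple(0.3 * upper)
    b = tuple(0.7 * upper)
    return NetworkTemplate(
        name=name, nodes=((a, amplitude, sigma), (b, amplitude, sigma))
    )


def best_assignment(gt_maps: np.ndarray, comp_maps: np.ndarray) -> np.ndarray:
    """Optimal one-to-one |correlation| between ground-truth and component
    maps (rows flattened); returns the per-ground-truth matched values."""
    k = gt_maps.shape[0]
    C = np.abs(np.corrcoef(np.vstack([gt_maps, comp_maps]))[:k, k:])
    r, c = linear_sum_assignment(-C)
    return C[r, c]


@pytest.fixture(scope="session")
def compact_grid() -> VolumeGrid:
    return make_compact_grid()


@pytest.fixture(scope="session")
def compact_templates():
    return make_compact_templates()


@pytest.fixture(scope="session")
def compact_gt_maps(compact_grid, compact_templates) -> np.ndarray:
    return np.stack(
        [
            gaussian_smooth(render_network_map(t, compact_grid), 6.0).values.ravel()
            for t in compact_templates
        ]
    )


@pytest.fixture(scope="session")
def compact_rest_run(compact_grid, compact_templates):
    run = simulate_rest_run(
        compact_templates, compact_grid, n_volumes=150, noise_sd=1.0, seed=1
    )
    return smooth_run(discard_initial_volumes(run, 3), 6.0)


@pytest.fixture(scope="session")
def compact_decomp(compact_rest_run):
    return decompose_rest(compact_rest_run, ICAConfig(n_components=10, seed=1))


@pytest.fixture(scope="session")
def mni_grid():
    return default_grid(3.0)


@pytest.fixture(scope="session")
def mni_templates():
    return default_network_templates()


@pytest.fixture(scope="session")
def mni_rest_decomp(mni_grid, mni_templates):
    """One preprocessed default-template resting run, decomposed."""
    run = simulate_rest_run(
        list(mni_templates.values()), mni_grid, n_volumes=150, noise_sd=1.0, seed=1
    )
    run = smooth_run(discard_initial_volumes(run, 3), 6.0)
    return decompose_rest(run, ICAConfig(n_components=10, seed=1))


@pytest.fixture(scope="session")
def mni_gt_maps(mni_grid, mni_templates):
    names = list(mni_templates)
    maps = np.stack(
        [
            gaussian_smooth(render_network_map(mni_templates[n], mni_grid), 6.0)
            .values[mni_grid.brain_mask]
            for n in names
        ]
    )
    return names, maps
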