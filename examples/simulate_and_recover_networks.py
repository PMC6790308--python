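"""Plant six resting-state networks in a synthetic BOLD run and recover
them with spatial Infomax ICA.

Builds a 20x20x20 voxel box (3 mm), plants six two-node Gaussian networks
with independent 0.01-0.1 Hz time courses plus unit white noise, runs the
preprocessing + ICA chain, and prints the best-assignment spatial
correlation between each planted map and its recovered component.  Values
near 1 mean the decomposition found the planted network almost exactly.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from langmap import (
    ICAConfig,
    decompose_rest,
    discard_initial_volumes,
    gaussian_smooth,
    render_network_map,
    simulate_rest_run,
    smooth_run,
)
from langmap.grid import VolumeGrid
from langmap.simulate import NetworkTemplate

affine = np.eye(4)
affine[:3, :3] *= 3.0
grid = VolumeGrid(shape=(20, 20, 20), affine=affine, brain_mask=np.ones((20, 20, 20), bool))

node_sets = [
    [(9, 9, 9), (48, 48, 48)], [(48, 9, 9), (9, 48, 48)], [(9, 48, 9), (48, 9, 48)],
    [(9, 9, 48), (48, 48, 9)], [(28, 28, 9), (28, 9, 28)], [(9, 28, 28), (48, 28, 28)],
]
templates = [
    NetworkTemplate(name=f"N{i}", nodes=tuple(((x, y, z), 1.0, 6.0) for x, y, z in ns))
    for i, ns in enumerate(node_sets)
]

run = simulate_rest_run(templates, grid, n_volumes=150, noise_sd=1.0, seed=1)
run = smooth_run(discard_initial_volumes(run, 3), fwhm_mm=6.0)
decomp = decompose_rest(run, ICAConfig(n_components=10, seed=1))

gt = np.stack(
    [gaussian_smooth(render_network_map(t, grid), 6.0).values.ravel() for t in templates]
)
comp = np.stack([m.values.ravel() for m in decomp.spatial_maps])
C = np.abs(np.corrcoef(np.vstack([gt, comp]))[: len(templates), len(templates):])
rows, cols = linear_sum_assignment(-C)

print("planted network -> matched component (|spatial correlation|)")
for i, j in zip(rows, cols):
    print(f"  {templates[i].name} -> IC{j}   r = {C[i, j]:.3f}")
print(f"\nInfomax converged in {decomp.diagnostics['iterations']} passes; "
      f"correlations >= 0.9 mean the planted networks were recovered.")
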