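"""Volume grid, coordinates, smoothing, peak extraction, NIfTI round-trip."""

from __future__ import annotations

import numpy as np
import pytest

from langmap import (
    StatMap,
    default_grid,
    gaussian_smooth,
    local_maxima,
    mni_to_voxel,
    peaks_to_tsv,
    read_stat_map,
    voxel_to_mni,
    write_stat_map,
)
from langmap.grid import PeakSet, Peak

from conftest import make_compact_grid


@pytest.fixture(scope="module")
def grid():
    return default_grid(3.0)


class TestCoordinates:
    def test_affine_origin_is_voxel_zero(self, grid):
        origin = grid.affine[:3, 3]
        assert mni_to_voxel(grid, origin) == (0, 0, 0)

    def test_round_trip_voxel(self, grid):
        xyz = voxel_to_mni(grid, (10, 12, 7))
        assert mni_to_voxel(grid, xyz) == (10, 12, 7)

    def test_round_trip_within_half_voxel(self, grid):
        rng = np.random.default_rng(0)
        for _ in range(50):
            xyz = rng.uniform([-70, -100, -40], [70, 60, 90])
            ijk = mni_to_voxel(grid, xyz)
            back = voxel_to_mni(grid, ijk)
            assert np.all(np.abs(back - xyz) <= grid.voxel_size_mm / 2 + 1e-9)

    def test_nearest_voxel_matches_exhaustive_scan(self, grid):
        # oracle: brute-force nearest voxel-centre search over the whole grid
        target = np.array([-63.0, -28.0, -9.0])  # left middle temporal gyrus
        coords = grid.coordinate_grid()
        d2 = sum((coords[a] - target[a]) ** 2 for a in range(3))
        oracle = np.unravel_index(np.argmin(d2), grid.shape)
        assert mni_to_voxel(grid, target) == tuple(oracle)

    def test_out_of_box_coordinate_raises_naming_it(self, grid):
        with pytest.raises(ValueError, match="500"):
            mni_to_voxel(grid, (500.0, 0.0, 0.0))

    def test_mask_invariants(self, grid):
        assert grid.brain_mask.shape == grid.shape
        assert np.all(grid.voxel_size_mm > 0)
        assert abs(np.linalg.det(grid.affine[:3, :3])) > 0


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, grid):
        rng = np.random.default_rng(1)
        m = StatMap(grid=grid, values=rng.standard_normal(grid.shape), kind="z")
        out = gaussian_smooth(m, 0.0)
        assert out is m

    def test_constant_map_stays_constant_inside_mask(self):
        g = make_compact_grid(16)
        m = StatMap(grid=g, values=np.full(g.shape, 3.5), kind="amplitude")
        out = gaussian_smooth(m, 8.0)
        assert np.allclose(out.values[g.brain_mask], 3.5, atol=1e-9)

    def test_impulse_matches_separable_gaussian(self):
        g = make_compact_grid(21)
        vals = np.zeros(g.shape)
        vals[10, 10, 10] = 1.0
        out = gaussian_smooth(StatMap(grid=g, values=vals, kind="amplitude"), 6.0)
        sigma_vox = 6.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 3.0
        ax = np.arange(21) - 10.0
        k1 = np.exp(-(ax**2) / (2 * sigma_vox**2))
        k1 /= k1.sum()
        expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        assert np.abs(out.values - expected).max() < 1e-3 * expected.max()

    def test_negative_fwhm_raises(self, grid):
        m = StatMap(grid=grid, values=np.zeros(grid.shape), kind="z")
        with pytest.raises(ValueError):
            gaussian_smooth(m, -1.0)

    def test_conserves_in_mask_sum_of_compact_support(self):
        g = make_compact_grid(30)
        vals = np.zeros(g.shape)
        vals[13:17, 13:17, 13:17] = 2.0  # support far from the mask edge
        out = gaussian_smooth(StatMap(grid=g, values=vals, kind="amplitude"), 6.0)
        assert abs(out.values.sum() - vals.sum()) / vals.sum() < 0.01


def brute_force_peaks(values: np.ndarray, threshold: float, min_sep_vox: float):
    """Independent oracle: exhaustive 26-neighbour scan + greedy suppression."""
    shape = values.shape
    candidates = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                v = values[i, j, k]
                if v <= threshold:
                    continue
                is_max = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            if di == dj == dk == 0:
                                continue
                            ni, nj, nk = i + di, j + dj, k + dk
                            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                                if values[ni, nj, nk] > v:
                                    is_max = False
                if is_max:
                    candidates.append((v, (i, j, k)))
    candidates.sort(key=lambda t: (-t[0], np.ravel_multi_index(t[1], shape)))
    kept = []
    for v, idx in candidates:
        p = np.array(idx, float)
        if all(np.linalg.norm(p - np.array(q, float)) >= min_sep_vox for _, q in kept):
            kept.append((v, idx))
    return kept


class TestLocalMaxima:
    def test_all_zero_map_gives_empty_set(self):
        g = make_compact_grid(10)
        m = StatMap(grid=g, values=np.zeros(g.shape), kind="z")
        assert len(local_maxima(m, threshold=2.0)) == 0

    def test_two_separated_impulses_both_found_larger_first(self):
        g = make_compact_grid(20)
        vals = np.zeros(g.shape)
        vals[2, 2, 2] = 3.0
        vals[12, 12, 12] = 5.0  # 30 mm along each axis
        peaks = local_maxima(
            StatMap(grid=g, values=vals, kind="z"), threshold=1.0, min_separation_mm=8.0
        )
        assert len(peaks) == 2
        assert peaks.peaks[0].value == 5.0
        assert peaks.peaks[0].rank == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_on_random_smooth_maps(self, seed):
        g = make_compact_grid(20)
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal(g.shape)
        smooth = gaussian_smooth(StatMap(grid=g, values=raw, kind="z"), 9.0)
        peaks = local_maxima(smooth, threshold=0.05, min_separation_mm=8.0)
        oracle = brute_force_peaks(smooth.values, 0.05, 8.0 / 3.0)
        assert len(peaks) == len(oracle)
        for got, (v, idx) in zip(peaks, oracle):
            assert got.value == pytest.approx(v)
            assert mni_to_voxel(g, got.mni_xyz) == idx

    def test_min_separation_suppresses_nearby_peaks(self):
        g = make_compact_grid(20)
        vals = np.zeros(g.shape)
        vals[5, 5, 5] = 4.0
        vals[5, 5, 7] = 3.0  # 6 mm away
        peaks = local_maxima(
            StatMap(grid=g, values=vals, kind="z"), threshold=1.0, min_separation_mm=8.0
        )
        assert len(peaks) == 1 and peaks.peaks[0].value == 4.0


class TestNiftiRoundTrip:
    def test_values_exact_affine_close(self, tmp_path):
        g = default_grid(6.0)
        rng = np.random.default_rng(3)
        vals = np.where(g.brain_mask, rng.standard_normal(g.shape), np.nan)
        m = StatMap(grid=g, values=vals, kind="t")
        path = tmp_path / "map.nii.gz"
        write_stat_map(m, path)
        back = read_stat_map(path, kind="t")
        assert np.array_equal(
            back.values[back.grid.brain_mask], m.values[g.brain_mask]
        )
        assert np.abs(back.grid.affine - g.affine).max() < 1e-6
        assert np.array_equal(back.grid.brain_mask, g.brain_mask)


def test_peaks_tsv_has_contract_columns(tmp_path):
    ps = PeakSet(
        peaks=(
            Peak(mni_xyz=(-63.0, -28.0, -9.0), value=5.0, rank=1),
            Peak(mni_xyz=(57.0, -55.0, 36.0), value=3.0, rank=2),
        ),
        source="IC3",
    )
    df = peaks_to_tsv([ps], tmp_path / "peaks.tsv")
    assert list(df.columns) == ["source", "rank", "x", "y", "z", "value"]
    assert (tmp_path / "peaks.tsv").read_text().splitlines()[0].split("\t") == [
        "source", "rank", "x", "y", "z", "value"
    ]


def test_peakset_rejects_unsorted_or_duplicate_ranks():
    with pytest.raises(ValueError):
        PeakSet(peaks=(Peak((0, 0, 0), 1.0, 1), Peak((9, 9, 9), 2.0, 2)))
    with pytest.raises(ValueError):
        PeakSet(peaks=(Peak((0, 0, 0), 2.0, 1), Peak((9, 9, 9), 1.0, 1)))


def test_statmap_rejects_nonfinite_inside_mask():
    g = make_compact_grid(8)
    vals = np.zeros(g.shape)
    vals[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        StatMap(grid=g, values=vals, kind="z")
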