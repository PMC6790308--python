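"""Design matrix, HRF, OLS fitting, t-contrasts, thresholding."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from langmap import (
    BlockDesign,
    ThresholdSpec,
    apply_threshold,
    build_design,
    canonical_hrf,
    discard_initial_volumes,
    fit_glm,
    simulate_task_run,
    t_contrast,
)
from langmap.glm import dct_drift_basis, max_cluster_null_glm
from langmap.grid import StatMap

from conftest import make_compact_grid, make_fitting_template


class TestCanonicalHrf:
    def test_peaks_near_five_seconds(self):
        h = canonical_hrf(0.01)
        t_peak = np.argmax(h) * 0.01
        assert t_peak == pytest.approx(5.0, abs=0.05)

    def test_length_at_protocol_tr(self):
        assert len(canonical_hrf(2.28)) == 15  # floor(32 / 2.28) + 1

    def test_integral_positive_and_peak_normalised(self):
        h = canonical_hrf(0.5)
        assert h.sum() > 0
        assert h.max() == pytest.approx(1.0)

    def test_matches_reference_double_gamma(self):
        # independent oracle: nilearn's SPM HRF on a fine grid, sampled at
        # our kernel's times and peak-normalised
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        tr, over = 1.0, 50
        ours = canonical_hrf(tr)
        fine = spm_hrf(tr, oversampling=over)
        fine_t = np.arange(len(fine)) * tr / over
        ref = np.array(
            [fine[np.argmin(np.abs(fine_t - k * tr))] for k in range(len(ours))]
        )
        ref = ref / ref.max()
        assert np.corrcoef(ours, ref)[0, 1] > 0.999

    def test_invalid_tr_raises(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestDiscard:
    def test_270_becomes_267(self):
        g = make_compact_grid(8)
        t = make_fitting_template(g)
        d = BlockDesign.alternating(270, 2.28, start_s=3 * 2.28)
        run = simulate_task_run(t, d, g, n_volumes=270, seed=0)
        out = discard_initial_volumes(run, 3)
        assert out.n_volumes == 267
        assert np.array_equal(out.condition_track, run.condition_track[3:])

    def test_zero_is_identity_and_full_raises(self):
        g = make_compact_grid(8)
        t = make_fitting_template(g)
        d = BlockDesign.alternating(30, 2.28)
        run = simulate_task_run(t, d, g, n_volumes=30, seed=0)
        assert discard_initial_volumes(run, 0) is run
        with pytest.raises(ValueError):
            discard_initial_volumes(run, 30)


class TestBuildDesign:
    def test_dct_column_count_at_protocol_length(self):
        # 267 volumes x 2.28 s = 608.76 s -> floor(2 * 608.76 / 128) = 9
        d = BlockDesign.alternating(267, 2.28)
        X = build_design(d, canonical_hrf(2.28), 267, 2.28, 128.0)
        drift_cols = [n for n in X.names if n.startswith("drift_")]
        assert len(drift_cols) == 9

    def test_short_run_has_no_drift_columns(self):
        assert dct_drift_basis(40, 2.28, 128.0).shape[1] == 1  # 91.2 s run
        assert dct_drift_basis(20, 2.28, 128.0).shape[1] == 0  # 45.6 s run

    def test_task_regressors_anticorrelated(self):
        d = BlockDesign.alternating(267, 2.28)
        X = build_design(d, canonical_hrf(2.28), 267, 2.28)
        r = np.corrcoef(X.column("SG"), X.column("TL"))[0, 1]
        assert r < 0

    def test_onset_outside_run_raises(self):
        d = BlockDesign(epoch_s=16.0, onsets={"SG": (700.0,)})
        with pytest.raises(ValueError):
            build_design(d, canonical_hrf(2.28), 267, 2.28)

    def test_rank_deficient_design_names_columns(self):
        from langmap.glm import DesignMatrix

        col = np.sin(np.arange(20))
        with pytest.raises(ValueError, match="collinear"):
            DesignMatrix(
                names=("SG", "TL", "intercept"),
                values=np.column_stack([col, col, np.ones(20)]),
                tr_s=2.28,
            )

    def test_no_global_signal_column(self):
        d = BlockDesign.alternating(100, 2.28)
        X = build_design(d, canonical_hrf(2.28), 100, 2.28)
        assert set(X.names) == {"SG", "TL", "intercept"} | {
            n for n in X.names if n.startswith("drift_")
        }


def _planted_run(n_volumes=150, noise_sd=0.0, drift_amplitude=0.0, seed=0, effect=1.0):
    g = make_compact_grid(12)
    t = make_fitting_template(g)
    d = BlockDesign.alternating(n_volumes, 2.28)
    run = simulate_task_run(
        t, d, g, n_volumes=n_volumes, effect_size=effect,
        noise_sd=noise_sd, drift_amplitude=drift_amplitude, seed=seed,
    )
    X = build_design(d, canonical_hrf(2.28), n_volumes, 2.28)
    return run, X, t


class TestFitGlm:
    def test_noise_free_contrast_recovery_exact(self):
        run, X, t = _planted_run()
        fit = fit_glm(run, X)
        diff = fit.beta["SG"].values - fit.beta["TL"].values
        active = next(iter(run.ground_truth["maps"].values())).values
        core = active > 0.9
        assert core.any()
        assert np.allclose(diff[core], active[core], atol=1e-6)

    def test_default_drift_bias_below_one_percent(self):
        run, X, _ = _planted_run(drift_amplitude=1.0, noise_sd=0.0)
        fit = fit_glm(run, X)
        diff = fit.beta["SG"].values - fit.beta["TL"].values
        active = next(iter(run.ground_truth["maps"].values())).values
        core = active > 0.9
        assert np.abs(diff[core] - active[core]).max() < 0.01

    def test_null_t_distribution_matches_student(self):
        run, X, _ = _planted_run(noise_sd=1.0, effect=0.0, seed=3)
        fit = fit_glm(run, X)
        tmap = t_contrast(fit)
        tvals = tmap.values[tmap.grid.brain_mask]
        _, p = stats.kstest(tvals, "t", args=(fit.dof,))
        assert p > 0.01

    def test_constant_run_gives_zero_task_betas(self):
        g = make_compact_grid(8)
        from langmap.simulate import BoldRun

        run = BoldRun(grid=g, data=np.full(g.shape + (60,), 7.0), tr_s=2.28)
        X = build_design(BlockDesign.alternating(60, 2.28), canonical_hrf(2.28), 60, 2.28)
        fit = fit_glm(run, X)
        assert np.allclose(fit.beta["SG"].values, 0.0, atol=1e-9)
        assert np.allclose(fit.beta["TL"].values, 0.0, atol=1e-9)

    def test_length_mismatch_raises(self):
        run, X, _ = _planted_run()
        short = discard_initial_volumes(run, 3)
        with pytest.raises(ValueError):
            fit_glm(short, X)

    def test_dof_is_n_minus_rank(self):
        run, X, _ = _planted_run()
        fit = fit_glm(run, X)
        assert fit.dof == X.n_timepoints - np.linalg.matrix_rank(X.values)


class TestHighpass:
    def test_harmonic_slow_drift_removed_exactly(self):
        # a drift lying on a retained DCT harmonic (period 243.5 s) vanishes
        n, tr = 267, 2.28
        t = np.arange(n)
        drift = np.cos(np.pi * 5 * (t + 0.5) / n)
        X = build_design(BlockDesign.alternating(n, tr), canonical_hrf(tr), n, tr)
        beta, *_ = np.linalg.lstsq(X.values, drift, rcond=None)
        assert np.abs(drift - X.values @ beta).max() < 1e-10

    def test_generic_slow_drift_removed_to_one_percent_rms(self):
        # off-harmonic 300-s cosine: residual is edge leakage only, < 1% RMS
        n, tr = 267, 2.28
        t = np.arange(n) * tr
        drift = np.cos(2 * np.pi * t / 300.0)
        X = build_design(BlockDesign.alternating(n, tr), canonical_hrf(tr), n, tr)
        beta, *_ = np.linalg.lstsq(X.values, drift, rcond=None)
        resid = drift - X.values @ beta
        assert np.sqrt((resid**2).mean()) < 0.01


class TestTContrast:
    def test_sign_flips_with_negated_contrast(self):
        run, X, _ = _planted_run(noise_sd=0.5, seed=4)
        fit = fit_glm(run, X)
        a = t_contrast(fit, {"SG": 1.0, "TL": -1.0})
        b = t_contrast(fit, {"SG": -1.0, "TL": 1.0})
        m = a.grid.brain_mask
        assert np.allclose(a.values[m], -b.values[m])

    def test_unknown_regressor_raises(self):
        run, X, _ = _planted_run()
        fit = fit_glm(run, X)
        with pytest.raises(ValueError):
            t_contrast(fit, {"nope": 1.0})

    def test_zero_variance_voxels_masked_out(self):
        g = make_compact_grid(8)
        from langmap.simulate import BoldRun

        run = BoldRun(grid=g, data=np.zeros(g.shape + (60,)), tr_s=2.28)
        X = build_design(BlockDesign.alternating(60, 2.28), canonical_hrf(2.28), 60, 2.28)
        tmap = t_contrast(fit_glm(run, X))
        assert not tmap.grid.brain_mask.any()

    def test_t_invariant_to_joint_rescaling(self):
        run, X, _ = _planted_run(noise_sd=1.0, seed=5)
        fit = fit_glm(run, X)
        t1 = t_contrast(fit)
        from dataclasses import replace

        run2 = replace(run, data=run.data * 10.0)
        fit2 = fit_glm(run2, X)
        t2 = t_contrast(fit2)
        m = t1.grid.brain_mask
        assert np.allclose(t1.values[m], t2.values[m], atol=1e-8)


class TestApplyThreshold:
    def test_null_map_survives_nothing(self):
        g = make_compact_grid(10)
        tmap = StatMap(grid=g, values=np.zeros(g.shape), kind="t")
        thr, table = apply_threshold(tmap, ThresholdSpec(), dof=100)
        assert (thr.values[g.brain_mask] == 0).all()
        assert len(table) == 0

    def test_planted_activation_survives_fwe(self):
        run, X, tpl = _planted_run(noise_sd=1.0, seed=6)
        fit = fit_glm(run, X)
        tmap = t_contrast(fit)
        thr, table = apply_threshold(tmap, ThresholdSpec(alpha=0.05), fit.dof)
        assert len(table) >= 1
        # every planted node has surviving signal within a voxel or two
        from langmap.grid import local_maxima

        peaks = local_maxima(thr, 0.0, 8.0)
        coords = peaks.coordinates()
        for node, _, _ in tpl.nodes:
            assert np.linalg.norm(coords - np.array(node), axis=1).min() <= 6.0

    def test_fdr_cluster_requires_null(self):
        g = make_compact_grid(10)
        tmap = StatMap(grid=g, values=np.zeros(g.shape), kind="t")
        with pytest.raises(ValueError, match="null"):
            apply_threshold(tmap, ThresholdSpec(family="FDR_cluster"), dof=20)

    def test_fdr_cluster_finds_planted_cluster(self):
        run, X, _ = _planted_run(noise_sd=1.0, seed=7)
        fit = fit_glm(run, X)
        tmap = t_contrast(fit)
        null = max_cluster_null_glm(
            fit, {"SG": 1.0, "TL": -1.0}, n_permutations=100, seed=0
        )
        thr, table = apply_threshold(
            tmap,
            ThresholdSpec(family="FDR_cluster", alpha=0.05),
            fit.dof,
            null_max_cluster_sizes=null,
        )
        assert len(table) >= 1
        assert table["k"].max() > 5
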