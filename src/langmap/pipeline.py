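"""End-to-end orchestration: the synthetic-cohort demo workflow and the
recomputation of the reference-cohort statistics from the bundled fixtures.

The demo simulates a cohort of synthetic "patients" (one resting and one
task run each), runs the full analysis chain — volume discard, smoothing,
GLM contrast with voxel-level FWE thresholding, spatial ICA with rule-based
language-network selection, laterality indices — and scores both modalities
against a planted stimulation site with the 10-mm concordance rule.  All
randomness is funnelled through one seeded generator per run, so identical
seeds give identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .concordance import (
    ConcordanceRecord,
    SensitivityReport,
    StimulationSite,
    load_reference_concordance,
    sensitivity,
    site_detected,
)
from .glm import (
    ThresholdSpec,
    build_design,
    canonical_hrf,
    discard_initial_volumes,
    fit_glm,
    smooth_run,
    t_contrast,
    threshold_peaks,
)
from .grid import VolumeGrid, default_grid
from .ica import ICAConfig, decompose_rest
from .laterality import laterality_index
from .networks import (
    RoiAtlas,
    component_peaks,
    default_atlas,
    default_rules,
    region_laterality,
    peaks_in_region,
    select_language_component,
)
from .simulate import (
    BlockDesign,
    NetworkTemplate,
    default_network_templates,
    simulate_rest_run,
    simulate_task_run,
)

__all__ = ["PipelineConfig", "desk_config", "DemoReport", "run_demo", "reproduce_reference_results"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline constants in one place.

    The acquisition and analysis defaults are the clinical protocol values
    (16-s epochs, 270 volumes at TR 2.28 s, 3 discarded volumes, 6-mm FWHM
    smoothing, z = 2 component threshold, voxel-level FWE 0.05, 128-s
    high-pass, 10-mm concordance radius, 3-mm grid); the simulation knobs
    (noise, effect size, component count) are the generator's defaults.
    """

    voxel_size_mm: float = 3.0
    n_volumes: int = 270
    tr_s: float = 2.28
    n_discard: int = 3
    epoch_s: float = 16.0
    fwhm_mm: float = 6.0
    z_threshold: float = 2.0
    fwe_alpha: float = 0.05
    highpass_s: float = 128.0
    concordance_radius_mm: float = 10.0
    min_peak_separation_mm: float = 8.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    n_components: int = 20
    noise_sd: float = 1.0
    effect_size: float = 1.0

    def grid(self) -> VolumeGrid:
        return default_grid(self.voxel_size_mm)


def desk_config(**overrides) -> PipelineConfig:
    """Desk-scale configuration: the native 3 mm MNI box with shorter runs
    and fewer components, sized so the full chain runs in well under a
    minute per synthetic patient.  The 3 mm resolution is kept because the
    6 mm-sigma network nodes need it: at coarser voxel sizes the network
    variance falls below the PCA noise floor and ICA recovery degrades."""
    defaults = dict(n_volumes=150, n_components=10)
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@dataclass(frozen=True)
class DemoReport:
    table: pd.DataFrame
    records: tuple[ConcordanceRecord, ...]
    sensitivities: dict[str, SensitivityReport]
    seed: int


REPORT_REGIONS = ("MTG", "ANG", "TP", "IFG", "SMA_preSMA", "dACC", "AIFO")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_demo(
    config: PipelineConfig | None = None,
    seed: int = 1,
    n_patients: int = 5,
    templates: dict[str, NetworkTemplate] | None = None,
    atlas: RoiAtlas | None = None,
) -> DemoReport:
    """Simulate a synthetic cohort and score both modalities against a
    planted stimulation site at the language network's MTG node."""
    if n_patients <= 0:
        raise ValueError("n_patients must be >= 1")
    config = config or desk_config()
    templates = templates or default_network_templates()
    atlas = atlas or default_atlas()
    rules = default_rules()
    if "LANG" not in templates:
        raise ValueError("templates must include a LANG network")
    lang = templates["LANG"]
    site_xyz = lang.nodes[0][0]  # the MTG node
    grid = config.grid()
    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=(n_patients, 2))
    hrf = canonical_hrf(config.tr_s)
    rows = []
    records = []
    for i in range(n_patients):
        rest_seed, task_seed = (int(s) for s in run_seeds[i])
        # --- resting-state arm ---
        rest = _stage("simulate_rest")(
            simulate_rest_run,
            list(templates.values()),
            grid,
            n_volumes=config.n_volumes,
            tr_s=config.tr_s,
            band_hz=config.band_hz,
            noise_sd=config.noise_sd,
            seed=rest_seed,
        )
        rest = _stage("preprocess_rest")(
            lambda r: smooth_run(discard_initial_volumes(r, config.n_discard), config.fwhm_mm),
            rest,
        )
        ica_cfg = ICAConfig(n_components=config.n_components, seed=rest_seed)
        decomp = _stage("ica")(decompose_rest, rest, ica_cfg)
        selection = _stage("classify")(
            select_language_component, decomp, atlas, rules, config.z_threshold
        )
        if selection is not None:
            comp_idx, label = selection
            rest_peaks = component_peaks(
                decomp, comp_idx, config.z_threshold, config.min_peak_separation_mm
            )
            rest_li = laterality_index(
                decomp.spatial_maps[comp_idx], threshold=config.z_threshold
            )
        else:
            comp_idx, label, rest_peaks, rest_li = None, None, None, None
        # --- task arm ---
        design = BlockDesign.alternating(
            config.n_volumes,
            config.tr_s,
            epoch_s=config.epoch_s,
            start_s=config.n_discard * config.tr_s,
        )
        task = _stage("simulate_task")(
            simulate_task_run,
            lang,
            design,
            grid,
            n_volumes=config.n_volumes,
            tr_s=config.tr_s,
            effect_size=config.effect_size,
            noise_sd=config.noise_sd,
            seed=task_seed,
        )
        task = _stage("preprocess_task")(
            lambda r: smooth_run(discard_initial_volumes(r, config.n_discard), config.fwhm_mm),
            task,
        )
        design_shifted = design.shifted(-config.n_discard * config.tr_s)
        X = _stage("design")(
            build_design,
            design_shifted,
            hrf,
            task.n_volumes,
            config.tr_s,
            config.highpass_s,
        )
        fit = _stage("glm")(fit_glm, task, X)
        tmap = _stage("contrast")(t_contrast, fit)
        _, _, task_peaks = _stage("threshold")(
            threshold_peaks,
            tmap,
            ThresholdSpec(family="FWE_voxel", alpha=config.fwe_alpha),
            fit.dof,
            config.min_peak_separation_mm,
            f"patient{i}-task",
        )
        task_li = laterality_index(tmap, threshold=0.0)
        # --- concordance against the planted site ---
        site = StimulationSite(patient=i, outcome="aphasia", mni_xyz=site_xyz)
        task_det = site_detected(task_peaks, site, config.concordance_radius_mm)
        rest_det = (
            site_detected(rest_peaks, site, config.concordance_radius_mm)
            if rest_peaks is not None
            else False
        )
        records.append(
            ConcordanceRecord(
                patient=i,
                cm_positive=True,
                sites=(site,),
                detections={"task": (task_det,), "rest": (rest_det,)},
            )
        )
        row = {
            "patient": i,
            "lang_component": comp_idx,
            "lang_identified": selection is not None,
            "rest_li": None if rest_li is None or not rest_li.defined else round(rest_li.li, 1),
            "task_li": None if not task_li.defined else round(task_li.li, 1),
            "task_detected": task_det,
            "rest_detected": rest_det,
        }
        for region in REPORT_REGIONS:
            row[f"task_{region}"] = (
                region_laterality(peaks_in_region(task_peaks, atlas, region))
            )
            row[f"rest_{region}"] = (
                region_laterality(peaks_in_region(rest_peaks, atlas, region))
                if rest_peaks is not None
                else "No"
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    sens = {m: sensitivity(records, m) for m in ("task", "rest")}
    return DemoReport(table=table, records=tuple(records), sensitivities=sens, seed=seed)


def reproduce_reference_results() -> dict:
    """Recompute the reference-cohort quantities from the bundled fixtures.

    Returns concordance sensitivities (percent), demographic counts and
    means, the left-handed subgroup summary, and the histology grouping, on
    the scales the source tables use.
    """
    records = load_reference_concordance()
    task = sensitivity(records, "task")
    rest = sensitivity(records, "rest")
    cohort = cohort_mod.load_cohort()
    summary = cohort_mod.summarize(cohort)
    lat = cohort_mod.load_laterality_table()
    hands = cohort_mod.left_hander_summary(lat)
    return {
        "task_sensitivity_pct": task.sensitivity,
        "rest_sensitivity_pct": rest.sensitivity,
        "n_cm_positive": task.n_cm_positive,
        "n_male": summary["n_male"],
        "n_female": summary["n_female"],
        "mean_age_years": round(summary["mean_age"], 1),
        "sd_age_years": round(summary["sd_age"], 1),
        "mean_anxiety": round(summary["mean_anxiety"], 1),
        "mean_success": round(summary["mean_success"], 1),
        "n_language_disturbance": summary["n_language_disturbance"],
        "n_glial_tumors": summary["n_glial"],
        "n_left_handed": hands["n_left_handed"],
        "left_hander_edinburgh_mean": round(hands["mean_edinburgh_unit"], 2),
        "n_right_dominant_rest_left_handers": hands["n_right_dominant_rest"],
        "n_right_dominant_task_left_handers": hands["n_right_dominant_task"],
    }
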