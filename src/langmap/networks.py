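"""Rule-based identification of resting-state networks from component peaks.

The consensus of two human raters is replaced by a deterministic rule
engine: each ICA component is reduced to its suprathreshold peaks, peaks are
matched to spherical anatomical regions, and a network label is assigned
when every required region of a rule contains a peak (unilaterally or
bilaterally) and no exclusion region does.  The angular gyrus versus
supramarginal/temporo-parietal-junction opposition discriminates the
language network from the ventral attention network, which is its main
false-positive risk.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import PeakSet, local_maxima
from .ica import ICADecomposition

__all__ = [
    "RoiAtlas",
    "NetworkRule",
    "NetworkLabel",
    "default_atlas",
    "default_rules",
    "peaks_in_region",
    "region_laterality",
    "classify_component",
    "select_language_component",
    "classification_report",
]

#: fixed tie-break priority between fully satisfied rules
RULE_PRIORITY = ("LANG", "VAN", "SN", "DAN", "lFPC")


@dataclass(frozen=True)
class RoiAtlas:
    """Named regions, each a set of spheres (centre mm, radius mm, hemisphere)."""

    regions: dict[str, tuple[tuple[tuple[float, float, float], float, str], ...]]

    def __post_init__(self) -> None:
        for name, spheres in self.regions.items():
            for center, radius, hemi in spheres:
                if radius <= 0:
                    raise ValueError(f"region {name}: sphere radius must be > 0")
                if hemi not in ("L", "R", "M"):
                    raise ValueError(f"region {name}: hemisphere must be L, R or M")
                if hemi == "L" and center[0] >= 0:
                    raise ValueError(f"region {name}: left sphere must have x < 0")
                if hemi == "R" and center[0] <= 0:
                    raise ValueError(f"region {name}: right sphere must have x > 0")

    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)


@dataclass(frozen=True)
class NetworkRule:
    network: str
    required: tuple[str, ...]
    exclusion: tuple[str, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if set(self.required) & set(self.exclusion):
            raise ValueError(
                f"rule {self.network}: required and exclusion regions overlap"
            )


@dataclass(frozen=True)
class NetworkLabel:
    component: int
    network: str  # network name or "unclassified"
    matched_regions: tuple[str, ...]
    score: float  # fraction of required regions hit; 0 when unclassified

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def _load_atlas_yaml(path: str | Path | None = None) -> dict:
    if path is None:
        ref = importlib.resources.files("langmap.data") / "atlas.yaml"
        return yaml.safe_load(ref.read_text())
    return yaml.safe_load(Path(path).read_text())


def default_atlas(path: str | Path | None = None) -> RoiAtlas:
    raw = _load_atlas_yaml(path)
    return RoiAtlas(
        regions={
            name: tuple(((x, y, z), r, hemi) for x, y, z, r, hemi in spheres)
            for name, spheres in raw["regions"].items()
        }
    )


def default_rules(path: str | Path | None = None) -> tuple[NetworkRule, ...]:
    raw = _load_atlas_yaml(path)
    return tuple(
        NetworkRule(
            network=r["network"],
            required=tuple(r["required"]),
            exclusion=tuple(r.get("exclusion", ())),
            notes=r.get("notes", ""),
        )
        for r in raw["rules"]
    )


def peaks_in_region(
    peaks: PeakSet, atlas: RoiAtlas, region: str
) -> dict[str, list]:
    """Peaks falling inside a region's spheres, keyed by hemisphere.

    A peak matches when its Euclidean distance to some sphere centre is
    strictly less than the sphere radius plus numerical tolerance is not
    applied: the test is ``distance <= radius``.
    """
    if region not in atlas.regions:
        raise KeyError(f"unknown region {region!r}; atlas has {atlas.names()}")
    out: dict[str, list] = {"L": [], "R": [], "M": []}
    for peak in peaks:
        p = np.asarray(peak.mni_xyz)
        for center, radius, hemi in atlas.regions[region]:
            if np.linalg.norm(p - np.asarray(center)) <= radius:
                out[hemi].append(peak)
                break
    return out


def region_laterality(matched: dict[str, list]) -> str:
    """Collapse hemisphere matches to the Left/Right/Bi/No report vocabulary."""
    left = bool(matched["L"]) or bool(matched["M"])
    right = bool(matched["R"]) or bool(matched["M"])
    if matched["M"] and not matched["L"] and not matched["R"]:
        # a midline-only hit counts as present without a lateral preference
        return "Bi"
    if left and right:
        return "Bi"
    if left:
        return "Left"
    if right:
        return "Right"
    return "No"


def classify_component(
    peaks: PeakSet,
    atlas: RoiAtlas,
    rules: tuple[NetworkRule, ...],
    component: int = 0,
) -> NetworkLabel:
    """Deterministic rule evaluation for one component's peak set.

    Every rule is evaluated; among fully satisfied rules the one with the
    largest summed matched-peak value wins, then the fixed rule priority.
    When no rule is fully satisfied the component is "unclassified".
    """
    satisfied = []
    for rule in rules:
        matched_regions = []
        summed = 0.0
        for region in rule.required:
            matched = peaks_in_region(peaks, atlas, region)
            hits = matched["L"] + matched["R"] + matched["M"]
            if hits:
                matched_regions.append(region)
                summed += sum(p.value for p in hits)
        vetoed = False
        for region in rule.exclusion:
            matched = peaks_in_region(peaks, atlas, region)
            if matched["L"] or matched["R"] or matched["M"]:
                vetoed = True
                break
        score = len(matched_regions) / len(rule.required)
        if score == 1.0 and not vetoed:
            prio = (
                RULE_PRIORITY.index(rule.network)
                if rule.network in RULE_PRIORITY
                else len(RULE_PRIORITY)
            )
            satisfied.append((-summed, prio, rule.network, tuple(matched_regions)))
    if not satisfied:
        return NetworkLabel(component=component, network="unclassified", matched_regions=(), score=0.0)
    satisfied.sort()
    _, _, network, matched_regions = satisfied[0]
    return NetworkLabel(
        component=component, network=network, matched_regions=matched_regions, score=1.0
    )


def component_peaks(
    decomp: ICADecomposition,
    component: int,
    z_threshold: float = 2.0,
    min_separation_mm: float = 8.0,
) -> PeakSet:
    """Peaks of one z-scored component above the z threshold."""
    return local_maxima(
        decomp.spatial_maps[component],
        threshold=z_threshold,
        min_separation_mm=min_separation_mm,
        source=f"IC{component}",
    )


def classify_decomposition(
    decomp: ICADecomposition,
    atlas: RoiAtlas | None = None,
    rules: tuple[NetworkRule, ...] | None = None,
    z_threshold: float = 2.0,
) -> list[NetworkLabel]:
    atlas = atlas or default_atlas()
    rules = rules or default_rules()
    labels = []
    for k in range(decomp.n_components):
        peaks = component_peaks(decomp, k, z_threshold=z_threshold)
        labels.append(classify_component(peaks, atlas, rules, component=k))
    return labels


def select_language_component(
    decomp: ICADecomposition,
    atlas: RoiAtlas | None = None,
    rules: tuple[NetworkRule, ...] | None = None,
    z_threshold: float = 2.0,
) -> tuple[int, NetworkLabel] | None:
    """The LANG-labelled component with the strongest evidence, or None.

    Ties on score are broken by the summed matched-peak z, then by the lower
    component index.
    """
    atlas = atlas or default_atlas()
    rules = rules or default_rules()
    best = None
    for k in range(decomp.n_components):
        peaks = component_peaks(decomp, k, z_threshold=z_threshold)
        label = classify_component(peaks, atlas, rules, component=k)
        if label.network != "LANG":
            continue
        summed = sum(
            p.value
            for region in label.matched_regions
            for hemi_hits in peaks_in_region(peaks, atlas, region).values()
            for p in hemi_hits
        )
        key = (-label.score, -summed, k)
        if best is None or key < best[0]:
            best = (key, k, label)
    if best is None:
        return None
    return best[1], best[2]


def classification_report(
    decomp: ICADecomposition,
    atlas: RoiAtlas | None = None,
    rules: tuple[NetworkRule, ...] | None = None,
    z_threshold: float = 2.0,
    regions: tuple[str, ...] = ("MTG", "ANG", "TP", "IFG", "SMA_preSMA", "dACC", "AIFO"),
) -> pd.DataFrame:
    """Audit table: one row per component, Left/Right/Bi/No per region plus
    the assigned network — the machine analogue of a rater's worksheet."""
    atlas = atlas or default_atlas()
    rules = rules or default_rules()
    rows = []
    for k in range(decomp.n_components):
        peaks = component_peaks(decomp, k, z_threshold=z_threshold)
        label = classify_component(peaks, atlas, rules, component=k)
        row = {"component": k, "network": label.network}
        for region in regions:
            row[region] = region_laterality(peaks_in_region(peaks, atlas, region))
        rows.append(row)
    return pd.DataFrame(rows)
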