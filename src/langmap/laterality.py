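"""Hemispheric lateralization index of a statistical map.

LI = 100 * (R - L) / (R + L), where R and L are the summed suprathreshold
statistic in the right (MNI x > +midline exclusion) and left (x < -midline
exclusion) hemispheres.  Note the sign convention: POSITIVE means
right-hemisphere dominance, matching the reference cohort tables this
package ships; the common LI-toolbox convention is the opposite
(positive = left).  The index is the deterministic mass-based core of the
toolbox LI; bootstrapped or threshold-free variants are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import StatMap

__all__ = ["LateralityResult", "laterality_index", "classify_dominance"]

MIDLINE_EXCLUSION_DEFAULT_MM = 5.0


@dataclass(frozen=True)
class LateralityResult:
    li: float | None  # -100 (all left) .. +100 (all right); None when undefined
    left_mass: float
    right_mass: float
    threshold: float
    midline_exclusion_mm: float

    @property
    def defined(self) -> bool:
        return self.li is not None


def laterality_index(
    stat_map: StatMap,
    threshold: float = 0.0,
    midline_exclusion_mm: float = MIDLINE_EXCLUSION_DEFAULT_MM,
) -> LateralityResult:
    """Mass-based LI of the suprathreshold part of a map.

    Voxels with |x| <= midline exclusion contribute to neither hemisphere.
    When no suprathreshold mass remains the index is undefined (``li`` is
    None), never silently zero.
    """
    grid = stat_map.grid
    mask = grid.brain_mask
    x = grid.coordinate_grid()[0]
    vals = np.where(mask, stat_map.values, 0.0)
    supra = np.where(vals > threshold, vals, 0.0)
    left = float(supra[mask & (x < -midline_exclusion_mm)].sum())
    right = float(supra[mask & (x > midline_exclusion_mm)].sum())
    total = left + right
    li = 100.0 * (right - left) / total if total > 0 else None
    return LateralityResult(
        li=li,
        left_mass=left,
        right_mass=right,
        threshold=threshold,
        midline_exclusion_mm=midline_exclusion_mm,
    )


def classify_dominance(
    result: LateralityResult | float, bilateral_band: float | None = None
) -> str:
    """'left' / 'right' / 'bilateral' dominance from an LI.

    Default criterion is the sign alone (right iff LI > 0); when
    ``bilateral_band`` is given, |LI| < band is called 'bilateral' instead.
    An undefined LI raises.
    """
    li = result.li if isinstance(result, LateralityResult) else float(result)
    if li is None:
        raise ValueError("laterality index is undefined (no suprathreshold mass)")
    if bilateral_band is not None and abs(li) < bilateral_band:
        return "bilateral"
    if li > 0:
        return "right"
    if li < 0:
        return "left"
    return "bilateral"
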