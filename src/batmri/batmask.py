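"""Rule-based BAT candidate mask for visualization and seeding QC.

A voxel is a BAT candidate when all three criteria hold:

1. total signal above ``mean + 2 SD`` of the total-signal image (statistics
   over the entire image, background included);
2. a fat-signal criterion one SD below the entire fat-image mean — by
   default read as an *upper* bound (fat < mean - SD: BAT is fat-poor
   relative to WAT), the alternative lower-bound reading is available via
   ``fat_criterion='above'``;
3. fat fraction above 20%, with no upper bound.

This mask is a visualization/QC aid, not the analysis ROI (see
:mod:`batmri.segment`).  Note that on images dominated by low-fat voxels the
fat-image mean minus one SD can fall below zero, in which case the default
upper-bound criterion admits no voxel; the thresholds actually applied are
stored on the result so such degeneracies are visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .volumes import FatFractionMap, WaterFatVolumes, check_congruent


@dataclass
class BatMask:
    """Boolean BAT candidate grid plus the thresholds actually applied."""

    mask: np.ndarray
    total_signal_cut: float
    fat_signal_cut: float
    ff_cut: float
    fat_criterion: str
    spacing_mm: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def bat_candidate_mask(
    wf: WaterFatVolumes,
    ff: FatFractionMap,
    *,
    total_k: float = 2.0,
    fat_k: float = 1.0,
    ff_min: float = 0.20,
    fat_criterion: str = "below",
) -> BatMask:
    """Apply the three-criterion BAT candidate rule.

    ``fat_criterion='below'`` (default) requires fat < mean - fat_k*SD;
    ``'above'`` requires fat > mean - fat_k*SD.  Image statistics are taken
    over the entire image including background.  The mask is restricted to
    valid FF voxels.
    """
    if fat_criterion not in ("below", "above"):
        raise ConfigError(f"fat_criterion must be 'below' or 'above', got {fat_criterion!r}")
    check_congruent(wf.water, ff.ff)

    total = wf.total
    total_cut = float(total.mean() + total_k * total.std())
    fat_cut = float(wf.fat.mean() - fat_k * wf.fat.std())

    mask = (total > total_cut) & ff.valid & (ff.ff > ff_min)
    if fat_criterion == "below":
        mask &= wf.fat < fat_cut
    else:
        mask &= wf.fat > fat_cut
    return BatMask(mask, total_cut, fat_cut, ff_min, fat_criterion, wf.spacing_mm)
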