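"""Two-point water-fat separation and fat-fraction mapping.

At the in-phase echo the water and fat magnetizations add (IP = W + F); at
the opposed-phase echo they subtract (OP = |W - F|).  Solving the two
equations gives the dominant and non-dominant species per voxel:

    dominant     = (IP + OP) / 2
    non-dominant = (IP - OP) / 2

Magnitude data cannot say which species dominates; the assignment comes from
a dominance policy — a global assumption ('water' or 'fat') or a per-voxel
boolean map as delivered by a scanner's phase-based reconstruction.  Regions
where that assignment is wrong are fat/water swaps; :func:`flag_swaps`
detects suspect components (advisory only, never modifies data).

The fat signal fraction is FF = F / (F + W), a two-point signal-fraction
estimate (no multi-peak fat or relaxation modelling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .volumes import (
    DualEchoVolume,
    FatFractionMap,
    SignalMask,
    WaterFatVolumes,
    check_congruent,
)

#: Warn when more than this fraction of voxels needed negative clipping
#: (noise too high for magnitude-based separation).
NEGATIVE_CLIP_WARN_FRACTION = 0.01


def separate_water_fat(
    echoes: DualEchoVolume,
    dominance: str | np.ndarray = "water",
) -> WaterFatVolumes:
    """Separate water and fat from in-phase / opposed-phase magnitudes.

    Parameters
    ----------
    echoes:
        Dual-echo magnitude volumes.
    dominance:
        ``'water'`` (default) assumes water >= fat everywhere, ``'fat'`` the
        reverse; a boolean array (True where water dominates) applies a
        per-voxel assignment, e.g. one produced by a phase-resolved scanner
        reconstruction.

    Negative separated values (possible under noise) are clipped to zero and
    counted; a clipped fraction above 1% of voxels triggers a warning.
    """
    ip, op = echoes.in_phase, echoes.opposed_phase
    if isinstance(dominance, str):
        if dominance not in ("water", "fat"):
            raise ConfigError(f"dominance must be 'water', 'fat' or a boolean map, got {dominance!r}")
        water_dominant = np.full(ip.shape, dominance == "water")
    else:
        water_dominant = np.asarray(dominance, dtype=bool)
        check_congruent(ip, water_dominant)

    dominant = (ip + op) / 2.0
    minor = (ip - op) / 2.0
    water = np.where(water_dominant, dominant, minor)
    fat = np.where(water_dominant, minor, dominant)

    negative = (water < 0) | (fat < 0)
    clipped_fraction = float(negative.mean())
    # Pure-noise background voxels are negative half the time by symmetry;
    # only clipping inside appreciable-signal voxels indicates trouble.
    foreground = ip > ip.mean() + 2.0 * ip.std()
    if foreground.any():
        fg_clipped = float(negative[foreground].mean())
        if fg_clipped > NEGATIVE_CLIP_WARN_FRACTION:
            warnings.warn(
                f"{fg_clipped:.1%} of appreciable-signal voxels required negative "
                "clipping after separation; noise may be too high for "
                "magnitude-based two-point Dixon",
                stacklevel=2,
            )
    return WaterFatVolumes(
        np.maximum(water, 0.0),
        np.maximum(fat, 0.0),
        echoes.spacing_mm,
        clipped_fraction=clipped_fraction,
    )


def compute_fat_fraction(
    wf: WaterFatVolumes, eps_rel: float = 1e-6
) -> FatFractionMap:
    """Fat signal fraction FF = F / (F + W) with a validity mask.

    Voxels whose combined signal is at or below ``eps_rel`` times the image
    maximum are marked invalid (avoids 0/0 in the background); FF is clipped
    to [0, 1] on valid voxels.
    """
    total = wf.total
    eps = eps_rel * float(total.max()) if total.size else 0.0
    valid = total > eps
    ff = np.zeros_like(total)
    np.divide(wf.fat, total, out=ff, where=valid)
    np.clip(ff, 0.0, 1.0, out=ff)
    ff[~valid] = 0.0
    return FatFractionMap(ff, valid, wf.spacing_mm)


def signal_mask(wf: WaterFatVolumes, k: float = 2.0) -> SignalMask:
    """Appreciable-signal mask: total > mean + k*SD over the entire image.

    The mean and SD include all voxels (background noise included) and are
    stored on the mask so the threshold is reproducible.
    """
    total = wf.total
    mean = float(total.mean())
    sd = float(total.std())
    if sd == 0.0:
        warnings.warn("total signal is constant; appreciable-signal mask is empty", stacklevel=2)
        return SignalMask(np.zeros(total.shape, dtype=bool), mean, sd, k, wf.spacing_mm)
    return SignalMask(total > mean + k * sd, mean, sd, k, wf.spacing_mm)


@dataclass(frozen=True)
class SwapComponent:
    """One suspect fat/water-swapped connected component (advisory)."""

    component_id: int
    n_voxels: int
    median_ff: float
    centroid_mm: tuple[float, float, float]
    bounding_box: tuple[tuple[int, int], ...]

    def mask_from(self, labels: np.ndarray) -> np.ndarray:
        return labels == self.component_id


def flag_swaps(
    ff: FatFractionMap,
    wf: WaterFatVolumes,
    *,
    ff_suspect: float = 0.80,
    min_voxels: int = 30,
    signal: SignalMask | None = None,
    signal_floor_k: float = 0.5,
) -> tuple[list[SwapComponent], np.ndarray]:
    """Flag connected high-signal components that look fat/water swapped.

    In a neonatal torso nearly all tissue is water-dominant; genuine adipose
    tissue tops out around WAT fat fractions (~0.7).  A compact component of
    genuine signal whose median FF is near-complementary to soft tissue
    (median FF >= ``ff_suspect``) is therefore suspect.  Advisory only: the
    data are never modified; callers exclude subjects whose flagged
    components lie in or near analysis regions.

    Swaps can occur in moderately bright tissue, so the default signal floor
    is looser (mean + ``signal_floor_k`` * SD of total signal) than the
    appreciable-signal mask; pass ``signal`` to override it.

    Returns the flagged components and the connected-component label grid
    (for mapping components back to masks).
    """
    sig = signal if signal is not None else signal_mask(wf, k=signal_floor_k)
    check_congruent(ff.ff, sig.mask)
    candidate = sig.mask & ff.valid & (ff.ff > 0.5)
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=bool))
    flagged = []
    spacing = np.asarray(ff.spacing_mm)
    for cid in range(1, n + 1):
        comp = labels == cid
        size = int(comp.sum())
        if size < min_voxels:
            continue
        med = float(np.median(ff.ff[comp]))
        if med >= ff_suspect:
            idx = np.argwhere(comp)
            centroid = tuple(float(c) for c in idx.mean(axis=0) * spacing)
            bbox = tuple((int(lo), int(hi) + 1) for lo, hi in zip(idx.min(axis=0), idx.max(axis=0)))
            flagged.append(SwapComponent(cid, size, med, centroid, bbox))
    return flagged, labels
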