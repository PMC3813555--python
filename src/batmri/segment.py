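"""Seeded, threshold-constrained region segmentation of adipose depots.

Reimplements the semi-automated protocol used for neonatal depot
segmentation: seed bubbles are placed in a depot, an eligibility set is
defined by intensity thresholds (the 20-60% fat-fraction band for BAT; the
above-lowest-quartile fat image for nuchal WAT) and the labelled region
evolves from the seeds for a fixed number of iterations, never leaving the
eligibility set.

The evolution is morphological region growing: each iteration adds at most
one voxel shell (26-connected) of eligible neighbours, followed by a
curvature-like smoothing step that rejects candidate voxels with too few
neighbours in the grown region, suppressing one-voxel tendrils.  Iterations
therefore map one-to-one to shells and the iteration count is the stopping
rule.  Growth is monotone: the region after k iterations is contained in the
region after k+1.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ProtocolError, SeedPlacementError
from .volumes import FatFractionMap, RegionMask, SignalMask, check_congruent

_CONN26 = np.ones((3, 3, 3), dtype=bool)
_NEIGHBOR_KERNEL = _CONN26.astype(np.uint8).copy()
_NEIGHBOR_KERNEL[1, 1, 1] = 0


@dataclass(frozen=True)
class SeedSpec:
    """One seed bubble: anatomical region, center (mm) and radius (mm)."""

    region: str
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ConfigError(f"seed radius must be positive, got {self.radius_mm}")


@dataclass(frozen=True)
class SegmentationProtocol:
    """Protocol constants of the semi-automated segmentation.

    BAT regions are confined to the 20-60% FF band; iteration counts are
    fixed at 50 for the heterogeneous supraclavicular/axillary regions,
    default 50 (configurable 40-60) for the spine, and 100 for nuchal WAT.
    Seed bubbles are 3 mm for BAT and 5 mm for WAT; seed counts are capped at
    4 per side for supraclavicular and axillary regions and one per side per
    vertebra for spinal levels T1-T5 only.
    """

    ff_band: tuple[float, float] = (0.20, 0.60)
    spine_iterations: int = 50
    supraclavicular_iterations: int = 50
    axillary_iterations: int = 50
    wat_iterations: int = 100
    wat_quantile: float = 0.25
    wat_seed_radius_mm: float = 5.0
    max_seeds_per_side: int = 4
    spine_levels: tuple[int, int] = (1, 5)
    smoothing_min_neighbors: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.ff_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigError(f"FF band must satisfy 0 <= lo < hi <= 1, got {self.ff_band}")
        if not 40 <= self.spine_iterations <= 60:
            raise ConfigError("spine iterations must lie in [40, 60]")
        for name in ("supraclavicular_iterations", "axillary_iterations", "wat_iterations"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    def iterations_for(self, group: str) -> int:
        return {
            "supraclavicular": self.supraclavicular_iterations,
            "axillary": self.axillary_iterations,
            "spine": self.spine_iterations,
            "nuchal_wat": self.wat_iterations,
        }[group]


_SPINE_RE = re.compile(r"^spine_T(\d+)_([LR])$")


def region_group(label: str) -> str:
    """Map a seed/depot label to its protocol group."""
    if label.startswith("supraclavicular"):
        return "supraclavicular"
    if label.startswith("axillary"):
        return "axillary"
    if label.startswith("spine"):
        return "spine"
    if label == "nuchal_wat":
        return "nuchal_wat"
    raise ProtocolError(f"unknown region label {label!r}")


def _validate_seed_counts(seeds: list[SeedSpec], group: str, proto: SegmentationProtocol) -> None:
    if group in ("supraclavicular", "axillary"):
        per_side: dict[str, int] = {}
        for s in seeds:
            side = s.region.rsplit("_", 1)[-1]
            per_side[side] = per_side.get(side, 0) + 1
        for side, n in per_side.items():
            if n > proto.max_seeds_per_side:
                raise ProtocolError(
                    f"{group}: {n} seeds on side {side} exceeds the protocol "
                    f"limit of {proto.max_seeds_per_side} per side"
                )
    elif group == "spine":
        lo, hi = proto.spine_levels
        slots: dict[tuple[int, str], int] = {}
        for s in seeds:
            m = _SPINE_RE.match(s.region)
            if not m:
                raise ProtocolError(f"spine seed label {s.region!r} is not of the form spine_Tn_L/R")
            level = int(m.group(1))
            if not lo <= level <= hi:
                raise ProtocolError(f"spine level T{level} outside the protocol range T{lo}-T{hi}")
            key = (level, m.group(2))
            slots[key] = slots.get(key, 0) + 1
            if slots[key] > 1:
                raise ProtocolError(f"more than one seed at spine level T{key[0]} side {key[1]}")


def rasterize_seed(
    seed: SeedSpec, shape: tuple[int, ...], spacing: tuple[float, float, float]
) -> np.ndarray:
    """Rasterize a spherical seed bubble (physical mm, anisotropy respected)."""
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, seed.center_mm))
    return d2 <= seed.radius_mm**2


def _seed_voxel(seed: SeedSpec, shape, spacing) -> tuple[int, ...]:
    idx = tuple(int(round(c / s)) for c, s in zip(seed.center_mm, spacing))
    if any(i < 0 or i >= n for i, n in zip(idx, shape)):
        raise SeedPlacementError(f"seed {seed.region!r} center {seed.center_mm} outside the grid")
    return idx


def _grow(
    start: np.ndarray,
    eligible: np.ndarray,
    iterations: int,
    min_neighbors: int,
) -> tuple[np.ndarray, int]:
    """Monotone shell-per-iteration growth of ``start`` within ``eligible``.

    Each iteration dilates by one 26-connected shell intersected with the
    eligibility set, then drops candidate voxels supported by fewer than
    ``min_neighbors`` neighbours of the dilated region (curvature smoothing);
    previously accepted voxels are never removed.  Returns the grown mask and
    the number of iterations actually run (growth may saturate early).
    """
    # Work inside the eligible bounding box: growth cannot leave it.
    domain = eligible | start
    if not domain.any():
        return start.copy(), 0
    bbox = ndimage.find_objects(domain.astype(np.int8), max_label=1)[0]
    region = start[bbox].copy()
    elig = eligible[bbox]
    ran = 0
    for _ in range(iterations):
        cand = ndimage.binary_dilation(region, structure=_CONN26) & elig & ~region
        if not cand.any():
            break
        support = ndimage.convolve(
            (region | cand).astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant"
        )
        keep = cand & (support >= min_neighbors)
        if not keep.any():
            keep = cand  # never stall outright on thin but eligible growth
        region |= keep
        ran += 1
    out = np.zeros_like(start)
    out[bbox] = region
    return out, ran


def _keep_seeded_components(mask: np.ndarray, seed_voxels: list[tuple[int, ...]]) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=_CONN26)
    wanted = {labels[v] for v in seed_voxels if labels[v] > 0}
    return np.isin(labels, sorted(wanted)) if wanted else np.zeros_like(mask)


def segment_bat_region(
    ff: FatFractionMap,
    seeds: list[SeedSpec],
    proto: SegmentationProtocol = SegmentationProtocol(),
    signal: SignalMask | None = None,
    *,
    label: str | None = None,
) -> RegionMask:
    """Segment one BAT region from seed bubbles, confined to the FF band.

    All seeds must belong to one protocol group (supraclavicular, axillary or
    spine); the group sets the iteration count.  The eligibility set is
    ``{lo <= FF <= hi}`` intersected with the FF validity mask and, if given,
    the appreciable-signal mask.  Every returned connected component contains
    at least one seed.
    """
    if not seeds:
        raise ProtocolError("at least one seed is required")
    groups = {region_group(s.region) for s in seeds}
    if len(groups) > 1:
        raise ProtocolError(f"seeds span multiple protocol groups: {sorted(groups)}")
    group = groups.pop()
    if group == "nuchal_wat":
        raise ProtocolError("use segment_wat_nuchal for the nuchal WAT region")
    _validate_seed_counts(seeds, group, proto)

    lo, hi = proto.ff_band
    eligible = ff.valid & (ff.ff >= lo) & (ff.ff <= hi)
    if signal is not None:
        check_congruent(ff.ff, signal.mask)
        eligible &= signal.mask

    seed_voxels = []
    start = np.zeros(ff.shape, dtype=bool)
    for seed in seeds:
        v = _seed_voxel(seed, ff.shape, ff.spacing_mm)
        if not eligible[v]:
            raise SeedPlacementError(
                f"seed {seed.region!r} at {seed.center_mm} mm lies outside the "
                f"eligibility set (FF band {lo:.2f}-{hi:.2f} within appreciable signal)"
            )
        seed_voxels.append(v)
        start |= rasterize_seed(seed, ff.shape, ff.spacing_mm)
    start &= eligible

    iterations = proto.iterations_for(group)
    mask, ran = _grow(start, eligible, iterations, proto.smoothing_min_neighbors)
    mask = _keep_seeded_components(mask, seed_voxels)
    return RegionMask(
        mask,
        label or group,
        ff.spacing_mm,
        provenance={
            "seeds": [(s.region, s.center_mm, s.radius_mm) for s in seeds],
            "iterations_requested": iterations,
            "iterations_run": ran,
            "ff_band": (lo, hi),
            "group": group,
        },
    )


def segment_wat_nuchal(
    fat: np.ndarray,
    seed: SeedSpec,
    proto: SegmentationProtocol = SegmentationProtocol(),
    signal: SignalMask | None = None,
    *,
    spacing_mm: tuple[float, float, float] | None = None,
) -> RegionMask:
    """Segment nuchal WAT on the fat-only image.

    Eligibility is fat signal above the lowest quartile, the quartile being
    computed within the appreciable-signal mask; the evolution runs
    ``proto.wat_iterations`` (100) from a single 5 mm seed.  A constant fat
    image makes the quartile threshold degenerate; a warning is issued and
    eligibility falls back to the signal mask.
    """
    fat = np.asarray(fat, dtype=np.float64)
    if spacing_mm is None:
        spacing_mm = signal.spacing_mm if signal is not None else (0.97, 0.97, 1.0)
    if seed.region != "nuchal_wat":
        raise ProtocolError(f"nuchal WAT segmentation requires a nuchal_wat seed, got {seed.region!r}")
    if abs(seed.radius_mm - proto.wat_seed_radius_mm) > 1e-9:
        raise ProtocolError(
            f"nuchal WAT seed radius must be {proto.wat_seed_radius_mm} mm, got {seed.radius_mm}"
        )
    if signal is not None:
        check_congruent(fat, signal.mask)
        domain = signal.mask
    else:
        domain = np.ones(fat.shape, dtype=bool)

    inside = fat[domain]
    if inside.size == 0 or np.ptp(inside) == 0:
        warnings.warn(
            "fat image is constant within the signal mask; quartile threshold "
            "is degenerate, eligibility falls back to the signal mask",
            stacklevel=2,
        )
        eligible = domain.copy()
        q1 = float(inside[0]) if inside.size else float("nan")
    else:
        q1 = float(np.quantile(inside, proto.wat_quantile))
        eligible = domain & (fat > q1)

    v = _seed_voxel(seed, fat.shape, spacing_mm)
    if not eligible[v]:
        raise SeedPlacementError(
            f"nuchal WAT seed at {seed.center_mm} mm lies in a sub-quartile voxel "
            f"(fat {fat[v]:.4g} <= threshold {q1:.4g})"
        )
    start = rasterize_seed(seed, fat.shape, spacing_mm) & eligible
    mask, ran = _grow(start, eligible, proto.wat_iterations, proto.smoothing_min_neighbors)
    mask = _keep_seeded_components(mask, [v])
    return RegionMask(
        mask,
        "nuchal_wat",
        spacing_mm,
        provenance={
            "seeds": [(seed.region, seed.center_mm, seed.radius_mm)],
            "iterations_requested": proto.wat_iterations,
            "iterations_run": ran,
            "fat_quartile_threshold": q1,
        },
    )


def union_region(a: RegionMask, b: RegionMask, label: str = "union") -> RegionMask:
    """Voxel-set union of two region masks (overlap counted once)."""
    check_congruent(a.mask, b.mask)
    return RegionMask(
        a.mask | b.mask,
        label if a.label != b.label else a.label,
        a.spacing_mm,
        provenance={"union_of": (a.label, b.label)},
    )


def snap_seeds_to_eligibility(
    seeds: list[SeedSpec],
    ff: FatFractionMap,
    proto: SegmentationProtocol = SegmentationProtocol(),
    signal: SignalMask | None = None,
    *,
    max_shift_mm: float = 3.0,
) -> list[SeedSpec]:
    """Move each seed to the nearest eligible voxel within ``max_shift_mm``.

    Emulates what a human rater does implicitly: seeds are dropped on voxels
    that visibly belong to the target tissue.  BAT seeds snap within the FF
    band; the nuchal WAT seed is left untouched (its eligibility threshold is
    data-dependent and its depot is large).
    """
    lo, hi = proto.ff_band
    eligible = ff.valid & (ff.ff >= lo) & (ff.ff <= hi)
    if signal is not None:
        eligible &= signal.mask
    spacing = np.asarray(ff.spacing_mm)
    out = []
    for seed in seeds:
        if region_group(seed.region) == "nuchal_wat":
            out.append(seed)
            continue
        v = _seed_voxel(seed, ff.shape, ff.spacing_mm)
        if eligible[v]:
            out.append(seed)
            continue
        r_vox = np.ceil(max_shift_mm / spacing).astype(int)
        sl = tuple(
            slice(max(0, i - r), min(n, i + r + 1))
            for i, r, n in zip(v, r_vox, ff.shape)
        )
        local = eligible[sl]
        if not local.any():
            raise SeedPlacementError(
                f"no eligible voxel within {max_shift_mm} mm of seed {seed.region!r}"
            )
        idx = np.argwhere(local) + [s.start for s in sl]
        d = np.linalg.norm((idx - v) * spacing, axis=1)
        best = idx[int(np.argmin(d))]
        out.append(SeedSpec(seed.region, tuple(best * spacing), seed.radius_mm))
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / float(denom) if denom else 1.0
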