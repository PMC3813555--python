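"""In-memory containers for 3D MRI volumes.

All grids are numpy arrays indexed (x, y, z) with voxel spacing in mm.
Physical coordinates follow a plain scanner-free convention: voxel (i, j, k)
has its center at ``(i * dx, j * dy, k * dz)`` — phantoms are axis-aligned,
so no orientation matrix is carried beyond the affine written to NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CongruenceError

#: Voxel spacing of the acquisition protocol (mm), used as the default
#: everywhere a spacing is not given explicitly.
DEFAULT_SPACING_MM: tuple[float, float, float] = (0.97, 0.97, 1.0)


def voxel_volume_mm3(spacing: tuple[float, float, float]) -> float:
    return float(spacing[0] * spacing[1] * spacing[2])


def check_congruent(*grids: np.ndarray) -> None:
    """Raise CongruenceError unless all grids share one shape."""
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise CongruenceError(f"grids are not congruent: shapes {sorted(shapes)}")


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise CongruenceError(f"voxel spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class DualEchoVolume:
    """Co-registered in-phase / opposed-phase magnitude volumes.

    The in-phase echo carries water + fat signal, the opposed-phase echo
    carries |water - fat|; echo times are metadata only (the separation is
    purely algebraic).
    """

    in_phase: np.ndarray
    opposed_phase: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    te_ms: tuple[float, float] = (2.45, 3.675)

    def __post_init__(self) -> None:
        self.in_phase = np.asarray(self.in_phase, dtype=np.float64)
        self.opposed_phase = np.asarray(self.opposed_phase, dtype=np.float64)
        check_congruent(self.in_phase, self.opposed_phase)
        self.spacing_mm = _validate_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.in_phase.shape


@dataclass
class WaterFatVolumes:
    """Separated water (W) and fat (F) magnitude volumes, both >= 0."""

    water: np.ndarray
    fat: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    #: fraction of voxels whose W or F came out negative and was clipped to 0
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.water = np.asarray(self.water, dtype=np.float64)
        self.fat = np.asarray(self.fat, dtype=np.float64)
        check_congruent(self.water, self.fat)
        self.spacing_mm = _validate_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.water.shape

    @property
    def total(self) -> np.ndarray:
        return self.water + self.fat


@dataclass
class FatFractionMap:
    """Per-voxel fat signal fraction FF = F / (F + W), defined on ``valid``.

    FF is stored as a fraction in [0, 1]; reports render percent. Voxels with
    negligible combined signal are marked invalid rather than set to 0/0.
    """

    ff: np.ndarray
    valid: np.ndarray
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        self.ff = np.asarray(self.ff, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        check_congruent(self.ff, self.valid)
        self.spacing_mm = _validate_spacing(self.spacing_mm)
        inside = self.ff[self.valid]
        if inside.size and (inside.min() < 0 or inside.max() > 1):
            raise ValueError("fat fraction outside [0, 1] on valid voxels")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ff.shape


@dataclass
class SignalMask:
    """Voxels with appreciable combined signal.

    Threshold is mean + k*SD of the total signal over the entire image,
    background included; the statistics used are stored so the mask can be
    reproduced.
    """

    mask: np.ndarray
    mean: float
    sd: float
    k: float = 2.0
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing_mm = _validate_spacing(self.spacing_mm)

    @property
    def threshold(self) -> float:
        return self.mean + self.k * self.sd

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


@dataclass
class RegionMask:
    """Labelled voxel set for one anatomical ROI, with provenance."""

    mask: np.ndarray
    label: str
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing_mm = _validate_spacing(self.spacing_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * voxel_volume_mm3(self.spacing_mm) / 1000.0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape
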