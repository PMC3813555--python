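"""Synthetic dual-echo water-fat phantoms for pipeline validation.

No neonatal scan data are distributed with this package; every stage of the
analysis is instead exercised on digital phantoms whose ground truth is known
analytically:

* **vial phantoms** — two ellipsoidal "glass tubes", one filled with a brown
  adipose tissue (BAT)-like fat-fraction (FF) distribution, one with a white
  adipose tissue (WAT)-like distribution, mimicking ex-vivo imaging of
  excised rodent depots;
* **torso phantoms** — a water-dominant soft-tissue body containing the
  neonatal depots of interest: bilateral supraclavicular and axillary BAT,
  bilateral spinal BAT at five thoracic levels (T1–T5) and a subcutaneous
  nuchal WAT pad;
* **cohorts** — collections of torso phantoms whose per-subject depot volumes
  and mean FFs are drawn from stated between-subject distributions;
* **rescans** — a second acquisition of the same subject (same noiseless
  signal, fresh noise, optional smooth gain drift emulating a re-shim);
* **seed jitter** — perturbed segmentation seed points emulating different
  human raters.

Per-voxel FF values are drawn from a skew-normal law moment-matched to a
requested mean / SD / skewness, the only shape information available for
adipose FF distributions.

Forward signal model (magnitude two-point chemical-shift imaging): a voxel
with total signal ``S`` and fat fraction ``ff`` has water ``W = S*(1-ff)``
and fat ``F = S*ff``; the in-phase echo is ``W + F`` and the opposed-phase
echo ``|W - F|``, each plus additive Gaussian noise, clipped at zero.
Magnitude echoes alone cannot tell which of W/F dominates a voxel, so the
ground truth carries a per-voxel dominance map standing in for the
phase-based resolution a scanner reconstruction performs.  Fat/water swap
artifacts are simulated by inverting that map inside declared regions, which
exchanges the reconstructed water and fat values there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (
    ConfigError,
    GeometryError,
    SeedPlacementError,
    UnrepresentableDistributionError,
)
from .segment import SeedSpec
from .volumes import DEFAULT_SPACING_MM, DualEchoVolume, voxel_volume_mm3

#: Supremum of |skewness| attainable by the skew-normal family.
MAX_ABS_SKEWNESS = 0.9952717464311565

_BACKGROUND = "background"
_BODY = "other_soft_tissue"


# ---------------------------------------------------------------------------
# Tissue FF distributions (skew-normal, moment matched)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueDistribution:
    """Fat-fraction distribution of one tissue: mean, SD and skewness.

    ``sd_ff == 0`` is accepted as a degenerate point mass.
    """

    name: str
    mean_ff: float
    sd_ff: float
    skewness: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_ff < 1.0:
            raise ConfigError(f"{self.name}: mean_ff must be in (0, 1), got {self.mean_ff}")
        if self.sd_ff < 0:
            raise ConfigError(f"{self.name}: sd_ff must be >= 0, got {self.sd_ff}")
        if abs(self.skewness) >= MAX_ABS_SKEWNESS:
            raise UnrepresentableDistributionError(
                f"{self.name}: |skewness| = {abs(self.skewness):.4f} is not attainable "
                f"by a skew-normal law (must be < {MAX_ABS_SKEWNESS:.4f})"
            )


def skewnorm_params(mean: float, sd: float, skewness: float) -> tuple[float, float, float]:
    """Moment-match a skew-normal: return scipy's ``(a, loc, scale)``.

    Uses the closed-form inversion of the skew-normal moment equations:
    with ``b = sqrt(2/pi)`` and ``g = |skewness|``,

        delta^2 = (pi/2) * g^(2/3) / (g^(2/3) + ((4-pi)/2)^(2/3))
        scale   = sd / sqrt(1 - b^2 delta^2)
        loc     = mean - scale * delta * b
    """
    if abs(skewness) >= MAX_ABS_SKEWNESS:
        raise UnrepresentableDistributionError(
            f"|skewness| = {abs(skewness):.4f} exceeds the skew-normal limit"
        )
    if skewness == 0.0:
        return 0.0, mean, sd
    b2 = 2.0 / math.pi
    g23 = abs(skewness) ** (2.0 / 3.0)
    delta2 = (math.pi / 2.0) * g23 / (g23 + ((4.0 - math.pi) / 2.0) ** (2.0 / 3.0))
    delta = math.copysign(math.sqrt(delta2), skewness)
    scale = sd / math.sqrt(1.0 - b2 * delta2)
    loc = mean - scale * delta * math.sqrt(b2)
    a = delta / math.sqrt(1.0 - delta2)
    return a, loc, scale


class FFSample(NamedTuple):
    values: np.ndarray
    clip_fraction: float


def sample_ff(
    dist: TissueDistribution,
    n: int,
    rng: np.random.Generator | int,
    clip: tuple[float, float] = (0.0, 1.0),
) -> FFSample:
    """Draw ``n`` fat-fraction values from a moment-matched skew-normal.

    Values are clipped to ``clip`` (default the physical [0, 1] range) and
    the fraction of clipped draws is reported alongside.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if dist.sd_ff == 0.0:
        return FFSample(np.full(n, dist.mean_ff), 0.0)
    a, loc, scale = skewnorm_params(dist.mean_ff, dist.sd_ff, dist.skewness)
    values = stats.skewnorm.rvs(a, loc=loc, scale=scale, size=n, random_state=rng)
    lo, hi = clip
    clipped = int(np.count_nonzero((values < lo) | (values > hi)))
    return FFSample(np.clip(values, lo, hi), clipped / max(n, 1))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepotGeometry:
    """Axis-aligned ellipsoidal blob: center and principal semi-axes in mm."""

    region: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise GeometryError(f"{self.region}: semi-axes must be positive, got {self.radii_mm}")

    @property
    def true_volume_cc(self) -> float:
        a, b, c = self.radii_mm
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_mm)
        d = (p - np.asarray(self.center_mm)) / np.asarray(self.radii_mm)
        return (d**2).sum(axis=1) <= 1.0


def ellipsoid_geometry(
    region: str,
    center_mm: Sequence[float],
    volume_cc: float,
    axis_ratio: Sequence[float] = (1.0, 1.0, 1.0),
) -> DepotGeometry:
    """Build an ellipsoid of a prescribed analytic volume and axis ratios."""
    if volume_cc <= 0:
        raise GeometryError(f"{region}: volume must be positive, got {volume_cc}")
    ratio = np.asarray(axis_ratio, dtype=float)
    s = (volume_cc * 1000.0 / (4.0 / 3.0 * math.pi * float(np.prod(ratio)))) ** (1.0 / 3.0)
    return DepotGeometry(region, tuple(float(c) for c in center_mm), tuple(ratio * s))


@dataclass(frozen=True)
class Depot:
    """One labelled tissue compartment: geometry + FF distribution + signal.

    ``signal`` is the total (water+fat) magnitude relative to the adipose
    reference signal of 1.0; ``ff_clip`` bounds the generated per-voxel FF so
    tissue classes stay inside their nominal FF range by construction.
    """

    geometry: DepotGeometry
    tissue: TissueDistribution
    signal: float = 1.0
    ff_clip: tuple[float, float] = (0.0, 1.0)


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    depots: tuple[Depot, ...]
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    noise_sd: float = 0.02
    swap_regions: tuple[DepotGeometry, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigError("voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise sd must be >= 0")


@dataclass
class GroundTruth:
    """Noiseless truth grids and per-region truth for a generated phantom."""

    labels: np.ndarray  # int region id per voxel; 0 = background
    region_names: dict[int, str]
    water: np.ndarray
    fat: np.ndarray
    spacing_mm: tuple[float, float, float]
    depots: tuple[Depot, ...]
    #: True per-voxel water dominance (water >= fat).
    water_dominant: np.ndarray = field(default=None)
    #: Dominance map as a scanner reconstruction would deliver it — equal to
    #: ``water_dominant`` except inside simulated swap regions.
    recon_dominance: np.ndarray = field(default=None)

    @property
    def total(self) -> np.ndarray:
        return self.water + self.fat

    @property
    def ff(self) -> np.ndarray:
        total = self.total
        out = np.zeros_like(total)
        np.divide(self.fat, total, out=out, where=total > 0)
        return out

    def region_mask(self, region: str) -> np.ndarray:
        ids = [i for i, name in self.region_names.items() if name == region]
        if not ids:
            raise KeyError(f"unknown region {region!r}")
        return np.isin(self.labels, ids)

    def region_table(self) -> pd.DataFrame:
        """Per-region voxel count, voxelized volume (cc) and true mean FF."""
        vv = voxel_volume_mm3(self.spacing_mm)
        ff = self.ff
        rows = []
        analytic = {d.geometry.region: d.geometry.true_volume_cc for d in self.depots}
        for rid, name in sorted(self.region_names.items()):
            m = self.labels == rid
            n = int(m.sum())
            rows.append(
                {
                    "region": name,
                    "label": rid,
                    "n_voxels": n,
                    "volume_cc": n * vv / 1000.0,
                    "mean_ff": float(ff[m].mean()) if n else float("nan"),
                    "analytic_volume_cc": analytic.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def _voxel_center_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_ellipsoid(
    geom: DepotGeometry,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the ellipsoid."""
    # Evaluate only inside the bounding box for speed.
    lo = [max(0, int((c - r) / s) - 1) for c, r, s in zip(geom.center_mm, geom.radii_mm, spacing)]
    hi = [
        min(n, int((c + r) / s) + 2)
        for c, r, s, n in zip(geom.center_mm, geom.radii_mm, spacing, shape)
    ]
    mask = np.zeros(shape, dtype=bool)
    if any(l >= h for l, h in zip(lo, hi)):
        return mask
    sub_axes = [np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)]
    gx, gy, gz = np.meshgrid(*sub_axes, indexing="ij")
    d = sum(
        ((g - c) / r) ** 2 for g, c, r in zip((gx, gy, gz), geom.center_mm, geom.radii_mm)
    )
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d <= 1.0
    return mask


def _check_inside_grid(geom: DepotGeometry, shape, spacing) -> None:
    extent = [n * s for n, s in zip(shape, spacing)]
    for c, r, e, name in zip(geom.center_mm, geom.radii_mm, extent, "xyz"):
        if c - r < 0 or c + r > e:
            raise GeometryError(
                f"depot {geom.region!r} extends outside the grid along {name} "
                f"(center {c:.1f} mm, semi-axis {r:.1f} mm, extent {e:.1f} mm)"
            )


def build_truth(spec: PhantomSpec, *, enforce_in_grid: bool = True) -> GroundTruth:
    """Paint all depots onto the grid and return noiseless truth volumes.

    Depots are painted in list order; a voxel claimed by two non-body depots
    is a geometry error.  The ``other_soft_tissue`` body (if present) is
    painted first and depots may legally override it (they are embedded in,
    or bulge out of, the body).
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = tuple(spec.grid_shape)
    labels = np.zeros(shape, dtype=np.int16)
    signal = np.zeros(shape, dtype=np.float64)
    ff = np.zeros(shape, dtype=np.float64)
    region_names = {0: _BACKGROUND}

    body = [d for d in spec.depots if d.geometry.region == _BODY]
    others = [d for d in spec.depots if d.geometry.region != _BODY]
    claimed = np.zeros(shape, dtype=bool)

    next_id = 1
    for depot in body + others:
        geom = depot.geometry
        if enforce_in_grid and geom.region != _BODY:
            _check_inside_grid(geom, shape, spec.spacing_mm)
        mask = rasterize_ellipsoid(geom, shape, spec.spacing_mm)
        if geom.region != _BODY:
            if np.any(mask & claimed):
                raise GeometryError(f"depot {geom.region!r} overlaps another depot")
            claimed |= mask
        n = int(mask.sum())
        values = sample_ff(depot.tissue, n, rng, clip=depot.ff_clip).values
        ff[mask] = values
        signal[mask] = depot.signal
        labels[mask] = next_id
        region_names[next_id] = geom.region
        next_id += 1

    water = signal * (1.0 - ff)
    fat = signal * ff
    water_dominant = water >= fat
    recon = water_dominant.copy()
    for swap in spec.swap_regions:
        recon ^= rasterize_ellipsoid(swap, shape, spec.spacing_mm)
    return GroundTruth(
        labels=labels,
        region_names=region_names,
        water=water,
        fat=fat,
        spacing_mm=spec.spacing_mm,
        depots=tuple(spec.depots),
        water_dominant=water_dominant,
        recon_dominance=recon,
    )


def forward_echoes(
    truth: GroundTruth, noise_sd: float, rng: np.random.Generator | int
) -> DualEchoVolume:
    """Emit magnitude in-phase / opposed-phase echoes from truth W/F grids."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ip = truth.water + truth.fat
    op = np.abs(truth.water - truth.fat)
    if noise_sd > 0:
        ip = ip + rng.normal(0.0, noise_sd, ip.shape)
        op = op + rng.normal(0.0, noise_sd, op.shape)
    return DualEchoVolume(np.maximum(ip, 0.0), np.maximum(op, 0.0), truth.spacing_mm)


# ---------------------------------------------------------------------------
# Vial phantom (ex-vivo emulation)
# ---------------------------------------------------------------------------

#: Ex-vivo interscapular BAT voxel FF distribution (fractions).
EX_VIVO_BAT = TissueDistribution("ex_vivo_bat", 0.437, 0.078, -0.27)
#: Ex-vivo perirenal WAT voxel FF distribution (fractions).
EX_VIVO_WAT = TissueDistribution("ex_vivo_wat", 0.733, 0.104, -0.85)
#: In-situ counterparts (skewness not separately characterized; assumed
#: skew-normal with the in-situ mean/SD and the ex-vivo shape left at 0).
IN_SITU_BAT = TissueDistribution("in_situ_bat", 0.430, 0.141, 0.0)
IN_SITU_WAT = TissueDistribution("in_situ_wat", 0.679, 0.156, 0.0)


def vial_phantom_spec(
    bat: TissueDistribution = EX_VIVO_BAT,
    wat: TissueDistribution = EX_VIVO_WAT,
    *,
    grid_shape: tuple[int, int, int] = (64, 32, 32),
    noise_sd: float = 0.02,
    rng_seed: int = 0,
) -> PhantomSpec:
    """Two ellipsoidal vials (one BAT-like, one WAT-like) in air."""
    dx, dy, dz = DEFAULT_SPACING_MM
    ext = [n * s for n, s in zip(grid_shape, DEFAULT_SPACING_MM)]
    radii = (
        min(9.0, ext[0] / 5.5),
        min(9.0, ext[1] / 2.6),
        min(12.0, ext[2] / 2.6),
    )
    y, z = ext[1] / 2, ext[2] / 2
    depots = (
        Depot(DepotGeometry("bat_vial", (ext[0] * 0.28, y, z), radii), bat),
        Depot(DepotGeometry("wat_vial", (ext[0] * 0.72, y, z), radii), wat),
    )
    return PhantomSpec(grid_shape, depots, noise_sd=noise_sd, rng_seed=rng_seed)


def make_vial_phantom(spec: PhantomSpec) -> tuple[DualEchoVolume, GroundTruth]:
    """Build a two-vial ex-vivo phantom: echoes + ground truth."""
    if len(spec.depots) != 2:
        raise ConfigError("vial phantom needs exactly two vial depots (one BAT, one WAT)")
    means = sorted(d.tissue.mean_ff for d in spec.depots)
    if not means[0] < means[1]:
        raise ConfigError("the two vials must have distinct FF distributions")
    truth = build_truth(spec)
    echoes = forward_echoes(truth, spec.noise_sd, np.random.default_rng(spec.rng_seed + 1))
    return echoes, truth


# ---------------------------------------------------------------------------
# Torso phantom (neonate emulation)
# ---------------------------------------------------------------------------

# Depot layout at scale 1.0 (mm): centers chosen so all depots are embedded
# in (or bulge from) the body ellipsoid without touching one another at the
# largest cohort volumes.  x = left-right, y = anterior-posterior,
# z = inferior-superior.
_BODY_CENTER = (62.1, 46.5, 32.0)
_BODY_RADII = (52.0, 36.0, 30.0)
_LAYOUT = {
    "supraclavicular": {"x_off": 24.0, "y": 38.0, "z": 54.0, "ratio": (1.2, 1.0, 0.8)},
    "axillary": {"x_off": 42.0, "y": 46.0, "z": 38.0, "ratio": (1.2, 1.0, 0.8)},
    "spine": {"x_off": 9.0, "y": 62.0, "z_levels": (52.0, 42.0, 32.0, 22.0, 12.0),
              "ratio": (1.1, 1.1, 0.75)},
    "nuchal_wat": {"center": (62.1, 78.0, 48.0), "ratio": (1.6, 0.55, 1.1)},
    # Anterior subcutaneous fat pads: moderate-FF adipose away from every
    # analysis depot.  They give the appreciable-signal mask the moderate-fat
    # tissue real torsos have, anchoring the lowest-quartile fat threshold of
    # the WAT protocol well below WAT fat levels for all cohort draws.
    "subcutaneous_pad": {"x_off": 20.0, "y": 20.0, "z": 30.0, "ratio": (1.3, 0.6, 1.3)},
}
#: Fixed supraclavicular share of the combined supraclavicular+axillary
#: (union) volume, from the cohort mean volumes 2.95 cc and 3.76 cc.
UNION_SPLIT_SUPRACLAVICULAR = 2.95 / (2.95 + 3.76)

#: Generation-time FF clip bands per tissue class (fractions).
BAT_FF_CLIP = (0.205, 0.595)
WAT_FF_CLIP = (0.58, 0.95)
BODY_FF_CLIP = (0.0, 0.18)

_SEED_RADIUS_BAT_MM = 3.0
_SEED_RADIUS_WAT_MM = 5.0


def torso_phantom_spec(
    *,
    supraclavicular_volume_cc: float = 2.95,
    axillary_volume_cc: float = 3.76,
    spine_volume_cc: float = 3.65,
    nuchal_volume_cc: float = 5.0,
    supraclavicular_ff: float = 0.289,
    axillary_ff: float = 0.303,
    spine_ff: float = 0.322,
    nuchal_ff: float = 0.677,
    body_ff: float = 0.06,
    bat_within_sd: float = 0.04,
    wat_within_sd: float = 0.05,
    body_within_sd: float = 0.03,
    body_signal: float = 0.5,
    noise_sd: float = 0.02,
    scale: float = 1.0,
    grid_shape: tuple[int, int, int] | None = None,
    swap_regions: tuple[DepotGeometry, ...] = (),
    rng_seed: int = 0,
) -> PhantomSpec:
    """Neonate torso phantom spec with the standard depot layout.

    Volumes are interpreted at ``scale=1`` and shrink with ``scale**3`` so a
    scaled-down scene keeps the same proportions (handy for fast tests).
    Bilateral volumes (supraclavicular, axillary, spine) are split equally
    between sides; the spinal volume is split over 10 depots (5 levels x 2).
    """
    if scale <= 0:
        raise ConfigError("scale must be positive")
    if grid_shape is None:
        grid_shape = tuple(max(8, round(n * scale)) for n in (128, 96, 64))
    v3 = scale**3

    def _geom(region, center, volume_cc, ratio):
        return ellipsoid_geometry(region, tuple(c * scale for c in center), volume_cc * v3, ratio)

    depots = [
        Depot(
            DepotGeometry(
                _BODY,
                tuple(c * scale for c in _BODY_CENTER),
                tuple(r * scale for r in _BODY_RADII),
            ),
            TissueDistribution(_BODY, body_ff, body_within_sd),
            signal=body_signal,
            ff_clip=BODY_FF_CLIP,
        )
    ]
    cx = _BODY_CENTER[0]
    for region in ("supraclavicular", "axillary"):
        lay = _LAYOUT[region]
        vol = {"supraclavicular": supraclavicular_volume_cc, "axillary": axillary_volume_cc}[region]
        ff = {"supraclavicular": supraclavicular_ff, "axillary": axillary_ff}[region]
        for side, sgn in (("L", -1.0), ("R", 1.0)):
            depots.append(
                Depot(
                    _geom(
                        f"{region}_{side}",
                        (cx + sgn * lay["x_off"], lay["y"], lay["z"]),
                        vol / 2.0,
                        lay["ratio"],
                    ),
                    TissueDistribution(f"{region}_{side}", ff, bat_within_sd),
                    ff_clip=BAT_FF_CLIP,
                )
            )
    lay = _LAYOUT["spine"]
    for level, z in enumerate(lay["z_levels"], start=1):
        for side, sgn in (("L", -1.0), ("R", 1.0)):
            depots.append(
                Depot(
                    _geom(
                        f"spine_T{level}_{side}",
                        (cx + sgn * lay["x_off"], lay["y"], z),
                        spine_volume_cc / 10.0,
                        lay["ratio"],
                    ),
                    TissueDistribution(f"spine_T{level}_{side}", spine_ff, bat_within_sd),
                    ff_clip=BAT_FF_CLIP,
                )
            )
    lay = _LAYOUT["nuchal_wat"]
    depots.append(
        Depot(
            _geom("nuchal_wat", lay["center"], nuchal_volume_cc, lay["ratio"]),
            TissueDistribution("nuchal_wat", nuchal_ff, wat_within_sd),
            ff_clip=WAT_FF_CLIP,
        )
    )
    lay = _LAYOUT["subcutaneous_pad"]
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        region = f"subcutaneous_pad_{side}"
        depots.append(
            Depot(
                _geom(region, (cx + sgn * lay["x_off"], lay["y"], lay["z"]), 4.0, lay["ratio"]),
                TissueDistribution(region, 0.45, 0.05),
                ff_clip=(0.30, 0.60),
            )
        )
    return PhantomSpec(
        grid_shape,
        tuple(depots),
        noise_sd=noise_sd,
        swap_regions=swap_regions,
        rng_seed=rng_seed,
    )


_REQUIRED_TORSO_REGIONS = (
    ["supraclavicular_L", "supraclavicular_R", "axillary_L", "axillary_R", "nuchal_wat"]
    + [f"spine_T{t}_{s}" for t in range(1, 6) for s in "LR"]
)


def canonical_seeds(truth: GroundTruth) -> list[SeedSpec]:
    """"Rater 0" seeds: one per analysis depot at its voxelized centroid.

    BAT depots get 3 mm bubbles, the nuchal WAT depot a 5 mm bubble,
    matching the segmentation protocol's seed sizes.  Non-analysis tissue
    (body, subcutaneous pads) is not seeded.
    """
    seeds = []
    spacing = np.asarray(truth.spacing_mm)
    for rid, name in sorted(truth.region_names.items()):
        if name not in _REQUIRED_TORSO_REGIONS:
            continue
        idx = np.argwhere(truth.labels == rid)
        if idx.size == 0:
            continue
        center = idx.mean(axis=0) * spacing
        radius = _SEED_RADIUS_WAT_MM if name == "nuchal_wat" else _SEED_RADIUS_BAT_MM
        seeds.append(SeedSpec(name, tuple(float(c) for c in center), radius))
    return seeds


def make_torso_phantom(
    spec: PhantomSpec,
) -> tuple[DualEchoVolume, GroundTruth, list[SeedSpec]]:
    """Build a torso phantom: echoes, ground truth and canonical seeds."""
    regions = {d.geometry.region for d in spec.depots}
    missing = [r for r in _REQUIRED_TORSO_REGIONS if r not in regions]
    if missing and regions - {_BODY}:
        raise ConfigError(f"torso phantom spec is missing depots: {missing}")
    truth = build_truth(spec)
    echoes = forward_echoes(truth, spec.noise_sd, np.random.default_rng(spec.rng_seed + 1))
    return echoes, truth, canonical_seeds(truth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Between-subject distributions of true depot volumes and mean FFs.

    Defaults reproduce the study cohort: n = 22 subjects, union
    (supraclavicular + axillary) volume 6.50 +/- 3.10 cc split between the
    two depots at the mean-volume ratio, spinal volume 3.65 +/- 1.40 cc,
    BAT FFs around 29-32% and nuchal WAT FF 67.7 +/- 4.6%.  The nuchal WAT
    volume is not part of the reported cohort statistics; a plausible
    5.0 +/- 1.5 cc is used.  Draws are truncated to the stated ranges.

    With ``stratified=True`` (default) each quantity is drawn by inverse-CDF
    at independently permuted stratified uniforms, so small-cohort sample
    moments track the specified population values.
    """

    n_subjects: int = 22
    union_volume: tuple[float, float] = (6.50, 3.10)
    union_volume_range: tuple[float, float] = (1.0, 15.0)
    spine_volume: tuple[float, float] = (3.65, 1.40)
    spine_volume_range: tuple[float, float] = (0.8, 7.0)
    nuchal_volume: tuple[float, float] = (5.0, 1.5)
    nuchal_volume_range: tuple[float, float] = (2.5, 8.0)
    supraclavicular_ff: tuple[float, float] = (0.289, 0.040)
    axillary_ff: tuple[float, float] = (0.303, 0.033)
    spine_ff: tuple[float, float] = (0.322, 0.032)
    nuchal_ff: tuple[float, float] = (0.677, 0.046)
    bat_ff_range: tuple[float, float] = (0.215, 0.55)
    wat_ff_range: tuple[float, float] = (0.58, 0.90)
    bat_within_sd: float = 0.04
    wat_within_sd: float = 0.05
    noise_sd: float = 0.02
    scale: float = 1.0
    stratified: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("a cohort needs at least 2 subjects")
        for name in ("union_volume", "spine_volume", "nuchal_volume",
                     "supraclavicular_ff", "axillary_ff", "spine_ff", "nuchal_ff"):
            if getattr(self, name)[1] < 0:
                raise ConfigError(f"{name}: sd must be >= 0")


def _draw(rng, n, mean_sd, bounds, stratified):
    mean, sd = mean_sd
    if sd == 0:
        return np.full(n, mean)
    if stratified:
        u = (rng.permutation(n) + rng.uniform(0, 1, n)) / n
        z = stats.norm.ppf(u)
    else:
        z = rng.standard_normal(n)
    return np.clip(mean + sd * z, *bounds)


def sample_cohort_parameters(cspec: CohortSpec) -> pd.DataFrame:
    """Per-subject true depot volumes (cc) and mean FFs (fractions)."""
    rng = np.random.default_rng(cspec.rng_seed)
    n, strat = cspec.n_subjects, cspec.stratified
    union = _draw(rng, n, cspec.union_volume, cspec.union_volume_range, strat)
    spine = _draw(rng, n, cspec.spine_volume, cspec.spine_volume_range, strat)
    nuchal = _draw(rng, n, cspec.nuchal_volume, cspec.nuchal_volume_range, strat)
    sc_ff = _draw(rng, n, cspec.supraclavicular_ff, cspec.bat_ff_range, strat)
    ax_ff = _draw(rng, n, cspec.axillary_ff, cspec.bat_ff_range, strat)
    sp_ff = _draw(rng, n, cspec.spine_ff, cspec.bat_ff_range, strat)
    wat_ff = _draw(rng, n, cspec.nuchal_ff, cspec.wat_ff_range, strat)
    return pd.DataFrame(
        {
            "subject": np.arange(n),
            "union_volume_cc": union,
            "supraclavicular_volume_cc": union * UNION_SPLIT_SUPRACLAVICULAR,
            "axillary_volume_cc": union * (1.0 - UNION_SPLIT_SUPRACLAVICULAR),
            "spine_volume_cc": spine,
            "nuchal_volume_cc": nuchal,
            "supraclavicular_ff": sc_ff,
            "axillary_ff": ax_ff,
            "spine_ff": sp_ff,
            "nuchal_ff": wat_ff,
        }
    )


@dataclass
class SubjectPhantom:
    subject: int
    echoes: DualEchoVolume
    truth: GroundTruth
    seeds: list[SeedSpec]
    params: dict


def make_cohort(cspec: CohortSpec, *, swap_subjects: Sequence[int] = ()) -> list[SubjectPhantom]:
    """Generate one torso phantom per subject from cohort-level statistics.

    ``swap_subjects`` lists subject indices that receive a simulated
    fat/water swap artifact in the soft tissue adjacent to the right
    supraclavicular depot (the exclusion scenario of the analysis protocol).
    """
    params = sample_cohort_parameters(cspec)
    seeds = np.random.SeedSequence(cspec.rng_seed).spawn(cspec.n_subjects)
    subjects = []
    for i, row in params.iterrows():
        swap = ()
        if i in set(swap_subjects):
            s = cspec.scale
            # Soft-tissue blob just inferior to the right supraclavicular
            # depot: its reconstructed FF is near-complementary (~0.94).
            swap = (
                DepotGeometry(
                    "swap_artifact",
                    ((_BODY_CENTER[0] + 24.0) * s, 47.0 * s, 46.0 * s),
                    (6.0 * s, 6.0 * s, 5.0 * s),
                ),
            )
        spec = torso_phantom_spec(
            supraclavicular_volume_cc=row["supraclavicular_volume_cc"],
            axillary_volume_cc=row["axillary_volume_cc"],
            spine_volume_cc=row["spine_volume_cc"],
            nuchal_volume_cc=row["nuchal_volume_cc"],
            supraclavicular_ff=row["supraclavicular_ff"],
            axillary_ff=row["axillary_ff"],
            spine_ff=row["spine_ff"],
            nuchal_ff=row["nuchal_ff"],
            bat_within_sd=cspec.bat_within_sd,
            wat_within_sd=cspec.wat_within_sd,
            noise_sd=cspec.noise_sd,
            scale=cspec.scale,
            swap_regions=swap,
            rng_seed=int(seeds[i].generate_state(1)[0] % (2**31)),
        )
        echoes, truth, seed_list = make_torso_phantom(spec)
        subjects.append(SubjectPhantom(int(i), echoes, truth, seed_list, dict(row)))
    return subjects


# ---------------------------------------------------------------------------
# Rescans and rater emulation
# ---------------------------------------------------------------------------


def make_rescan(
    truth: GroundTruth,
    noise_sd: float,
    rng_seed: int,
    *,
    bias_amplitude: float = 0.0,
    bias_smoothness_mm: float = 25.0,
) -> DualEchoVolume:
    """Second acquisition of the same subject: fresh noise on the same truth.

    An optional smooth multiplicative gain field (peak amplitude
    ``bias_amplitude``, correlation length ``bias_smoothness_mm``) emulates
    the independent shim/pre-scan calibration of a repeat acquisition.
    """
    rng = np.random.default_rng(rng_seed)
    if bias_amplitude > 0:
        sigma_vox = [bias_smoothness_mm / s for s in truth.spacing_mm]
        raw = ndimage.gaussian_filter(rng.standard_normal(truth.water.shape), sigma_vox)
        peak = np.abs(raw).max()
        bias = 1.0 + bias_amplitude * raw / peak if peak > 0 else np.ones_like(raw)
        biased = replace_truth_signal(truth, bias)
        return forward_echoes(biased, noise_sd, rng)
    return forward_echoes(truth, noise_sd, rng)


def replace_truth_signal(truth: GroundTruth, gain: np.ndarray) -> GroundTruth:
    """Scale the noiseless water/fat grids by a gain field (FF unchanged)."""
    return replace(truth, water=truth.water * gain, fat=truth.fat * gain)


def jitter_seeds(
    seeds: Sequence[SeedSpec],
    magnitude_mm: float,
    truth: GroundTruth,
    rng_seed: int,
    *,
    max_attempts: int = 100,
) -> list[SeedSpec]:
    """Displace each seed by an isotropic Gaussian vector, staying in-depot.

    The per-axis SD is chosen so the expected displacement norm equals
    ``magnitude_mm`` (for a 3D isotropic Gaussian, E||d|| = sigma * 2*sqrt(2/pi),
    hence sigma = magnitude / (2*sqrt(2/pi))).  Displacements landing outside
    the seed's source depot are redrawn, up to ``max_attempts`` times.
    """
    if magnitude_mm < 0:
        raise ConfigError("jitter magnitude must be >= 0")
    if magnitude_mm == 0:
        return list(seeds)
    rng = np.random.default_rng(rng_seed)
    sigma = magnitude_mm / (2.0 * math.sqrt(2.0 / math.pi))
    out = []
    for seed in seeds:
        depot_mask = truth.region_mask(seed.region)
        spacing = np.asarray(truth.spacing_mm)
        placed = False
        for _ in range(max_attempts):
            new_center = np.asarray(seed.center_mm) + rng.normal(0.0, sigma, 3)
            idx = np.round(new_center / spacing).astype(int)
            if np.all(idx >= 0) and np.all(idx < truth.labels.shape) and depot_mask[tuple(idx)]:
                out.append(SeedSpec(seed.region, tuple(float(c) for c in new_center), seed.radius_mm))
                placed = True
                break
        if not placed:
            raise SeedPlacementError(
                f"could not place jittered seed inside depot {seed.region!r} "
                f"after {max_attempts} attempts (depot too small for {magnitude_mm} mm jitter?)"
            )
    return out
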