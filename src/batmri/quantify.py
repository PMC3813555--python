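"""Per-depot volume / fat-fraction statistics and cohort aggregation.

Volumes are voxel count x voxel volume, reported in cc (= mL); fat fractions
are stored as fractions and rendered in percent in summaries.  Cohort
summaries use the sample SD (n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, EmptyRoiError, InsufficientDataError
from .volumes import FatFractionMap, RegionMask, check_congruent, voxel_volume_mm3


@dataclass(frozen=True)
class DepotStats:
    """Volume and FF statistics of one depot in one subject."""

    subject: int | str
    region: str
    volume_cc: float
    mean_ff: float
    sd_ff: float
    n_voxels: int


def depot_stats(
    mask: RegionMask, ff: FatFractionMap, subject: int | str = 0
) -> DepotStats:
    """Depot volume (cc) and mean/SD fat fraction over valid voxels."""
    check_congruent(mask.mask, ff.ff)
    n = mask.n_voxels
    if n == 0:
        raise EmptyRoiError(f"region {mask.label!r} is empty")
    values = ff.ff[mask.mask & ff.valid]
    if values.size == 0:
        raise EmptyRoiError(f"region {mask.label!r} contains no valid FF voxels")
    volume_cc = n * voxel_volume_mm3(mask.spacing_mm) / 1000.0
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return DepotStats(subject, mask.label, volume_cc, float(values.mean()), sd, n)


@dataclass
class CohortTable:
    """Per-subject depot statistics plus per-region cohort summaries."""

    rows: pd.DataFrame  # subject, region, volume_cc, mean_ff, sd_ff, n_voxels
    summary: pd.DataFrame
    missing: pd.DataFrame  # (subject, region) pairs absent from a region's summary

    def region_values(self, region: str, column: str) -> pd.Series:
        sub = self.rows[self.rows["region"] == region]
        return sub.set_index("subject")[column]


def cohort_summary(stats: list[DepotStats]) -> CohortTable:
    """Aggregate per-subject depot statistics into per-region summaries.

    For each region: mean, sample SD (n-1), min and max of depot volume (cc)
    and of mean FF (reported in percent).  Subjects missing a region are
    listed in the completeness report and excluded from that region's
    summary.
    """
    if not stats:
        raise InsufficientDataError("no depot statistics supplied")
    rows = pd.DataFrame([s.__dict__ for s in stats])
    subjects = rows["subject"].unique()
    if len(subjects) < 2:
        raise InsufficientDataError("cohort summary needs at least 2 subjects")

    missing_rows = []
    for region in rows["region"].unique():
        present = set(rows.loc[rows["region"] == region, "subject"])
        for s in subjects:
            if s not in present:
                missing_rows.append({"subject": s, "region": region})
    missing = pd.DataFrame(missing_rows, columns=["subject", "region"])

    def _agg(group: pd.DataFrame) -> pd.Series:
        vol = group["volume_cc"]
        ffp = group["mean_ff"] * 100.0
        return pd.Series(
            {
                "n_subjects": len(group),
                "volume_mean_cc": vol.mean(),
                "volume_sd_cc": vol.std(ddof=1),
                "volume_min_cc": vol.min(),
                "volume_max_cc": vol.max(),
                "ff_mean_pct": ffp.mean(),
                "ff_sd_pct": ffp.std(ddof=1),
                "ff_min_pct": ffp.min(),
                "ff_max_pct": ffp.max(),
            }
        )

    summary = (
        rows.groupby("region", sort=False)[["volume_cc", "mean_ff"]]
        .apply(_agg)
        .reset_index()
    )
    return CohortTable(rows, summary, missing)


@dataclass(frozen=True)
class PairedFFResult:
    """WAT vs BAT paired fat-fraction comparison, in percentage points."""

    delta_pct: float  # mean of per-subject (WAT - BAT) differences
    delta_of_means_pct: float  # difference of the two cohort means (equal here)
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool  # zero variance of the paired differences


def paired_wat_bat(
    table: CohortTable, bat_region: str = "union", wat_region: str = "nuchal_wat"
) -> PairedFFResult:
    """Paired WAT-minus-BAT mean-FF difference with a two-sided paired t test.

    The mean of paired differences and the difference of means coincide on a
    complete layout; both are reported.  Zero variance of the differences
    makes the t statistic undefined and is reported as degenerate rather
    than an error.
    """
    bat = table.region_values(bat_region, "mean_ff")
    wat = table.region_values(wat_region, "mean_ff")
    common = bat.index.intersection(wat.index)
    if len(common) < 2:
        raise InsufficientDataError(
            f"paired comparison needs >= 2 subjects with both regions, got {len(common)}"
        )
    diff = (wat.loc[common] - bat.loc[common]).to_numpy() * 100.0
    delta = float(diff.mean())
    delta_of_means = float(wat.loc[common].mean() - bat.loc[common].mean()) * 100.0
    if diff.std(ddof=1) == 0.0:
        return PairedFFResult(delta, delta_of_means, float("nan"), float("nan"), len(common), True)
    t, p = stats.ttest_rel(wat.loc[common], bat.loc[common])
    return PairedFFResult(delta, delta_of_means, float(t), float(p), len(common), False)


def paired_wat_bat_wilcoxon(
    table: CohortTable, bat_region: str = "union", wat_region: str = "nuchal_wat"
) -> tuple[float, float]:
    """Wilcoxon signed-rank alternative to the paired t test."""
    bat = table.region_values(bat_region, "mean_ff")
    wat = table.region_values(wat_region, "mean_ff")
    common = bat.index.intersection(wat.index)
    if len(common) < 2:
        raise InsufficientDataError("paired comparison needs >= 2 subjects with both regions")
    res = stats.wilcoxon(wat.loc[common], bat.loc[common])
    return float(res.statistic), float(res.pvalue)


def ff_volume_correlation(table: CohortTable, region: str) -> tuple[float, float]:
    """Pearson correlation between depot volume and mean FF across subjects."""
    sub = table.rows[table.rows["region"] == region]
    if len(sub) < 3:
        raise InsufficientDataError(f"correlation needs >= 3 subjects, region {region!r} has {len(sub)}")
    vol = sub["volume_cc"].to_numpy()
    ff = sub["mean_ff"].to_numpy()
    if np.std(vol) == 0.0 or np.std(ff) == 0.0:
        raise DegenerateDataError(f"zero variance in region {region!r}; correlation undefined")
    r, p = stats.pearsonr(vol, ff)
    return float(r), float(p)
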