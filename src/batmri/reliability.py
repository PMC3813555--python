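"""Reliability analysis: rater variance decomposition, scan-rescan agreement
and ROC calibration of the BAT classification thresholds.

Rater reliability uses a two-way random-effects ANOVA (subjects x raters,
single measurement, absolute agreement).  The expected-mean-squares
decomposition yields three variance components — between-subject, between-
rater and residual — whose shares of total variance are reported as

* ICC: between-subject variance / total variance,
* WSC: between-rater (within-subject) variance / total variance,
* N:   residual ("noise") variance / total variance,

with negative component estimates truncated at zero and the shares
renormalized so ICC + WSC + N = 1.  With three ratings (rater 1 twice —
ratings 1a and 1b — plus rater 2), the inter-rater ICC is the average of the
pairwise (1a vs 2) and (1b vs 2) decompositions and the intra-rater ICC is
(1a vs 1b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, LayoutError
from .volumes import FatFractionMap, RegionMask, SignalMask, check_congruent

# ---------------------------------------------------------------------------
# ICC / WSC / N decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceDecomposition:
    """Variance components and their shares for one region x metric."""

    icc: float
    wsc: float
    noise: float
    var_subject: float
    var_rater: float
    var_residual: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def _as_matrix(table: pd.DataFrame, region: str, metric: str, raters: list[str]) -> np.ndarray:
    sub = table[(table["region"] == region) & (table["metric"] == metric)]
    sub = sub[sub["rater"].isin(raters)]
    pivot = sub.pivot_table(index="subject", columns="rater", values="value", aggfunc="first")
    if pivot.isna().any().any() or set(pivot.columns) != set(raters):
        raise LayoutError(
            f"incomplete two-way layout for region {region!r}, metric {metric!r}, "
            f"raters {raters}: every subject must be rated by every rater"
        )
    if len(pivot) < 2:
        raise InsufficientDataError("variance decomposition needs >= 2 subjects")
    return pivot[raters].to_numpy(dtype=float)


def decompose_matrix(y: np.ndarray) -> VarianceDecomposition:
    """Two-way random-effects decomposition of a subjects x raters matrix.

    Expected-mean-squares estimators:
        sigma2_subject  = (MS_subject - MS_error) / k
        sigma2_rater    = (MS_rater   - MS_error) / n
        sigma2_residual = MS_error
    Negative estimates are truncated at 0 and the shares renormalized.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 raters")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ms_subject = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_rater = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ms_error = np.sum(resid**2) / ((n - 1) * (k - 1))

    var_s = max((ms_subject - ms_error) / k, 0.0)
    var_r = max((ms_rater - ms_error) / n, 0.0)
    var_e = max(ms_error, 0.0)
    total = var_s + var_r + var_e
    if total == 0.0:
        return VarianceDecomposition(
            float("nan"), float("nan"), float("nan"), 0.0, 0.0, 0.0, n, k, degenerate=True
        )
    return VarianceDecomposition(
        var_s / total, var_r / total, var_e / total, var_s, var_r, var_e, n, k
    )


def icc_decompose(
    table: pd.DataFrame, region: str, metric: str, raters: list[str] | None = None
) -> VarianceDecomposition:
    """Decompose one region x metric of a rater table into ICC / WSC / N.

    ``table`` has columns (subject, rater, region, metric, value) and must be
    a complete two-way layout for the selected raters.
    """
    if raters is None:
        raters = sorted(table["rater"].unique())
    return decompose_matrix(_as_matrix(table, region, metric, raters))


def _average_decompositions(parts: list[VarianceDecomposition]) -> VarianceDecomposition:
    icc = float(np.mean([p.icc for p in parts]))
    wsc = float(np.mean([p.wsc for p in parts]))
    noise = float(np.mean([p.noise for p in parts]))
    return VarianceDecomposition(
        icc,
        wsc,
        noise,
        float(np.mean([p.var_subject for p in parts])),
        float(np.mean([p.var_rater for p in parts])),
        float(np.mean([p.var_residual for p in parts])),
        parts[0].n_subjects,
        parts[0].n_raters,
        degenerate=any(p.degenerate for p in parts),
    )


def reliability_report(
    table: pd.DataFrame,
    *,
    rating_1a: str = "1a",
    rating_1b: str = "1b",
    rater_2: str = "2",
) -> pd.DataFrame:
    """Inter- and intra-rater ICC/WSC/N per region x metric.

    Inter-rater values average the pairwise decompositions (1a vs 2) and
    (1b vs 2); intra-rater values come from (1a vs 1b).
    """
    rows = []
    for region in table["region"].unique():
        for metric in table.loc[table["region"] == region, "metric"].unique():
            inter = _average_decompositions(
                [
                    icc_decompose(table, region, metric, [rating_1a, rater_2]),
                    icc_decompose(table, region, metric, [rating_1b, rater_2]),
                ]
            )
            intra = icc_decompose(table, region, metric, [rating_1a, rating_1b])
            for kind, d in (("inter", inter), ("intra", intra)):
                rows.append(
                    {
                        "region": region,
                        "metric": metric,
                        "comparison": kind,
                        "icc": d.icc,
                        "wsc": d.wsc,
                        "noise": d.noise,
                        "var_subject": d.var_subject,
                        "var_rater": d.var_rater,
                        "var_residual": d.var_residual,
                        "degenerate": d.degenerate,
                    }
                )
    return pd.DataFrame(rows)


def simulate_rater_table(
    *,
    n_subjects: int,
    raters: list[str],
    sigma_subject: float,
    sigma_rater: float,
    sigma_residual: float,
    mean: float = 0.0,
    region: str = "union",
    metric: str = "volume_cc",
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Simulate a complete rater table from known variance components.

    value(subject s, rater r) = mean + subject_s + rater_r + noise_{sr} with
    the three effects independent zero-mean Gaussians.  Population
    ICC = sigma_subject^2 / (sigma_subject^2 + sigma_rater^2 + sigma_residual^2).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    subj = rng.normal(0.0, sigma_subject, n_subjects)
    rat = rng.normal(0.0, sigma_rater, len(raters))
    rows = []
    for i in range(n_subjects):
        for j, r in enumerate(raters):
            rows.append(
                {
                    "subject": i,
                    "rater": r,
                    "region": region,
                    "metric": metric,
                    "value": mean + subj[i] + rat[j] + rng.normal(0.0, sigma_residual),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scan-rescan voxelwise agreement
# ---------------------------------------------------------------------------


def rescan_agreement(
    ff1: FatFractionMap,
    ff2: FatFractionMap,
    compartments: dict[str, RegionMask],
    signal: SignalMask,
    *,
    min_voxels: int = 10,
) -> pd.DataFrame:
    """Voxelwise FF agreement between two acquisitions, per compartment.

    For each named compartment (plus ``all_other`` = appreciable signal minus
    the union of the compartments) the Pearson correlation of jointly valid
    voxel FFs and the mean absolute FF residual (percentage points) are
    reported.  No registration is applied.  Compartments with fewer than
    ``min_voxels`` jointly valid voxels are skipped with a warning.
    """
    check_congruent(ff1.ff, ff2.ff, signal.mask)
    joint_valid = ff1.valid & ff2.valid
    comp_masks = dict(compartments)
    others = signal.mask.copy()
    for rm in comp_masks.values():
        check_congruent(others, rm.mask)
        others &= ~rm.mask
    rows = []
    for name, mask in [*((k, v.mask) for k, v in comp_masks.items()), ("all_other", others)]:
        sel = mask & joint_valid
        n = int(sel.sum())
        if n < min_voxels:
            warnings.warn(f"compartment {name!r} has only {n} valid voxels; skipped", stacklevel=2)
            continue
        a, b = ff1.ff[sel], ff2.ff[sel]
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(a, b)
        rows.append(
            {
                "compartment": name,
                "n_voxels": n,
                "pearson_r": float(r),
                "p_value": float(p),
                "mean_abs_residual_pct": float(np.abs(a - b).mean()) * 100.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC calibration of FF classification thresholds
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    """Threshold sweep over FF and the chosen operating points.

    ``bat_below[t]`` is the fraction of BAT samples with FF < threshold t,
    ``wat_below[t]`` the corresponding WAT fraction (the false-positive rate
    of an upper threshold at t).
    """

    thresholds: np.ndarray
    bat_below: np.ndarray
    wat_below: np.ndarray
    upper_threshold: float
    lower_threshold: float
    #: operating statistics at the canonical (0.20, 0.60) cuts
    bat_below_060: float
    wat_below_060: float
    bat_above_020: float
    auc: float


def roc_calibrate(
    bat_ff: np.ndarray,
    wat_ff: np.ndarray,
    *,
    step: float = 0.001,
    wat_fpr_max: float = 0.10,
    bat_tpr_min: float = 0.999,
) -> RocResult:
    """Sweep FF thresholds and choose BAT classification operating points.

    The upper threshold is the largest cut whose WAT false-positive rate
    (fraction of WAT below the cut) stays under ``wat_fpr_max``; the lower
    threshold is the largest cut that keeps the fraction of BAT above it at
    least ``bat_tpr_min``.  Rates at the canonical 20% and 60% cuts and the
    trapezoidal AUC (probability a random BAT FF is below a random WAT FF)
    are reported.
    """
    bat = np.asarray(bat_ff, dtype=float)
    wat = np.asarray(wat_ff, dtype=float)
    if bat.size == 0 or wat.size == 0:
        raise InsufficientDataError("both BAT and WAT samples must be nonempty")
    if np.ptp(bat) == 0 and np.ptp(wat) == 0 and bat[0] == wat[0]:
        raise DegenerateDataError("identical constant samples: no threshold separates them")

    thresholds = np.arange(0.0, 1.0 + step / 2, step)
    bat_sorted = np.sort(bat)
    wat_sorted = np.sort(wat)
    bat_below = np.searchsorted(bat_sorted, thresholds, side="left") / bat.size
    wat_below = np.searchsorted(wat_sorted, thresholds, side="left") / wat.size

    ok_upper = thresholds[wat_below < wat_fpr_max]
    upper = float(ok_upper.max()) if ok_upper.size else float("nan")
    ok_lower = thresholds[1.0 - bat_below >= bat_tpr_min]
    lower = float(ok_lower.max()) if ok_lower.size else float("nan")

    i020 = int(round(0.20 / step))
    i060 = int(round(0.60 / step))
    auc = float(
        (bat[:, None] < wat[None, :]).mean() + 0.5 * (bat[:, None] == wat[None, :]).mean()
    ) if bat.size * wat.size <= 10**7 else float(np.trapezoid(bat_below, wat_below))
    return RocResult(
        thresholds,
        bat_below,
        wat_below,
        upper,
        lower,
        bat_below_060=float(bat_below[i060]),
        wat_below_060=float(wat_below[i060]),
        bat_above_020=float(1.0 - bat_below[i020]),
        auc=auc,
    )
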