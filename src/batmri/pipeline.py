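"""End-to-end pipeline: simulate -> separate -> mask -> segment -> quantify
-> reliability, with a run manifest for reproducibility.

The pipeline operates on a synthetic cohort: each subject is a torso phantom
whose dual-echo volumes are separated, FF-mapped, screened for fat/water
swap artifacts (subjects with a swap near an analysis region are excluded,
mirroring the acquisition exclusion protocol), segmented by up to three
emulated raters and quantified.  All tables, masks and a manifest with
per-file checksums are written to the output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from . import __version__
from .batmask import bat_candidate_mask
from .dixon import compute_fat_fraction, flag_swaps, separate_water_fat, signal_mask
from .errors import BatmriError, ConfigError
from .phantom import CohortSpec, SubjectPhantom, jitter_seeds, make_cohort, make_rescan
from .quantify import (
    CohortTable,
    cohort_summary,
    depot_stats,
    ff_volume_correlation,
    paired_wat_bat,
)
from .reliability import reliability_report, rescan_agreement
from .segment import (
    SeedSpec,
    SegmentationProtocol,
    region_group,
    segment_bat_region,
    segment_wat_nuchal,
    snap_seeds_to_eligibility,
    union_region,
)
from .volumes import FatFractionMap, RegionMask, SignalMask

logger = logging.getLogger("batmri")


class StageError(BatmriError):
    """A pipeline stage failed; the stage is named in the message."""


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort run."""

    out_dir: str = "batmri_run"
    n_subjects: int = 4
    scale: float = 1.0
    noise_sd: float = 0.02
    rng_seed: int = 0
    swap_subjects: tuple[int, ...] = ()
    protocol: SegmentationProtocol = field(default_factory=SegmentationProtocol)
    #: rater emulation: seed jitter magnitudes (mm); set raters=False to skip
    raters: bool = True
    intra_rater_jitter_mm: float = 1.0
    inter_rater_jitter_mm: float = 1.5
    rescan: bool = True
    write_volumes: bool = False
    #: distance (mm) from a flagged swap to a seed that triggers exclusion
    swap_exclusion_margin_mm: float = 10.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        proto = data.pop("protocol", None)
        try:
            cfg = cls(**data)
        except TypeError as e:
            raise ConfigError(f"invalid pipeline config: {e}") from e
        if proto:
            for key in ("ff_band", "spine_levels"):
                if key in proto:
                    proto[key] = tuple(proto[key])
            cfg.protocol = SegmentationProtocol(**proto)
        if isinstance(cfg.swap_subjects, list):
            cfg.swap_subjects = tuple(cfg.swap_subjects)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, dict]
    exclusions: list[dict]
    timings_s: dict[str, float]

    def save(self, path: str | Path) -> str:
        path = Path(path)
        path.write_text(json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "outputs": self.outputs,
                "exclusions": self.exclusions,
                "timings_s": self.timings_s,
            },
            indent=2,
            default=str,
        ))
        return str(path)


ANALYSIS_REGIONS = ("supraclavicular", "axillary", "union", "spine", "nuchal_wat")


def segment_subject(
    ff: FatFractionMap,
    fat: np.ndarray,
    seeds: list[SeedSpec],
    proto: SegmentationProtocol,
    signal: SignalMask,
    *,
    snap: bool = True,
) -> dict[str, RegionMask]:
    """Segment all analysis regions of one subject from its seed set.

    Returns masks for supraclavicular, axillary, their union, spine (T1-T5
    pooled) and nuchal WAT.  With ``snap=True`` BAT seeds are moved to the
    nearest in-band voxel first (raters place seeds on visibly in-band
    voxels).
    """
    if snap:
        seeds = snap_seeds_to_eligibility(seeds, ff, proto, signal)
    groups: dict[str, list[SeedSpec]] = {}
    for s in seeds:
        groups.setdefault(region_group(s.region), []).append(s)

    masks: dict[str, RegionMask] = {}
    for group in ("supraclavicular", "axillary", "spine"):
        masks[group] = segment_bat_region(ff, groups[group], proto, signal, label=group)
    masks["union"] = union_region(masks["supraclavicular"], masks["axillary"])
    wat_seeds = groups.get("nuchal_wat", [])
    if len(wat_seeds) != 1:
        raise ConfigError(f"expected exactly one nuchal WAT seed, got {len(wat_seeds)}")
    masks["nuchal_wat"] = segment_wat_nuchal(
        fat, wat_seeds[0], proto, signal, spacing_mm=ff.spacing_mm
    )
    return masks


def analyze_cohort(
    subjects: list[SubjectPhantom],
    proto: SegmentationProtocol | None = None,
) -> CohortTable:
    """Separate, segment and quantify every subject of a synthetic cohort.

    Runs the measurement pipeline (two-point separation with the
    reconstruction dominance map, FF mapping, appreciable-signal masking,
    seeded segmentation of all analysis regions) and aggregates the per-depot
    statistics into a cohort table.
    """
    proto = proto or SegmentationProtocol()
    stats = []
    for s in subjects:
        wf = separate_water_fat(s.echoes, dominance=s.truth.recon_dominance)
        ff = compute_fat_fraction(wf)
        sig = signal_mask(wf)
        masks = segment_subject(ff, wf.fat, s.seeds, proto, sig)
        stats += [depot_stats(masks[r], ff, subject=s.subject) for r in ANALYSIS_REGIONS]
    return cohort_summary(stats)


def _swap_excludes(flags, labels, seeds, spacing, margin_mm) -> bool:
    spacing = np.asarray(spacing)
    for comp in flags:
        coords = np.argwhere(labels == comp.component_id) * spacing
        for seed in seeds:
            d = np.linalg.norm(coords - np.asarray(seed.center_mm), axis=1).min()
            if d <= margin_mm:
                return True
    return False


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full synthetic pipeline and write all artifacts + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, dict] = {}
    exclusions: list[dict] = []
    timings: dict[str, float] = {}

    def _record(name: str, path: str) -> None:
        outputs[name] = {"path": str(path), "sha256": bio.sha256_of(path)}

    def _stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    # --- simulate ---------------------------------------------------------
    t0 = _stage("simulate")
    try:
        cspec = CohortSpec(
            n_subjects=config.n_subjects,
            noise_sd=config.noise_sd,
            scale=config.scale,
            rng_seed=config.rng_seed,
        )
        subjects = make_cohort(cspec, swap_subjects=config.swap_subjects)
        truth_rows = []
        for s in subjects:
            truth_rows.append({"subject": s.subject, **s.params})
            bio.save_seeds_csv(s.seeds, out / f"sub-{s.subject:02d}_seeds.csv")
            _record(f"sub-{s.subject:02d}_seeds", out / f"sub-{s.subject:02d}_seeds.csv")
            if config.write_volumes:
                for name, path in bio.save_dual_echo(s.echoes, out / f"sub-{s.subject:02d}").items():
                    _record(f"sub-{s.subject:02d}_{name}", path)
        truth_path = out / "cohort_truth.csv"
        pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
        _record("cohort_truth", truth_path)
    except BatmriError as e:
        raise StageError(f"stage 'simulate' failed: {e}") from e
    timings["simulate"] = time.perf_counter() - t0

    # --- separate + screen ------------------------------------------------
    t0 = _stage("dixon")
    processed = []
    try:
        for s in subjects:
            wf = separate_water_fat(s.echoes, dominance=s.truth.recon_dominance)
            ff = compute_fat_fraction(wf)
            sig = signal_mask(wf)
            flags, flag_labels = flag_swaps(ff, wf)
            if _swap_excludes(flags, flag_labels, s.seeds, ff.spacing_mm,
                              config.swap_exclusion_margin_mm):
                exclusions.append(
                    {"subject": s.subject, "reason": "fat/water swap near analysis region",
                     "n_flagged_components": len(flags)}
                )
                logger.warning("subject %d excluded: swap artifact near analysis region", s.subject)
                continue
            processed.append((s, wf, ff, sig))
    except BatmriError as e:
        raise StageError(f"stage 'dixon' failed: {e}") from e
    if not processed:
        raise StageError("stage 'dixon' failed: all subjects excluded")
    timings["dixon"] = time.perf_counter() - t0

    # --- BAT candidate mask (visualization/QC) ----------------------------
    t0 = _stage("mask")
    try:
        s0, wf0, ff0, sig0 = processed[0]
        bm = bat_candidate_mask(wf0, ff0)
        bm_path = bio.save_nifti(bm.mask, ff0.spacing_mm, out / "sub-00_batmask.nii", np.uint8)
        _record("sub-00_batmask", bm_path)
        (out / "sub-00_batmask.json").write_text(json.dumps(
            {"total_signal_cut": bm.total_signal_cut, "fat_signal_cut": bm.fat_signal_cut,
             "ff_cut": bm.ff_cut, "fat_criterion": bm.fat_criterion, "n_voxels": bm.n_voxels}
        ))
        _record("sub-00_batmask_thresholds", out / "sub-00_batmask.json")
    except BatmriError as e:
        raise StageError(f"stage 'mask' failed: {e}") from e
    timings["mask"] = time.perf_counter() - t0

    # --- segment + quantify -----------------------------------------------
    t0 = _stage("segment+quantify")
    try:
        stats = []
        rater_rows = []
        raters: list[tuple[str, float]] = [("1a", 0.0)]
        if config.raters:
            raters += [("1b", config.intra_rater_jitter_mm), ("2", config.inter_rater_jitter_mm)]
        for s, wf, ff, sig in processed:
            for rater, jitter_mm in raters:
                seeds = s.seeds
                if jitter_mm > 0:
                    rater_offset = {"1b": 1, "2": 2}.get(rater, 3)
                    jit_seed = (config.rng_seed + s.subject * 1000 + rater_offset * 131) % (2**31)
                    seeds = jitter_seeds(seeds, jitter_mm, s.truth, jit_seed)
                masks = segment_subject(ff, wf.fat, seeds, config.protocol, sig)
                for region in ANALYSIS_REGIONS:
                    d = depot_stats(masks[region], ff, subject=s.subject)
                    if rater == "1a":
                        stats.append(d)
                        if config.write_volumes:
                            p = bio.save_region_mask(
                                masks[region], out / f"sub-{s.subject:02d}_{region}.nii"
                            )
                            _record(f"sub-{s.subject:02d}_{region}", p)
                    rater_rows.append({"subject": s.subject, "rater": rater, "region": region,
                                       "metric": "volume_cc", "value": d.volume_cc})
                    rater_rows.append({"subject": s.subject, "rater": rater, "region": region,
                                       "metric": "mean_ff", "value": d.mean_ff})

        table = cohort_summary(stats)
        table.rows.to_csv(out / "cohort_stats.csv", index=False)
        table.summary.to_csv(out / "cohort_summary.csv", index=False)
        _record("cohort_stats", out / "cohort_stats.csv")
        _record("cohort_summary", out / "cohort_summary.csv")
        analysis = _cohort_analysis(table)
        (out / "cohort_analysis.json").write_text(json.dumps(analysis, indent=2))
        _record("cohort_analysis", out / "cohort_analysis.json")
    except BatmriError as e:
        raise StageError(f"stage 'segment+quantify' failed: {e}") from e
    timings["segment+quantify"] = time.perf_counter() - t0

    # --- reliability -------------------------------------------------------
    if config.raters and len(processed) >= 2:
        t0 = _stage("reliability")
        try:
            rater_table = pd.DataFrame(rater_rows)
            rater_table.to_csv(out / "rater_table.csv", index=False)
            _record("rater_table", out / "rater_table.csv")
            report = reliability_report(rater_table)
            report.to_csv(out / "reliability.csv", index=False)
            _record("reliability", out / "reliability.csv")
        except BatmriError as e:
            raise StageError(f"stage 'reliability' failed: {e}") from e
        timings["reliability"] = time.perf_counter() - t0

    # --- scan-rescan --------------------------------------------------------
    if config.rescan:
        t0 = _stage("rescan")
        try:
            s, wf, ff, sig = processed[0]
            echoes2 = make_rescan(s.truth, config.noise_sd, config.rng_seed + 10_001)
            wf2 = separate_water_fat(echoes2, dominance=s.truth.recon_dominance)
            ff2 = compute_fat_fraction(wf2)
            masks = segment_subject(ff, wf.fat, s.seeds, config.protocol, sig)
            bat_all = union_region(masks["union"], masks["spine"], label="bat_all")
            agreement = rescan_agreement(
                ff, ff2, {"bat": bat_all, "nuchal_wat": masks["nuchal_wat"]}, sig
            )
            agreement.to_csv(out / "rescan_agreement.csv", index=False)
            _record("rescan_agreement", out / "rescan_agreement.csv")
        except BatmriError as e:
            raise StageError(f"stage 'rescan' failed: {e}") from e
        timings["rescan"] = time.perf_counter() - t0

    manifest = RunManifest(config.to_dict(), __version__, outputs, exclusions, timings)
    manifest.save(out / "manifest.json")
    logger.info("pipeline complete: %d subjects analysed, %d excluded",
                len(processed), len(exclusions))
    return manifest


def _cohort_analysis(table: CohortTable) -> dict:
    """Headline cohort statistics: paired WAT-BAT contrast and FF-volume r."""
    paired = paired_wat_bat(table)
    out = {
        "delta_wat_bat_pct": paired.delta_pct,
        "delta_of_means_pct": paired.delta_of_means_pct,
        "paired_t": paired.t_statistic,
        "paired_p": paired.p_value,
        "n": paired.n,
        "degenerate": paired.degenerate,
        "ff_volume_r": {},
    }
    for region in ("supraclavicular", "axillary", "union", "spine"):
        try:
            r, p = ff_volume_correlation(table, region)
            out["ff_volume_r"][region] = {"r": r, "p": p}
        except BatmriError as e:
            out["ff_volume_r"][region] = {"error": str(e)}
    return out
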