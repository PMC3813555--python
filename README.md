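# batmri

Quantification of brown adipose tissue (BAT) from two-point water–fat MRI,
built for neonatal torso imaging and validated end to end on synthetic
phantoms with analytic ground truth.

## The problem

BAT is the thermogenic, water-rich adipose tissue of newborns; white adipose
tissue (WAT) is unilocular and fat-rich. On chemical-shift ("Dixon") MRI the
two separate cleanly on the **fat signal fraction**

```
FF = F / (F + W)
```

the per-voxel ratio of fat signal to combined fat+water signal: neonatal BAT
sits roughly in the 20–60 % FF band while WAT lies above it. `batmri`
implements the full measurement chain a BAT imaging study needs:

* **dixon** — two-point in-phase/opposed-phase separation
  (`W = (IP+OP)/2`, `F = (IP−OP)/2` under per-voxel dominance), FF mapping
  with a validity mask, appreciable-signal masking (total signal
  > mean + 2 SD over the whole image), and advisory flagging of fat/water
  swap artifacts;
* **batmask** — the three-criterion rule-based BAT candidate mask for
  visualization/QC (total-signal, fat-signal and FF > 20 % cuts);
* **segment** — seeded, threshold-constrained region growing reproducing a
  semi-automated protocol: 3 mm seed bubbles, FF band 20–60 % for BAT
  (50 iterations; spine limited to vertebrae T1–T5, one seed per side per
  level), and nuchal WAT on the fat-only image above its lowest quartile
  (single 5 mm seed, 100 iterations);
* **quantify** — depot volume (voxel count × 0.97 × 0.97 × 1 mm³) and FF
  statistics, cohort summaries, paired WAT−BAT contrast, FF–volume
  correlations;
* **reliability** — two-way random-effects variance decomposition reported
  as ICC (between-subject share), WSC (between-rater share) and N (residual
  share), scan–rescan voxelwise FF agreement, and ROC calibration of the
  20 % / 60 % classification thresholds;
* **phantom** — the synthetic-data generator: ex-vivo vial phantoms and
  neonate torso phantoms (bilateral supraclavicular, axillary and spinal
  T1–T5 BAT depots plus nuchal WAT) whose voxel FF values follow skew-normal
  laws moment-matched to published tissue statistics, cohorts with stated
  between-subject distributions, scan–rescan replicates and rater seed
  jitter.

No scan data ship with the package; every number below is computed at run
time from phantoms.

## Worked example

Generate a 22-subject synthetic cohort, push every subject through
separation, segmentation and quantification, and summarize:

```python
from batmri.phantom import CohortSpec, make_cohort
from batmri.pipeline import analyze_cohort
from batmri.quantify import paired_wat_bat

cohort = make_cohort(CohortSpec(n_subjects=22, rng_seed=0))
table = analyze_cohort(cohort)
print(table.summary.set_index("region").round(2))
paired = paired_wat_bat(table)   # nuchal WAT vs supraclavicular+axillary union
print(f"WAT-BAT contrast: {paired.delta_pct:.1f} pp (p = {paired.p_value:.1e})")
```

which prints (volumes in cc, FF in percent):

```
                 volume_mean_cc  volume_sd_cc  volume_min_cc  volume_max_cc  ff_mean_pct  ff_sd_pct
supraclavicular            2.80          1.32           0.43           5.60        29.21       3.52
axillary                   3.63          1.69           0.56           7.14        30.55       3.17
union                      6.43          3.01           0.99          12.74        30.01       2.19
spine                      3.61          1.35           0.99           6.02        32.20       3.14
nuchal_wat                 5.04          1.46           2.50           8.01        68.08       4.36
WAT-BAT contrast: 38.1 pp (p = 3.9e-21)
```

The segmented depot volumes and fat fractions recover the generating
cohort statistics (union BAT ~6.5 cc at ~30 % FF, nuchal WAT at ~68 % FF),
and the paired WAT−BAT fat-fraction contrast is ~38 percentage points —
water content, not fat, is what distinguishes BAT.

The same run is available from the shell, including rater-jitter reliability
and a scan–rescan stage:

```bash
batmri run-all --subjects 4 --seed 0 --out demo_run
batmri simulate --kind vials --out vial && batmri dixon --echoes vial --out vial
```

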