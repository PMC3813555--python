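"""ICC/WSC/N variance decomposition, scan-rescan agreement, ROC calibration."""

import numpy as np
import pandas as pd
import pytest

from batmri.dixon import compute_fat_fraction, separate_water_fat
from batmri.errors import DegenerateDataError, LayoutError
from batmri.phantom import EX_VIVO_BAT, EX_VIVO_WAT, make_rescan, sample_ff
from batmri.reliability import (
    decompose_matrix,
    icc_decompose,
    reliability_report,
    rescan_agreement,
    roc_calibrate,
    simulate_rater_table,
)
from batmri.volumes import FatFractionMap, RegionMask, SignalMask


def _oracle_components(y):
    """Independent expected-mean-squares ANOVA oracle (sums of squares)."""
    n, k = y.shape
    grand = y.mean()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_rater = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_rater
    ms_subj = ss_subj / (n - 1)
    ms_rater = ss_rater / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return max((ms_subj - ms_err) / k, 0), max((ms_rater - ms_err) / n, 0), ms_err


class TestIccDecomposition:
    def test_identical_raters_all_subject_variance(self):
        y = np.column_stack([np.arange(6.0)] * 2)
        d = decompose_matrix(y)
        assert d.icc == pytest.approx(1.0)
        assert d.wsc == pytest.approx(0.0) and d.noise == pytest.approx(0.0)

    def test_rater_offset_all_rater_variance(self):
        y = np.column_stack([np.full(6, 3.0), np.full(6, 5.0)])
        d = decompose_matrix(y)
        assert d.wsc == pytest.approx(1.0)
        assert d.icc == pytest.approx(0.0) and d.noise == pytest.approx(0.0)

    def test_random_tables_match_anova_oracle(self, rng):
        """Components of random 6 x 2 tables equal the mean-squares oracle."""
        for _ in range(20):
            y = rng.normal(10, 2, size=(6, 2))
            d = decompose_matrix(y)
            s, r, e = _oracle_components(y)
            assert d.var_subject == pytest.approx(s, abs=1e-10)
            assert d.var_rater == pytest.approx(r, abs=1e-10)
            assert d.var_residual == pytest.approx(e, abs=1e-10)
            total = s + r + e
            assert d.icc == pytest.approx(s / total, abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        """Without truncation, the subject-variance share equals ICC(2,1)."""
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(5, 1, size=(8, 3)) + rng.normal(0, 1, 8)[:, None]
        d = decompose_matrix(y)
        if min(d.var_subject, d.var_rater) > 0:  # truncation-free case
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(8), 3),
                    "rater": np.tile(np.arange(3), 8),
                    "value": y.ravel(),
                }
            )
            icc_table = pingouin.intraclass_corr(
                df, targets="subject", raters="rater", ratings="value"
            ).set_index("Type")
            # single-measurement absolute-agreement ICC (a.k.a. ICC2)
            key = "ICC(A,1)" if "ICC(A,1)" in icc_table.index else "ICC2"
            icc2 = icc_table.loc[key, "ICC"]
            assert d.icc == pytest.approx(icc2, abs=1e-6)

    def test_shares_sum_to_one_and_in_range(self, rng):
        for _ in range(50):
            y = rng.normal(0, rng.uniform(0.5, 5), size=(rng.integers(2, 12), rng.integers(2, 4)))
            d = decompose_matrix(y)
            if not d.degenerate:
                assert d.icc + d.wsc + d.noise == pytest.approx(1.0, abs=1e-12)
                for v in (d.icc, d.wsc, d.noise):
                    assert 0.0 <= v <= 1.0

    def test_affine_invariance(self, rng):
        y = rng.normal(3, 1, size=(7, 2))
        a, b = decompose_matrix(y), decompose_matrix(4.2 * y - 17.0)
        assert a.icc == pytest.approx(b.icc, abs=1e-10)
        assert a.wsc == pytest.approx(b.wsc, abs=1e-10)
        assert a.noise == pytest.approx(b.noise, abs=1e-10)

    def test_degenerate_zero_variance_flagged(self):
        d = decompose_matrix(np.full((4, 2), 2.5))
        assert d.degenerate and np.isnan(d.icc)

    def test_incomplete_layout_rejected(self):
        table = simulate_rater_table(
            n_subjects=4, raters=["1a", "2"], sigma_subject=1, sigma_rater=0.1,
            sigma_residual=0.1, rng=0,
        )
        with pytest.raises(LayoutError):
            icc_decompose(table.iloc[:-1], "union", "volume_cc", ["1a", "2"])

    @pytest.mark.parametrize("pop_icc", [0.41, 0.61, 0.86, 0.97])
    def test_population_icc_recovered(self, pop_icc):
        """Simulated tables recover population ICC across the reported range
        (0.41-0.97) within 3 Monte-Carlo standard errors."""
        sigma_s = np.sqrt(pop_icc)
        sigma_e = np.sqrt(1.0 - pop_icc)
        reps = 30
        estimates = []
        for rep in range(reps):
            table = simulate_rater_table(
                n_subjects=40, raters=["1a", "2"], sigma_subject=sigma_s,
                sigma_rater=0.0, sigma_residual=sigma_e, rng=rep,
            )
            estimates.append(icc_decompose(table, "union", "volume_cc", ["1a", "2"]).icc)
        se = np.std(estimates, ddof=1) / np.sqrt(reps)
        assert np.mean(estimates) == pytest.approx(pop_icc, abs=max(3 * se, 0.02))

    def test_report_structure_inter_intra(self):
        parts = []
        for rater, jitter in [("1a", 0.0), ("1b", 0.05), ("2", 0.3)]:
            t = simulate_rater_table(
                n_subjects=10, raters=[rater], sigma_subject=1.0, sigma_rater=0.0,
                sigma_residual=0.1, rng=7,
            )
            parts.append(t)
        table = pd.concat(parts, ignore_index=True)
        report = reliability_report(table)
        assert set(report["comparison"]) == {"inter", "intra"}
        ok = report[~report["degenerate"]]
        np.testing.assert_allclose(
            ok[["icc", "wsc", "noise"]].sum(axis=1), 1.0, atol=1e-9
        )


def _ffmap(values, valid=None):
    values = np.asarray(values, dtype=float)
    valid = np.ones(values.shape, dtype=bool) if valid is None else valid
    return FatFractionMap(values, valid)


class TestRescanAgreement:
    def _scene(self, rng, noise=0.0):
        base = rng.uniform(0.2, 0.8, size=(12, 12, 4))
        ff1 = _ffmap(np.clip(base + rng.normal(0, noise, base.shape), 0, 1))
        ff2 = _ffmap(np.clip(base + rng.normal(0, noise, base.shape), 0, 1))
        bat = np.zeros(base.shape, dtype=bool)
        bat[2:6, 2:6, :] = True
        sig = SignalMask(np.ones(base.shape, dtype=bool), 0.0, 1.0)
        return ff1, ff2, {"bat": RegionMask(bat, "bat")}, sig

    def test_identical_inputs_perfect_agreement(self, rng):
        ff1, _, comp, sig = self._scene(rng)
        out = rescan_agreement(ff1, ff1, comp, sig).set_index("compartment")
        assert out.loc["bat", "pearson_r"] == pytest.approx(1.0)
        assert out.loc["bat", "mean_abs_residual_pct"] == 0.0

    def test_independent_maps_uncorrelated(self, rng):
        shape = (20, 20, 5)
        ff1 = _ffmap(rng.uniform(0, 1, shape))
        ff2 = _ffmap(rng.uniform(0, 1, shape))
        sig = SignalMask(np.ones(shape, dtype=bool), 0.0, 1.0)
        out = rescan_agreement(ff1, ff2, {}, sig).set_index("compartment")
        assert abs(out.loc["all_other", "pearson_r"]) < 0.05

    def test_symmetric_in_inputs(self, rng):
        ff1, ff2, comp, sig = self._scene(rng, noise=0.02)
        a = rescan_agreement(ff1, ff2, comp, sig).set_index("compartment")
        b = rescan_agreement(ff2, ff1, comp, sig).set_index("compartment")
        pd.testing.assert_frame_equal(a, b)

    def test_small_compartment_skipped(self, rng):
        ff1, ff2, comp, sig = self._scene(rng)
        tiny = np.zeros(ff1.shape, dtype=bool)
        tiny[0, 0, 0] = True
        comp["tiny"] = RegionMask(tiny, "tiny")
        with pytest.warns(UserWarning, match="tiny"):
            out = rescan_agreement(ff1, ff2, comp, sig)
        assert "tiny" not in set(out["compartment"])

    def test_phantom_residual_matches_direct_simulation(self, torso_small):
        """Pipeline-measured scan/rescan residual equals a direct two-draw
        simulation at the same noise level."""
        truth = torso_small["truth"]
        noise = 0.02
        ff1 = compute_fat_fraction(
            separate_water_fat(make_rescan(truth, noise, 31), dominance=truth.recon_dominance)
        )
        ff2 = compute_fat_fraction(
            separate_water_fat(make_rescan(truth, noise, 32), dominance=truth.recon_dominance)
        )
        bat = RegionMask(truth.region_mask("supraclavicular_L"), "bat", truth.spacing_mm)
        sig = SignalMask(truth.total > 0.75, 0.0, 1.0)
        out = rescan_agreement(ff1, ff2, {"bat": bat}, sig).set_index("compartment")
        # direct oracle: ff noise sd per echo pair, |difference| of two draws
        rng = np.random.default_rng(77)
        w, f = truth.water[bat.mask], truth.fat[bat.mask]
        draws = []
        for _ in range(60):
            d = []
            for _ in range(2):
                ip = w + f + rng.normal(0, noise, w.shape)
                op = np.abs(w - f) + rng.normal(0, noise, w.shape)
                fat = np.maximum((ip - op) / 2, 0)
                wat = np.maximum((ip + op) / 2, 0)
                d.append(fat / np.maximum(fat + wat, 1e-9))
            draws.append(np.abs(d[0] - d[1]).mean())
        assert out.loc["bat", "mean_abs_residual_pct"] == pytest.approx(
            np.mean(draws) * 100, rel=0.15
        )


class TestRocCalibration:
    def test_perfectly_separated_samples(self):
        roc = roc_calibrate(np.full(50, 0.3), np.full(50, 0.8))
        assert roc.wat_below_060 == 0.0
        assert roc.bat_below_060 == 1.0
        assert roc.bat_above_020 == 1.0
        assert roc.auc == pytest.approx(1.0)
        assert 0.3 < roc.upper_threshold <= 0.8

    def test_ex_vivo_operating_points(self):
        """Moment-matched ex-vivo samples reproduce the threshold statistics:
        ~99% of BAT below 60% FF and ~99.7% above 20% FF."""
        bat = sample_ff(EX_VIVO_BAT, 200_000, rng=5).values
        wat = sample_ff(EX_VIVO_WAT, 200_000, rng=6).values
        roc = roc_calibrate(bat, wat)
        assert roc.bat_below_060 * 100 == pytest.approx(98.8, abs=0.3)
        assert roc.bat_above_020 * 100 == pytest.approx(99.7, abs=0.2)
        # WAT false-positive rate at the 60% cut sits near 11% for the
        # skew-normal reconstruction of the ex-vivo WAT distribution
        assert roc.wat_below_060 * 100 == pytest.approx(11.4, abs=0.6)
        assert roc.upper_threshold < 0.60  # the <10% FPR cut is a bit stricter

    def test_rates_monotone_in_threshold(self, rng):
        roc = roc_calibrate(rng.uniform(0.2, 0.6, 1000), rng.uniform(0.5, 0.9, 1000))
        assert (np.diff(roc.bat_below) >= 0).all()
        assert (np.diff(roc.wat_below) >= 0).all()

    def test_auc_trapezoid_equals_pairwise_probability(self, rng):
        """Trapezoidal area under the ROC curve equals the brute-force
        probability that a random BAT FF lies below a random WAT FF."""
        bat = rng.uniform(0.1, 0.7, 40)
        wat = rng.uniform(0.4, 0.9, 30)
        roc = roc_calibrate(bat, wat)
        trapezoid = float(np.trapezoid(roc.bat_below, roc.wat_below))
        assert roc.auc == pytest.approx(trapezoid, abs=0.01)

    def test_identical_constants_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_calibrate(np.full(10, 0.5), np.full(10, 0.5))
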