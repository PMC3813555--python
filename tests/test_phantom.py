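"""Phantom generator: moment matching, forward model, cohorts, rescans, jitter."""

import numpy as np
import pytest
from scipy import stats

from batmri.dixon import compute_fat_fraction, separate_water_fat
from batmri.errors import (
    ConfigError,
    GeometryError,
    UnrepresentableDistributionError,
)
from batmri.phantom import (
    EX_VIVO_BAT,
    EX_VIVO_WAT,
    CohortSpec,
    Depot,
    DepotGeometry,
    PhantomSpec,
    TissueDistribution,
    build_truth,
    forward_echoes,
    jitter_seeds,
    make_cohort,
    make_rescan,
    make_torso_phantom,
    make_vial_phantom,
    sample_cohort_parameters,
    sample_ff,
    skewnorm_params,
    torso_phantom_spec,
    vial_phantom_spec,
)

from conftest import SMALL_SCALE


class TestSampleFF:
    @pytest.mark.parametrize("dist", [EX_VIVO_BAT, EX_VIVO_WAT])
    def test_moments_recovered(self, dist):
        """Large samples reproduce the requested mean, SD and skewness."""
        n = 400_000
        values, clip_frac = sample_ff(dist, n, rng=42)
        assert clip_frac < 1e-3
        assert values.mean() == pytest.approx(dist.mean_ff, abs=3 * dist.sd_ff / np.sqrt(n))
        assert values.std() == pytest.approx(dist.sd_ff, abs=0.002)
        assert stats.skew(values) == pytest.approx(dist.skewness, abs=3 * np.sqrt(6 / n))
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_moment_matching_is_exact_analytically(self):
        """Matched skew-normal parameters yield the requested moments exactly."""
        for mean, sd, skew in [(0.437, 0.078, -0.27), (0.733, 0.104, -0.85), (0.5, 0.1, 0.6)]:
            a, loc, scale = skewnorm_params(mean, sd, skew)
            m, v, s = stats.skewnorm.stats(a, loc=loc, scale=scale, moments="mvs")
            assert m == pytest.approx(mean, abs=1e-12)
            assert np.sqrt(v) == pytest.approx(sd, abs=1e-12)
            assert s == pytest.approx(skew, abs=1e-9)

    def test_degenerate_point_mass(self):
        values, clip_frac = sample_ff(TissueDistribution("x", 0.5, 0.0), 100, rng=0)
        assert np.all(values == 0.5) and clip_frac == 0.0

    def test_unattainable_skewness_rejected(self):
        with pytest.raises(UnrepresentableDistributionError):
            TissueDistribution("x", 0.5, 0.1, 0.9999)
        with pytest.raises(UnrepresentableDistributionError):
            skewnorm_params(0.5, 0.1, -1.2)


class TestVialPhantom:
    def test_roundtrip_roi_means(self, vial):
        """Measured vial FF means land on the generating distribution means."""
        echoes, truth = vial
        wf = separate_water_fat(echoes, dominance=truth.recon_dominance)
        ff = compute_fat_fraction(wf)
        for region, expected in [("bat_vial", 0.437), ("wat_vial", 0.733)]:
            m = truth.region_mask(region) & ff.valid
            assert ff.ff[m].mean() == pytest.approx(expected, abs=0.006)

    def test_equal_water_fat_cancels_opposed_phase(self):
        """FF = 0.5 everywhere makes the noiseless opposed-phase echo vanish."""
        half = TissueDistribution("half", 0.5, 0.0)
        base = vial_phantom_spec(noise_sd=0.0, rng_seed=0)
        depots = tuple(Depot(d.geometry, half) for d in base.depots)
        with pytest.raises(ConfigError):
            # identical distributions are rejected: vials must differ
            make_vial_phantom(PhantomSpec(base.grid_shape, depots, noise_sd=0.0))
        truth = build_truth(PhantomSpec(base.grid_shape, depots, noise_sd=0.0))
        echoes = forward_echoes(truth, 0.0, 0)
        inside = truth.labels > 0
        assert np.allclose(echoes.opposed_phase[inside], 0.0)
        assert np.allclose(echoes.in_phase[inside], 1.0)

    def test_overlapping_vials_rejected(self):
        d = TissueDistribution("a", 0.4, 0.05)
        e = TissueDistribution("b", 0.7, 0.05)
        g = DepotGeometry("v1", (15.0, 15.0, 15.0), (8.0, 8.0, 8.0))
        h = DepotGeometry("v2", (20.0, 15.0, 15.0), (8.0, 8.0, 8.0))
        with pytest.raises(GeometryError):
            make_vial_phantom(PhantomSpec((32, 32, 32), (Depot(g, d), Depot(h, e))))

    def test_zero_noise_forward_inverse_identity(self):
        echoes, truth = make_vial_phantom(vial_phantom_spec(noise_sd=0.0, rng_seed=5))
        wf = separate_water_fat(echoes, dominance=truth.recon_dominance)
        np.testing.assert_allclose(wf.water, truth.water, atol=1e-12)
        np.testing.assert_allclose(wf.fat, truth.fat, atol=1e-12)


def _ellipsoid_volume_bounds(geom, spacing):
    """Analytic volumes of the ellipsoid grown/shrunk by one voxel shell."""
    h = max(spacing)
    grow = np.prod([r + h for r in geom.radii_mm])
    shrink = np.prod([max(r - h, 0.0) for r in geom.radii_mm])
    return (4 / 3 * np.pi * shrink / 1000.0, 4 / 3 * np.pi * grow / 1000.0)


class TestTorsoPhantom:
    def test_depot_volumes_within_voxel_shell(self, torso_small):
        """Voxelized depot volumes bracket the analytic ellipsoid volume."""
        truth = torso_small["truth"]
        table = truth.region_table().set_index("region")
        for depot in truth.depots:
            region = depot.geometry.region
            if region == "other_soft_tissue":
                continue
            lo, hi = _ellipsoid_volume_bounds(depot.geometry, truth.spacing_mm)
            assert lo <= table.loc[region, "volume_cc"] <= hi

    def test_bat_ff_in_band_wat_above(self, torso_small):
        truth = torso_small["truth"]
        ff = truth.ff
        for region in ("supraclavicular_L", "axillary_R", "spine_T3_L"):
            vals = ff[truth.region_mask(region)]
            assert vals.min() >= 0.20 and vals.max() <= 0.60
        wat = ff[truth.region_mask("nuchal_wat")]
        assert wat.min() > 0.55
        body = ff[truth.region_mask("other_soft_tissue")]
        assert np.quantile(body, 0.99) < 0.20

    def test_true_ff_is_fat_over_total(self, torso_small):
        truth = torso_small["truth"]
        total = truth.water + truth.fat
        inside = total > 0
        np.testing.assert_allclose(
            truth.ff[inside], truth.fat[inside] / total[inside], atol=1e-12
        )

    def test_seeds_are_centroids_inside_depots(self, torso_small):
        truth, seeds = torso_small["truth"], torso_small["seeds"]
        assert len(seeds) == 15  # 2 sc + 2 ax + 10 spine + 1 WAT
        spacing = np.asarray(truth.spacing_mm)
        for s in seeds:
            idx = tuple(np.round(np.asarray(s.center_mm) / spacing).astype(int))
            assert truth.region_names[int(truth.labels[idx])] == s.region

    def test_empty_depot_list_gives_all_background(self):
        truth = build_truth(PhantomSpec((16, 16, 16), ()))
        assert np.all(truth.labels == 0)
        assert np.all(truth.water == 0) and np.all(truth.fat == 0)

    def test_depot_outside_grid_rejected(self):
        spec = torso_phantom_spec(scale=SMALL_SCALE, grid_shape=(30, 20, 12))
        with pytest.raises(GeometryError):
            make_torso_phantom(spec)

    def test_missing_depot_rejected(self):
        spec = torso_phantom_spec(scale=SMALL_SCALE)
        partial = PhantomSpec(spec.grid_shape, spec.depots[:4], noise_sd=0.0)
        with pytest.raises(ConfigError):
            make_torso_phantom(partial)


class TestCohort:
    def test_parameter_sampling_matches_population(self):
        """A default 22-subject cohort tracks the generative cohort statistics."""
        params = sample_cohort_parameters(CohortSpec(rng_seed=3))
        assert len(params) == 22
        assert params["union_volume_cc"].mean() == pytest.approx(6.50, abs=0.5)
        assert params["union_volume_cc"].std() == pytest.approx(3.10, abs=1.2)
        assert params["nuchal_ff"].mean() == pytest.approx(0.677, abs=0.01)
        assert params["supraclavicular_ff"].mean() == pytest.approx(0.289, abs=0.01)
        # union split preserved exactly
        np.testing.assert_allclose(
            params["supraclavicular_volume_cc"] + params["axillary_volume_cc"],
            params["union_volume_cc"],
        )

    def test_zero_sd_gives_identical_subjects(self):
        cspec = CohortSpec(
            n_subjects=2,
            union_volume=(6.5, 0.0),
            spine_volume=(3.65, 0.0),
            nuchal_volume=(5.0, 0.0),
            supraclavicular_ff=(0.289, 0.0),
            axillary_ff=(0.303, 0.0),
            spine_ff=(0.322, 0.0),
            nuchal_ff=(0.677, 0.0),
        )
        params = sample_cohort_parameters(cspec)
        assert (params.drop(columns="subject").nunique() == 1).all()

    def test_determinism_bitwise(self):
        cspec = CohortSpec(n_subjects=2, scale=0.45, rng_seed=9)
        a = make_cohort(cspec)
        b = make_cohort(cspec)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.echoes.in_phase, sb.echoes.in_phase)
            np.testing.assert_array_equal(sa.echoes.opposed_phase, sb.echoes.opposed_phase)
            np.testing.assert_array_equal(sa.truth.labels, sb.truth.labels)
            np.testing.assert_array_equal(sa.truth.fat, sb.truth.fat)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec(n_subjects=1)


class TestRescan:
    def test_zero_noise_rescan_identical(self, torso_small):
        truth = torso_small["truth"]
        a = make_rescan(truth, 0.0, 1)
        b = make_rescan(truth, 0.0, 2)
        np.testing.assert_array_equal(a.in_phase, b.in_phase)
        np.testing.assert_array_equal(a.in_phase, truth.water + truth.fat)

    def test_ff_difference_unbiased_and_matches_mc_oracle(self, torso_small):
        """Scan/rescan FF residuals are centered and sized like a direct
        two-realization Monte-Carlo simulation of the same forward model."""
        truth = torso_small["truth"]
        noise_sd = 0.02
        e1 = make_rescan(truth, noise_sd, 21)
        e2 = make_rescan(truth, noise_sd, 22)
        ff1 = compute_fat_fraction(separate_water_fat(e1, dominance=truth.recon_dominance))
        ff2 = compute_fat_fraction(separate_water_fat(e2, dominance=truth.recon_dominance))
        bat = truth.region_mask("axillary_L") & ff1.valid & ff2.valid
        diff = ff1.ff[bat] - ff2.ff[bat]
        assert abs(diff.mean()) < 5 * diff.std() / np.sqrt(diff.size)

        # independent brute-force oracle on the same voxels
        rng = np.random.default_rng(99)
        w, f = truth.water[bat], truth.fat[bat]
        reps = 40
        resid = []
        for _ in range(reps):
            ffs = []
            for _ in range(2):
                ip = w + f + rng.normal(0, noise_sd, w.shape)
                op = np.abs(w - f) + rng.normal(0, noise_sd, w.shape)
                wat = (np.maximum(ip, 0) + np.maximum(op, 0)) / 2
                fat = (np.maximum(ip, 0) - np.maximum(op, 0)) / 2
                fat = np.maximum(fat, 0)
                ffs.append(fat / np.maximum(wat + fat, 1e-9))
            resid.append(np.abs(ffs[0] - ffs[1]).mean())
        oracle = np.mean(resid)
        assert np.abs(diff).mean() == pytest.approx(oracle, rel=0.15)

    def test_bias_field_changes_signal_not_ff(self, torso_small):
        truth = torso_small["truth"]
        e = make_rescan(truth, 0.0, 5, bias_amplitude=0.1)
        wf = separate_water_fat(e, dominance=truth.recon_dominance)
        ff = compute_fat_fraction(wf)
        m = truth.region_mask("nuchal_wat")
        assert not np.allclose(e.in_phase[m], (truth.water + truth.fat)[m])
        np.testing.assert_allclose(ff.ff[m], truth.ff[m], atol=1e-9)


class TestJitterSeeds:
    def test_zero_magnitude_identity(self, torso_small):
        seeds = torso_small["seeds"]
        assert jitter_seeds(seeds, 0.0, torso_small["truth"], 1) == list(seeds)

    def test_mean_displacement_matches_law(self, torso_small):
        """E||displacement|| equals the requested magnitude (chi-3 law)."""
        truth, seeds = torso_small["truth"], torso_small["seeds"]
        nuchal = [s for s in seeds if s.region == "nuchal_wat"]
        disp = []
        for k in range(400):
            j = jitter_seeds(nuchal, 1.0, truth, 1000 + k)[0]
            disp.append(np.linalg.norm(np.subtract(j.center_mm, nuchal[0].center_mm)))
        assert np.mean(disp) == pytest.approx(1.0, abs=0.1)

    def test_jittered_seeds_stay_inside_depot(self, torso_small):
        truth, seeds = torso_small["truth"], torso_small["seeds"]
        spacing = np.asarray(truth.spacing_mm)
        jittered = jitter_seeds(seeds, 1.0, truth, 77)
        for s in jittered:
            idx = tuple(np.round(np.asarray(s.center_mm) / spacing).astype(int))
            assert truth.region_names[int(truth.labels[idx])] == s.region
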