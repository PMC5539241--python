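import dataclasses
import math

import numpy as np
import pytest

from ceusvv import (
    ConfigurationError,
    GroupSpec,
    InvalidParameterError,
    KineticsParams,
    MarkerParams,
    PhantomGeometry,
    calibrate_marker,
    default_cohort_config,
    marker_for_target_correlation,
    render_cine_loop,
    replenishment_intensity,
    simulate_cohort,
    simulate_histology_counts,
    true_density_count_correlation,
)
from ceusvv.synth import DEFAULT_GROUP_DENSITIES, default_phantom, default_rois


class TestGeometry:
    def test_compartments_partition_the_image(self, fixture_geometry):
        masks = fixture_geometry.masks()
        total = np.zeros((16, 16), int)
        for m in masks.values():
            total += m.astype(int)
        assert np.all(total == 1)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomGeometry(16, 16, (6, 10), ((3, 7), (11, 13)))

    def test_band_outside_image_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomGeometry(16, 16, (6, 10), ((3, 5), (11, 17)))

    def test_plaque_must_stay_inside_lumen(self):
        geom = PhantomGeometry(
            16, 16, (6, 10), ((3, 5), (11, 13)),
            plaque_polygon=np.array([[2, 2], [6, 2], [6, 9], [2, 9]]),
        )
        with pytest.raises(ConfigurationError):
            geom.masks()

    def test_default_phantoms_are_valid_for_all_groups(self):
        cfg = default_cohort_config(n_per_group=2)
        for plaque, occl in [(False, False), (True, False), (True, True)]:
            geom = default_phantom(cfg, plaque, occl)
            masks = geom.masks()
            assert all(m.any() for m in masks.values())
            for roi in default_rois(geom).values():
                assert roi.vertices.shape[0] >= 3


class TestRenderCineLoop:
    def test_noiseless_compartments_follow_closed_form(self, noiseless_loop):
        lum = KineticsParams(10.0, 40.0, 0.5, 2.0)
        expected = replenishment_intensity(lum, noiseless_loop.timestamps)
        lumen_pixels = noiseless_loop.frames[:, 6:10, :]
        assert np.max(np.abs(lumen_pixels - expected[:, None, None])) == 0.0

    def test_frame_count_and_timebase(self, noiseless_loop):
        assert noiseless_loop.n_frames == int(22.0 * 5.0) + 1
        assert noiseless_loop.timestamps[0] == 0.0
        assert noiseless_loop.timestamps[-1] == pytest.approx(22.0)

    def test_zero_duration_single_frame_at_baseline(self, fixture_geometry):
        loop = render_cine_loop(
            fixture_geometry,
            KineticsParams(10.0, 40.0, 0.5, 0.0),
            KineticsParams(12.0, 16.0, 0.5, 0.0),
            noise_sd=0.0,
            frame_rate=5.0,
            duration=0.0,
            background_level=20.0,
        )
        assert loop.n_frames == 1
        assert np.all(loop.frames[0, 6:10, :] == 10.0)
        assert np.all(loop.frames[0, 3:5, :] == 12.0)

    def test_noisy_roi_mean_within_clt_bound(self, fixture_geometry):
        """With sd=5 noise the per-frame lumen mean stays within 3 sd/sqrt(n)
        of the noiseless curve (n = 64 lumen pixels here)."""
        lum = KineticsParams(60.0, 80.0, 0.5, 2.0)
        adv = KineticsParams(60.0, 30.0, 0.5, 2.0)
        loop = render_cine_loop(
            fixture_geometry, lum, adv,
            noise_sd=5.0, frame_rate=5.0, duration=20.0, seed=123,
            background_level=60.0,
        )
        n_pix = 4 * 16
        means = loop.frames[:, 6:10, :].reshape(loop.n_frames, -1).mean(axis=1)
        expected = replenishment_intensity(lum, loop.timestamps)
        assert np.max(np.abs(means - expected)) < 3.0 * 5.0 / math.sqrt(n_pix)

    def test_same_seed_bit_identical(self, fixture_geometry):
        kw = dict(noise_sd=3.0, frame_rate=5.0, duration=4.0, seed=9)
        lum = KineticsParams(10.0, 40.0, 0.5, 1.0)
        adv = KineticsParams(10.0, 16.0, 0.5, 1.0)
        a = render_cine_loop(fixture_geometry, lum, adv, **kw)
        b = render_cine_loop(fixture_geometry, lum, adv, **kw)
        assert np.array_equal(a.frames, b.frames)

    def test_plaque_kinetics_consistency_enforced(self, fixture_geometry):
        lum = KineticsParams(10.0, 40.0, 0.5)
        adv = KineticsParams(10.0, 16.0, 0.5)
        plq = KineticsParams(10.0, 8.0, 0.25)
        with pytest.raises(ConfigurationError):
            render_cine_loop(
                fixture_geometry, lum, adv, plq,
                noise_sd=0.0, frame_rate=5.0, duration=1.0,
            )


class TestHistology:
    def test_density_free_link_has_flat_expectation(self, rng):
        marker = MarkerParams(a=2.0, b=0.0)
        out = simulate_histology_counts(5.0, marker, rng=rng)
        assert out.expected == 2.0

    def test_observer_mean_is_arithmetic_mean(self, rng):
        out = simulate_histology_counts(1.0, MarkerParams(3.0, 4.0), rng=rng)
        assert out.mean == pytest.approx(np.mean(out.observer_counts))
        assert len(out.observer_counts) == 2

    def test_sample_mean_recovers_rate_within_three_se(self):
        """Calibrated link (control ~1.3, early-atherosclerosis VEGF ~3.58):
        200 simulated animals recover the Poisson rate within 3 SE."""
        marker = calibrate_marker(0.146, 1.3, 0.3565, 3.58)
        rng = np.random.default_rng(20170801)
        for density in (0.146, 0.3565):
            lam = marker.rate(density)
            means = [
                simulate_histology_counts(density, marker, rng=rng).mean
                for _ in range(200)
            ]
            se = math.sqrt(lam / 2.0 / 200)  # observer mean has var lam/2
            assert abs(np.mean(means) - lam) < 3.0 * se

    def test_negative_inputs_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            MarkerParams(-0.1, 1.0)
        with pytest.raises(InvalidParameterError):
            simulate_histology_counts(-1.0, MarkerParams(1.0, 1.0), rng=rng)

    def test_calibrated_defaults_hit_both_anchors_or_clamp(self):
        m = calibrate_marker(0.1, 1.0, 0.4, 4.0)  # feasible: exact line
        assert m.rate(0.1) == pytest.approx(1.0)
        assert m.rate(0.4) == pytest.approx(4.0)
        m2 = calibrate_marker(0.146, 1.9, 0.3565, 6.21)  # infeasible intercept
        assert m2.a == 0.0 and m2.b > 0


class TestSimulateCohort:
    def test_row_count_and_occlusive_missingness(self, small_sim):
        df = small_sim.cohort
        assert len(df) == 12
        assert df["nmve"].isna().sum() == 2
        assert set(df.loc[df["nmve"].isna(), "group_id"]) == {5}

    def test_same_seed_bit_identical_table(self):
        cfg = default_cohort_config(n_per_group=2, seed=11, duration=10.0)
        a = simulate_cohort(cfg, render="tics").cohort.to_csv(index=False)
        b = simulate_cohort(cfg, render="tics").cohort.to_csv(index=False)
        assert a == b

    def test_truth_ratio_is_exact_amplitude_ratio(self, small_sim):
        t = small_sim.truth
        assert np.allclose(
            t["true_nmve"], t["true_adv_amplitude"] / t["true_lumen_amplitude"]
        )

    def test_group_densities_non_decreasing_in_default_design(self):
        assert list(DEFAULT_GROUP_DENSITIES) == sorted(DEFAULT_GROUP_DENSITIES)

    def test_rendered_and_cached_tics_agree_without_noise(self):
        cfg = default_cohort_config(
            n_per_group=1, seed=5, noise_sd=0.0, duration=10.0,
            include_occlusive=False,
        )
        a = simulate_cohort(cfg, render="frames").cohort
        b = simulate_cohort(cfg, render="tics").cohort
        assert np.allclose(a["nmve"], b["nmve"], atol=1e-9)

    def test_empty_group_list_rejected(self):
        with pytest.raises(ConfigurationError):
            default_cohort_config(n_per_group=2).__class__(groups=())

    def test_plaque_flags_constrained_to_late_groups(self):
        with pytest.raises(ConfigurationError):
            GroupSpec(group_id=1, n_animals=2, vv_density=0.2, plaque_present=True)
        with pytest.raises(ConfigurationError):
            GroupSpec(
                group_id=4, n_animals=2, vv_density=0.6,
                plaque_present=True, plaque_occlusive=True,
            )


class TestLinkageCalibration:
    def test_analytic_correlation_matches_monte_carlo(self):
        cfg = default_cohort_config(n_per_group=10, include_occlusive=False)
        marker = MarkerParams(a=0.5, b=3.0)
        rho = true_density_count_correlation(cfg, marker)
        rng = np.random.default_rng(7)
        groups = [g for g in cfg.groups]
        n = 200_000
        gi = rng.integers(0, len(groups), n)
        d = np.array([g.vv_density for g in groups])[gi]
        d = d * rng.lognormal(-0.125, 0.5, n)
        lam = marker.a + marker.b * d
        c = (rng.poisson(lam) + rng.poisson(lam)) / 2.0
        rho_mc = np.corrcoef(d, c)[0, 1]
        assert rho == pytest.approx(rho_mc, abs=0.01)

    def test_target_correlation_solver_round_trips(self):
        cfg = default_cohort_config(n_per_group=10, include_occlusive=False)
        marker = marker_for_target_correlation(cfg, 0.6, slope=2.0)
        assert true_density_count_correlation(cfg, marker) == pytest.approx(0.6)
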