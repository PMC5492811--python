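import numpy as np
import pytest

from canopytrait import (
    SimulationConfig,
    aggregate_plot,
    clumping_profile,
    compute_index,
    ground_band_set,
    simulate_gap_field,
    simulate_mosaic,
    simulate_traits,
    simulate_two_sensor_spectra,
    soil_reflectance,
    uav_band_set,
    vegetation_reflectance,
)
from canopytrait.simulate import (
    GREEN_CENTER_NM,
    GREEN_WIDTH_NM,
    NIR_BASE,
    NIR_GAIN,
    NIR_LAI_RATE,
    RED_EDGE_CENTER_NM,
    RED_EDGE_WIDTH_NM,
    TROUGH_AMPLITUDE,
    TROUGH_CHL_RATE,
    TROUGH_FLOOR,
    GREEN_AMPLITUDE,
    GREEN_CHL_RATE,
    GREEN_FLOOR,
    PlotRect,
    default_strip_layout,
)


class TestSimulateTraits:
    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(seed=11)
        a = simulate_traits(cfg)
        b = simulate_traits(cfg)
        assert [(t.plot_id, t.dap, t.leaf_chl, t.lai) for t in a] == [
            (t.plot_id, t.dap, t.leaf_chl, t.lai) for t in b
        ]

    def test_mixed_final_lai_below_nonmixed_without_noise(self):
        cfg = SimulationConfig(seed=1, lai_sd=0.0, chl_sd=0.0, gc_sd=0.0)
        traits = simulate_traits(cfg)
        last = max(t.dap for t in traits)
        mixed = [t.lai for t in traits if t.dap == last and t.treatment == "mixed"]
        non = [t.lai for t in traits if t.dap == last and t.treatment == "non-mixed"]
        assert np.mean(mixed) < np.mean(non)

    def test_leaf_chlorophyll_declines_in_expectation(self):
        cfg = SimulationConfig(seed=2, lai_sd=0.0, chl_sd=0.0, gc_sd=0.0)
        traits = simulate_traits(cfg)
        by_date = {}
        for t in traits:
            if t.treatment == "non-mixed":
                by_date.setdefault(t.dap, []).append(t.leaf_chl)
        means = [np.mean(by_date[d]) for d in sorted(by_date)]
        assert np.all(np.diff(means) < 0)

    def test_trait_records_satisfy_invariants(self, cfg):
        for t in simulate_traits(cfg):
            assert t.lai >= 0 and 0 <= t.ground_cover <= 1
            assert t.canopy_chl == pytest.approx(t.leaf_chl * t.lai * 0.01)

    def test_sample_sds_match_configured(self):
        # large design: 250 blocks x 4 plots = 1000 plots
        cfg = SimulationConfig(seed=3, n_blocks=250, dap_schedule=(75,))
        traits = simulate_traits(cfg)
        non = [t for t in traits if t.treatment == "non-mixed"]
        lai = np.array([t.lai for t in non])
        chl = np.array([t.leaf_chl for t in non])
        # plot effect (sd/2) plus residual (sd) in quadrature
        exp_lai = cfg.lai_sd * np.sqrt(1.25)
        exp_chl = cfg.chl_sd * np.sqrt(1.25)
        assert abs(lai.std(ddof=1) - exp_lai) / exp_lai < 0.10
        assert abs(chl.std(ddof=1) - exp_chl) / exp_chl < 0.10


class TestVegetationReflectance:
    def test_chlorophyll_deepens_red_trough(self, uav_bs):
        r0 = vegetation_reflectance(0.0, 3.0, uav_bs)
        r50 = vegetation_reflectance(50.0, 3.0, uav_bs)
        i670 = int(np.argmin(np.abs(uav_bs.centers - 670)))
        assert r0.values[i670] >= r50.values[i670]

    def test_lai_raises_nir_plateau(self, uav_bs):
        i800 = int(np.argmin(np.abs(uav_bs.centers - 800)))
        r1 = vegetation_reflectance(40.0, 1.5, uav_bs)
        r2 = vegetation_reflectance(40.0, 3.0, uav_bs)
        assert r2.values[i800] > r1.values[i800]

    def test_closed_form_oracle(self, uav_bs):
        # independent re-evaluation of the stated closed form
        chl, lai = 40.0, 3.0
        lam = uav_bs.centers
        r_trough = TROUGH_FLOOR + TROUGH_AMPLITUDE * np.exp(-TROUGH_CHL_RATE * chl)
        r_green = GREEN_FLOOR + GREEN_AMPLITUDE * np.exp(-GREEN_CHL_RATE * chl)
        bump = np.exp(-(((lam - GREEN_CENTER_NM) / GREEN_WIDTH_NM) ** 2))
        r_vis = r_trough + (r_green - r_trough) * bump
        r_nir = NIR_BASE + NIR_GAIN * (1 - np.exp(-NIR_LAI_RATE * lai))
        ramp = 1 / (1 + np.exp(-(lam - RED_EDGE_CENTER_NM) / RED_EDGE_WIDTH_NM))
        expected = r_vis + (r_nir - r_vis) * ramp
        got = vegetation_reflectance(chl, lai, uav_bs)
        np.testing.assert_allclose(got.values, expected, rtol=1e-12)

    def test_negative_inputs_rejected(self, uav_bs):
        with pytest.raises(ValueError):
            vegetation_reflectance(-1.0, 3.0, uav_bs)


class TestTwoSensorSpectra:
    def test_equal_sampling_gives_equal_means_at_shared_bands(self):
        cfg = SimulationConfig(seed=5, row_concentration=1.0, spectral_noise_sd=0.0)
        traits = simulate_traits(cfg)
        uav, ground = simulate_two_sensor_spectra(traits, cfg)
        ubs, gbs = uav_band_set(), ground_band_set()
        shared = [c for c in gbs.centers if c in ubs.centers]
        for pu, pg in zip(uav, ground):
            su, sg = aggregate_plot(pu), aggregate_plot(pg)
            for c in shared:
                iu = int(np.argmin(np.abs(ubs.centers - c)))
                ig = int(np.argmin(np.abs(gbs.centers - c)))
                assert su.values[iu] == pytest.approx(sg.values[ig], abs=1e-12)

    def test_full_cover_independent_of_soil(self):
        cfg = SimulationConfig(seed=6, spectral_noise_sd=0.0)
        traits = simulate_traits(cfg)
        full = [t for t in traits if t.ground_cover >= 1.0]
        if not full:
            # force full cover on one record
            from canopytrait import TraitRecord

            t = traits[0]
            full = [
                TraitRecord(t.plot_id, t.dap, t.leaf_chl, t.lai,
                            t.leaf_chl * t.lai * 0.01, 1.0, t.treatment)
            ]
        uav, _ = simulate_two_sensor_spectra(full, cfg)
        veg = vegetation_reflectance(full[0].leaf_chl, full[0].lai, uav_band_set())
        np.testing.assert_allclose(uav[0].reflectance[0], veg.values, atol=1e-12)

    def test_ground_ndvi_exceeds_uav_in_expectation(self):
        cfg = SimulationConfig(seed=7, row_concentration=1.6)
        traits = simulate_traits(cfg)
        uav, ground = simulate_two_sensor_spectra(traits, cfg)
        diffs = []
        for pu, pg, t in zip(uav, ground, traits):
            if t.ground_cover < 1.0 / cfg.row_concentration:
                diffs.append(
                    compute_index(aggregate_plot(pg), "NDVI")
                    - compute_index(aggregate_plot(pu), "NDVI")
                )
        assert len(diffs) > 5
        assert np.mean(diffs) > 0


class TestGapField:
    def test_omega_one_homogeneous(self):
        grids = simulate_gap_field(2.0, 40.0, 1.0, seed=1)
        for g in grids:
            for i in range(15):
                assert np.ptp(g.gap[i]) == 0.0
        prof = clumping_profile(grids, 40.0)
        np.testing.assert_allclose(prof, 1.0, atol=1e-12)

    def test_zero_lai_all_open(self):
        grids = simulate_gap_field(0.0, 40.0, 0.8, seed=2)
        for g in grids:
            assert np.all(g.gap == 1.0)

    def test_lang_xiang_recovers_target(self):
        grids = simulate_gap_field(3.0, 40.0, 0.8, seed=3)
        prof = clumping_profile(grids, 40.0)
        assert 0.78 <= np.nanmean(prof) <= 0.82
        np.testing.assert_allclose(prof, 0.8, atol=0.02)

    def test_ring_means_follow_clumped_poisson(self):
        from canopytrait.dhp import gap_model, ring_centers_deg

        grids = simulate_gap_field(2.5, 50.0, 0.85, seed=4)
        gap = np.stack([g.gap for g in grids])
        ring_means = gap.mean(axis=(0, 2))
        expected = gap_model(2.5, 50.0, 0.85, ring_centers_deg())
        np.testing.assert_allclose(ring_means, expected, rtol=1e-9)

    def test_invalid_omega_rejected(self):
        with pytest.raises(ValueError):
            simulate_gap_field(2.0, 40.0, 0.0, seed=5)

    def test_determinism(self):
        a = simulate_gap_field(3.0, 40.0, 0.8, seed=9)
        b = simulate_gap_field(3.0, 40.0, 0.8, seed=9)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga.gap, gb.gap)


class TestMosaic:
    def test_noise_free_exact_rectangles(self):
        layout = default_strip_layout(2)
        raster, origin = simulate_mosaic(layout, 0.6, noise_sd=0.0, seed=0)
        values = np.unique(raster)
        assert set(values) == {0.1, 0.6}
        # plot P01 spans x 7-17 m, y 2-5 m at 0.2 m pixels
        assert np.all(raster[11:24, 36:84] == 0.6)
        assert np.all(raster[:, :34] == 0.1)

    def test_seeded_rasters_identical(self):
        layout = default_strip_layout(3)
        a, _ = simulate_mosaic(layout, 0.6, noise_sd=0.02, seed=4)
        b, _ = simulate_mosaic(layout, 0.6, noise_sd=0.02, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_overlapping_plots_rejected(self):
        layout = [
            PlotRect("a", 0, 0, 10, 3),
            PlotRect("b", 5, 1, 10, 3),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_mosaic(layout, 0.6, seed=0)


def test_soil_reflectance_rises_toward_nir(ground_bs):
    soil = soil_reflectance(ground_bs)
    assert np.all(np.diff(soil.values) > 0)
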