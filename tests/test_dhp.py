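import itertools

import numpy as np
import pytest

from canopytrait import (
    CanopyParams,
    GapFractionGrid,
    LutSpec,
    bin_to_grid,
    classify_vegetation,
    clumping_lang_xiang,
    clumping_profile,
    g_function,
    gap_model,
    ground_cover,
    invert_canopy,
    simulate_gap_field,
)
from canopytrait.dhp import (
    N_AZIMUTH,
    N_RINGS,
    ala_from_chi,
    chi_from_ala,
    ring_centers_deg,
)


class TestGFunction:
    def test_spherical_value_at_nadir(self):
        assert g_function(0.0, 1.0) == pytest.approx(0.4997, abs=5e-4)

    def test_spherical_distribution_is_flat(self):
        theta = np.linspace(0, 75, 40)
        g = g_function(theta, 1.0)
        assert np.all(np.abs(g - 0.5) < 1e-3)

    def test_planophile_limit_at_nadir(self):
        # chi -> infinity: horizontal leaves fully project at nadir
        assert g_function(0.0, 100.0) == pytest.approx(1.0, abs=0.05)

    def test_chi_must_be_positive(self):
        with pytest.raises(ValueError):
            g_function(30.0, 0.0)

    def test_chi_ala_conversion_round_trips(self):
        for ala in (15.0, 30.0, 45.0, 60.0, 75.0):
            assert ala_from_chi(chi_from_ala(ala)) == pytest.approx(ala, abs=1e-9)

    def test_spherical_chi_maps_near_57deg(self):
        # the spherical LIDF has a mean inclination near 57 degrees; the
        # empirical chi-ALA relation is good to about a degree there
        assert ala_from_chi(1.0) == pytest.approx(57.0, abs=1.5)


class TestGapModel:
    def test_empty_canopy_fully_open(self):
        assert gap_model(0.0, 40.0, 1.0, 0.0) == 1.0

    def test_hand_value_spherical(self):
        # P = exp(-G(0,1) * 2) with G(0,1) = 0.4997
        assert gap_model(2.0, ala_from_chi(1.0), 1.0, 0.0) == pytest.approx(
            0.3681, abs=2e-4
        )

    def test_clumping_halves_exponent(self):
        p1 = gap_model(3.0, 40.0, 1.0, 20.0)
        p_half = gap_model(3.0, 40.0, 0.5, 20.0)
        assert np.log(p_half) == pytest.approx(0.5 * np.log(p1))

    def test_monotone_decreasing_in_lai_and_omega(self):
        lais = np.linspace(0, 8, 20)
        p = gap_model(lais, 40.0, 1.0, 10.0)
        assert np.all(np.diff(p) < 0)
        omegas = np.linspace(0.2, 1.0, 10)
        p = gap_model(3.0, 40.0, omegas, 10.0)
        assert np.all(np.diff(p) < 0)

    def test_horizontal_view_rejected(self):
        with pytest.raises(ValueError):
            gap_model(1.0, 40.0, 1.0, 90.0)


class TestClumping:
    def test_homogeneous_ring_gives_one(self):
        assert clumping_lang_xiang([0.4, 0.4, 0.4]) == pytest.approx(1.0)

    def test_two_cell_hand_value(self):
        # gaps e^-1 and e^-3: ln(0.2088...) / (-2) = 0.7832
        omega = clumping_lang_xiang([np.exp(-1), np.exp(-3)])
        assert omega == pytest.approx(0.7832, abs=2e-4)

    def test_heterogeneity_always_below_one(self, rng):
        for _ in range(20):
            gaps = rng.uniform(0.05, 1.0, 30)
            if np.ptp(gaps) < 1e-12:
                continue
            omega = clumping_lang_xiang(gaps)
            assert 0 < omega <= 1

    def test_zero_gap_rejected_before_replacement(self):
        with pytest.raises(ValueError):
            clumping_lang_xiang([0.0, 0.5])

    def test_profile_recovers_generator_target(self):
        grids = simulate_gap_field(3.0, 40.0, 0.8, seed=2)
        prof = clumping_profile(grids, 40.0)
        assert np.nanmean(prof) == pytest.approx(0.8, abs=0.02)


class TestBinToGrid:
    def test_uniform_gap_fraction(self, rng):
        mask = (rng.uniform(size=(400, 400)) > 0.3).astype(np.uint8)
        grid = bin_to_grid(mask)
        populated = grid.counts > 100
        # per-cell estimates are binomial; allow 6 sd at the count floor
        assert np.allclose(grid.gap[populated], 0.30, atol=6 * np.sqrt(0.21 / 100))
        weighted = np.sum(grid.gap[populated] * grid.counts[populated])
        assert weighted / grid.counts[populated].sum() == pytest.approx(0.30, abs=0.01)

    def test_pixel_count_conserved(self):
        mask = np.ones((200, 200), np.uint8)
        grid = bin_to_grid(mask)
        from canopytrait.dhp import equidistant_projection

        zen, _ = equidistant_projection(mask.shape)
        expected = np.sum(np.isfinite(zen) & (zen < 37.5))
        assert grid.counts.sum() == expected

    def test_constructed_ring_split(self):
        # vegetation only below 20 deg zenith: inner rings closed, outer open
        mask = np.zeros((401, 401), np.uint8)
        from canopytrait.dhp import equidistant_projection

        zen, _ = equidistant_projection(mask.shape)
        mask[np.isfinite(zen) & (zen < 20.0)] = 1
        grid = bin_to_grid(mask)
        inner = grid.gap[:8][grid.counts[:8] > 0]
        outer = grid.gap[8:][grid.counts[8:] > 0]
        assert np.all(inner < 0.05)
        assert np.mean(outer) > 0.95

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            bin_to_grid(np.zeros((4, 4, 3)))


class TestClassifyVegetation:
    def test_pure_green_image_all_vegetation(self):
        img = np.zeros((10, 10, 3))
        img[:, :, 1] = 0.8
        assert classify_vegetation(img).all()

    def test_soil_image_all_gap(self):
        img = np.full((10, 10, 3), 0.4)
        img[:, :, 0] = 0.5  # reddish-bright soil
        assert not classify_vegetation(img).any()

    def test_bimodal_image_low_misclassification(self, rng):
        truth = rng.uniform(size=(120, 120)) < 0.4
        img = np.empty((120, 120, 3))
        soil = np.array([0.45, 0.40, 0.35])
        veg = np.array([0.10, 0.35, 0.08])
        img[~truth] = soil
        img[truth] = veg
        img += rng.normal(0, 0.02, img.shape)
        mask = classify_vegetation(np.clip(img, 0, 1))
        misclass = np.mean(mask != truth)
        assert misclass < 0.02

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            classify_vegetation(np.zeros((5, 5)))


def _uniform_grid(gap_value, count=10.0):
    return GapFractionGrid(
        gap=np.full((N_RINGS, N_AZIMUTH), gap_value),
        counts=np.full((N_RINGS, N_AZIMUTH), count),
    )


class TestGroundCover:
    def test_fully_vegetated(self):
        assert ground_cover([_uniform_grid(0.0)]) == pytest.approx(1.0)

    def test_uniform_quarter_gap(self):
        assert ground_cover([_uniform_grid(0.25)]) == pytest.approx(0.75)

    def test_weighted_mean_matches_brute_force(self, rng):
        gap = rng.uniform(0, 1, (N_RINGS, N_AZIMUTH))
        counts = rng.integers(0, 30, (N_RINGS, N_AZIMUTH)).astype(float)
        grid = GapFractionGrid(gap=gap, counts=counts)
        total = num = 0.0
        for i in range(8):  # rings fully within 0-20 deg
            for a in range(N_AZIMUTH):
                if counts[i, a] > 0:
                    total += counts[i, a]
                    num += counts[i, a] * gap[i, a]
        assert ground_cover([grid]) == pytest.approx(1 - num / total, rel=1e-12)

    def test_empty_near_nadir_rejected(self):
        grid = GapFractionGrid(
            gap=np.full((N_RINGS, N_AZIMUTH), np.nan),
            counts=np.zeros((N_RINGS, N_AZIMUTH)),
        )
        grid.counts[10:] = 5.0
        grid.gap[10:] = 0.5
        with pytest.raises(ValueError):
            ground_cover([grid])


def brute_force_invert(grids, lut):
    """Independent triple search coded straight from the model equations."""
    theta = ring_centers_deg()
    best = None
    for eff in lut.effective_ala_grid:
        p_sat = gap_model(10.0, eff, 1.0, theta)
        mean_gap = np.full(N_RINGS, np.nan)
        mean_log = np.full(N_RINGS, np.nan)
        wsum = np.zeros(N_RINGS)
        for i in range(N_RINGS):
            vals, ws = [], []
            for g in grids:
                for a in range(N_AZIMUTH):
                    if g.counts[i, a] > 0:
                        vals.append(min(1.0, max(g.gap[i, a], p_sat[i])))
                        ws.append(g.counts[i, a])
            if ws:
                vals, ws = np.array(vals), np.array(ws)
                wsum[i] = ws.sum()
                mean_gap[i] = np.sum(ws * vals) / wsum[i]
                mean_log[i] = np.sum(ws * np.log(vals)) / wsum[i]
        omega = np.where(mean_log < 0, np.log(mean_gap) / mean_log, 1.0)
        omega = np.clip(omega, None, 1.0)
        pop = wsum > 0
        w = wsum[pop] / wsum[pop].sum()
        for lai in lut.lai_grid:
            for ala in lut.ala_grid:
                p_mod = gap_model(lai, ala, omega[pop], theta[pop])
                cost = np.sqrt(np.sum(w * (p_mod - mean_gap[pop]) ** 2))
                key = (cost, lai, ala, eff)
                if best is None or key < best[0]:
                    best = (key, lai, ala, eff)
    _, lai, ala, eff = best
    return lai, ala, eff


class TestInvertCanopy:
    def test_noise_free_recovery(self):
        grids = simulate_gap_field(3.0, 40.0, 1.0, seed=3)
        params = invert_canopy(grids)
        assert 2.95 <= params.lai <= 3.05
        assert params.ala_deg in (38.0, 40.0, 42.0)
        assert params.omega_mean == pytest.approx(1.0, abs=0.01)

    def test_empty_canopy_recovers_zero(self):
        grids = simulate_gap_field(0.0, 40.0, 1.0, seed=4)
        assert invert_canopy(grids).lai == 0.0

    def test_noise_robustness(self):
        clean = invert_canopy(simulate_gap_field(3.0, 40.0, 0.9, seed=5))
        noisy = invert_canopy(
            simulate_gap_field(3.0, 40.0, 0.9, seed=5, gap_noise_sd=0.01)
        )
        assert abs(noisy.lai - clean.lai) < 0.2

    def test_matches_brute_force_oracle(self):
        lut = LutSpec(
            lai_grid=np.round(np.arange(0.0, 5.01, 0.25), 2),
            ala_grid=np.arange(20.0, 61.0, 10.0),
            effective_ala_grid=np.arange(20.0, 61.0, 10.0),
        )
        cases = [
            (1.0, 30.0, 1.0, 10),
            (2.5, 40.0, 0.8, 11),
            (4.0, 50.0, 0.9, 12),
            (0.5, 60.0, 0.75, 13),
            (3.25, 20.0, 0.85, 14),
        ]
        for lai, ala, om, seed in cases:
            grids = simulate_gap_field(lai, ala, om, seed=seed)
            params = invert_canopy(grids, lut)
            b_lai, b_ala, b_eff = brute_force_invert(grids, lut)
            assert params.lai == pytest.approx(b_lai)
            assert params.ala_deg == pytest.approx(b_ala)
            assert params.effective_ala_deg == pytest.approx(b_eff)

    def test_parameter_recovery_random_sample(self, rng):
        # a desk-scale slice of the recovery study (full version in the
        # acceptance suite)
        for i in range(8):
            lai = round(float(rng.uniform(0.5, 6.0)), 2)
            ala = float(rng.choice(np.arange(20.0, 71.0, 2.0)))
            om = float(rng.uniform(0.7, 1.0))
            params = invert_canopy(simulate_gap_field(lai, ala, om, seed=100 + i))
            assert abs(params.lai - lai) <= max(0.05, 0.05 * lai)
            assert abs(params.ala_deg - ala) <= 2.0
            assert abs(params.omega_mean - om) <= 0.03

    def test_empty_grids_rejected(self):
        grid = GapFractionGrid(
            gap=np.full((N_RINGS, N_AZIMUTH), np.nan),
            counts=np.zeros((N_RINGS, N_AZIMUTH)),
        )
        with pytest.raises(ValueError):
            invert_canopy([grid])


def test_canopy_params_validation():
    with pytest.raises(ValueError):
        CanopyParams(lai=11.0, ala_deg=40.0, omega=np.ones(15), effective_ala_deg=40.0)
    with pytest.raises(ValueError):
        CanopyParams(lai=2.0, ala_deg=5.0, omega=np.ones(15), effective_ala_deg=40.0)
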