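"""Synthetic-data generator emulating the two-level field campaign.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: per-plot trait trajectories
over the season, two-sensor reflectance sampling (many full-plot pixels
for the UAV versus four row-centered footprints for the ground
radiometer), hemispherical gap-fraction fields with known LAI, leaf
inclination and clumping, and a strip-layout vegetation-index mosaic
for the plot-boundary extraction stage.

The spectral forward model is a deliberately simple parametric stand-in
for a radiative-transfer model: a chlorophyll-controlled visible trough
with a green bump, a logistic red edge, and an LAI-controlled NIR
plateau, mixed linearly with a soil endmember according to the
vegetation fraction seen by each sensor.  It reproduces the rank and
shape behaviors the analysis relies on (deeper red trough with more
chlorophyll, brighter NIR with more leaf area, stronger vegetation
signal for the row-centered ground sensor at incomplete cover), not
absolute reflectance magnitudes.

All generators are pure functions of (config, seed): a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .core import (
    PlotSpectra,
    SpectralBandSet,
    Spectrum,
    TraitRecord,
    ground_band_set,
    uav_band_set,
)
from .dhp import (
    N_AZIMUTH,
    N_RINGS,
    GapFractionGrid,
    gap_model,
    ring_centers_deg,
)

__all__ = [
    "SimulationConfig",
    "simulate_traits",
    "vegetation_reflectance",
    "soil_reflectance",
    "simulate_two_sensor_spectra",
    "simulate_gap_field",
    "simulate_mosaic",
    "default_strip_layout",
]

# spectral forward-model constants (see docs/methods.md)
NIR_BASE = 0.28
NIR_GAIN = 0.20
NIR_LAI_RATE = 0.6
TROUGH_FLOOR = 0.03
TROUGH_AMPLITUDE = 0.25
TROUGH_CHL_RATE = 0.045
GREEN_FLOOR = 0.08
GREEN_AMPLITUDE = 0.25
GREEN_CHL_RATE = 0.028
GREEN_CENTER_NM = 550.0
GREEN_WIDTH_NM = 45.0
RED_EDGE_CENTER_NM = 720.0
RED_EDGE_WIDTH_NM = 12.0
SOIL_BASE = 0.10
SOIL_SLOPE_PER_NM = 0.00025  # gentle brightening toward the NIR


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic campaign.

    Defaults mirror the field design: a generalized randomized block
    layout with 3 blocks and 2 replicates of each of two treatments
    (12 plots), five acquisitions from 43 to 99 days after planting,
    and a late-season decline of leaf area and chlorophyll that is
    stronger for the disease-prone "mixed" treatment.
    """

    seed: int = 0
    n_blocks: int = 3
    reps_per_treatment: int = 2
    dap_schedule: tuple = (43, 62, 75, 84, 99)
    #: expected LAI trajectory control points (dap -> m^2 m^-2)
    lai_points: tuple = ((43, 1.2), (62, 3.0), (75, 3.5), (84, 3.4), (99, 2.6))
    #: expected leaf chlorophyll at first/last date (ug cm^-2)
    chl_start: float = 48.0
    chl_end: float = 30.0
    #: additional final-date declines for the "mixed" treatment
    mixed_lai_decline: float = 0.8
    mixed_chl_decline: float = 4.0
    #: between-plot and measurement noise
    lai_sd: float = 0.20
    chl_sd: float = 2.0
    gc_sd: float = 0.02
    spectral_noise_sd: float = 0.01
    #: ground sensor samples crop rows preferentially
    row_concentration: float = 1.6
    n_ground_footprints: int = 4
    n_uav_pixels: int = 120
    #: canopy structure used for gap-field generation
    ala_deg: float = 40.0
    omega_target: float = 0.85
    n_photos: int = 4
    pixels_per_cell: int = 200

    def __post_init__(self):
        if self.spectral_noise_sd < 0 or self.lai_sd < 0 or self.chl_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if any(d <= 0 for d in self.dap_schedule):
            raise ValueError("dap_schedule entries must be positive")
        if self.row_concentration <= 0:
            raise ValueError("row_concentration must be positive")

    def rng_for(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream derived from the global seed.

        The stage tag enters through a stable digest so substreams are
        reproducible across processes and platforms.
        """
        import hashlib

        tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
        ss = np.random.SeedSequence(self.seed, spawn_key=(tag % 2**31,))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# spectra


def soil_reflectance(band_set: SpectralBandSet) -> Spectrum:
    """Bare-soil endmember: a gentle linear brightening toward the NIR."""
    values = SOIL_BASE + SOIL_SLOPE_PER_NM * (band_set.centers - 450.0)
    return Spectrum(band_set, values)


def vegetation_reflectance(
    leaf_chl: float, lai: float, band_set: SpectralBandSet
) -> Spectrum:
    """Closed-form pure-vegetation spectrum at the band centers.

    Visible region: a chlorophyll absorption trough (Beer-type decay
    with leaf chlorophyll) carrying a Gaussian green bump at 550 nm.
    The red edge is a logistic ramp centered at 720 nm toward an NIR
    plateau that saturates with LAI.
    """
    if leaf_chl < 0 or lai < 0:
        raise ValueError("leaf_chl and lai must be non-negative")
    lam = band_set.centers
    r_trough = TROUGH_FLOOR + TROUGH_AMPLITUDE * np.exp(-TROUGH_CHL_RATE * leaf_chl)
    r_green = GREEN_FLOOR + GREEN_AMPLITUDE * np.exp(-GREEN_CHL_RATE * leaf_chl)
    bump = np.exp(-(((lam - GREEN_CENTER_NM) / GREEN_WIDTH_NM) ** 2))
    r_vis = r_trough + (r_green - r_trough) * bump
    r_nir = NIR_BASE + NIR_GAIN * (1.0 - np.exp(-NIR_LAI_RATE * lai))
    ramp = 1.0 / (1.0 + np.exp(-(lam - RED_EDGE_CENTER_NM) / RED_EDGE_WIDTH_NM))
    return Spectrum(band_set, r_vis + (r_nir - r_vis) * ramp)


# ---------------------------------------------------------------------------
# traits


def _plot_ids(cfg: SimulationConfig):
    """(plot_id, treatment) pairs of the block design."""
    out = []
    for b in range(1, cfg.n_blocks + 1):
        k = 0
        for treatment in ("non-mixed", "mixed"):
            for _ in range(cfg.reps_per_treatment):
                k += 1
                out.append((f"B{b}P{k}", treatment))
    return out


def expected_traits(cfg: SimulationConfig, dap: int, treatment: str):
    """Noise-free expected (leaf_chl, lai) for one date and treatment."""
    daps = [p[0] for p in cfg.lai_points]
    lais = [p[1] for p in cfg.lai_points]
    lai = float(np.interp(dap, daps, lais))
    d0, d1 = cfg.dap_schedule[0], cfg.dap_schedule[-1]
    frac = (dap - d0) / (d1 - d0) if d1 > d0 else 0.0
    chl = cfg.chl_start + (cfg.chl_end - cfg.chl_start) * frac
    if treatment == "mixed" and dap == cfg.dap_schedule[-1]:
        lai = max(0.0, lai - cfg.mixed_lai_decline)
        chl = max(0.0, chl - cfg.mixed_chl_decline)
    return chl, lai


def simulate_traits(cfg: SimulationConfig) -> list[TraitRecord]:
    """Per-plot trait trajectories over the acquisition schedule.

    Leaf chlorophyll declines over the season, LAI rises to a
    mid-season plateau and declines at the end — more strongly for the
    "mixed" treatment, emulating late-blight impact.  Ground cover
    follows 1 - exp(-0.5 * LAI) before noise; canopy chlorophyll is
    computed exactly from the noisy leaf chlorophyll and LAI.
    """
    rng = cfg.rng_for("traits")
    records = []
    for plot_id, treatment in _plot_ids(cfg):
        # persistent plot-level random effect
        plot_chl_eff = rng.normal(0.0, cfg.chl_sd / 2.0)
        plot_lai_eff = rng.normal(0.0, cfg.lai_sd / 2.0)
        for dap in cfg.dap_schedule:
            chl0, lai0 = expected_traits(cfg, dap, treatment)
            chl = max(0.0, chl0 + plot_chl_eff + rng.normal(0.0, cfg.chl_sd))
            lai = max(0.0, lai0 + plot_lai_eff + rng.normal(0.0, cfg.lai_sd))
            gc = float(np.clip(1.0 - np.exp(-0.5 * lai), 0.0, 1.0))
            gc = float(np.clip(gc + rng.normal(0.0, cfg.gc_sd), 0.0, 1.0))
            records.append(
                TraitRecord(
                    plot_id=plot_id,
                    dap=int(dap),
                    leaf_chl=chl,
                    lai=lai,
                    canopy_chl=chl * lai * 0.01,
                    ground_cover=gc,
                    treatment=treatment,
                )
            )
    return records


# ---------------------------------------------------------------------------
# two-sensor reflectance sampling


def simulate_two_sensor_spectra(
    traits: list[TraitRecord], cfg: SimulationConfig
) -> tuple[list[PlotSpectra], list[PlotSpectra]]:
    """Per-plot reflectance observations for the UAV and ground sensors.

    Every observation is a linear mixture
    ``R = f_veg * R_veg + (1 - f_veg) * R_soil + noise``.  UAV pixels
    see the plot-average vegetation fraction (the ground cover); the
    ground radiometer points at the crop rows, so its footprints see
    ``min(1, ground_cover * row_concentration)``.  With
    row_concentration > 1 and incomplete cover the ground sensor
    therefore records a systematically stronger vegetation signal —
    the sampling contrast between acquisition levels.
    """
    rng = cfg.rng_for("spectra")
    uav_bs, ground_bs = uav_band_set(), ground_band_set()
    soil = {bs.sensor_label: soil_reflectance(bs).values for bs in (uav_bs, ground_bs)}
    uav_records, ground_records = [], []
    for t in traits:
        veg = {
            bs.sensor_label: vegetation_reflectance(t.leaf_chl, t.lai, bs).values
            for bs in (uav_bs, ground_bs)
        }
        f_uav = t.ground_cover
        obs = f_uav * veg["uav"] + (1 - f_uav) * soil["uav"]
        uav = np.clip(
            obs[None, :]
            + rng.normal(0.0, cfg.spectral_noise_sd, (cfg.n_uav_pixels, len(uav_bs))),
            0.0,
            None,
        )
        uav_records.append(
            PlotSpectra(t.plot_id, t.treatment, t.dap, uav_bs, uav)
        )
        f_ground = min(1.0, t.ground_cover * cfg.row_concentration)
        obs_g = f_ground * veg["ground"] + (1 - f_ground) * soil["ground"]
        ground = np.clip(
            obs_g[None, :]
            + rng.normal(
                0.0,
                cfg.spectral_noise_sd,
                (cfg.n_ground_footprints, len(ground_bs)),
            ),
            0.0,
            None,
        )
        ground_records.append(
            PlotSpectra(t.plot_id, t.treatment, t.dap, ground_bs, ground)
        )
    return uav_records, ground_records


# ---------------------------------------------------------------------------
# hemispherical gap fields


def _mixture_for_ring(mean_gap: float, omega: float, n_cells: int):
    """Two-density cell mixture hitting a ring's mean gap and clumping.

    A fraction ``k/n`` of cells is wide open (gap g1, close to 1), the
    rest dense (gap g2), such that the arithmetic mean equals
    ``mean_gap`` and the log-mean equals ``ln(mean_gap) / omega`` — so
    the Lang-Xiang estimator recovers ``omega`` exactly.  Returns
    (k, g1, g2).
    """
    m = mean_gap
    target_log = np.log(m) / omega

    def imbalance(k):
        p = k / n_cells
        if p >= m:
            return -np.inf
        g2 = (m - p) / (1 - p)
        return p * 0.0 + (1 - p) * np.log(g2) - target_log

    # smallest count of open cells able to carry the heterogeneity
    k = 1
    while k < n_cells and imbalance(k) > 0:
        k += 1
    p = k / n_cells
    if p >= m:
        raise ValueError(
            f"cannot realize omega={omega} at mean gap {m} with {n_cells} cells"
        )

    def f(g1):
        g2 = (m - p * g1) / (1 - p)
        return p * np.log(g1) + (1 - p) * np.log(g2) - target_log

    hi = min(1.0, (m - 1e-12) / p) if p > 0 else 1.0
    if f(hi) > 0:  # numerically flat case: accept the boundary
        return k, hi, (m - p * hi) / (1 - p)
    g1 = brentq(f, m, hi, xtol=1e-14)
    g2 = (m - p * g1) / (1 - p)
    return k, g1, g2


def simulate_gap_field(
    lai: float,
    ala_deg: float,
    omega_target: float,
    n_photos: int = 4,
    seed: int = 0,
    pixels_per_cell: int = 200,
    gap_noise_sd: float = 0.0,
) -> list[GapFractionGrid]:
    """Gap-fraction grids of one plot with known canopy parameters.

    Ring means follow the clumped Poisson model
    ``P(theta) = exp(-G(theta, ala) * omega * LAI / cos theta)`` and the
    between-cell heterogeneity is calibrated so the Lang-Xiang
    estimator returns ``omega_target`` on the noise-free field.
    """
    if not 0 < omega_target <= 1:
        raise ValueError("omega_target must lie in (0, 1]")
    if lai < 0:
        raise ValueError("lai must be >= 0")
    rng = np.random.default_rng(seed)
    theta = ring_centers_deg()
    n_cells = n_photos * N_AZIMUTH
    gap = np.empty((n_photos, N_RINGS, N_AZIMUTH))
    if lai == 0:
        gap[:] = 1.0
    else:
        means = gap_model(lai, ala_deg, omega_target, theta)
        for i, m in enumerate(means):
            if omega_target == 1.0:
                cells = np.full(n_cells, m)
            else:
                k, g1, g2 = _mixture_for_ring(float(m), omega_target, n_cells)
                cells = np.full(n_cells, g2)
                open_cells = rng.permutation(n_cells)[:k]
                cells[open_cells] = g1
            gap[:, i, :] = cells.reshape(n_photos, N_AZIMUTH)
    if gap_noise_sd > 0:
        gap = np.clip(gap + rng.normal(0.0, gap_noise_sd, gap.shape), 1e-6, 1.0)
    counts = np.full((N_RINGS, N_AZIMUTH), float(pixels_per_cell))
    return [GapFractionGrid(gap=gap[j], counts=counts.copy()) for j in range(n_photos)]


# ---------------------------------------------------------------------------
# strip mosaic


@dataclass(frozen=True)
class PlotRect:
    """Axis-aligned plot rectangle in map coordinates (meters)."""

    plot_id: str
    x0: float
    y0: float
    width: float
    height: float
    treatment: str = ""

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot rectangle must have positive area")


def default_strip_layout(
    n_plots: int = 6,
    plot_length: float = 10.0,
    plot_width: float = 3.0,
    buffer_length: float = 5.0,
    margin: float = 2.0,
) -> list[PlotRect]:
    """Plots in a single strip along x, separated by soil buffers."""
    rects = []
    x = margin + buffer_length
    for i in range(n_plots):
        rects.append(
            PlotRect(f"P{i + 1:02d}", x, margin, plot_length, plot_width)
        )
        x += plot_length + buffer_length
    return rects


def simulate_mosaic(
    plot_layout: list[PlotRect],
    vi_levels,
    noise_sd: float = 0.02,
    seed: int = 0,
    pixel_size: float = 0.2,
    soil_level: float = 0.1,
    margin: float = 2.0,
):
    """Single-band vegetation-index raster of a plot strip over soil.

    ``vi_levels`` is a scalar or one value per plot.  Returns
    ``(raster, origin)`` where origin is the map coordinate of the
    top-left pixel center.  Plots must not overlap.
    """
    vi_levels = np.broadcast_to(np.asarray(vi_levels, float), (len(plot_layout),))
    for i, a in enumerate(plot_layout):
        for b in plot_layout[i + 1 :]:
            if (
                a.x0 < b.x0 + b.width
                and b.x0 < a.x0 + a.width
                and a.y0 < b.y0 + b.height
                and b.y0 < a.y0 + a.height
            ):
                raise ValueError(f"plots {a.plot_id} and {b.plot_id} overlap")
    x_max = max(r.x0 + r.width for r in plot_layout) + margin
    y_max = max(r.y0 + r.height for r in plot_layout) + margin
    cols = int(round(x_max / pixel_size))
    rows = int(round(y_max / pixel_size))
    raster = np.full((rows, cols), soil_level)
    # pixel centers
    xc = (np.arange(cols) + 0.5) * pixel_size
    yc = (np.arange(rows) + 0.5) * pixel_size
    for rect, level in zip(plot_layout, vi_levels):
        in_x = (xc >= rect.x0) & (xc < rect.x0 + rect.width)
        in_y = (yc >= rect.y0) & (yc < rect.y0 + rect.height)
        raster[np.ix_(in_y, in_x)] = level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raster = raster + rng.normal(0.0, noise_sd, raster.shape)
    origin = (0.5 * pixel_size, 0.5 * pixel_size)
    return raster, origin
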