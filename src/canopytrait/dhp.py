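"""Canopy structure from downward hemispherical photography.

The chain implemented here goes from an RGB (or binary) canopy image to
plot-level canopy parameters:

1. segment the image into vegetation and gap pixels;
2. bin the binary mask into an angular grid of gap fractions
   (15 zenith rings of 2.5 deg covering 0-37.5 deg, 72 azimuth cells of
   5 deg), keeping per-cell valid-pixel counts;
3. estimate the clumping index per zenith ring with the logarithmic
   gap-averaging method of Lang and Xiang,

       Omega(theta_i) = ln(mean gap) / mean(ln gap),

   where both means are taken over the azimuth cells of all photos of a
   plot, weighted by non-masked pixel counts, and fully vegetated cells
   are replaced by the saturated gap fraction of a canopy with LAI = 10
   at a candidate effective leaf inclination;
4. invert the Poisson gap-fraction model

       P(theta) = exp(-G(theta, chi) * Omega(theta) * LAI / cos(theta))

   over a look-up table of (LAI, ALA, effective-ALA) triples, with an
   ellipsoidal leaf inclination distribution linking the average leaf
   angle (ALA) to the ellipsoid shape parameter chi.

Optical inversion cannot separate leaves from stems, so the retrieved
"LAI" is strictly a plant area index; the clumping correction makes it
the clumping-adjusted plant area index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_RINGS",
    "N_AZIMUTH",
    "RING_WIDTH_DEG",
    "ring_centers_deg",
    "GapFractionGrid",
    "CanopyParams",
    "LutSpec",
    "classify_vegetation",
    "bin_to_grid",
    "chi_from_ala",
    "ala_from_chi",
    "g_function",
    "gap_model",
    "clumping_lang_xiang",
    "clumping_profile",
    "invert_canopy",
    "ground_cover",
]

N_RINGS = 15
N_AZIMUTH = 72
RING_WIDTH_DEG = 2.5
MAX_ZENITH_DEG = N_RINGS * RING_WIDTH_DEG  # 37.5
SATURATION_LAI = 10.0
#: rings whose full [lower, upper] zenith interval lies within 0-20 deg,
#: used for ground-cover estimation
GROUND_COVER_RINGS = slice(0, 8)


def ring_centers_deg() -> np.ndarray:
    return (np.arange(N_RINGS) + 0.5) * RING_WIDTH_DEG


@dataclass
class GapFractionGrid:
    """Zenith-ring x azimuth-cell gap fractions of one photograph.

    ``gap`` holds the per-cell gap fraction in [0, 1] (nan where the
    cell has no valid pixels); ``counts`` the number of non-masked
    pixels per cell.
    """

    gap: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.gap = np.asarray(self.gap, float)
        self.counts = np.asarray(self.counts, float)
        if self.gap.shape != (N_RINGS, N_AZIMUTH):
            raise ValueError(
                f"gap grid must be {N_RINGS} rings x {N_AZIMUTH} azimuth cells"
            )
        if self.counts.shape != self.gap.shape:
            raise ValueError("counts must match gap in shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        populated = self.counts > 0
        vals = self.gap[populated]
        if vals.size and (np.any(vals < 0) or np.any(vals > 1)):
            raise ValueError("gap fractions must lie in [0, 1]")


@dataclass
class CanopyParams:
    """Retrieved canopy parameters of one plot.

    ``lai`` is the clumping-adjusted plant area index, ``omega`` the
    per-ring clumping profile of the winning effective leaf inclination.
    """

    lai: float
    ala_deg: float
    omega: np.ndarray
    effective_ala_deg: float
    ground_cover: float = np.nan

    def __post_init__(self):
        if not 0 <= self.lai <= 10:
            raise ValueError("lai outside the invertible range [0, 10]")
        if not 10 <= self.ala_deg <= 80:
            raise ValueError("ala outside [10, 80] deg")

    @property
    def omega_mean(self) -> float:
        return float(np.nanmean(self.omega))


@dataclass(frozen=True)
class LutSpec:
    """Look-up-table grids for the Poisson-model inversion."""

    lai_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 10.0 + 1e-9, 0.01), 2)
    )
    ala_grid: np.ndarray = field(
        default_factory=lambda: np.arange(10.0, 81.0, 2.0)
    )
    effective_ala_grid: np.ndarray = field(
        default_factory=lambda: np.arange(10.0, 81.0, 2.0)
    )


# ---------------------------------------------------------------------------
# segmentation and angular binning


def classify_vegetation(rgb_image: np.ndarray) -> np.ndarray:
    """Binary vegetation mask from an RGB image (1 = vegetation, 0 = gap).

    Segmentation uses the excess-green transform 2G - R - B followed by
    a between-class-variance (Otsu) threshold — a deliberately simple
    stand-in for more elaborate color-transform threshold optimizations.
    """
    img = np.asarray(rgb_image, float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (rows, cols, 3)")
    exg = 2.0 * img[:, :, 1] - img[:, :, 0] - img[:, :, 2]
    if np.ptp(exg) < 1e-9:
        # degenerate single-class image: sign of excess green decides
        return (exg > 0).astype(np.uint8)
    from skimage.filters import threshold_otsu

    thr = threshold_otsu(exg)
    return (exg > thr).astype(np.uint8)


def equidistant_projection(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Ideal equidistant fisheye: zenith proportional to radial distance.

    The inscribed image circle maps linearly to the sampled zenith range
    0-37.5 deg; returns per-pixel (zenith_deg, azimuth_deg), with nan
    zenith outside the image circle.
    """
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    r = np.hypot(yy - cy, xx - cx)
    rmax = min(cy, cx)
    zen = np.where(r <= rmax, MAX_ZENITH_DEG * r / rmax, np.nan)
    az = np.degrees(np.arctan2(xx - cx, -(yy - cy))) % 360.0
    return zen, az


def bin_to_grid(mask: np.ndarray, projection=None) -> GapFractionGrid:
    """Bin a binary vegetation mask into the angular gap-fraction grid.

    ``projection`` maps the mask to per-pixel (zenith_deg, azimuth_deg)
    arrays; by default an ideal equidistant fisheye centered on the
    image is assumed.  Gap fraction per cell is the fraction of gap
    (mask == 0) pixels among the cell's valid pixels.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if projection is None:
        zen, az = equidistant_projection(mask.shape)
    else:
        zen, az = projection
    valid = np.isfinite(zen) & (zen < MAX_ZENITH_DEG)
    ring = np.floor(zen[valid] / RING_WIDTH_DEG).astype(int)
    cell = np.floor(az[valid] / (360.0 / N_AZIMUTH)).astype(int) % N_AZIMUTH
    flat = ring * N_AZIMUTH + cell
    counts = np.bincount(flat, minlength=N_RINGS * N_AZIMUTH).astype(float)
    gaps = np.bincount(
        flat, weights=(mask[valid] == 0), minlength=N_RINGS * N_AZIMUTH
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        gap = np.where(counts > 0, gaps / np.where(counts > 0, counts, 1), np.nan)
    return GapFractionGrid(
        gap.reshape(N_RINGS, N_AZIMUTH), counts.reshape(N_RINGS, N_AZIMUTH)
    )


# ---------------------------------------------------------------------------
# leaf angle distribution and gap model


def chi_from_ala(ala_deg) -> np.ndarray:
    """Ellipsoid shape parameter chi from the average leaf angle (deg).

    Inverts the empirical relation ALA_rad = 9.65 * (3 + chi)^(-1.65)
    of the ellipsoidal leaf inclination distribution literature.
    """
    ala_rad = np.radians(np.asarray(ala_deg, float))
    if np.any(ala_rad <= 0):
        raise ValueError("ala must be positive")
    return (ala_rad / 9.65) ** (-1.0 / 1.65) - 3.0


def ala_from_chi(chi) -> np.ndarray:
    chi = np.asarray(chi, float)
    if np.any(chi <= 0):
        raise ValueError("chi must be positive")
    return np.degrees(9.65 * (3.0 + chi) ** (-1.65))


def g_function(theta_deg, chi) -> np.ndarray:
    """Mean projection of unit leaf area at view zenith theta.

    Ellipsoidal leaf inclination distribution:

        G(theta, chi) = cos(theta) * sqrt(chi^2 + tan^2 theta)
                        / (chi + 1.774 * (chi + 1.182)^(-0.733))

    At chi = 1 (spherical distribution) G is 0.5 for every theta to
    within 1e-3.
    """
    chi = np.asarray(chi, float)
    if np.any(chi <= 0):
        raise ValueError("chi must be positive")
    theta = np.radians(np.asarray(theta_deg, float))
    norm = chi + 1.774 * (chi + 1.182) ** (-0.733)
    return np.cos(theta) * np.sqrt(chi**2 + np.tan(theta) ** 2) / norm


def gap_model(lai, ala_deg, omega, theta_deg) -> np.ndarray:
    """Poisson gap-fraction model with clumping.

    P(theta) = exp(-G(theta, chi(ala)) * omega * lai / cos(theta))
    """
    theta_deg = np.asarray(theta_deg, float)
    if np.any(theta_deg >= 90):
        raise ValueError("view zenith must be < 90 deg")
    g = g_function(theta_deg, chi_from_ala(ala_deg))
    return np.exp(
        -g * np.asarray(omega, float) * np.asarray(lai, float)
        / np.cos(np.radians(theta_deg))
    )


# ---------------------------------------------------------------------------
# clumping and inversion


def clumping_lang_xiang(gaps, weights=None) -> float:
    """Lang-Xiang clumping index of one zenith ring.

    Ratio of the log of the (weighted) mean gap fraction to the
    (weighted) mean of the log gap fractions, over the azimuth cells of
    all photos of a plot.  Equals 1 for a homogeneous ring and falls
    below 1 with between-cell heterogeneity (Jensen's inequality).
    Gap values must be in (0, 1]; saturated (zero-gap) cells are
    expected to have been replaced beforehand.
    """
    gaps = np.asarray(gaps, float)
    if gaps.size == 0:
        raise ValueError("no populated cells in ring")
    if np.any(gaps <= 0) or np.any(gaps > 1):
        raise ValueError("gap fractions must lie in (0, 1]")
    w = np.ones_like(gaps) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    mean_gap = float((w * gaps).sum() / wsum)
    mean_log = float((w * np.log(gaps)).sum() / wsum)
    if mean_log == 0.0:  # every cell fully open
        return 1.0
    return float(np.log(mean_gap) / mean_log)


def _stacked_cells(grids):
    """(gap, count) arrays of shape (n_photos, N_RINGS, N_AZIMUTH)."""
    gap = np.stack([g.gap for g in grids])
    counts = np.stack([g.counts for g in grids])
    return gap, counts


def _replaced_gaps(gap, counts, saturation_ala_deg):
    """Clip cell gaps to [P_sat(theta), 1] for the saturated-gap rule."""
    theta = ring_centers_deg()
    p_sat = gap_model(SATURATION_LAI, saturation_ala_deg, 1.0, theta)
    clipped = np.clip(gap, p_sat[None, :, None], 1.0)
    return np.where(counts > 0, clipped, np.nan)


def _ring_statistics(gap, counts, saturation_ala_deg):
    """Per-ring weighted mean gap, mean log gap and total weight."""
    g = _replaced_gaps(gap, counts, saturation_ala_deg)
    w = np.where(counts > 0, counts, 0.0)
    wsum = w.sum(axis=(0, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_gap = np.nansum(w * g, axis=(0, 2)) / np.where(wsum > 0, wsum, np.nan)
        mean_log = np.nansum(w * np.log(g), axis=(0, 2)) / np.where(
            wsum > 0, wsum, np.nan
        )
    return mean_gap, mean_log, wsum


def clumping_profile(grids, saturation_ala_deg: float) -> np.ndarray:
    """Lang-Xiang clumping index per zenith ring for a set of photos.

    Cell averages are weighted by non-masked pixel counts; zero-gap
    cells are replaced by the saturated gap fraction of an LAI-10
    canopy at the given effective leaf inclination.  Rings with no
    populated cells are nan.
    """
    gap, counts = _stacked_cells(grids)
    mean_gap, mean_log, wsum = _ring_statistics(gap, counts, saturation_ala_deg)
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.where(
            mean_log < 0, np.log(mean_gap) / np.where(mean_log < 0, mean_log, 1), 1.0
        )
    omega = np.where(wsum > 0, omega, np.nan)
    return np.clip(omega, None, 1.0)


def invert_canopy(grids, lut: LutSpec | None = None) -> CanopyParams:
    """LUT inversion of the clumped Poisson model for one plot.

    For every candidate effective leaf inclination the clumping profile
    and the measured (saturation-replaced, count-weighted) ring gap
    fractions are computed; for every (LAI, ALA) pair the modeled ring
    gaps are compared with the measurements by count-weighted RMS.  The
    minimizing triple wins, with ties broken toward the lowest LAI,
    then lowest ALA, then lowest effective ALA.
    """
    if lut is None:
        lut = LutSpec()
    gap, counts = _stacked_cells(grids)
    theta = ring_centers_deg()
    cos_t = np.cos(np.radians(theta))
    g_ala = g_function(theta[None, :], chi_from_ala(lut.ala_grid)[:, None])
    lai = lut.lai_grid

    n_lai, n_ala, n_eff = lai.size, lut.ala_grid.size, lut.effective_ala_grid.size
    cost = np.full((n_lai, n_ala, n_eff), np.inf)
    profiles = []
    any_ring = False
    for k, eff in enumerate(lut.effective_ala_grid):
        mean_gap, mean_log, wsum = _ring_statistics(gap, counts, eff)
        with np.errstate(invalid="ignore", divide="ignore"):
            omega = np.where(mean_log < 0, np.log(mean_gap) / mean_log, 1.0)
        omega = np.clip(omega, None, 1.0)
        populated = wsum > 0
        if not populated.any():
            profiles.append(np.full(N_RINGS, np.nan))
            continue
        any_ring = True
        profiles.append(np.where(populated, omega, np.nan))
        w = wsum[populated] / wsum[populated].sum()
        a = (g_ala[:, populated] * omega[None, populated]) / cos_t[None, populated]
        # modeled gap per (lai, ala, ring)
        p_model = np.exp(-lai[:, None, None] * a[None, :, :])
        resid = p_model - mean_gap[None, None, populated]
        cost[:, :, k] = np.sqrt((w[None, None, :] * resid**2).sum(axis=2))
    if not any_ring:
        raise ValueError("no populated rings in the gap grids")
    best = np.unravel_index(np.argmin(cost), cost.shape)
    i_lai, i_ala, i_eff = best
    return CanopyParams(
        lai=float(lai[i_lai]),
        ala_deg=float(lut.ala_grid[i_ala]),
        omega=profiles[i_eff],
        effective_ala_deg=float(lut.effective_ala_grid[i_eff]),
        ground_cover=ground_cover(grids),
    )


def ground_cover(grids) -> float:
    """Fraction of ground covered by vegetation from near-nadir gaps.

    One minus the count-weighted mean raw gap fraction over the zenith
    rings fully contained in the 0-20 deg interval.
    """
    gap, counts = _stacked_cells(grids)
    gap = gap[:, GROUND_COVER_RINGS, :]
    counts = counts[:, GROUND_COVER_RINGS, :]
    w = counts[counts > 0]
    if w.size == 0:
        raise ValueError("no populated cells within 0-20 deg zenith")
    g = gap[counts > 0]
    return float(1.0 - (w * g).sum() / w.sum())
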