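"""Core domain types shared by every stage of the pipeline.

Conventions used throughout the package:

* Reflectance is stored as a fraction (0-1), not percent.  All ratio-based
  vegetation indices are invariant to this choice; WDVI is not, and its
  documentation flags that.
* Missing values are encoded as ``nan`` and excluded from all means.
* Rasters are row-major with the (0, 0) pixel at the top-left corner and
  coordinates referring to pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralBandSet",
    "Spectrum",
    "PlotSpectra",
    "HyperCube",
    "TraitRecord",
    "aggregate_plot",
    "uav_band_set",
    "ground_band_set",
]

#: conversion factor: leaf chlorophyll in ug cm^-2 times LAI (m^2 m^-2)
#: to canopy chlorophyll in g m^-2.
CHL_UNIT_FACTOR = 0.01


@dataclass(frozen=True)
class SpectralBandSet:
    """An ordered set of narrow spectral bands for one sensor.

    Parameters
    ----------
    sensor_label : str
        Free-form sensor tag; ``"uav"`` and ``"ground"`` are the two
        sensors of the study design.
    centers : ndarray
        Band center wavelengths in nm, strictly increasing, all within
        [400, 1000] nm.
    fwhm : ndarray
        Full width at half maximum per band, nm, all positive.
    """

    sensor_label: str
    centers: np.ndarray
    fwhm: np.ndarray

    def __post_init__(self):
        centers = np.array(self.centers, dtype=float, copy=True)
        fwhm = np.array(self.fwhm, dtype=float, copy=True)
        if fwhm.ndim == 0:
            fwhm = np.full(centers.shape, float(fwhm))
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("centers must be a non-empty 1-D sequence")
        if fwhm.shape != centers.shape:
            raise ValueError("fwhm must match centers in length")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(fwhm <= 0):
            raise ValueError("fwhm must be positive")
        if centers.min() < 400 or centers.max() > 1000:
            raise ValueError("band centers must lie within [400, 1000] nm")
        centers.flags.writeable = False
        fwhm.flags.writeable = False
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "fwhm", fwhm)

    def __len__(self) -> int:
        return self.centers.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralBandSet):
            return NotImplemented
        return (
            self.sensor_label == other.sensor_label
            and np.array_equal(self.centers, other.centers)
            and np.array_equal(self.fwhm, other.fwhm)
        )

    def __hash__(self):
        return hash((self.sensor_label, self.centers.tobytes()))


def uav_band_set() -> SpectralBandSet:
    """Band set of the UAV pushbroom spectrometer: 450-910 nm at 10 nm."""
    centers = np.arange(450.0, 915.0, 10.0)
    return SpectralBandSet("uav", centers, np.full(centers.size, 10.0))


def ground_band_set() -> SpectralBandSet:
    """Eleven-band handheld radiometer set (490-870 nm).

    Centers cover every nominal band the index library requires of the
    ground sensor; FWHM of the instrument class varies between 7.3 and
    13 nm and is represented here by a nominal 10 nm.
    """
    centers = np.array(
        [490.0, 530.0, 550.0, 570.0, 670.0, 700.0, 710.0, 740.0, 750.0, 780.0, 870.0]
    )
    return SpectralBandSet("ground", centers, np.full(centers.size, 10.0))


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance observation on one band set.

    Values are fractions; values above 1 are allowed but flagged via
    :attr:`suspect`.  ``nan`` marks missing bands.
    """

    band_set: SpectralBandSet
    values: np.ndarray

    def __post_init__(self):
        values = np.array(self.values, dtype=float, copy=True)
        if values.shape != (len(self.band_set),):
            raise ValueError(
                f"expected {len(self.band_set)} reflectance values, got {values.shape}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(values < 0):
                raise ValueError("reflectance values must be >= 0")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @property
    def suspect(self) -> bool:
        """True when any band exceeds 1 (physically dubious reflectance)."""
        with np.errstate(invalid="ignore"):
            return bool(np.any(self.values > 1.0))


@dataclass
class PlotSpectra:
    """All reflectance observations of one plot on one date by one sensor.

    ``reflectance`` is an (n_obs, n_bands) array; ``weights`` (optional)
    weight the observations in plot-level aggregation, e.g. per-footprint
    valid-pixel counts.
    """

    plot_id: str
    treatment: str
    dap: int
    band_set: SpectralBandSet
    reflectance: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.reflectance.shape[1] != len(self.band_set):
            raise ValueError("reflectance columns must match band set size")
        if self.dap <= 0:
            raise ValueError("dap must be a positive number of days")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.reflectance.shape[0],):
                raise ValueError("weights must have one entry per observation")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")

    @property
    def sensor_label(self) -> str:
        return self.band_set.sensor_label

    @property
    def n_obs(self) -> int:
        return self.reflectance.shape[0]

    def spectra(self) -> list[Spectrum]:
        return [Spectrum(self.band_set, row) for row in self.reflectance]


def aggregate_plot(ps: PlotSpectra) -> Spectrum:
    """Band-wise (weighted) arithmetic mean of the member spectra.

    Missing values (nan) are excluded band by band; the aggregate is the
    plot-level reflectance signature used everywhere downstream.
    """
    if ps.n_obs == 0:
        raise ValueError("cannot aggregate an empty PlotSpectra")
    w = ps.weights if ps.weights is not None else np.ones(ps.n_obs)
    if np.sum(w) == 0:
        raise ValueError("aggregation weights sum to zero")
    valid = ~np.isnan(ps.reflectance)
    ww = np.where(valid, w[:, None], 0.0)
    totals = ww.sum(axis=0)
    num = np.where(valid, ps.reflectance, 0.0) * w[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(totals > 0, num.sum(axis=0) / totals, np.nan)
    return Spectrum(ps.band_set, mean)


@dataclass
class HyperCube:
    """Band-stacked raster of reflectance spectra.

    ``data`` has shape (rows, cols, bands), row-major with pixel (0, 0)
    at the top-left; ``origin`` is the map coordinate of that pixel's
    center and ``pixel_size`` the ground sampling distance in meters.
    """

    band_set: SpectralBandSet
    data: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != len(self.band_set):
            raise ValueError("cube band dimension must match band set size")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinate (x, y) of a pixel center; y increases downward."""
        x0, y0 = self.origin
        return (x0 + col * self.pixel_size, y0 + row * self.pixel_size)


@dataclass
class TraitRecord:
    """Ground-truth crop traits of one plot on one date.

    canopy_chl must equal leaf_chl * lai * 0.01 (the unit conversion from
    ug cm^-2 times m^2 m^-2 to g m^-2) whenever all three are present.
    """

    plot_id: str
    dap: int
    leaf_chl: float = np.nan  # ug cm^-2
    lai: float = np.nan  # m^2 m^-2
    canopy_chl: float = np.nan  # g m^-2
    ground_cover: float = np.nan  # fraction
    treatment: str = ""

    def __post_init__(self):
        if not np.isnan(self.lai) and self.lai < 0:
            raise ValueError("lai must be >= 0")
        if not np.isnan(self.ground_cover) and not 0 <= self.ground_cover <= 1:
            raise ValueError("ground_cover must lie in [0, 1]")
        if not (
            np.isnan(self.leaf_chl) or np.isnan(self.lai) or np.isnan(self.canopy_chl)
        ):
            expected = self.leaf_chl * self.lai * CHL_UNIT_FACTOR
            if abs(self.canopy_chl - expected) > 1e-9:
                raise ValueError(
                    "canopy_chl inconsistent with leaf_chl * lai * 0.01 "
                    f"({self.canopy_chl} vs {expected})"
                )
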