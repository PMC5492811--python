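"""Narrow-band vegetation index library.

Sixteen indices relating Vis-NIR reflectance to leaf chlorophyll, leaf
area index, canopy chlorophyll and ground cover.  Every index is defined
by a formula over reflectances at nominal band centers; the nominal
centers differ slightly between the UAV and ground sensor (e.g. the
ground radiometer has no 800 nm band and substitutes 780 nm in NDVI and
OSAVI).  Bands are resolved against a sensor's band set by nearest
center within a tolerance — no spectral response convolution.

All ratio-based indices are invariant to a positive rescaling of the
spectrum.  WDVI is not: it is linear in reflectance and therefore
scale-dependent, and additionally requires a soil line (the ratio
C = RSoil870 / RSoil670 of bare-soil reflectances).

Undefined values (zero denominators) propagate as ``nan`` rather than
raising, so a single bad pixel cannot kill an index map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import HyperCube, SpectralBandSet, Spectrum

__all__ = [
    "IndexDefinition",
    "SoilLine",
    "INDEX_REGISTRY",
    "index_names",
    "resolve_band",
    "compute_index",
    "index_map",
    "estimate_soil_line",
]


@dataclass(frozen=True)
class SoilLine:
    """Soil-line ratio C = RSoil870 / RSoil670 used by WDVI."""

    c_ratio: float

    def __post_init__(self):
        if not self.c_ratio > 0:
            raise ValueError("soil-line ratio must be positive")


def resolve_band(
    band_set: SpectralBandSet, nominal_nm: float, tolerance_nm: float = 10.0
) -> int:
    """Index of the band whose center is nearest ``nominal_nm``.

    Ties (a nominal center equidistant from two bands) resolve to the
    shorter wavelength.  Raises if no center lies within the tolerance.
    """
    dist = np.abs(band_set.centers - nominal_nm)
    pos = int(np.argmin(dist))  # argmin takes the first (lower) on ties
    if dist[pos] > tolerance_nm:
        raise ValueError(
            f"no band within {tolerance_nm} nm of {nominal_nm} nm in "
            f"{band_set.sensor_label!r} band set"
        )
    return pos


def _safe_div(num, den):
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out


def _ndvi(red, nir):
    return _safe_div(nir - red, nir + red)


def _wdvi(red, nir, c):
    return nir - c * red


def _osavi(red, nir):
    return _safe_div(1.16 * (nir - red), nir + red + 0.16)


def _mcari(g, red, re):
    return ((re - red) - 0.2 * (re - g)) * _safe_div(re, red)


def _tcari(g, red, re):
    return 3.0 * ((re - red) - 0.2 * (re - g) * _safe_div(re, red))


def _mcari_osavi(g, red, re, nir):
    return _safe_div(_mcari(g, red, re), _osavi(red, nir))


def _tcari_osavi(g, red, re, nir):
    return _safe_div(_tcari(g, red, re), _osavi(red, nir))


def _mcari_re(g, re1, re2):
    # red-edge variant: 705 and 750 nm replace 670 and 700 nm
    return ((re2 - re1) - 0.2 * (re2 - g)) * _safe_div(re2, re1)


def _osavi_re(re1, re2):
    return _safe_div(1.16 * (re2 - re1), re2 + re1 + 0.16)


def _mcari_osavi_re(g, re1, re2):
    return _safe_div(_mcari_re(g, re1, re2), _osavi_re(re1, re2))


def _tcari_re(g, re1, re2):
    return 3.0 * ((re2 - re1) - 0.2 * (re2 - g) * _safe_div(re2, re1))


def _tcari_osavi_re(g, re1, re2):
    return _safe_div(_tcari_re(g, re1, re2), _osavi_re(re1, re2))


def _ci(denom_band, nir):
    return _safe_div(nir, denom_band) - 1.0


def _mcari2(g, red, nir):
    num = 1.5 * (2.5 * (nir - red) - 1.3 * (nir - g))
    with np.errstate(invalid="ignore"):
        disc = (2.0 * nir + 1.0) ** 2 - (6.0 * nir - 5.0 * np.sqrt(np.abs(red))) - 0.5
        den = np.sqrt(np.where(disc > 0, disc, np.nan))
    return _safe_div(num, den)


def _rep(red, re700, re740, nir):
    # four-point interpolation: red-edge-point reflectance is the mean of
    # the NIR shoulder and the chlorophyll absorption trough, located
    # proportionally between the 700 and 740 nm bands
    target = (red + nir) / 2.0
    return 700.0 + 40.0 * _safe_div(target - re700, re740 - re700)


def _mtci(red, re1, re2):
    return _safe_div(re2 - re1, re1 - red)


def _pri(b531, b570):
    return _safe_div(b570 - b531, b570 + b531)


@dataclass(frozen=True)
class IndexDefinition:
    """One vegetation index: a formula plus per-sensor nominal bands."""

    name: str
    func: Callable
    bands: dict  # sensor_label -> tuple of nominal centers (nm)
    scale: str  # 'leaf' or 'canopy' sensitivity tag
    needs_soil: bool = False

    def nominal_bands(self, sensor_label: str) -> tuple:
        # unknown (custom) sensors evaluate on the UAV nominal centers
        return self.bands.get(sensor_label, self.bands["uav"])


def _defn(name, func, ground, uav, scale, needs_soil=False):
    return IndexDefinition(
        name, func, {"ground": tuple(ground), "uav": tuple(uav)}, scale, needs_soil
    )


INDEX_REGISTRY: dict[str, IndexDefinition] = {
    d.name: d
    for d in [
        _defn("NDVI", _ndvi, (670, 780), (670, 800), "leaf+canopy"),
        _defn("WDVI", _wdvi, (670, 870), (670, 870), "canopy", needs_soil=True),
        _defn("OSAVI", _osavi, (670, 780), (670, 800), "leaf+canopy"),
        _defn("MCARI", _mcari, (550, 670, 700), (550, 670, 700), "leaf"),
        _defn("TCARI", _tcari, (550, 670, 700), (550, 670, 700), "leaf"),
        _defn("MCARI_OSAVI", _mcari_osavi, (550, 670, 700, 780), (550, 670, 700, 800), "leaf"),
        _defn("TCARI_OSAVI", _tcari_osavi, (550, 670, 700, 780), (550, 670, 700, 800), "leaf"),
        _defn("MCARI_re", _mcari_re, (550, 700, 750), (550, 705, 750), "leaf"),
        _defn("MCARI_OSAVI_re", _mcari_osavi_re, (550, 700, 750), (550, 705, 750), "leaf"),
        _defn("TCARI_OSAVI_re", _tcari_osavi_re, (550, 700, 750), (550, 705, 750), "leaf"),
        _defn("CI_re", _ci, (710, 780), (710, 780), "leaf"),
        # CI_g replaces the red-edge band of CI_re by the green band:
        # R780 / R550 - 1 on both sensors
        _defn("CI_g", _ci, (550, 780), (550, 780), "leaf"),
        _defn("MCARI2", _mcari2, (550, 670, 780), (550, 670, 800), "canopy"),
        _defn("REP", _rep, (670, 700, 740, 780), (670, 700, 740, 780), "leaf+canopy"),
        _defn("MTCI", _mtci, (670, 710, 750), (680, 710, 755), "leaf+canopy"),
        _defn("PRI", _pri, (530, 570), (530, 570), "leaf+canopy"),
    ]
}

_ALIASES = {
    "MCARI/OSAVI": "MCARI_OSAVI",
    "TCARI/OSAVI": "TCARI_OSAVI",
    "MCARI/OSAVI_RE": "MCARI_OSAVI_re",
    "TCARI/OSAVI_RE": "TCARI_OSAVI_re",
    "MCARI_RE": "MCARI_re",
    "MCARI/OSAVIRE": "MCARI_OSAVI_re",
    "CIRE": "CI_re",
    "CI_RE": "CI_re",
    "CIG": "CI_g",
    "CI_G": "CI_g",
}


def index_names() -> list[str]:
    return list(INDEX_REGISTRY)


def get_definition(name: str) -> IndexDefinition:
    if name in INDEX_REGISTRY:
        return INDEX_REGISTRY[name]
    key = _ALIASES.get(name.upper())
    if key is None and name.upper() in {k.upper(): k for k in INDEX_REGISTRY}:
        key = {k.upper(): k for k in INDEX_REGISTRY}[name.upper()]
    if key is None:
        raise KeyError(f"unknown vegetation index {name!r}")
    return INDEX_REGISTRY[key]


def _resolved_positions(defn: IndexDefinition, band_set: SpectralBandSet,
                        tolerance_nm: float = 10.0) -> list[int]:
    return [
        resolve_band(band_set, nm, tolerance_nm)
        for nm in defn.nominal_bands(band_set.sensor_label)
    ]


def compute_index(
    spectrum: Spectrum, name: str, soil_line: SoilLine | None = None
) -> float:
    """Evaluate one vegetation index on a single spectrum.

    Returns ``nan`` when the formula is undefined (zero denominator).
    """
    defn = get_definition(name)
    pos = _resolved_positions(defn, spectrum.band_set)
    args = [spectrum.values[p] for p in pos]
    if defn.needs_soil:
        if soil_line is None:
            raise ValueError(f"{defn.name} requires a soil line")
        args.append(soil_line.c_ratio)
    return float(defn.func(*args))


def index_map(
    cube: HyperCube, name: str, soil_line: SoilLine | None = None
) -> np.ndarray:
    """Per-pixel index values as a 2-D array; undefined pixels are nan."""
    defn = get_definition(name)
    pos = _resolved_positions(defn, cube.band_set)
    args = [cube.data[:, :, p] for p in pos]
    if defn.needs_soil:
        if soil_line is None:
            raise ValueError(f"{defn.name} requires a soil line")
        args.append(soil_line.c_ratio)
    out = np.asarray(defn.func(*args), dtype=float)
    return out


def estimate_soil_line(soil_spectra: list[Spectrum]) -> SoilLine:
    """Soil-line ratio from bare-soil spectra: mean of R870 / R670."""
    if not soil_spectra:
        raise ValueError("need at least one soil spectrum")
    ratios = []
    for s in soil_spectra:
        p670 = resolve_band(s.band_set, 670)
        p870 = resolve_band(s.band_set, 870)
        r670, r870 = s.values[p670], s.values[p870]
        if not r670 > 0:
            raise ValueError("soil reflectance at 670 nm must be positive")
        ratios.append(r870 / r670)
    return SoilLine(float(np.mean(ratios)))
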