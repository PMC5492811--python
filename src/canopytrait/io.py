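"""Readers and writers for the plain-file interfaces between stages.

Formats
-------
Spectra tables
    CSV with columns ``plot_id, treatment, dap, sensor`` followed by one
    column per band named by its integer center wavelength in nm
    (optionally prefixed with ``R``, e.g. ``R670``).
Trait tables
    CSV with columns ``plot_id, dap, leaf_chl, lai, canopy_chl,
    ground_cover`` (plus optional ``treatment``).
Hyperspectral cubes
    Either a (Geo)TIFF whose image description carries per-band
    wavelength metadata as JSON, or an ENVI-style pair: an ASCII
    ``.hdr`` with ``wavelength = {...}`` next to a flat band-sequential
    binary file.
Gap-fraction grids
    Long-format CSV with columns ``photo, ring, azimuth, gap, count``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import HyperCube, PlotSpectra, SpectralBandSet, TraitRecord

__all__ = [
    "read_spectra_table",
    "write_spectra_table",
    "read_trait_table",
    "write_trait_table",
    "read_cube",
    "write_cube",
    "read_gap_grids",
    "write_gap_grids",
]

_META_COLS = ("plot_id", "treatment", "dap", "sensor")


def _band_column_name(center: float) -> str:
    return str(int(round(center)))


def write_spectra_table(records: list[PlotSpectra], path) -> None:
    """Write PlotSpectra observations (one row per spectrum) to CSV."""
    if not records:
        raise ValueError("no records to write")
    band_set = records[0].band_set
    rows = []
    for ps in records:
        if ps.band_set != band_set:
            raise ValueError("all records in one table must share a band set")
        w = ps.weights if ps.weights is not None else np.ones(ps.n_obs)
        for obs, wi in zip(ps.reflectance, w):
            row = {
                "plot_id": ps.plot_id,
                "treatment": ps.treatment,
                "dap": ps.dap,
                "sensor": ps.sensor_label,
                "weight": wi,
            }
            row.update(
                {_band_column_name(c): v for c, v in zip(band_set.centers, obs)}
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_spectra_table(path, band_set: SpectralBandSet) -> list[PlotSpectra]:
    """Read a spectra CSV back into PlotSpectra, grouped by (plot, dap, sensor).

    Band columns must match the band-set centers exactly; a missing or
    unmatched band column is an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")
    band_cols = []
    for center in band_set.centers:
        name = _band_column_name(center)
        if name in df.columns:
            band_cols.append(name)
        elif f"R{name}" in df.columns:
            band_cols.append(f"R{name}")
        else:
            raise ValueError(
                f"band column for {name} nm absent from {path} "
                f"(band set {band_set.sensor_label!r})"
            )
    extra = [
        c
        for c in df.columns
        if c not in _META_COLS and c != "weight" and c not in band_cols
        and re.fullmatch(r"R?\d+", str(c))
    ]
    if extra:
        raise ValueError(
            f"band columns {extra} in {path} do not match the "
            f"{band_set.sensor_label!r} band set"
        )
    out = []
    for (plot_id, dap, sensor), grp in df.groupby(
        ["plot_id", "dap", "sensor"], sort=True
    ):
        if sensor != band_set.sensor_label:
            raise ValueError(
                f"sensor {sensor!r} in table does not match band set "
                f"{band_set.sensor_label!r}"
            )
        treatment = str(grp["treatment"].iloc[0])
        weights = grp["weight"].to_numpy(float) if "weight" in grp else None
        out.append(
            PlotSpectra(
                plot_id=str(plot_id),
                treatment=treatment,
                dap=int(dap),
                band_set=band_set,
                reflectance=grp[band_cols].to_numpy(float),
                weights=weights,
            )
        )
    return out


_TRAIT_COLS = ["plot_id", "dap", "leaf_chl", "lai", "canopy_chl", "ground_cover"]


def write_trait_table(records: list[TraitRecord], path) -> None:
    rows = [
        {
            "plot_id": t.plot_id,
            "dap": t.dap,
            "leaf_chl": t.leaf_chl,
            "lai": t.lai,
            "canopy_chl": t.canopy_chl,
            "ground_cover": t.ground_cover,
            "treatment": t.treatment,
        }
        for t in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_trait_table(path) -> list[TraitRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRAIT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table {path} missing columns {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            TraitRecord(
                plot_id=str(r["plot_id"]),
                dap=int(r["dap"]),
                leaf_chl=float(r["leaf_chl"]),
                lai=float(r["lai"]),
                canopy_chl=float(r["canopy_chl"]),
                ground_cover=float(r["ground_cover"]),
                treatment=str(r.get("treatment", "")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# hyperspectral cubes


def write_cube(cube: HyperCube, path) -> None:
    """Write a cube as TIFF (+JSON wavelength metadata) or ENVI pair."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        meta = {
            "wavelength": list(map(float, cube.band_set.centers)),
            "fwhm": list(map(float, cube.band_set.fwhm)),
            "sensor_label": cube.band_set.sensor_label,
            "pixel_size": cube.pixel_size,
            "origin": list(cube.origin),
        }
        # store bands as pages, rows x cols each
        tifffile.imwrite(
            path,
            np.moveaxis(cube.data, 2, 0),
            description=json.dumps(meta),
        )
    elif path.suffix.lower() == ".hdr":
        _write_envi(cube, path)
    else:
        raise ValueError(f"unsupported cube format: {path.suffix!r}")


def read_cube(path) -> HyperCube:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path)
    if path.suffix.lower() == ".hdr":
        return _read_envi(path)
    raise ValueError(f"unsupported cube format: {path.suffix!r}")


def _read_tiff(path: Path) -> HyperCube:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description
        data = tf.asarray()
    if not desc:
        raise ValueError(f"{path} carries no wavelength metadata")
    try:
        meta = json.loads(desc)
        wavelengths = meta["wavelength"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise ValueError(f"{path} carries no wavelength metadata") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    if data.shape[0] != len(wavelengths):
        raise ValueError(
            f"{path}: {data.shape[0]} bands in raster vs "
            f"{len(wavelengths)} wavelengths in metadata"
        )
    band_set = SpectralBandSet(
        meta.get("sensor_label", "unknown"),
        np.asarray(wavelengths, float),
        np.asarray(meta.get("fwhm", [10.0] * len(wavelengths)), float),
    )
    return HyperCube(
        band_set,
        np.moveaxis(data, 0, 2).astype(float),
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )


def _write_envi(cube: HyperCube, hdr_path: Path) -> None:
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{c:g}" for c in cube.band_set.centers)
    fw = ", ".join(f"{f:g}" for f in cube.band_set.fwhm)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "data type = 5\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"sensor type = {cube.band_set.sensor_label}\n"
        f"pixel size = {{{cube.pixel_size:g}, {cube.pixel_size:g}}}\n"
        f"map origin = {{{cube.origin[0]:g}, {cube.origin[1]:g}}}\n"
        f"wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
        f"fwhm = {{{fw}}}\n"
    )
    hdr_path.write_text(hdr)
    raw = hdr_path.with_suffix(".img")
    np.moveaxis(cube.data, 2, 0).astype("<f8").tofile(raw)


def _parse_envi_header(text: str) -> dict:
    # collapse {...} blocks spanning lines, then key = value pairs
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    return fields


def _envi_list(value: str) -> list[float]:
    return [float(x) for x in value.strip("{} ").split(",") if x.strip()]


def _read_envi(hdr_path: Path) -> HyperCube:
    fields = _parse_envi_header(hdr_path.read_text())
    if "wavelength" not in fields:
        raise ValueError(f"{hdr_path} carries no wavelength metadata")
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    wavelengths = _envi_list(fields["wavelength"])
    if len(wavelengths) != bands:
        raise ValueError(
            f"{hdr_path}: bands = {bands} but {len(wavelengths)} wavelengths listed"
        )
    fwhm = _envi_list(fields["fwhm"]) if "fwhm" in fields else [10.0] * bands
    data = np.fromfile(hdr_path.with_suffix(".img"), dtype="<f8")
    if data.size != rows * cols * bands:
        raise ValueError(f"{hdr_path}: binary payload size mismatch")
    data = np.moveaxis(data.reshape(bands, rows, cols), 0, 2)
    pixel_size = _envi_list(fields.get("pixel size", "{1, 1}"))[0]
    origin = tuple(_envi_list(fields.get("map origin", "{0, 0}")))
    band_set = SpectralBandSet(
        fields.get("sensor type", "unknown"), np.asarray(wavelengths), np.asarray(fwhm)
    )
    return HyperCube(band_set, data, pixel_size=pixel_size, origin=origin)


# ---------------------------------------------------------------------------
# gap-fraction grids


def write_gap_grids(grids, path) -> None:
    """Write a sequence of GapFractionGrid as long-format CSV."""
    rows = []
    for j, g in enumerate(grids):
        for i in range(g.gap.shape[0]):
            for a in range(g.gap.shape[1]):
                rows.append(
                    {
                        "photo": j,
                        "ring": i,
                        "azimuth": a,
                        "gap": g.gap[i, a],
                        "count": g.counts[i, a],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_gap_grids(path):
    from .dhp import GapFractionGrid

    df = pd.read_csv(path, float_precision="round_trip")
    grids = []
    for _, grp in df.groupby("photo", sort=True):
        n_rings = int(grp["ring"].max()) + 1
        n_az = int(grp["azimuth"].max()) + 1
        gap = np.full((n_rings, n_az), np.nan)
        counts = np.zeros((n_rings, n_az))
        gap[grp["ring"], grp["azimuth"]] = grp["gap"]
        counts[grp["ring"], grp["azimuth"]] = grp["count"]
        grids.append(GapFractionGrid(gap=gap, counts=counts))
    return grids
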