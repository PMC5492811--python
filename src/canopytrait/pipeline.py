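"""End-to-end orchestration of the synthetic two-sensor campaign.

Stages hand data to each other through plain files (CSV rasters and
tables) so that every stage is callable standalone and a run is fully
inspectable.  A run manifest (JSON) records the config hash, seed,
stage list and the files each stage read and wrote; re-running with an
identical config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import intercompare, separation
from .core import aggregate_plot, ground_band_set, uav_band_set
from .dhp import invert_canopy
from .extraction import detect_edges, edges_to_plots
from .indices import SoilLine, compute_index, index_names
from .io import (
    read_gap_grids,
    read_spectra_table,
    read_trait_table,
    write_gap_grids,
    write_spectra_table,
    write_trait_table,
)
from .retrieval import model_matrix
from .simulate import (
    SimulationConfig,
    default_strip_layout,
    simulate_gap_field,
    simulate_mosaic,
    simulate_traits,
    simulate_two_sensor_spectra,
    soil_reflectance,
)

__all__ = ["STAGES", "load_config", "run_pipeline"]

log = logging.getLogger("canopytrait")

STAGES = (
    "simulate",
    "indices",
    "invert_dhp",
    "extract",
    "fit",
    "compare",
    "discriminate",
)

TRAITS = ["leaf_chl", "lai", "canopy_chl", "ground_cover"]


def load_config(path) -> dict:
    """Load a flat YAML/JSON config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SimulationConfig)} | {
        "cv_repeats",
        "cv_folds",
        "stages",
        "n_mosaic_plots",
        "mosaic_noise_sd",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return raw


def _sim_config(config: dict) -> SimulationConfig:
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {k: v for k, v in config.items() if k in fields}
    if "dap_schedule" in kwargs:
        kwargs["dap_schedule"] = tuple(kwargs["dap_schedule"])
    if "lai_points" in kwargs:
        kwargs["lai_points"] = tuple(tuple(p) for p in kwargs["lai_points"])
    return SimulationConfig(**kwargs)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {path}; run its upstream stage first"
        )
    return path


def run_pipeline(config: dict | str | Path, out_dir, stages=None, verbose=False):
    """Run the requested stages in dependency order; return the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    if verbose:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="[%(name)s] %(message)s")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _sim_config(config)
    stages = list(stages or config.get("stages") or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]  # dependency order

    manifest = {
        "tool_version": __version__,
        "config_hash": _config_hash(config),
        "seed": cfg.seed,
        "stages": [],
    }
    runners = {
        "simulate": _stage_simulate,
        "indices": _stage_indices,
        "invert_dhp": _stage_invert_dhp,
        "extract": _stage_extract,
        "fit": _stage_fit,
        "compare": _stage_compare,
        "discriminate": _stage_discriminate,
    }
    for stage in stages:
        log.info("stage %s: starting", stage)
        outputs = runners[stage](cfg, config, out)
        manifest["stages"].append({"name": stage, "outputs": outputs})
        log.info("stage %s: wrote %s", stage, ", ".join(outputs))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: SimulationConfig, config: dict, out: Path) -> list[str]:
    traits = simulate_traits(cfg)
    write_trait_table(traits, out / "traits.csv")
    uav, ground = simulate_two_sensor_spectra(traits, cfg)
    write_spectra_table(uav, out / "spectra_uav.csv")
    write_spectra_table(ground, out / "spectra_ground.csv")
    gap_dir = out / "gaps"
    gap_dir.mkdir(exist_ok=True)
    written = ["traits.csv", "spectra_uav.csv", "spectra_ground.csv"]
    seed_rng = cfg.rng_for("gapfields")
    for t in traits:
        grids = simulate_gap_field(
            t.lai,
            cfg.ala_deg,
            cfg.omega_target,
            n_photos=cfg.n_photos,
            seed=int(seed_rng.integers(2**31)),
            pixels_per_cell=cfg.pixels_per_cell,
        )
        name = f"gaps/{t.plot_id}_{t.dap}.csv"
        write_gap_grids(grids, out / name)
        written.append(name)
    layout = default_strip_layout(int(config.get("n_mosaic_plots", 6)))
    raster, origin = simulate_mosaic(
        layout,
        vi_levels=0.6,
        noise_sd=float(config.get("mosaic_noise_sd", 0.02)),
        seed=cfg.seed,
    )
    np.savetxt(out / "mosaic.csv", raster, delimiter=",")
    pd.DataFrame([dataclasses.asdict(r) for r in layout]).to_csv(
        out / "layout.csv", index=False
    )
    (out / "mosaic_meta.json").write_text(
        json.dumps({"origin": list(origin), "pixel_size": 0.2})
    )
    written += ["mosaic.csv", "layout.csv", "mosaic_meta.json"]
    return written


def _soil_line(band_set) -> SoilLine:
    from .indices import estimate_soil_line

    return estimate_soil_line([soil_reflectance(band_set)])


def _stage_indices(cfg: SimulationConfig, config: dict, out: Path) -> list[str]:
    written = []
    for sensor, band_set in (("uav", uav_band_set()), ("ground", ground_band_set())):
        path = _require(out / f"spectra_{sensor}.csv", "indices")
        records = read_spectra_table(path, band_set)
        soil = _soil_line(band_set)
        rows = []
        for ps in records:
            spectrum = aggregate_plot(ps)
            row = {
                "plot_id": ps.plot_id,
                "treatment": ps.treatment,
                "dap": ps.dap,
                "sensor": sensor,
            }
            for name in index_names():
                row[name] = compute_index(spectrum, name, soil_line=soil)
            rows.append(row)
        name = f"vi_{sensor}.csv"
        pd.DataFrame(rows).to_csv(out / name, index=False)
        written.append(name)
    return written


def _stage_invert_dhp(cfg: SimulationConfig, config: dict, out: Path) -> list[str]:
    traits = read_trait_table(_require(out / "traits.csv", "invert_dhp"))
    rows = []
    for t in traits:
        grids = read_gap_grids(
            _require(out / "gaps" / f"{t.plot_id}_{t.dap}.csv", "invert_dhp")
        )
        params = invert_canopy(grids)
        rows.append(
            {
                "plot_id": t.plot_id,
                "dap": t.dap,
                "lai": params.lai,
                "ala_deg": params.ala_deg,
                "omega_mean": params.omega_mean,
                "ground_cover": params.ground_cover,
            }
        )
    pd.DataFrame(rows).to_csv(out / "canopy.csv", index=False)
    return ["canopy.csv"]


def _stage_extract(cfg: SimulationConfig, config: dict, out: Path) -> list[str]:
    raster = np.loadtxt(_require(out / "mosaic.csv", "extract"), delimiter=",")
    meta = json.loads(_require(out / "mosaic_meta.json", "extract").read_text())
    layout_df = pd.read_csv(_require(out / "layout.csv", "extract"))
    from .simulate import PlotRect

    layout = [
        PlotRect(r.plot_id, r.x0, r.y0, r.width, r.height, r.treatment or "")
        for r in layout_df.fillna({"treatment": ""}).itertuples()
    ]
    edges = detect_edges(raster)
    recovered = edges_to_plots(
        edges, layout, pixel_size=meta["pixel_size"], origin=tuple(meta["origin"])
    )
    pd.DataFrame([dataclasses.asdict(r) for r in recovered]).to_csv(
        out / "plots_recovered.csv", index=False
    )
    return ["plots_recovered.csv"]


def _vi_tables(out: Path, stage: str) -> pd.DataFrame:
    frames = [
        pd.read_csv(_require(out / f"vi_{sensor}.csv", stage))
        for sensor in ("uav", "ground")
    ]
    return pd.concat(frames, ignore_index=True)


def _stage_fit(cfg: SimulationConfig, config: dict, out: Path) -> list[str]:
    vi = _vi_tables(out, "fit")
    traits = pd.read_csv(_require(out / "traits.csv", "fit"))
    table = model_matrix(
        vi,
        traits[["plot_id", "dap"] + TRAITS],
        traits=TRAITS,
        indices=index_names(),
        k=int(config.get("cv_folds", 10)),
        repeats=int(config.get("cv_repeats", 100)),
        seed=cfg.seed,
    )
    table.to_csv(out / "models.csv", index=False)
    return ["models.csv"]


def _stage_compare(cfg: SimulationConfig, config: dict, out: Path) -> list[str]:
    uav = pd.read_csv(_require(out / "vi_uav.csv", "compare"))
    ground = pd.read_csv(_require(out / "vi_ground.csv", "compare"))
    merged = uav.merge(ground, on=["plot_id", "dap"], suffixes=("_uav", "_ground"))
    rows = []
    for name in index_names():
        res = intercompare(
            merged[f"{name}_uav"], merged[f"{name}_ground"], index=name
        )
        rows.append(
            {
                "index": name,
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.r2,
                "ds": res.ds,
                "n": res.n,
            }
        )
    pd.DataFrame(rows).to_csv(out / "intercomp.csv", index=False)
    return ["intercomp.csv"]


def _stage_discriminate(cfg: SimulationConfig, config: dict, out: Path) -> list[str]:
    vi = _vi_tables(out, "discriminate")
    last = vi[vi["dap"] == vi["dap"].max()]
    rows = []
    for sensor, grp in last.groupby("sensor"):
        t1 = grp[grp["treatment"] == "non-mixed"]
        t2 = grp[grp["treatment"] == "mixed"]
        for name in index_names():
            res = separation(t1[name].to_numpy(), t2[name].to_numpy(), index=name)
            rows.append(
                {
                    "sensor": sensor,
                    "index": name,
                    "b_coeff": res.b_coeff,
                    "separation": res.separation,
                }
            )
    pd.DataFrame(rows).to_csv(out / "separation.csv", index=False)
    return ["separation.csv"]
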