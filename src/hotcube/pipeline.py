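"""Configuration-driven orchestration of the full analysis chain.

A pipeline run reads (or simulates) events, filters to the elderly role of
interest, projects to planar metres, and executes the requested stages —
``kde``, ``hotspots``, ``cube``, ``emerging``, ``stkde`` — writing every
artefact plus a run manifest (parameters, row accounting, SHA-256 of each
output) so identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cube as cube_mod
from . import emerging as emerging_mod
from . import events as events_mod
from . import gistar as gistar_mod
from . import grid as grid_mod
from . import kde as kde_mod
from . import stkde as stkde_mod
from . import synthetic

logger = logging.getLogger(__name__)

ALL_STAGES = ("kde", "hotspots", "cube", "emerging", "stkde")

#: every analysis parameter is an explicit, overridable default
DEFAULT_CONFIG = {
    "input": None,            # CSV path; or use "scenario"
    "scenario": None,         # e.g. "seoul_like"
    "schema": {},             # column mapping for read_events
    "role": None,             # "driver" | "victim" | None (no filter)
    "min_age": 65,
    "crs_tag": "tm:127.0,37.55",
    "seed": 0,
    "stages": list(ALL_STAGES),
    "out_dir": "hotcube_out",
    "kde": {"radius": "auto", "kernel": "quartic", "cell_size": 150.0},
    "hotspots": {"cell_size": 425.0, "band": "auto",
                 "candidate_bands": None},
    "cube": {"modes": ["cyclic_hour", "calendar_month"],
             "cell_size": 430.0, "band": None},
    "emerging": {"alpha": 0.05, "prevalence": 0.90, "time_lag": 1},
    "stkde": {"h_s": 1000.0, "h_t": 720.0, "scale_factor": 1e10,
              "dx": 500.0, "dy": 500.0, "dt": 180.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Build a validated pipeline config from defaults, an optional YAML
    file, and programmatic overrides (applied in that order)."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    cfg = _merge(cfg, overrides or {})
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Check stage parameters; raise ``ValueError`` naming the bad field."""
    unknown = set(cfg["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if cfg["input"] is None and cfg["scenario"] is None:
        raise ValueError("config needs either 'input' (CSV path) or 'scenario'")
    if cfg["role"] not in (None, "driver", "victim"):
        raise ValueError(f"invalid role {cfg['role']!r}")
    if "stkde" in cfg["stages"]:
        for fld in ("h_s", "h_t", "scale_factor", "dx", "dy", "dt"):
            if cfg["stkde"].get(fld) is None:
                raise ValueError(f"stkde stage enabled but field 'stkde.{fld}' is missing")
    for sec, fld in (("kde", "radius"), ("hotspots", "cell_size"),
                     ("cube", "cell_size")):
        if sec in cfg["stages"] and cfg[sec].get(fld) is None:
            raise ValueError(f"{sec} stage enabled but field '{sec}.{fld}' is missing")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages in order and return the manifest.

    Artefacts and ``manifest.json`` are written under ``cfg["out_dir"]``.
    A stage failure aborts the run with the failing stage named.
    """
    validate_config(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": copy.deepcopy(cfg), "stages": {}, "outputs": {}}
    t0 = time.time()

    def _register(path: Path):
        manifest["outputs"][path.name] = _sha256(path)

    stage = "load"
    try:
        if cfg["scenario"] is not None:
            if cfg["scenario"] != "seoul_like":
                raise ValueError(f"unknown scenario {cfg['scenario']!r}")
            scen = synthetic.seoul_like_preset(seed=int(cfg["seed"]))
            events, truth = synthetic.generate_scenario(scen)
            synthetic.write_scenario(events, truth,
                                     out_dir / "events.csv",
                                     out_dir / "events_truth.csv")
            _register(out_dir / "events.csv")
            _register(out_dir / "events_truth.csv")
            read_report = events_mod.ReadReport(
                n_rows_in=len(events), n_retained=len(events))
        else:
            events, read_report = events_mod.read_events(cfg["input"],
                                                         schema=cfg["schema"])
        manifest["stages"]["load"] = {"n_rows_in": read_report.n_rows_in,
                                      "n_retained": read_report.n_retained,
                                      "n_dropped": read_report.n_dropped}

        stage = "filter"
        if cfg["role"] is not None:
            events, rep = events_mod.filter_elderly(
                events, cfg["role"], min_age=cfg["min_age"], return_report=True)
            manifest["stages"]["filter"] = rep
        if len(events) == 0:
            raise ValueError("no events left after filtering")

        stage = "project"
        points = events_mod.project_to_planar(events, cfg["crs_tag"])

        if "kde" in cfg["stages"]:
            stage = "kde"
            radius = cfg["kde"]["radius"]
            if radius == "auto":
                radius = kde_mod.search_radius(points)
            lattice = grid_mod.make_grid(points, float(cfg["kde"]["cell_size"]))
            surf = kde_mod.kde_surface(points, lattice, float(radius),
                                       kernel=cfg["kde"]["kernel"])
            kde_mod.surface_to_csv(surf, out_dir / "kde_surface.csv")
            _register(out_dir / "kde_surface.csv")
            manifest["stages"]["kde"] = {"radius_m": float(radius),
                                         "kernel": cfg["kde"]["kernel"]}

        if "hotspots" in cfg["stages"]:
            stage = "hotspots"
            cell = cfg["hotspots"]["cell_size"]
            if cell == "auto":
                probe = grid_mod.make_grid(points, 425.0)
                counts = grid_mod.bin_points(points, probe)
                bands = (cfg["hotspots"]["candidate_bands"]
                         or [425.0 * k for k in range(1, 7)])
                cell = gistar_mod.peak_autocorr_distance(counts, bands)
            cell = float(cell)
            g = grid_mod.make_grid(points, cell)
            counts = grid_mod.bin_points(points, g)
            band = cfg["hotspots"]["band"]
            band = 1.5 * cell if band in (None, "auto") else float(band)
            weights = gistar_mod.build_weights(g, band)
            field = gistar_mod.gi_star(counts, weights)
            gistar_mod.gi_field_to_csv(field, out_dir / "hotspots.csv")
            gistar_mod.gi_field_to_geojson(field, counts,
                                           out_dir / "hotspots.geojson")
            _register(out_dir / "hotspots.csv")
            _register(out_dir / "hotspots.geojson")
            manifest["stages"]["hotspots"] = {
                "cell_size_m": cell, "band_m": band,
                "n_hot99": int((field.classes == "hot99").sum())}

        cubes = {}
        if "cube" in cfg["stages"] or "emerging" in cfg["stages"]:
            stage = "cube"
            cell = float(cfg["cube"]["cell_size"])
            g = grid_mod.make_grid(points, cell)
            band = cfg["cube"]["band"] or 1.5 * cell
            weights = gistar_mod.build_weights(g, band)
            modes = (cfg["cube"]["modes"] if "cube" in cfg["stages"]
                     else ["calendar_month"])
            if "emerging" in cfg["stages"] and "calendar_month" not in modes:
                modes = list(modes) + ["calendar_month"]
            for mode in modes:
                c = cube_mod.build_cube(events, points, g, mode)
                cubes[mode] = (c, weights)
                if "cube" in cfg["stages"]:
                    cube_mod.cube_to_csv(c, out_dir / f"cube_{mode}.csv")
                    _register(out_dir / f"cube_{mode}.csv")
                    fields = cube_mod.slice_hotspots(c, weights)
                    rows = []
                    for t, f in enumerate(fields):
                        rr, cc = np.nonzero(f.classes != "none")
                        for r_, c_ in zip(rr, cc):
                            rows.append((c.bins[t], int(r_), int(c_),
                                         float(f.z[r_, c_]),
                                         f.classes[r_, c_]))
                    pd.DataFrame(rows, columns=["time_bin", "row", "col",
                                                "z", "class"]).to_csv(
                        out_dir / f"slice_hotspots_{mode}.csv", index=False)
                    _register(out_dir / f"slice_hotspots_{mode}.csv")
            manifest["stages"]["cube"] = {
                "cell_size_m": cell, "modes": list(modes),
                "totals": {m: cubes[m][0].total for m in cubes}}

        if "emerging" in cfg["stages"]:
            stage = "emerging"
            c, weights = cubes["calendar_month"]
            zt = emerging_mod.st_gi_star(c, weights,
                                         time_lag=int(cfg["emerging"]["time_lag"]))
            field = emerging_mod.classify_emerging(
                zt, c, alpha=float(cfg["emerging"]["alpha"]),
                prevalence=float(cfg["emerging"]["prevalence"]))
            emerging_mod.trend_field_to_csv(field, out_dir / "emerging_trends.csv")
            _register(out_dir / "emerging_trends.csv")
            lab, cnt = np.unique(field.labels.astype(str), return_counts=True)
            manifest["stages"]["emerging"] = {
                "label_counts": dict(zip(lab.tolist(), cnt.astype(int).tolist()))}

        if "stkde" in cfg["stages"]:
            stage = "stkde"
            p = cfg["stkde"]
            params = stkde_mod.StkdeParams(
                h_s=float(p["h_s"]), h_t=float(p["h_t"]),
                scale_factor=float(p["scale_factor"]),
                dx=float(p["dx"]), dy=float(p["dy"]), dt=float(p["dt"]))
            t_hours = ((pd.to_datetime(events["timestamp"])
                        - pd.Timestamp(f"{pd.to_datetime(events['timestamp']).dt.year.min()}-01-01"))
                       .dt.total_seconds() / 3600.0).to_numpy()
            vol = stkde_mod.stkde_density(points.x, points.y, t_hours, params)
            vol = stkde_mod.classify_equal_interval(vol)
            stkde_mod.export_voxels(vol, out_dir / "stkde_voxels.csv",
                                    format="xyzv_csv")
            stkde_mod.export_voxels(vol, out_dir / "stkde_voxels.vtk",
                                    format="vtk_structured")
            _register(out_dir / "stkde_voxels.csv")
            _register(out_dir / "stkde_voxels.vtk")
            imax = np.unravel_index(np.argmax(vol.intensity),
                                    vol.intensity.shape)
            manifest["stages"]["stkde"] = {
                "h_s_m": params.h_s, "h_t_h": params.h_t,
                "peak_intensity": float(vol.intensity.max()),
                "peak_voxel": {"x": float(vol.x[imax[0]]),
                               "y": float(vol.y[imax[1]]),
                               "t_hours": float(vol.t[imax[2]])}}
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
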