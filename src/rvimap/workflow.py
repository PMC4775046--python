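"""Reproducible experiment driver.

A single YAML-serialisable :class:`ExperimentConfig` describes a
scenario (2D sheet, idealised cuboid scar, generated synthetic 3D scar,
or marker-CSV-only analysis) plus optional sweep axes (search radius,
electrode pitch, distal APD, coupling interval, scar depth). Each sweep
point writes its marker CSV, RVI map CSV and summary JSON into the
output directory; failures are isolated per sweep point and the run
continues. All randomness flows from one integer seed and every output
embeds the config hash.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell import CellParams, calibrate_gks_for_apd, make_region_params
from .geometry import (EllipsoidScarSpec, ScarGenSpec, TissueModel,
                       build_2d_sheet, build_cuboid_with_scar, generate_scar)
from .io import write_summary_json
from .markers import MarkerMap, extract_markers
from .regions import Region
from .rvi import RVIConfig, compute_rvi, summarise
from .tissue import (ConductivityField, classify_outcome,
                     cuboid_face_protocol, run_monodomain,
                     sheet_point_protocol)

__all__ = ["ExperimentConfig", "run_experiment"]

SCENARIOS = ("sheet2d", "cuboid_scar", "synthetic_scar_3d", "markers_only")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment (plus sweeps)."""

    scenario: str = "sheet2d"
    outdir: str = "rvimap_out"
    seed: int = 0

    # geometry
    sheet_side_cm: float = 2.5
    cuboid_dims_cm: tuple = (2.0, 2.0, 1.0)
    dx_um: float = 200.0
    scar_depth_mm: float = 0.0

    # electrophysiology / protocol
    sigma_S_m: float = 0.1
    ci_ms: float = 300.0
    n_s1: int = 2
    s1_cl_ms: float = 500.0
    distal_apd_ms: Optional[float] = None  # None: default distal g_Ks
    dt_ms: float = 0.1
    t_obs_ms: float = 600.0

    # RVI
    search_radius_mm: float = 2.5
    electrode_pitch_mm: float = 0.0
    rvi_mode: str = "surface"

    # synthetic 3D scar generation
    n_seeds: int = 12
    d_scar_um: float = 5000.0
    d_bz_um: float = 7000.0

    # markers_only input
    markers_csv: Optional[str] = None

    # sweep axes (None = no sweep on that axis)
    sweep_radius_mm: Optional[list] = None
    sweep_pitch_mm: Optional[list] = None
    sweep_distal_apd_ms: Optional[list] = None
    sweep_ci_ms: Optional[list] = None
    sweep_depth_mm: Optional[list] = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("sweep_radius_mm", "sweep_pitch_mm",
                     "sweep_distal_apd_ms", "sweep_ci_ms", "sweep_depth_mm"):
            v = getattr(self, name)
            if v is not None and len(v) == 0:
                raise ValueError(f"{name} must be non-empty when given")
        if self.scenario == "markers_only":
            if not self.markers_csv or not Path(self.markers_csv).exists():
                raise FileNotFoundError(
                    f"markers_csv {self.markers_csv!r} does not exist")

    # ------------------------------------------------------------- io
    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sweep_points(cfg: ExperimentConfig):
    """Cartesian-free sweep: one axis varied at a time (matching the
    one-dimensional parameter sweeps of the study design)."""
    axes = {
        "search_radius_mm": cfg.sweep_radius_mm,
        "electrode_pitch_mm": cfg.sweep_pitch_mm,
        "distal_apd_ms": cfg.sweep_distal_apd_ms,
        "ci_ms": cfg.sweep_ci_ms,
        "scar_depth_mm": cfg.sweep_depth_mm,
    }
    active = {k: v for k, v in axes.items() if v is not None}
    if not active:
        yield {}, "base"
        return
    for name, values in active.items():
        for v in values:
            yield {name: v}, f"{name}={v:g}"


def _simulate_markers(cfg: ExperimentConfig, point: dict):
    """Build the model + protocol for one sweep point, run the solver,
    and return (markers, outcome, model)."""
    p = {**{k: getattr(cfg, k) for k in (
        "search_radius_mm", "electrode_pitch_mm", "distal_apd_ms",
        "ci_ms", "scar_depth_mm")}, **point}

    if cfg.scenario == "sheet2d":
        model = build_2d_sheet(cfg.sheet_side_cm, cfg.dx_um)
        cells = {}
        if p["distal_apd_ms"] is not None:
            gks = calibrate_gks_for_apd(p["distal_apd_ms"],
                                        cl_ms=cfg.s1_cl_ms)
            cells[int(Region.DISTAL)] = CellParams(gks=gks)
        proto = sheet_point_protocol(model, ci_ms=p["ci_ms"], n_s1=cfg.n_s1,
                                     s1_cl_ms=cfg.s1_cl_ms)
        cond = ConductivityField(sigma_S_m=cfg.sigma_S_m)
    else:
        model = build_cuboid_with_scar(
            cfg.cuboid_dims_cm, cfg.dx_um,
            EllipsoidScarSpec(depth_mm=p["scar_depth_mm"]))
        if cfg.scenario == "synthetic_scar_3d":
            blank = model.with_labels(
                np.full(model.n_nodes, int(Region.HEALTHY)))
            model = generate_scar(blank, ScarGenSpec(
                n_seeds=cfg.n_seeds, seed=cfg.seed,
                d_scar_um=cfg.d_scar_um, d_bz_um=cfg.d_bz_um))
        proto = cuboid_face_protocol(ci_ms=p["ci_ms"], n_s1=cfg.n_s1,
                                     s1_cl_ms=cfg.s1_cl_ms)
        cond = ConductivityField(sigma_S_m=cfg.sigma_S_m)
        cells = {}

    res = run_monodomain(model, proto, cond=cond, cells=cells,
                         t_end=proto.t_s2 + cfg.t_obs_ms, dt=cfg.dt_ms)
    outcome = classify_outcome(res)
    return extract_markers(res), outcome, model


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the configured scenario (with sweeps) and write the bundle.

    Returns the summary dict (also written as ``summary.json``); the
    per-point table has columns (point, outcome, rvi_min_ms, pct_below_50,
    n_bins). Failures at individual sweep points are recorded and do not
    abort the run.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    rows = []
    errors = {}
    marker_cache: dict = {}
    for point, tag in _sweep_points(cfg):
        try:
            if cfg.scenario == "markers_only":
                markers = MarkerMap.from_csv(cfg.markers_csv)
                outcome = None
            else:
                # markers depend only on the simulation axes
                sim_key = tuple(sorted(
                    (k, v) for k, v in point.items()
                    if k in ("distal_apd_ms", "ci_ms", "scar_depth_mm")))
                if sim_key not in marker_cache:
                    marker_cache[sim_key] = _simulate_markers(cfg, point)
                markers, outcome, _ = marker_cache[sim_key]

            rcfg = RVIConfig(
                search_radius_mm=point.get("search_radius_mm",
                                           cfg.search_radius_mm),
                electrode_pitch_mm=point.get("electrode_pitch_mm",
                                             cfg.electrode_pitch_mm),
                mode=cfg.rvi_mode)
            rmap = compute_rvi(markers, rcfg)
            rvi_min, pct = summarise(rmap, 50.0)

            safe = tag.replace("=", "_")
            markers.to_csv(outdir / f"markers_{safe}.csv")
            rmap.to_csv(outdir / f"rvi_{safe}.csv")
            rows.append({
                "point": tag,
                "outcome": outcome.outcome.value if outcome else "",
                "rvi_min_ms": rvi_min,
                "pct_below_50": pct,
                "n_bins": rmap.n_bins,
            })
        except Exception as exc:  # isolate sweep-point failures
            errors[tag] = f"{type(exc).__name__}: {exc}"
            traceback.print_exc()

    table = pd.DataFrame(rows)
    table.to_csv(outdir / "sweep_table.csv", index=False)
    summary = {
        "scenario": cfg.scenario,
        "config_hash": cfg.digest(),
        "version": __version__,
        "seed": cfg.seed,
        "n_points": len(rows),
        "errors": errors,
        "table": rows,
    }
    write_summary_json(outdir / "summary.json", summary)
    return summary
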