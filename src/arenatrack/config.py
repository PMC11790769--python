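"""Declarative run configuration (YAML) shared by all CLI subcommands.

The interactive steps of a point-and-click tracking session — picking
calibration points, drawing arenas and ROIs, choosing frames — are recast
here as explicit coordinates in a single YAML file, so every analysis is
scriptable and reproducible.  Every output file embeds the SHA-256 of the
config and the seed used.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .geometry import ArenaLayout, Calibration, calibrate
from .synth import PopulationSpec, SceneSpec, ScriptedPath
from .tracking import DetectionSettings


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    cfg["_dir"] = str(path.parent)  # referenced files resolve relative to the config
    return cfg


def config_hash(cfg: dict) -> str:
    clean = {k: v for k, v in cfg.items() if not k.startswith("_")}
    return hashlib.sha256(json.dumps(clean, sort_keys=True, default=str).encode()).hexdigest()[:16]


def resolve_path(cfg: dict, value: str) -> Path:
    p = Path(value)
    if not p.is_absolute() and "_dir" in cfg:
        p = Path(cfg["_dir"]) / p
    return p


def stamp(cfg: dict, seed: int) -> str:
    return f"# arenatrack config_sha256={config_hash(cfg)} seed={seed}"


def write_csv(df: pd.DataFrame, path: Path, cfg: dict, seed: int) -> None:
    """CSV with a provenance comment line (readable back with comment='#')."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(stamp(cfg, seed) + "\n")
        df.to_csv(fh, index=False)


# ---- section builders ------------------------------------------------------

def build_calibration(cfg: dict) -> Calibration:
    c = cfg["calibration"]
    return calibrate(tuple(c["point_a"]), tuple(c["point_b"]), float(c["real_length_cm"]))


def build_arenas(cfg: dict) -> dict[int, tuple[float, float, float, float]]:
    arenas = {int(k): tuple(map(float, v)) for k, v in cfg["arenas"].items()}
    if not 1 <= len(arenas) <= 4:
        raise ValueError("1..4 arenas required")
    return arenas


def build_layout(cfg: dict) -> ArenaLayout:
    arenas = build_arenas(cfg)
    rois: dict[int, list] = {}
    for arena_id, items in (cfg.get("rois") or {}).items():
        lst = []
        for item in items:
            shape = item.get("rect") or item["polygon"]
            lst.append((item["name"], tuple(map(tuple, shape)) if item.get("polygon") else tuple(shape)))
        rois[int(arena_id)] = lst
    return ArenaLayout(arenas=arenas, rois=rois, complement_roi=cfg.get("complement_roi"))


def build_detection(cfg: dict) -> DetectionSettings:
    d = cfg.get("detection") or {}
    return DetectionSettings(
        threshold=float(d.get("threshold", 50.0)),
        min_blob_area_px=int(d.get("min_blob_area_px", 20)),
        polarity=d.get("polarity", "darker"),
        morphology_radius_px=int(d.get("morphology_radius_px", 0)),
        fps_override=d.get("fps_override"),
    )


def build_scene(cfg: dict, seed: int) -> SceneSpec:
    s = cfg["scene"]
    return SceneSpec(
        frame_size=tuple(s.get("frame_size", (320, 240))),
        background_level=int(s.get("background_level", 230)),
        arenas=tuple(tuple(map(float, a)) for a in s["arenas"]),
        blob=tuple(s.get("blob", (14.0, 8.0, 20))),
        noise_sigma=float(s.get("noise_sigma", 0.0)),
        seed=int(s.get("seed", seed)),
        leader_s=float(s.get("leader_s", 2.0)),
    )


def build_paths(cfg: dict) -> dict[int, ScriptedPath]:
    out = {}
    for arena_id, p in cfg["paths"].items():
        out[int(arena_id)] = ScriptedPath(
            waypoints=tuple(map(tuple, p["waypoints"])),
            duration_s=float(p["duration_s"]),
            fps=float(p["fps"]),
        )
    return out


def build_population(cfg: dict, seed: int) -> PopulationSpec:
    p = cfg["population"]
    return PopulationSpec(
        cluster_archetypes=tuple(p["cluster_archetypes"]),
        n_per_cluster=int(p.get("n_per_cluster", 5)),
        length=int(p.get("length", 60)),
        noise_sigma=float(p.get("noise_sigma", 0.02)),
        seed=int(p.get("seed", seed)),
    )
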