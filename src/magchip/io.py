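"""Configuration loading and artifact serialization.

Config files are YAML with explicit unit suffixes in key names
(``gap_um``, ``field_oe``, ``freq_hz`` ...) to prevent unit drift.
Every run writes a manifest JSON capturing the config hash, the seed and
the produced files, so numeric outputs are regenerable bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import InvalidSpecError
from .field_energy import ExternalField
from .geometry import BendSpec, MagnetPattern, TrackSpec

CONFIG_SCHEMA_VERSION = 1


def load_config(path) -> dict:
    """Load and validate a YAML run config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidSpecError(f"{path}: config must be a mapping")
    return cfg


def _require(section: dict, key: str, where: str):
    if key not in section:
        raise InvalidSpecError(f"missing config key {where}.{key}")
    return section[key]


def track_spec_from_config(cfg: dict) -> TrackSpec:
    tr = _require(cfg, "track", "<root>")
    return TrackSpec(
        drop_length=_require(tr, "drop_length_um", "track"),
        drop_width=_require(tr, "drop_width_um", "track"),
        neck=_require(tr, "neck_um", "track"),
        gap=_require(tr, "gap_um", "track"),
        n_units=int(tr.get("n_units", 5)),
    )


def bend_spec_from_config(cfg: dict) -> BendSpec:
    bd = _require(cfg, "bend", "<root>")
    arm = track_spec_from_config(cfg) if "track" in cfg else TrackSpec()
    return BendSpec(
        style=_require(bd, "style", "bend"),
        turn_angle=float(bd.get("turn_angle_deg", 90.0)),
        arm_spec=arm,
        corner_params=bd.get("corner_params", {}),
    )


def field_from_config(cfg: dict) -> ExternalField:
    fd = cfg.get("field", {})
    return ExternalField(
        h_inplane_oe=float(fd.get("inplane_oe", 70.0)),
        h_vertical_oe=float(fd.get("vertical_oe", 70.0)),
        frequency_hz=float(fd.get("freq_hz", 0.2)),
        phase0=float(fd.get("phase0_rad", 0.0)),
        sense=fd.get("sense", "ccw"),
    )


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, seed, files, command: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "magchip_version": __version__,
        "command": command,
        "config_hash": config_hash(cfg),
        "config": cfg,
        "seed": seed,
        "files": [str(f) for f in files],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# pattern / trajectory export
# ---------------------------------------------------------------------------

def pattern_to_json(pattern: MagnetPattern) -> str:
    return json.dumps({
        "label": pattern.label,
        "thickness_um": pattern.thickness,
        "labels": list(pattern.labels),
        "polygons": [p.tolist() for p in pattern.polygons],
        "metadata": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in pattern.metadata.items()},
    }, indent=2)


def pattern_to_svg(pattern: MagnetPattern, stroke: str = "none",
                   fill: str = "#444") -> str:
    xmin, ymin, xmax, ymax = pattern.bounding_box(pad=5)
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" '
             f'viewBox="{xmin:.2f} {-ymax:.2f} {xmax - xmin:.2f} {ymax - ymin:.2f}">']
    for poly in pattern.polygons:
        pts = " ".join(f"{x:.3f},{-y:.3f}" for x, y in poly)
        parts.append(f'<polygon points="{pts}" fill="{fill}" stroke="{stroke}" />')
    parts.append("</svg>")
    return "\n".join(parts)


def trajectory_to_csv(traj, path):
    import pandas as pd
    df = pd.DataFrame({
        "t_s": traj.times,
        "x_um": traj.positions[:, 0],
        "y_um": traj.positions[:, 1],
        "z_um": traj.positions[:, 2],
        "particle_id": traj.particle.id if traj.particle else 0,
    })
    df.to_csv(path, index=False)
    return path


def landscape_to_csv(landscape, path):
    np.savetxt(path, landscape.grid, delimiter=",")
    meta = {
        "z_um": landscape.z, "t_s": landscape.t,
        "extent_um": list(map(float, landscape.extent)),
        "normalized": landscape.normalized,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path
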