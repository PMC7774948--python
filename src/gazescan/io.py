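"""Session file I/O and configuration.

Sessions are interchanged as plain CSV (one row per 120 Hz sample) plus a
JSON/YAML sidecar with metadata. Columns, exactly:

    t_s, eye_yaw_deg, eye_pitch_deg, eye_valid,
    head_yaw_deg, head_pitch_deg, [head_roll_deg,] head_valid

The sidecar carries participant, condition, group and the trial windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .kinematics import PlanarRect, SceneGeometry
from .traces import EffectorTrace, Session

REQUIRED_COLUMNS = (
    "t_s",
    "eye_yaw_deg",
    "eye_pitch_deg",
    "eye_valid",
    "head_yaw_deg",
    "head_pitch_deg",
    "head_valid",
)


def _sidecar_path(path: Path) -> Path:
    for ext in (".json", ".yaml", ".yml"):
        cand = path.with_suffix(ext)
        if cand.exists():
            return cand
    return path.with_suffix(".json")


def write_session(session: Session, path) -> Path:
    """Write a session as CSV + JSON sidecar; returns the CSV path.

    Floats round-trip exactly through write_session -> read_session.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "t_s": session.eye.t,
        "eye_yaw_deg": session.eye.yaw,
        "eye_pitch_deg": session.eye.pitch,
        "eye_valid": session.eye.valid.astype(int),
        "head_yaw_deg": session.head.yaw,
        "head_pitch_deg": session.head.pitch,
    }
    if session.head.roll is not None:
        data["head_roll_deg"] = session.head.roll
    data["head_valid"] = session.head.valid.astype(int)
    # default float formatting is the shortest exact repr; combined with the
    # round_trip parser in read_session the CSV round-trips bit-exactly
    pd.DataFrame(data).to_csv(path, index=False)
    meta = {
        "participant": session.participant,
        "condition": session.condition,
        "group": session.group,
        "trial_windows": [[float(a), float(b)] for a, b in session.trial_windows],
        "nominal_rate_hz": session.eye.nominal_rate,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_session(path) -> Session:
    """Read a session CSV (+ sidecar) back into a typed Session."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session file {path} is missing required column(s): {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        idx = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"t_s must be strictly increasing; violation at row {idx}")
    for col in df.columns:
        if col.endswith("_deg"):
            vals = df[col].to_numpy(dtype=float)
            valid_col = "eye_valid" if col.startswith("eye") else "head_valid"
            bad = np.flatnonzero(~np.isfinite(vals) & (df[valid_col].to_numpy() != 0))
            if bad.size:
                raise ValueError(
                    f"non-finite {col} at valid row(s) starting at {int(bad[0])}"
                )
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        text = sidecar.read_text()
        meta = yaml.safe_load(text) if sidecar.suffix in (".yaml", ".yml") else json.loads(text)
    rate = float(meta.get("nominal_rate_hz", 120.0))
    eye = EffectorTrace(
        "eye",
        "head_frame",
        t,
        df["eye_yaw_deg"].to_numpy(float),
        df["eye_pitch_deg"].to_numpy(float),
        valid=df["eye_valid"].to_numpy() != 0,
        nominal_rate=rate,
    )
    head = EffectorTrace(
        "head",
        "world_frame",
        t,
        df["head_yaw_deg"].to_numpy(float),
        df["head_pitch_deg"].to_numpy(float),
        roll=df["head_roll_deg"].to_numpy(float) if "head_roll_deg" in df.columns else None,
        valid=df["head_valid"].to_numpy() != 0,
        nominal_rate=rate,
    )
    return Session(
        participant=str(meta.get("participant", path.stem)),
        condition=str(meta.get("condition", "optimal")),
        group=str(meta.get("group", "lower")),
        eye=eye,
        head=head,
        trial_windows=[tuple(w) for w in meta.get("trial_windows", [])],
    )


def load_geometry(path) -> SceneGeometry:
    """SceneGeometry from a JSON/YAML file of plane corner coordinates.

    Expected structure (right-handed world frame, +x right, +y up,
    +z forward, meters)::

        eye_origin: [0, 0, 0]
        central_screen: {corners: [c0, c1, c2]}   # corner + 2 adjacent
        device: {corners: [c0, c1, c2]}
    """
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    def rect(node):
        c0, c1, c2 = node["corners"]
        return PlanarRect.from_corners(c0, c1, c2)

    return SceneGeometry(
        eye_origin=np.asarray(raw.get("eye_origin", [0.0, 0.0, 0.0]), dtype=float),
        central_screen=rect(raw["central_screen"]),
        device=rect(raw["device"]),
    )


@dataclass
class PipelineConfig:
    """End-to-end run configuration; defaults mirror the analysis constants
    (120 ms bins, 1 degree density grid, 20-occurrence threshold)."""

    session_paths: list = field(default_factory=list)
    simulate: Optional[dict] = None  # CohortSpec kwargs; used if no paths
    geometry_path: Optional[str] = None
    reconstruct_mode: str = "compose"
    bin_ms: float = 120.0
    entropy_theta_deg: float = 1.0
    entropy_mode: str = "standard"
    density_bin_deg: float = 1.0
    density_min_count: int = 20
    stats_mode: str = "paper_df"
    out_dir: str = "gazescan_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**known)
        for p in cfg.session_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"session file not found: {p}")
        if cfg.geometry_path and not Path(cfg.geometry_path).exists():
            raise FileNotFoundError(f"geometry file not found: {cfg.geometry_path}")
        return cfg
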