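"""Gaze-in-space reconstruction, ray-plane intersection and AOI labeling.

World frame is right-handed: +x right, +y up, +z forward from the driver.
Yaw is a rotation about the vertical axis (positive = right), applied before
pitch about the rotated horizontal axis (positive = up). Head roll is
ignored. A direction with yaw y and pitch p is the unit vector

    d = (cos p * sin y, sin p, cos p * cos y).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .traces import EffectorTrace

AOI_LABELS = ("central_screen", "device", "other")


# ---------------------------------------------------------------------------
# angle <-> direction conversions

def angles_to_direction(yaw_deg, pitch_deg) -> np.ndarray:
    """Unit direction vector(s) for yaw/pitch in degrees. Shape (..., 3)."""
    y = np.deg2rad(np.asarray(yaw_deg, dtype=float))
    p = np.deg2rad(np.asarray(pitch_deg, dtype=float))
    return np.stack([np.cos(p) * np.sin(y), np.sin(p), np.cos(p) * np.cos(y)], axis=-1)


def direction_to_angles(d) -> tuple:
    """Inverse of :func:`angles_to_direction`; returns (yaw_deg, pitch_deg)."""
    d = np.asarray(d, dtype=float)
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    dn = d / norm
    pitch = np.rad2deg(np.arcsin(np.clip(dn[..., 1], -1.0, 1.0)))
    yaw = np.rad2deg(np.arctan2(dn[..., 0], dn[..., 2]))
    return yaw, pitch


def rotation_matrix(yaw_deg, pitch_deg) -> np.ndarray:
    """World-frame rotation: yaw about +y, then pitch about the rotated x axis.

    Maps the head-frame forward vector (0, 0, 1) to
    ``angles_to_direction(yaw, pitch)``. Shape (..., 3, 3).
    """
    y = np.deg2rad(np.asarray(yaw_deg, dtype=float))
    p = np.deg2rad(np.asarray(pitch_deg, dtype=float))
    y, p = np.broadcast_arrays(y, p)
    cy, sy, cp, sp = np.cos(y), np.sin(y), np.cos(p), np.sin(p)
    one = np.ones_like(cy)
    zero = np.zeros_like(cy)
    # R_y(yaw) @ R_x(-pitch) with R_x(a) the standard rotation about +x
    ry = np.stack(
        [
            np.stack([cy, zero, sy], axis=-1),
            np.stack([zero, one, zero], axis=-1),
            np.stack([-sy, zero, cy], axis=-1),
        ],
        axis=-2,
    )
    rx = np.stack(
        [
            np.stack([one, zero, zero], axis=-1),
            np.stack([zero, cp, sp], axis=-1),
            np.stack([zero, -sp, cp], axis=-1),
        ],
        axis=-2,
    )
    return ry @ rx


# ---------------------------------------------------------------------------
# synchronization

def resample_and_sync(
    eye: EffectorTrace,
    head: EffectorTrace,
    rate: float = 120.0,
    max_gap_s: float = 0.1,
) -> tuple:
    """Resample both traces onto one uniform clock over their overlap.

    Linear interpolation between valid samples; a resampled point whose
    bracketing valid source samples are more than ``max_gap_s`` apart is
    flagged invalid (dropouts must not be papered over by interpolation).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    start = max(eye.t[0], head.t[0])
    end = min(eye.t[-1], head.t[-1])
    if end < start:
        raise ValueError("eye and head traces do not overlap in time")
    n = int(np.floor((end - start) * rate)) + 1
    grid = start + np.arange(n) / rate
    out = []
    for trace in (eye, head):
        tv = trace.t[trace.valid]
        if tv.size < 2:
            raise ValueError(f"{trace.effector} trace has fewer than 2 valid samples")
        yaw = np.interp(grid, tv, trace.yaw[trace.valid])
        pitch = np.interp(grid, tv, trace.pitch[trace.valid])
        roll = (
            np.interp(grid, tv, trace.roll[trace.valid]) if trace.roll is not None else None
        )
        # gap between the valid samples bracketing each grid point
        idx = np.searchsorted(tv, grid, side="right")
        lo = tv[np.clip(idx - 1, 0, tv.size - 1)]
        hi = tv[np.clip(idx, 0, tv.size - 1)]
        gap = np.where((idx > 0) & (idx < tv.size), hi - lo, 0.0)
        valid = gap <= max_gap_s
        out.append(
            replace(
                trace, t=grid, yaw=yaw, pitch=pitch, roll=roll, valid=valid, nominal_rate=rate
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# gaze reconstruction

def reconstruct_gaze(
    eye: EffectorTrace, head: EffectorTrace, mode: str = "compose"
) -> EffectorTrace:
    """Combine eye-in-head and head-in-world rotations into gaze-in-world.

    mode="compose" applies the head rotation matrix to the eye-in-head
    direction vector (exact for large angles); mode="additive" simply adds
    yaw and pitch angles (the small-angle approximation). Both agree when
    either input is at zero, and exactly when pitch is identically zero.
    """
    if eye.frame != "head_frame":
        raise ValueError("eye trace must be in head_frame")
    if head.frame != "world_frame":
        raise ValueError("head trace must be in world_frame")
    if len(eye) != len(head) or not np.allclose(eye.t, head.t):
        raise ValueError("traces must share a common clock; run resample_and_sync first")
    if mode == "additive":
        yaw = eye.yaw + head.yaw
        pitch = eye.pitch + head.pitch
    elif mode == "compose":
        d_eye = angles_to_direction(eye.yaw, eye.pitch)
        r_head = rotation_matrix(head.yaw, head.pitch)
        d_world = np.einsum("...ij,...j->...i", r_head, d_eye)
        yaw, pitch = direction_to_angles(d_world)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'compose' or 'additive'")
    return EffectorTrace(
        effector="gaze",
        frame="world_frame",
        t=eye.t.copy(),
        yaw=yaw,
        pitch=pitch,
        valid=eye.valid & head.valid,
        nominal_rate=eye.nominal_rate,
    )


# ---------------------------------------------------------------------------
# scene geometry

@dataclass
class PlanarRect:
    """Bounded rectangle in 3D: corner ``origin`` plus edge vectors e1, e2."""

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.e1 = np.asarray(self.e1, dtype=float)
        self.e2 = np.asarray(self.e2, dtype=float)
        if np.linalg.norm(np.cross(self.e1, self.e2)) < 1e-12:
            raise ValueError("degenerate rectangle: edge vectors are collinear")

    @classmethod
    def from_corners(cls, c0, c1, c2) -> "PlanarRect":
        """Rectangle from corner c0 and its two adjacent corners c1, c2."""
        c0 = np.asarray(c0, dtype=float)
        return cls(c0, np.asarray(c1, dtype=float) - c0, np.asarray(c2, dtype=float) - c0)

    @classmethod
    def facing(cls, center, distance_axis_yaw_pitch, half_width, half_height) -> "PlanarRect":
        """Rectangle centered along a viewing direction, facing the origin.

        ``distance_axis_yaw_pitch`` = (distance_m, yaw_deg, pitch_deg) of the
        rectangle center as seen from ``center`` (usually the eye origin).
        """
        dist, yaw, pitch = distance_axis_yaw_pitch
        c = np.asarray(center, dtype=float) + dist * angles_to_direction(yaw, pitch)
        normal = angles_to_direction(yaw, pitch)
        up = np.array([0.0, 1.0, 0.0])
        right = np.cross(up, normal)
        right /= np.linalg.norm(right)
        up_in_plane = np.cross(normal, right)
        origin = c - half_width * right - half_height * up_in_plane
        return cls(origin, 2 * half_width * right, 2 * half_height * up_in_plane)

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.e1, self.e2)
        return n / np.linalg.norm(n)

    @property
    def center(self) -> np.ndarray:
        return self.origin + 0.5 * self.e1 + 0.5 * self.e2


def intersect_plane(origin, direction, rect: PlanarRect, eps: float = 1e-12):
    """Forward ray-rectangle intersection point, or None.

    ``direction`` must be a unit vector. Returns None for rays parallel to
    the plane, intersections behind the origin, or hits outside the bounds.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    n = rect.normal
    denom = float(direction @ n)
    if abs(denom) < eps:
        return None
    tau = float((rect.origin - origin) @ n) / denom
    if tau <= eps:
        return None
    hit = origin + tau * direction
    rel = hit - rect.origin
    s = float(rel @ rect.e1) / float(rect.e1 @ rect.e1)
    u = float(rel @ rect.e2) / float(rect.e2 @ rect.e2)
    if -eps <= s <= 1 + eps and -eps <= u <= 1 + eps:
        return hit
    return None


@dataclass
class SceneGeometry:
    """Driving-simulator scene: eye origin, central screen and device planes."""

    eye_origin: np.ndarray
    central_screen: PlanarRect
    device: PlanarRect

    def __post_init__(self) -> None:
        self.eye_origin = np.asarray(self.eye_origin, dtype=float)

    @classmethod
    def default(cls) -> "SceneGeometry":
        """Default cockpit layout.

        Central screen 2.2 m ahead spanning roughly +/-32 deg x +/-20 deg;
        8-inch navigation device on the center console ~0.7 m away,
        down-right of straight ahead (yaw +20 deg, pitch -15 deg).
        """
        screen = PlanarRect.facing(
            (0.0, 0.0, 0.0), (2.2, 0.0, 0.0), half_width=1.4, half_height=0.8
        )
        device = PlanarRect.facing(
            (0.0, 0.0, 0.0), (0.7, 20.0, -15.0), half_width=0.082, half_height=0.062
        )
        return cls(np.zeros(3), screen, device)


def _hit_mask(origin: np.ndarray, dirs: np.ndarray, rect: PlanarRect) -> np.ndarray:
    """Vectorized forward-hit test for many unit rays from one origin."""
    n = rect.normal
    denom = dirs @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = ((rect.origin - origin) @ n) / denom
    ok = (np.abs(denom) > 1e-12) & (tau > 1e-12)
    hit = origin + tau[:, None] * dirs
    rel = hit - rect.origin
    s = rel @ rect.e1 / (rect.e1 @ rect.e1)
    u = rel @ rect.e2 / (rect.e2 @ rect.e2)
    return ok & (s >= 0) & (s <= 1) & (u >= 0) & (u <= 1)


def assign_aoi(gaze: EffectorTrace, geom: SceneGeometry) -> np.ndarray:
    """Per-sample AOI label for a world-frame gaze trace.

    Device is tested before the screen (it is nearer and occludes it along
    shared rays); invalid samples are labeled "other".
    """
    if gaze.frame != "world_frame":
        raise ValueError("gaze trace must be in world_frame")
    dirs = angles_to_direction(gaze.yaw, gaze.pitch)
    labels = np.full(len(gaze), "other", dtype=object)
    on_device = _hit_mask(geom.eye_origin, dirs, geom.device)
    on_screen = _hit_mask(geom.eye_origin, dirs, geom.central_screen)
    labels[on_screen] = "central_screen"
    labels[on_device] = "device"
    labels[~gaze.valid] = "other"
    return labels
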