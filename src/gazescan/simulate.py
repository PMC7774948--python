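"""Synthetic dual-task driving sessions with known generative parameters.

The generator emulates the structure the analysis assumes: a ~6.5 min drive
sampled at 120 Hz, with 7 randomly timed 6 s visual-search trials during
which gaze alternates between the road center and a navigation device
down-right of straight ahead. Between trials gaze stays near the road
center, refixating and occasionally glancing at mirrors at rates scaled by
``state_randomness``.

Gaze shifts are synthesized gaze-first: the gaze-in-world signal makes a
fast first-order approach to the current target, the head makes a slow
first-order approach to ``head_gain`` times its *anchor*, and the
eye-in-head signal is their difference (the vestibulo-ocular reflex keeps
gaze on target while the head moves). The head anchor is the task locus
rather than the instantaneous gaze target: during a visual-search trial
the head orients toward the navigation device and stays there while the
eyes flick between road and device. On top of this the head carries slow
postural sway (an Ornstein-Uhlenbeck process) that the VOR compensates.
Together these reproduce the compensatory regime in which the empirical
head-versus-eye regression slope is negative and grows in magnitude with
head involvement, while preserving the steady-state split of an isolated
shift of amplitude A into head ``head_gain * A`` and eye
``(1 - head_gain) * A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .traces import EffectorTrace, Session

CONDITIONS = ("optimal", "degraded")
GROUPS = ("lower", "higher")

#: mirror glance targets (yaw_deg, pitch_deg): left mirror, rearview, right mirror
_MIRRORS = np.array([[-40.0, -5.0], [10.0, 8.0], [40.0, -8.0]])

#: refixation rate (1/s) at state_randomness = 1
_REFIX_RATE_MAX = 2.2
#: mirror-glance rate (1/s) at state_randomness = 1
_MIRROR_RATE_MAX = 0.25
_MIRROR_DWELL_S = 0.6


@dataclass
class SimulationParams:
    """Generative parameters for one session.

    ``head_gain_yaw``/``head_gain_pitch`` are the fractions of each gaze
    shift carried by the head (per axis). ``state_randomness`` in [0, 1]
    scales the refixation and mirror-glance rates and therefore how
    unpredictable bin-to-bin movement is. Dwell times during trials are
    exponential with the given means, rescaled so the total road+device
    switch rate equals ``switch_rate_in_trial``.
    """

    duration_s: float = 390.0
    sample_rate_hz: float = 120.0
    n_trials: int = 7
    trial_duration_s: float = 6.0
    road_center: tuple = (0.0, 0.0)
    device_center: tuple = (20.0, -15.0)
    fixation_jitter_sd: float = 0.5
    head_gain_yaw: float = 0.15
    head_gain_pitch: float = 0.08
    dwell_mean_road_s: float = 1.0
    dwell_mean_device_s: float = 1.5
    switch_rate_in_trial: float = 0.8
    state_randomness: float = 0.55
    noise_sd_eye: float = 0.15
    noise_sd_head: float = 0.15
    head_sway_sd: float = 2.6
    head_recruit_sd: float = 0.9
    tau_gaze_s: float = 0.05
    tau_head_s: float = 1.5
    tau_sway_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("head_gain_yaw", "head_gain_pitch", "state_randomness"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "duration_s",
            "sample_rate_hz",
            "trial_duration_s",
            "dwell_mean_road_s",
            "dwell_mean_device_s",
            "tau_gaze_s",
            "tau_head_s",
            "tau_sway_s",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        for name in ("fixation_jitter_sd", "noise_sd_eye", "noise_sd_head",
                     "head_sway_sd", "head_recruit_sd", "switch_rate_in_trial"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative and finite, got {v}")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if self.n_trials * self.trial_duration_s > self.duration_s:
            raise ValueError("trials do not fit inside the session duration")


#: per-(condition, group) overrides of the optimal-vision baseline. The
#: degraded condition recruits the head more for horizontal shifts, scans
#: less randomly (more stereotyped), and dwells longer on the device; the
#: higher-degradation group gets the larger offsets. Under optimal vision
#: the two groups are indistinguishable by design.
_CONDITION_OVERRIDES = {
    ("optimal", "lower"): {},
    ("optimal", "higher"): {},
    ("degraded", "lower"): {
        "head_gain_yaw": 0.30,
        "state_randomness": 0.50,
        "dwell_mean_device_s": 2.0,
    },
    ("degraded", "higher"): {
        "head_gain_yaw": 0.38,
        "state_randomness": 0.45,
        "dwell_mean_device_s": 2.2,
    },
}


def default_params(condition: str, group: str) -> SimulationParams:
    """Scenario-shell defaults (390 s, 120 Hz, 7 trials of 6 s) for a cell."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; valid: {CONDITIONS}")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; valid: {GROUPS}")
    return SimulationParams(**_CONDITION_OVERRIDES[(condition, group)])


def _draw_trial_windows(params: SimulationParams, rng: np.random.Generator) -> list:
    """Randomly timed, non-overlapping trial windows with a margin and gap."""
    k = params.n_trials
    if k == 0:
        return []
    margin = min(5.0, 0.01 * params.duration_s)
    gap = min(2.0, 0.1 * params.trial_duration_s)
    slot = params.trial_duration_s + gap
    free = params.duration_s - 2 * margin - k * slot
    if free < 0:
        raise ValueError("trials (plus margins) do not fit inside the session")
    offsets = np.sort(rng.uniform(0.0, free, size=k))
    starts = margin + offsets + np.arange(k) * slot
    return [(float(s), float(s + params.trial_duration_s)) for s in starts]


def _road_segment(t0, t1, params, rng, events):
    """Road fixation with Poisson refixations and occasional mirror glances."""
    refix_rate = _REFIX_RATE_MAX * params.state_randomness
    mirror_rate = _MIRROR_RATE_MAX * params.state_randomness
    jit = params.fixation_jitter_sd
    center = np.asarray(params.road_center)

    gains = np.array([params.head_gain_yaw, params.head_gain_pitch])

    def road_point():
        return center + np.clip(rng.normal(0.0, jit, size=2), -2.0, 2.0)

    # outside trials the head simply carries its share of the gaze target
    p = road_point()
    events.append((t0, "road", p, gains * p))
    t = t0
    while True:
        dt_refix = rng.exponential(1.0 / refix_rate) if refix_rate > 0 else np.inf
        dt_mirror = rng.exponential(1.0 / mirror_rate) if mirror_rate > 0 else np.inf
        dt = min(dt_refix, dt_mirror)
        if not np.isfinite(dt) or t + dt >= t1:
            return
        t += dt
        if dt_mirror < dt_refix:
            target = _MIRRORS[rng.integers(len(_MIRRORS))] + np.clip(
                rng.normal(0, jit, 2), -2, 2
            )
            events.append((t, "mirror", target, gains * target))
            t += _MIRROR_DWELL_S
            if t >= t1:
                return
            p = road_point()
            events.append((t, "road", p, gains * p))
        else:
            p = road_point()
            events.append((t, "road", p, gains * p))


def _trial_segment(t0, t1, params, rng, events):
    """Device turns on: semi-Markov alternation between device and road."""
    dr, dd = params.dwell_mean_road_s, params.dwell_mean_device_s
    if params.switch_rate_in_trial > 0:
        scale = 2.0 / (params.switch_rate_in_trial * (dr + dd))
    else:
        scale = 1.0
    means = {"road": scale * dr, "device": scale * dd}
    centers = {
        "road": np.asarray(params.road_center),
        "device": np.asarray(params.device_center),
    }
    jit = params.fixation_jitter_sd
    gains = np.array([params.head_gain_yaw, params.head_gain_pitch])
    t, aoi = t0, "device"
    head_target = np.zeros(2)
    while t < t1:
        target = centers[aoi] + np.clip(rng.normal(0.0, jit, size=2), -2.0, 2.0)
        if aoi == "device":
            # variable head recruitment: each device glance carries a
            # different head share (sometimes eye-only, sometimes a full
            # head turn), with mean share head_gain; the head then stays
            # oriented toward the task locus through road check-backs
            share = np.clip(gains * (1.0 + rng.normal(0.0, params.head_recruit_sd)), 0, 1)
            head_target = share * target
        events.append((t, aoi, target, head_target))
        t += rng.exponential(means[aoi])
        aoi = "road" if aoi == "device" else "device"


def _first_order(target: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Exponential approach y[n] = a y[n-1] + (1-a) x[n], started at x[0]."""
    a = float(np.exp(-dt / tau))
    y = lfilter([1.0 - a], [1.0, -a], target)
    # remove the zero-initial-condition transient: start on target
    y += target[0] * a ** np.arange(1, target.size + 1)
    return y


def simulate_session(
    params: SimulationParams,
    participant: str = "P01",
    condition: str = "optimal",
    group: str = "lower",
) -> Session:
    """Generate one session from the given parameters.

    The returned Session holds the eye trace in the head frame and the head
    trace in the world frame, plus a ``ground_truth`` dict with the latent
    AOI sequence, the noise-free target/gaze/head signals and the params.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    windows = _draw_trial_windows(params, rng)

    events: list = []
    cursor = 0.0
    for (ws, we) in windows:
        if ws > cursor:
            _road_segment(cursor, ws, params, rng, events)
        _trial_segment(ws, we, params, rng, events)
        cursor = we
    if cursor < params.duration_s:
        _road_segment(cursor, params.duration_s, params, rng, events)

    ev_t = np.array([e[0] for e in events])
    ev_aoi = np.array([e[1] for e in events], dtype=object)
    ev_target = np.array([e[2] for e in events])
    ev_head_target = np.array([e[3] for e in events])

    dt = 1.0 / params.sample_rate_hz
    n = int(round(params.duration_s * params.sample_rate_hz))
    t = np.arange(n) * dt
    idx = np.clip(np.searchsorted(ev_t, t, side="right") - 1, 0, len(events) - 1)
    target_yaw, target_pitch = ev_target[idx, 0], ev_target[idx, 1]
    latent_aoi = ev_aoi[idx]

    gaze_yaw = _first_order(target_yaw, params.tau_gaze_s, dt)
    gaze_pitch = _first_order(target_pitch, params.tau_gaze_s, dt)
    head_yaw = _first_order(ev_head_target[idx, 0], params.tau_head_s, dt)
    head_pitch = _first_order(ev_head_target[idx, 1], params.tau_head_s, dt)

    # postural head sway, VOR-compensated: it moves the head, not the gaze
    def sway(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(n)
        a = float(np.exp(-dt / params.tau_sway_s))
        innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), n)
        return lfilter([1.0], [1.0, -a], innov)

    # postural steadiness co-varies with scan randomness: stereotyped
    # scanning comes with a steadier head
    sway_sd = params.head_sway_sd * params.state_randomness
    sway_yaw = sway(sway_sd)
    sway_pitch = sway(0.5 * sway_sd)
    head_yaw = head_yaw + sway_yaw
    head_pitch = head_pitch + sway_pitch
    eye_yaw = gaze_yaw - head_yaw
    eye_pitch = gaze_pitch - head_pitch

    eye = EffectorTrace(
        "eye",
        "head_frame",
        t,
        eye_yaw + rng.normal(0.0, params.noise_sd_eye, n),
        eye_pitch + rng.normal(0.0, params.noise_sd_eye, n),
        nominal_rate=params.sample_rate_hz,
    )
    head = EffectorTrace(
        "head",
        "world_frame",
        t,
        head_yaw + rng.normal(0.0, params.noise_sd_head, n),
        head_pitch + rng.normal(0.0, params.noise_sd_head, n),
        nominal_rate=params.sample_rate_hz,
    )
    truth = {
        "params": params,
        "latent_aoi": latent_aoi,
        "target_yaw": target_yaw,
        "target_pitch": target_pitch,
        "gaze_yaw": gaze_yaw,
        "gaze_pitch": gaze_pitch,
        "head_yaw": head_yaw,
        "head_pitch": head_pitch,
    }
    return Session(
        participant=participant,
        condition=condition,
        group=group,
        eye=eye,
        head=head,
        trial_windows=windows,
        ground_truth=truth,
    )


def simulate_regression_pairs(
    slope: float, n: int = 5000, noise_sd: float = 1.0, seed: int = 0
) -> tuple:
    """(eye, head) angle pairs with a known generative regression slope.

    Eye angles follow a two-component mixture (a dense cluster at the road
    center plus a sparser cluster at device eccentricity, so a density
    filter has structure to act on); head = slope * eye + Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    on_road = rng.random(n) < 0.8
    eye = np.where(on_road, rng.normal(0.0, 3.0, n), rng.normal(15.0, 4.0, n))
    head = slope * eye + rng.normal(0.0, noise_sd, n)
    return eye, head


@dataclass
class CohortSpec:
    """A within-subject cohort: every participant does both conditions.

    ``n_per_group`` maps degradation group to participant count (the study
    shell is 11 lower + 10 higher). ``param_offsets`` maps
    (condition, group) to additive overrides applied on top of the
    defaults. ``participant_sd`` gives between-participant trait SDs,
    applied identically in both of a participant's sessions (this is what
    makes a within-subject analysis meaningful).
    """

    n_per_group: dict = field(default_factory=lambda: {"lower": 11, "higher": 10})
    conditions: tuple = CONDITIONS
    param_offsets: dict = field(default_factory=dict)
    participant_sd: dict = field(
        default_factory=lambda: {"state_randomness": 0.05, "head_gain_yaw": 0.05}
    )
    duration_s: Optional[float] = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; valid: {GROUPS}")
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1, got {n}")


def simulate_cohort(spec: CohortSpec) -> tuple:
    """Generate all sessions of a cohort plus the ground-truth table.

    Returns (sessions, truth_rows) where truth_rows is a list of dicts, one
    per session, recording the realized generative parameters. Deterministic
    given ``spec.master_seed``; per-session seeds are derived from
    (master_seed, participant index, condition index) so realizations are
    independent across cells.
    """
    import pandas as pd

    sessions, rows = [], []
    pid = 0
    for group in GROUPS:
        if group not in spec.n_per_group:
            continue
        for _ in range(spec.n_per_group[group]):
            pid += 1
            participant = f"P{pid:02d}"
            trait_rng = np.random.default_rng(
                np.random.SeedSequence([spec.master_seed, pid, 10_000])
            )
            traits = {
                k: float(trait_rng.normal(0.0, sd)) for k, sd in spec.participant_sd.items()
            }
            for ci, condition in enumerate(spec.conditions):
                params = default_params(condition, group)
                overrides = dict(spec.param_offsets.get((condition, group), {}))
                updates = {}
                for k, dv in overrides.items():
                    updates[k] = getattr(params, k) + dv
                for k, dv in traits.items():
                    updates[k] = np.clip(
                        updates.get(k, getattr(params, k)) + dv, 0.0, 1.0
                    )
                if spec.duration_s is not None:
                    updates["duration_s"] = spec.duration_s
                seed_seq = np.random.SeedSequence([spec.master_seed, pid, ci])
                updates["seed"] = int(seed_seq.generate_state(1)[0] % (2**31))
                params = replace(params, **updates)
                sessions.append(
                    simulate_session(params, participant, condition, group)
                )
                row = {"participant": participant, "condition": condition, "group": group}
                for f in fields(SimulationParams):
                    v = getattr(params, f.name)
                    row[f.name] = v if np.isscalar(v) else str(v)
                rows.append(row)
    return sessions, pd.DataFrame(rows)
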