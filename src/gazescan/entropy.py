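"""Time-based transition entropy of eye, head and gaze signals.

The signal is cut into fixed 120 ms bins (about the minimum fixation
duration), each bin is reduced to a net displacement — the Euclidean
distance sqrt(dyaw^2 + dpitch^2) between its first and last valid sample —
and the bin sequence is discretized into states. A first-order Markov
transition model over consecutive bins then yields the conditional entropy

    H = - sum_i p_i sum_j p(j|i) log2 p(j|i)          (mode="standard")

normalized by log2(n_states) to [0, 1]. Low values mean stereotyped,
predictable scanning; high values mean complex, explorative scanning.

An alternative mode="literal" evaluates - sum_i p_i sum_j p(i,j) log2 p(i,j)
with the *joint* probability inside the logarithm, kept for comparison with
formulations that print the equation that way; it is not the Shannon
conditional entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .traces import EffectorTrace, Session

#: sentinel state for bins excluded from the transition model
INVALID_STATE = -1


@dataclass
class BinSeries:
    """Fixed-width time bins of a trace: start times, net displacements."""

    bin_ms: float
    t_start: np.ndarray
    displacement: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return self.t_start.size


@dataclass
class TransitionModel:
    """Empirical first-order transition model over bin states.

    ``states`` are the realized state ids (sorted); ``counts[i, j]`` counts
    consecutive valid-bin pairs going from states[i] to states[j].
    ``p_joint`` is counts normalized by the total pair count, ``p_i`` its
    row marginal and ``p_cond`` the row-normalized conditional matrix.
    """

    states: np.ndarray
    counts: np.ndarray
    p_joint: np.ndarray
    p_i: np.ndarray
    p_cond: np.ndarray
    n_pairs: int

    @property
    def n_states(self) -> int:
        return self.states.size


@dataclass
class EntropyResult:
    """Raw (bits) and normalized [0, 1] transition entropy for one signal."""

    effector: str
    raw_bits: float
    normalized: float
    n_states: int
    n_bins: int
    policy: str
    mode: str


# ---------------------------------------------------------------------------
# binning

def bin_series(trace: EffectorTrace, bin_ms: float = 120.0) -> BinSeries:
    """Cut a uniform-clock trace into half-open 120 ms bins.

    Net displacement per bin is the Euclidean (yaw, pitch) distance between
    the first and last *valid* sample in the bin (a single displacement, not
    an arc length). The trailing partial bin is discarded; bins with more
    than 50% invalid samples are flagged invalid.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if len(trace) == 0:
        return BinSeries(bin_ms, np.empty(0), np.empty(0), np.empty(0, dtype=bool))
    bin_s = bin_ms / 1000.0
    rel = trace.t - trace.t[0]
    total = rel[-1] + 1.0 / trace.nominal_rate  # span covered by the samples
    n_bins = int(np.floor(total / bin_s + 1e-9))
    idx = np.floor(rel / bin_s + 1e-9).astype(int)
    keep = idx < n_bins
    idx = idx[keep]

    yaw, pitch, valid = trace.yaw[keep], trace.pitch[keep], trace.valid[keep]
    counts = np.bincount(idx, minlength=n_bins)
    valid_counts = np.bincount(idx, weights=valid.astype(float), minlength=n_bins)
    # idx is non-decreasing, so the valid samples of each bin are contiguous
    disp = np.zeros(n_bins)
    v = np.flatnonzero(valid)
    if v.size:
        bv = idx[v]
        uniq, first_pos = np.unique(bv, return_index=True)
        last_pos = np.searchsorted(bv, uniq, side="right") - 1
        fi, li = v[first_pos], v[last_pos]
        disp[uniq] = np.hypot(yaw[li] - yaw[fi], pitch[li] - pitch[fi])
    bin_valid = (counts > 0) & (valid_counts > 0.5 * counts)
    t_start = trace.t[0] + np.arange(n_bins) * bin_s
    return BinSeries(bin_ms, t_start, disp, bin_valid)


# ---------------------------------------------------------------------------
# state policies

@dataclass
class DisplacementThreshold:
    """Two states: "shift" if net displacement > theta degrees, else "stay"."""

    theta: float = 1.0

    def describe(self) -> str:
        return f"displacement_threshold(theta={self.theta}deg)"

    def __call__(self, bins: BinSeries, aoi: Optional[np.ndarray] = None) -> np.ndarray:
        states = (bins.displacement > self.theta).astype(int)
        states[~bins.valid] = INVALID_STATE
        return states


@dataclass
class DisplacementQuantiles:
    """k states by empirical quantile edges of valid-bin displacements.

    Values equal to an edge are assigned to the lower state.
    """

    k: int = 2

    def describe(self) -> str:
        return f"displacement_quantiles(k={self.k})"

    def __call__(self, bins: BinSeries, aoi: Optional[np.ndarray] = None) -> np.ndarray:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        d = bins.displacement[bins.valid]
        if d.size == 0:
            return np.full(len(bins), INVALID_STATE)
        edges = np.quantile(d, np.arange(1, self.k) / self.k)
        states = np.searchsorted(edges, bins.displacement, side="left").astype(int)
        states[~bins.valid] = INVALID_STATE
        return states


@dataclass
class AoiLabels:
    """Per-bin majority AOI label (gaze signals only).

    Requires a per-sample AOI sequence aligned with the binned trace; the
    bin state is the modal label among its valid samples.
    """

    labels: tuple = ("central_screen", "device", "other")

    def describe(self) -> str:
        return "aoi_labels"

    def __call__(self, bins: BinSeries, aoi: Optional[np.ndarray] = None) -> np.ndarray:
        if aoi is None:
            raise ValueError(
                "aoi_labels policy requires a per-sample AOI sequence "
                "(only available for gaze traces)"
            )
        raise NotImplementedError  # bound via assign_states, which slices samples


StatePolicy = Union[DisplacementThreshold, DisplacementQuantiles, AoiLabels]


def assign_states(
    bins: BinSeries,
    policy: StatePolicy,
    trace: Optional[EffectorTrace] = None,
    aoi: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Discretize a BinSeries into integer states (INVALID_STATE = excluded).

    For the AOI policy, ``trace`` (the binned trace) and ``aoi`` (per-sample
    labels from :func:`gazescan.kinematics.assign_aoi`) must be supplied.
    """
    if isinstance(policy, AoiLabels):
        if aoi is None or trace is None:
            raise ValueError(
                "aoi_labels policy requires the source trace and its per-sample "
                "AOI labels; it applies to gaze traces only"
            )
        bin_s = bins.bin_ms / 1000.0
        rel = trace.t - trace.t[0]
        idx = np.floor(rel / bin_s + 1e-9).astype(int)
        code = {lab: i for i, lab in enumerate(policy.labels)}
        codes = np.array([code[l] for l in aoi])
        states = np.full(len(bins), INVALID_STATE)
        # samples of each bin are contiguous (timestamps sorted)
        starts = np.searchsorted(idx, np.arange(len(bins)))
        ends = np.searchsorted(idx, np.arange(1, len(bins) + 1))
        for b in range(len(bins)):
            if not bins.valid[b]:
                continue
            sl = slice(starts[b], ends[b])
            sel = trace.valid[sl]
            if not np.any(sel):
                continue
            states[b] = int(np.bincount(codes[sl][sel]).argmax())
        return states
    return policy(bins)


# ---------------------------------------------------------------------------
# transition model and entropy

def transition_model(states: Sequence[int]) -> TransitionModel:
    """Empirical transition model over consecutive valid-bin pairs.

    Pairs spanning an invalid (sentinel) bin are dropped, so dropouts do not
    fabricate transitions. p_i is defined as the row marginal of the joint,
    which makes the model internally consistent by construction.
    """
    states = np.asarray(states, dtype=int)
    a, b = states[:-1], states[1:]
    ok = (a != INVALID_STATE) & (b != INVALID_STATE)
    a, b = a[ok], b[ok]
    if a.size < 1:
        raise ValueError("need at least 2 valid consecutive bins to build a model")
    realized = np.unique(np.concatenate([a, b]))
    remap = np.searchsorted(realized, np.stack([a, b]))
    n = realized.size
    counts = np.zeros((n, n), dtype=int)
    np.add.at(counts, (remap[0], remap[1]), 1)
    p_joint = counts / counts.sum()
    p_i = p_joint.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = np.where(p_i[:, None] > 0, p_joint / p_i[:, None], 0.0)
    return TransitionModel(realized, counts, p_joint, p_i, p_cond, int(counts.sum()))


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def conditional_entropy(
    model: TransitionModel, mode: str = "standard", effector: str = "", n_bins: int = 0,
    policy: str = "",
) -> EntropyResult:
    """Transition entropy of a first-order chain, in bits and normalized.

    mode="standard": H = -sum_i p_i sum_j p(j|i) log2 p(j|i), the Shannon
    conditional entropy H(next | current). mode="literal": the joint
    probability replaces the conditional inside the log. Normalization
    divides by log2 of the realized state count (0 by convention for a
    single-state chain).
    """
    if mode == "standard":
        raw = float(-np.sum(model.p_i * np.sum(_xlogx(model.p_cond), axis=1)))
    elif mode == "literal":
        raw = float(-np.sum(model.p_i * np.sum(_xlogx(model.p_joint), axis=1)))
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'standard' or 'literal'")
    raw = max(raw, 0.0)
    n = model.n_states
    normalized = raw / np.log2(n) if n > 1 else 0.0
    return EntropyResult(effector, raw, normalized, n, n_bins, policy, mode)


def session_entropy(
    session: Session,
    effector: str,
    policy: Optional[StatePolicy] = None,
    mode: str = "standard",
    bin_ms: float = 120.0,
    reconstruct_mode: str = "compose",
    geometry=None,
) -> EntropyResult:
    """Full-session transition entropy for one effector.

    Composition bin_series -> assign_states -> transition_model ->
    conditional_entropy over the whole scenario (not only the trial
    windows). For effector="gaze" the gaze trace is reconstructed from eye
    and head if the session does not carry one.
    """
    from .kinematics import assign_aoi, reconstruct_gaze

    if policy is None:
        policy = DisplacementThreshold(1.0)
    if effector == "eye":
        trace = session.eye
    elif effector == "head":
        trace = session.head
    elif effector == "gaze":
        trace = session.gaze or reconstruct_gaze(session.eye, session.head, reconstruct_mode)
    else:
        raise ValueError(f"unknown effector {effector!r}")
    bins = bin_series(trace, bin_ms)
    if isinstance(policy, AoiLabels):
        if effector != "gaze":
            raise ValueError("aoi_labels policy applies to gaze traces only")
        if geometry is None:
            from .kinematics import SceneGeometry

            geometry = SceneGeometry.default()
        aoi = assign_aoi(trace, geometry)
        states = assign_states(bins, policy, trace=trace, aoi=aoi)
    else:
        states = assign_states(bins, policy)
    model = transition_model(states)
    return conditional_entropy(
        model, mode=mode, effector=effector, n_bins=len(bins), policy=policy.describe()
    )
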