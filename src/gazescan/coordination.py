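"""Eye-head coordination: density-filtered head-vs-eye regression slopes.

Within the visual-search trial windows, simultaneous (eye, head) angle
pairs are collected per axis, pairs falling in sparsely occupied 1x1 degree
bins (fewer than 20 occurrences) are discarded as artefacts, and the
ordinary least-squares slope of head angle on eye angle is fitted. A slope
of 0 means the eyes move without the head; larger magnitudes mean more head
involvement in gaze shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .traces import EffectorTrace, Session


@dataclass
class DensityGrid:
    """Occupancy counts of (eye, head) pairs on a square angular grid.

    Bins are half-open [k*bin_deg, (k+1)*bin_deg) per axis, anchored at 0.
    """

    bin_deg: float
    origins: np.ndarray  # (m, 2) lower corners of occupied bins
    counts: np.ndarray  # (m,) occurrence counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class RegressionResult:
    axis: str
    slope: float
    intercept: float
    n_retained: int
    n_total: int
    participant: str = ""
    condition: str = ""
    group: str = ""


def restrict_to_trials(trace: EffectorTrace, windows: Sequence) -> EffectorTrace:
    """Samples with t inside any half-open [start, end) window, concatenated."""
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ValueError("windows must be sorted and non-overlapping")
    if not windows:
        return trace.take(np.zeros(0, dtype=int))
    mask = np.zeros(len(trace), dtype=bool)
    for start, end in windows:
        mask |= (trace.t >= start) & (trace.t < end)
    return trace.take(np.flatnonzero(mask))


def density_filter(
    pairs: np.ndarray, bin_deg: float = 1.0, min_count: int = 20
) -> tuple:
    """Drop pairs lying in grid bins occupied fewer than ``min_count`` times.

    Returns (mask of retained pairs, DensityGrid). The grid is anchored at
    0 degrees so binning does not depend on the data range.
    """
    if bin_deg <= 0:
        raise ValueError("bin_deg must be positive")
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        return np.zeros(0, dtype=bool), DensityGrid(
            bin_deg, np.empty((0, 2)), np.empty(0, dtype=int)
        )
    cells = np.floor(pairs / bin_deg).astype(np.int64)
    uniq, inverse, counts = np.unique(
        cells, axis=0, return_inverse=True, return_counts=True
    )
    mask = counts[inverse] >= min_count
    grid = DensityGrid(bin_deg, uniq * bin_deg, counts)
    return mask, grid


def fit_eye_head_slope(
    eye_deg: np.ndarray,
    head_deg: np.ndarray,
    axis: str,
    n_total: Optional[int] = None,
    participant: str = "",
    condition: str = "",
    group: str = "",
) -> RegressionResult:
    """OLS of head angle (response) on eye angle (predictor)."""
    eye_deg = np.asarray(eye_deg, dtype=float)
    head_deg = np.asarray(head_deg, dtype=float)
    if eye_deg.size < 2 or np.unique(eye_deg).size < 2:
        raise ValueError(
            f"degenerate eye angles (need >= 2 distinct values) for "
            f"participant={participant!r} condition={condition!r} axis={axis}"
        )
    fit = sps.linregress(eye_deg, head_deg)
    return RegressionResult(
        axis=axis,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_retained=int(eye_deg.size),
        n_total=int(n_total if n_total is not None else eye_deg.size),
        participant=participant,
        condition=condition,
        group=group,
    )


def session_slopes(
    session: Session,
    bin_deg: float = 1.0,
    min_count: int = 20,
    axes: Sequence[str] = ("yaw", "pitch"),
) -> list:
    """Trial-restricted, density-filtered slopes for one session, per axis.

    The filter is applied per participant x condition (this session's own
    pairs), not on data pooled across participants.
    """
    eye = restrict_to_trials(session.eye, session.trial_windows)
    head = restrict_to_trials(session.head, session.trial_windows)
    ok = eye.valid & head.valid
    results = []
    for axis in axes:
        pairs = np.column_stack(
            [getattr(eye, axis)[ok], getattr(head, axis)[ok]]
        )
        mask, _ = density_filter(pairs, bin_deg=bin_deg, min_count=min_count)
        kept = pairs[mask]
        results.append(
            fit_eye_head_slope(
                kept[:, 0],
                kept[:, 1],
                axis,
                n_total=pairs.shape[0],
                participant=session.participant,
                condition=session.condition,
                group=session.group,
            )
        )
    return results


def group_average_slopes(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Mean +/- SD of slopes per condition x group x axis.

    Cells with a single result get NaN SD (flagged via n); empty cells are
    simply absent from the table rather than reported as zero.
    """
    rows = [
        {
            "axis": r.axis,
            "condition": r.condition,
            "group": r.group,
            "slope": r.slope,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["axis", "condition", "group"])["slope"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out
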