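"""Curve-comparison statistics: density difference and dynamic time warping.

Two ways to score how far a sample's abundance curve sits from a control's:

* density difference — one minus the overlap of the two normalized curves,
  ``1 - sum_bins min(x_bin, y_bin)``.  Bounded in [0, 1], 0 when the
  curves coincide, 1 when they share no mass.
* DTW — the minimal cumulative |x_i - y_j| cost over all monotone warping
  paths between the two sequences, endpoints anchored.  Unlike the density
  difference it credits shape similarity under intensity shifts, which is
  what makes it sensitive to a dose-induced spectral displacement.

The two-color variant runs the same dynamic program over paired curves,
with the local cost the Euclidean norm of the difference between the
2-component abundance points (an L1 alternative is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .curves import AbundanceCurve, CurveConfigError, EmptyCurveError, PairedCurve, align


@dataclass
class DistanceValue:
    metric: str  # "density_diff" | "dtw1" | "dtw2"
    channels: str  # "R", "G", "B" or "RvG", "GvB", "RvB"
    value: float
    sample_id: str = ""
    control_id: str = ""


def density_difference(x: AbundanceCurve, y: AbundanceCurve) -> DistanceValue:
    """1 - sum of bin-wise minima of two normalized curves, in [0, 1]."""
    if x.channel != y.channel:
        raise CurveConfigError(f"channel mismatch: {x.channel} vs {y.channel}")
    _, fx, fy = align(x, y)
    value = 1.0 - float(np.minimum(fx, fy).sum())
    # guard against round-off leaking outside the defined range; identical
    # curves must score exactly 0 even though fractions sum to 1 only to eps
    if value < 1e-12:
        value = 0.0
    value = min(value, 1.0)
    return DistanceValue(
        metric="density_diff",
        channels=x.channel,
        value=value,
        sample_id=x.source_id,
        control_id=y.source_id,
    )


@njit(cache=True)
def _dtw_accumulate(cost: np.ndarray) -> float:
    """Anchored DTW over a precomputed local-cost matrix.

    D[i, j] = cost[i, j] + min(D[i-1, j], D[i-1, j-1], D[i, j-1]) with
    D[0, 0] = cost[0, 0]; returns D[-1, -1].  Rolling single-row buffer.
    """
    n, m = cost.shape
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = cost[0, 0]
    for j in range(1, m):
        prev[j] = prev[j - 1] + cost[0, j]
    for i in range(1, n):
        cur[0] = prev[0] + cost[i, 0]
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = cost[i, j] + best
        prev, cur = cur, prev
    return prev[m - 1]


def dtw_distance(
    x: np.ndarray | AbundanceCurve,
    y: np.ndarray | AbundanceCurve,
    normalize: str = "none",
) -> DistanceValue:
    """Minimal cumulative |x_i - y_j| over monotone warping paths.

    Accepts raw sequences or abundance curves (curves are aligned on their
    union support first).  ``normalize="path_length"`` divides by n + m - 1,
    the length of the longest admissible path; the default reports the raw
    alignment distance.
    """
    channels, sample_id, control_id = "", "", ""
    if isinstance(x, AbundanceCurve) and isinstance(y, AbundanceCurve):
        if x.channel != y.channel:
            raise CurveConfigError(f"channel mismatch: {x.channel} vs {y.channel}")
        channels, sample_id, control_id = x.channel, x.source_id, y.source_id
        _, xv, yv = align(x, y)
    else:
        xv = np.asarray(x, dtype=np.float64).ravel()
        yv = np.asarray(y, dtype=np.float64).ravel()
    if len(xv) == 0 or len(yv) == 0:
        raise EmptyCurveError("DTW requires non-empty sequences")
    cost = np.abs(xv[:, None] - yv[None, :])
    value = float(_dtw_accumulate(cost))
    if normalize == "path_length":
        value /= len(xv) + len(yv) - 1
    elif normalize != "none":
        raise ValueError("normalize must be 'none' or 'path_length'")
    return DistanceValue(
        metric="dtw1",
        channels=channels,
        value=value,
        sample_id=sample_id,
        control_id=control_id,
    )


def dtw_two_color(
    x: PairedCurve,
    y: PairedCurve,
    normalize: str = "none",
    local_cost: str = "euclidean",
) -> DistanceValue:
    """DTW between paired curves; local cost is the norm of the 2-vector gap."""
    if x.channels != y.channels:
        raise CurveConfigError(f"channel-pair mismatch: {x.channels} vs {y.channels}")
    if x.threshold_used != y.threshold_used:
        raise CurveConfigError("paired curves built under different thresholds")
    support = np.union1d(x.support, y.support)
    xv = np.zeros((len(support), 2))
    yv = np.zeros((len(support), 2))
    xv[np.searchsorted(support, x.support)] = x.vectors
    yv[np.searchsorted(support, y.support)] = y.vectors
    diff = xv[:, None, :] - yv[None, :, :]
    if local_cost == "euclidean":
        cost = np.sqrt((diff**2).sum(axis=2))
    elif local_cost == "l1":
        cost = np.abs(diff).sum(axis=2)
    else:
        raise ValueError("local_cost must be 'euclidean' or 'l1'")
    value = float(_dtw_accumulate(cost))
    if normalize == "path_length":
        value /= cost.shape[0] + cost.shape[1] - 1
    elif normalize != "none":
        raise ValueError("normalize must be 'none' or 'path_length'")
    return DistanceValue(
        metric="dtw2",
        channels=x.channels,
        value=value,
        sample_id=x.source_id,
        control_id=y.source_id,
    )
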