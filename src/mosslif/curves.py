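"""Density histograms and percent-abundance curves.

After thresholding, each channel's retained pixels are binned by DCV and
normalized by the retained pixel count, giving a "percent abundance" curve
— the fraction of frond pixels at each intensity code.  These curves are
what every distance in the pipeline compares.  Curves are stored on the
fraction scale (summing to 1); multiplying by 100 for display is a
presentation choice, exposed via ``scale`` in serialization only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import ChannelPixels
from .preprocess import dcv_histogram


class EmptyCurveError(ValueError):
    """No retained pixels: no curve can be formed."""


class CurveConfigError(ValueError):
    """Curves built under different threshold specs cannot be combined."""


@dataclass
class ChannelHistogram:
    channel: str
    counts: np.ndarray
    source_id: str = ""

    @property
    def n_retained(self) -> int:
        return int(self.counts.sum())


@dataclass
class AbundanceCurve:
    """Normalized per-DCV fraction curve for one channel.

    ``support`` lists the DCV bins kept after thresholding (strictly
    increasing); ``fractions`` are the corresponding pixel fractions and
    sum to 1.  Bins removed by the threshold are dropped from the support
    entirely rather than kept as structural zeros, so the empty background
    region cannot dominate curve alignment.
    """

    channel: str
    support: np.ndarray
    fractions: np.ndarray
    threshold_used: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if len(self.support) != len(self.fractions):
            raise ValueError("support/fractions length mismatch")
        if len(self.support) == 0:
            raise EmptyCurveError("empty abundance curve")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class PairedCurve:
    """Two channel curves from one image, aligned on a shared support."""

    channels: str  # "RvG", "GvB" or "RvB"
    support: np.ndarray
    vectors: np.ndarray  # shape (len(support), 2)
    threshold_used: int
    source_id: str = ""


PAIR_LABELS = {("R", "G"): "RvG", ("G", "B"): "GvB", ("R", "B"): "RvB"}


def histogram(ch: ChannelPixels) -> ChannelHistogram:
    """Count retained pixels per DCV bin."""
    if len(ch.values) == 0:
        raise EmptyCurveError(f"no retained pixels in channel {ch.channel}")
    return ChannelHistogram(
        channel=ch.channel,
        counts=dcv_histogram(ch.values),
        source_id=ch.source_id,
    )


def abundance(hist: ChannelHistogram, threshold_used: int = 0) -> AbundanceCurve:
    """Normalize a histogram into an abundance curve.

    The support covers every DCV bin >= ``threshold_used`` (zero-count
    bins included), so curves thresholded identically always share a
    support.
    """
    n = hist.n_retained
    if n == 0:
        raise EmptyCurveError("histogram has no retained pixels")
    support = np.arange(threshold_used, 256)
    fractions = hist.counts[threshold_used:] / n
    return AbundanceCurve(
        channel=hist.channel,
        support=support,
        fractions=fractions,
        threshold_used=threshold_used,
        source_id=hist.source_id,
    )


def align(a: AbundanceCurve, b: AbundanceCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Put two curves on their union support, filling missing bins with 0.

    Returns (support, a_fractions, b_fractions).  Curves built under
    different thresholds cannot be meaningfully aligned and raise.
    """
    if a.threshold_used != b.threshold_used:
        raise CurveConfigError(
            f"threshold mismatch: {a.threshold_used} vs {b.threshold_used}"
        )
    support = np.union1d(a.support, b.support)
    fa = np.zeros(len(support))
    fb = np.zeros(len(support))
    fa[np.searchsorted(support, a.support)] = a.fractions
    fb[np.searchsorted(support, b.support)] = b.fractions
    return support, fa, fb


def pair(a: AbundanceCurve, b: AbundanceCurve) -> PairedCurve:
    """Join two channels of one image into a two-color curve (RvG/GvB/RvB)."""
    label = PAIR_LABELS.get((a.channel, b.channel))
    if label is None:
        raise CurveConfigError(
            f"unsupported channel pair ({a.channel}, {b.channel}); "
            "expected one of RvG, GvB, RvB"
        )
    support, fa, fb = align(a, b)
    return PairedCurve(
        channels=label,
        support=support,
        vectors=np.column_stack([fa, fb]),
        threshold_used=a.threshold_used,
        source_id=a.source_id,
    )


def curves_to_frame(curves: list[AbundanceCurve], scale: str = "fraction") -> pd.DataFrame:
    """Serialize curves as a long table (source_id, channel, dcv, fraction)."""
    if scale not in ("fraction", "percent"):
        raise ValueError("scale must be 'fraction' or 'percent'")
    k = 100.0 if scale == "percent" else 1.0
    frames = [
        pd.DataFrame(
            {
                "source_id": c.source_id,
                "channel": c.channel,
                "dcv": c.support,
                "fraction": c.fractions * k,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)
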