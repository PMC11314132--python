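"""Background removal by manual or automatic (Otsu) thresholding.

Frond images are captured over a black oxidized-aluminum sheet, which piles
a large pixel mass at DCVs at or near zero.  Those background codes must be
removed before any histogram comparison, otherwise the (identical)
background dominates every distance.  Two strategies are supported:

* manual: drop every pixel with DCV below a fixed cutoff.  "Remove the
  first 10 DCV" means codes 0-9 go, codes >= 10 stay.
* automatic: Otsu's between-class-variance criterion picks the cutoff per
  channel (or on a grayscale version); pixels strictly below it go.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import ChannelPixels

#: Manual cutoffs explored by the study design: steps of 5 up to 10% of 256.
DEFAULT_MANUAL_CUTOFFS = (0, 5, 10, 15, 20, 25)

#: The preset every frond image is run with by default.
DEFAULT_CUTOFF = 10


class DegenerateHistogramError(ValueError):
    """Automatic thresholding needs at least two occupied intensity bins."""


@dataclass(frozen=True)
class ThresholdSpec:
    """How background pixels are identified.

    mode   : "manual" (fixed cutoff) or "automatic" (Otsu per input).
    cutoff : integer DCV, only meaningful in manual mode.
    scope  : "per_channel" or "grayscale".
    """

    mode: str = "manual"
    cutoff: int = DEFAULT_CUTOFF
    scope: str = "per_channel"

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "automatic"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.scope not in ("per_channel", "grayscale"):
            raise ValueError(f"unknown threshold scope {self.scope!r}")
        if not 0 <= self.cutoff <= 255:
            raise ValueError("cutoff must lie in [0, 255]")


@dataclass
class ThresholdResult:
    """Retained pixels plus the removal bookkeeping."""

    retained: ChannelPixels
    threshold_used: int
    n_removed: int
    all_removed: bool = False

    @property
    def fraction_removed(self) -> float:
        n = self.retained.n_total
        return self.n_removed / n if n else 0.0


def manual_threshold(ch: ChannelPixels, cutoff: int) -> ThresholdResult:
    """Remove pixels with DCV < cutoff (cutoff 10 removes codes 0-9)."""
    if not 0 <= cutoff <= 255:
        raise ValueError("cutoff must lie in [0, 255]")
    keep = ch.values >= cutoff
    retained = ChannelPixels(
        channel=ch.channel,
        values=ch.values[keep],
        n_total=ch.n_total,
        source_id=ch.source_id,
    )
    n_removed = int(len(ch.values) - keep.sum())
    return ThresholdResult(
        retained=retained,
        threshold_used=cutoff,
        n_removed=n_removed,
        all_removed=len(retained.values) == 0,
    )


def dcv_histogram(values: np.ndarray) -> np.ndarray:
    """256-bin count histogram over the DCV axis."""
    return np.bincount(np.asarray(values, dtype=np.int64), minlength=256)


def otsu_threshold(counts: np.ndarray) -> int:
    """Exhaustive between-class-variance argmax over t in [0, 255].

    Classes are {v < t} (background) and {v >= t} (foreground); the
    returned t maximizes w0*w1*(mu0 - mu1)^2, ties broken by the smallest
    t.  Requires at least two occupied bins, otherwise no split separates
    anything and the histogram is degenerate.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    if (counts > 0).sum() < 2:
        raise DegenerateHistogramError(
            "automatic thresholding needs >= 2 occupied bins"
        )
    total = counts.sum()
    dcv = np.arange(256, dtype=np.float64)
    # cum0[t] = pixels with v < t; moments accumulated the same way
    cum_n = np.concatenate(([0.0], np.cumsum(counts)))
    cum_s = np.concatenate(([0.0], np.cumsum(counts * dcv)))
    w0 = cum_n[:256]
    w1 = total - w0
    s0 = cum_s[:256]
    s1 = cum_s[256] - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, s0 / w0, 0.0)
        mu1 = np.where(w1 > 0, s1 / w1, 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return int(np.argmax(between))  # argmax takes the first (smallest) tie


def auto_threshold(ch: ChannelPixels) -> ThresholdResult:
    """Otsu-threshold one channel: drop pixels strictly below the argmax t.

    Binarization assigns 0 to pixels below the threshold and 1 above; the
    0-class is discarded, so retention is {v >= t} with t from
    :func:`otsu_threshold`.
    """
    t = otsu_threshold(dcv_histogram(ch.values))
    res = manual_threshold(ch, t)
    return ThresholdResult(
        retained=res.retained,
        threshold_used=t,
        n_removed=res.n_removed,
        all_removed=res.all_removed,
    )


def apply_threshold(ch: ChannelPixels, spec: ThresholdSpec) -> ThresholdResult:
    """Dispatch on the spec's mode."""
    if spec.mode == "manual":
        return manual_threshold(ch, spec.cutoff)
    return auto_threshold(ch)
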