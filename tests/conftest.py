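import numpy as np
import pytest

from mosslif.curves import AbundanceCurve, abundance, histogram
from mosslif.image_io import ChannelPixels


def channel(values, channel="R", source_id="", n_total=None):
    """Build a ChannelPixels from a plain value list."""
    values = np.asarray(values, dtype=np.int64)
    return ChannelPixels(
        channel=channel,
        values=values,
        n_total=n_total if n_total is not None else len(values),
        source_id=source_id,
    )


def curve_from_values(values, threshold=0, ch="R", source_id=""):
    """Abundance curve of a raw pixel-value list (already thresholded)."""
    return abundance(histogram(channel(values, ch, source_id)), threshold)


def curve(fractions, support=None, ch="R", threshold=0, source_id=""):
    """Abundance curve directly from fractions (support defaults to 0..k)."""
    fractions = np.asarray(fractions, dtype=np.float64)
    if support is None:
        support = np.arange(len(fractions))
    return AbundanceCurve(
        channel=ch,
        support=np.asarray(support),
        fractions=fractions,
        threshold_used=threshold,
        source_id=source_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240724)
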