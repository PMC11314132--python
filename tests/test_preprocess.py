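import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.filters import threshold_otsu

from conftest import channel
from mosslif.image_io import RGBImage, split_channels
from mosslif.preprocess import (
    DegenerateHistogramError,
    ThresholdSpec,
    auto_threshold,
    dcv_histogram,
    manual_threshold,
    otsu_threshold,
)
from oracles import otsu_bruteforce


class TestManualThreshold:
    def test_cutoff_removes_codes_below(self):
        res = manual_threshold(channel([0, 5, 10, 255]), 10)
        assert list(res.retained.values) == [10, 255]
        assert res.n_removed == 2
        assert not res.all_removed

    def test_cutoff_zero_is_identity(self):
        res = manual_threshold(channel([0, 1, 254]), 0)
        assert res.n_removed == 0
        assert list(res.retained.values) == [0, 1, 254]

    def test_background_plus_foreground(self):
        vals = [3] * 1000 + [200] * 10
        res = manual_threshold(channel(vals), 10)
        assert list(res.retained.values) == [200] * 10
        assert res.n_removed == 1000

    def test_all_removed_flag(self):
        res = manual_threshold(channel([1, 2, 3]), 10)
        assert res.all_removed and res.n_removed == 3

    @given(
        vals=st.lists(st.integers(0, 255), min_size=1, max_size=60),
        c1=st.integers(0, 255),
        c2=st.integers(0, 255),
    )
    @settings(derandomize=True, deadline=None)
    def test_conservation_and_monotonicity(self, vals, c1, c2):
        ch = channel(vals)
        r1, r2 = manual_threshold(ch, c1), manual_threshold(ch, c2)
        for r in (r1, r2):
            assert r.n_removed + len(r.retained.values) == ch.n_total
            assert (r.retained.values >= r.threshold_used).all()
        if c1 <= c2:  # raising the cutoff never increases retention
            assert len(r1.retained.values) >= len(r2.retained.values)


class TestOtsu:
    def test_two_mass_histogram(self):
        counts = np.zeros(256, dtype=int)
        counts[10], counts[200] = 100, 100
        t = otsu_threshold(counts)
        assert 10 < t <= 200
        assert t == otsu_bruteforce(counts)

    def test_single_occupied_bin_degenerate(self):
        counts = np.zeros(256, dtype=int)
        counts[50] = 1000
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(counts)
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.zeros(256, dtype=int))

    def test_bimodal_gaussian_mixture(self, rng):
        """The threshold cleanly separates the two modes.  Between-class
        variance is flat across a zero-count gap, so the smallest-t tie rule
        lands just past the low mode rather than mid-gap."""
        low = rng.normal(20, 10, 5000)
        high = rng.normal(180, 10, 5000)
        vals = np.clip(np.round(np.concatenate([low, high])), 0, 255).astype(int)
        counts = dcv_histogram(vals)
        t = otsu_threshold(counts)
        assert t == otsu_bruteforce(counts)
        assert 40 <= t <= 160
        assert (np.clip(low, 0, 255) < t).mean() > 0.99
        assert (np.clip(high, 0, 255) >= t).mean() > 0.99

    @given(st.data())
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_matches_bruteforce_on_random_histograms(self, data):
        occupied = data.draw(
            st.lists(st.integers(0, 255), min_size=2, max_size=12, unique=True)
        )
        counts = np.zeros(256, dtype=int)
        for v in occupied:
            counts[v] = data.draw(st.integers(1, 500))
        assert otsu_threshold(counts) == otsu_bruteforce(counts)

    def test_agrees_with_skimage(self, rng):
        """skimage thresholds with foreground {v > t}; ours retains {v >= t},
        so our threshold sits one code above skimage's on the same histogram."""
        for _ in range(25):
            vals = rng.integers(0, 256, size=2000)
            counts = dcv_histogram(vals)
            sk = threshold_otsu(hist=(counts, np.arange(256)))
            assert otsu_threshold(counts) == sk + 1


class TestAutoThreshold:
    def test_two_mass_retains_high_mass(self):
        vals = [10] * 100 + [200] * 50
        res = auto_threshold(channel(vals))
        assert list(np.unique(res.retained.values)) == [200]
        assert res.n_removed == 100

    def test_rethresholding_at_computed_cutoff_is_identity(self):
        res = auto_threshold(channel([10] * 100 + [200] * 50))
        again = manual_threshold(res.retained, res.threshold_used)
        assert np.array_equal(again.retained.values, res.retained.values)
        assert again.n_removed == 0

    def test_per_channel_mode_thresholds_independently(self, rng):
        """Channels with foreground humps at different intensities get
        different automatic cutoffs (background spike shared)."""
        h, w = 40, 40
        n = h * w
        fg = rng.random((h, w)) < 0.4
        px = np.zeros((h, w, 3))
        for k, (mu, sd) in enumerate(((200, 25), (90, 18), (40, 8))):
            px[:, :, k] = rng.normal(3, 2, size=(h, w))
            px[:, :, k][fg] = rng.normal(mu, sd, size=int(fg.sum()))
        px = np.clip(np.round(px), 0, 255).astype(np.int64)
        chans = split_channels(RGBImage(pixels=px))
        thresholds = {c: auto_threshold(chans[c]).threshold_used for c in "RGB"}
        assert len(set(thresholds.values())) == 3
        # every channel's cutoff falls between its background and foreground
        for c, t in thresholds.items():
            assert 3 < t < {"R": 200, "G": 90, "B": 40}[c]

    def test_conservation(self):
        ch = channel([10] * 100 + [200] * 50)
        res = auto_threshold(ch)
        assert res.n_removed + len(res.retained.values) == ch.n_total


def test_threshold_spec_validation():
    with pytest.raises(ValueError):
        ThresholdSpec(mode="magic")
    with pytest.raises(ValueError):
        ThresholdSpec(cutoff=300)
    with pytest.raises(ValueError):
        ThresholdSpec(scope="global")
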