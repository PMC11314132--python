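import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import curve
from mosslif.curves import CurveConfigError, EmptyCurveError, pair
from mosslif.distances import density_difference, dtw_distance, dtw_two_color
from oracles import dtw2_bruteforce, dtw_bruteforce

seqs = st.lists(
    st.floats(-5, 5, allow_nan=False, allow_infinity=False), min_size=1, max_size=6
)


class TestDensityDifference:
    def test_identical_curves_give_zero(self):
        x = curve([0.2, 0.8])
        assert density_difference(x, curve([0.2, 0.8])).value == 0.0

    def test_disjoint_curves_give_one(self):
        x = curve([1.0], support=[0])
        y = curve([1.0], support=[5])
        assert density_difference(x, y).value == pytest.approx(1.0)

    def test_direct_evaluation(self):
        x = curve([0.5, 0.5, 0.0])
        y = curve([0.25, 0.25, 0.5])
        assert density_difference(x, y).value == pytest.approx(0.5)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(CurveConfigError):
            density_difference(curve([1.0], ch="R"), curve([1.0], ch="G"))

    @given(st.data())
    @settings(derandomize=True, deadline=None)
    def test_bounded_and_symmetric(self, data):
        n = data.draw(st.integers(1, 8))
        seed = data.draw(st.integers(0, 2**16))
        rng = np.random.default_rng(seed)
        x = curve(rng.dirichlet(np.ones(n)))
        y = curve(rng.dirichlet(np.ones(n)))
        d_xy = density_difference(x, y).value
        d_yx = density_difference(y, x).value
        assert 0.0 <= d_xy <= 1.0
        assert d_xy == pytest.approx(d_yx)


class TestDTW:
    def test_identical_sequences_give_zero(self):
        assert dtw_distance([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]).value == 0.0

    def test_singletons_forced_alignment(self):
        assert dtw_distance([3.0], [7.5]).value == pytest.approx(4.5)

    def test_small_grid_example(self):
        # brute-force enumeration over the 3x3 grid gives 1.0
        assert dtw_distance([1, 2, 3], [1, 3, 3]).value == pytest.approx(1.0)
        assert dtw_bruteforce([1, 2, 3], [1, 3, 3]) == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(EmptyCurveError):
            dtw_distance([], [1.0])

    def test_path_length_normalization(self):
        raw = dtw_distance([0.0, 4.0], [1.0]).value
        norm = dtw_distance([0.0, 4.0], [1.0], normalize="path_length").value
        assert norm == pytest.approx(raw / 2)

    @given(x=seqs, y=seqs)
    @settings(derandomize=True, deadline=None)
    def test_matches_bruteforce_enumeration(self, x, y):
        assert dtw_distance(x, y).value == pytest.approx(dtw_bruteforce(x, y))

    @given(x=seqs, y=seqs)
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_symmetric_and_bounded_by_diagonal(self, x, y):
        d = dtw_distance(x, y).value
        assert d >= 0.0
        assert d == pytest.approx(dtw_distance(y, x).value)
        if len(x) == len(y):
            diag = sum(abs(a - b) for a, b in zip(x, y))
            assert d <= diag + 1e-9

    def test_aligns_curves_on_union_support(self):
        x = curve([0.5, 0.5], support=[0, 2])
        y = curve([0.5, 0.5], support=[1, 2])
        d = dtw_distance(x, y)
        assert d.channels == "R"
        assert d.value == pytest.approx(
            dtw_bruteforce([0.5, 0.0, 0.5], [0.0, 0.5, 0.5])
        )


class TestTwoColorDTW:
    def test_identical_pairs_give_zero(self, rng):
        fa, fb = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        x = pair(curve(fa, ch="R"), curve(fb, ch="B"))
        y = pair(curve(fa, ch="R", source_id="y"), curve(fb, ch="B", source_id="y"))
        assert dtw_two_color(x, y).value == pytest.approx(0.0)

    def test_single_point_euclidean(self):
        x = pair(curve([1.0], ch="R"), curve([1.0], ch="B"))
        # fudge the vectors directly to get distinct single points
        x.vectors = np.array([[0.1, 0.2]])
        y = pair(curve([1.0], ch="R"), curve([1.0], ch="B"))
        y.vectors = np.array([[0.4, 0.6]])
        expected = np.hypot(0.3, 0.4)
        assert dtw_two_color(x, y).value == pytest.approx(expected)

    def test_zero_component_reduces_to_single_color(self, rng):
        """When one channel is identically 0 in both pairs, dtw2 equals dtw1
        on the other channel."""
        fa = rng.dirichlet(np.ones(6))
        fc = rng.dirichlet(np.ones(6))
        x, y = [
            pair(curve(f, ch="R", source_id=sid), curve(f, ch="B", source_id=sid))
            for f, sid in ((fa, "x"), (fc, "y"))
        ]
        # zero out the B component after construction (an all-zero curve is
        # not a valid AbundanceCurve on its own)
        x.vectors[:, 1] = 0.0
        y.vectors[:, 1] = 0.0
        d2 = dtw_two_color(x, y).value
        d1 = dtw_distance(fa, fc).value
        assert d2 == pytest.approx(d1)

    def test_pair_mismatch_rejected(self, rng):
        fa = rng.dirichlet(np.ones(4))
        x = pair(curve(fa, ch="R"), curve(fa, ch="B"))
        y = pair(curve(fa, ch="G"), curve(fa, ch="B"))
        with pytest.raises(CurveConfigError):
            dtw_two_color(x, y)

    @given(st.integers(0, 2**16))
    @settings(derandomize=True, deadline=None, max_examples=40)
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        xv = rng.random((n, 2))
        yv = rng.random((n, 2))
        x = pair(curve([1.0], ch="R"), curve([1.0], ch="B"))
        y = pair(curve([1.0], ch="R"), curve([1.0], ch="B"))
        x.support, x.vectors = np.arange(n), xv
        y.support, y.vectors = np.arange(n), yv
        assert dtw_two_color(x, y).value == pytest.approx(
            dtw2_bruteforce(list(xv), list(yv))
        )
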