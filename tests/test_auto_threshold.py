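"""Histogram-numbers auto-threshold: rounding, peaks, chosen-peak criteria."""

import numpy as np
import pytest

from lungseg.auto_threshold import (
    DegenerateResponseError,
    HistogramNumbers,
    binarize,
    choose_peaks,
    find_peaks,
    histogram_numbers,
    round_half_away,
    select_threshold,
)


def counts_to_response(counts, mn):
    """Synthesize a response whose rounded histogram is exactly `counts`."""
    vals = []
    for i, c in enumerate(counts):
        vals.extend([mn + i] * int(c))
    return np.asarray(vals, dtype=float)


class TestHistogramNumbers:
    def test_worked_example(self):
        h = histogram_numbers(np.array([-1.4, -1.4, 0.2, 3.6]))
        assert (h.mn, h.mx) == (-1, 4)
        assert h.counts.tolist() == [2, 1, 0, 0, 0, 1]

    def test_counts_conserve_pixel_count(self, rng):
        resp = rng.normal(0, 20, size=(37, 53))
        h = histogram_numbers(resp)
        assert h.counts.sum() == resp.size
        assert len(h.counts) == h.mx - h.mn + 1

    def test_half_away_from_zero_rounding(self):
        assert round_half_away(np.array([0.5, -0.5, 1.5, -2.5])).tolist() == [1, -1, 2, -3]

    def test_constant_response_is_degenerate(self):
        with pytest.raises(DegenerateResponseError):
            histogram_numbers(np.zeros((8, 8)))


class TestFindPeaks:
    def test_two_interior_peaks(self):
        h = HistogramNumbers(counts=np.array([1, 5, 1, 5, 1]), mn=0, mx=4)
        p = find_peaks(h)
        assert p.locations.tolist() == [1, 3]
        assert p.heights.tolist() == [5, 5]

    def test_monotone_counts_have_no_peaks(self):
        h = HistogramNumbers(counts=np.arange(1, 9), mn=0, mx=7)
        assert find_peaks(h).locations.size == 0

    def test_single_spike_above_mean(self):
        h = HistogramNumbers(counts=np.array([1, 1, 50, 1, 1]), mn=-2, mx=2)
        assert find_peaks(h).locations.tolist() == [2]

    def test_plateau_counts_once_at_first_index(self):
        h = HistogramNumbers(counts=np.array([1, 9, 9, 9, 1, 1, 1]), mn=0, mx=6)
        p = find_peaks(h)
        assert p.locations.tolist() == [1]

    def test_endpoints_are_never_peaks(self):
        h = HistogramNumbers(counts=np.array([9, 1, 1, 1, 9]), mn=0, mx=4)
        assert find_peaks(h).locations.size == 0

    def test_peaks_below_minimum_height_rejected(self):
        # local maxima of height 3 sit below the mean (mph)
        h = HistogramNumbers(counts=np.array([1, 3, 1, 60, 1, 3, 1]), mn=0, mx=6)
        assert find_peaks(h).locations.tolist() == [3]


class TestChoosePeaks:
    @staticmethod
    def _tail_histogram(peak_height):
        # dominant mode at index 2, lone candidate peak at index 50
        counts = np.ones(100, dtype=int)
        counts[2] = 3000
        counts[50] = peak_height
        return HistogramNumbers(counts=counts, mn=0, mx=99)

    def test_peak_after_global_max_within_band_is_chosen(self):
        h = self._tail_histogram(150)
        assert 3 * h.mph <= 150 <= 8 * h.mph
        chosen = choose_peaks(find_peaks(h), h)
        assert chosen.candidate_thresholds.tolist() == [50]

    def test_oddly_high_peak_excluded(self):
        h = self._tail_histogram(400)
        assert 400 > 8 * h.mph
        chosen = choose_peaks(find_peaks(h), h)
        assert chosen.candidate_thresholds.size == 0

    def test_too_low_peak_excluded(self):
        h = self._tail_histogram(60)
        assert h.mph < 60 < 3 * h.mph
        chosen = choose_peaks(find_peaks(h), h)
        assert chosen.candidate_thresholds.size == 0

    def test_peak_before_global_max_excluded(self):
        counts = np.ones(100, dtype=int)
        counts[50] = 3000
        counts[20] = 150  # qualifying height, wrong side of the mode
        h = HistogramNumbers(counts=counts, mn=0, mx=99)
        chosen = choose_peaks(find_peaks(h), h)
        assert chosen.candidate_thresholds.size == 0

    def test_candidates_mapped_to_pixel_values(self):
        counts = np.ones(100, dtype=int)
        counts[2] = 3000
        counts[50] = 150
        h = HistogramNumbers(counts=counts, mn=-30, mx=69)
        chosen = choose_peaks(find_peaks(h), h)
        assert chosen.candidate_thresholds.tolist() == [20]  # index 50 -> -30 + 50


class TestSelectThreshold:
    def test_maximum_of_candidate_list_wins(self):
        # three qualifying peaks at values 12, 30, 41 after a global max at 0
        counts = np.zeros(50, dtype=int)
        counts[0] = 1200
        counts[12] = 160
        counts[30] = 170
        counts[41] = 150
        counts[1:] += 1
        h = HistogramNumbers(counts=counts, mn=0, mx=49)
        mph = h.mph
        for v in (12, 30, 41):
            assert 3 * mph <= counts[v] <= 8 * mph
        resp = counts_to_response(counts, mn=0)
        result = select_threshold(resp)
        assert result.value == 41.0
        assert not result.fallback

    def test_fallback_uses_98th_percentile_of_positive_values(self, rng):
        resp = rng.normal(0, 30, size=(64, 64))  # smooth tail: rarely a chosen peak
        result = select_threshold(resp)
        if result.fallback:
            rounded = round_half_away(resp).ravel()
            positive = rounded[rounded > 0]
            assert result.value == pytest.approx(np.percentile(positive, 98))

    def test_all_negative_response_yields_empty_mask(self):
        resp = -np.abs(np.random.default_rng(0).normal(5, 1, size=(32, 32))) - 1
        result = select_threshold(resp)
        mask = binarize(resp, result)
        if np.isinf(result.value):
            assert not mask.any()

    def test_degenerate_response_flagged(self):
        result = select_threshold(np.zeros((16, 16)))
        assert result.degenerate and np.isinf(result.value)
        assert not binarize(np.zeros((16, 16)), result).any()

    @pytest.mark.parametrize("shift", [-7, 3, 25])
    def test_integer_shift_covariance(self, shift):
        counts = np.zeros(50, dtype=int)
        counts[0] = 1200
        counts[30] = 170
        counts[1:] += 1
        resp = counts_to_response(counts, mn=0)
        base = select_threshold(resp)
        moved = select_threshold(resp + shift)
        assert not base.fallback and not moved.fallback
        assert moved.value == base.value + shift

    def test_threshold_exceeds_global_maximum_location(self, rng):
        # whenever a peak is chosen, it lies strictly right of the histogram mode
        for seed in range(20):
            r = np.random.default_rng(seed)
            resp = np.concatenate(
                [r.normal(0, 10, 3000), r.normal(r.uniform(20, 60), 2, r.integers(100, 800))]
            )
            result = select_threshold(resp)
            if not result.fallback:
                h = histogram_numbers(resp)
                mode_value = h.mn + int(np.argmax(h.counts))
                assert result.value > mode_value


class TestBinarize:
    def test_threshold_above_max_gives_empty_mask(self, rng):
        resp = rng.normal(size=(16, 16))
        assert not binarize(resp, resp.max() + 1).any()

    def test_threshold_at_min_gives_full_mask(self, rng):
        resp = rng.normal(size=(16, 16))
        assert binarize(resp, resp.min()).all()
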