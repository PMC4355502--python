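"""Automatic per-response threshold from histogram-number peaks.

For each oriented Gaussian-derivative response the threshold is chosen by
analysing the histogram of the integer-rounded response values ("histogram
numbers", H_N): every single integer value between the rounded minimum and
maximum gets its own count, with no binning. Peaks of H_N are strict local
maxima exceeding the minimum peak height mph (the mean of H_N). A peak is
*chosen* when it lies strictly after the histogram's global maximum and its
height is between 3*mph and 8*mph (true peaks, but not "oddly high" ones).
The threshold is the largest pixel value among chosen-peak locations — the
end of the histogram peaks — so that only the strongest gradient magnitudes
survive the thresholding.

When no peak qualifies (a failure mode that real radiographs do exhibit) a
documented fallback is used: the 98th percentile of the strictly positive
rounded values; if the response has no positive values at all, the
orientation contributes an empty mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateResponseError(ValueError):
    """Raised when a response rounds to a single integer value."""


@dataclass
class HistogramNumbers:
    """Occurrence counts per integer value of a rounded response.

    ``counts[k]`` is the number of pixels whose rounded value equals
    ``mn + k``; the index range covers the contiguous integers [mn, mx].
    """

    counts: np.ndarray
    mn: int
    mx: int

    @property
    def mph(self) -> float:
        """Minimum peak height: the arithmetic mean of the counts."""
        return float(self.counts.mean())

    def value_at(self, index: int) -> int:
        return self.mn + int(index)


@dataclass
class PeakSet:
    """Peaks of a histogram-numbers vector and the chosen subset."""

    heights: np.ndarray
    locations: np.ndarray  # indices into HistogramNumbers.counts
    chosen: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    candidate_thresholds: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


@dataclass
class ThresholdResult:
    """Selected threshold, in response-value units.

    ``value`` is ``+inf`` when the response has no usable positive tail
    (thresholding then yields an empty mask). ``fallback`` marks thresholds
    not derived from a chosen histogram peak.
    """

    value: float
    fallback: bool = False
    degenerate: bool = False


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def histogram_numbers(resp) -> HistogramNumbers:
    """Unbinned integer histogram of a rounded Gaussian response.

    Raises :class:`DegenerateResponseError` when every pixel rounds to the
    same integer (mn == mx), e.g. for a constant response.
    """
    values = resp.values if hasattr(resp, "values") else np.asarray(resp)
    if not np.all(np.isfinite(values)):
        raise ValueError("response contains non-finite values")
    rounded = round_half_away(values).astype(np.int64).ravel()
    mn = int(rounded.min())
    mx = int(rounded.max())
    if mn == mx:
        raise DegenerateResponseError(f"response rounds to the single value {mn}")
    counts = np.bincount(rounded - mn, minlength=mx - mn + 1).astype(np.int64)
    return HistogramNumbers(counts=counts, mn=mn, mx=mx)


def find_peaks(h: HistogramNumbers) -> PeakSet:
    """Strict local maxima of the counts exceeding the minimum peak height.

    A plateau (run of equal counts rising on the left and falling on the
    right) counts as a single peak at its first index; endpoints are never
    peaks.
    """
    counts = h.counts
    mph = h.mph
    locs: list[int] = []
    heights: list[int] = []
    n = len(counts)
    i = 1
    while i < n - 1:
        if counts[i] > counts[i - 1]:
            j = i
            while j + 1 < n and counts[j + 1] == counts[i]:
                j += 1
            if j < n - 1 and counts[j + 1] < counts[i] and counts[i] > mph:
                locs.append(i)
                heights.append(int(counts[i]))
            i = j + 1
        else:
            i += 1
    return PeakSet(
        heights=np.asarray(heights, dtype=np.int64), locations=np.asarray(locs, dtype=np.int64)
    )


def choose_peaks(
    peaks: PeakSet, h: HistogramNumbers, lo: float = 3.0, hi: float = 8.0
) -> PeakSet:
    """Apply the chosen-peak criteria and map locations to pixel values.

    A peak is chosen when its location is strictly after the location of the
    global maximum of the counts and its height lies in ``[lo*mph, hi*mph]``.
    """
    mph = h.mph
    gmax = int(np.argmax(h.counts))  # first index on ties
    chosen = (
        (peaks.locations > gmax)
        & (peaks.heights >= lo * mph)
        & (peaks.heights <= hi * mph)
    )
    candidates = (h.mn + peaks.locations[chosen]).astype(np.int64)
    return PeakSet(
        heights=peaks.heights,
        locations=peaks.locations,
        chosen=chosen,
        candidate_thresholds=candidates,
    )


def select_threshold(
    resp, lo: float = 3.0, hi: float = 8.0, fallback_pct: float = 98.0
) -> ThresholdResult:
    """Pick the threshold for one response: max of the chosen-peak values.

    Falls back to the ``fallback_pct`` percentile of the strictly positive
    rounded values when no peak qualifies; a response with no positive values
    yields ``+inf`` (empty mask).
    """
    values = resp.values if hasattr(resp, "values") else np.asarray(resp)
    try:
        h = histogram_numbers(values)
    except DegenerateResponseError:
        return ThresholdResult(value=np.inf, fallback=True, degenerate=True)
    peaks = choose_peaks(find_peaks(h), h, lo=lo, hi=hi)
    if peaks.candidate_thresholds.size:
        return ThresholdResult(value=float(peaks.candidate_thresholds.max()))
    rounded = round_half_away(values).ravel()
    positive = rounded[rounded > 0]
    if positive.size == 0:
        return ThresholdResult(value=np.inf, fallback=True, degenerate=True)
    return ThresholdResult(value=float(np.percentile(positive, fallback_pct)), fallback=True)


def binarize(resp, threshold: ThresholdResult | float) -> np.ndarray:
    """Mask of pixels at or above the threshold (positive-tail polarity)."""
    values = resp.values if hasattr(resp, "values") else np.asarray(resp)
    t = threshold.value if isinstance(threshold, ThresholdResult) else float(threshold)
    if np.isinf(t):
        return np.zeros(values.shape, dtype=bool)
    return values >= t
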