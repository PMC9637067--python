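"""Iterative adaptive thresholding driven by grayscale-histogram criteria.

A candidate binarization is produced by comparing each pixel against the
Gaussian-weighted mean of its ``s x s`` neighborhood minus an offset ``C``;
pixels darker than that local threshold become foreground (255).  A
binarization is considered valid when the histogram of *original* gray
values at its foreground pixels (after Savitzky-Golay smoothing) is
unimodal, its peak range contains the prototype colony's mean gray value,
and — among all valid candidates — the area under the peak is maximal.

The histogram is taken over original gray values at foreground pixels: a
histogram of the binary mask itself would have only two bins and could not
express "unimodal around the prototype gray".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import correlate1d
from scipy.signal import find_peaks, savgol_filter

from .errors import NoPeakError, ParameterError, ThresholdSearchError

__all__ = [
    "ThresholdParams",
    "HistogramAssessment",
    "adaptive_binarize",
    "foreground_histogram",
    "smooth_savgol",
    "find_peak_range",
    "assess_binarization",
    "search_threshold_params",
    "combine_color_masks",
    "gaussian_kernel_1d",
    "local_gaussian_mean",
]


@dataclass(frozen=True)
class ThresholdParams:
    """The (s, C) pair of the adaptive-threshold formula."""

    s: int  # window size, odd pixels
    C: float  # offset, gray levels

    def __post_init__(self):
        if self.s < 3 or self.s % 2 == 0:
            raise ParameterError(f"window size s must be odd and >= 3, got {self.s}")


def gaussian_kernel_1d(s: int) -> np.ndarray:
    """Normalized 1-D Gaussian weights for an s-tap window.

    sigma follows the common ksize->sigma rule ``0.3*((s-1)*0.5 - 1) + 0.8``.
    """
    sigma = 0.3 * ((s - 1) * 0.5 - 1) + 0.8
    i = np.arange(s, dtype=np.float64) - (s - 1) / 2.0
    k = np.exp(-(i**2) / (2.0 * sigma**2))
    return k / k.sum()


def local_gaussian_mean(gray: np.ndarray, s: int) -> np.ndarray:
    """Gaussian-weighted mean of the s x s window centered at each pixel.

    Borders are edge-replicated.  Separable implementation; float64.
    """
    k = gaussian_kernel_1d(s)
    tmp = correlate1d(np.asarray(gray, dtype=np.float64), k, axis=0, mode="nearest")
    return correlate1d(tmp, k, axis=1, mode="nearest")


def adaptive_binarize(gray: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Binarize against the local Gaussian mean minus C.

    ``dst = 255`` where ``src < T`` and ``0`` where ``src > T`` with
    ``T = local_gaussian_mean - C``.  Equality is assigned to background (0),
    biasing ties against single-pixel noise.  Foreground therefore captures
    pixels darker than their local surround — dark colonies on a backlit
    plate.
    """
    T = local_gaussian_mean(gray, params.s) - params.C
    return np.where(np.asarray(gray, dtype=np.float64) < T, 255, 0).astype(np.uint8)


def foreground_histogram(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """256-bin histogram of gray values at foreground (255) pixels."""
    gray = np.asarray(gray)
    mask = np.asarray(mask)
    if mask.shape != gray.shape:
        raise ParameterError("mask and gray raster shapes differ")
    vals = gray[mask == 255]
    return np.bincount(vals.ravel(), minlength=256)[:256].astype(np.int64)


def smooth_savgol(signal: Sequence[float], window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (least-squares local polynomial fit)."""
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"Savitzky-Golay window must be odd and >= 3, got {window}")
    if polyorder >= window or polyorder < 0:
        raise ParameterError(
            f"polyorder must satisfy 0 <= polyorder < window, got {polyorder} / {window}"
        )
    return savgol_filter(np.asarray(signal, dtype=np.float64), window, polyorder, mode="interp")


def find_peak_range(smoothed: np.ndarray, rise_epsilon: float = 0.0) -> tuple[int, int]:
    """Inclusive bin range of the run continuously decreasing from the maximum.

    From the global-maximum bin the range is extended rightwards while values
    keep decreasing and symmetrically leftwards.  ``rise_epsilon`` (absolute
    counts) permits small upticks before a run is considered ended; with the
    default 0 any non-decrease (including a plateau) ends the run.  Bins at
    or below ``rise_epsilon`` are never entered, so the range stops at the
    peak's foot rather than swallowing an empty tail.
    """
    s = np.asarray(smoothed, dtype=np.float64)
    if s.size == 0 or np.nanmax(s) <= 0:
        raise NoPeakError("signal has no positive mass")
    p = int(np.argmax(s))

    hi = p
    while hi + 1 < s.size and rise_epsilon < s[hi + 1] < s[hi] + rise_epsilon:
        hi += 1
    lo = p
    while lo - 1 >= 0 and rise_epsilon < s[lo - 1] < s[lo] + rise_epsilon:
        lo -= 1
    return lo, hi


def count_modes(
    smoothed: np.ndarray,
    rel_height: float = 0.05,
    rel_prominence: float = 0.2,
) -> int:
    """Number of local maxima that are both tall and prominent.

    A mode must exceed ``rel_height`` x global max in height and
    ``rel_prominence`` x global max in prominence; the prominence gate keeps
    sampling ripple on a broad peak from counting as extra modes.  The
    signal is padded below its minimum so boundary maxima are counted.
    """
    s = np.asarray(smoothed, dtype=np.float64)
    top = s.max()
    if top <= 0:
        return 0
    pad = s.min() - 1.0
    padded = np.concatenate([[pad], s, [pad]])
    peaks, _ = find_peaks(padded, height=rel_height * top, prominence=rel_prominence * top)
    return int(len(peaks))


@dataclass
class HistogramAssessment:
    """Evaluation of one candidate binarization against the three criteria."""

    raw_hist: np.ndarray = field(repr=False)
    smoothed: np.ndarray = field(repr=False)
    peak_lo: int = 0
    peak_hi: int = 0
    unimodal: bool = False
    contains_prototype_gray: bool = False
    area_under_peak: float | None = None
    failure: str | None = None

    @property
    def valid(self) -> bool:
        return self.failure is None and self.unimodal and self.contains_prototype_gray


def assess_binarization(
    gray: np.ndarray,
    mask: np.ndarray,
    prototype,
    *,
    sg_window: int = 11,
    sg_polyorder: int = 3,
    unimodal_rel_height: float = 0.05,
    unimodal_rel_prominence: float = 0.2,
    peak_rise_tol: float = 0.1,
) -> HistogramAssessment:
    """Assess one binarization: histogram, smoothing, peak range, criteria.

    ``peak_rise_tol`` is a fraction of the smoothed maximum converted to the
    absolute ``rise_epsilon`` of :func:`find_peak_range`.  The area under the
    peak is computed only when the prototype's mean gray lies inside the
    peak range (short-circuit); negative smoothed values contribute zero.
    A no-peak histogram yields a failed assessment, not an exception.
    """
    hist = foreground_histogram(gray, mask)
    if hist.sum() == 0:
        return HistogramAssessment(
            raw_hist=hist, smoothed=np.zeros(256), failure="empty foreground"
        )
    smoothed = smooth_savgol(hist, sg_window, sg_polyorder)
    try:
        lo, hi = find_peak_range(smoothed, rise_epsilon=peak_rise_tol * float(smoothed.max()))
    except NoPeakError:
        return HistogramAssessment(raw_hist=hist, smoothed=smoothed, failure="no peak")
    nmodes = count_modes(smoothed, unimodal_rel_height, unimodal_rel_prominence)
    unimodal = nmodes == 1
    contains = lo <= prototype.mean_gray <= hi
    area = None
    if contains:
        area = float(np.clip(smoothed[lo : hi + 1], 0.0, None).sum())
    return HistogramAssessment(
        raw_hist=hist,
        smoothed=smoothed,
        peak_lo=lo,
        peak_hi=hi,
        unimodal=unimodal,
        contains_prototype_gray=bool(contains),
        area_under_peak=area,
    )


def default_s_grid(prototype, image_shape=None, steps: int = 8) -> list[int]:
    """Window-size grid seeded by the prototype bounding box.

    Starts at the larger bounding-box dimension (rounded up to odd, >= 3) so
    the window exceeds the colony and avoids donut-shaped segments, stepping
    by ``2 * max(2, s0 // 4)`` to stay odd.
    """
    s0 = int(max(prototype.bbox_w, prototype.bbox_h))
    s0 = max(3, s0 if s0 % 2 == 1 else s0 + 1)
    delta = max(2, s0 // 4)
    grid = [s0 + 2 * i * delta for i in range(steps)]
    if image_shape is not None:
        cap = min(image_shape[:2])
        cap = cap if cap % 2 == 1 else cap - 1
        grid = [s for s in grid if s <= cap] or [min(grid[0], cap)]
    return grid


def search_threshold_params(
    gray: np.ndarray,
    prototype,
    *,
    roi_mask: np.ndarray | None = None,
    s_grid: Iterable[int] | None = None,
    c_grid: Iterable[float] | None = None,
    s_steps: int = 8,
    sg_window: int = 11,
    sg_polyorder: int = 3,
    unimodal_rel_height: float = 0.05,
    unimodal_rel_prominence: float = 0.2,
    peak_rise_tol: float = 0.1,
) -> tuple[ThresholdParams, np.ndarray, HistogramAssessment]:
    """Grid-search (s, C) for the valid binarization with the largest peak area.

    Iterates s ascending then C ascending and keeps a candidate only when it
    strictly improves the area under the peak, so ties deterministically
    resolve to the smallest s, then the smallest C.  When an ROI mask is
    given, foreground outside it is cleared before assessment.
    """
    if s_grid is None:
        s_grid = default_s_grid(prototype, np.asarray(gray).shape, steps=s_steps)
    if c_grid is None:
        c_grid = range(1, 31, 2)
    s_values = sorted(set(int(s) for s in s_grid))
    c_values = sorted(set(float(c) for c in c_grid))
    if not s_values or not c_values:
        raise ParameterError("empty search grid")

    best: tuple[ThresholdParams, np.ndarray, HistogramAssessment] | None = None
    best_partial: HistogramAssessment | None = None
    gray64 = np.asarray(gray, dtype=np.float64)
    for s in s_values:
        local_mean = local_gaussian_mean(gray, s)
        for c in c_values:
            mask = np.where(gray64 < local_mean - c, 255, 0).astype(np.uint8)
            if roi_mask is not None:
                mask[~roi_mask] = 0
            assessment = assess_binarization(
                gray,
                mask,
                prototype,
                sg_window=sg_window,
                sg_polyorder=sg_polyorder,
                unimodal_rel_height=unimodal_rel_height,
                unimodal_rel_prominence=unimodal_rel_prominence,
                peak_rise_tol=peak_rise_tol,
            )
            if assessment.valid:
                if best is None or assessment.area_under_peak > best[2].area_under_peak:
                    best = (ThresholdParams(s=s, C=c), mask, assessment)
            elif best_partial is None or _partial_rank(assessment) > _partial_rank(best_partial):
                best_partial = assessment
    if best is None:
        raise ThresholdSearchError(
            "no (s, C) pair satisfied the histogram criteria "
            f"over {len(s_values)} x {len(c_values)} candidates",
            best_partial=best_partial,
        )
    return best


def _partial_rank(a: HistogramAssessment) -> tuple:
    return (a.failure is None, a.unimodal, a.contains_prototype_gray, int(a.raw_hist.sum()))


def combine_color_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise logical OR of per-color binary masks."""
    if not masks:
        raise ParameterError("no masks to combine")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ParameterError("mask shapes differ")
    out = np.zeros(shape, dtype=np.uint8)
    for m in masks:
        out |= (np.asarray(m) > 0).astype(np.uint8)
    return (out * 255).astype(np.uint8)
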