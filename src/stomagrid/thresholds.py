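"""Histogram auto-thresholding: Li, Moments, Minimum and Percentile.

All methods operate on a 256-bin intensity histogram (the classic particle
analysis convention regardless of bit depth) and return a single integer
bin index ``t``; the dark-object binary keeps pixels whose bin index is
``<= t``. Stomata and vein/border structures are non-fluorescent, so every
consumer of these cuts keeps the low-intensity side.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .image import Image2D

METHODS = ("moments", "li", "minimum", "percentile")
NBINS = 256


class ThresholdError(RuntimeError):
    """A threshold method could not produce a cut on this histogram."""


def histogram256(image: Image2D) -> np.ndarray:
    """256-bin histogram over the image's native intensity range."""
    shift = image.bit_depth - 8
    bins = image.pixels >> shift if shift else image.pixels
    return np.bincount(bins.ravel(), minlength=NBINS).astype(np.float64)


def binary_below(image: Image2D, threshold_bin: int) -> np.ndarray:
    """Boolean raster of pixels at or below the threshold bin (dark side)."""
    shift = image.bit_depth - 8
    bins = image.pixels >> shift if shift else image.pixels
    return bins <= threshold_bin


def auto_threshold(
    histogram: np.ndarray, method: str, percentile_target: float = 0.5
) -> int:
    """One scalar cut per method; see the per-method functions for details."""
    h = np.asarray(histogram, np.float64)
    if h.ndim != 1 or h.size < 2:
        raise ThresholdError("histogram must be a 1-D array with >= 2 bins")
    if h.sum() <= 0:
        raise ThresholdError("all-zero histogram")
    if np.count_nonzero(h) < 2:
        raise ThresholdError("histogram needs >= 2 non-zero bins")
    if method == "li":
        return threshold_li(h)
    if method == "moments":
        return threshold_moments(h)
    if method == "minimum":
        return threshold_minimum(h)
    if method == "percentile":
        return threshold_percentile(h, percentile_target)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def threshold_li(h: np.ndarray, tolerance: float = 0.5, max_iter: int = 100) -> int:
    """Minimum cross-entropy fixed point (Li & Tam's iterative form).

    Starting from the overall mean, the cut is refined as
    ``t = (mu_b - mu_f) / (ln mu_b - ln mu_f)`` where ``mu_b``/``mu_f`` are
    the mean intensities below/above the current cut, until it moves by less
    than ``tolerance`` bins.
    """
    eps = 1e-9
    c = np.arange(h.size, dtype=np.float64) + eps  # keep logs defined at bin 0
    t = float((h * c).sum() / h.sum())
    for _ in range(max_iter):
        below = c <= t
        wb, wf = h[below].sum(), h[~below].sum()
        if wb == 0 or wf == 0:
            break
        mb = (h[below] * c[below]).sum() / wb
        mf = (h[~below] * c[~below]).sum() / wf
        t_new = (
            (mb - mf) / (np.log(mb) - np.log(mf))
            if mb != mf
            else t
        )
        if abs(t_new - t) < tolerance:
            t = t_new
            break
        t = t_new
    return int(t)


def threshold_moments(h: np.ndarray) -> int:
    """Moment-preserving bilevel threshold (Tsai).

    Finds the two-level image (values ``z0 < z1``, dark fraction ``p0``)
    whose first three moments equal the histogram's, then cuts at the bin
    where the cumulative fraction is closest to ``p0``.
    """
    p = h / h.sum()
    c = np.arange(h.size, dtype=np.float64)
    m1 = (p * c).sum()
    m2 = (p * c**2).sum()
    m3 = (p * c**3).sum()
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ThresholdError("zero-variance histogram")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise ThresholdError("moments threshold undefined (complex roots)")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ThresholdError("degenerate moment roots")
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    return int(np.argmin(np.abs(cum - p0)))


def _local_maxima(h: np.ndarray) -> list[int]:
    """Indices of local maxima; a flat plateau counts once (at its start)."""
    out = []
    n = h.size
    i = 1
    while i < n - 1:
        if h[i] > h[i - 1]:
            j = i
            while j < n - 1 and h[j + 1] == h[i]:
                j += 1
            if j == n - 1 or h[j + 1] < h[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def threshold_minimum(h: np.ndarray, max_smoothings: int = 10000) -> int:
    """Valley between the two modes of an iteratively smoothed histogram.

    The histogram is mean-filtered (width 3) until exactly two local maxima
    remain; the cut is the minimum between them. Fails explicitly if the
    histogram never becomes bimodal.
    """
    hs = h.astype(np.float64)
    for _ in range(max_smoothings + 1):
        maxima = _local_maxima(hs)
        if len(maxima) == 2:
            lo, hi = maxima
            return lo + int(np.argmin(hs[lo : hi + 1]))
        if len(maxima) < 2:
            raise ThresholdError(
                "histogram is unimodal and never becomes bimodal under smoothing"
            )
        hs = ndi.uniform_filter1d(hs, 3, mode="reflect")
    raise ThresholdError("histogram did not reach bimodality while smoothing")


def threshold_percentile(h: np.ndarray, target: float = 0.5) -> int:
    """Smallest bin at which the cumulative fraction reaches ``target``."""
    if not (0.0 < target < 1.0):
        raise ValueError("percentile target must lie in (0, 1)")
    cum = np.cumsum(h) / h.sum()
    return int(np.argmax(cum >= target))
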