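"""Cotyledon-node localization from the plant image bottom edge.

Plants are photographed dark-on-white with the cotyledon node tangent to
the bottom edge of the image.  The image is binarized twice — with Otsu's
between-class-variance threshold and with the triangle (peak-to-tail)
threshold — and the two dark-side masks are intersected to suppress the
errors either method makes alone.  The cotyledon node is then the mean
position of the foreground pixels on the bottom image row.
"""

from __future__ import annotations

import numpy as np

from .errors import CotyledonError, InputError
from .geometry import Point

__all__ = [
    "gray_histogram",
    "rgb_to_gray",
    "otsu_threshold",
    "triangle_threshold",
    "binarize_combined",
    "locate_cotyledon_node",
    "bottom_row_run_count",
]

N_LEVELS = 256


def _check_histogram(h: np.ndarray) -> np.ndarray:
    h = np.asarray(h, dtype=np.float64)
    if h.shape != (N_LEVELS,):
        raise InputError(f"histogram must have {N_LEVELS} bins, got {h.shape}")
    if np.any(h < 0) or h.sum() <= 0:
        raise InputError("histogram counts must be non-negative with positive total")
    return h


def gray_histogram(gray: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of an 8-bit grayscale image."""
    gray = np.asarray(gray)
    if gray.size == 0:
        raise InputError("empty image")
    return np.bincount(gray.astype(np.uint8).ravel(), minlength=N_LEVELS)


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Luma conversion with the Rec. 601 weights, rounded to uint8."""
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(np.uint8)
    rgb = img[..., :3].astype(np.float64)
    luma = rgb @ np.array([0.299, 0.587, 0.114])
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)


def otsu_threshold(h: np.ndarray) -> int:
    """Threshold maximizing the between-class variance of {<= t} vs {> t}.

    Ties resolve to the smallest level; a histogram concentrated on a
    single level returns that level.
    """
    h = _check_histogram(h)
    total = h.sum()
    levels = np.arange(N_LEVELS, dtype=np.float64)
    w0 = np.cumsum(h)
    m0 = np.cumsum(h * levels)
    mu_total = m0[-1]
    valid = (w0 > 0) & (w0 < total)
    if not valid.any():  # all mass at one level
        return int(np.flatnonzero(h)[0])
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        var_between = w0 * w1 * (mean0 - mean1) ** 2
    var_between[~valid] = -np.inf
    return int(np.argmax(var_between))  # argmax returns the first (smallest) tie


def triangle_threshold(h: np.ndarray) -> int:
    """Threshold at the knee of the histogram's longer tail.

    A line joins the histogram peak to the far end of its longer tail; the
    level maximizing the perpendicular distance from the histogram curve to
    that line is the threshold.  Equal tails resolve toward the brighter
    side (the background of a dark-on-white image), ties between levels to
    the smallest level, and a completely flat histogram to mid-range 127.
    """
    h = _check_histogram(h)
    if h.max() == h.min():
        return 127
    peak = int(np.argmax(h))  # first peak among ties
    nz = np.flatnonzero(h)
    first_nz, last_nz = int(nz[0]), int(nz[-1])
    left_tail = peak - first_nz
    right_tail = last_nz - peak
    end = last_nz if right_tail >= left_tail else first_nz
    if end == peak:
        return peak
    x1, y1 = float(peak), float(h[peak])
    x2, y2 = float(end), float(h[end])
    lo, hi = min(peak, end), max(peak, end)
    ts = np.arange(lo, hi + 1, dtype=np.float64)
    # distance from (t, h[t]) to the peak-end line
    num = np.abs((y2 - y1) * ts - (x2 - x1) * h[lo : hi + 1] + x2 * y1 - y2 * x1)
    return int(lo + np.argmax(num))  # first maximum = smallest level


def binarize_combined(gray: np.ndarray) -> np.ndarray:
    """Foreground mask as the intersection of the two dark-side masks.

    A pixel is plant foreground only when it is at or below *both* the Otsu
    and the triangle threshold.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise InputError("empty image")
    if gray.ndim != 2:
        gray = rgb_to_gray(gray)
    h = gray_histogram(gray)
    t_otsu = otsu_threshold(h)
    t_tri = triangle_threshold(h)
    return (gray <= t_otsu) & (gray <= t_tri)


def locate_cotyledon_node(mask: np.ndarray) -> Point:
    """Cotyledon node from the bottom image row of a foreground mask.

    Returns the bottom row index paired with the mean column of the
    foreground pixels in that row.  The acquisition protocol keeps the
    cotyledon node tangent to the bottom edge, so an empty bottom row is
    an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or mask.ndim != 2:
        raise InputError("mask must be a non-empty 2-D raster")
    cols = np.flatnonzero(mask[-1])
    if cols.size == 0:
        raise CotyledonError("cotyledon not tangent to bottom edge")
    return Point(float(mask.shape[0] - 1), float(cols.mean()))


def bottom_row_run_count(mask: np.ndarray) -> int:
    """Number of disjoint foreground runs on the bottom row.

    More than one run means the bottom-edge mean may fall between plant
    parts; callers can flag such plants for review.
    """
    row = np.asarray(mask, dtype=bool)[-1]
    if not row.any():
        return 0
    return int(np.count_nonzero(np.diff(row.astype(np.int8)) == 1) + int(row[0]))
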