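"""Automatic intensity thresholding by maximisation of Rényi entropies.

The threshold selector operates on a 256-bin intensity histogram.  For a
candidate threshold ``t`` the histogram is split into a background class
(bins ``0..t``) and a foreground class (bins ``t+1..255``); each class is
renormalised and its Rényi entropy of order ``rho`` computed,

    H_rho = 1 / (1 - rho) * ln( sum_i q_i ** rho ),

with the Shannon (Kapur) entropy as the ``rho -> 1`` limit.  The
single-order selector returns the ``t`` maximising the sum of the two class
entropies; ties are broken toward the lower threshold.

The default ``sahoo_combined`` method computes the single-order thresholds
at rho = 0.5, 1 and 2 and combines them with the classic three-threshold
weighting rule used by the common open-source auto-threshold
implementations: the three thresholds are sorted, weights (beta1, beta2,
beta3) are assigned according to how far apart they lie (within 5 bins of
each other or not), and the final threshold is

    t* = t1 * (P(t1) + 0.25 * w * b1)
         + 0.25 * t2 * w * b2
         + t3 * (1 - P(t3) + 0.25 * w * b3)

where P is the cumulative histogram and w = P(t3) - P(t1).

Images of any integer or float dtype are supported by rescaling the observed
intensity range onto 256 bins and mapping the selected bin back to a native
intensity value, so thresholding is covariant under intensity shifts.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateHistogramError, InvalidArgumentError

N_BINS = 256


def _validate_hist(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size != N_BINS:
        raise InvalidArgumentError(f"histogram must have {N_BINS} bins, got shape {hist.shape}")
    if np.any(hist < 0):
        raise InvalidArgumentError("histogram counts must be non-negative")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")
    return hist


def _single_order_threshold(hist: np.ndarray, rho: float) -> int:
    """Arg-max of background + foreground Rényi entropy over all splits.

    Candidates are thresholds t for which both classes have positive mass and
    bin t itself is occupied (an empty bin t gives a score identical to t-1,
    so each tie plateau is represented by its lowest member); the first
    (lowest) maximiser is returned.
    """
    total = hist.sum()
    p = hist / total
    cum = np.cumsum(hist)                       # exact when counts are integers
    fg_count = total - cum
    valid = (cum[:-1] > 0) & (fg_count[:-1] > 0) & (hist[:-1] > 0)
    p1 = np.cumsum(p)
    p2 = np.cumsum(p[::-1])[::-1]               # foreground mass, no cancellation
    with np.errstate(divide="ignore", invalid="ignore"):
        if abs(rho - 1.0) < 1e-12:
            # Kapur/Shannon limit: H = ln P + S / P with S = -sum p ln p
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
            s_bg = np.cumsum(plogp)
            s_fg = np.cumsum(plogp[::-1])[::-1]
            h_bg = np.log(p1[:-1]) - s_bg[:-1] / p1[:-1]
            h_fg = np.log(p2[1:]) - s_fg[1:] / p2[1:]
        else:
            prho = p**rho
            r_bg = np.cumsum(prho)
            r_fg = np.cumsum(prho[::-1])[::-1]
            inv = 1.0 / (1.0 - rho)
            h_bg = inv * (np.log(r_bg[:-1]) - rho * np.log(p1[:-1]))
            h_fg = inv * (np.log(r_fg[1:]) - rho * np.log(p2[1:]))

    score = np.where(valid, h_bg + h_fg, -np.inf)
    return int(np.argmax(score))       # argmax takes the first maximum: lower tie-break


def renyi_threshold(hist: np.ndarray, method: str = "sahoo_combined", rho: float = 1.0) -> int:
    """Select a threshold bin index from a 256-bin histogram.

    Parameters
    ----------
    hist:
        Counts per intensity bin (length 256).
    method:
        ``"single_order"`` maximises the order-``rho`` class entropies;
        ``"sahoo_combined"`` (default) combines the rho = 0.5, 1, 2
        thresholds with the three-threshold weighting rule.
    rho:
        Entropy order for ``single_order``; ignored otherwise.

    Returns
    -------
    int
        Bin index t; foreground is everything in bins strictly above t.
    """
    hist = _validate_hist(hist)
    p = hist / hist.sum()

    if method == "single_order":
        if rho <= 0:
            raise InvalidArgumentError("rho must be > 0")
        return _single_order_threshold(hist, rho)
    if method != "sahoo_combined":
        raise InvalidArgumentError(f"unknown threshold method {method!r}")

    t1, t2, t3 = sorted(
        _single_order_threshold(hist, r) for r in (0.5, 1.0, 2.0)
    )
    p1 = np.cumsum(p)
    # weights depend on the spread of the three single-order thresholds
    if abs(t1 - t2) <= 5:
        if abs(t2 - t3) <= 5:
            b1, b2, b3 = 1, 2, 1
        else:
            b1, b2, b3 = 0, 1, 3
    else:
        if abs(t2 - t3) <= 5:
            b1, b2, b3 = 3, 1, 0
        else:
            b1, b2, b3 = 1, 2, 1
    omega = p1[t3] - p1[t1]
    t_star = (
        t1 * (p1[t1] + 0.25 * omega * b1)
        + 0.25 * t2 * omega * b2
        + t3 * (1.0 - p1[t3] + 0.25 * omega * b3)
    )
    return int(t_star)


def image_histogram_256(img: np.ndarray) -> tuple[np.ndarray, float, float]:
    """256-bin histogram of an image plus the intensity range it spans.

    8-bit images use one bin per grey level; other dtypes are rescaled from
    their observed ``[min, max]`` range onto 256 bins.  Returns
    ``(counts, lo, hi)``.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise InvalidArgumentError("empty image")
    if img.dtype == np.uint8:
        counts = np.bincount(img.ravel(), minlength=N_BINS).astype(float)
        return counts, 0.0, 255.0
    lo = float(img.min())
    hi = float(img.max())
    if hi <= lo:
        raise DegenerateHistogramError("image is flat; no threshold exists")
    scaled = np.floor((img.astype(np.float64) - lo) * (N_BINS - 1.0) / (hi - lo))
    scaled = np.clip(scaled, 0, N_BINS - 1).astype(np.intp)
    counts = np.bincount(scaled.ravel(), minlength=N_BINS).astype(float)
    return counts, lo, hi


def threshold_image(img: np.ndarray, method: str = "sahoo_combined", rho: float = 1.0) -> float:
    """Entropy threshold of an image, returned on the native intensity scale.

    Foreground is defined as ``img > threshold``.  For 8-bit images the value
    equals the ImageJ convention (bin index + a sub-quantum epsilon below the
    next grey level); for other dtypes the selected bin edge is mapped back
    through the rescaling used for histogramming, so adding a constant to all
    pixels shifts the returned threshold by exactly that constant.
    """
    counts, lo, hi = image_histogram_256(img)
    t = renyi_threshold(counts, method=method, rho=rho)
    if np.asarray(img).dtype == np.uint8:
        return float(t) + 0.5
    width = (hi - lo) / (N_BINS - 1.0)
    # upper edge of bin t, nudged down so boundary pixels stay foreground
    return lo + (t + 1) * width - width * 1e-6
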