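"""Intensity-only thresholding baselines: Otsu and iterative Triclass.

Both operate on a single-channel 8-bit image and report the raw split:
``mask`` marks the *upper* class (values strictly above the threshold).
For histology, where tissue is darker than background, callers threshold
the inverted grayscale so the upper class is the tissue/stain side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateImageError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ThresholdResult:
    """Outcome of a thresholding baseline.

    ``threshold`` is the final split point in [0, 255], ``mask`` the upper
    (foreground-side) class, and ``iterations`` the number of Otsu passes
    (always 1 for plain Otsu).
    """

    threshold: int
    mask: np.ndarray
    iterations: int = 1


def _otsu_from_counts(counts: np.ndarray) -> int:
    """Exact Otsu threshold from a 256-bin histogram.

    Maximizes the between-class variance (equivalently minimizes the
    weighted intra-class variance) over all split points ``{<=t, >t}``
    using exact integer arithmetic, breaking ties by the smallest t.
    """
    counts = [int(c) for c in counts]
    total = sum(counts)
    grand = sum(v * c for v, c in enumerate(counts))
    best_t = None
    best_num, best_den = -1, 1
    w1 = s1 = 0
    for t in range(256):
        w1 += counts[t]
        s1 += t * counts[t]
        w2 = total - w1
        if w1 == 0 or w2 == 0:
            continue
        # between-class variance ∝ (s1*total - grand*w1)^2 / (w1*w2)
        num = (s1 * total - grand * w1) ** 2
        den = w1 * w2
        if num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    if best_t is None:
        raise DegenerateImageError("constant image: no threshold separates two classes")
    return best_t


def otsu_threshold(img: np.ndarray) -> ThresholdResult:
    """Otsu's method: the split minimizing weighted intra-class variance."""
    img = np.asarray(img)
    counts = np.bincount(img.ravel().astype(np.int64), minlength=256)
    t = _otsu_from_counts(counts)
    return ThresholdResult(threshold=t, mask=img > t, iterations=1)


def triclass_threshold(
    img: np.ndarray, min_region: int = 50, max_iter: int = 20
) -> ThresholdResult:
    """Iterative Triclass thresholding.

    Each pass applies Otsu to the current region, splitting it at ``t``
    into upper/lower classes with means ``mu_u``/``mu_l``.  Pixels at or
    above ``mu_u`` join the foreground, pixels at or below ``mu_l`` join
    the background, and the ambiguous middle class in ``(mu_l, mu_u)`` is
    re-thresholded.  Iteration stops when the middle region shrinks below
    ``min_region`` pixels, successive thresholds differ by less than one
    gray level, or ``max_iter`` is reached; the residual middle is then
    split once by the last threshold and its upper part joins the
    foreground.
    """
    img = np.asarray(img)
    if min_region < 1:
        raise ParameterError("min_region must be >= 1")
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    if np.unique(img).size < 2:
        raise DegenerateImageError("constant image: no threshold separates two classes")

    region = np.ones(img.shape, dtype=bool)
    fg = np.zeros(img.shape, dtype=bool)
    t_prev: int | None = None
    t = 0
    iterations = 0
    while iterations < max_iter:
        vals = img[region]
        if np.unique(vals).size < 2:
            # nothing left to split; residual joins foreground above last t
            fg |= region & (img > t)
            return ThresholdResult(threshold=t, mask=fg, iterations=max(iterations, 1))
        counts = np.bincount(vals.astype(np.int64), minlength=256)
        t = _otsu_from_counts(counts)
        iterations += 1
        upper = region & (img > t)
        lower = region & (img <= t)
        mu_u = img[upper].mean()
        mu_l = img[lower].mean()
        fg |= region & (img >= mu_u)
        middle = region & (img > mu_l) & (img < mu_u)
        converged = t_prev is not None and abs(t - t_prev) < 1
        if middle.sum() < min_region or converged or iterations == max_iter:
            if iterations == max_iter and middle.sum() >= min_region and not converged:
                logger.warning("triclass: max_iter=%d reached before convergence", max_iter)
            fg |= middle & (img > t)
            return ThresholdResult(threshold=t, mask=fg, iterations=iterations)
        region = middle
        t_prev = t
    return ThresholdResult(threshold=t, mask=fg, iterations=iterations)
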