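"""ROI segmentation for staining images contaminated by defocused stains.

The pipeline distinguishes the focused tissue section from defocused
"dirty" stains by *texture sharpness* rather than pixel value.  A focused,
textured region has a large local fourth-order central moment (a
higher-order-statistics, HOS, focus measure); a defocused blob is locally
smooth and scores near zero.  The six segmentation steps are:

1. grayscale (``imgio.to_grayscale``)
2. HOS transform                  (:func:`hos_transform`)
3. local-density filtering        (:func:`density_filter`)
4. dilation                       (:func:`dilate_mask`)
5. hole filling                   (:func:`fill_solid`)
6. size-ranked denoising          (:func:`denoise_small_objects`)

composed by :func:`segment_roi`.  Everything here is deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig
from .errors import ParameterError

logger = logging.getLogger(__name__)

#: Down-scaling factor mapping raw fourth-moment values into [0, 255].
HOS_SCALE = 300.0


def fourth_central_moment_map(img: np.ndarray, window_radius: int = 2) -> np.ndarray:
    """Local fourth-order central moment at every pixel (uncapped).

    For each pixel, over its ``(2r+1) x (2r+1)`` neighborhood, compute the
    window mean ``m`` and then ``mean((I - m)**4)`` over the window.
    Borders use half-sample symmetric reflection (the edge pixel is
    repeated; ``np.pad(mode="symmetric")``), which avoids the spurious
    moment spikes that zero padding would create where tissue touches the
    frame.

    Uses the moment expansion
    ``E[(X-m)^4] = E[X^4] - 4 m E[X^3] + 6 m^2 E[X^2] - 3 m^4`` with
    separable uniform filters, after subtracting the global mean to keep
    the expansion numerically well-conditioned (central moments are
    shift-invariant, and a constant image yields exactly zero).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ParameterError(f"expected a non-empty 2-D image, got shape {img.shape}")
    r = int(window_radius)
    if r < 1:
        raise ParameterError("window_radius must be >= 1")
    size = 2 * r + 1
    h, w = img.shape
    if size > 2 * h or size > 2 * w:
        raise ParameterError(
            f"window size {size} exceeds twice the image extent {img.shape}"
        )
    x = img - img.mean()
    uf = lambda a: ndimage.uniform_filter(a, size=size, mode="reflect")
    m1 = uf(x)
    m2 = uf(x * x)
    m3 = uf(x ** 3)
    m4 = uf(x ** 4)
    mu4 = m4 - 4.0 * m1 * m3 + 6.0 * m1 ** 2 * m2 - 3.0 * m1 ** 4
    np.maximum(mu4, 0.0, out=mu4)  # guard against tiny negative round-off
    return mu4


def hos_transform(img: np.ndarray, window_radius: int = 2) -> np.ndarray:
    """HOS map: fourth central moment down-scaled by 300, capped at 255.

    ``HOS(x, y) = min(255, mu4(x, y) / 300)``.  A constant image maps to
    an all-zero HOS map.
    """
    mu4 = fourth_central_moment_map(img, window_radius)
    return np.minimum(mu4 / HOS_SCALE, 255.0)


def binarize_hos(hos: np.ndarray, cutoff: float) -> np.ndarray:
    """Candidate foreground: pixels with ``HOS >= cutoff`` (inclusive)."""
    if not 0 <= cutoff <= 255:
        raise ParameterError(f"cutoff must be in [0, 255], got {cutoff}")
    return np.asarray(hos) >= cutoff


def local_density(coords: np.ndarray, k: int) -> np.ndarray:
    """Local density score LD for each point of a 2-D point set.

    For point ``p_i`` with its ``k`` nearest other points at Euclidean
    distances ``d_ij``, the mean neighbor distance is
    ``dbar_i = mean(d_ij)`` and

    ``LD(p_i) = mean(exp(-d_ij / dbar_i))``

    Because each point is normalized by its own mean neighbor distance,
    Jensen's inequality bounds LD below by ``exp(-1)`` (equality when all
    k neighbor distances coincide), so LD lives in ``[1/e, 1)``: cutoffs
    below ~0.368 act as a conservative pass-through that only drops
    degenerate points.  If fewer than ``k`` other points exist, ``k`` is
    reduced to the available count (logged).  A single point has no
    neighbors and gets LD = 0.
    """
    pts = np.asarray(coords, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError(f"expected an (n, 2) point array, got shape {pts.shape}")
    n = len(pts)
    if n == 0:
        raise ParameterError("point set is empty")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if n == 1:
        logger.warning("single-point set: local density defined as 0")
        return np.zeros(1)
    k_eff = min(int(k), n - 1)
    if k_eff < k:
        logger.info("reduced k from %d to %d (only %d points)", k, k_eff, n)
    nn = NearestNeighbors(n_neighbors=k_eff + 1, algorithm="kd_tree").fit(pts)
    dist, _ = nn.kneighbors(pts)
    d = dist[:, 1:]  # drop self-distance 0
    dbar = d.mean(axis=1)
    return np.exp(-d / dbar[:, None]).mean(axis=1)


def density_filter(mask: np.ndarray, k: int, ld_cutoff: float) -> np.ndarray:
    """Drop candidate pixels whose local density falls below ``ld_cutoff``."""
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if len(coords) == 0:
        return mask.copy()
    ld = local_density(coords, k)
    keep = coords[ld >= ld_cutoff]
    out = np.zeros_like(mask)
    out[keep[:, 0], keep[:, 1]] = True
    return out


def dilate_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological dilation with a disk structuring element (radius 0 = identity)."""
    mask = np.asarray(mask, dtype=bool)
    if radius < 0:
        raise ParameterError("dilate radius must be >= 0")
    if radius == 0:
        return mask.copy()
    return dilation(mask, footprint=disk(radius)).astype(bool)


def fill_solid(mask: np.ndarray) -> np.ndarray:
    """Fill holes: background regions not 4-connected to the image border."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def denoise_small_objects(mask: np.ndarray, keep_area_fraction: float) -> np.ndarray:
    """Remove small residual objects by cumulative-area ranking.

    8-connected objects are sorted by area (descending, ties by lower
    label first) and the smallest prefix whose cumulative area reaches
    ``keep_area_fraction`` of the total foreground area is retained;
    everything else is deleted.
    """
    if not 0 < keep_area_fraction <= 1:
        raise ParameterError(
            f"keep_area_fraction must be in (0, 1], got {keep_area_fraction}"
        )
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())[1:]
    order = np.lexsort((np.arange(n), -areas))  # area desc, then label asc
    cum = np.cumsum(areas[order])
    total = cum[-1]
    stop = int(np.searchsorted(cum, keep_area_fraction * total, side="left"))
    keep_labels = order[: stop + 1] + 1
    return np.isin(labels, keep_labels)


def segment_roi(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Segment the tissue ROI of a grayscale staining image.

    Composition of the HOS transform, binarization, local-density
    filtering, dilation, hole filling and size-ranked denoising, using the
    parameters in ``cfg``.  An image with no focused texture (e.g. a blank
    frame) yields an empty ROI and a logged warning rather than an error.
    """
    cfg = cfg or PipelineConfig()
    hos = hos_transform(img, cfg.hos_window_radius)
    cand = binarize_hos(hos, cfg.hos_cutoff)
    cand = density_filter(cand, cfg.knn_k, cfg.ld_cutoff)
    if not cand.any():
        logger.warning("candidate mask empty after density filtering; empty ROI")
        return cand
    roi = dilate_mask(cand, cfg.dilate_radius)
    roi = fill_solid(roi)
    roi = denoise_small_objects(roi, cfg.keep_area_fraction)
    return roi
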