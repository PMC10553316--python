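"""Seeded generator of synthetic staining slides with ground-truth masks.

A slide emulates the optical situation the pipeline is built for: a
*focused* tissue section carries sharp per-pixel texture (high local
fourth central moment), while off-target "dirty" stains are *defocused* —
rendered as heavily Gaussian-blurred blobs with no fine texture.  An
optional dark sub-region inside the section plays the positive
calcification stain.  Every slide comes with exact ground-truth masks for
the tissue (ROI), the positive stain, and the noise blobs, so segmentation
and quantification can be scored without any real microscope image.

Three canned scenarios mirror the classic failure modes of intensity-only
thresholding: (1) weak stain plus abundant strong off-tissue dirt, (2) no
stain with dirt blended across the tissue border, and (3) massive strong
stain dominating the section.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError


@dataclass(frozen=True)
class SlideParams:
    """Rendering parameters of a synthetic slide.

    All gray levels are 8-bit.  The tissue object is textured with
    per-pixel uniform noise of ``texture_amplitude`` (its focus
    signature); the background is near-constant; noise blobs are drawn at
    ``noise_gray`` and blurred with ``noise_blur_sigma`` so their local
    fourth moment stays near zero.  ``noise_overlap`` chooses whether
    blobs are placed clear of the tissue (``off_object``) or alpha-blended
    across its border (``blended``, opacity ``blend_alpha`` so the tissue
    texture stays partly visible beneath, as translucent dirt does).
    """

    canvas: tuple = (800, 800)
    object_shape: str = "disk"  # "disk" | "blob"
    object_radius_frac: float = 0.725
    object_gray_mean: int = 180
    texture_amplitude: int = 24
    stain_fraction: float = 0.25
    stain_gray: int = 60
    background_gray: int = 235
    background_amplitude: int = 2
    n_noise_blobs: int = 3
    noise_gray: int = 160
    noise_blob_radius_frac: tuple = (0.05, 0.0875)
    noise_blur_sigma: float = 10.0
    noise_overlap: str = "off_object"  # "off_object" | "blended"
    blend_alpha: float = 0.35

    def __post_init__(self) -> None:
        if not 0 <= self.stain_fraction <= 1:
            raise ParameterError("stain_fraction must be in [0, 1]")
        if self.object_shape not in ("disk", "blob"):
            raise ParameterError(f"unknown object_shape {self.object_shape!r}")
        if self.noise_overlap not in ("off_object", "blended"):
            raise ParameterError(f"unknown noise_overlap {self.noise_overlap!r}")
        if self.noise_blur_sigma < 4:
            raise ParameterError(
                "noise_blur_sigma must be >= 4 px: noise must be defocused, i.e. "
                "blurred well beyond the 1-px tissue texture scale"
            )
        if not 0 < self.blend_alpha < 1:
            raise ParameterError("blend_alpha must be in (0, 1)")


@dataclass
class SyntheticSlide:
    """A rendered slide plus its ground truth.

    ``image`` is (H, W, 3) uint8 RGB; ``roi_truth``/``stain_truth``/
    ``noise_truth`` are boolean masks of the tissue, the positive stain
    and the (pre-blur) noise-blob footprints.
    """

    image: np.ndarray
    roi_truth: np.ndarray
    stain_truth: np.ndarray
    noise_truth: np.ndarray
    params: SlideParams
    seed: int


def _object_mask(params: SlideParams, rng: np.random.Generator):
    h, w = params.canvas
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = params.object_radius_frac * min(h, w) / 2.0
    if 2 * radius > min(h, w):
        raise ParameterError("tissue object larger than the canvas")
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    if params.object_shape == "disk":
        obj = dist <= radius
    else:  # smooth random blob: radius modulated by low-order harmonics
        theta = np.arctan2(dy, dx)
        phases = rng.uniform(0, 2 * np.pi, size=2)
        mod = 1.0 + 0.10 * np.cos(2 * theta + phases[0]) + 0.06 * np.cos(3 * theta + phases[1])
        obj = dist <= radius * np.minimum(mod, (min(h, w) / 2.0 - 1) / radius)
    stain_radius = radius * np.sqrt(params.stain_fraction)
    stain = dist <= stain_radius if params.stain_fraction > 0 else np.zeros_like(obj)
    stain &= obj
    return obj, stain, (cy, cx), radius, dist


def _place_blob(
    rng: np.random.Generator,
    shape: tuple,
    center: tuple,
    obj_radius: float,
    blob_r: float,
    mode: str,
):
    h, w = shape
    cy, cx = center
    if mode == "blended":
        ang = rng.uniform(0, 2 * np.pi)
        return cy + obj_radius * np.sin(ang), cx + obj_radius * np.cos(ang)
    # off_object: rejection-sample a center clear of the tissue; if the
    # geometry leaves no room, fall back to the farthest draw seen
    need = obj_radius + blob_r + 6.0
    best, best_d = None, -1.0
    for _ in range(500):
        by = rng.uniform(blob_r + 2, h - blob_r - 3)
        bx = rng.uniform(blob_r + 2, w - blob_r - 3)
        d = np.hypot(by - cy, bx - cx)
        if d >= need:
            return by, bx
        if d > best_d:
            best, best_d = (by, bx), d
    return best


def generate_slide(params: SlideParams | None = None, seed: int = 0) -> SyntheticSlide:
    """Render one synthetic slide; bit-identical for the same seed and params."""
    params = params or SlideParams()
    rng = np.random.default_rng(seed)
    h, w = params.canvas
    obj, stain, center, radius, dist = _object_mask(params, rng)

    img = params.background_gray + rng.integers(
        -params.background_amplitude, params.background_amplitude + 1, size=(h, w)
    ).astype(np.float64)
    amp = params.texture_amplitude
    img[obj] = params.object_gray_mean + rng.integers(-amp, amp + 1, size=int(obj.sum()))
    if stain.any():
        img[stain] = params.stain_gray + rng.integers(-amp, amp + 1, size=int(stain.sum()))

    alpha = np.zeros((h, w))
    noise_truth = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    opacity = 1.0 if params.noise_overlap == "off_object" else params.blend_alpha
    for _ in range(params.n_noise_blobs):
        blob_r = rng.uniform(*params.noise_blob_radius_frac) * min(h, w)
        pos = _place_blob(rng, (h, w), center, radius, blob_r, params.noise_overlap)
        if pos is None:
            continue
        by, bx = pos
        blob = np.hypot(yy - by, xx - bx) <= blob_r
        alpha[blob] = opacity
        noise_truth |= blob
    if noise_truth.any():
        a = ndimage.gaussian_filter(alpha, params.noise_blur_sigma)
        c = ndimage.gaussian_filter(alpha * params.noise_gray, params.noise_blur_sigma)
        img = (1.0 - a) * img + c

    img8 = np.clip(np.round(img), 0, 255).astype(np.uint8)
    rgb = np.repeat(img8[:, :, None], 3, axis=2)
    return SyntheticSlide(
        image=rgb,
        roi_truth=obj,
        stain_truth=stain,
        noise_truth=noise_truth,
        params=params,
        seed=seed,
    )


def scenario_suite(seed: int = 0, canvas: tuple = (800, 800)) -> list:
    """The three canned difficult scenarios, one slide each.

    1. weak stain (5% of the section) + six strong off-tissue defocused
       dirt blobs whose intensity exceeds the tissue's;
    2. no stain, three large dirt blobs blended across the tissue border;
    3. massive strong stain covering 60% of the section.
    """
    base = SlideParams(canvas=canvas)
    scenarios = [
        dataclasses.replace(
            base,
            stain_fraction=0.05,
            n_noise_blobs=6,
            noise_gray=100,
            noise_blur_sigma=16.0,  # strong dirt must be heavily defocused
            noise_blob_radius_frac=(0.05, 0.0875),
            noise_overlap="off_object",
        ),
        dataclasses.replace(
            base,
            stain_fraction=0.0,
            n_noise_blobs=3,
            noise_gray=80,  # dirt intensity inside the tissue's own range
            noise_blob_radius_frac=(0.125, 0.1625),
            noise_overlap="blended",
        ),
        dataclasses.replace(base, stain_fraction=0.6, n_noise_blobs=2),
    ]
    return [generate_slide(p, seed + i) for i, p in enumerate(scenarios)]


def spike_slide(seed: int = 0, canvas: tuple = (256, 256)):
    """A "strong spike + weak foreground" image for the Triclass baseline.

    A small saturated disk (the spike, gray 255) stretches the histogram
    so that plain Otsu places its threshold above the weak object (gray
    ~100 on a ~60 background) and misses it; Triclass re-thresholds the
    middle class and recovers part of it.

    Returns ``(image, weak_mask, spike_mask)`` with a 2-D uint8 image.
    """
    rng = np.random.default_rng(seed)
    h, w = canvas
    img = 60 + rng.integers(-3, 4, size=(h, w)).astype(np.int64)
    yy, xx = np.mgrid[0:h, 0:w]
    weak_r = 0.179 * min(h, w)  # ~10% of the canvas area
    spike_r = 0.098 * min(h, w)  # ~3%
    weak = np.hypot(yy - 0.5 * h, xx - 0.35 * w) <= weak_r
    spike = np.hypot(yy - 0.5 * h, xx - 0.8 * w) <= spike_r
    img[weak] = 100 + rng.integers(-3, 4, size=int(weak.sum()))
    img[spike] = 255  # saturated strong signal
    return np.clip(img, 0, 255).astype(np.uint8), weak, spike


def sweep_slides(
    stain_fractions=(0.05, 0.1, 0.25, 0.5), seed: int = 0, canvas: tuple = (800, 800)
) -> list:
    """One default slide per stain fraction (for parameter-recovery checks)."""
    out = []
    for i, f in enumerate(stain_fractions):
        p = SlideParams(canvas=canvas, stain_fraction=float(f))
        out.append(generate_slide(p, seed + i))
    return out


def benchmark_batch(n: int = 50, seed: int = 0, canvas: tuple = (800, 800)) -> list:
    """A batch of slides with varied geometry and stain load for self-benchmarking."""
    rng = np.random.default_rng(seed)
    slides = []
    for i in range(n):
        p = SlideParams(
            canvas=canvas,
            object_radius_frac=float(rng.uniform(0.65, 0.75)),
            stain_fraction=float(rng.uniform(0.05, 0.6)),
            n_noise_blobs=int(rng.integers(1, 5)),
        )
        slides.append(generate_slide(p, seed=int(rng.integers(0, 2**31 - 1))))
    return slides
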