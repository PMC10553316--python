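"""Raster image I/O and grayscale conversion.

Images are held as plain numpy arrays, following the scikit-image
convention: an RGB image is ``(H, W, 3) uint8``, a grayscale image is
``(H, W) uint8`` and a mask is ``(H, W) bool``.  Coordinates are row-major
with the origin at the top-left, 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import FormatError, ImageIOError

#: BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an ``(H, W, 3) uint8`` RGB array.

    An alpha channel is discarded; 8/16-bit grayscale images are expanded
    to three identical channels; 16-bit inputs are rescaled to 8 bits
    (divide by 257, round) so that fixed 8-bit thresholds keep their
    meaning.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("RGB", "RGBA", "L", "LA", "P", "1"):
                rgb = np.asarray(im.convert("RGB"))
            elif mode in ("I;16", "I;16B", "I;16L", "I"):
                arr = np.asarray(im, dtype=np.float64)
                if arr.max() > 65535 or arr.min() < 0:
                    raise FormatError(f"{path}: unsupported bit depth (mode {mode})")
                gray = np.round(arr / 257.0).clip(0, 255).astype(np.uint8)
                rgb = np.stack([gray] * 3, axis=-1)
            else:
                raise FormatError(f"{path}: unsupported image mode {mode!r}")
    except UnidentifiedImageError as exc:
        raise ImageIOError(f"cannot decode image file {path}: {exc}") from exc
    except FileNotFoundError as exc:
        raise ImageIOError(f"image file not found: {path}") from exc
    except OSError as exc:  # truncated/corrupt data surfaces here from PIL
        raise ImageIOError(f"cannot read image file {path}: {exc}") from exc
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"{path}: expected 3 channels, got shape {rgb.shape}")
    return np.ascontiguousarray(rgb, dtype=np.uint8)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale with BT.601 luma weights.

    ``gray = round(0.299 R + 0.587 G + 0.114 B)`` (round half up), so a
    gray triple ``(v, v, v)`` maps exactly to ``v``.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected an (H, W, 3) RGB array, got shape {img.shape}")
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    luma = img.astype(np.float64) @ w
    return np.floor(luma + 0.5).clip(0, 255).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground 255, background 0)."""
    mask = np.asarray(mask, dtype=bool)
    arr = np.where(mask, np.uint8(255), np.uint8(0))
    try:
        Image.fromarray(arr, mode="L").save(Path(path), format="PNG")
    except OSError as exc:
        raise ImageIOError(f"cannot write mask to {path}: {exc}") from exc


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG written by :func:`write_mask` back to booleans."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageIOError(f"cannot read mask file {path}: {exc}") from exc
    return arr > 127
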