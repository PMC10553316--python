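"""Positive-stain identification and per-image quantitative readouts.

The quantification convention mirrors the manual ImageJ procedure used as
the benchmark: the 8-bit grayscale is *inverted* (darker stain => higher
value), positive staining is identified by an inclusive threshold on the
inverted intensity inside the ROI, and the intensity percentage is
normalized by the maximum possible ROI intensity (ROI area x 255).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MaskConsistencyError, ParameterError


def invert_intensity(img: np.ndarray) -> np.ndarray:
    """Invert an 8-bit grayscale image: ``v -> 255 - v`` (an involution)."""
    img = np.asarray(img, dtype=np.uint8)
    return (255 - img.astype(np.int16)).astype(np.uint8)


def positive_stain_mask(
    inv: np.ndarray, roi: np.ndarray, stain_threshold: int
) -> np.ndarray:
    """Positive staining: ROI pixels with inverted intensity >= threshold."""
    if not 0 <= stain_threshold <= 255:
        raise ParameterError(f"stain_threshold must be in [0, 255], got {stain_threshold}")
    inv = np.asarray(inv)
    roi = np.asarray(roi, dtype=bool)
    return roi & (inv >= stain_threshold)


@dataclass
class QuantResult:
    """Per-image readouts.

    Areas are pixel counts; intensities are exact integer sums of the
    inverted 8-bit values; the two percentages are
    ``100 * stained_area / total_area`` and
    ``100 * stained_intensity / (total_area * 255)``.
    """

    total_area: int
    total_intensity: int
    stained_area: int
    stained_intensity: int
    stained_area_pct: float
    stain_intensity_pct: float
    warnings: tuple = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "total_area": self.total_area,
            "total_intensity": self.total_intensity,
            "stained_area": self.stained_area,
            "stained_intensity": self.stained_intensity,
            "stained_area_pct": round(self.stained_area_pct, 4),
            "stain_intensity_pct": round(self.stain_intensity_pct, 4),
            "warnings": ";".join(self.warnings),
        }


def quantify(inv: np.ndarray, roi: np.ndarray, stain: np.ndarray) -> QuantResult:
    """Compute the four readouts and derived percentages.

    ``inv`` is the inverted grayscale, ``roi`` the tissue mask and
    ``stain`` the positive-stain mask (must be contained in ``roi``).
    All sums use exact integer arithmetic.  An empty ROI yields all-zero
    readouts with a warning flag.
    """
    inv = np.asarray(inv)
    roi = np.asarray(roi, dtype=bool)
    stain = np.asarray(stain, dtype=bool)
    if inv.shape != roi.shape or roi.shape != stain.shape:
        raise MaskConsistencyError(
            f"shape mismatch: image {inv.shape}, roi {roi.shape}, stain {stain.shape}"
        )
    if (stain & ~roi).any():
        raise MaskConsistencyError("stain mask is not contained in the ROI mask")
    total_area = int(roi.sum())
    if total_area == 0:
        return QuantResult(0, 0, 0, 0, 0.0, 0.0, warnings=("empty_roi",))
    inv64 = inv.astype(np.int64)
    total_intensity = int(inv64[roi].sum())
    stained_area = int(stain.sum())
    stained_intensity = int(inv64[stain].sum())
    return QuantResult(
        total_area=total_area,
        total_intensity=total_intensity,
        stained_area=stained_area,
        stained_intensity=stained_intensity,
        stained_area_pct=100.0 * stained_area / total_area,
        stain_intensity_pct=100.0 * stained_intensity / (total_area * 255),
    )
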