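"""Pipeline configuration.

All tunable parameters of the segmentation/quantification pipeline live in
one flat :class:`PipelineConfig`.  A config can be round-tripped through a
plain ``key=value`` text file so that a batch run is fully described by one
small artifact, and :meth:`PipelineConfig.config_hash` gives a short digest
that is echoed into every report row for exact-rerun checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

from .errors import ParameterError

#: Positive-staining thresholds (on the inverted 8-bit grayscale) for the
#: two calcification assays: Alizarin Red and von Kossa.
STAIN_PRESETS = {"AR": 100, "VK": 140}


@dataclass
class PipelineConfig:
    """Parameters of the staining-quantification pipeline.

    Parameters
    ----------
    hos_window_radius:
        Half-width of the square neighborhood used for the local
        fourth-central-moment (HOS) transform; the window is
        ``(2r+1) x (2r+1)`` pixels.
    hos_cutoff:
        Binarization cutoff applied to the HOS map (0-255, inclusive ``>=``).
    knn_k:
        Number of nearest neighbors used for the local-density score of
        each candidate foreground pixel.
    ld_cutoff:
        Minimum local density ``LD`` for a candidate pixel to survive the
        density filter.  A uniformly spaced cluster has ``LD = exp(-1)``;
        the default 0.3 sits below that bound so coherent regions always
        pass (see :func:`stainquant.segment.local_density` for the range
        LD can actually take).
    dilate_radius:
        Disk radius (pixels) of the single morphological dilation pass.
    keep_area_fraction:
        Fraction of total foreground *area* retained by the size-ranked
        denoising step (largest objects first).
    stain_threshold:
        Positive-stain cutoff on the inverted grayscale inside the ROI.
        ``None`` resolves from ``stain_preset``.
    stain_preset:
        ``"AR"``, ``"VK"`` or ``"custom"`` (the latter requires an explicit
        ``stain_threshold``).
    """

    hos_window_radius: int = 2
    hos_cutoff: float = 20.0
    knn_k: int = 10
    ld_cutoff: float = 0.3
    dilate_radius: int = 3
    keep_area_fraction: float = 0.95
    stain_threshold: int | None = None
    stain_preset: str = "AR"

    def __post_init__(self) -> None:
        if self.stain_preset not in (*STAIN_PRESETS, "custom"):
            raise ParameterError(
                f"unknown stain preset {self.stain_preset!r}; "
                f"expected one of {sorted(STAIN_PRESETS)} or 'custom'"
            )
        if self.stain_threshold is None:
            if self.stain_preset == "custom":
                raise ParameterError("stain_preset='custom' needs an explicit stain_threshold")
            self.stain_threshold = STAIN_PRESETS[self.stain_preset]
        if not 0 <= self.stain_threshold <= 255:
            raise ParameterError(f"stain_threshold must be in [0, 255], got {self.stain_threshold}")
        if not 0 <= self.hos_cutoff <= 255:
            raise ParameterError(f"hos_cutoff must be in [0, 255], got {self.hos_cutoff}")
        if self.hos_window_radius < 1:
            raise ParameterError("hos_window_radius must be >= 1")
        if self.knn_k < 1:
            raise ParameterError("knn_k must be >= 1")
        if not 0 < self.keep_area_fraction <= 1:
            raise ParameterError(
                f"keep_area_fraction must be in (0, 1], got {self.keep_area_fraction}"
            )
        if self.dilate_radius < 0:
            raise ParameterError("dilate_radius must be >= 0")
        if self.ld_cutoff < 0:
            raise ParameterError("ld_cutoff must be >= 0")

    @classmethod
    def with_preset(cls, preset: str, **overrides) -> "PipelineConfig":
        """Build a config for a named stain preset (``AR`` or ``VK``)."""
        return cls(stain_preset=preset, **overrides)

    # -- flat key=value file round-trip -----------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key=value`` config file (``#`` starts a comment)."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ParameterError(f"{path}:{lineno}: unknown parameter {key!r}")
            if key == "stain_preset":
                values[key] = raw
            elif key in ("hos_window_radius", "knn_k", "dilate_radius", "stain_threshold"):
                values[key] = int(raw)
            else:
                values[key] = float(raw)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in sorted(dataclasses.asdict(self).items())]
        Path(path).write_text("\n".join(lines) + "\n")

    def config_hash(self) -> str:
        """Short stable digest of all parameter values."""
        blob = ";".join(f"{k}={v}" for k, v in sorted(dataclasses.asdict(self).items()))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
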