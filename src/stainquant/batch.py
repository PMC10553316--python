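"""Batch orchestration: run the pipeline over a directory, report, compare.

A batch run applies one method (``sq``, ``otsu`` or ``triclass``) and one
shared config to every image in a directory, writes per-image ROI and
stain masks plus a consolidated CSV report, and can then be compared
against a benchmark report with the agreement statistics of
:mod:`stainquant.evalstats`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import evalstats
from .baselines import otsu_threshold, triclass_threshold
from .config import PipelineConfig
from .errors import MaskConsistencyError, ParameterError, StainQuantError
from .imgio import read_image, to_grayscale, write_mask
from .quantify import invert_intensity, positive_stain_mask, quantify
from .segment import segment_roi

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

METHODS = ("sq", "otsu", "triclass")

#: Order of the per-image CSV columns (timestamp last so that determinism
#: of everything else is testable by dropping one column).
REPORT_COLUMNS = [
    "image_id",
    "method",
    "config_hash",
    "total_area",
    "total_intensity",
    "stained_area",
    "stained_intensity",
    "stained_area_pct",
    "stain_intensity_pct",
    "warnings",
    "timestamp",
]

#: Metrics compared between two reports, Table-style: the four direct
#: readouts plus the two derived proportions.
DIRECT_METRICS = ["total_area", "total_intensity", "stained_area", "stained_intensity"]
PROP_METRICS = {
    "stained_area_prop": ("stained_area", "total_area"),
    "stained_intensity_prop": ("stained_intensity", "total_intensity"),
}


@dataclass
class BatchReport:
    """Result of one batch run: the per-image rows and bookkeeping."""

    rows: pd.DataFrame
    skipped: list
    config_hash: str
    csv_path: Path | None = None


def segment_with_method(gray: np.ndarray, cfg: PipelineConfig, method: str) -> np.ndarray:
    """ROI mask for one grayscale image under the chosen method.

    The intensity-only baselines threshold the *inverted* grayscale and
    take the upper class, so foreground means "darker than background" for
    every method.
    """
    if method == "sq":
        return segment_roi(gray, cfg)
    inv = invert_intensity(gray)
    if method == "otsu":
        return otsu_threshold(inv).mask
    if method == "triclass":
        return triclass_threshold(inv).mask
    raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")


def process_image(gray: np.ndarray, cfg: PipelineConfig, method: str = "sq"):
    """Run segmentation + stain identification + quantification on one image.

    Returns ``(roi_mask, stain_mask, QuantResult)``.
    """
    roi = segment_with_method(gray, cfg, method)
    inv = invert_intensity(gray)
    stain = positive_stain_mask(inv, roi, cfg.stain_threshold)
    return roi, stain, quantify(inv, roi, stain)


def run_batch(
    input_dir: str | Path,
    cfg: PipelineConfig | None = None,
    method: str = "sq",
    out_dir: str | Path | None = None,
    save_masks: bool = True,
) -> BatchReport:
    """Process every image in ``input_dir`` under one shared config.

    Corrupt images are logged and skipped, not fatal.  Files are processed
    in lexicographic filename order; results do not depend on that order.
    """
    cfg = cfg or PipelineConfig()
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")
    input_dir = Path(input_dir)
    files = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not files:
        raise ParameterError(f"no readable images in {input_dir}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    chash = cfg.config_hash()
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    rows, skipped = [], []
    for path in files:
        t0 = time.perf_counter()
        try:
            gray = to_grayscale(read_image(path))
        except StainQuantError as exc:
            logger.error("skipping %s: %s", path.name, exc)
            skipped.append(path.name)
            continue
        roi, stain, q = process_image(gray, cfg, method)
        if "empty_roi" in q.warnings:
            logger.warning("%s: empty ROI", path.name)
        if save_masks and out_dir is not None:
            write_mask(roi, out_dir / f"{path.stem}_roi.png")
            write_mask(stain, out_dir / f"{path.stem}_stain.png")
        row = {"image_id": path.stem, "method": method, "config_hash": chash}
        row.update(q.as_dict())
        row["timestamp"] = stamp
        rows.append(row)
        logger.info(
            "%s: roi=%d px stain=%d px (%.2f s)",
            path.stem,
            q.total_area,
            q.stained_area,
            time.perf_counter() - t0,
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    csv_path = None
    if out_dir is not None:
        csv_path = out_dir / "report.csv"
        df.to_csv(csv_path, index=False)
    return BatchReport(rows=df, skipped=skipped, config_hash=chash, csv_path=csv_path)


def _load_report(src) -> pd.DataFrame:
    if isinstance(src, pd.DataFrame):
        return src
    return pd.read_csv(src)


def compare_batches(report_a, report_b, margin: float = evalstats.DEFAULT_MARGIN):
    """Agreement statistics between two batch reports, joined on image_id.

    ``report_a`` is the measurement under test (x), ``report_b`` the
    benchmark (y).  Returns ``(DataFrame, dict)``: one row / entry per
    metric with Pearson's r (direct readouts only), mean relative
    difference in percent with 95% CI, the TOST equivalence p-value and
    the success rate at the margin.
    """
    a = _load_report(report_a)
    b = _load_report(report_b)
    ids_a, ids_b = set(a["image_id"]), set(b["image_id"])
    if ids_a != ids_b:
        raise MaskConsistencyError(
            f"image_id mismatch between reports: only in A={sorted(ids_a - ids_b)}, "
            f"only in B={sorted(ids_b - ids_a)}"
        )
    merged = a.merge(b, on="image_id", suffixes=("_x", "_y")).sort_values("image_id")

    stats_by_metric: dict = {}
    rows = []
    for metric in DIRECT_METRICS:
        cs = evalstats.compare_measurements(
            merged[f"{metric}_x"].to_numpy(float),
            merged[f"{metric}_y"].to_numpy(float),
            margin,
        )
        stats_by_metric[metric] = cs
    for name, (num, den) in PROP_METRICS.items():
        xp = merged[f"{num}_x"].to_numpy(float) / merged[f"{den}_x"].to_numpy(float)
        yp = merged[f"{num}_y"].to_numpy(float) / merged[f"{den}_y"].to_numpy(float)
        cs = evalstats.compare_measurements(xp, yp, margin)
        stats_by_metric[name] = cs
    for name, cs in stats_by_metric.items():
        rows.append(
            {
                "metric": name,
                "n": cs.n,
                "pearson_r": cs.pearson_r if name in DIRECT_METRICS else np.nan,
                "mean_diff_pct": cs.mean_diff_pct,
                "ci_low_pct": cs.ci95[0],
                "ci_high_pct": cs.ci95[1],
                "p_equiv": cs.p_equiv,
                "success_rate": cs.success_rate,
                "n_flagged": cs.n_flagged,
            }
        )
    return pd.DataFrame(rows), stats_by_metric
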