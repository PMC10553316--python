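"""Batch-level agreement statistics between two measurement sets.

Given per-image readouts from the pipeline (x) and from a benchmark (y),
agreement is summarized by Pearson's r, the relative difference
``(x - y) / y`` (internally a fraction; reported as a percentage), a
t-based 95% CI of its mean, an equivalence test of ``|mean| < 0.05``
formalized as two one-sided t-tests (TOST), and the success rate — the
fraction of images whose absolute relative difference is below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

#: Equivalence margin on fractional differences (5%).
DEFAULT_MARGIN = 0.05


@dataclass
class ComparisonStats:
    """Agreement summary for one metric across a batch of n images."""

    n: int
    pearson_r: float | None
    mean_diff_pct: float
    ci95: tuple
    p_equiv: float
    success_rate: float
    n_flagged: int = 0


def pearson_r(x, y) -> float:
    """Pearson's correlation coefficient.

    ``r = (N Σxy − Σx Σy) / sqrt([N Σx² − (Σx)²][N Σy² − (Σy)²])``
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ParameterError("need at least 3 pairs")
    sx, sy = x.sum(), y.sum()
    den2 = (n * (x * x).sum() - sx * sx) * (n * (y * y).sum() - sy * sy)
    if den2 <= 0:
        raise ParameterError("correlation undefined for a constant vector")
    return float((n * (x * y).sum() - sx * sy) / np.sqrt(den2))


def diff_pct(x: float, y: float) -> float:
    """Relative difference of x against benchmark y, as a percentage."""
    if y == 0:
        raise ZeroDivisionError("benchmark value is zero; difference undefined")
    return 100.0 * (x - y) / y


def prop_diff_pct(x_stained: float, x_total: float, y_stained: float, y_total: float) -> float:
    """Percentage difference of the stained/total proportions of two readouts."""
    if x_total == 0 or y_total == 0:
        raise ZeroDivisionError("total readout is zero; proportion undefined")
    x_prop = x_stained / x_total
    y_prop = y_stained / y_total
    if y_prop == 0:
        raise ZeroDivisionError("benchmark proportion is zero; difference undefined")
    return 100.0 * (x_prop - y_prop) / y_prop


def equivalence_test(diffs, margin: float = DEFAULT_MARGIN):
    """Mean, t-based 95% CI and TOST equivalence p-value of fractional diffs.

    Null hypothesis: the absolute true mean exceeds ``margin``.  The
    returned ``p_equiv`` is the larger of the two one-sided one-sample
    t-test p-values against the bounds ``-margin`` and ``+margin``;
    ``p_equiv < 0.05`` concludes equivalence within the margin.  A
    zero-variance sample is resolved by exact comparison of the mean to
    the bounds.
    """
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim != 1 or len(d) < 3:
        raise ParameterError("need at least 3 differences")
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        p = 0.0 if abs(mean) < margin else 1.0
        return mean, (mean, mean), p
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    ci = (mean - tcrit * se, mean + tcrit * se)
    t_lower = (mean + margin) / se  # H0: mu <= -margin vs H1: mu > -margin
    t_upper = (mean - margin) / se  # H0: mu >= +margin vs H1: mu < +margin
    p_lower = float(stats.t.sf(t_lower, n - 1))
    p_upper = float(stats.t.cdf(t_upper, n - 1))
    return mean, ci, max(p_lower, p_upper)


def success_rate(diffs, cutoff: float = DEFAULT_MARGIN) -> float:
    """Fraction of images with absolute fractional difference below cutoff."""
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim != 1 or len(d) == 0:
        raise ParameterError("need at least 1 difference")
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    return float((np.abs(d) < cutoff).mean())


def compare_measurements(x, y, margin: float = DEFAULT_MARGIN) -> ComparisonStats:
    """Full agreement summary of measurement vector x against benchmark y.

    Rows with a zero benchmark are flagged and excluded from the
    difference statistics (but counted in ``n_flagged``); Pearson's r uses
    all rows.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = y != 0
    n_flagged = int((~ok).sum())
    diffs = (x[ok] - y[ok]) / y[ok]
    try:
        r = pearson_r(x, y)
    except ParameterError:
        r = None
    mean, ci, p = equivalence_test(diffs, margin)
    return ComparisonStats(
        n=len(x),
        pearson_r=r,
        mean_diff_pct=100.0 * mean,
        ci95=(100.0 * ci[0], 100.0 * ci[1]),
        p_equiv=p,
        success_rate=success_rate(diffs, margin),
        n_flagged=n_flagged,
    )
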