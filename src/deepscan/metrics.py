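"""Evaluation and vessel-noise exposure metrics.

Accuracy against manual labels is the per-file proportion
rho = (N - n_err)/N, where an error is either a false vessel detection or a
missed vessel. Exposure metrics summarize each detected segment relative to
the file's median SPL: Peak Difference (max above median), Mean Difference
(mean of above-median values minus median) and Area Size — the trapezoidal
integral of the above-median SPL excess, the paper-and-pencil proxy for the
sound exposure level (SEL) of the pass-by. Cumulative SEL per station sums
those areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import LabelTable
from .energy import CandidateSegment, FrameEnergySeries
from .scanner import DetectionRecord, FileResult

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "SELMetrics",
    "accuracy",
    "evaluate",
    "sel_metrics",
    "cumulative_sel",
    "detection_timeseries",
]


@dataclass
class EvaluationResult:
    """Per-file confusion rollup and the detection accuracy rho."""

    n_total: int
    n_error: int
    rho: float
    false_positives: int
    false_negatives: int


@dataclass
class SELMetrics:
    """Above-median SPL summary of one detected segment."""

    peak_difference: float
    mean_difference: float
    area_size: float  # dB*s; the SEL proxy
    segment: tuple[float, float]


def accuracy(n_total: int, n_error: int) -> float:
    """Detection accuracy rho = (N - n_err) / N, exact rational arithmetic."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_error <= n_total):
        raise ValueError("need 0 <= n_error <= n_total")
    return float(Fraction(n_total - n_error, n_total))


def evaluate(results: Sequence[FileResult], labels: LabelTable) -> EvaluationResult:
    """Compare per-file decisions to manual labels.

    An error is marked when the scanner flagged a vessel in a file the
    reviewer did not (false positive), or missed one the reviewer saw
    (false negative). Every scanned file must be labeled.
    """
    fp = fn = 0
    for r in results:
        if r.source_id not in labels:
            raise KeyError(f"no manual label for {r.source_id!r}")
        truth = labels[r.source_id]
        if r.vessel_present and not truth:
            fp += 1
        elif truth and not r.vessel_present:
            fn += 1
    n = len(results)
    n_err = fp + fn
    return EvaluationResult(
        n_total=n,
        n_error=n_err,
        rho=accuracy(n, n_err),
        false_positives=fp,
        false_negatives=fn,
    )


def sel_metrics(
    series: FrameEnergySeries,
    segment: CandidateSegment,
    file_wide_mean: bool = False,
) -> SELMetrics:
    """Peak/Mean Difference and trapezoidal Area Size for one segment.

    Below-median excursions are clamped to zero: the area measures noise
    energy added above the soundscape's median level. A segment with no
    frame above the median yields (0, 0, 0). With ``file_wide_mean`` the
    Mean Difference averages all above-median frames in the file rather
    than only those inside the segment.
    """
    in_seg = (series.frame_centers >= segment.start) & (
        series.frame_centers <= segment.end
    )
    if not in_seg.any():
        raise ValueError("segment contains no SPL frames")
    med = series.spl_median
    seg_spl = series.spl[in_seg]
    excess = np.maximum(seg_spl - med, 0.0)
    if not (seg_spl > med).any():
        return SELMetrics(0.0, 0.0, 0.0, (segment.start, segment.end))
    peak = float(seg_spl.max() - med)
    pool = series.spl if file_wide_mean else seg_spl
    above = pool[pool > med]
    mean = float(above.mean() - med)
    area = float(np.trapezoid(excess, dx=series.frame_length))
    return SELMetrics(peak, mean, area, (segment.start, segment.end))


def sel_metrics_linear(series: FrameEnergySeries, segment: CandidateSegment) -> float:
    """Linear-energy SEL alternative: trapezoidal integral of 10^(excess/10).

    Provided alongside the dB*s Area Size because equating that area with an
    SEL is a heuristic; integrating linear relative power is the physically
    additive variant. Returns the integral in (relative power)*s.
    """
    in_seg = (series.frame_centers >= segment.start) & (
        series.frame_centers <= segment.end
    )
    excess = np.maximum(series.spl[in_seg] - series.spl_median, 0.0)
    return float(np.trapezoid(10.0 ** (excess / 10.0) - 1.0, dx=series.frame_length))


def cumulative_sel(
    detections: Iterable[tuple[DetectionRecord, SELMetrics]],
    station_key: Callable[[DetectionRecord], str] = lambda d: d.source_id.split("_")[0],
) -> dict[str, float]:
    """Sum Area Size per station over positive detections (SELcum)."""
    out: dict[str, float] = {}
    for det, m in detections:
        k = station_key(det)
        out[k] = out.get(k, 0.0) + m.area_size
    return out


def detection_timeseries(
    file_results: Sequence[FileResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count positive files per (date, hour-of-day) cell.

    Returns ``(counts, coverage)`` DataFrames indexed by date with hour
    columns 0–23; ``coverage`` counts files recorded in each cell so that
    empty cells are distinguishable from zero-detection cells. Files without
    a timestamp are excluded with a warning.
    """
    rows = []
    for r in file_results:
        if r.start_time is None:
            logger.warning("%s has no timestamp; excluded from time series",
                           r.source_id)
            continue
        rows.append(
            {
                "date": r.start_time.date(),
                "hour": r.start_time.hour,
                "positive": int(r.vessel_present),
            }
        )
    hours = list(range(24))
    if not rows:
        empty = pd.DataFrame(columns=hours)
        return empty, empty.copy()
    df = pd.DataFrame(rows)
    dates = sorted(df["date"].unique())
    counts = (
        df.pivot_table(index="date", columns="hour", values="positive",
                       aggfunc="sum", fill_value=0)
        .reindex(index=dates, columns=hours, fill_value=0)
    )
    coverage = (
        df.pivot_table(index="date", columns="hour", values="positive",
                       aggfunc="count", fill_value=0)
        .reindex(index=dates, columns=hours, fill_value=0)
    )
    return counts, coverage
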