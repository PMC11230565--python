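"""Deep Scanning orchestration: clean -> SPL gate -> feature -> classify.

Per file the pipeline is: optional snap cleaning, framed broadband SPL with
file-wide median, candidate-segment gating, one feature window per candidate
(tiled every Delta_t/2 for segments longer than Delta_t, max score taken),
and a neural-network score per candidate. A positive anywhere in the file
marks the file vessel-positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import ClassifierModel, predict
from .cleaning import remove_snaps
from .config import PipelineConfig
from .core_io import AudioRecording, CalibrationSpec, read_wav
from .energy import CandidateSegment, candidate_segments, spl_series
from .features import extract_feature

logger = logging.getLogger(__name__)

__all__ = ["DetectionRecord", "FileResult", "scan_file", "scan_batch",
           "events_frame", "files_frame"]


@dataclass
class DetectionRecord:
    """One classified candidate segment."""

    source_id: str
    event_time: float
    score: float
    decision: bool
    segment: CandidateSegment
    peak_excess_db: float
    mean_excess_db: float


@dataclass
class FileResult:
    """Per-file rollup: the OR of candidate decisions."""

    source_id: str
    vessel_present: bool
    detections: list[DetectionRecord] = field(default_factory=list)
    spl_median: float = float("nan")
    start_time: object = None
    error: str | None = None


def _window_centers(seg: CandidateSegment, delta_t: float, duration: float) -> list[float]:
    centers = [seg.peak_time]
    if seg.duration > delta_t:
        tile = np.arange(seg.start + delta_t / 2.0, seg.end - delta_t / 2.0 + 1e-9,
                         delta_t / 2.0)
        centers.extend(float(t) for t in tile)
    return [min(max(c, 0.0), duration) for c in centers]


def scan_file(
    rec: AudioRecording,
    model: ClassifierModel,
    cal: CalibrationSpec,
    config: PipelineConfig,
) -> FileResult:
    """Run the two-stage scan on one recording."""
    if config.cleaning_enabled:
        rec = remove_snaps(rec, config.cleaning)
    series = spl_series(rec, cal, config.spl)
    segments = candidate_segments(
        series,
        margin=config.gate_margin,
        min_duration=config.gate_min_duration,
        merge_gap=config.gate_merge_gap,
    )
    detections: list[DetectionRecord] = []
    for seg in segments:
        scores = [
            predict(model, extract_feature(rec, c, config.features))
            for c in _window_centers(seg, config.features.delta_t, rec.duration)
        ]
        score = float(max(scores))
        in_seg = (series.frame_centers >= seg.start) & (series.frame_centers <= seg.end)
        seg_spl = series.spl[in_seg]
        above = seg_spl[seg_spl > series.spl_median]
        mean_excess = float(above.mean() - series.spl_median) if above.size else 0.0
        detections.append(
            DetectionRecord(
                source_id=rec.source_id,
                event_time=seg.peak_time,
                score=score,
                decision=score >= config.score_threshold,
                segment=seg,
                peak_excess_db=seg.peak_excess,
                mean_excess_db=mean_excess,
            )
        )
    return FileResult(
        source_id=rec.source_id,
        vessel_present=any(d.decision for d in detections),
        detections=detections,
        spl_median=series.spl_median,
        start_time=rec.start_time,
    )


def scan_batch(
    paths: list,
    model: ClassifierModel,
    cal: CalibrationSpec,
    config: PipelineConfig,
) -> list[FileResult]:
    """Scan a batch of WAV paths (or in-memory recordings), order-stable.

    A failure on one file is logged and recorded as an error row; it never
    aborts the batch.
    """
    if not paths:
        raise ValueError("empty path list")
    results: list[FileResult] = []
    for p in paths:
        try:
            rec = p if isinstance(p, AudioRecording) else read_wav(p)
            results.append(scan_file(rec, model, cal, config))
        except Exception as exc:  # noqa: BLE001 - isolation contract
            name = p.source_id if isinstance(p, AudioRecording) else Path(p).name
            logger.error("scan failed for %s: %s", name, exc)
            results.append(FileResult(source_id=name, vessel_present=False,
                                      error=str(exc)))
    return results


def events_frame(results: list[FileResult]) -> pd.DataFrame:
    """Per-event table (``events.csv`` layout)."""
    rows = [
        {
            "source": d.source_id,
            "event_time_s": d.event_time,
            "score": d.score,
            "decision": int(d.decision),
            "peak_excess_db": d.peak_excess_db,
        }
        for r in results
        for d in r.detections
    ]
    return pd.DataFrame(rows, columns=["source", "event_time_s", "score",
                                       "decision", "peak_excess_db"])


def files_frame(results: list[FileResult]) -> pd.DataFrame:
    """Per-file table (``files.csv`` layout)."""
    return pd.DataFrame(
        [
            {
                "source": r.source_id,
                "vessel_present": int(r.vessel_present),
                "n_detections": len(r.detections),
                "spl_median_db": r.spl_median,
                "error": r.error or "",
            }
            for r in results
        ]
    )
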