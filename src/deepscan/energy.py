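"""Stage 1: framed broadband SPL and median gating.

Each recording is divided into consecutive non-overlapping frames (default
0.5 s). Per frame, a Hann-tapered single-sided power spectrum is summed over
the analysis band and converted to SPL re 1 uPa via the calibration
correction S = M_h + G + 20*log10(1/V_ADC):

    SPL = 10*log10( sum_{f_low..f_high} P_ss(f) / B ) - S

The Hann taper is normalized by its mean (coherent-gain correction) before
the DFT, so that after the division by the window's power bandwidth factor
B (= 1.5 for Hann) both tonal and noise-like signals are amplitude-accurate.
Frames whose SPL exceeds the file-wide median by a configurable margin are
merged into candidate segments for stage 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import hann

from .core_io import AudioRecording, CalibrationSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SplParams",
    "FrameEnergySeries",
    "CandidateSegment",
    "correction_factor",
    "frame_spl",
    "spl_series",
    "candidate_segments",
]

#: Sentinel SPL for an all-zero frame.
SILENT_SPL = -np.inf


@dataclass(frozen=True)
class SplParams:
    """Framing and band parameters for the SPL computation.

    ``band_low``/``band_high`` bound the summed band in Hz (the broadband
    default is 1–40,000 Hz; the upper edge is clipped to Nyquist at read
    time). ``bandwidth_factor`` is the window's power bandwidth B (1.5 for
    the Hann taper used here).
    """

    frame_length: float = 0.5
    band_low: float = 1.0
    band_high: float = 40_000.0
    window: str = "hann"
    bandwidth_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.frame_length <= 0:
            raise ValueError("frame_length must be positive")
        if not (0 <= self.band_low < self.band_high):
            raise ValueError("need 0 <= band_low < band_high")
        if self.bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be positive")
        if self.window != "hann":
            raise ValueError("only the Hann taper is supported")


@dataclass
class FrameEnergySeries:
    """Per-frame SPL values for one file, with the file-wide median."""

    frame_centers: np.ndarray
    spl: np.ndarray
    spl_median: float
    frame_length: float

    def __len__(self) -> int:
        return len(self.spl)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"frame_center_s": self.frame_centers, "spl_db": self.spl}
        ).to_csv(path, index=False)


@dataclass
class CandidateSegment:
    """A contiguous above-median region flagged for stage-2 inspection."""

    start: float
    end: float
    peak_time: float
    peak_excess: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError("segment must have start < end")
        if not (self.start <= self.peak_time <= self.end):
            raise ValueError("peak_time must lie within the segment")

    @property
    def duration(self) -> float:
        return self.end - self.start


def correction_factor(cal: CalibrationSpec) -> float:
    """Calibration correction S = M_h + G + 20*log10(1/V_ADC), in dB."""
    if cal.v_adc <= 0:
        raise ValueError("v_adc must be positive")
    return cal.hydrophone_sensitivity + cal.gain + 20.0 * np.log10(1.0 / cal.v_adc)


def _band_power(frames: np.ndarray, sample_rate: float, params: SplParams) -> np.ndarray:
    """Band-summed single-sided power of Hann-tapered frames (last axis = time)."""
    n = frames.shape[-1]
    w = hann(n, sym=False)
    w = w / w.mean()  # coherent-gain normalization; B then corrects noise power
    spec = rfft(frames * w, axis=-1)
    pss = 2.0 * np.abs(spec / n) ** 2
    pss[..., 0] /= 2.0
    if n % 2 == 0:
        pss[..., -1] /= 2.0
    f = rfftfreq(n, d=1.0 / sample_rate)
    mask = (f >= params.band_low) & (f <= min(params.band_high, sample_rate / 2.0))
    return pss[..., mask].sum(axis=-1) / params.bandwidth_factor


def frame_spl(
    frame: np.ndarray,
    sample_rate: float,
    cal: CalibrationSpec,
    params: SplParams = SplParams(),
) -> float:
    """Broadband SPL (dB re 1 uPa) of a single frame.

    An all-zero frame returns ``-inf`` with a warning rather than raising.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size < 2:
        raise ValueError("frame must contain at least 2 samples")
    total = _band_power(frame[np.newaxis, :], sample_rate, params)[0]
    if total <= 0.0:
        logger.warning("all-zero/empty-band frame; SPL is -inf")
        return SILENT_SPL
    return 10.0 * np.log10(total) - correction_factor(cal)


def spl_series(
    rec: AudioRecording,
    cal: CalibrationSpec,
    params: SplParams = SplParams(),
) -> FrameEnergySeries:
    """Frame a recording and compute per-frame SPL plus the file-wide median.

    Frames are consecutive and non-overlapping; a final partial frame is
    dropped. The median is computed over the entire file, as the gating
    reference for candidate selection.
    """
    frame_samples = int(round(params.frame_length * rec.sample_rate))
    if frame_samples < 2 or len(rec) < frame_samples:
        raise ValueError(
            f"recording ({len(rec)} samples) shorter than one "
            f"{params.frame_length} s frame"
        )
    n_frames = len(rec) // frame_samples
    frames = rec.samples[: n_frames * frame_samples].reshape(n_frames, frame_samples)
    power = _band_power(frames, rec.sample_rate, params)
    s = correction_factor(cal)
    with np.errstate(divide="ignore"):
        spl = np.where(power > 0.0, 10.0 * np.log10(np.maximum(power, 1e-300)) - s,
                       SILENT_SPL)
    centers = (np.arange(n_frames) + 0.5) * params.frame_length
    return FrameEnergySeries(
        frame_centers=centers,
        spl=spl,
        spl_median=float(np.median(spl)),
        frame_length=params.frame_length,
    )


def candidate_segments(
    series: FrameEnergySeries,
    margin: float = 3.0,
    min_duration: float = 1.0,
    merge_gap: float = 1.0,
) -> list[CandidateSegment]:
    """Gate above-median frames into candidate segments.

    Frames with ``spl > spl_median + margin`` (strictly) are marked; runs of
    marked frames separated by gaps no longer than ``merge_gap`` are merged;
    segments shorter than ``min_duration`` are discarded. ``margin = 0``
    gates literally at the median. The peak is the center of the max-SPL
    frame inside the segment (earliest on ties).
    """
    if len(series) == 0:
        raise ValueError("empty SPL series")
    fl = series.frame_length
    marked = np.flatnonzero(series.spl > series.spl_median + margin)
    if marked.size == 0:
        return []
    gap_frames = int(round(merge_gap / fl))
    breaks = np.flatnonzero(np.diff(marked) > gap_frames + 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_stops = np.concatenate((breaks, [marked.size - 1]))
    out: list[CandidateSegment] = []
    for a, b in zip(run_starts, run_stops):
        first, last = int(marked[a]), int(marked[b])
        start, end = first * fl, (last + 1) * fl
        if end - start < min_duration:
            continue
        seg_spl = series.spl[first : last + 1]
        peak_idx = first + int(np.argmax(seg_spl))
        out.append(
            CandidateSegment(
                start=start,
                end=end,
                peak_time=float(series.frame_centers[peak_idx]),
                peak_excess=float(series.spl[peak_idx] - series.spl_median),
            )
        )
    return out
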