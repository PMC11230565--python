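"""Snapping-shrimp transient removal.

Snaps are millisecond broadband impulses, among the loudest natural sounds in
estuaries; in a spectrogram they appear as full-spectrum vertical stripes and
they contaminate broadband SPL and spectrogram features alike. Detection is an
amplitude-versus-moving-RMS-envelope threshold; removal replaces excised
samples with a centered moving average of the surrounding non-snap samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core_io import AudioRecording

logger = logging.getLogger(__name__)

__all__ = ["CleaningParams", "detect_snaps", "remove_snaps"]


@dataclass(frozen=True)
class CleaningParams:
    """Tunables of the snap cleaner.

    envelope_window : seconds
        Length of the sliding window for the local RMS envelope (default
        50 ms — long relative to a ~1 ms snap, short relative to vessel
        passes, so the envelope tracks the background, not the snap).
    spike_factor : dimensionless
        A sample is marked when |x| exceeds ``spike_factor`` times the local
        envelope (default 4).
    replacement_window : seconds
        Window of the centered moving average used to fill excised samples
        (default 20 ms).
    guard : seconds
        Padding added on each side of a marked sample before intervals are
        merged, to excise the full snap transient (default 0.5 ms).
    min_marked : int
        An interval is kept only if it contains at least this many marked
        samples, or a single mark exceeding ``2*spike_factor`` times the
        envelope. Isolated single crossings at ~4 sigma are expected from
        Gaussian background alone and are not snaps, which span dozens of
        samples at field sample rates.
    """

    envelope_window: float = 0.05
    spike_factor: float = 4.0
    replacement_window: float = 0.02
    guard: float = 0.0005
    min_marked: int = 2

    def __post_init__(self) -> None:
        if min(self.envelope_window, self.spike_factor, self.replacement_window) <= 0:
            raise ValueError("cleaning parameters must be positive")


def _rms_envelope(x: np.ndarray, window_samples: int) -> np.ndarray:
    w = max(int(window_samples), 1)
    return np.sqrt(np.maximum(uniform_filter1d(x * x, size=w, mode="reflect"), 0.0))


def detect_snaps(
    rec: AudioRecording, params: CleaningParams = CleaningParams()
) -> list[tuple[int, int]]:
    """Locate snap transients as half-open sample-index intervals.

    Returns sorted, non-overlapping ``(start, stop)`` pairs. Every returned
    interval contains at least one sample whose magnitude exceeds
    ``spike_factor`` times the local RMS envelope.
    """
    x = rec.samples
    if len(x) == 0:
        raise ValueError("empty recording")
    fs = rec.sample_rate
    env = _rms_envelope(x, round(params.envelope_window * fs))
    ratio = np.abs(x) / np.maximum(env, np.finfo(np.float64).tiny)
    marked = ratio > params.spike_factor
    idx = np.flatnonzero(marked)
    if idx.size == 0:
        return []
    pad = max(int(round(params.guard * fs)), 1)
    # merge padded marks into candidate intervals
    breaks = np.flatnonzero(np.diff(idx) > 2 * pad)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    intervals: list[tuple[int, int]] = []
    for a, b in zip(starts, stops):
        lo = max(int(idx[a]) - pad, 0)
        hi = min(int(idx[b]) + pad + 1, len(x))
        n_marked = int(b - a + 1)
        strong = float(ratio[idx[a] : idx[b] + 1].max()) > 2.0 * params.spike_factor
        if n_marked >= params.min_marked or strong:
            intervals.append((lo, hi))
    return intervals


def remove_snaps(
    rec: AudioRecording, params: CleaningParams = CleaningParams()
) -> AudioRecording:
    """Return a copy of ``rec`` with snap intervals filled by a moving average.

    Samples outside detected intervals are bit-identical to the input. The
    fill for each excised sample is the centered moving average (over
    ``replacement_window``) of the surrounding non-snap samples; where a gap
    is wider than the window, linear interpolation between the nearest good
    samples is used.
    """
    intervals = detect_snaps(rec, params)
    if not intervals:
        return AudioRecording(rec.samples.copy(), rec.sample_rate,
                              rec.source_id, rec.start_time)
    x = rec.samples
    good = np.ones(len(x), dtype=bool)
    for a, b in intervals:
        good[a:b] = False
    if not good.any():
        logger.warning("%s: detected snap interval spans the entire file; "
                       "returning input unchanged", rec.source_id)
        return AudioRecording(x.copy(), rec.sample_rate, rec.source_id, rec.start_time)

    w = max(int(round(params.replacement_window * rec.sample_rate)), 1)
    num = uniform_filter1d(np.where(good, x, 0.0), size=w, mode="reflect")
    den = uniform_filter1d(good.astype(np.float64), size=w, mode="reflect")
    out = x.copy()
    bad = ~good
    with np.errstate(invalid="ignore", divide="ignore"):
        fill = num / den
    covered = den > 1e-12
    out[bad & covered] = fill[bad & covered]
    orphan = bad & ~covered
    if orphan.any():
        gi = np.flatnonzero(good)
        out[orphan] = np.interp(np.flatnonzero(orphan), gi, x[gi])
    return AudioRecording(out, rec.sample_rate, rec.source_id, rec.start_time)
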