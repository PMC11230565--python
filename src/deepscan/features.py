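"""Stage 2 inputs: fixed-size spectrogram feature windows.

A feature window is a Delta_t x Delta_f patch of log-magnitude spectrogram
energy around a candidate instant, restricted to the 800–10,000 Hz band
(below 800 Hz fish chorusing dominates estuarine soundscapes in spring and
summer; above 10 kHz adds little vessel information for considerable storage),
resampled to a fixed grid and standardized per window so the classifier
judges spectro-temporal shape rather than absolute loudness — loudness is
stage 1's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import map_coordinates

from .core_io import AudioRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureParams",
    "FeatureWindow",
    "TrainingSet",
    "Spectrogram",
    "spectrogram",
    "extract_feature",
    "build_training_set",
]

#: Event kinds that count as burst-broadband vessel signatures.
BB_KINDS = frozenset({"burst_narrow", "burst_wide"})


@dataclass(frozen=True)
class FeatureParams:
    """Geometry of the classifier's input window.

    ``delta_t`` (default 5.5 s) is the temporal span, matching the mean
    narrow-burst duration; ``f_low``/``f_high`` bound the band (800–10,000 Hz
    by default, clipped to Nyquist); ``fft_length``/``hop`` control the
    underlying short-time FFT; ``grid`` is the fixed (n_time, n_freq) output
    resolution the spectrogram patch is bilinearly resampled to.
    """

    delta_t: float = 5.5
    f_low: float = 800.0
    f_high: float = 10_000.0
    fft_length: int = 2048
    hop: int = 1024
    grid: tuple[int, int] = (32, 32)

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if not (0 <= self.f_low < self.f_high):
            raise ValueError("need 0 <= f_low < f_high")
        if self.fft_length < 2 or self.hop < 1:
            raise ValueError("fft_length >= 2 and hop >= 1 required")
        if min(self.grid) < 8:
            raise ValueError("grid dimensions must be >= 8")

    @property
    def input_dim(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class FeatureWindow:
    """One standardized time-frequency patch (rows = time, cols = frequency)."""

    values: np.ndarray
    center_time: float
    source_id: str = ""
    label: int | None = None

    def flat(self) -> np.ndarray:
        return self.values.ravel()


@dataclass
class TrainingSet:
    """Parallel feature windows and binary vessel/non-vessel targets."""

    windows: list[FeatureWindow]
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if len(self.windows) != len(self.targets):
            raise ValueError("windows and targets must have equal length")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def X(self) -> np.ndarray:
        return np.stack([w.flat() for w in self.windows])

    @property
    def y(self) -> np.ndarray:
        return self.targets

    def save(self, directory: str | Path) -> None:
        """Serialize as a matrix file plus an index CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "features.npy", self.X)
        pd.DataFrame(
            {
                "source": [w.source_id for w in self.windows],
                "center_s": [w.center_time for w in self.windows],
                "label": self.targets.astype(int),
            }
        ).to_csv(directory / "index.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path, grid: tuple[int, int]) -> "TrainingSet":
        directory = Path(directory)
        X = np.load(directory / "features.npy")
        idx = pd.read_csv(directory / "index.csv")
        windows = [
            FeatureWindow(x.reshape(grid), float(c), str(s), int(l))
            for x, s, c, l in zip(X, idx["source"], idx["center_s"], idx["label"])
        ]
        return cls(windows, idx["label"].to_numpy(dtype=np.float64))


class Spectrogram(NamedTuple):
    times: np.ndarray  # column centers, seconds
    freqs: np.ndarray  # Hz, up to Nyquist
    power: np.ndarray  # (n_freq, n_time) magnitude-squared


def spectrogram(rec: AudioRecording, fft_length: int = 2048, hop: int = 1024) -> Spectrogram:
    """Hann-tapered short-time power spectrogram.

    Column count is ``floor((N - fft_length)/hop) + 1``; time axis in
    seconds, frequency axis in Hz up to Nyquist.
    """
    if len(rec) < fft_length:
        raise ValueError("recording shorter than one FFT frame")
    freqs, times, sxx = sps.spectrogram(
        rec.samples,
        fs=rec.sample_rate,
        window="hann",
        nperseg=fft_length,
        noverlap=fft_length - hop,
        detrend=False,
        mode="psd",
    )
    return Spectrogram(times=times, freqs=freqs, power=sxx)


def _resize_bilinear(mat: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rows = np.linspace(0.0, mat.shape[0] - 1.0, shape[0])
    cols = np.linspace(0.0, mat.shape[1] - 1.0, shape[1])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(mat, [rr, cc], order=1, mode="nearest")


def extract_feature(
    rec: AudioRecording,
    center_time: float,
    params: FeatureParams = FeatureParams(),
) -> FeatureWindow:
    """Cut the standardized Delta_t x Delta_f patch centered at an instant.

    The time window is clipped to the file bounds and zero-padded back to a
    full ``delta_t`` so the output shape is always ``params.grid``. The patch
    is converted to dB with a floor 100 dB below the patch maximum, then
    standardized to zero mean and unit variance — making the feature
    invariant to absolute amplitude scaling of the source audio.
    """
    if not (0.0 <= center_time <= rec.duration):
        raise ValueError(
            f"center_time {center_time} outside recording [0, {rec.duration:.3f}]"
        )
    fs = rec.sample_rate
    n_win = int(round(params.delta_t * fs))
    start = int(round(center_time * fs)) - n_win // 2
    lo, hi = max(start, 0), min(start + n_win, len(rec))
    seg = np.zeros(n_win, dtype=np.float64)
    seg[lo - start : lo - start + (hi - lo)] = rec.samples[lo:hi]
    spec = spectrogram(
        AudioRecording(seg, fs, rec.source_id), params.fft_length, params.hop
    )
    f_hi = min(params.f_high, fs / 2.0)
    band = (spec.freqs >= params.f_low) & (spec.freqs <= f_hi)
    if band.sum() < 2:
        raise ValueError("analysis band resolves fewer than 2 frequency bins")
    patch = spec.power[band, :]  # (freq, time)
    peak = patch.max()
    if peak <= 0.0:
        values = np.zeros(params.grid)
    else:
        db = 10.0 * np.log10(np.maximum(patch, peak * 1e-10))
        values = _resize_bilinear(db.T, params.grid)  # rows = time
        sd = values.std()
        if sd < 1e-12:
            values = np.zeros(params.grid)
        else:
            values = (values - values.mean()) / sd
    return FeatureWindow(values=values, center_time=center_time,
                         source_id=rec.source_id)


def _bb_intervals(truth) -> list[tuple[float, float]]:
    return [(ev.start, ev.end) for ev in truth.events if ev.kind in BB_KINDS]


def _clear_of_bursts(center: float, bursts: Sequence[tuple[float, float]],
                     delta_t: float) -> bool:
    for a, b in bursts:
        if a - delta_t <= center <= b + delta_t:
            return False
    return True


def build_training_set(
    scenes: Sequence[tuple[AudioRecording, "object"]],
    params: FeatureParams = FeatureParams(),
    negatives_per_positive: int = 15,
    seed: int | None = 0,
) -> TrainingSet:
    """Assemble vessel / non-vessel feature windows from labeled scenes.

    ``scenes`` pairs each recording with its event log (an object with an
    ``events`` list carrying ``kind``/``start``/``end``). Positives are
    centered on burst midpoints; negatives are drawn (seeded) from instants
    at least ``delta_t`` away from any burst, ``negatives_per_positive`` per
    positive overall.
    """
    rng = np.random.default_rng(seed)
    windows: list[FeatureWindow] = []
    targets: list[float] = []
    half = params.delta_t / 2.0
    neg_pool: list[tuple[AudioRecording, list[tuple[float, float]]]] = []
    n_pos = 0
    for rec, truth in scenes:
        bursts = _bb_intervals(truth)
        for a, b in bursts:
            center = min(max((a + b) / 2.0, half), rec.duration - half)
            w = extract_feature(rec, center, params)
            w.label = 1
            windows.append(w)
            targets.append(1.0)
            n_pos += 1
        neg_pool.append((rec, bursts))
    if n_pos == 0:
        raise ValueError("no burst events in the provided scenes")

    n_neg_target = n_pos * negatives_per_positive
    attempts = 0
    n_neg = 0
    max_attempts = 200 * max(n_neg_target, 1)
    while n_neg < n_neg_target:
        if attempts >= max_attempts:
            raise ValueError("could not place enough negative windows clear of bursts")
        attempts += 1
        rec, bursts = neg_pool[int(rng.integers(len(neg_pool)))]
        if rec.duration <= params.delta_t:
            continue
        center = float(rng.uniform(half, rec.duration - half))
        if not _clear_of_bursts(center, bursts, params.delta_t):
            continue
        w = extract_feature(rec, center, params)
        w.label = 0
        windows.append(w)
        targets.append(0.0)
        n_neg += 1
    return TrainingSet(windows, np.asarray(targets))
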