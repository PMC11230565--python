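"""WAV ingestion, calibration metadata and manual-label tables.

Amplitudes are kept ADC-normalized (dimensionless, in [-1, 1]) throughout;
conversion to absolute pressure happens in exactly one place, the calibration
correction applied by :mod:`deepscan.energy`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "AudioRecording",
    "CalibrationSpec",
    "LabelTable",
    "read_wav",
    "write_wav",
    "load_labels",
    "timestamp_from_filename",
]


@dataclass
class AudioRecording:
    """A mono calibratable waveform.

    Parameters
    ----------
    samples
        ADC-normalized amplitudes in [-1, 1] (float64).
    sample_rate
        Sampling rate in Hz.
    source_id
        Provenance label, normally the file basename.
    start_time
        Wall-clock time of the first sample, when known.
    """

    samples: np.ndarray
    sample_rate: float
    source_id: str = ""
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording holds mono audio (1-D samples)")

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CalibrationSpec:
    """Hydrophone/recorder calibration constants.

    ``hydrophone_sensitivity`` (M_h) in dB re V/uPa, ``gain`` (G) in dB and
    ``v_adc`` (V_ADC), the zero-to-peak voltage of the ADC, in volts. These
    three enter the correction factor S = M_h + G + 20*log10(1/V_ADC).

    The default sensitivity is -185.5 dBV/uPa with 20 dB gain and a 1 V ADC,
    the constants of the DSG-Ocean recorders this tool was written for.
    """

    hydrophone_sensitivity: float = -185.5
    gain: float = 20.0
    v_adc: float = 1.0

    def __post_init__(self) -> None:
        if self.v_adc <= 0:
            raise ValueError(f"v_adc must be positive, got {self.v_adc}")


@dataclass
class LabelTable:
    """Mapping from file identifier to manually-reviewed vessel presence."""

    labels: dict[str, bool] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, key: str) -> bool:
        return self.labels[key]

    def __contains__(self, key: str) -> bool:
        return key in self.labels

    def items(self):
        return self.labels.items()


_PCM_SCALES = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Accepts 16/24/32-bit integer PCM and 32-bit float files. Multi-channel
    files are reduced to channel 0 with a logged warning (the target recorders
    are single-hydrophone).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        logger.warning("%s has %d channels; taking channel 0", path.name, data.shape[1])
        data = data[:, 0]
    if data.size == 0:
        raise ValueError(f"{path} contains no audio samples")
    dtype = data.dtype
    if dtype in _PCM_SCALES:
        samples = data.astype(np.float64) / _PCM_SCALES[dtype]
    elif dtype in (np.dtype(np.float32), np.dtype(np.float64)):
        samples = data.astype(np.float64)
    elif dtype == np.dtype(np.uint8):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise ValueError(f"unsupported WAV sample format {dtype} in {path}")
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{path} contains non-finite samples")
    return AudioRecording(samples=samples, sample_rate=float(rate), source_id=path.name)


def write_wav(rec: AudioRecording, path: str | Path, bit_depth: int = 16) -> Path:
    """Write a recording as integer PCM WAV (16- or 32-bit).

    Out-of-range amplitudes are clipped with a warning. Quantization uses a
    2**(bit_depth-1) scale with clipping at full positive scale, so a
    read-back round trip is exact to within one LSB.
    """
    path = Path(path)
    if bit_depth not in (16, 32):
        raise ValueError(f"bit_depth must be 16 or 32, got {bit_depth}")
    x = np.asarray(rec.samples, dtype=np.float64)
    if np.any(np.abs(x) > 1.0):
        logger.warning("%s: clipping %d out-of-range samples before write",
                       path.name, int(np.sum(np.abs(x) > 1.0)))
        x = np.clip(x, -1.0, 1.0)
    full = 2 ** (bit_depth - 1)
    q = np.clip(np.round(x * full), -full, full - 1)
    dtype = np.int16 if bit_depth == 16 else np.int32
    wavfile.write(str(path), int(round(rec.sample_rate)), q.astype(dtype))
    return path


def load_labels(path: str | Path) -> LabelTable:
    """Load a ``file,label`` CSV of manual vessel-presence labels.

    Labels must be 0 or 1; duplicate filenames and unparseable labels raise.
    An empty file yields an empty table with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s is empty; returning an empty label table", path)
        return LabelTable()
    if df.empty:
        logger.warning("%s has no label rows", path)
        return LabelTable()
    missing = {"file", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df["file"].duplicated().any():
        dups = df.loc[df["file"].duplicated(), "file"].tolist()
        raise ValueError(f"{path}: duplicate filename(s) {dups}")
    labels: dict[str, bool] = {}
    for _, row in df.iterrows():
        raw = str(row["label"]).strip()
        if raw not in {"0", "1"}:
            raise ValueError(f"{path}: label for {row['file']!r} must be 0 or 1, got {raw!r}")
        labels[str(row["file"])] = raw == "1"
    return LabelTable(labels)


DEFAULT_TIMESTAMP_PATTERN = r"(?P<ts>\d{14})"


def timestamp_from_filename(
    name: str,
    pattern: str = DEFAULT_TIMESTAMP_PATTERN,
    fmt: str = "%Y%m%d%H%M%S",
) -> datetime | None:
    """Extract a timestamp from a filename via a configurable regex.

    ``pattern`` must contain a named group ``ts`` whose match parses with
    ``fmt``. Returns None when the pattern does not match.
    """
    m = re.search(pattern, name)
    if m is None:
        return None
    try:
        return datetime.strptime(m.group("ts"), fmt)
    except ValueError:
        return None
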