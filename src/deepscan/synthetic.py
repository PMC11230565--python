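"""Labeled synthetic estuarine soundscapes.

Scenes emulate the four ingredients the detector must cope with: Gaussian
broadband background; snapping-shrimp snaps (~1 ms full-spectrum transients
at several times the background RMS, in a Poisson train); fish chorus
(band-limited 50–800 Hz noise, the classic stage-1 false alarm); and vessel
events. Burst-broadband events are shaped broadband noise with a Tukey
temporal envelope — the burst class is defined by its broadband spectrogram
appearance, not engine harmonics — with narrow/wide durations drawn from
truncated normals at 5.9 +/- 2.1 s and 15.9 +/- 6.6 s. Variable-broadband
and low-frequency generators are included as confounders even though only
burst-broadband detection is in scope.

Event and chorus levels are in dB above background within the component's
own band: the component's power spectral density is 10^(L/10) times the
background's. Everything is deterministic per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft
from scipy.signal.windows import hann, tukey

from .core_io import AudioRecording, LabelTable, write_wav

logger = logging.getLogger(__name__)

__all__ = [
    "EventSpec",
    "ChorusSpec",
    "SceneSpec",
    "TruthEvent",
    "TruthLog",
    "CorpusItem",
    "simulate_scene",
    "simulate_corpus",
    "sample_burst_durations",
]

#: Mean and SD (seconds) of burst-broadband durations by subtype.
BURST_DURATIONS = {"burst_narrow": (5.9, 2.1), "burst_wide": (15.9, 6.6)}
BB_KINDS = frozenset(BURST_DURATIONS)

_DEFAULT_BANDS = {
    "burst_narrow": (100.0, 30_000.0),
    "burst_wide": (100.0, 30_000.0),
    "variable_broadband": (100.0, 25_000.0),
    "low_frequency": (50.0, 1_000.0),
}
_DEFAULT_DURATIONS = {"variable_broadband": 60.0, "low_frequency": 60.0}
_SNAP_LENGTH = 0.001  # seconds


@dataclass(frozen=True)
class EventSpec:
    """One vessel event: kind, onset, optional fixed duration/band, level."""

    kind: str
    start: float
    duration: float | None = None
    level_db: float = 12.0
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _DEFAULT_BANDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start < 0:
            raise ValueError("event start must be >= 0")


@dataclass(frozen=True)
class ChorusSpec:
    """Fish-chorus component: band-limited low-frequency noise."""

    enabled: bool = False
    band: tuple[float, float] = (50.0, 800.0)
    level_db: float = 15.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one 2-minute synthetic soundscape."""

    duration: float = 120.0
    sample_rate: float = 80_000.0
    background_rms: float = 0.02
    snap_rate: float = 5.0
    snap_amplitude_factor: float = 8.0
    chorus: ChorusSpec = field(default_factory=ChorusSpec)
    events: tuple[EventSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class TruthEvent:
    kind: str
    start: float
    end: float
    level_db: float


@dataclass
class TruthLog:
    """Ground truth for one scene; stands in for manual review."""

    events: list[TruthEvent]
    bb_present: bool
    snap_times: list[float] = field(default_factory=list)
    normalization_gain: float = 1.0


def sample_burst_durations(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw burst durations from a truncated (>= 0.5 s) normal."""
    mean, sd = BURST_DURATIONS[kind]
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        keep = draw[draw >= 0.5]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to ``band`` via FFT masking."""
    white = rng.normal(0.0, 1.0, n)
    spec = rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = irfft(spec, n=n)
    rms = np.sqrt(np.mean(x * x))
    if rms <= 0:
        raise ValueError(f"band {band} resolves no frequency bins at fs={fs}")
    return x / rms


def _component_rms(spec: SceneSpec, band: tuple[float, float], level_db: float) -> float:
    """RMS so the component's in-band PSD is 10^(L/10) x background's."""
    nyq = spec.sample_rate / 2.0
    frac = (band[1] - band[0]) / nyq
    return spec.background_rms * np.sqrt(frac * 10.0 ** (level_db / 10.0))


def _clip_band(band: tuple[float, float], fs: float) -> tuple[float, float]:
    hi = min(band[1], 0.95 * fs / 2.0)
    if band[0] >= hi:
        raise ValueError(f"sample rate {fs} Hz too low for band {band}")
    return (band[0], hi)


def simulate_scene(spec: SceneSpec) -> tuple[AudioRecording, TruthLog]:
    """Render a scene to a waveform plus its ground-truth log.

    Deterministic per ``spec.seed``. The waveform is peak-normalized only if
    it would clip, with the applied gain recorded in the log.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    x = rng.normal(0.0, spec.background_rms, n)

    if spec.chorus.enabled:
        band = _clip_band(spec.chorus.band, fs)
        x += _component_rms(spec, band, spec.chorus.level_db) * _bandlimited_noise(
            n, fs, band, rng
        )

    truth_events: list[TruthEvent] = []
    for ev in spec.events:
        dur = ev.duration
        if dur is None:
            if ev.kind in BURST_DURATIONS:
                dur = float(sample_burst_durations(ev.kind, 1, rng)[0])
            else:
                dur = _DEFAULT_DURATIONS[ev.kind]
        if ev.start + dur > spec.duration + 1e-9:
            raise ValueError(
                f"{ev.kind} event at {ev.start:.1f}s with duration {dur:.1f}s "
                f"exceeds the {spec.duration:.1f}s scene"
            )
        band = _clip_band(ev.band or _DEFAULT_BANDS[ev.kind], fs)
        n_ev = int(round(dur * fs))
        seg = _bandlimited_noise(n_ev, fs, band, rng)
        seg *= _component_rms(spec, band, ev.level_db) * tukey(n_ev, alpha=0.25)
        i0 = int(round(ev.start * fs))
        x[i0 : i0 + n_ev] += seg
        truth_events.append(TruthEvent(ev.kind, ev.start, ev.start + dur, ev.level_db))

    snap_times: list[float] = []
    if spec.snap_rate > 0:
        n_snaps = int(rng.poisson(spec.snap_rate * spec.duration))
        n_sn = max(int(round(_SNAP_LENGTH * fs)), 4)
        amp = spec.snap_amplitude_factor * spec.background_rms
        t_local = np.arange(n_sn) / fs
        env = hann(n_sn, sym=True)
        for _ in range(n_snaps):
            t0 = float(rng.uniform(0.0, spec.duration - 2 * _SNAP_LENGTH))
            f_c = float(rng.uniform(2_000.0, min(6_000.0, 0.35 * fs)))
            phase = float(rng.uniform(0.0, 2.0 * np.pi))
            i0 = int(round(t0 * fs))
            x[i0 : i0 + n_sn] += amp * env * np.cos(2 * np.pi * f_c * t_local + phase)
            snap_times.append(t0)
        snap_times.sort()

    gain = 1.0
    peak = float(np.max(np.abs(x))) if n else 0.0
    if peak > 0.999:
        gain = 0.999 / peak
        x *= gain
        logger.warning("scene seed=%d peak-normalized by gain %.4f", spec.seed, gain)

    rec = AudioRecording(x, fs, source_id=f"scene_{spec.seed}")
    return rec, TruthLog(
        events=truth_events,
        bb_present=any(ev.kind in BB_KINDS for ev in truth_events),
        snap_times=snap_times,
        normalization_gain=gain,
    )


@dataclass
class CorpusItem:
    """One corpus file: its scene spec, identity and ground truth.

    The waveform is not retained; :meth:`render` regenerates it bit-identically
    from the stored spec, so corpora of any size stay cheap to hold.
    """

    spec: SceneSpec
    filename: str
    start_time: datetime
    truth: TruthLog
    path: Path | None = None

    def render(self) -> AudioRecording:
        rec, _ = simulate_scene(self.spec)
        rec.source_id = self.filename
        rec.start_time = self.start_time
        return rec


def simulate_corpus(
    n_files: int,
    prevalence: float,
    template: SceneSpec = SceneSpec(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    station: str = "SYN",
    start: datetime = datetime(2018, 6, 1, 0, 0, 0),
    interval_minutes: float = 20.0,
    chorus_prob: float = 0.5,
) -> tuple[list[CorpusItem], LabelTable]:
    """Generate a labeled corpus of scenes.

    Exactly ``round(n_files * prevalence)`` files contain at least one
    burst-broadband event (1–2 bursts, narrow with probability 0.7). When
    the template's chorus is enabled, each file independently receives a
    chorus with probability ``chorus_prob`` — chorus-only files are the
    stage-2 discrimination test. With ``out_dir`` set, 16-bit WAVs plus
    ``labels.csv`` and ``truth.csv`` are written there.
    """
    if n_files <= 0:
        raise ValueError("n_files must be positive")
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_files * prevalence))
    positive = np.zeros(n_files, dtype=bool)
    positive[:n_pos] = True
    rng.shuffle(positive)

    items: list[CorpusItem] = []
    labels: dict[str, bool] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    for i in range(n_files):
        ts = start + timedelta(minutes=i * interval_minutes)
        filename = f"{station}_{i:04d}_{ts:%Y%m%d%H%M%S}.wav"
        file_seed = int(rng.integers(0, 2**31 - 1))
        chorus = replace(
            template.chorus,
            enabled=template.chorus.enabled and bool(rng.random() < chorus_prob),
        )
        events: list[EventSpec] = []
        if positive[i]:
            n_ev = 1 + int(rng.random() < 0.3)
            placed: list[tuple[float, float]] = []
            for _ in range(n_ev):
                kind = "burst_narrow" if rng.random() < 0.7 else "burst_wide"
                dur = float(sample_burst_durations(kind, 1, rng)[0])
                dur = min(dur, template.duration - 6.0)
                for _try in range(50):
                    t0 = float(rng.uniform(2.0, template.duration - 2.0 - dur))
                    if all(t0 + dur < a or t0 > b for a, b in placed):
                        placed.append((t0, t0 + dur))
                        events.append(EventSpec(kind, t0, duration=dur))
                        break
        spec = replace(template, chorus=chorus, events=tuple(events), seed=file_seed)
        rec, truth = simulate_scene(spec)
        rec.source_id = filename
        rec.start_time = ts
        path = None
        if out_path is not None:
            path = write_wav(rec, out_path / filename)
        items.append(CorpusItem(spec, filename, ts, truth, path))
        labels[filename] = truth.bb_present

    if out_path is not None:
        pd.DataFrame(
            {"file": list(labels), "label": [int(v) for v in labels.values()]}
        ).to_csv(out_path / "labels.csv", index=False)
        pd.DataFrame(
            [
                {
                    "file": it.filename,
                    "kind": ev.kind,
                    "start_s": ev.start,
                    "end_s": ev.end,
                    "level_db": ev.level_db,
                }
                for it in items
                for ev in it.truth.events
            ],
            columns=["file", "kind", "start_s", "end_s", "level_db"],
        ).to_csv(out_path / "truth.csv", index=False)

    return items, LabelTable(labels)
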