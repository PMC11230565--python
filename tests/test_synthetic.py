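"""The soundscape simulator: levels, durations, spectra, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq

from deepscan import (
    CalibrationSpec,
    EventSpec,
    SceneSpec,
    SplParams,
    detect_snaps,
    load_labels,
    sample_burst_durations,
    simulate_corpus,
    simulate_scene,
    spl_series,
)
from deepscan.synthetic import BURST_DURATIONS, ChorusSpec

FS = 16_000.0


class TestSceneBasics:
    def test_plain_background_rms(self):
        """No events, snaps or chorus: measured RMS ~ background_rms."""
        spec = SceneSpec(duration=30.0, sample_rate=FS, snap_rate=0.0, seed=1)
        rec, truth = simulate_scene(spec)
        rms = float(np.sqrt(np.mean(rec.samples**2)))
        assert rms == pytest.approx(spec.background_rms, rel=0.02)
        assert not truth.bb_present
        assert truth.events == [] and truth.snap_times == []

    def test_seed_determinism_bit_identical(self):
        spec = SceneSpec(duration=20.0, sample_rate=FS, seed=9,
                         chorus=ChorusSpec(enabled=True),
                         events=(EventSpec("burst_narrow", 5.0),))
        r1, t1 = simulate_scene(spec)
        r2, t2 = simulate_scene(spec)
        np.testing.assert_array_equal(r1.samples, r2.samples)
        assert t1.events == t2.events and t1.snap_times == t2.snap_times

    def test_event_exceeding_duration_rejected(self):
        spec = SceneSpec(duration=10.0, sample_rate=FS,
                         events=(EventSpec("burst_narrow", 8.0, duration=5.0),))
        with pytest.raises(ValueError, match="exceeds"):
            simulate_scene(spec)

    def test_band_unresolvable_at_low_rate(self):
        spec = SceneSpec(duration=5.0, sample_rate=1000.0,
                         events=(EventSpec("burst_narrow", 1.0, duration=2.0,
                                           band=(2000.0, 8000.0)),))
        with pytest.raises(ValueError, match="too low"):
            simulate_scene(spec)

    def test_truth_log_consistency(self):
        spec = SceneSpec(duration=60.0, sample_rate=FS, seed=10,
                         events=(EventSpec("burst_narrow", 10.0, duration=6.0),
                                 EventSpec("low_frequency", 30.0, duration=20.0)))
        _, truth = simulate_scene(spec)
        assert truth.bb_present
        kinds = [e.kind for e in truth.events]
        assert kinds == ["burst_narrow", "low_frequency"]
        for e in truth.events:
            assert 0 <= e.start < e.end <= 60.0


class TestBurstDurations:
    @pytest.mark.parametrize("kind", ["burst_narrow", "burst_wide"])
    def test_sampled_duration_statistics(self, kind):
        """1,000 draws reproduce the subtype's mean and SD.

        Tolerances are 3 standard errors of each statistic (SE_mean =
        sd/sqrt(n), SE_sd ~ sd/sqrt(2n)); for the narrow subtype these round
        to the 0.2 s / 0.3 s bands the duration survey quotes.
        """
        mean, sd = BURST_DURATIONS[kind]
        n = 1000
        draws = sample_burst_durations(kind, n, np.random.default_rng(12))
        mean_tol = max(3 * sd / np.sqrt(n), 0.2)
        sd_tol = max(3 * sd / np.sqrt(2 * n), 0.3)
        assert abs(draws.mean() - mean) < mean_tol
        assert abs(draws.std(ddof=1) - sd) < sd_tol
        assert draws.min() >= 0.5


class TestSpectralContent:
    def test_chorus_power_concentrated_below_800(self):
        """>= 90% of chorus-added power sits below 800 Hz."""
        base = SceneSpec(duration=30.0, sample_rate=FS, snap_rate=0.0, seed=13)
        rec, _ = simulate_scene(
            SceneSpec(duration=30.0, sample_rate=FS, snap_rate=0.0, seed=13,
                      chorus=ChorusSpec(enabled=True))
        )
        f = rfftfreq(len(rec), 1.0 / FS)
        p = np.abs(rfft(rec.samples)) ** 2
        bg_psd = base.background_rms**2 * len(rec)  # E|X_k|^2 = n sigma^2
        below = f < 800.0
        added_below = p[below].sum() - bg_psd * below.sum()
        added_above = p[~below].sum() - bg_psd * (~below).sum()
        frac = added_below / (added_below + max(added_above, 0.0))
        assert frac >= 0.9

    def test_burst_raises_in_band_spl_by_nominal_level(self, cal_zero):
        """A +12 dB burst lifts 800-8000 Hz frame SPL by >= 9 dB."""
        level = 12.0
        spec = SceneSpec(duration=60.0, sample_rate=FS, snap_rate=0.0, seed=14,
                         events=(EventSpec("burst_narrow", 30.0, duration=6.0,
                                           level_db=level),))
        rec, _ = simulate_scene(spec)
        band = SplParams(frame_length=0.5, band_low=800.0, band_high=8000.0)
        series = spl_series(rec, cal_zero, band)
        burst_frames = series.spl[(series.frame_centers > 31)
                                  & (series.frame_centers < 35)]
        rise = burst_frames.max() - series.spl_median
        assert rise >= level - 3.0

    def test_logged_bursts_have_above_median_spl(self, cal_zero):
        spec = SceneSpec(duration=120.0, sample_rate=FS, seed=15,
                         events=(EventSpec("burst_narrow", 40.0, duration=6.0),
                                 EventSpec("burst_wide", 80.0, duration=16.0)))
        rec, truth = simulate_scene(spec)
        series = spl_series(rec, cal_zero, SplParams(band_high=FS / 2))
        for ev in truth.events:
            sel = ((series.frame_centers >= ev.start)
                   & (series.frame_centers <= ev.end))
            assert series.spl[sel].max() > series.spl_median

    def test_snaps_recalled_by_cleaning(self):
        """detect_snaps recovers >= 95% of injected snaps at default params."""
        spec = SceneSpec(duration=60.0, seed=16)  # default 80 kHz
        rec, truth = simulate_scene(spec)
        intervals = detect_snaps(rec)
        fs = spec.sample_rate
        hits = sum(
            any(lo < (t0 + 0.001) * fs and hi > t0 * fs for lo, hi in intervals)
            for t0 in truth.snap_times
        )
        assert len(truth.snap_times) > 100
        assert hits / len(truth.snap_times) >= 0.95
        false = sum(
            not any(t0 * fs < hi and (t0 + 0.001) * fs > lo
                    for t0 in truth.snap_times)
            for lo, hi in intervals
        )
        assert false / max(len(intervals), 1) <= 0.05


class TestCorpus:
    def test_prevalence_count_and_labels(self, tmp_path):
        items, labels = simulate_corpus(
            20, 0.3, template=SceneSpec(duration=20.0, sample_rate=FS),
            seed=17, out_dir=tmp_path,
        )
        assert sum(it.truth.bb_present for it in items) == 6
        table = load_labels(tmp_path / "labels.csv")
        assert len(table) == 20
        for it in items:
            assert table[it.filename] == it.truth.bb_present

    def test_corpus_determinism_and_render(self):
        template = SceneSpec(duration=20.0, sample_rate=FS)
        a, _ = simulate_corpus(5, 0.4, template=template, seed=18)
        b, _ = simulate_corpus(5, 0.4, template=template, seed=18)
        for ia, ib in zip(a, b):
            assert ia.filename == ib.filename
            np.testing.assert_array_equal(ia.render().samples, ib.render().samples)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_corpus(0, 0.3)
        with pytest.raises(ValueError):
            simulate_corpus(5, 1.5)

    def test_timestamps_spaced_by_interval(self):
        items, _ = simulate_corpus(3, 0.0,
                                   template=SceneSpec(duration=5.0, sample_rate=FS),
                                   seed=19, interval_minutes=20)
        deltas = [(b.start_time - a.start_time).total_seconds()
                  for a, b in zip(items, items[1:])]
        assert deltas == [1200.0, 1200.0]
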