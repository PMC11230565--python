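"""Accuracy, SEL exposure metrics and detection time series."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from deepscan import (
    CandidateSegment,
    FrameEnergySeries,
    LabelTable,
    accuracy,
    cumulative_sel,
    detection_timeseries,
    evaluate,
    sel_metrics,
)
from deepscan.metrics import SELMetrics, sel_metrics_linear
from deepscan.scanner import DetectionRecord, FileResult


def _series(spl, median=None, fl=0.5):
    spl = np.asarray(spl, dtype=float)
    med = float(np.median(spl)) if median is None else float(median)
    return FrameEnergySeries((np.arange(len(spl)) + 0.5) * fl, spl, med, fl)


class TestAccuracy:
    def test_basic_values(self):
        assert accuracy(200, 2) == 0.99
        assert accuracy(50, 50) == 0.0
        for n in (1, 7, 4188):
            assert accuracy(n, 0) == 1.0

    def test_matches_reported_rounding(self):
        """4188 files with 33 errors prints as 99.21%."""
        rho = accuracy(4188, 33)
        assert f"{rho:.2%}" == "99.21%"
        assert rho == pytest.approx(0.99212, abs=5e-6)

    def test_exact_for_integer_pairs(self):
        from fractions import Fraction

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 10_000))
            e = int(rng.integers(0, n + 1))
            assert accuracy(n, e) == float(Fraction(n - e, n))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            accuracy(0, 0)
        with pytest.raises(ValueError):
            accuracy(10, 11)


def _results(preds, prefix="f"):
    return [FileResult(source_id=f"{prefix}{i}.wav", vessel_present=bool(p))
            for i, p in enumerate(preds)]


def _labels(truths, prefix="f"):
    return LabelTable({f"{prefix}{i}.wav": bool(t) for i, t in enumerate(truths)})


class TestEvaluate:
    def test_perfect_agreement(self):
        preds = [i % 3 == 0 for i in range(50)]
        ev = evaluate(_results(preds), _labels(preds))
        assert (ev.rho, ev.false_positives, ev.false_negatives) == (1.0, 0, 0)

    def test_all_inverted(self):
        preds = [i % 2 == 0 for i in range(20)]
        ev = evaluate(_results([not p for p in preds]), _labels(preds))
        assert ev.rho == 0.0
        assert ev.n_error == 20

    def test_single_error_among_hundred(self):
        truths = [i < 30 for i in range(100)]
        preds = truths.copy()
        preds[0] = False  # one forced miss
        ev = evaluate(_results(preds), _labels(truths))
        assert ev.rho == 0.99
        assert (ev.false_positives, ev.false_negatives) == (0, 1)

    def test_unlabeled_file_raises(self):
        with pytest.raises(KeyError):
            evaluate(_results([True]), LabelTable({}))

    def test_symmetry_under_inversion(self):
        """Inverting both predictions and labels preserves the error count."""
        rng = np.random.default_rng(1)
        truths = rng.random(60) < 0.4
        preds = rng.random(60) < 0.4
        a = evaluate(_results(list(preds)), _labels(list(truths)))
        b = evaluate(_results(list(~preds)), _labels(list(~truths)))
        assert a.n_error == b.n_error
        assert a.false_positives == b.false_negatives


class TestSelMetrics:
    def test_constant_at_median_all_zero(self):
        series = _series([100.0] * 10, median=100.0)
        seg = CandidateSegment(start=1.0, end=4.0, peak_time=2.0, peak_excess=0.0)
        m = sel_metrics(series, seg)
        assert (m.peak_difference, m.mean_difference, m.area_size) == (0.0, 0.0, 0.0)

    def test_hand_trapezoid(self):
        """Adjacent excesses 2 and 4 dB at 0.5 s spacing -> area 1.5 dB*s."""
        series = _series([100, 100, 102, 104, 100, 100], median=100.0, fl=0.5)
        seg = CandidateSegment(start=1.0, end=2.0, peak_time=1.75, peak_excess=4.0)
        m = sel_metrics(series, seg)
        assert m.area_size == pytest.approx(1.5)
        assert m.peak_difference == pytest.approx(4.0)
        assert m.mean_difference == pytest.approx(3.0)

    def test_linearity_under_excess_scaling(self):
        base = np.array([100, 103, 106, 104, 100], dtype=float)
        seg = CandidateSegment(0.0, 2.5, 1.25, 6.0)
        m1 = sel_metrics(_series(base, median=100.0), seg)
        scaled = 100.0 + 2.0 * (base - 100.0)
        m2 = sel_metrics(_series(scaled, median=100.0), seg)
        assert m2.peak_difference == pytest.approx(2 * m1.peak_difference)
        assert m2.mean_difference == pytest.approx(2 * m1.mean_difference)
        assert m2.area_size == pytest.approx(2 * m1.area_size)

    def test_matches_halved_spacing_riemann_oracle(self):
        """Trapezoid area tracks a midpoint Riemann sum at half spacing."""

        def excess(t):
            return 8.0 * np.exp(-0.5 * ((t - 5.0) / 1.5) ** 2)

        fl = 0.5
        centers = (np.arange(20) + 0.5) * fl
        series = _series(100.0 + excess(centers), median=100.0, fl=fl)
        seg = CandidateSegment(0.5, 9.5, 5.25, 8.0)
        m = sel_metrics(series, seg)
        in_seg = (centers >= seg.start) & (centers <= seg.end)
        t0, t1 = centers[in_seg][0], centers[in_seg][-1]
        half = np.arange(t0, t1, fl / 2.0) + fl / 4.0
        oracle = float(np.sum(excess(half)) * fl / 2.0)
        assert m.area_size == pytest.approx(oracle, rel=0.02)

    def test_file_wide_mean_flag(self):
        series = _series([100, 101, 105, 103, 100, 102], median=100.0)
        seg = CandidateSegment(1.0, 2.0, 1.25, 5.0)
        in_seg = sel_metrics(series, seg).mean_difference
        file_wide = sel_metrics(series, seg, file_wide_mean=True).mean_difference
        assert in_seg == pytest.approx(4.0)  # frames 105,103
        assert file_wide == pytest.approx(np.mean([1, 5, 3, 2]))


def _det(source):
    seg = CandidateSegment(0.0, 1.0, 0.5, 5.0)
    return DetectionRecord(source, 0.5, 0.9, True, seg, 5.0, 3.0)


class TestCumulativeSel:
    def test_single_station_sum(self):
        pairs = [(_det("37M_a.wav"), SELMetrics(5, 3, a, (0, 1)))
                 for a in (1.0, 2.5, 0.5)]
        assert cumulative_sel(pairs) == {"37M": pytest.approx(4.0)}

    def test_empty_is_empty(self):
        assert cumulative_sel([]) == {}

    def test_two_stations_order_insensitive(self):
        pairs = [
            (_det("9M_x.wav"), SELMetrics(5, 3, 2.0, (0, 1))),
            (_det("14M_y.wav"), SELMetrics(5, 3, 1.0, (0, 1))),
            (_det("9M_z.wav"), SELMetrics(5, 3, 3.0, (0, 1))),
        ]
        out = cumulative_sel(pairs)
        assert out == cumulative_sel(list(reversed(pairs)))
        assert out["9M"] == pytest.approx(5.0)
        assert out["14M"] == pytest.approx(1.0)


class TestDetectionTimeseries:
    def test_hour_counts(self):
        results = [
            FileResult("a", True, start_time=datetime(2018, 6, 1, 9, 0)),
            FileResult("b", True, start_time=datetime(2018, 6, 1, 9, 20)),
            FileResult("c", True, start_time=datetime(2018, 6, 1, 14, 0)),
            FileResult("d", False, start_time=datetime(2018, 6, 1, 15, 0)),
        ]
        counts, coverage = detection_timeseries(results)
        d = datetime(2018, 6, 1).date()
        assert counts.loc[d, 9] == 2
        assert counts.loc[d, 14] == 1
        assert counts.loc[d, 15] == 0
        assert coverage.loc[d, 15] == 1
        assert coverage.loc[d, 16] == 0  # no files in that cell

    def test_total_conservation(self):
        rng = np.random.default_rng(2)
        results = [
            FileResult(f"f{i}", bool(rng.random() < 0.3),
                       start_time=datetime(2018, 6, 1 + int(rng.integers(0, 5)),
                                           int(rng.integers(0, 24)), 0))
            for i in range(40)
        ]
        counts, _ = detection_timeseries(results)
        assert counts.to_numpy().sum() == sum(r.vessel_present for r in results)

    def test_missing_timestamp_excluded_with_warning(self, caplog):
        results = [FileResult("x", True, start_time=None)]
        with caplog.at_level("WARNING"):
            counts, coverage = detection_timeseries(results)
        assert counts.empty
        assert any("timestamp" in r.message for r in caplog.records)


def test_sel_linear_variant_positive_and_zero():
    series = _series([100, 102, 104, 100], median=100.0)
    seg = CandidateSegment(0.0, 2.0, 1.25, 4.0)
    assert sel_metrics_linear(series, seg) > 0.0
    flat = _series([100.0] * 4, median=100.0)
    assert sel_metrics_linear(flat, seg) == 0.0
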