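"""Signal pipeline: filtering, baseline, QC, detection, metrics, classes."""

import numpy as np
import pytest

from nanopipette.events import (
    EventClass,
    TimeSeries,
    baseline_normalize,
    bessel_lowpass,
    classify_event,
    detect_events,
    event_metrics,
    qc_trace,
    snr,
)

FS = 250_000.0


def _ts(samples, fs=FS):
    return TimeSeries(np.asarray(samples, dtype=float), fs)


class TestBesselFilter:
    def test_unit_dc_gain(self):
        out = bessel_lowpass(_ts(np.full(50_000, 123.0)))
        assert out.samples[-1000:] == pytest.approx(123.0, rel=1e-6)

    def test_minus_3db_at_cutoff(self):
        t = np.arange(int(1.0 * FS)) / FS
        x = np.sin(2 * np.pi * 2000.0 * t)
        y = bessel_lowpass(_ts(x), cutoff=2000.0).samples
        steady = y[len(y) // 2:]
        gain = np.sqrt(2.0) * np.std(steady)
        assert gain == pytest.approx(10 ** (-3.0 / 20.0), abs=0.02)

    def test_noise_variance_reduced(self, rng):
        x = rng.normal(0, 5, 100_000)
        y = bessel_lowpass(_ts(x)).samples
        assert np.var(y) < np.var(x)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bessel_lowpass(_ts(np.zeros(100), fs=1000.0), cutoff=600.0)

    def test_zero_phase_mode_has_no_delay(self):
        x = np.zeros(20_000)
        x[10_000:10_500] = -100.0
        causal = bessel_lowpass(_ts(x)).samples
        zp = bessel_lowpass(_ts(x), zero_phase=True).samples
        assert abs(np.argmin(zp) - 10_250) < abs(np.argmin(causal) - 10_250)


class TestBaseline:
    def test_constant_trace(self):
        zeroed, i_open = baseline_normalize(_ts(np.full(10_000, 100.0)))
        assert i_open == pytest.approx(100.0)
        assert np.allclose(zeroed.samples, 0.0)

    def test_rectangular_dip_preserved(self):
        x = np.full(100_000, 200.0)
        x[40_000:45_000] = 120.0
        zeroed, i_open = baseline_normalize(_ts(x))
        assert i_open == pytest.approx(200.0)
        assert zeroed.samples[42_000] == pytest.approx(-80.0)

    def test_mostly_blocked_trace_rejected(self):
        x = np.full(10_000, 100.0)
        x[: 8_000] = 30.0  # "baseline" is the minority level
        with pytest.raises(ValueError, match="baseline"):
            baseline_normalize(_ts(x))

    def test_open_pore_recovered_under_noise_and_drift(self, rng):
        n = int(2.0 * FS)
        t = np.arange(n) / FS
        x = 300.0 + 1.0 * t + rng.normal(0, 3.0, n)
        x[int(0.5 * FS): int(0.5 * FS) + 250] -= 120.0
        _, i_open = baseline_normalize(_ts(x))
        assert i_open == pytest.approx(300.5, abs=3.0)  # within 1%


class TestQC:
    def test_clean_trace_passes(self, fixture_suite):
        ts, _ = fixture_suite["qc_pass"]
        report = qc_trace(ts, voltage=1.0)
        assert report.passed
        assert report.p2p_noise < 30.0

    def test_noisy_trace_fails_p2p(self, fixture_suite):
        ts, _ = fixture_suite["qc_fail"]
        report = qc_trace(ts, voltage=1.0)
        assert not report.passed
        assert report.p2p_noise > 30.0

    def test_overrange_voltage_fails(self, fixture_suite):
        ts, _ = fixture_suite["qc_pass"]
        report = qc_trace(ts, voltage=1.5)
        assert not report.in_voltage_range
        assert not report.passed


class TestDetection:
    def test_flat_trace_yields_nothing(self, rng):
        x = rng.normal(0, 3.0, 100_000)
        assert detect_events(_ts(x), i_open=300.0) == []

    def test_single_rectangular_event_recovered(self, rng):
        n = int(1.0 * FS)
        x = rng.normal(0, 3.0, n)
        k0 = n // 2
        width = int(1.0e-3 * FS)
        x[k0: k0 + width] -= 120.0  # 40% of 300 pA
        events = detect_events(_ts(x), i_open=300.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.fractional_blockade == pytest.approx(40.0, abs=3.0)
        assert ev.dwell == pytest.approx(1.0, abs=0.17)

    def test_two_separated_events(self, rng):
        n = int(1.0 * FS)
        x = rng.normal(0, 3.0, n)
        w = int(1.0e-3 * FS)
        for k0 in (n // 4, 3 * n // 4):
            x[k0: k0 + w] -= 150.0
        events = detect_events(_ts(x), i_open=300.0)
        assert len(events) == 2

    def test_zero_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            detect_events(_ts(np.zeros(1000)), i_open=300.0)


class TestEventMetrics:
    def test_blockade_arithmetic(self):
        window = np.zeros(500)
        window[100:400] = -35.0
        fb, dwell = event_metrics(window, i_open=100.0, sampling_rate=FS)
        assert fb == pytest.approx(35.0)

    def test_unfiltered_rectangular_dwell_exact(self):
        width = int(round(1.15e-3 * FS))
        window = np.zeros(3 * width)
        window[width: 2 * width] = -60.0
        _, dwell = event_metrics(window, i_open=100.0, sampling_rate=FS)
        assert dwell == pytest.approx(1.15, abs=1.5 / FS * 1e3)


class TestClassification:
    @pytest.mark.parametrize(
        "fb,dwell,expected",
        [
            (34.0, 1.0, EventClass.SINGLE),
            (65.0, 1.3, EventClass.TRIPLE),
            (54.0, 1.15, EventClass.DOUBLE),
            (45.0, 1.1, EventClass.UNCLASSIFIED),  # between FB bands
            (34.0, 1.3, EventClass.UNCLASSIFIED),  # FB/dwell disagree
            (float("nan"), 1.0, EventClass.UNCLASSIFIED),
        ],
    )
    def test_band_assignment(self, fb, dwell, expected):
        assert classify_event(fb, dwell) is expected


class TestSNR:
    def test_ratio(self):
        value, capped = snr(30.0, 10.0)
        assert value == pytest.approx(3.0)
        assert not capped

    def test_zero_noise_capped_and_flagged(self):
        value, capped = snr(30.0, 0.0)
        assert capped
        assert value == 1e6
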