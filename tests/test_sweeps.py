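"""Trace-derived observables (pure arithmetic; no solver runs here)."""

import io

import numpy as np
import pytest

from nanopipette.sweeps import (
    IVCurve,
    PositionTrace,
    average_speed,
    blockade_fluctuation,
    fractional_blockade,
    mse_compare,
    rectification_ratio,
    translocation_extent,
)


def _trace(z, current, i_open):
    return PositionTrace(np.asarray(z, float), np.asarray(current, float),
                         i_open=i_open)


class TestRectification:
    def test_ohmic_curve_gives_unity(self):
        iv = IVCurve(np.linspace(-1, 1, 11), 3e-9 * np.linspace(-1, 1, 11))
        assert rectification_ratio(iv) == pytest.approx(1.0)

    def test_ratio_is_max_over_min(self):
        iv = IVCurve([-0.2, 0.0, 0.2], [-1.0e-9, 0.0, 2.0e-9])
        assert rectification_ratio(iv) == pytest.approx(2.0)
        assert rectification_ratio(iv) >= 1.0

    def test_zero_current_rejected(self):
        iv = IVCurve([-0.2, 0.0, 0.2], [0.0, 0.0, 1e-9])
        with pytest.raises(ValueError):
            rectification_ratio(iv)

    def test_voltages_must_increase(self):
        with pytest.raises(ValueError):
            IVCurve([0.2, 0.0, -0.2], [1, 0, -1])

    def test_curve_must_bracket_zero(self):
        with pytest.raises(ValueError):
            IVCurve([0.2, 0.4], [1, 2])


class TestFractionalBlockade:
    def test_arithmetic(self):
        z = np.linspace(-5, 5, 21)
        current = np.full_like(z, 100e-12)
        current[10] = 60e-12
        tr = _trace(z, current, 100e-12)
        assert fractional_blockade(tr) == pytest.approx(40.0)

    def test_minimum_on_boundary_rejected(self):
        z = np.linspace(-5, 5, 11)
        tr = _trace(z, np.linspace(50e-12, 100e-12, 11), 100e-12)
        with pytest.raises(ValueError, match="boundary"):
            fractional_blockade(tr)

    def test_zero_open_current_rejected(self):
        z = np.linspace(-5, 5, 11)
        tr = _trace(z, np.ones(11), 0.0)
        with pytest.raises(ValueError):
            fractional_blockade(tr)


class TestExtent:
    def test_constructed_interval(self):
        # deviation beyond 0.5% only on z in [-3, +14]
        z = np.arange(-10.0, 15.5, 0.5)
        current = np.full_like(z, 100e-12)
        inside = (z >= -3.0) & (z <= 14.0)
        current[inside] = 80e-12
        tr = _trace(z, current, 100e-12)
        ext, flagged = translocation_extent(tr)
        assert not flagged
        assert ext == pytest.approx(17.0)

    def test_no_crossing_returns_zero_flagged(self):
        z = np.arange(-5.0, 5.5, 0.5)
        tr = _trace(z, np.full_like(z, 100e-12), 100e-12)
        ext, flagged = translocation_extent(tr, tol=100.0)
        assert ext == 0.0
        assert flagged


class TestFluctuation:
    def test_constant_plateau_between_minima_is_zero(self):
        z = np.arange(-5.0, 5.25, 0.25)
        current = np.full_like(z, 100e-12)
        inside = np.abs(z) <= 3.0
        current[inside] = 60e-12
        current[np.isclose(z, -3.0)] = 55e-12  # two sharp minima framing
        current[np.isclose(z, 3.0)] = 55e-12  # a flat plateau
        tr = _trace(z, current, 100e-12)
        fluct, flagged = blockade_fluctuation(tr)
        assert not flagged
        assert fluct == pytest.approx(100 * 2.5 / 59.6, abs=0.5)

    def test_single_minimum_uses_flagged_fallback(self):
        z = np.arange(-6.0, 6.25, 0.25)
        current = (100 - 40 * np.exp(-0.5 * (z / 1.5) ** 2)) * 1e-12
        tr = _trace(z, current, 100e-12)
        fluct, flagged = blockade_fluctuation(tr)
        assert flagged
        assert fluct > 0

    def test_chain_ripple_measured_between_minima(self):
        # entry/exit ramps around a rippled plateau, like a chain sweep:
        # the fluctuation must reflect only the ripple, not the ramps
        z = np.arange(-8.0, 8.25, 0.25)
        current = np.full_like(z, 100.0)
        ramp = (np.abs(z) > 5.0) & (np.abs(z) <= 6.0)
        current[ramp] = 60.0 + 40.0 * (np.abs(z[ramp]) - 5.0)
        plateau = np.abs(z) <= 5.0
        current[plateau] = 60.0 + 3.0 * np.cos(2 * np.pi * z[plateau] / 3.4)
        tr = _trace(z, current * 1e-12, 100e-12)
        fluct, flagged = blockade_fluctuation(tr)
        assert not flagged
        # ripple half-range 3 pA on a ~60 pA mean -> ~5%
        assert fluct == pytest.approx(5.0, abs=1.5)


class TestSpeed:
    def test_speed_examples(self):
        assert average_speed(17.68, 1.0) == pytest.approx(17.68)
        assert average_speed(20.0, 2.0) == pytest.approx(10.0)
        assert average_speed(0.0, 1.0) == 0.0

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            average_speed(10.0, 0.0)


class TestMSE:
    def test_identical_traces_zero(self):
        t = np.linspace(0, 1e-3, 100)
        x = -np.exp(-0.5 * ((t - 5e-4) / 1e-4) ** 2)
        assert mse_compare(t, x, t, x) == pytest.approx(0.0, abs=1e-30)

    def test_constant_offset_gives_offset_squared(self):
        t = np.linspace(0, 1e-3, 100)
        x = -np.exp(-0.5 * ((t - 5e-4) / 1e-4) ** 2)
        assert mse_compare(t, x, t, x + 0.3) == pytest.approx(0.09, rel=1e-6)

    def test_alignment_by_minimum_registration(self):
        t = np.linspace(0, 2e-3, 400)
        pulse = lambda c: -np.exp(-0.5 * ((t - c) / 1e-4) ** 2)
        # same shape shifted in time must still match closely (residual
        # limited by the sub-sample registration offset)
        assert mse_compare(t, pulse(6e-4), t, pulse(1.2e-3)) < 1e-3

    def test_degenerate_support_rejected(self):
        t = np.linspace(0, 1e-3, 50)
        x = -np.exp(-0.5 * ((t - 5e-4) / 1e-4) ** 2)
        with pytest.raises(ValueError):
            mse_compare(t[:1], x[:1], t, x)


class TestCSVRoundTrip:
    def test_position_trace(self):
        z = np.linspace(-5, 5, 21)
        tr = PositionTrace(z, 1e-9 * np.cos(z / 5), i_open=1.1e-9,
                           metadata={"n_proteins": 2})
        buf = io.StringIO()
        tr.to_csv(buf)
        buf.seek(0)
        back = PositionTrace.from_csv(buf)
        assert np.allclose(back.z, tr.z)
        assert np.allclose(back.current, tr.current)
        assert back.i_open == pytest.approx(tr.i_open)
        assert back.metadata["n_proteins"] == "2"

    def test_iv_curve(self):
        iv = IVCurve(np.linspace(-1, 1, 11), np.linspace(-2, 2, 11) * 1e-9,
                     metadata={"step_V": 0.2})
        buf = io.StringIO()
        iv.to_csv(buf)
        buf.seek(0)
        back = IVCurve.from_csv(buf)
        assert np.allclose(back.voltages, iv.voltages)
        assert np.allclose(back.currents, iv.currents)
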