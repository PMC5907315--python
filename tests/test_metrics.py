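"""Milestone extraction, checked against closed-form synthetic signals."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from neurocalc import (MetricsError, compute_metrics, oscillation_decay_time,
                       ptp_opening_times, spike_peak)
from neurocalc.simulate import Trajectory


def make_traj(t, series: dict) -> Trajectory:
    states = np.zeros((len(t), 13))
    names = ("CAC", "CAM", "CAER", "a", "PTPh", "PTPl", "y", "H_M", "PSI",
             "NADH_m", "ADP_m", "ADP_i", "h")
    for name, values in series.items():
        states[:, names.index(name)] = values
    return Trajectory(t=np.asarray(t, dtype=float), states=states)


class TestSpikePeak:
    def test_constant_series(self):
        t = np.linspace(0.0, 100.0, 1001)
        traj = make_traj(t, {"CAC": np.full_like(t, 0.3)})
        tp, vp = spike_peak(traj, "CAC", window=(10.0, 60.0))
        assert vp == 0.3
        assert tp == 10.0

    def test_gaussian_pulse_refined(self):
        t = np.arange(0.0, 100.0, 0.5)
        t0, width, amp = 31.13, 5.0, 1.7
        x = amp * np.exp(-((t - t0) / width) ** 2)
        traj = make_traj(t, {"CAC": x})
        tp, vp = spike_peak(traj, "CAC", window=(0.0, 100.0))
        # quadratic refinement recovers the analytic peak far better than
        # the 0.5 grid spacing
        assert tp == pytest.approx(t0, abs=0.02)
        assert vp == pytest.approx(amp, rel=1e-3)

    def test_empty_window_rejected(self):
        t = np.linspace(0.0, 10.0, 11)
        traj = make_traj(t, {"CAC": t})
        with pytest.raises(MetricsError):
            spike_peak(traj, "CAC", window=(50.0, 60.0))


class TestDecayTime:
    def test_flat_series_zero(self):
        t = np.linspace(0.0, 50.0, 501)
        traj = make_traj(t, {"CAC": np.full_like(t, 0.05)})
        res = oscillation_decay_time(traj, "CAC", baseline=0.05)
        assert res.time == 0.0 and res.decayed

    def test_pure_exponential_closed_form(self):
        """x = A e^{-t/tau}: the band exit is at tau * ln(1/frac)."""
        tau, amp, frac = 12.0, 2.0, 0.05
        t = np.arange(0.0, 120.0, 0.01)
        traj = make_traj(t, {"CAC": amp * np.exp(-t / tau)})
        res = oscillation_decay_time(traj, "CAC", baseline=0.0, frac=frac)
        assert res.decayed
        assert res.time == pytest.approx(tau * math.log(1.0 / frac),
                                         abs=0.01)

    def test_damped_sinusoid_against_root_finder(self):
        """Damped sinusoid: the last excursion outside the envelope band
        is located independently with a root finder on the continuous
        signal."""
        amp, tau, omega, frac = 1.0, 15.0, 2.0, 0.05
        band = frac * amp

        def x(t):
            return amp * math.exp(-t / tau) * math.cos(omega * t)

        # scan a fine analytic grid from the end for the last |x| = band
        fine = np.arange(0.0, 150.0, 0.002)
        g = np.array([abs(x(ti)) - band for ti in fine])
        sign_change = np.where(g[:-1] * g[1:] < 0)[0]
        t_exact = brentq(lambda ti: abs(x(ti)) - band,
                         fine[sign_change[-1]], fine[sign_change[-1] + 1])

        t = np.arange(0.0, 150.0, 0.01)
        traj = make_traj(t, {"CAC": [x(ti) for ti in t]})
        res = oscillation_decay_time(traj, "CAC", baseline=0.0, frac=frac)
        assert res.decayed
        assert res.time == pytest.approx(t_exact, abs=0.02)

    def test_not_decayed_flagged(self):
        t = np.linspace(0.0, 50.0, 501)
        traj = make_traj(t, {"CAC": t})   # still climbing at the end
        res = oscillation_decay_time(traj, "CAC", baseline=0.0)
        assert not res.decayed
        assert res.time == pytest.approx(50.0)

    def test_bad_inputs_rejected(self):
        t = np.linspace(0.0, 1.0, 11)
        traj = make_traj(t, {"CAC": t})
        with pytest.raises(MetricsError):
            oscillation_decay_time(traj, "CAC", baseline=math.nan)
        with pytest.raises(MetricsError):
            oscillation_decay_time(traj, "CAC", baseline=0.0, frac=1.5)


class TestPtpOpening:
    def test_closed_gate(self):
        t = np.linspace(0.0, 100.0, 1001)
        traj = make_traj(t, {"PTPh": np.zeros_like(t)})
        res = ptp_opening_times(traj)
        assert not res.opened
        assert res.onset is None and res.duration is None

    def test_step_within_grid_spacing(self):
        dt = 0.1
        t = np.arange(0.0, 100.0, dt)
        traj = make_traj(t, {"PTPh": (t >= 50.0).astype(float)})
        res = ptp_opening_times(traj)
        assert res.opened
        assert res.onset == pytest.approx(50.0, abs=dt)
        assert res.completion == pytest.approx(50.0, abs=dt)
        assert res.duration <= dt

    def test_exponential_relaxation_closed_form(self):
        """PTPh = 1 - e^{-(t-t0)/tau}: level crossings sit at
        t0 + tau * ln(1/(1-level))."""
        t0, tau = 40.0, 12.5
        t = np.arange(0.0, 200.0, 0.05)
        x = np.where(t >= t0, 1.0 - np.exp(-(t - t0) / tau), 0.0)
        traj = make_traj(t, {"PTPh": x})
        res = ptp_opening_times(traj, low=0.01, high=0.99)
        assert res.onset == pytest.approx(
            t0 + tau * math.log(1 / 0.99), abs=0.01)
        assert res.completion == pytest.approx(
            t0 + tau * math.log(1 / 0.01), abs=0.01)
        assert res.duration == pytest.approx(tau * math.log(99.0), abs=0.02)

    @pytest.mark.parametrize("low,high", [(0.02, 0.99), (0.01, 0.9)])
    def test_threshold_monotonicity(self, low, high):
        """Raising `low` never decreases onset; lowering `high` never
        increases completion."""
        t0, tau = 40.0, 12.5
        t = np.arange(0.0, 200.0, 0.05)
        x = np.where(t >= t0, 1.0 - np.exp(-(t - t0) / tau), 0.0)
        traj = make_traj(t, {"PTPh": x})
        base = ptp_opening_times(traj, low=0.01, high=0.99)
        moved = ptp_opening_times(traj, low=low, high=high)
        assert moved.onset >= base.onset
        assert moved.completion <= base.completion

    def test_bad_thresholds_rejected(self):
        t = np.linspace(0.0, 1.0, 11)
        traj = make_traj(t, {"PTPh": t})
        with pytest.raises(MetricsError):
            ptp_opening_times(traj, low=0.5, high=0.5)


class TestReport:
    def test_full_report_on_synthetic_run(self):
        t = np.arange(0.0, 300.0, 0.05)
        spike = 1.5 * np.exp(-((t - 15.0) / 4.0) ** 2)
        cac = 0.05 + spike + 0.3 * np.exp(-t / 30.0) * np.sin(2.0 * t)
        ptp_h = np.where(t >= 200.0, 1.0 - np.exp(-(t - 200.0) / 10.0), 0.0)
        traj = make_traj(t, {"CAC": cac, "PTPh": ptp_h})
        report = compute_metrics(traj, window=(10.0, 60.0))
        grid_max = cac[(t >= 10.0) & (t <= 60.0)].max()
        assert report.spike_peak_value == pytest.approx(grid_max, abs=0.01)
        assert report.spike_peak_value >= grid_max
        assert report.ptp_opened
        assert report.ptp_onset_time < report.ptp_completion_time
        assert report.ptp_opening_duration == pytest.approx(
            report.ptp_completion_time - report.ptp_onset_time, rel=1e-12)
        text = report.to_json()
        assert '"scenario"' in text
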