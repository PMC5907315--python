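"""Trajectory milestones: spike peak, oscillation decay time, and
PTP opening times.

All crossing times are located by linear interpolation between grid
points; the spike peak is refined by a local quadratic fit through the
discrete maximum and its neighbours.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import MetricsError
from .simulate import Trajectory

__all__ = [
    "DecayResult",
    "PtpOpening",
    "MetricsReport",
    "spike_peak",
    "oscillation_decay_time",
    "ptp_opening_times",
    "compute_metrics",
]


@dataclass(frozen=True)
class DecayResult:
    """Decay time of an oscillatory excursion.

    ``time`` is the last instant the series sits outside the tolerance
    band around baseline (0 if it never leaves the band); ``decayed`` is
    False when the trajectory ends still outside the band.
    """

    time: float
    decayed: bool

    def __float__(self):
        return self.time


@dataclass(frozen=True)
class PtpOpening:
    """Onset/completion/duration of the high-conductance transition.

    ``opened`` is False (and the times None) when the gate never leaves
    the closed state.
    """

    onset: Optional[float]
    completion: Optional[float]
    duration: Optional[float]
    opened: bool
    low: float = 0.01
    high: float = 0.99


@dataclass(frozen=True)
class MetricsReport:
    scenario: str
    spike_peak_value: float
    spike_peak_time: float
    oscillation_decay_time: float
    decayed: bool
    ptp_onset_time: Optional[float]
    ptp_completion_time: Optional[float]
    ptp_opening_duration: Optional[float]
    ptp_opened: bool
    final_CAC: float
    final_CAM: float
    final_CAER: float
    final_a: float
    final_PTPh: float
    thresholds: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def spike_peak(traj: Trajectory, variable: str,
               window: Optional[tuple[float, float]] = None
               ) -> tuple[float, float]:
    """Maximum of ``variable`` over ``window``, quadratically refined.

    The default window runs from the stimulus onset to 50 time units
    after it.  Returns ``(t_peak, value)``.
    """
    t = traj.t
    x = traj[variable]
    if window is None:
        if traj.stim is None:
            raise MetricsError("no stimulus attached to trajectory; pass an "
                               "explicit window")
        window = (traj.stim.init, traj.stim.init + 50.0)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise MetricsError(f"window {window} contains no samples")
    ts, xs = t[mask], x[mask]
    i = int(np.argmax(xs))
    if xs.max() == xs.min():
        return float(ts[0]), float(xs[0])
    if 0 < i < len(xs) - 1:
        # quadratic through three points around the discrete maximum
        t3 = ts[i - 1:i + 2]
        x3 = xs[i - 1:i + 2]
        denom = ((t3[0] - t3[1]) * (t3[0] - t3[2]) * (t3[1] - t3[2]))
        if denom != 0:
            a = (t3[2] * (x3[1] - x3[0]) + t3[1] * (x3[0] - x3[2])
                 + t3[0] * (x3[2] - x3[1])) / denom
            b = (t3[2] ** 2 * (x3[0] - x3[1]) + t3[1] ** 2 * (x3[2] - x3[0])
                 + t3[0] ** 2 * (x3[1] - x3[2])) / denom
            if a < 0:
                tp = -b / (2 * a)
                if t3[0] <= tp <= t3[2]:
                    c = x3[0] - a * t3[0] ** 2 - b * t3[0]
                    vp = a * tp * tp + b * tp + c
                    return float(tp), float(max(vp, x3[1]))
    return float(ts[i]), float(xs[i])


def oscillation_decay_time(traj: Trajectory, variable: str, baseline: float,
                           frac: float = 0.05) -> DecayResult:
    """Last time ``variable`` sits outside the band
    ``baseline +/- frac*(peak - baseline)``.

    ``peak`` is the global maximum excursion of the series from baseline.
    Returns time 0 if the band is never left; ``decayed=False`` if the
    trajectory ends outside the band.
    """
    if not np.isfinite(baseline):
        raise MetricsError("baseline must be finite")
    if not 0 < frac < 1:
        raise MetricsError("frac must be in (0, 1)")
    t = traj.t
    dev = np.abs(traj[variable] - baseline)
    amp = float(dev.max())
    if amp == 0:
        return DecayResult(0.0, True)
    band = frac * amp
    outside = dev > band
    if not outside.any():
        return DecayResult(0.0, True)
    last = int(np.where(outside)[0][-1])
    if last == len(t) - 1:
        return DecayResult(float(t[-1]), False)
    t_cross = _interp_crossing(t[last], t[last + 1], dev[last], dev[last + 1],
                               band)
    return DecayResult(float(t_cross), True)


def ptp_opening_times(traj: Trajectory, low: float = 0.01,
                      high: float = 0.99) -> PtpOpening:
    """First upward crossings of PTPh through ``low`` and ``high``.

    Crossings are located on the output grid by linear interpolation,
    accurate to well under one grid spacing for the smooth relaxation the
    gate follows.
    """
    if not 0 < low < high < 1:
        raise MetricsError("thresholds must satisfy 0 < low < high < 1")
    t = traj.t
    x = traj["PTPh"]

    def first_up(level):
        above = x >= level
        if x[0] >= level:
            return float(t[0])
        idx = np.where(~above[:-1] & above[1:])[0]
        if idx.size == 0:
            return None
        i = int(idx[0])
        return float(_interp_crossing(t[i], t[i + 1], x[i], x[i + 1], level))

    onset = first_up(low)
    completion = first_up(high)
    if onset is None and completion is None:
        return PtpOpening(None, None, None, False, low, high)
    if onset is None or (completion is not None and completion < onset):
        raise MetricsError(
            "PTPh crosses the high threshold before the low threshold; "
            "trajectory data are inconsistent")
    if completion is None:
        return PtpOpening(onset, None, None, True, low, high)
    return PtpOpening(onset, completion, completion - onset, True, low, high)


def compute_metrics(traj: Trajectory, variable: str = "CAC",
                    baseline: Optional[float] = None, frac: float = 0.05,
                    window: Optional[tuple[float, float]] = None,
                    low: float = 0.01, high: float = 0.99) -> MetricsReport:
    """Full milestone report for one trajectory.

    ``baseline`` defaults to the initial value of ``variable``.
    """
    if baseline is None:
        baseline = float(traj[variable][0])
    t_peak, v_peak = spike_peak(traj, variable, window=window)
    decay = oscillation_decay_time(traj, variable, baseline, frac=frac)
    opening = ptp_opening_times(traj, low=low, high=high)
    final = traj.final_state()
    return MetricsReport(
        scenario=traj.scenario,
        spike_peak_value=v_peak,
        spike_peak_time=t_peak,
        oscillation_decay_time=decay.time,
        decayed=decay.decayed,
        ptp_onset_time=opening.onset,
        ptp_completion_time=opening.completion,
        ptp_opening_duration=opening.duration,
        ptp_opened=opening.opened,
        final_CAC=float(traj["CAC"][-1]),
        final_CAM=float(traj["CAM"][-1]),
        final_CAER=float(traj["CAER"][-1]),
        final_a=float(traj["a"][-1]),
        final_PTPh=float(traj["PTPh"][-1]),
        thresholds={"ptp_low": low, "ptp_high": high, "decay_frac": frac,
                    "baseline": baseline},
    )
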