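"""Temporal pulse structures of commercial IPL systems.

Four categories are modeled -- free discharge, square pulse, close pulse
stacking, spaced pulse stacking -- each as a train of trapezoidal
sub-pulses (rise/hold/fall/off).  Every sub-pulse carries an equal share
of the delivered radiant exposure, and the train's instantaneous power
fraction integrates to exactly 1 over the full envelope, so scaling by
the fluence gives the thermal drive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

#: Table-normalized total energy per train (arbitrary device units); the
#: per-pulse energy is this divided by the number of sub-pulses.
TRAIN_ENERGY_TOTAL = 30.0


class PulseCategory(str, Enum):
    FREE_DISCHARGE = "free_discharge"
    SQUARE_PULSE = "square_pulse"
    CLOSE_PULSE_STACK = "close_pulse_stack"
    SPACED_PULSE_STACK = "spaced_pulse_stack"


@dataclass(frozen=True)
class PulseSegment:
    """One trapezoidal sub-pulse: linear rise, plateau, linear fall, off."""

    rise: float
    hold: float
    fall: float
    off: float

    def __post_init__(self):
        if min(self.rise, self.hold, self.fall, self.off) < 0:
            raise ValueError("segment times must be non-negative")
        if self.rise + self.hold + self.fall <= 0:
            raise ValueError("segment must have positive on-time")

    @property
    def on_time(self) -> float:
        return self.rise + self.hold + self.fall

    @property
    def duration(self) -> float:
        return self.on_time + self.off

    @property
    def area_per_unit_peak(self) -> float:
        """Integral of the unit-peak trapezoid."""
        return 0.5 * self.rise + self.hold + 0.5 * self.fall


@dataclass(frozen=True)
class PulseTrain:
    category: PulseCategory
    segments: tuple[PulseSegment, ...]
    energy_per_pulse: float

    def __post_init__(self):
        if len(self.segments) == 0:
            raise ValueError("train must contain at least one segment")

    @property
    def n_pulses(self) -> int:
        return len(self.segments)

    @property
    def total_duration(self) -> float:
        """Full duration including every off interval (observation padding)."""
        return sum(s.duration for s in self.segments)


# Rise, hold, fall, off times (s), number of sub-pulses.
_TABLE = {
    PulseCategory.FREE_DISCHARGE: (0.0015, 0.002, 0.003, 0.005, 1),
    PulseCategory.SQUARE_PULSE: (0.0001, 0.02, 0.0001, 0.005, 1),
    PulseCategory.CLOSE_PULSE_STACK: (0.0001, 0.004, 0.0001, 0.001, 7),
    PulseCategory.SPACED_PULSE_STACK: (0.0001, 0.002, 0.0001, 0.015, 5),
}


def standard_train(category: PulseCategory | str) -> PulseTrain:
    """The tabulated parameterization of one of the four categories.

    All sub-pulses of a train are identical trapezoids; the per-pulse
    energy is the 30.00-unit train total split evenly (4.29 for the
    7-pulse close stack, 6.00 for the 5-pulse spaced stack, after
    rounding to the printed precision).
    """
    category = PulseCategory(category)
    rise, hold, fall, off, n = _TABLE[category]
    seg = PulseSegment(rise=rise, hold=hold, fall=fall, off=off)
    return PulseTrain(category=category, segments=(seg,) * n,
                      energy_per_pulse=TRAIN_ENERGY_TOTAL / n)


def envelope_duration(train: PulseTrain) -> float:
    """Duration of the emission envelope: all on-times plus the interior
    off intervals, excluding the trailing off (post-pulse padding)."""
    total = sum(s.on_time for s in train.segments)
    total += sum(s.off for s in train.segments[:-1])
    return total


def _segment_peak(train: PulseTrain, seg: PulseSegment) -> float:
    # each sub-pulse integrates to 1/n_pulses of the unit total
    return (1.0 / train.n_pulses) / seg.area_per_unit_peak


def power_fraction(train: PulseTrain, t) -> np.ndarray | float:
    """Instantaneous fraction of the total fluence delivered per second.

    Piecewise-linear trapezoids; zero during off intervals and after the
    train; the integral over the full train is exactly 1.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    start = 0.0
    for seg in train.segments:
        peak = _segment_peak(train, seg)
        tau = t_arr - start
        if seg.rise > 0:
            sel = (tau >= 0) & (tau < seg.rise)
            out[sel] = peak * tau[sel] / seg.rise
        t1 = seg.rise + seg.hold
        sel = (tau >= seg.rise) & (tau < t1)
        out[sel] = peak
        if seg.fall > 0:
            t2 = t1 + seg.fall
            sel = (tau >= t1) & (tau < t2)
            out[sel] = peak * (t2 - tau[sel]) / seg.fall
        start += seg.duration
    return float(out[0]) if np.isscalar(t) else out


def cumulative_fraction(train: PulseTrain, t) -> np.ndarray | float:
    """Analytic integral of :func:`power_fraction` from 0 to t."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    start = 0.0
    for seg in train.segments:
        peak = _segment_peak(train, seg)
        tau = np.clip(t_arr - start, 0.0, None)
        # rise
        x = np.clip(tau, 0.0, seg.rise)
        out += peak * 0.5 * x * x / seg.rise if seg.rise > 0 else 0.0
        # hold
        x = np.clip(tau - seg.rise, 0.0, seg.hold)
        out += peak * x
        # fall
        if seg.fall > 0:
            x = np.clip(tau - seg.rise - seg.hold, 0.0, seg.fall)
            out += peak * (x - 0.5 * x * x / seg.fall)
        start += seg.duration
    return float(out[0]) if np.isscalar(t) else out


def average_power_fraction(train: PulseTrain, t0: float, t1: float) -> float:
    """Exact time-average of the power fraction over [t0, t1] (1/s).

    Used by the thermal solver so the time-integrated source matches the
    absorbed-energy map exactly regardless of the step size.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    return (cumulative_fraction(train, t1) - cumulative_fraction(train, t0)) / (t1 - t0)
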