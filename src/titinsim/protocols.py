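"""Length protocols and stretch-shortening cycle analysis.

A length protocol prescribes the half-sarcomere length l(t) as a
piecewise-linear function of time.  Canonical protocols: a single ramp
(e.g. 1 -> 2 um), stretch-shortening hysteresis cycles with an optional
rest period, and repeated triangular cycling about a long base length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "LengthProtocol",
    "make_ramp",
    "make_hysteresis_protocol",
    "make_cycles",
    "cycle_intervals",
    "analyze_cycles",
    "CycleAnalysis",
]


@dataclass(frozen=True)
class LengthProtocol:
    """Piecewise-linear half-sarcomere length vs time (SI units)."""

    times: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        l = np.asarray(self.lengths, dtype=float)
        if t.ndim != 1 or t.size < 2 or t.shape != l.shape:
            raise ValidationError("need matching 1-D times and lengths, n >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("breakpoint times must be strictly increasing")
        if np.any(l < 0):
            raise ValidationError("lengths must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lengths", l)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def t0(self) -> float:
        return float(self.times[0])

    def length_at(self, t):
        """l(t) by linear interpolation (clamped outside the time range)."""
        return np.interp(t, self.times, self.lengths)

    def time_grid(self, dt: float) -> np.ndarray:
        """Uniform solver grid from t0 to the end, step dt (end included)."""
        if dt <= 0:
            raise ValidationError("dt must be positive")
        n = int(np.ceil(self.duration / dt - 1e-9))
        return self.times[0] + dt * np.arange(n + 1)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times,
                      "length_um": self.lengths * 1e6}).to_csv(path,
                                                               index=False)

    @classmethod
    def from_csv(cls, path) -> "LengthProtocol":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["length_um"].to_numpy() * 1e-6)


def make_ramp(l_start: float, l_end: float, speed: float,
              t0: float = 0.0) -> LengthProtocol:
    """Single linear ramp from l_start to l_end at the given speed (m/s)."""
    if not (l_end > l_start > 0):
        raise ValidationError("need l_end > l_start > 0")
    if speed <= 0:
        raise ValidationError("speed must be positive")
    duration = (l_end - l_start) / speed
    return LengthProtocol(np.array([t0, t0 + duration]),
                          np.array([l_start, l_end]))


def make_hysteresis_protocol(l_low: float = 1.0e-6, l_high: float = 1.7e-6,
                             speed: float = 1.0e-6, n_pre: int = 2,
                             rest: float = 30.0, n_post: int = 1
                             ) -> LengthProtocol:
    """Stretch-shortening cycles with a rest period.

    ``n_pre`` back-to-back cycles l_low -> l_high -> l_low, a hold of
    ``rest`` seconds at l_low, then ``n_post`` further cycles.  The default
    reproduces the double cycle + 30 s rest + third cycle setting used to
    study hysteresis recovery.
    """
    if not (l_high > l_low > 0) or speed <= 0:
        raise ValidationError("need l_high > l_low > 0 and speed > 0")
    if n_pre < 1 or n_post < 0 or rest < 0:
        raise ValidationError("need n_pre >= 1, n_post >= 0, rest >= 0")
    half = (l_high - l_low) / speed
    times = [0.0]
    lengths = [l_low]
    t = 0.0
    for _ in range(n_pre):
        t += half; times.append(t); lengths.append(l_high)
        t += half; times.append(t); lengths.append(l_low)
    if n_post > 0 and rest > 0:
        t += rest; times.append(t); lengths.append(l_low)
    for _ in range(n_post):
        t += half; times.append(t); lengths.append(l_high)
        t += half; times.append(t); lengths.append(l_low)
    return LengthProtocol(np.array(times), np.array(lengths))


def make_cycles(base: float, amplitude: float, n_cycles: int, speed: float,
                rest_after: float | None = None) -> LengthProtocol:
    """Triangular cycling: base -> base+amplitude -> base, repeated.

    Produces ``2 * n_cycles + 1`` breakpoints (plus one if a trailing rest
    is requested).  ``n_cycles = 0`` gives a constant-length protocol of
    1 s (or ``rest_after`` seconds).
    """
    if not (0 < amplitude < base):
        raise ValidationError("need 0 < amplitude < base")
    if speed <= 0 or n_cycles < 0:
        raise ValidationError("speed must be > 0 and n_cycles >= 0")
    half = amplitude / speed
    times = [0.0]
    lengths = [base]
    t = 0.0
    for _ in range(n_cycles):
        t += half; times.append(t); lengths.append(base + amplitude)
        t += half; times.append(t); lengths.append(base)
    if n_cycles == 0:
        t = rest_after if rest_after else 1.0
        times.append(t); lengths.append(base)
    elif rest_after:
        t += rest_after; times.append(t); lengths.append(base)
    return LengthProtocol(np.array(times), np.array(lengths))


# ---------------------------------------------------------------------------
# Cycle analysis
# ---------------------------------------------------------------------------

def cycle_intervals(protocol: LengthProtocol) -> list[tuple[float, float]]:
    """Half-open time intervals [t_i, t_{i+1}) of the protocol's cycles.

    A cycle starts at a breakpoint where the length begins to increase.
    Holds and shortening phases belong to the preceding cycle; the last
    cycle owns the protocol tail.
    """
    t, l = protocol.times, protocol.lengths
    rising = np.diff(l) > 0
    starts = [i for i in range(len(rising))
              if rising[i] and (i == 0 or not rising[i - 1])]
    if not starts:
        raise ValidationError("protocol has no loading phase; not cyclic")
    bounds = [t[i] for i in starts] + [t[-1]]
    return [(bounds[i], bounds[i + 1]) for i in range(len(starts))]


@dataclass
class CycleAnalysis:
    """Per-cycle hysteresis areas (J) and peak forces (N) of a force trace."""

    intervals: list[tuple[float, float]]
    hysteresis_areas: np.ndarray
    peak_forces: np.ndarray
    loading_curves: list[tuple[np.ndarray, np.ndarray]]
    unloading_curves: list[tuple[np.ndarray, np.ndarray]]

    @property
    def n_cycles(self) -> int:
        return len(self.intervals)


def _trace_arrays(result):
    """Extract (times, lengths, force) from a simulation result or tuple."""
    if isinstance(result, tuple) and len(result) == 3:
        return tuple(np.asarray(a, dtype=float) for a in result)
    times = np.asarray(result.times, dtype=float)
    lengths = np.asarray(result.lengths, dtype=float)
    for attr in ("mean_force", "expected_force"):
        f = getattr(result, attr, None)
        if f is not None:
            return times, lengths, np.asarray(f, dtype=float)
    raise ValidationError(
        "result must expose mean_force or expected_force, or be a "
        "(times, lengths, forces) tuple")


def analyze_cycles(result, protocol: LengthProtocol) -> CycleAnalysis:
    """Split a force trace into cycles; compute hysteresis area and peaks.

    The hysteresis area of a cycle is the loop integral of F dl over the
    cycle (trapezoidal rule), i.e. the loading-minus-unloading area; for a
    trace that returns to its starting length this is the dissipated
    energy.  The peak force is the maximum over the cycle's loading phase.
    """
    times, lengths, force = _trace_arrays(result)
    intervals = cycle_intervals(protocol)
    areas, peaks = [], []
    loading, unloading = [], []
    for (a, b) in intervals:
        sel = (times >= a) & (times <= b)  # closed end for integration
        t, l, f = times[sel], lengths[sel], force[sel]
        if t.size < 3:
            raise ValidationError("trace too coarse to resolve a cycle")
        dl = np.diff(l)
        areas.append(float(np.sum(0.5 * (f[1:] + f[:-1]) * dl)))
        # a point belongs to the loading (unloading) curve if it bounds a
        # rising (falling) segment; turning points belong to both
        up = np.concatenate([dl > 0, [False]]) | np.concatenate(
            [[False], dl > 0])
        down = np.concatenate([dl < 0, [False]]) | np.concatenate(
            [[False], dl < 0])
        peaks.append(float(f[up].max()) if np.any(up) else float(f.max()))
        loading.append((l[up], f[up]))
        unloading.append((l[down], f[down]))
    return CycleAnalysis(intervals, np.array(areas), np.array(peaks),
                         loading, unloading)
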