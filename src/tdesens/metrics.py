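"""Time-distance calculus between two cooling curves.

Given two monotonically decreasing cooling curves T1(t), T2(t) measured at
two nearby probe locations, the deviation of the death-time estimates they
imply is quantified in *time* units: both curves are inverted into
time-since-death estimators t_i(T), evaluated along the pointwise-mean
reference curve T_R, and the maximum absolute difference

    D_MAX = max_k | t1(T_R(t^k)) - t2(T_R(t^k)) |

is taken over a regular K-point grid on the joint domain [t_MIN, t_MAX].
Local variants D_MAX,Qi restrict the max to the four Q intervals of
normalised excess temperature Q = (T_R - T_A)/(T0 - T_A), with boundaries
q = 1, 0.5, 0.3, 0.2, 0.1 (the first three are the classical normed
temperature ranges used for death-time tolerance radii).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Q_BOUNDS",
    "CoolingCurve",
    "ComparisonFrame",
    "DeviationResult",
    "reference_curve",
    "normalize_q",
    "q_to_temperature",
    "invert_curve",
    "build_frame",
    "d_max",
    "deviation_difference",
]

#: Q-interval boundaries q0..q4 (dimensionless normalised excess temperature)
Q_BOUNDS = (1.0, 0.5, 0.3, 0.2, 0.1)

_MONOTONE_TOL = 1e-6  # K; allowed per-sample non-decrease before rejection


@dataclass
class CoolingCurve:
    """Temperature samples at one probe over time.

    times : strictly increasing sample times, hours
    temps : temperatures, deg C
    """

    times: np.ndarray
    temps: np.ndarray
    probe_id: str = ""
    T_A: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.shape != self.temps.shape or self.times.ndim != 1:
            raise ValueError("times and temps must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.temps))):
            raise ValueError("curve contains non-finite samples")

    def at(self, t) -> np.ndarray | float:
        """Piecewise-linear evaluation (no extrapolation)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.times[0] - 1e-12) or np.any(t_arr > self.times[-1] + 1e-12):
            raise ValueError("evaluation time outside the curve domain")
        return np.interp(t_arr, self.times, self.temps)

    def clipped(self, a: float, b: float) -> "CoolingCurve":
        """Restriction to [a, b] with interpolated endpoint samples."""
        if not (self.times[0] <= a < b <= self.times[-1] + 1e-12):
            raise ValueError(f"[{a}, {b}] not contained in the curve domain")
        inner = (self.times > a) & (self.times < b)
        ts = np.concatenate(([a], self.times[inner], [b]))
        return CoolingCurve(times=ts, temps=np.interp(ts, self.times, self.temps),
                            probe_id=self.probe_id, T_A=self.T_A)


def _monotone_window(curve: CoolingCurve, a: float, b: float) -> CoolingCurve:
    """Clip to [a, b], drop the initial plateau, verify strict decrease.

    Deep probes can plateau (or warm marginally) early postmortem; the
    evaluation window starts at the curve maximum within [a, b].  After
    that the curve must decrease; an increase beyond the tolerance is a
    data error.  Exact ties collapse to their earliest time.
    """
    c = curve.clipped(a, b)
    i0 = int(np.argmax(c.temps))
    ts, Ts = c.times[i0:], c.temps[i0:]
    if np.any(np.diff(Ts) > _MONOTONE_TOL):
        raise ValueError(
            f"curve {curve.probe_id!r} is not monotonically decreasing on "
            f"[{ts[0]:.3g}, {b:.3g}] h"
        )
    # keep the earliest sample of any flat stretch -> strictly decreasing
    keep = np.concatenate(([True], np.minimum.accumulate(Ts)[1:] < np.minimum.accumulate(Ts)[:-1]))
    Ts = np.minimum.accumulate(Ts)
    if len(ts[keep]) < 2:
        raise ValueError(f"curve {curve.probe_id!r} has no cooling signal on the window")
    return CoolingCurve(times=ts[keep], temps=Ts[keep],
                        probe_id=curve.probe_id, T_A=curve.T_A)


def reference_curve(T1: CoolingCurve, T2: CoolingCurve) -> CoolingCurve:
    """Pointwise mean of two cooling curves on a shared time grid.

    Curves on different grids are first resampled (linearly) onto the
    union of the two grids.
    """
    if len(T1.times) == len(T2.times) and np.allclose(T1.times, T2.times, atol=1e-12):
        ts = T1.times
        y1, y2 = T1.temps, T2.temps
    else:
        lo = max(T1.times[0], T2.times[0])
        hi = min(T1.times[-1], T2.times[-1])
        if hi <= lo:
            raise ValueError("curves have no overlapping time domain")
        ts = np.union1d(T1.times, T2.times)
        ts = ts[(ts >= lo) & (ts <= hi)]
        y1 = np.interp(ts, T1.times, T1.temps)
        y2 = np.interp(ts, T2.times, T2.temps)
    return CoolingCurve(times=ts.copy(), temps=0.5 * (y1 + y2),
                        probe_id="reference", T_A=T1.T_A)


def normalize_q(T_R: CoolingCurve, T_A: float, T0: float) -> CoolingCurve:
    """Normalised excess temperature Q(t) = (T_R(t) - T_A)/(T0 - T_A)."""
    if T0 <= T_A:
        raise ValueError("no cooling signal: initial temperature at or below ambient")
    return CoolingCurve(times=T_R.times.copy(),
                        temps=(T_R.temps - T_A) / (T0 - T_A),
                        probe_id="Q", T_A=0.0)

def q_to_temperature(q: float, T0: float, T_A: float) -> float:
    """Temperature at normalised excess q: q (T0 - T_A) + T_A."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if T0 <= T_A:
        raise ValueError("requires T0 > T_A")
    return q * (T0 - T_A) + T_A


def invert_curve(T: CoolingCurve, temp) -> np.ndarray | float:
    """Time at which a strictly decreasing curve attains ``temp``.

    Piecewise-linear interpolation between samples; the inverse of the
    cooling curve is the time-since-death estimator t(T).
    """
    temps = np.asarray(temp, dtype=float)
    dec = np.diff(T.temps)
    if np.any(dec > _MONOTONE_TOL):
        raise ValueError("curve is not monotonically decreasing; cannot invert")
    y = T.temps[::-1]
    x = T.times[::-1]
    y = np.minimum.accumulate(T.temps)[::-1]  # guard against flat ties
    lo, hi = y[0], y[-1]
    if np.any(temps < lo - 1e-9) or np.any(temps > hi + 1e-9):
        raise ValueError("temperature outside the curve range")
    out = np.interp(np.clip(temps, lo, hi), y, x)
    return out if temps.ndim else float(out)


@dataclass
class ComparisonFrame:
    """Shared evaluation frame for one pair of cooling curves.

    Built once per pair: the monotone windows, the reference curve, the
    joint temperature range [T_MIN, T_MAX] and its preimage
    [t_MIN, t_MAX] under T_R, the regular K-point time grid, and the Q
    boundary times t_q0..t_q4 (+-inf where the corresponding temperature
    lies outside the reference range).
    """

    T1: CoolingCurve
    T2: CoolingCurve
    T_R: CoolingCurve
    T_A: float
    T0: float
    T_MIN: float
    T_MAX: float
    t_MIN: float
    t_MAX: float
    K: int
    dt: float
    grid: np.ndarray
    t_q: np.ndarray          # five boundary times, may contain +-inf
    a: float
    b: float

    @property
    def t_Q(self) -> list[tuple[float, float]]:
        """Half-open Q-interval times ]t_q(n-1), t_qn], n = 1..4."""
        return [(self.t_q[n - 1], self.t_q[n]) for n in range(1, 5)]


def build_frame(
    T1: CoolingCurve,
    T2: CoolingCurve,
    K: int = 1000,
    a: float = 1.0,
    b: float = 45.0,
) -> ComparisonFrame:
    """Construct the comparison frame for a curve pair.

    The initial temperature T0 := T_R(0) is taken from the unrestricted
    curves at time zero; everything else is computed on the monotone
    windows inside [a, b] (curves are clipped before the range bounds are
    taken).
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if not 0 <= a < b:
        raise ValueError("need 0 <= a < b")
    T_A = T1.T_A if np.isfinite(T1.T_A) else T2.T_A
    T0 = 0.5 * (float(T1.at(0.0)) + float(T2.at(0.0)))

    W1 = _monotone_window(T1, a, b)
    W2 = _monotone_window(T2, a, b)
    T_R = reference_curve(W1, W2)

    T_MAX = min(W1.temps[0], W2.temps[0])
    T_MIN = max(W1.temps[-1], W2.temps[-1])
    if T_MAX <= T_MIN:
        raise ValueError("degenerate joint temperature range (T_MAX <= T_MIN)")

    t_MIN = float(invert_curve(T_R, T_MAX))
    t_MAX = float(invert_curve(T_R, T_MIN))
    grid = np.linspace(t_MIN, t_MAX, K)
    dt = (t_MAX - t_MIN) / (K - 1)

    t_q = np.empty(5)
    for n, q in enumerate(Q_BOUNDS):
        Tq = q_to_temperature(q, T0, T_A)
        if Tq > T_MAX + 1e-12:
            t_q[n] = -np.inf      # reached before the window opens
        elif Tq < T_MIN - 1e-12:
            t_q[n] = np.inf       # never cooled that far within the window
        else:
            t_q[n] = float(invert_curve(T_R, Tq))

    return ComparisonFrame(T1=W1, T2=W2, T_R=T_R, T_A=T_A, T0=T0,
                           T_MIN=T_MIN, T_MAX=T_MAX, t_MIN=t_MIN,
                           t_MAX=t_MAX, K=K, dt=dt, grid=grid, t_q=t_q,
                           a=a, b=b)


@dataclass
class DeviationResult:
    """Global and Q-local maximum time distances for one curve pair."""

    d_max_global: float
    d_max_local: dict[int, float] = field(default_factory=dict)
    K_i: dict[int, int] = field(default_factory=dict)


def d_max(T1: CoolingCurve, T2: CoolingCurve,
          frame: ComparisonFrame | None = None,
          K: int = 1000, a: float = 1.0, b: float = 45.0) -> DeviationResult:
    """Maximum time-since-death deviation between two cooling curves.

    Evaluates |t1(T_R(t^k)) - t2(T_R(t^k))| on the frame's regular grid;
    the global maximum runs over all K points, the local maxima over the
    grid points falling in each half-open Q-interval (intervals without
    grid points are absent from the result).
    """
    if frame is None:
        frame = build_frame(T1, T2, K=K, a=a, b=b)
    Tk = frame.T_R.at(frame.grid)
    diffs = np.abs(invert_curve(frame.T1, Tk) - invert_curve(frame.T2, Tk))
    res = DeviationResult(d_max_global=float(np.max(diffs)))
    for i, (t_lo, t_hi) in enumerate(frame.t_Q, start=1):
        inside = (frame.grid > t_lo) & (frame.grid <= t_hi)
        n = int(inside.sum())
        if n:
            res.d_max_local[i] = float(np.max(diffs[inside]))
            res.K_i[i] = n
    return res


def deviation_difference(d1: DeviationResult, d2: DeviationResult):
    """Signed difference of two deviation results (model-pair contrast).

    Returns (global difference, {Qi: difference for intervals present in
    both results}).
    """
    dg = d1.d_max_global - d2.d_max_global
    dq = {i: d1.d_max_local[i] - d2.d_max_local[i]
          for i in d1.d_max_local if i in d2.d_max_local}
    return dg, dq
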