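"""Eye-trace container and trace conditioning filters.

The conditioning steps mirror standard video-oculography practice for
~20 Hz eye-position recordings:

* a centered 2 s rolling-mean for the vestibular traces (plus centering on
  a 0 deg axis),
* a 1 s running median for the optokinetic traces, which removes noise
  while leaving the steep, monotone position change of a saccade intact,
* a combined Wiener + median smoother followed by linear detrending for
  the sinusoidal-stimulus traces,
* first/second derivatives by central differences.

All windows are given in seconds and converted to an odd sample count;
edges are handled with shrinking windows so no data is fabricated at the
phase boundaries where short-time metrics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "EyeTrace",
    "rolling_mean_center",
    "median_smooth",
    "wiener_median_detrend",
    "kinematics",
    "boxcar_gain",
    "window_samples",
]


@dataclass
class EyeTrace:
    """Uniformly sampled angular eye-position series for one eye and plane."""

    positions: np.ndarray
    sample_rate: float
    plane: str = "vertical"  # "vertical" (front camera) | "horizontal" (top)
    eye: str = "left"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.plane not in ("vertical", "horizontal"):
            raise ValueError("plane must be 'vertical' or 'horizontal'")

    def __len__(self) -> int:
        return self.positions.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.positions.size) / self.sample_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return self.positions.size / self.sample_rate

    def with_positions(self, positions: np.ndarray) -> "EyeTrace":
        return replace(self, positions=np.asarray(positions, dtype=float))

    def slice(self, start_s: float, stop_s: float) -> "EyeTrace":
        """Sub-trace covering [start_s, stop_s) relative to t0."""
        i0 = int(round(start_s * self.sample_rate))
        i1 = int(round(stop_s * self.sample_rate))
        return replace(self, positions=self.positions[i0:i1],
                       t0=self.t0 + i0 / self.sample_rate)


def window_samples(window_s: float, sample_rate: float, *,
                   force_odd: bool = True, warn_even: bool = False) -> int:
    """Convert a window in seconds to a sample count (rounded, forced odd)."""
    n = max(int(round(window_s * sample_rate)), 1)
    if force_odd and n % 2 == 0:
        if warn_even:
            warnings.warn(
                f"even window of {n} samples adjusted up to {n + 1}",
                stacklevel=3)
        n += 1
    return n


def _centered_filter(x: np.ndarray, n: int, kind: str) -> np.ndarray:
    """Centered running mean/median with symmetrically shrinking edges.

    Near the trace ends the window shrinks symmetrically (half-width
    ``min(i, N-1-i, n//2)``), so monotone stretches map onto themselves
    and no data is fabricated at phase boundaries.
    """
    series = pd.Series(x).rolling(n, center=True, min_periods=n)
    out = (series.mean() if kind == "mean" else series.median()).to_numpy()
    half = n // 2
    for i in range(min(half, x.size)):
        h = min(i, x.size - 1 - i)
        wins = (x[i - h:i + h + 1], x[x.size - 1 - i - h:x.size - i + h])
        vals = ([w.mean() for w in wins] if kind == "mean"
                else [np.median(w) for w in wins])
        out[i] = vals[0]
        out[x.size - 1 - i] = vals[1]
    return out


def rolling_mean_center(trace: EyeTrace, window: float = 2.0) -> EyeTrace:
    """Centered rolling-mean smoothing plus centering on the 0 deg axis.

    The window shrinks at the edges; the output mean is exactly zero.
    """
    n = window_samples(window, trace.sample_rate)
    if n < 2:
        raise ValueError("window must span at least 2 samples")
    if len(trace) < n:
        raise ValueError("trace shorter than the smoothing window")
    sm = _centered_filter(trace.positions, n, "mean")
    return trace.with_positions(sm - sm.mean())


def median_smooth(trace: EyeTrace, window: float = 1.0) -> EyeTrace:
    """Running median; removes impulsive noise, preserves steps and ramps."""
    n = window_samples(window, trace.sample_rate, warn_even=True)
    if n < 3:
        raise ValueError("median window must span at least 3 samples")
    if len(trace) < n:
        raise ValueError("trace shorter than the median window")
    return trace.with_positions(_centered_filter(trace.positions, n,
                                                 "median"))


def _wiener(x: np.ndarray, n: int) -> np.ndarray:
    """Adaptive local-variance (Wiener) smoother.

    The noise power is taken as the global median of the local variances, a
    robust floor that leaves genuinely modulated stretches untouched.
    """
    local_mean = _centered_filter(x, n, "mean")
    local_sq = _centered_filter(x * x, n, "mean")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    noise = float(np.median(local_var))
    if noise <= 0.0 and not np.any(local_var > 0):
        return local_mean
    denom = np.maximum(local_var, noise)
    gain = np.where(denom > 0, np.maximum(local_var - noise, 0.0) / denom, 0.0)
    return local_mean + gain * (x - local_mean)


def wiener_median_detrend(trace: EyeTrace, wiener_window: float = 1.0,
                          median_window: float = 1.0) -> EyeTrace:
    """Wiener then median smoothing, then removal of the least-squares line.

    Output has zero mean and zero linear trend.  A zero-variance input
    returns all zeros.
    """
    x = trace.positions
    if np.ptp(x) == 0.0:
        return trace.with_positions(np.zeros_like(x))
    nw = window_samples(wiener_window, trace.sample_rate)
    y = _wiener(x, nw)
    y = median_smooth(trace.with_positions(y), median_window).positions
    t = np.arange(x.size) / trace.sample_rate
    coef = np.polyfit(t, y, 1)
    return trace.with_positions(y - np.polyval(coef, t))


def kinematics(trace: EyeTrace):
    """Velocity (deg/s) and acceleration (deg/s^2) series.

    Central differences in the interior, one-sided at the ends.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples for derivatives")
    v = np.gradient(trace.positions, trace.dt)
    a = np.gradient(v, trace.dt)
    return v, a


def boxcar_gain(frequency: float, window_s: float, sample_rate: float) -> float:
    """Analytic magnitude response of the centered rolling mean at ``frequency``.

    For an N-sample boxcar at sample rate fs the gain at frequency f is
    ``|sin(pi f N / fs) / (N sin(pi f / fs))|`` (Dirichlet kernel).
    """
    n = window_samples(window_s, sample_rate)
    if frequency == 0:
        return 1.0
    num = np.sin(np.pi * frequency * n / sample_rate)
    den = n * np.sin(np.pi * frequency / sample_rate)
    return float(abs(num / den))
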