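"""Scalar outcome measures for the optokinetic and vestibular pipelines.

* ``vor_score`` -- Fourier amplitude of the (smoothed, centered) eye trace
  at the head-rotation frequency, in degrees.  The projection is computed
  exactly at that frequency after trimming to an integer number of
  periods, so arbitrary trace lengths introduce no spectral leakage.
* ``compute_sta`` -- stimulus-triggered average over one stimulus period,
  with rejection of periods where more than half the samples deviate from
  the leave-one-out mean by more than the leave-one-out standard
  deviation (residual saccade artifacts).
* ``fit_sine_linear`` -- least-squares fit of ``A sin(2 pi f t + phi) +
  c + m t`` with the frequency fixed to the stimulus; the amplitude and
  linearity are free.  Optionally, plateau samples (the response pinned
  near its extremum for a sustained stretch) are excluded, since they
  would otherwise drag the sine amplitude down.
* ``gain`` -- eye/stimulus amplitude ratio; velocity-based for the
  vestibular reflex, peak-to-peak position-based for OKR.
* ``xcorr_phase_lag`` -- lag of the normalized cross-correlation peak
  (with parabolic sub-sample refinement), in degrees of stimulus cycle;
  positive means the eye lags.
* ``top_of_descent_phase`` -- phase difference between the points where
  the eye and the stimulus leave their response peak, which stays
  meaningful when the eye trace is plateau-clipped; negative values are
  phase advances (the eye reverses before the stimulus does).
* constant-rotation metrics, dynamic range, cumulative averages and
  tuning grids over spatial frequency x angular velocity (x RR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EyeTrace, window_samples
from .stimulus import StimulusPhase, PhaseKind, temporal_frequency

__all__ = [
    "STAResult", "SineLinearFit", "vor_score", "compute_sta",
    "fit_sine_linear", "gain", "xcorr_phase_lag", "top_of_descent_phase",
    "constant_rotation_metrics", "dynamic_range", "cumulative_average",
    "tuning_grid", "wrap_cycle_deg",
]


@dataclass
class STAResult:
    """Average response to one stimulus period."""

    times: np.ndarray          # one period, starting at 0
    mean: np.ndarray           # deg
    sd: np.ndarray             # per-sample spread over periods used
    periods_used: int
    periods_rejected: int
    sample_rate: float

    @property
    def period(self) -> float:
        return self.times.size / self.sample_rate


@dataclass
class SineLinearFit:
    amplitude: float       # deg, >= 0
    frequency: float       # Hz, fixed to the stimulus
    phase: float           # deg; fit is A sin(2 pi f t + phase)
    offset: float          # deg
    slope: float           # deg/s
    excluded: np.ndarray   # bool mask of samples excluded from the fit

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        w = 2 * np.pi * self.frequency
        return (self.amplitude * np.sin(w * t + np.radians(self.phase))
                + self.offset + self.slope * t)


def wrap_cycle_deg(phase_deg: float) -> float:
    """Wrap a phase to (-180, 180] degrees of cycle."""
    return float(-((-np.asarray(phase_deg) + 180.0) % 360.0 - 180.0))


def vor_score(trace: EyeTrace, rotation_frequency: float) -> float:
    """Single-frequency Fourier amplitude (deg) at the rotation frequency.

    The trace is trimmed to an integer number of rotation periods (at
    least two are required) and the amplitude ``2 |sum x exp(-i w t)| / N``
    is evaluated exactly at the rotation frequency.
    """
    n_per_period = trace.sample_rate / rotation_frequency
    n_periods = int(np.floor(len(trace) / n_per_period + 1e-9))
    if n_periods < 2:
        raise ValueError("need at least two rotation periods")
    n = int(round(n_periods * n_per_period))
    x = trace.positions[:n]
    t = np.arange(n) / trace.sample_rate
    z = np.sum(x * np.exp(-2j * np.pi * rotation_frequency * t))
    return float(2.0 * np.abs(z) / n)


def compute_sta(trace: EyeTrace, period: float,
                rejection: bool = True) -> STAResult:
    """Fold a trace into stimulus periods and average, rejecting outliers.

    A period is rejected when more than 50% of its samples deviate from
    the mean of all *other* periods by more than the per-sample standard
    deviation over those other periods.  With only two periods the
    rejection rule has no robust reference and is disabled with a warning.
    """
    length = int(round(period * trace.sample_rate))
    if abs(length - period * trace.sample_rate) > 1e-6:
        raise ValueError("stimulus period is not an integer sample count")
    n_periods = len(trace) // length
    if n_periods < 2:
        raise ValueError("trace must cover at least two stimulus periods")
    folded = trace.positions[:n_periods * length].reshape(n_periods, length)

    keep = np.ones(n_periods, dtype=bool)
    if rejection and n_periods == 2:
        warnings.warn("only two periods: leave-one-out rejection disabled",
                      stacklevel=2)
        rejection = False
    if rejection:
        frac = np.empty(n_periods)
        for p in range(n_periods):
            others = np.delete(folded, p, axis=0)
            mu = others.mean(axis=0)
            sd = others.std(axis=0, ddof=1)
            frac[p] = np.mean(np.abs(folded[p] - mu) > sd)
        # never reject a majority: the rule flags outliers against the
        # bulk, so at most floor(P/2) periods (the worst offenders) go
        worst = np.argsort(-frac)
        for p in worst[:n_periods // 2]:
            if frac[p] > 0.5:
                keep[p] = False
        if not keep.any():
            raise ValueError("all periods rejected")
    used = folded[keep]
    sd = (used.std(axis=0, ddof=1) if used.shape[0] > 1
          else np.zeros(length))
    return STAResult(times=np.arange(length) / trace.sample_rate,
                     mean=used.mean(axis=0), sd=sd,
                     periods_used=int(keep.sum()),
                     periods_rejected=int((~keep).sum()),
                     sample_rate=trace.sample_rate)


def _plateau_mask(y: np.ndarray, delta_frac: float = 0.05,
                  min_dwell_frac: float = 0.10) -> np.ndarray:
    """Samples pinned within ``delta_frac`` of the response extremum for at
    least ``min_dwell_frac`` of the period."""
    span = np.ptp(y)
    if span == 0:
        return np.zeros(y.size, dtype=bool)
    delta = delta_frac * span
    min_run = max(int(np.ceil(min_dwell_frac * y.size)), 2)
    mask = np.zeros(y.size, dtype=bool)
    for near in (y >= y.max() - delta, y <= y.min() + delta):
        padded = np.concatenate(([False], near, [False]))
        edges = np.flatnonzero(np.diff(padded))
        for r0, r1 in zip(edges[0::2], edges[1::2]):
            if r1 - r0 >= min_run:
                mask[r0:r1] = True
    return mask


def fit_sine_linear(sta: STAResult, frequency: float,
                    plateau_exclusion: bool = True) -> SineLinearFit:
    """Least-squares sine + line fit to an STA with the frequency fixed.

    The model is linear in its parameters (sin/cos quadrature, offset,
    slope), so the fit is a single ``lstsq``.  With ``plateau_exclusion``
    the clipped extremum stretches are masked before fitting.
    """
    t, y = sta.times, sta.mean
    excluded = (_plateau_mask(y) if plateau_exclusion
                else np.zeros(y.size, dtype=bool))
    use = ~excluded
    if use.sum() < 8:
        raise ValueError("fewer than 8 samples left for the sine fit")
    w = 2 * np.pi * frequency
    design = np.column_stack([np.sin(w * t[use]), np.cos(w * t[use]),
                              np.ones(use.sum()), t[use]])
    coef, *_ = np.linalg.lstsq(design, y[use], rcond=None)
    a, b, c, m = coef
    return SineLinearFit(amplitude=float(np.hypot(a, b)),
                         frequency=frequency,
                         phase=float(np.degrees(np.arctan2(b, a))),
                         offset=float(c), slope=float(m), excluded=excluded)


def gain(eye_amplitude: float, stimulus_amplitude: float, *,
         mode: str = "okr", frequency: float | None = None) -> float:
    """Eye/stimulus response ratio.

    ``okr`` mode divides peak-to-peak fitted eye position by peak-to-peak
    stimulus position (both may equally be half-amplitudes).  ``vvor``
    mode converts a position amplitude into a velocity amplitude
    (``2 pi f A``) and divides by the peak head velocity.
    """
    if stimulus_amplitude == 0:
        raise ValueError("stimulus amplitude must be nonzero")
    if mode == "okr":
        return float(eye_amplitude / stimulus_amplitude)
    if mode == "vvor":
        if frequency is None:
            raise ValueError("vvor mode needs the rotation frequency")
        return float(2 * np.pi * frequency * eye_amplitude
                     / stimulus_amplitude)
    raise ValueError("mode must be 'okr' or 'vvor'")


def xcorr_phase_lag(eye: np.ndarray, stimulus: np.ndarray,
                    frequency: float, sample_rate: float) -> float:
    """Phase lag (deg of cycle) between eye and stimulus by correlation.

    Positive values mean the eye lags the stimulus.  The lag of the
    maximum cross-correlation of the two fundamental components is
    computed in closed form: projecting each demeaned series onto the
    quadrature pair at the stimulus frequency (over an integer number of
    periods) gives each signal's fundamental phase, and their difference
    is the sub-sample correlation-peak lag.  This avoids the overlap
    taper that biases a sampled correlogram's peak interpolation.
    """
    eye = np.asarray(eye, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    if eye.size != stimulus.size:
        raise ValueError("series must share a common sampling")
    samples_per_period = sample_rate / frequency
    n_periods = int(np.floor(eye.size / samples_per_period + 1e-9))
    if n_periods < 2:
        raise ValueError("need at least two stimulus periods")
    n = int(round(n_periods * samples_per_period))
    e = eye[:n] - eye[:n].mean()
    s = stimulus[:n] - stimulus[:n].mean()
    if np.std(e) == 0 or np.std(s) == 0:
        raise ValueError("zero-variance input")
    t = np.arange(n) / sample_rate
    carrier = np.exp(-2j * np.pi * frequency * t)
    z_eye = np.sum(e * carrier)
    z_stim = np.sum(s * carrier)
    if z_eye == 0 or z_stim == 0:
        raise ValueError("no power at the stimulus frequency")
    return wrap_cycle_deg(np.degrees(np.angle(z_stim) - np.angle(z_eye)))


def _top_of_descent(sta: STAResult, frequency: float,
                    smooth_window: float | None = None) -> float:
    """Time (s, within the period) where the response leaves its peak.

    The STA is treated as periodic.  The rolling-mean gradient is scanned
    from the fitted sine's maximum for the first point where it has fallen
    half a standard deviation below its value at the peak; the crossing is
    located with sub-sample (linear) interpolation.

    The gradient smoothing window defaults to 0.5 s but grows with slow
    stimuli (2% of the period) -- at repetition rates far below the
    design range the slow-phase gradient is tiny and a fixed short
    window would leave it buried in sample noise.
    """
    y = sta.mean
    n = y.size
    dt = 1.0 / sta.sample_rate
    if smooth_window is None:
        smooth_window = max(0.5, 0.02 * sta.period)
    # never smooth over more than a quarter period, or the gradient's
    # structure is destroyed for fast stimuli
    smooth_window = min(smooth_window, sta.period / 4.0)
    fit = fit_sine_linear(sta, frequency, plateau_exclusion=True)
    t_peak = ((90.0 - fit.phase) / 360.0 / frequency) % sta.period

    grad = np.gradient(np.concatenate([y[-2:], y, y[:2]]), dt)[2:-2]
    nwin = window_samples(smooth_window, sta.sample_rate)
    kernel = np.ones(nwin) / nwin
    pad = nwin // 2
    wrapped = np.concatenate([grad[-pad:], grad, grad[:pad]])
    gs = np.convolve(wrapped, kernel, mode="valid")[:n]
    sd = float(gs.std())
    if sd == 0:
        raise ValueError("flat gradient: top of descent undefined")

    i_peak = int(round(t_peak / dt)) % n
    threshold = gs[i_peak] - 0.5 * sd

    def scan(dwell: int) -> float | None:
        below = 0
        for step in range(1, n + dwell + 1):
            i = (i_peak + step) % n
            if gs[i] <= threshold:
                below += 1
                if below >= dwell:
                    first = step - dwell + 1
                    prev = gs[(i_peak + first - 1) % n]
                    cur = gs[(i_peak + first) % n]
                    frac = (0.0 if prev == cur
                            else (prev - threshold) / (prev - cur))
                    frac = float(np.clip(frac, 0.0, 1.0))
                    return ((i_peak + first - 1 + frac) * dt) % sta.period
            else:
                below = 0
        return None

    # The descent must hold the criterion for a sustained stretch (5% of
    # the period) so that a residual saccade step -- a gradient blip of
    # roughly one smoothing window -- cannot pass for the descent.  If
    # nothing sustains that long (heavily fragmented traces), fall back
    # to a minimal dwell rather than fail.
    for dwell in (max(2, int(round(0.05 * n))), max(2, nwin // 4), 1):
        tod = scan(dwell)
        if tod is not None:
            return tod
    raise ValueError("gradient never crossed the top-of-descent criterion")


def top_of_descent_phase(sta_eye: STAResult, sta_stimulus: STAResult,
                         frequency: float,
                         smooth_window: float | None = None) -> float:
    """Signed phase (deg of cycle) between eye and stimulus tops of descent.

    Positive means the eye leaves its peak after the stimulus does (a
    lag); negative is a phase advance.
    """
    tod_eye = _top_of_descent(sta_eye, frequency, smooth_window)
    tod_stim = _top_of_descent(sta_stimulus, frequency, smooth_window)
    return wrap_cycle_deg((tod_eye - tod_stim) * frequency * 360.0)


def constant_rotation_metrics(trace: EyeTrace, phase: StimulusPhase,
                              window_s: float = 4.0):
    """(gain, amplitude) of the initial following response.

    ``trace`` is the saccade-removed eye trace of one constant-rotation
    stimulation phase, starting at the phase onset.  The amplitude is the
    absolute eye deflection accumulated over the first ``window_s``
    seconds; the gain divides it by the stimulus excursion ``v_a *
    window_s``.
    """
    if phase.kind is not PhaseKind.CONSTANT:
        raise ValueError("phase must be a constant-rotation phase")
    if phase.duration < window_s or trace.duration < window_s:
        raise ValueError(f"phase shorter than {window_s} s")
    i1 = int(round(window_s * trace.sample_rate))
    amplitude = float(abs(trace.positions[i1] - trace.positions[0]))
    return amplitude / (phase.angular_velocity * window_s), amplitude


def dynamic_range(sta_or_amplitude, *, constant_rotation: bool = False) -> float:
    """Max minus min of an STA, or twice the one-directional 4-s amplitude
    for constant-rotation stimuli."""
    if constant_rotation:
        return float(2.0 * sta_or_amplitude)
    y = (sta_or_amplitude.mean if isinstance(sta_or_amplitude, STAResult)
         else np.asarray(sta_or_amplitude, dtype=float))
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.ptp(y))


def cumulative_average(traces, saccade_lists=None, directions=None):
    """Average phase-aligned traces, saccade-removed and direction-folded.

    ``saccade_lists`` may be None (the first-15-s variant keeps saccades
    in).  ``directions`` holds each phase's stimulus direction; counter-
    clockwise phases are sign-flipped before averaging so that following
    responses add up positively.
    """
    from .saccades import remove_saccades

    traces = list(traces)
    if not traces:
        raise ValueError("no traces to average")
    n = len(traces[0])
    if any(len(tr) != n for tr in traces):
        raise ValueError("traces must have equal length")
    if saccade_lists is not None:
        traces = [remove_saccades(tr, evs)
                  for tr, evs in zip(traces, saccade_lists)]
    stack = np.stack([tr.positions - tr.positions[0] for tr in traces])
    if directions is not None:
        stack = stack * np.asarray(directions, dtype=float)[:, None]
    return traces[0].with_positions(stack.mean(axis=0))


def tuning_grid(records) -> pd.DataFrame:
    """Aggregate per-condition metrics into a mean +/- sem tuning grid.

    ``records`` is an iterable of dicts with keys ``spatial_frequency``,
    ``angular_velocity``, optional ``repetition_rate``, and ``value``.
    Cells with a single replicate carry ``sem = NaN`` and are flagged.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("empty grid")
    keys = [k for k in ("spatial_frequency", "angular_velocity",
                        "repetition_rate") if k in df.columns]
    g = df.groupby(keys)["value"]
    out = g.agg(mean="mean", sem="sem", n="count").reset_index()
    out["single_replicate"] = out["n"] == 1
    out["temporal_frequency"] = [
        temporal_frequency(va, fs)
        for va, fs in zip(out["angular_velocity"], out["spatial_frequency"])
    ]
    return out
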