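"""Synthetic dual-camera eye traces with recoverable ground truth.

The generators emulate the statistical structure of ~20 Hz dual-camera
video-oculography of an embedded zebrafish larva:

* vestibular roll (vVOR) phases: a near-perfect sinusoid of vertical eye
  position locked to head roll position, Gaussian sensor noise, rare
  single-sample vibration outliers, and no saccades during rotation;
* constant-rotation OKR phases: a vertical start response rising to a
  plateau within a few seconds (vOKR) or the classic horizontal sawtooth
  of slow phases and resetting quick phases (hOKR), with spontaneous
  saccades and slow drift back toward a neutral position;
* sinusoidal-envelope OKR phases: a scaled, phase-shifted copy of the
  stimulus position, optionally clipped at a plateau cap, with
  spontaneous saccades adding persistent step offsets;
* saccades themselves: logistic sigmoid steps of 0.15-0.3 s whose peak
  velocity comfortably exceeds the detection thresholds.

True horizontal/vertical rotations are passed through the dual-camera
projection model, so apparent traces carry the front-camera artifact.

Calibration presets pin the generator to published summary values.
Because the analysis pipeline itself attenuates amplitudes (smoothing)
and offsets plateau-exit phases (clipping), calibrated presets are
specified in terms of the *pipeline-recovered* value: the generator
divides injected vestibular amplitudes by the analytic smoothing-filter
gain, and for sinusoidal presets it calibrates the injected amplitude
and time shift numerically against the deterministic noise-free pipeline
so that the recovered gain/phase equals the configured one.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EyeTrace, boxcar_gain
from .projection import EyeGeometry, project_eye_orientation
from .stimulus import PhaseKind, Protocol, StimulusPhase, stimulus_kinematics

__all__ = [
    "SyntheticConfig", "SyntheticDataset", "PRESETS", "get_preset",
    "inject_saccade", "generate_vvor_dataset", "generate_pause_dataset",
    "generate_constant_okr_dataset", "generate_sinusoidal_okr_dataset",
    "generate_saccade_population", "phase_segments",
]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic eye-movement generators.

    Rates are per minute for saccades and per second for vibration
    spikes; amplitudes and caps are in degrees; phases in degrees of
    stimulus cycle (positive = eye lags).
    """

    sample_rate: float = 20.0
    noise_sd: float = 0.3
    vibration_rate: float = 0.02          # spikes / s
    vibration_magnitude: float = 2.0      # deg, single sample
    spontaneous_saccade_rate: float = 0.82  # saccades / min
    #: per-plane amplitude distribution: (mean, sd, low, high), deg.
    #: The lower bounds keep the worst-case apparent peak velocity (a
    #: step split across two 20 Hz frames by the median filter halves
    #: the central-difference peak to ~5 |A| deg/s) above the plane's
    #: detection threshold.
    saccade_amplitude: dict = field(default_factory=lambda: {
        "vertical": (5.0, 1.5, 3.0, 9.0),
        "horizontal": (12.0, 4.0, 7.0, 25.0)})
    saccade_duration: tuple = (0.15, 0.30)  # s
    #: (p_vertical_only, p_horizontal_only, p_combined)
    cluster_probabilities: tuple = (0.105, 0.140, 0.755)
    vvor_amplitude: float = 15.9          # deg, pipeline-recovered
    vvor_phase: float = 0.0               # deg of cycle
    okr_gain: float = 0.23                # pipeline-recovered
    okr_phase: float = 0.0                # deg of cycle, pipeline-recovered
    plateau_deflection: float = 6.25      # deg; constant-vOKR plateau D
    time_constant: float = 1.5            # s; start-response tau
    drift_rate: float = 0.5               # deg/s back toward neutral
    decay_tau: float = 1.5                # s; offset decay in event batches
    plateau_cap: float | None = None      # deg; sinusoidal clipping
    reset_threshold: float = 18.0         # deg; hOKR quick-phase trigger
    reset_overshoot: float = 1.0          # deg
    min_event_gap: float = 1.5            # s
    event_count_mode: str = "poisson"     # "poisson" | "expected"
    smoothing_window: float = 2.0         # s; vVOR rolling-mean window
    geometry: EyeGeometry = field(default_factory=EyeGeometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.time_constant <= 0:
            raise ValueError("sample_rate and time_constant must be positive")
        if abs(sum(self.cluster_probabilities) - 1.0) > 1e-9:
            raise ValueError("cluster probabilities must sum to 1")
        if self.event_count_mode not in ("poisson", "expected"):
            raise ValueError("event_count_mode must be 'poisson' or 'expected'")
        for name in ("noise_sd", "vibration_rate", "vibration_magnitude",
                     "spontaneous_saccade_rate", "vvor_amplitude",
                     "okr_gain", "plateau_deflection", "drift_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(copy.deepcopy(self), **kw)


#: Calibration table: named presets pinned to published summary values.
#: Each entry: (config overrides, provenance note).
PRESETS: dict[str, tuple[dict, str]] = {
    "vvor-90-score": (
        {"vvor_amplitude": 15.9},
        "mean VOR score at 90 deg/s roll (0.25 Hz), deg"),
    "vvor-90-range": (
        {"vvor_amplitude": 16.15},
        "half the mean vVOR dynamic range (32.3 deg) at 90 deg/s, deg"),
    "pause-saccades": (
        {"spontaneous_saccade_rate": 0.82,
         "event_count_mode": "expected",
         "saccade_amplitude": {"vertical": (5.5, 1.2, 3.0, 8.0),
                               "horizontal": (12.0, 4.0, 5.0, 25.0)}},
        "spontaneous saccade rate during stationary pause phases, per min"),
    "cluster-mix": (
        {"cluster_probabilities": (0.105, 0.140, 0.755),
         "event_count_mode": "expected",
         "decay_tau": 2.5,
         # moderate horizontal components: keeps the front-camera
         # artifact from manufacturing spurious vertical events during
         # the post-saccadic return drift
         "saccade_amplitude": {"vertical": (5.0, 1.5, 3.0, 9.0),
                               "horizontal": (10.0, 2.5, 7.0, 15.0)}},
        "published apparent-direction cluster proportions of spontaneous "
        "saccades (vertical-only, horizontal-only, combined)"),
    "hokr-4s": (
        {"okr_gain": 16.92 / (28.12 * 4.0)},
        "horizontal eye deflection of 16.92 deg after 4 s of constant "
        "rotation at 28.12 deg/s"),
    "vokr-4s": (
        {"plateau_deflection": 5.81 / (1.0 - np.exp(-4.0 / 1.5)),
         "time_constant": 1.5},
        "vertical eye deflection of 5.81 deg after 4 s of constant "
        "rotation at 28.12 deg/s"),
    "sine-gain": (
        {"okr_gain": 0.23, "plateau_cap": None},
        "peak position gain 0.23 for the sinusoidal-envelope stimulus at "
        "5.55 deg/s, 0.041 cyc/deg, RR 0.125 Hz"),
    "phase-0.5Hz": (
        {"okr_phase": 65.76, "okr_gain": 0.15, "plateau_cap": None},
        "top-of-descent phase lag 65.76 deg of cycle at RR 0.5 Hz"),
    "phase-0.0078Hz": (
        {"okr_phase": -59.37, "okr_gain": 0.10, "plateau_cap": 5.0},
        "top-of-descent phase advance -59.37 deg of cycle at RR "
        "0.0078125 Hz, plateau-clipped response"),
}


def get_preset(name: str, **extra) -> SyntheticConfig:
    """Return the calibration preset ``name``, optionally overridden."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    overrides, _note = PRESETS[name]
    return SyntheticConfig(**{**overrides, **extra})


@dataclass
class SyntheticDataset:
    """Generated traces plus the ground truth needed to score recovery."""

    traces: dict[str, EyeTrace]
    ground_truth: dict
    config: SyntheticConfig
    protocol: Protocol | None = None


def phase_segments(protocol: Protocol, sample_rate: float):
    """Yield (phase, i0, i1) sample windows of each protocol phase."""
    t = 0.0
    for phase in protocol.phases:
        i0 = int(round(t * sample_rate))
        i1 = int(round((t + phase.duration) * sample_rate))
        yield phase, i0, i1
        t += phase.duration


# ---------------------------------------------------------------------------
# event machinery


def _sigmoid_step(t_local: np.ndarray, amplitude: float,
                  duration: float) -> np.ndarray:
    """Logistic step covering 2.5-97.5% of ``amplitude`` within ``duration``.

    Peak velocity is ``amplitude * ln(39) / (2 * duration)``, i.e. about
    1.83 x amplitude/duration.
    """
    k = 2.0 * np.log(39.0) / duration
    return amplitude / (1.0 + np.exp(-k * (t_local - duration / 2.0)))


def inject_saccade(trace: EyeTrace, t0: float, amplitude: float,
                   duration: float, existing=None) -> EyeTrace:
    """Add a sigmoidal saccade with a persistent offset to a trace.

    ``existing`` is an optional list of (start_s, end_s) intervals of
    previously injected events; overlap raises ``ValueError`` and the
    new interval is appended on success.
    """
    if duration > 0.5:
        raise ValueError("saccade duration must be <= 0.5 s")
    if t0 < 0 or t0 + duration > trace.duration:
        raise ValueError("saccade does not fit inside the trace")
    if existing is not None:
        for s, e in existing:
            if t0 < e and t0 + duration > s:
                raise ValueError(
                    f"saccade at {t0:.3f}s overlaps existing event ({s:.3f},"
                    f" {e:.3f})")
        existing.append((t0, t0 + duration))
    if amplitude == 0:
        return trace.with_positions(trace.positions.copy())
    t = np.arange(len(trace)) / trace.sample_rate
    x = trace.positions + np.where(
        t < t0, 0.0,
        np.where(t > t0 + duration, amplitude,
                 _sigmoid_step(t - t0, amplitude, duration)))
    return trace.with_positions(x)


def _event_times(rng: np.random.Generator, duration_s: float,
                 rate_per_min: float, min_gap: float, mode: str,
                 margin: float = 1.0) -> np.ndarray:
    """Event times of a (conditioned) Poisson process with a minimum gap.

    ``mode='expected'`` pins the count to round(rate * duration);
    ``'poisson'`` draws it.  Times are uniform conditional on the gap
    (stars-and-bars construction), exact for both modes.
    """
    if rate_per_min <= 0 or duration_s <= 2 * margin:
        return np.array([])
    expected = rate_per_min * duration_s / 60.0
    n = (int(round(expected)) if mode == "expected"
         else int(rng.poisson(expected)))
    usable = duration_s - 2 * margin
    while n > 0 and n * min_gap > 0.8 * usable:
        n -= 1
    if n == 0:
        return np.array([])
    u = np.sort(rng.uniform(0.0, usable - (n - 1) * min_gap, size=n))
    return margin + u + min_gap * np.arange(n)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= low) & (draw <= high)]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _offset_channel(n: int, fs: float, events, *, decay: str = "none",
                    drift_rate: float = 0.0, tau: float = 1.5) -> np.ndarray:
    """Piecewise offset from saccadic steps with optional decay to neutral.

    ``events``: (t0, amplitude, duration) sorted by time.  Between events
    the offset decays linearly at ``drift_rate`` (decay='linear'),
    exponentially with ``tau`` (decay='exp'), or persists (decay='none').
    """
    x = np.zeros(n)
    t = np.arange(n) / fs
    level = 0.0
    cursor = 0
    for t0, amp, dur in events:
        i0 = min(int(round(t0 * fs)), n)
        i1 = min(int(round((t0 + dur) * fs)) + 1, n)
        seg = slice(cursor, i0)
        dt_seg = t[seg] - t[cursor] if i0 > cursor else None
        if dt_seg is not None:
            if decay == "linear":
                x[seg] = np.sign(level) * np.maximum(
                    abs(level) - drift_rate * dt_seg, 0.0)
            elif decay == "exp":
                x[seg] = level * np.exp(-dt_seg / tau)
            else:
                x[seg] = level
            level = x[i0 - 1] if i0 > cursor else level
        x[i0:i1] = level + _sigmoid_step(
            t[i0:i1] - t0, amp, dur)
        level += amp
        cursor = i1
    if cursor < n:
        dt_seg = t[cursor:] - t[cursor]
        if decay == "linear":
            x[cursor:] = np.sign(level) * np.maximum(
                abs(level) - drift_rate * dt_seg, 0.0)
        elif decay == "exp":
            x[cursor:] = level * np.exp(-dt_seg / tau)
        else:
            x[cursor:] = level
    return x


#: plane peak-velocity detection thresholds used to bound event durations
_PLANE_PEAK_THR = {"vertical": 10.0, "horizontal": 30.0}


def _event_duration(rng: np.random.Generator, amplitudes: dict,
                    dur_range: tuple) -> float:
    """Draw a saccade duration honouring the 2x peak-velocity contract.

    A logistic step's peak velocity is ~1.83 |A| / duration, so the
    duration is capped at 0.95 * 1.83 |A| / (2 * threshold) for every
    plane the event moves in (floored at the configured minimum).
    """
    lo, hi = dur_range
    for plane, amp in amplitudes.items():
        if amp != 0.0:
            # peak velocity of the logistic step is |A| ln(39) / (2 d)
            hi = min(hi, 0.95 * np.log(39.0) / 2.0 * abs(amp)
                     / (2.0 * _PLANE_PEAK_THR[plane]))
    hi = max(hi, lo)
    return float(rng.uniform(lo, hi))


def _vibration(rng: np.random.Generator, n: int, fs: float,
               rate: float, magnitude: float) -> np.ndarray:
    out = np.zeros(n)
    count = int(rng.poisson(rate * n / fs))
    if count:
        idx = rng.integers(0, n, size=count)
        out[idx] += rng.choice([-magnitude, magnitude], size=count)
    return out


# ---------------------------------------------------------------------------
# generators


def generate_pause_dataset(config: SyntheticConfig, duration_s: float,
                           seed: int | None = None) -> SyntheticDataset:
    """Stationary (pause-phase) recording: spontaneous saccades + noise.

    Vertical-plane trace of one eye; saccade amplitudes follow the
    vertical-plane distribution with random sign, offsets drift back
    toward neutral.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sample_rate
    n = int(round(duration_s * fs))
    times = _event_times(rng, duration_s, config.spontaneous_saccade_rate,
                         config.min_event_gap, config.event_count_mode)
    mean, sd, lo, hi = config.saccade_amplitude["vertical"]
    amps = (_truncnorm(rng, mean, sd, lo, hi, times.size)
            * rng.choice([-1.0, 1.0], size=times.size))
    durs = [_event_duration(rng, {"vertical": a}, config.saccade_duration)
            for a in amps]
    events = list(zip(times, amps, durs))
    x = _offset_channel(n, fs, events, decay="linear",
                        drift_rate=config.drift_rate)
    x += rng.normal(0.0, config.noise_sd, size=n)
    trace = EyeTrace(x, fs, plane="vertical", eye="left")
    truth = {"saccades": [
        {"time_s": float(t), "amplitude_deg": float(a),
         "duration_s": float(d)} for t, a, d in events]}
    return SyntheticDataset({"left_vertical": trace}, truth, config)


def generate_vvor_dataset(config: SyntheticConfig, protocol: Protocol,
                          seed: int | None = None) -> SyntheticDataset:
    """Vertical VOR recording (front camera, both eyes).

    During rotation phases the eye follows head roll position:
    ``eye(t) = -direction * A * sin(2 pi f_rot t - phase)`` with the
    injected amplitude pre-compensated for the rolling-mean smoothing
    gain at the rotation frequency, so the pipeline-recovered amplitude
    equals the configured one.  No saccades occur during rotation;
    spontaneous saccades populate the pause phases.
    """
    for ph in protocol.stimulation_phases:
        if ph.kind is not PhaseKind.CONSTANT or ph.spatial_frequency != 0:
            raise ValueError("protocol is not a vestibular roll protocol")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sample_rate
    n = int(round(protocol.total_duration * fs))
    phi = np.radians(config.vvor_phase)

    base = np.zeros(n)
    phase_info = []
    truth_saccades = []
    for phase, i0, i1 in phase_segments(protocol, fs):
        t_local = np.arange(i1 - i0) / fs
        if phase.kind is PhaseKind.CONSTANT:
            f_rot = phase.rotation_frequency
            amp = config.vvor_amplitude / boxcar_gain(
                f_rot, config.smoothing_window, fs)
            base[i0:i1] = (-phase.direction * amp
                           * np.sin(2 * np.pi * f_rot * t_local - phi))
            phase_info.append({
                "start_s": i0 / fs, "duration_s": phase.duration,
                "rotation_frequency_hz": f_rot,
                "direction": phase.direction,
                "angular_velocity": phase.angular_velocity})
        else:
            times = _event_times(
                rng, phase.duration, config.spontaneous_saccade_rate,
                config.min_event_gap, config.event_count_mode)
            mean, sd, lo, hi = config.saccade_amplitude["vertical"]
            amps = (_truncnorm(rng, mean, sd, lo, hi, times.size)
                    * rng.choice([-1.0, 1.0], size=times.size))
            durs = [_event_duration(rng, {"vertical": a},
                                    config.saccade_duration) for a in amps]
            events = list(zip(times, amps, durs))
            base[i0:i1] = _offset_channel(
                i1 - i0, fs, events, decay="linear",
                drift_rate=config.drift_rate)
            truth_saccades += [
                {"time_s": float(i0 / fs + t), "amplitude_deg": float(a)}
                for t, a, _ in events]

    traces = {}
    for eye in ("left", "right"):
        x = base + rng.normal(0.0, config.noise_sd, size=n)
        x += _vibration(rng, n, fs, config.vibration_rate,
                        config.vibration_magnitude)
        traces[f"{eye}_vertical"] = EyeTrace(x, fs, plane="vertical", eye=eye)
    truth = {"amplitude_deg": config.vvor_amplitude,
             "phase_deg": config.vvor_phase,
             "stimulation_phases": phase_info,
             "saccades": truth_saccades}
    return SyntheticDataset(traces, truth, config, protocol)


def _apply_projection(h_true: np.ndarray, v_true: np.ndarray,
                      geometry: EyeGeometry):
    """True rotations -> apparent per-camera angle traces."""
    proj = project_eye_orientation(h_true, v_true, geometry)
    return np.asarray(proj["top"].angle), np.asarray(proj["front"].angle)


def _typed_events(rng, config: SyntheticConfig, times: np.ndarray,
                  n_types=None):
    """Assign cluster types and per-plane amplitudes/durations to events.

    Returns a list of dicts with vertical/horizontal amplitudes (0 for an
    absent component) and the ground-truth cluster label.
    """
    n = times.size
    p = np.asarray(config.cluster_probabilities)
    if config.event_count_mode == "expected":
        counts = np.floor(n * p).astype(int)
        order = np.argsort(-(n * p - counts))
        for i in range(n - counts.sum()):
            counts[order[i % 3]] += 1
        types = np.repeat([1, 2, 3], counts)
        rng.shuffle(types)
    else:
        types = rng.choice([1, 2, 3], size=n, p=p)
    vm, vs, vlo, vhi = config.saccade_amplitude["vertical"]
    hm, hs, hlo, hhi = config.saccade_amplitude["horizontal"]
    v_amp = _truncnorm(rng, vm, vs, vlo, vhi, n) * rng.choice([-1., 1.], n)
    h_amp = _truncnorm(rng, hm, hs, hlo, hhi, n) * rng.choice([-1., 1.], n)
    events = []
    for i, t0 in enumerate(times):
        ty = int(types[i])
        va = float(v_amp[i]) if ty in (1, 3) else 0.0
        ha = float(h_amp[i]) if ty in (2, 3) else 0.0
        if ty == 3:
            cluster = 3 if np.sign(va) == np.sign(ha) else 4
        else:
            cluster = ty
        dur = _event_duration(rng, {"vertical": va, "horizontal": ha},
                              config.saccade_duration)
        events.append({"time_s": float(t0), "vertical_deg": va,
                       "horizontal_deg": ha, "duration_s": dur,
                       "cluster": cluster})
    return events


def generate_saccade_population(config: SyntheticConfig, n_events: int,
                                rate_per_min: float = 10.0,
                                seed: int | None = None) -> SyntheticDataset:
    """Long stationary recording carrying ``n_events`` typed saccades.

    Events are vertical-only, horizontal-only or combined according to
    the configured cluster probabilities; both true rotation traces are
    passed through the dual-camera projection, so the apparent traces
    include the front-camera artifact.  Offsets decay exponentially back
    to neutral between events.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sample_rate
    duration_s = n_events * 60.0 / rate_per_min + 20.0
    n = int(round(duration_s * fs))
    gap = max(config.min_event_gap, 2.0)
    usable = duration_s - 2.0
    spacing = usable / n_events
    if spacing <= gap:
        raise ValueError("rate too high for the minimum event gap")
    # uniform-with-gap construction, pinned to exactly n_events
    u = np.sort(rng.uniform(0.0, usable - (n_events - 1) * gap,
                            size=n_events))
    times = 1.0 + u + gap * np.arange(n_events)
    events = _typed_events(rng, config, times)

    v_events = [(e["time_s"], e["vertical_deg"], e["duration_s"])
                for e in events if e["vertical_deg"] != 0.0]
    h_events = [(e["time_s"], e["horizontal_deg"], e["duration_s"])
                for e in events if e["horizontal_deg"] != 0.0]
    v_true = _offset_channel(n, fs, v_events, decay="exp",
                             tau=config.decay_tau)
    h_true = _offset_channel(n, fs, h_events, decay="exp",
                             tau=config.decay_tau)
    h_app, v_app = _apply_projection(h_true, v_true, config.geometry)
    v_app = v_app + rng.normal(0.0, config.noise_sd, size=n)
    h_app = h_app + rng.normal(0.0, config.noise_sd, size=n)
    traces = {
        "left_vertical": EyeTrace(v_app, fs, plane="vertical", eye="left"),
        "left_horizontal": EyeTrace(h_app, fs, plane="horizontal",
                                    eye="left"),
    }
    truth = {"saccades": events,
             "cluster_probabilities": list(config.cluster_probabilities)}
    return SyntheticDataset(traces, truth, config)


def generate_constant_okr_dataset(config: SyntheticConfig,
                                  protocol: Protocol, mode: str,
                                  seed: int | None = None) -> SyntheticDataset:
    """Constant-rotation OKR recording (both planes, one eye).

    ``mode='vokr'``: the vertical plane carries the start response
    ``direction * D * (1 - exp(-t / tau))``; spontaneous saccades start
    5 s into each stimulation phase.  ``mode='hokr'``: the horizontal
    plane ramps at ``gain * v_a`` and resets with a quick phase whenever
    the excursion reaches the reset threshold.  True rotations pass
    through the dual-camera projection model.
    """
    if mode not in ("vokr", "hokr"):
        raise ValueError("mode must be 'vokr' or 'hokr'")
    for ph in protocol.stimulation_phases:
        if ph.kind is not PhaseKind.CONSTANT:
            raise ValueError("protocol is not a constant-rotation protocol")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sample_rate
    n = int(round(protocol.total_duration * fs))
    v_true = np.zeros(n)
    h_true = np.zeros(n)
    truth_saccades = []
    phase_info = []

    for phase, i0, i1 in phase_segments(protocol, fs):
        m = i1 - i0
        t_local = np.arange(m) / fs
        if phase.kind is PhaseKind.PAUSE:
            # return to neutral from the previous phase's end position
            for arr in (v_true, h_true):
                if i0 > 0 and arr[i0 - 1] != 0.0:
                    lvl = arr[i0 - 1]
                    arr[i0:i1] = np.sign(lvl) * np.maximum(
                        abs(lvl) - config.drift_rate * t_local, 0.0)
            continue
        start0 = v_true[i0 - 1] if i0 > 0 else 0.0
        starth = h_true[i0 - 1] if i0 > 0 else 0.0
        if mode == "vokr":
            slow = (phase.direction * config.plateau_deflection
                    * (1.0 - np.exp(-t_local / config.time_constant)))
            times = _event_times(
                rng, phase.duration - 5.0, config.spontaneous_saccade_rate,
                config.min_event_gap, config.event_count_mode)
            times = times + 5.0
            events = _typed_events(rng, config, times)
            ve = [(e["time_s"], e["vertical_deg"], e["duration_s"])
                  for e in events if e["vertical_deg"] != 0.0]
            he = [(e["time_s"], e["horizontal_deg"], e["duration_s"])
                  for e in events if e["horizontal_deg"] != 0.0]
            v_true[i0:i1] = start0 + slow + _offset_channel(
                m, fs, ve, decay="linear", drift_rate=config.drift_rate)
            h_true[i0:i1] = starth + _offset_channel(
                m, fs, he, decay="linear", drift_rate=config.drift_rate)
            for e in events:
                e["time_s"] += i0 / fs
            truth_saccades += events
        else:
            slope = config.okr_gain * phase.angular_velocity
            reset_amp = config.reset_threshold + config.reset_overshoot
            pos = starth + phase.direction * slope * t_local
            t_next = ((config.reset_threshold - phase.direction * starth)
                      / slope if slope > 0 else np.inf)
            quick = []
            while t_next < phase.duration - 0.5:
                dur = float(rng.uniform(*config.saccade_duration))
                amp = -phase.direction * (reset_amp
                                          + rng.normal(0.0, 0.5))
                quick.append((t_next, amp, dur))
                t_next += abs(amp) / slope
            pos = pos + _offset_channel(m, fs, quick, decay="none")
            h_true[i0:i1] = pos
            v_true[i0:i1] = start0
            truth_saccades += [
                {"time_s": float(i0 / fs + t), "horizontal_deg": float(a),
                 "vertical_deg": 0.0, "duration_s": d, "cluster": 2}
                for t, a, d in quick]
        phase_info.append({
            "start_s": i0 / fs, "duration_s": phase.duration,
            "direction": phase.direction,
            "angular_velocity": phase.angular_velocity,
            "spatial_frequency": phase.spatial_frequency})

    h_app, v_app = _apply_projection(h_true, v_true, config.geometry)
    traces = {
        "left_vertical": EyeTrace(
            v_app + rng.normal(0, config.noise_sd, n), fs,
            plane="vertical", eye="left"),
        "left_horizontal": EyeTrace(
            h_app + rng.normal(0, config.noise_sd, n), fs,
            plane="horizontal", eye="left"),
    }
    truth = {"mode": mode, "saccades": truth_saccades,
             "stimulation_phases": phase_info,
             "plateau_deflection": config.plateau_deflection,
             "time_constant": config.time_constant,
             "gain": config.okr_gain}
    return SyntheticDataset(traces, truth, config, protocol)


def _sine_base(phase: StimulusPhase, fs: float, shift_s: float,
               gain_scale: float, cap: float | None) -> np.ndarray:
    """Noise-free slow component of a sinusoidal-stimulus response."""
    m = int(round(phase.duration * fs))
    t = np.arange(m) / fs
    w = 2 * np.pi * phase.repetition_rate
    amp = phase.direction * phase.angular_velocity / w
    # mean-removed stimulus position, delayed by shift_s
    base = -gain_scale * amp * np.cos(w * (t - shift_s))
    if cap is not None:
        base = np.clip(base, -cap, cap)
    return base


def _stimulus_sta(phase: StimulusPhase, fs: float):
    """One-period stimulus-position STA (mean removed)."""
    from .metrics import STAResult

    length = int(round(fs / phase.repetition_rate))
    t = np.arange(length) / fs
    pos, _ = stimulus_kinematics(phase, t)
    pos = np.asarray(pos) - np.mean(pos)
    return STAResult(times=t, mean=pos, sd=np.zeros(length),
                     periods_used=1, periods_rejected=0, sample_rate=fs)


def _calibrate_sine(config: SyntheticConfig,
                    phase: StimulusPhase) -> tuple[float, float]:
    """Numerically pre-compensate gain scale and time shift.

    Runs the deterministic noise-free pipeline (detrend -> STA -> sine
    fit / top-of-descent) and adjusts the injected scale and shift until
    the recovered gain and phase match the configured targets.
    """
    from . import metrics
    from .preprocess import median_smooth, wiener_median_detrend

    fs = config.sample_rate
    rr = phase.repetition_rate
    period = 1.0 / rr
    sta_stim = _stimulus_sta(phase, fs)
    stim_ptp = float(np.ptp(sta_stim.mean))

    scale = config.okr_gain
    shift = config.okr_phase / 360.0 * period
    # With a plateau cap the injected pre-clip scale *is* the configured
    # gain (the clipped amplitude is set by the cap); only the time shift
    # is calibrated.  Without a cap both scale and shift are calibrated.
    calibrate_scale = config.plateau_cap is None
    try:
        for _ in range(4):
            base = _sine_base(phase, fs, shift, scale, config.plateau_cap)
            trace = EyeTrace(base, fs, plane="vertical", eye="left")
            # mirror the measurement pipeline (median smoothing precedes
            # the Wiener stage; the noise-free trace has no saccades)
            flt = wiener_median_detrend(median_smooth(trace, 1.0))
            sta = metrics.compute_sta(flt, period, rejection=False)
            phi = metrics.top_of_descent_phase(sta, sta_stim, rr)
            shift += (config.okr_phase - phi) / 360.0 * period
            g_ok = True
            if calibrate_scale:
                fit = metrics.fit_sine_linear(sta, rr,
                                              plateau_exclusion=True)
                g = 2.0 * fit.amplitude / stim_ptp
                if g > 0:
                    scale *= config.okr_gain / g
                g_ok = (abs(g - config.okr_gain)
                        < 1e-3 * config.okr_gain + 1e-9)
            if abs(phi - config.okr_phase) < 0.05 and g_ok:
                break
    except ValueError:
        # phases the analysis cannot fold/score at this sample rate
        # (e.g. repetition rates near the Nyquist regime) fall back to
        # the analytic scale and shift
        return (config.okr_gain,
                config.okr_phase / 360.0 * period)
    return scale, shift


def generate_sinusoidal_okr_dataset(config: SyntheticConfig,
                                    protocol: Protocol,
                                    seed: int | None = None
                                    ) -> SyntheticDataset:
    """Sinusoidal-envelope OKR recording.

    The vertical slow component is a scaled, time-shifted copy of the
    mean-removed stimulus position, clipped at the plateau cap when
    configured; spontaneous saccades add persistent vertical step
    offsets.  Scale and shift are pre-compensated (see module docstring)
    so that the pipeline recovers the configured gain and phase.
    """
    for ph in protocol.stimulation_phases:
        if ph.kind is not PhaseKind.SINUSOIDAL:
            raise ValueError("protocol is not a sinusoidal-stimulus protocol")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sample_rate
    n = int(round(protocol.total_duration * fs))
    v_true = np.zeros(n)
    h_true = np.zeros(n)
    truth_saccades = []
    phase_info = []
    calib_cache: dict[tuple, tuple[float, float]] = {}

    for phase, i0, i1 in phase_segments(protocol, fs):
        if phase.kind is PhaseKind.PAUSE:
            continue
        key = (phase.repetition_rate, phase.angular_velocity,
               phase.direction)
        if key not in calib_cache:
            calib_cache[key] = _calibrate_sine(
                config, phase)
        scale, shift = calib_cache[key]
        m = i1 - i0
        base = _sine_base(phase, fs, shift, scale, config.plateau_cap)
        times = _event_times(
            rng, phase.duration, config.spontaneous_saccade_rate,
            config.min_event_gap, config.event_count_mode)
        mean, sd, lo, hi = config.saccade_amplitude["vertical"]
        amps = (_truncnorm(rng, mean, sd, lo, hi, times.size)
                * rng.choice([-1.0, 1.0], size=times.size))
        durs = [_event_duration(rng, {"vertical": a},
                                config.saccade_duration) for a in amps]
        events = list(zip(times, amps, durs))
        v_true[i0:i1] = base + _offset_channel(m, fs, events, decay="none")
        truth_saccades += [
            {"time_s": float(i0 / fs + t), "amplitude_deg": float(a)}
            for t, a, _ in events]
        phase_info.append({
            "start_s": i0 / fs, "duration_s": phase.duration,
            "direction": phase.direction,
            "repetition_rate": phase.repetition_rate,
            "angular_velocity": phase.angular_velocity,
            "spatial_frequency": phase.spatial_frequency,
            "calibrated_scale": scale, "calibrated_shift_s": shift})

    h_app, v_app = _apply_projection(h_true, v_true, config.geometry)
    traces = {
        "left_vertical": EyeTrace(
            v_app + rng.normal(0, config.noise_sd, n), fs,
            plane="vertical", eye="left"),
        "left_horizontal": EyeTrace(
            h_app + rng.normal(0, config.noise_sd, n), fs,
            plane="horizontal", eye="left"),
    }
    truth = {"gain": config.okr_gain, "phase_deg": config.okr_phase,
             "plateau_cap": config.plateau_cap,
             "saccades": truth_saccades,
             "stimulation_phases": phase_info}
    return SyntheticDataset(traces, truth, config, protocol)
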