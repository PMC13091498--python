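"""End-to-end analysis pipelines composing the per-module operations.

Each pipeline takes a (synthetic or tracked) dataset and reproduces the
full analysis chain of its experiment type:

* vestibular roll: rolling-mean smoothing + centering, VOR score at the
  rotation frequency, STA dynamic range, velocity gain, cross-correlation
  phase lag;
* constant-rotation OKR: median filtering, saccade detection and
  removal, 4-s gain/amplitude and doubled dynamic range;
* sinusoidal OKR: Wiener+median filtering and detrending, STA with
  outlier-period rejection, sine+line fit with plateau exclusion, gain,
  cross-correlation and top-of-descent phase;
* stationary pause: median filtering, saccade detection, rate;
* cluster mixes: per-plane detection plus coincidence classification.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import metrics
from .preprocess import (EyeTrace, median_smooth, rolling_mean_center,
                         wiener_median_detrend)
from .saccades import (classify_saccades, detect_saccades, remove_saccades,
                       saccade_rate)
from .stimulus import PhaseKind, StimulusPhase
from .synthetic import SyntheticDataset, _stimulus_sta, phase_segments

__all__ = [
    "vvor_metrics", "constant_okr_metrics", "sinusoidal_okr_metrics",
    "pause_saccade_rate", "cluster_proportions",
]


def _stimulus_series(phase: StimulusPhase, fs: float) -> np.ndarray:
    """Stimulus position samples over a whole phase."""
    from .stimulus import stimulus_kinematics

    t = np.arange(int(round(phase.duration * fs))) / fs
    pos, _ = stimulus_kinematics(phase, t)
    return np.asarray(pos)


def _phase_slice(trace: EyeTrace, start_s: float, duration_s: float):
    i0 = int(round(start_s * trace.sample_rate))
    i1 = i0 + int(round(duration_s * trace.sample_rate))
    return trace.with_positions(trace.positions[i0:i1])


def vvor_metrics(dataset: SyntheticDataset, smoothing_window: float = 2.0):
    """Per-phase vestibular metrics for every eye in the dataset.

    Returns a list of records with keys ``eye, angular_velocity,
    direction, vor_score, dynamic_range, gain, phase_lag_deg``.
    """
    records = []
    fs = next(iter(dataset.traces.values())).sample_rate
    for ph in dataset.ground_truth["stimulation_phases"]:
        f_rot = ph["rotation_frequency_hz"]
        t = np.arange(int(round(ph["duration_s"] * fs))) / fs
        head = -ph["direction"] * np.sin(2 * np.pi * f_rot * t)
        for key, trace in dataset.traces.items():
            seg = _phase_slice(trace, ph["start_s"], ph["duration_s"])
            sm = rolling_mean_center(seg, smoothing_window)
            score = metrics.vor_score(sm, f_rot)
            sta = metrics.compute_sta(sm, 1.0 / f_rot)
            fit = metrics.fit_sine_linear(sta, f_rot,
                                          plateau_exclusion=False)
            records.append({
                "eye": trace.eye,
                "angular_velocity": ph["angular_velocity"],
                "direction": ph["direction"],
                "vor_score": score,
                "dynamic_range": metrics.dynamic_range(sta),
                "gain": metrics.gain(fit.amplitude, ph["angular_velocity"],
                                     mode="vvor", frequency=f_rot),
                "phase_lag_deg": metrics.xcorr_phase_lag(
                    sm.positions, head, f_rot, fs),
            })
    return records


def constant_okr_metrics(dataset: SyntheticDataset, plane: str,
                         window_s: float = 4.0):
    """Per-phase 4-s gain/amplitude of a constant-rotation recording.

    The trace of the requested plane is median-filtered as a whole,
    sliced per stimulation phase, desaccaded, and scored over the first
    ``window_s`` seconds.
    """
    key = next(k for k, tr in dataset.traces.items() if tr.plane == plane)
    smooth = median_smooth(dataset.traces[key], 1.0)
    records = []
    for ph in dataset.ground_truth["stimulation_phases"]:
        seg = _phase_slice(smooth, ph["start_s"], ph["duration_s"])
        events = detect_saccades(seg)
        clean = remove_saccades(seg, events)
        sp = StimulusPhase(
            PhaseKind.CONSTANT, ph["duration_s"],
            direction=ph["direction"],
            angular_velocity=ph["angular_velocity"],
            spatial_frequency=ph["spatial_frequency"])
        gain_4s, amplitude_4s = metrics.constant_rotation_metrics(
            clean, sp, window_s)
        records.append({
            "spatial_frequency": ph["spatial_frequency"],
            "angular_velocity": ph["angular_velocity"],
            "direction": ph["direction"],
            "gain_4s": gain_4s,
            "amplitude_4s": amplitude_4s,
            "dynamic_range": metrics.dynamic_range(
                amplitude_4s, constant_rotation=True),
            "n_saccades": len(events),
        })
    return records


def sinusoidal_okr_metrics(dataset: SyntheticDataset,
                           rejection: bool | None = None,
                           desaccade: bool = True):
    """Per-phase gain and phase estimates of a sinusoidal-OKR recording.

    Spontaneous saccades shift the sinusoidal response by their
    amplitude; subtracting each detected saccade's displacement
    (``desaccade=True``) reverses those baseline shifts before the
    Wiener+median filtering, which keeps the desk-scale STAs (few
    periods per phase) free of step artifacts.  The leave-one-out period
    rejection then only has residual outliers to handle.
    """
    key = next(k for k, tr in dataset.traces.items()
               if tr.plane == "vertical")
    trace = dataset.traces[key]
    fs = trace.sample_rate
    records = []
    assert dataset.protocol is not None
    for ph, i0, i1 in phase_segments(dataset.protocol, fs):
        if ph.kind is not PhaseKind.SINUSOIDAL:
            continue
        rr = ph.repetition_rate
        seg = trace.with_positions(trace.positions[i0:i1])
        if desaccade:
            sm = median_smooth(seg, 1.0)
            seg = remove_saccades(sm, detect_saccades(sm))
        flt = wiener_median_detrend(seg)
        n_periods = int(round(ph.duration * rr))
        rej = rejection if rejection is not None else n_periods > 2
        try:
            sta = metrics.compute_sta(flt, 1.0 / rr, rejection=rej)
            sta_stim = _stimulus_sta(ph, fs)
            fit = metrics.fit_sine_linear(sta, rr, plateau_exclusion=True)
            stim_ptp = float(np.ptp(sta_stim.mean))
            record = {
                "repetition_rate": rr,
                "spatial_frequency": ph.spatial_frequency,
                "angular_velocity": ph.angular_velocity,
                "direction": ph.direction,
                "gain": metrics.gain(2.0 * fit.amplitude, stim_ptp),
                "dynamic_range": metrics.dynamic_range(sta),
                "phase_tod_deg": metrics.top_of_descent_phase(
                    sta, sta_stim, rr),
                "phase_xcorr_deg": metrics.xcorr_phase_lag(
                    flt.positions, _stimulus_series(ph, fs), rr, fs),
                "periods_rejected": sta.periods_rejected,
            }
        except ValueError as err:
            # phases the estimators cannot score at this sample rate
            # (non-integer samples per period, too few samples for the
            # fit, no descent in a flat response) are skipped
            warnings.warn(f"skipping RR={rr} Hz phase: {err}",
                          stacklevel=2)
            continue
        records.append(record)
    return records


def pause_saccade_rate(dataset: SyntheticDataset) -> dict:
    """Detected spontaneous saccade rate of a stationary recording."""
    key = next(iter(dataset.traces))
    trace = dataset.traces[key]
    sm = median_smooth(trace, 1.0)
    events = detect_saccades(sm)
    return {"n_events": len(events),
            "duration_s": trace.duration,
            "rate_per_min": saccade_rate(events, trace.duration)}


def cluster_proportions(dataset: SyntheticDataset, window: int = 5) -> dict:
    """Detect per plane, classify by coincidence, report cluster shares.

    A combined event (clusters 3/4) counts once.  Percentages are of all
    detected saccades, matching how published cluster proportions are
    quoted.
    """
    vert = detect_saccades(median_smooth(
        next(tr for tr in dataset.traces.values()
             if tr.plane == "vertical"), 1.0))
    horiz = detect_saccades(median_smooth(
        next(tr for tr in dataset.traces.values()
             if tr.plane == "horizontal"), 1.0))
    vc, hc = classify_saccades(vert, horiz, window=window)
    pairs = sum(1 for ev in vc if ev.cluster in (3, 4))
    total = len(vc) + len(hc) - pairs
    counts = {
        1: sum(1 for ev in vc if ev.cluster == 1),
        2: sum(1 for ev in hc if ev.cluster == 2),
        3: sum(1 for ev in vc if ev.cluster == 3),
        4: sum(1 for ev in vc if ev.cluster == 4),
        0: (sum(1 for ev in vc if ev.cluster == 0)
            + sum(1 for ev in hc if ev.cluster == 0)),
    }
    return {
        "total": total,
        "counts": counts,
        "percent": {k: 100.0 * v / total for k, v in counts.items()},
        "vertical_events": len(vc),
        "horizontal_events": len(hc),
    }
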