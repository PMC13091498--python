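"""Saccade detection, removal, classification and verification statistics.

Detection operates on median-smoothed traces and uses plane-specific
thresholds: a saccade must deflect the eye by at least 1 deg within a
0.5 s window, with a peak velocity of at least 30 deg/s (horizontal
plane) or 10 deg/s (vertical plane) and a mean velocity of at least
20 deg/s or 10 deg/s respectively.  Candidate start/end points are the
velocity sign changes (or near-zero dips) flanking each supra-threshold
velocity run; when several candidate pairs survive the thresholds, a
weighted score over rank-normalized amplitude, mean velocity, movement
direction consistency and peak acceleration picks the winner.  Finally
the frames adjacent to each endpoint are screened: if a neighbour holds
a more extreme eye deflection differing by more than 0.5 deg, the
endpoint shifts to that extremum.

Coincident events in the vertical and horizontal planes (starts within a
5-frame window) form the combined clusters 3 and 4; unmatched events are
cluster 1 (vertical only) or 2 (horizontal only); events with several
candidate partners in the other plane stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import EyeTrace, kinematics

__all__ = [
    "Saccade", "SaccadeThresholds", "detect_saccades", "remove_saccades",
    "classify_saccades", "saccade_rate", "minor_axis_change",
    "CLUSTER_VERTICAL", "CLUSTER_HORIZONTAL", "CLUSTER_COMBINED_EQUAL",
    "CLUSTER_COMBINED_OPPOSITE", "CLUSTER_UNASSIGNED",
]

CLUSTER_VERTICAL = 1
CLUSTER_HORIZONTAL = 2
CLUSTER_COMBINED_EQUAL = 3      # vertical and horizontal deflection same sign
CLUSTER_COMBINED_OPPOSITE = 4   # opposite signs
CLUSTER_UNASSIGNED = 0


@dataclass(frozen=True)
class SaccadeThresholds:
    """Detection thresholds; defaults follow the per-plane values above."""

    peak_velocity: dict = field(default_factory=lambda: {
        "horizontal": 30.0, "vertical": 10.0})
    mean_velocity: dict = field(default_factory=lambda: {
        "horizontal": 20.0, "vertical": 10.0})
    min_amplitude: float = 1.0          # deg
    max_duration: float = 0.5           # s
    refine_step: float = 0.5            # deg; endpoint extremum screening
    # Candidate scoring weights: amplitude, mean velocity, direction
    # consistency, peak acceleration (rank-normalized features).
    weights: tuple = (0.4, 0.3, 0.2, 0.1)


@dataclass
class Saccade:
    plane: str
    eye: str
    start: int              # sample index
    end: int                # sample index (inclusive)
    start_time: float       # s
    end_time: float         # s
    amplitude: float        # deg, signed
    peak_velocity: float    # deg/s, magnitude
    mean_velocity: float    # deg/s, magnitude
    peak_acceleration: float  # deg/s^2, magnitude
    direction: int          # sign of amplitude
    cluster: int = CLUSTER_UNASSIGNED
    score: float = 0.0


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs; stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    return list(zip(idx[0::2], idx[1::2]))


def _candidate_edges(x: np.ndarray, v: np.ndarray, i: int, sign: float,
                     limit: int, step: int, n_extrema: int = 1):
    """Candidate start (step=-1) or end (step=+1) indices for an event.

    Three kinds of candidate flank the supra-threshold velocity run
    bordered by sample ``i``: the run border itself (tight window), the
    first sample where the velocity has decayed below a fraction of the
    event's peak (velocity edge), and local position extrema -- minima of
    ``sign * x`` on the start side, maxima on the end side (wide window,
    best amplitude).  The scoring step chooses among them.
    """
    out: list[int] = [int(np.clip(i, 0, x.size - 1))]
    vpk = abs(v[i])
    floor = max(2.0, 0.2 * vpk)
    j = i
    for _ in range(limit):
        if not (0 <= j + step < x.size):
            break
        j += step
        if sign * v[j] < floor:
            if j not in out:
                out.append(j)
            break
    # extremum walk: extend outward only while the position keeps getting
    # materially (> 0.5 deg, the endpoint-refinement criterion) more
    # extreme, so baseline noise does not drag the endpoint away.
    y = sign * x * (1 if step > 0 else -1)
    best = i
    j = i
    for _ in range(limit):
        j += step
        if not (0 <= j < x.size):
            break
        if y[j] > y[best] + 0.5:
            best = j
    if best not in out:
        out.append(best)
    return out


def detect_saccades(trace: EyeTrace,
                    thresholds: SaccadeThresholds | None = None):
    """Detect saccades on a median-smoothed trace.

    Returns a time-sorted list of non-overlapping :class:`Saccade`.
    """
    th = thresholds or SaccadeThresholds()
    x = trace.positions
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples; smooth it first")
    if trace.plane not in th.peak_velocity:
        raise ValueError(f"unknown plane {trace.plane!r}")
    v, acc = kinematics(trace)
    fs = trace.sample_rate
    w_max = int(round(th.max_duration * fs))
    peak_thr = th.peak_velocity[trace.plane]
    mean_thr = th.mean_velocity[trace.plane]

    runs = _runs(np.abs(v) >= peak_thr)
    # split runs at velocity sign changes, merge nearby same-sign runs
    seeds = []
    for r0, r1 in runs:
        signs = np.sign(v[r0:r1])
        cur = r0
        for k in range(r0 + 1, r1):
            if signs[k - r0] != signs[k - 1 - r0]:
                seeds.append((cur, k))
                cur = k
        seeds.append((cur, r1))
    merged = []
    for s in seeds:
        if (merged and s[0] - merged[-1][1] <= 2
                and np.sign(v[s[0]]) == np.sign(v[merged[-1][0]])):
            merged[-1] = (merged[-1][0], s[1])
        else:
            merged.append(s)

    events: list[Saccade] = []
    for r0, r1 in merged:
        ip = r0 + int(np.argmax(np.abs(v[r0:r1])))
        sign = float(np.sign(v[ip]))
        starts = _candidate_edges(x, v, max(r0 - 1, 0), sign, w_max, -1)
        ends = _candidate_edges(x, v, min(r1, x.size - 1), sign, w_max, +1)
        cands = []
        for s in starts:
            for e in ends:
                if e <= s or (e - s) / fs > th.max_duration:
                    continue
                amp = x[e] - x[s]
                if abs(amp) < th.min_amplitude:
                    continue
                pv = float(np.max(np.abs(v[s:e + 1])))
                mv = abs(amp) / ((e - s) / fs)
                if pv < peak_thr or mv < mean_thr:
                    continue
                pa = float(np.max(np.abs(acc[s:e + 1])))
                consistency = float(np.mean(sign * v[s:e + 1] > 0))
                cands.append((s, e, amp, pv, mv, pa, consistency))
        if not cands:
            continue
        from scipy.stats import rankdata

        arr = np.array([(abs(c[2]), c[4], c[6], c[5]) for c in cands])
        # rank-normalize each feature to [0, 1] across candidates
        feats = np.zeros_like(arr)
        for k in range(4):
            feats[:, k] = ((rankdata(arr[:, k], method="average") - 1)
                           / max(len(cands) - 1, 1))
        feats[:, 2] = arr[:, 2]  # consistency is already in [0, 1]
        scores = feats @ np.array(th.weights)
        best = int(np.argmax(scores))
        s, e, amp, pv, mv, pa, _ = cands[best]
        s, e = _tighten_endpoints(x, s, e, np.sign(amp))
        s, e = _refine_endpoints(x, s, e, np.sign(amp), th.refine_step)
        amp = x[e] - x[s]
        dur = (e - s) / fs
        events.append(Saccade(
            plane=trace.plane, eye=trace.eye, start=s, end=e,
            start_time=trace.t0 + s / fs, end_time=trace.t0 + e / fs,
            amplitude=float(amp),
            peak_velocity=float(np.max(np.abs(v[s:e + 1]))),
            mean_velocity=float(abs(amp) / dur),
            peak_acceleration=float(np.max(np.abs(acc[s:e + 1]))),
            direction=int(np.sign(amp)), score=float(scores[best])))

    events.sort(key=lambda ev: ev.start)
    pruned: list[Saccade] = []
    for ev in events:
        if pruned and ev.start <= pruned[-1].end:
            if ev.score > pruned[-1].score:
                pruned[-1] = ev
            continue
        pruned.append(ev)
    return pruned


def _tighten_endpoints(x: np.ndarray, s: int, e: int, sign: float,
                       min_motion: float = 0.2):
    """Trim frames at the window borders that show no material movement in
    the event's direction; central differences widen the raw window by
    about one frame per side."""
    while e - s > 1 and sign * (x[s + 1] - x[s]) < min_motion:
        s += 1
    while e - s > 1 and sign * (x[e] - x[e - 1]) < min_motion:
        e -= 1
    return s, e


def _refine_endpoints(x: np.ndarray, s: int, e: int, sign: float,
                      step: float):
    """Shift endpoints one frame toward an adjacent extremum > ``step`` away.

    For a positive-going saccade the start extremum is a minimum and the
    end extremum a maximum (reversed for negative saccades).
    """
    for nb in (s - 1, s + 1):
        if 0 <= nb < x.size and nb < e and sign * (x[s] - x[nb]) > step:
            s = nb
            break
    for nb in (e + 1, e - 1):
        if 0 <= nb < x.size and nb > s and sign * (x[nb] - x[e]) > step:
            e = nb
            break
    return s, e


def remove_saccades(trace: EyeTrace, saccades) -> EyeTrace:
    """Subtract each saccade's net displacement from all later samples and
    bridge the saccadic interval linearly; slow phases are preserved."""
    x = trace.positions.copy()
    last_end = -1
    for ev in sorted(saccades, key=lambda s: s.start):
        if ev.start <= last_end:
            raise ValueError("overlapping saccades")
        last_end = ev.end
        # subtract the event's own displacement, not the raw endpoint
        # difference: slow-phase drift accumulated during the event then
        # survives the removal
        x[ev.end:] -= ev.amplitude
        x[ev.start:ev.end + 1] = np.linspace(
            x[ev.start], x[ev.end], ev.end - ev.start + 1)
    return trace.with_positions(x)


def classify_saccades(vertical_events, horizontal_events,
                      window: int = 5):
    """Assign direction clusters by cross-plane coincidence.

    Events of the two planes pair when their starts lie within ``window``
    frames (greedy nearest pairing).  Pairs go to cluster 3 (equal
    deflection signs) or 4 (opposite); unmatched vertical events are
    cluster 1, unmatched horizontal cluster 2, and any event with more
    than one candidate partner in the other plane is left unassigned
    (cluster 0), as are its partners.
    """
    vert = [replace(ev) for ev in vertical_events]
    horiz = [replace(ev) for ev in horizontal_events]
    v_starts = np.array([ev.start for ev in vert], dtype=float)
    h_starts = np.array([ev.start for ev in horiz], dtype=float)

    v_cands = [np.flatnonzero(np.abs(h_starts - s) <= window)
               for s in v_starts]
    h_cands = [np.flatnonzero(np.abs(v_starts - s) <= window)
               for s in h_starts]

    ambiguous_v = {i for i, c in enumerate(v_cands) if len(c) > 1}
    ambiguous_h = {j for j, c in enumerate(h_cands) if len(c) > 1}
    for i in list(ambiguous_v):
        ambiguous_h.update(v_cands[i].tolist())
    for j in list(ambiguous_h):
        ambiguous_v.update(h_cands[j].tolist())

    used_h: set[int] = set()
    for i, ev in enumerate(vert):
        if i in ambiguous_v:
            ev.cluster = CLUSTER_UNASSIGNED
            continue
        cand = [j for j in v_cands[i] if j not in used_h
                and j not in ambiguous_h]
        if not cand:
            ev.cluster = CLUSTER_VERTICAL
            continue
        j = min(cand, key=lambda j: abs(h_starts[j] - v_starts[i]))
        used_h.add(j)
        same = ev.direction == horiz[j].direction
        cl = CLUSTER_COMBINED_EQUAL if same else CLUSTER_COMBINED_OPPOSITE
        ev.cluster = cl
        horiz[j].cluster = cl
    for j, ev in enumerate(horiz):
        if j in ambiguous_h:
            ev.cluster = CLUSTER_UNASSIGNED
        elif j not in used_h:
            ev.cluster = CLUSTER_HORIZONTAL
    return vert, horiz


def saccade_rate(events, duration_s: float) -> float:
    """Events per minute over an effective duration in seconds."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(events) * 60.0 / duration_s


def minor_axis_change(pre_len: float, post_len: float,
                      major_len: float) -> float:
    """Normalized minor-axis change across a saccade: (post - pre)/major."""
    if min(pre_len, post_len, major_len) <= 0:
        raise ValueError("axis lengths must be positive")
    return (post_len - pre_len) / major_len
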