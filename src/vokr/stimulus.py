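"""Stimulus protocols for optokinetic and vestibular roll experiments.

Three kinds of protocol segment are modeled:

* ``pause`` -- static scene (or no rotation of the roll stage).
* ``constant`` -- rotation of the grating (or of the whole animal, for the
  vestibular protocol) at a fixed angular velocity.
* ``sinusoidal`` -- grating rotation whose *velocity* follows a sinusoidal
  envelope; the envelope frequency is the repetition rate (RR).  The phase
  starts at zero velocity and accelerates in the phase's direction, so the
  stimulus position is one-sided for direction +1.

Sign convention: +1 means clockwise as seen by the front camera; eye
position signs follow the same convention in the front (vertical) plane,
and in the top (horizontal) plane positive means a nasal rotation of the
left eye.  Keeping one global convention makes gains of following
responses positive.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "PhaseKind",
    "StimulusPhase",
    "Protocol",
    "stimulus_kinematics",
    "temporal_frequency",
    "build_protocol",
    "SPATIAL_FREQUENCIES",
    "ANGULAR_VELOCITIES",
    "REPETITION_RATES",
    "VVOR_VELOCITIES",
]

#: Spatial-frequency grid (cycles/deg) spanning the tested range on an
#: approximately geometric ladder.
SPATIAL_FREQUENCIES = (0.018, 0.027, 0.041, 0.061, 0.092, 0.138)

#: Angular-velocity grid (deg/s) for the grating protocols.
ANGULAR_VELOCITIES = (5.55, 8.32, 12.5, 18.7, 28.12)

#: Repetition-rate grid (Hz) for the sinusoidal-envelope tuning protocol.
REPETITION_RATES = (
    3.0, 2.0, 1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625, 0.0078125,
)

#: Roll velocities (deg/s) of the vestibular protocol; eight full rotations
#: are performed per stimulation phase.
VVOR_VELOCITIES = (90.0, 45.0, 22.5)


class PhaseKind(str, enum.Enum):
    PAUSE = "pause"
    CONSTANT = "constant"
    SINUSOIDAL = "sinusoidal"


@dataclass(frozen=True)
class StimulusPhase:
    """One protocol segment.

    Parameters
    ----------
    kind:
        ``pause``, ``constant`` or ``sinusoidal``.
    direction:
        +1 clockwise, -1 counter-clockwise (front-camera view).
    angular_velocity:
        deg/s; the *peak* velocity for sinusoidal phases.
    spatial_frequency:
        Grating cycles per degree; 0 for vestibular phases.
    repetition_rate:
        Frequency (Hz) of the sinusoidal velocity envelope; 0 otherwise.
    duration:
        Segment length in seconds.
    """

    kind: PhaseKind
    duration: float
    direction: int = 1
    angular_velocity: float = 0.0
    spatial_frequency: float = 0.0
    repetition_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PhaseKind(self.kind))
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if self.angular_velocity < 0:
            raise ValueError("angular_velocity must be >= 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.kind is PhaseKind.SINUSOIDAL and self.repetition_rate <= 0:
            raise ValueError("sinusoidal phase requires repetition_rate > 0")

    @property
    def rotation_frequency(self) -> float:
        """Full-rotation frequency (Hz) of a vestibular constant phase."""
        return self.angular_velocity / 360.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kind"] = self.kind.value
        return d


@dataclass
class Protocol:
    """Ordered list of stimulus phases plus the seed that ordered them."""

    phases: list[StimulusPhase]
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))

    @property
    def stimulation_phases(self) -> list[StimulusPhase]:
        return [p for p in self.phases if p.kind is not PhaseKind.PAUSE]

    def phase_start(self, index: int) -> float:
        """Start time (s) of phase ``index`` within the protocol."""
        return float(sum(p.duration for p in self.phases[:index]))

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "seed": self.seed,
                "metadata": self.metadata,
                "phases": [p.to_dict() for p in self.phases],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "Protocol":
        raw = yaml.safe_load(text)
        phases = [StimulusPhase(**p) for p in raw["phases"]]
        return cls(phases=phases, seed=raw.get("seed", 0),
                   metadata=raw.get("metadata", {}))


def stimulus_kinematics(phase: StimulusPhase, t):
    """Stimulus position (deg) and velocity (deg/s) at time ``t`` in a phase.

    ``t`` may be a scalar or an array; it must lie within ``[0, duration]``.

    * constant: ``position = direction * v_a * t``.
    * sinusoidal: ``velocity = direction * v_a * sin(2 pi RR t)`` so the
      position is ``direction * v_a / (2 pi RR) * (1 - cos(2 pi RR t))``.
    * pause: both zero.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-9) or np.any(t > phase.duration + 1e-9):
        raise ValueError("t outside the phase's [0, duration] interval")
    if phase.kind is PhaseKind.PAUSE:
        pos = np.zeros_like(t)
        vel = np.zeros_like(t)
    elif phase.kind is PhaseKind.CONSTANT:
        vel = np.full_like(t, phase.direction * phase.angular_velocity)
        pos = phase.direction * phase.angular_velocity * t
    else:
        if phase.repetition_rate <= 0:
            raise ValueError("sinusoidal phase requires repetition_rate > 0")
        w = 2.0 * np.pi * phase.repetition_rate
        va = phase.direction * phase.angular_velocity
        vel = va * np.sin(w * t)
        pos = va / w * (1.0 - np.cos(w * t))
    if pos.ndim == 0:
        return float(pos), float(vel)
    return pos, vel


def temporal_frequency(angular_velocity: float, spatial_frequency: float) -> float:
    """Temporal frequency (Hz) of a drifting grating: ``v_a * f_s``.

    The number of grating cycles crossing a fixed point per second.
    """
    if angular_velocity < 0 or spatial_frequency < 0:
        raise ValueError("angular_velocity and spatial_frequency must be >= 0")
    return angular_velocity * spatial_frequency


def _framed(stim_phases: list[StimulusPhase], pause_s: float) -> list[StimulusPhase]:
    """Interleave stimulation phases with framing pause phases."""
    out: list[StimulusPhase] = [StimulusPhase(PhaseKind.PAUSE, pause_s)]
    for p in stim_phases:
        out.append(p)
        out.append(StimulusPhase(PhaseKind.PAUSE, pause_s))
    return out


def build_protocol(name: str, seed: int = 0, *,
                   spatial_frequencies=SPATIAL_FREQUENCIES,
                   angular_velocities=ANGULAR_VELOCITIES,
                   repetition_rates=REPETITION_RATES,
                   vvor_velocities=VVOR_VELOCITIES,
                   n_rotations: int = 8,
                   n_periods: int = 6) -> Protocol:
    """Build one of the named stimulus protocols.

    * ``vvor`` -- 3 roll velocities x 2 directions, eight full rotations
      each, framed by 30 s pauses, randomized order.
    * ``okr_constant`` -- every (f_s, v_a) pair in both directions for 60 s,
      framed by 60 s pauses with a static grating, randomized pair order.
    * ``okr_rr`` -- each repetition rate presented twice (random order and
      direction), six stimulus periods per phase, framed by 20 s pauses.
    * ``okr_sine_grid`` -- the (f_s, v_a) grid with a sinusoidal envelope at
      RR = 0.125 Hz, six periods per phase, framed by 20 s pauses.
    """
    rng = np.random.default_rng(seed)
    if name == "vvor":
        combos = [(v, d) for v in vvor_velocities for d in (1, -1)]
        rng.shuffle(combos)
        stim = [
            StimulusPhase(PhaseKind.CONSTANT, n_rotations * 360.0 / v,
                          direction=d, angular_velocity=v)
            for v, d in combos
        ]
        phases = _framed(stim, 30.0)
        meta = {"velocities": list(vvor_velocities), "n_rotations": n_rotations}
    elif name == "okr_constant":
        pairs = [(fs, va) for fs in spatial_frequencies for va in angular_velocities]
        rng.shuffle(pairs)
        stim = []
        for fs, va in pairs:
            d0 = int(rng.choice([-1, 1]))
            for d in (d0, -d0):
                stim.append(StimulusPhase(
                    PhaseKind.CONSTANT, 60.0, direction=d,
                    angular_velocity=va, spatial_frequency=fs))
        phases = _framed(stim, 60.0)
        meta = {"spatial_frequencies": list(spatial_frequencies),
                "angular_velocities": list(angular_velocities)}
    elif name == "okr_rr":
        rrs = [rr for rr in repetition_rates for _ in range(2)]
        rng.shuffle(rrs)
        stim = [
            StimulusPhase(PhaseKind.SINUSOIDAL, n_periods / rr,
                          direction=int(rng.choice([-1, 1])),
                          angular_velocity=12.5, spatial_frequency=0.0611,
                          repetition_rate=rr)
            for rr in rrs
        ]
        phases = _framed(stim, 20.0)
        meta = {"repetition_rates": list(repetition_rates),
                "n_periods": n_periods}
    elif name == "okr_sine_grid":
        rr = 0.125
        pairs = [(fs, va) for fs in spatial_frequencies for va in angular_velocities]
        rng.shuffle(pairs)
        stim = []
        for fs, va in pairs:
            d0 = int(rng.choice([-1, 1]))
            for d in (d0, -d0):
                stim.append(StimulusPhase(
                    PhaseKind.SINUSOIDAL, n_periods / rr, direction=d,
                    angular_velocity=va, spatial_frequency=fs,
                    repetition_rate=rr))
        phases = _framed(stim, 20.0)
        meta = {"spatial_frequencies": list(spatial_frequencies),
                "angular_velocities": list(angular_velocities),
                "repetition_rate": rr, "n_periods": n_periods}
    else:
        raise ValueError(f"unknown protocol name: {name!r}")
    return Protocol(phases=phases, seed=seed, metadata=meta)
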