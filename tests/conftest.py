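import numpy as np
import pytest

from vokr.stimulus import PhaseKind, Protocol, StimulusPhase


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def rr_protocol(rr: float, n_periods: int, n_phases: int,
                seed: int = 0, angular_velocity: float = 12.5,
                spatial_frequency: float = 0.0611,
                pause_s: float = 20.0) -> Protocol:
    """Repetition-rate protocol with alternating directions."""
    phases = []
    for k in range(n_phases):
        phases.append(StimulusPhase(PhaseKind.PAUSE, pause_s))
        phases.append(StimulusPhase(
            PhaseKind.SINUSOIDAL, n_periods / rr,
            direction=1 if k % 2 == 0 else -1,
            angular_velocity=angular_velocity,
            spatial_frequency=spatial_frequency, repetition_rate=rr))
    phases.append(StimulusPhase(PhaseKind.PAUSE, pause_s))
    return Protocol(phases=phases, seed=seed)
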