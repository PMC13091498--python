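import numpy as np
import pytest

from conftest import rr_protocol
from vokr.preprocess import EyeTrace, boxcar_gain
from vokr.stimulus import PhaseKind, Protocol, StimulusPhase, build_protocol
from vokr.synthetic import (SyntheticConfig, _sine_base, generate_constant_okr_dataset,
                            generate_pause_dataset,
                            generate_saccade_population,
                            generate_sinusoidal_okr_dataset,
                            generate_vvor_dataset, get_preset,
                            inject_saccade)

FS = 20.0


def single_roll_protocol(velocity=90.0, n_rotations=8):
    return Protocol(phases=[
        StimulusPhase(PhaseKind.PAUSE, 30.0),
        StimulusPhase(PhaseKind.CONSTANT, n_rotations * 360.0 / velocity,
                      direction=1, angular_velocity=velocity),
        StimulusPhase(PhaseKind.PAUSE, 30.0),
    ])


class TestDeterminism:
    @pytest.mark.parametrize("make", [
        lambda s: generate_vvor_dataset(
            get_preset("vvor-90-score"), single_roll_protocol(), seed=s),
        lambda s: generate_pause_dataset(SyntheticConfig(), 300.0, seed=s),
        lambda s: generate_saccade_population(
            get_preset("cluster-mix"), 40, seed=s),
    ])
    def test_same_seed_identical_different_seed_differs(self, make):
        a = make(11)
        b = make(11)
        c = make(12)
        for key in a.traces:
            assert np.array_equal(a.traces[key].positions,
                                  b.traces[key].positions)
        assert any(not np.array_equal(a.traces[k].positions,
                                      c.traces[k].positions)
                   for k in a.traces)

    def test_ground_truth_always_emitted(self):
        ds = generate_pause_dataset(SyntheticConfig(), 300.0, seed=0)
        assert "saccades" in ds.ground_truth


class TestVvorGenerator:
    def test_noise_free_amplitude_is_precompensated(self):
        cfg = get_preset("vvor-90-score", noise_sd=0.0, vibration_rate=0.0,
                         spontaneous_saccade_rate=0.0, vvor_phase=0.0)
        prot = single_roll_protocol(90.0)
        ds = generate_vvor_dataset(cfg, prot, seed=0)
        tr = ds.traces["left_vertical"]
        ph = ds.ground_truth["stimulation_phases"][0]
        i0 = int(ph["start_s"] * FS)
        i1 = i0 + int(ph["duration_s"] * FS)
        t = np.arange(i1 - i0) / FS
        f = ph["rotation_frequency_hz"]
        design = np.column_stack([np.sin(2 * np.pi * f * t),
                                  np.cos(2 * np.pi * f * t)])
        coef, *_ = np.linalg.lstsq(design, tr.positions[i0:i1], rcond=None)
        expected = 15.9 / boxcar_gain(f, 2.0, FS)
        assert np.hypot(*coef) == pytest.approx(expected, rel=1e-6)

    def test_no_saccades_during_rotation(self):
        cfg = get_preset("vvor-90-score", spontaneous_saccade_rate=0.0)
        ds = generate_vvor_dataset(cfg, single_roll_protocol(), seed=1)
        assert ds.ground_truth["saccades"] == []

    def test_rejects_non_vestibular_protocol(self):
        cfg = get_preset("vvor-90-score")
        with pytest.raises(ValueError):
            generate_vvor_dataset(cfg, build_protocol("okr_rr", seed=0))


class TestConstantOkrGenerator:
    @staticmethod
    def protocol():
        return build_protocol("okr_constant", seed=0,
                              spatial_frequencies=(0.041,),
                              angular_velocities=(28.12,))

    def test_vokr_noise_free_start_response_closed_form(self):
        cfg = get_preset("vokr-4s", noise_sd=0.0,
                         spontaneous_saccade_rate=0.0)
        ds = generate_constant_okr_dataset(cfg, self.protocol(), "vokr",
                                           seed=0)
        tr = ds.traces["left_vertical"]
        ph = ds.ground_truth["stimulation_phases"][0]
        i0 = int(ph["start_s"] * FS)
        d4 = abs(tr.positions[i0 + int(4 * FS)] - tr.positions[i0])
        D, tau = cfg.plateau_deflection, cfg.time_constant
        assert d4 == pytest.approx(D * (1 - np.exp(-4.0 / tau)), abs=0.05)

    def test_hokr_quick_phase_count_matches_sawtooth_arithmetic(self):
        cfg = get_preset("hokr-4s", noise_sd=0.0)
        ds = generate_constant_okr_dataset(cfg, self.protocol(), "hokr",
                                           seed=3)
        slope = cfg.okr_gain * 28.12
        reset_amp = cfg.reset_threshold + cfg.reset_overshoot
        expected = int(slope * 60.0 / reset_amp)
        per_phase = {}
        for ev in ds.ground_truth["saccades"]:
            key = int(ev["time_s"] // 120)
            per_phase[key] = per_phase.get(key, 0) + 1
        for count in per_phase.values():
            assert abs(count - expected) <= 1

    def test_spontaneous_count_is_poisson_distributed(self):
        cfg = SyntheticConfig(spontaneous_saccade_rate=0.82,
                              event_count_mode="poisson")
        counts = [len(generate_pause_dataset(cfg, 600.0, seed=s)
                      .ground_truth["saccades"]) for s in range(50)]
        expected = 0.82 * 10.0
        se = np.sqrt(expected / 50)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_mode_validation(self):
        cfg = get_preset("vokr-4s")
        with pytest.raises(ValueError):
            generate_constant_okr_dataset(cfg, self.protocol(), "diagonal")


class TestSinusoidalGenerator:
    def test_base_ratio_equals_scale_without_cap(self):
        ph = StimulusPhase(PhaseKind.SINUSOIDAL, 48.0, direction=1,
                           angular_velocity=12.5, repetition_rate=0.125)
        base = _sine_base(ph, FS, shift_s=0.0, gain_scale=0.23, cap=None)
        stim_amp = 12.5 / (2 * np.pi * 0.125)
        assert np.ptp(base) == pytest.approx(2 * 0.23 * stim_amp, rel=1e-6)

    def test_cap_clips_excursion(self):
        ph = StimulusPhase(PhaseKind.SINUSOIDAL, 256.0, direction=1,
                           angular_velocity=12.5,
                           repetition_rate=0.0078125)
        base = _sine_base(ph, FS, 0.0, 0.1, cap=5.0)
        assert np.max(np.abs(base)) == pytest.approx(5.0)

    def test_configured_shift_recovered_by_crosscorrelation(self):
        from vokr.metrics import xcorr_phase_lag
        from vokr.stimulus import stimulus_kinematics

        rr = 0.125
        cfg = get_preset("sine-gain", okr_phase=90.0, noise_sd=0.0,
                         spontaneous_saccade_rate=0.0)
        prot = rr_protocol(rr, 6, 1, angular_velocity=5.55,
                           spatial_frequency=0.041)
        ds = generate_sinusoidal_okr_dataset(cfg, prot, seed=0)
        tr = ds.traces["left_vertical"]
        ph = prot.stimulation_phases[0]
        i0 = int(20.0 * FS)
        i1 = i0 + int(ph.duration * FS)
        t = np.arange(i1 - i0) / FS
        stim, _ = stimulus_kinematics(ph, t)
        lag = xcorr_phase_lag(tr.positions[i0:i1], np.asarray(stim), rr, FS)
        assert lag / 360.0 / rr == pytest.approx(2.0, abs=0.3)

    def test_saccade_offsets_persist(self):
        cfg = get_preset("sine-gain", noise_sd=0.0,
                         spontaneous_saccade_rate=2.0,
                         event_count_mode="expected")
        prot = rr_protocol(0.125, 6, 1)
        ds = generate_sinusoidal_okr_dataset(cfg, prot, seed=4)
        assert len(ds.ground_truth["saccades"]) >= 1


class TestSaccadePopulation:
    def test_exact_type_counts_in_expected_mode(self):
        cfg = get_preset("cluster-mix", seed=0)
        ds = generate_saccade_population(cfg, 200)
        clusters = [e["cluster"] for e in ds.ground_truth["saccades"]]
        assert len(clusters) == 200
        assert clusters.count(1) == round(200 * 0.105)
        assert clusters.count(2) == round(200 * 0.140)

    def test_combined_events_move_both_planes(self):
        cfg = get_preset("cluster-mix", seed=1)
        ds = generate_saccade_population(cfg, 100)
        for ev in ds.ground_truth["saccades"]:
            if ev["cluster"] in (3, 4):
                assert ev["vertical_deg"] != 0.0
                assert ev["horizontal_deg"] != 0.0
            sign_match = (np.sign(ev["vertical_deg"])
                          == np.sign(ev["horizontal_deg"]))
            if ev["cluster"] == 3:
                assert sign_match
            if ev["cluster"] == 4:
                assert not sign_match


class TestInjectSaccade:
    def flat(self, duration=60.0):
        return EyeTrace(np.zeros(int(duration * FS)), FS)

    def test_peak_velocity_bound(self):
        # instantaneous bound: measure on a finely sampled trace
        fine = EyeTrace(np.zeros(int(60 * 200)), 200.0)
        out = inject_saccade(fine, 10.0, 5.0, 0.2)
        v = np.diff(out.positions) * 200.0
        assert v.max() >= 39.0

    def test_zero_amplitude_is_identity(self):
        tr = self.flat()
        out = inject_saccade(tr, 10.0, 0.0, 0.2)
        assert np.array_equal(out.positions, tr.positions)

    def test_two_injections_superpose(self):
        out = inject_saccade(self.flat(), 10.0, 4.0, 0.2)
        out = inject_saccade(out, 30.0, -1.5, 0.2)
        assert out.positions[-1] == pytest.approx(2.5, abs=0.01)

    def test_overlap_rejected(self):
        events = []
        out = inject_saccade(self.flat(), 10.0, 4.0, 0.3, events)
        with pytest.raises(ValueError, match="overlap"):
            inject_saccade(out, 10.1, 2.0, 0.3, events)

    def test_duration_limit(self):
        with pytest.raises(ValueError):
            inject_saccade(self.flat(), 10.0, 4.0, 0.6)


class TestConfigValidation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SyntheticConfig(cluster_probabilities=(0.5, 0.2, 0.2))

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            get_preset("no-such-preset")
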