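import numpy as np
import pytest

from vokr import metrics
from vokr.metrics import (STAResult, compute_sta, constant_rotation_metrics,
                          cumulative_average, dynamic_range, fit_sine_linear,
                          gain, top_of_descent_phase, tuning_grid, vor_score,
                          wrap_cycle_deg, xcorr_phase_lag)
from vokr.preprocess import EyeTrace
from vokr.saccades import Saccade
from vokr.stimulus import PhaseKind, StimulusPhase

FS = 20.0


def trace(x, **kw):
    return EyeTrace(np.asarray(x, dtype=float), FS, **kw)


def sine(freq, amp=1.0, periods=8, phase=0.0, fs=FS):
    n = int(round(periods / freq * fs))
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase), t


def sta_from(x, fs=FS):
    x = np.asarray(x, dtype=float)
    return STAResult(times=np.arange(x.size) / fs, mean=x,
                     sd=np.zeros(x.size), periods_used=1,
                     periods_rejected=0, sample_rate=fs)


class TestVorScore:
    def test_zero_trace(self):
        assert vor_score(trace(np.zeros(640)), 0.25) == 0.0

    def test_unit_sine_identity(self):
        x, _ = sine(0.25, periods=8)
        assert vor_score(trace(x), 0.25) == pytest.approx(1.0, abs=1e-6)

    def test_orthogonal_harmonic_ignored(self):
        x, _ = sine(0.5, periods=16)
        assert vor_score(trace(x), 0.25) == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_phase_and_orthogonal_additions(self):
        x1, t = sine(0.25, amp=3.0, periods=8)
        x2, _ = sine(0.25, amp=3.0, periods=8, phase=1.1)
        extra, _ = sine(0.0625, amp=5.0, periods=2)
        s1 = vor_score(trace(x1), 0.25)
        s2 = vor_score(trace(x2), 0.25)
        s3 = vor_score(trace(x1 + extra), 0.25)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert s1 == pytest.approx(s3, abs=1e-9)

    def test_score_is_half_dynamic_range_for_pure_sine(self):
        x, _ = sine(0.25, amp=7.5, periods=8)
        tr = trace(x)
        sta = compute_sta(tr, 4.0)
        assert vor_score(tr, 0.25) == pytest.approx(
            dynamic_range(sta) / 2, abs=1e-6)

    def test_needs_two_periods(self):
        with pytest.raises(ValueError):
            vor_score(trace(np.zeros(60)), 0.25)


class TestComputeSta:
    def test_identical_periods_average_to_one_period(self):
        period = np.sin(2 * np.pi * np.arange(80) / 80.0)
        tr = trace(np.tile(period, 6))
        sta = compute_sta(tr, 4.0)
        assert np.allclose(sta.mean, period, atol=1e-12)
        assert np.allclose(sta.sd, 0.0)
        assert sta.periods_rejected == 0

    def test_offset_period_rejected(self):
        period = np.sin(2 * np.pi * np.arange(80) / 80.0)
        data = np.tile(period, 6)
        data[2 * 80:3 * 80] += 10.0
        sta = compute_sta(trace(data), 4.0)
        assert sta.periods_rejected == 1
        assert sta.periods_used == 5
        assert np.allclose(sta.mean, period, atol=1e-12)

    def test_two_periods_disables_rejection_with_warning(self):
        period = np.sin(2 * np.pi * np.arange(80) / 80.0)
        with pytest.warns(UserWarning, match="two periods"):
            sta = compute_sta(trace(np.tile(period, 2)), 4.0)
        assert sta.periods_used == 2

    def test_needs_two_periods(self):
        with pytest.raises(ValueError):
            compute_sta(trace(np.zeros(79)), 4.0)

    def test_non_integer_period_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            compute_sta(trace(np.zeros(200)), 4.03)


class TestFitSineLinear:
    def test_exact_sine_plus_line_recovered(self):
        t = np.arange(160) / FS
        y = (2.5 * np.sin(2 * np.pi * 0.125 * t + 0.7) + 1.2 + 0.3 * t)
        fit = fit_sine_linear(sta_from(y), 0.125, plateau_exclusion=False)
        assert fit.amplitude == pytest.approx(2.5, abs=1e-6)
        assert fit.phase == pytest.approx(np.degrees(0.7), abs=1e-6)
        assert fit.offset == pytest.approx(1.2, abs=1e-6)
        assert fit.slope == pytest.approx(0.3, abs=1e-6)

    def test_clipped_sine_needs_plateau_exclusion(self):
        t = np.arange(160) / FS
        y = np.clip(3.0 * np.sin(2 * np.pi * 0.125 * t), -2.4, 2.4)
        with_excl = fit_sine_linear(sta_from(y), 0.125,
                                    plateau_exclusion=True)
        without = fit_sine_linear(sta_from(y), 0.125,
                                  plateau_exclusion=False)
        assert with_excl.amplitude == pytest.approx(3.0, rel=0.05)
        assert without.amplitude < 0.9 * 3.0

    def test_zero_sta(self):
        fit = fit_sine_linear(sta_from(np.zeros(100)), 0.125)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_sine_linear(sta_from(np.zeros(5)), 0.125)


class TestGain:
    def test_perfect_following(self):
        assert gain(10.0, 10.0) == 1.0

    def test_vvor_velocity_gain_formula(self):
        g = gain(16.2, 90.0, mode="vvor", frequency=0.25)
        assert g == pytest.approx(2 * np.pi * 0.25 * 16.2 / 90.0)
        assert g == pytest.approx(0.283, abs=0.001)

    def test_okr_peak_to_peak_ratio(self):
        assert gain(7.32, 31.83) == pytest.approx(0.23, abs=0.001)

    def test_zero_stimulus_amplitude(self):
        with pytest.raises(ValueError):
            gain(1.0, 0.0)


class TestXcorrPhaseLag:
    def test_identical_signals(self):
        x, _ = sine(0.125, periods=6)
        assert xcorr_phase_lag(x, x, 0.125, FS) == pytest.approx(0.0,
                                                                 abs=0.5)

    def test_quarter_period_delay(self):
        x, t = sine(0.125, periods=6)
        delayed = np.sin(2 * np.pi * 0.125 * (t - 2.0))
        lag = xcorr_phase_lag(delayed, x, 0.125, FS)
        assert lag == pytest.approx(90.0, abs=1.0)

    def test_noisy_delay_recovered(self):
        rng = np.random.default_rng(0)
        x, t = sine(0.125, amp=1.0, periods=10)
        delayed = (np.sin(2 * np.pi * 0.125 * (t - 2.0))
                   + rng.normal(0, 0.1, t.size))
        lag = xcorr_phase_lag(delayed, x, 0.125, FS)
        assert lag == pytest.approx(90.0, abs=3.0)

    def test_zero_variance_rejected(self):
        x, _ = sine(0.125, periods=4)
        with pytest.raises(ValueError):
            xcorr_phase_lag(np.zeros_like(x), x, 0.125, FS)


class TestTopOfDescent:
    def test_identical_stas_zero_phase(self):
        x, _ = sine(0.125, periods=1)
        phase = top_of_descent_phase(sta_from(x), sta_from(x), 0.125)
        assert phase == pytest.approx(0.0, abs=1.0)

    def test_shifted_sine_positive_lag(self):
        freq = 0.125
        n = int(1 / freq * FS)
        t = np.arange(n) / FS
        stim = np.sin(2 * np.pi * freq * t)
        eye = np.sin(2 * np.pi * freq * (t - 1.0))  # 1/8 period later
        phase = top_of_descent_phase(sta_from(eye), sta_from(stim), freq)
        assert phase == pytest.approx(45.0, abs=5.0)

    def test_plateau_clipped_phase_advance_is_negative(self):
        freq = 0.0078125
        n = int(1 / freq * FS)
        t = np.arange(n) / FS
        w = 2 * np.pi * freq
        stim = -np.cos(w * t)
        # eye leaves its plateau a sixth of a period before the stimulus
        # turning point: a clear phase advance.  The unclipped wave
        # descends through +cap at angle 2 pi - arccos(-cap/A).
        exit_angle = 2 * np.pi - np.arccos(-0.2)
        delta = exit_angle / w - (1 / freq) * (0.5 - 1.0 / 6.0)
        eye = np.clip(-25.0 * np.cos(w * (t + delta)), -5.0, 5.0)
        phase = top_of_descent_phase(sta_from(eye), sta_from(stim), freq)
        assert phase < 0
        assert -95.0 < phase < -40.0

    def test_xcorr_and_tod_agree_for_unclipped_shifts(self):
        for freq in (0.5, 0.25, 0.125):
            n = int(4 / freq * FS)
            t = np.arange(n) / FS
            stim = np.sin(2 * np.pi * freq * t)
            shift = 0.15 / freq  # 54 deg of cycle
            eye = np.sin(2 * np.pi * freq * (t - shift))
            xc = xcorr_phase_lag(eye, stim, freq, FS)
            period = int(1 / freq * FS)
            tod = top_of_descent_phase(sta_from(eye[:period]),
                                       sta_from(stim[:period]), freq)
            assert abs(xc - tod) < 5.0


class TestConstantRotationMetrics:
    def phase(self, va=28.12):
        return StimulusPhase(PhaseKind.CONSTANT, 60.0, direction=1,
                             angular_velocity=va, spatial_frequency=0.041)

    def test_perfect_following_gain_one(self):
        t = np.arange(1200) / FS
        g, amp = constant_rotation_metrics(trace(28.12 * t), self.phase())
        assert g == pytest.approx(1.0)
        assert amp == pytest.approx(28.12 * 4)

    def test_immobile_eye(self):
        g, amp = constant_rotation_metrics(trace(np.zeros(1200)),
                                           self.phase())
        assert g == 0.0
        assert amp == 0.0

    def test_start_response_closed_form(self):
        t = np.arange(1200) / FS
        x = 6.0 * (1 - np.exp(-t / 1.5))
        _, amp = constant_rotation_metrics(trace(x), self.phase())
        assert amp == pytest.approx(6.0 * (1 - np.exp(-8.0 / 3.0)),
                                    abs=0.01)

    def test_short_phase_rejected(self):
        ph = StimulusPhase(PhaseKind.CONSTANT, 3.0, direction=1,
                           angular_velocity=10.0)
        with pytest.raises(ValueError):
            constant_rotation_metrics(trace(np.zeros(60)), ph)


class TestDynamicRange:
    def test_sine_gives_twice_amplitude(self):
        x, _ = sine(0.125, amp=4.0, periods=1)
        assert dynamic_range(sta_from(x)) == pytest.approx(8.0, rel=1e-3)

    def test_constant_trace_zero(self):
        assert dynamic_range(np.full(100, 2.0)) == 0.0

    def test_constant_rotation_doubling(self):
        assert dynamic_range(5.81, constant_rotation=True) == pytest.approx(
            11.62)


class TestCumulativeAverage:
    def test_identical_phases_average_to_themselves(self):
        x, _ = sine(0.125, periods=2)
        traces = [trace(x) for _ in range(4)]
        avg = cumulative_average(traces)
        assert np.allclose(avg.positions, x - x[0], atol=1e-12)

    def test_sawtooth_average_recovers_slow_phase_slope(self):
        slope = 4.0
        t = np.arange(1200) / FS
        traces, saccades = [], []
        for k in range(3):
            x = slope * t
            evs = []
            for j, reset in enumerate(range(100 + 37 * k, 1100, 240)):
                x[reset:] -= 12.0
                evs.append(Saccade(
                    plane="horizontal", eye="left", start=reset - 1,
                    end=reset, start_time=(reset - 1) / FS,
                    end_time=reset / FS, amplitude=-12.0,
                    peak_velocity=240.0, mean_velocity=240.0,
                    peak_acceleration=1e4, direction=-1))
            traces.append(trace(x, plane="horizontal"))
            saccades.append(evs)
        avg = cumulative_average(traces, saccades)
        expected = slope * t
        assert np.max(np.abs(avg.positions - expected)) < 0.3

    def test_start_response_average_flattens(self):
        t = np.arange(1200) / FS
        x = 6.0 * (1 - np.exp(-t / 1.5))
        avg = cumulative_average([trace(x), trace(x)], [[], []])
        g_early = (avg.positions[int(4 * FS)] - avg.positions[0]) / 4.0
        g_late = (avg.positions[int(15 * FS)]
                  - avg.positions[int(5 * FS)]) / 10.0
        assert g_late < 0.1 * g_early

    def test_direction_folding(self):
        t = np.arange(200) / FS
        up = trace(2.0 * t)
        down = trace(-2.0 * t)
        avg = cumulative_average([up, down], directions=[1, -1])
        assert np.allclose(avg.positions, 2.0 * t, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cumulative_average([trace(np.zeros(10)),
                                trace(np.zeros(12))])


class TestTuningGrid:
    def records(self):
        out = []
        for fs_ in (0.027, 0.041, 0.061):
            for rep in range(3):
                value = 10.0 if fs_ == 0.041 else 4.0
                out.append({"spatial_frequency": fs_,
                            "angular_velocity": 28.12,
                            "value": value + 0.1 * rep})
        return out

    def test_peak_location_recovered(self):
        grid = tuning_grid(self.records())
        best = grid.loc[grid["mean"].idxmax()]
        assert best["spatial_frequency"] == pytest.approx(0.041)
        assert best["temporal_frequency"] == pytest.approx(28.12 * 0.041)

    def test_single_replicate_flagged(self):
        grid = tuning_grid([{"spatial_frequency": 0.041,
                             "angular_velocity": 10.0, "value": 1.0}])
        assert bool(grid["single_replicate"].iloc[0])
        assert np.isnan(grid["sem"].iloc[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tuning_grid([])


class TestWrap:
    @pytest.mark.parametrize("raw,expected", [
        (0.0, 0.0), (190.0, -170.0), (-190.0, 170.0), (180.0, 180.0),
        (360.0, 0.0),
    ])
    def test_wrap_to_half_cycle(self, raw, expected):
        assert wrap_cycle_deg(raw) == pytest.approx(expected)
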