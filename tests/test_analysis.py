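import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isletsync.analysis import (
    SpectrogramConfig,
    Trace,
    TraceGroup,
    background_subtract,
    classify_entrainment,
    interpolate_upsample,
    major_period,
    stft_spectrogram,
    synchronization_index,
    analyze_group,
)
from isletsync.errors import (
    InsufficientDataError,
    InvalidParameterError,
)


def sine_trace(period_min, duration_min=90.0, dt=20.0, amp=1.0, phase=0.0,
               offset=0.0, slope=0.0):
    t = dt * np.arange(int(duration_min * 60.0 / dt) + 1)
    v = offset + slope * t + amp * np.sin(2 * np.pi * (t / (period_min * 60.0) + phase))
    return Trace(t, v)


class TestTrace:
    def test_rejects_nonuniform_sampling(self):
        with pytest.raises(InvalidParameterError):
            Trace(np.array([0.0, 20.0, 41.0]), np.zeros(3))

    def test_rejects_short(self):
        with pytest.raises(InvalidParameterError):
            Trace(np.array([0.0]), np.array([1.0]))


class TestBackgroundSubtract:
    def test_constant_becomes_zero(self):
        t = 20.0 * np.arange(50)
        out = background_subtract(Trace(t, np.full(50, 7.0)))
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_recovers_sine_under_linear_background(self):
        # long record: the line fit is barely contaminated by the sine
        clean = sine_trace(5.0, duration_min=600.0)
        dirty = Trace(clean.times, clean.values + 0.01 * clean.times + 42.0)
        out = background_subtract(dirty)
        rms = np.sqrt(np.mean((out.values - (clean.values - clean.values.mean())) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(clean.values**2))

    def test_output_has_no_linear_trend(self):
        rng = np.random.default_rng(0)
        t = 20.0 * np.arange(200)
        out = background_subtract(Trace(t, rng.normal(5.0, 1.0, 200) + 0.02 * t))
        coef = np.polynomial.polynomial.polyfit(out.times, out.values, 1)
        scale = np.max(np.abs(out.values)) + 1e-30
        assert abs(coef[1]) * t[-1] / scale < 1e-9 or abs(coef[1]) < 1e-12


class TestInterpolateUpsample:
    def test_two_point_insertion(self):
        tr = Trace(np.array([0.0, 60.0]), np.array([0.0, 3.0]))
        out = interpolate_upsample(tr, 2)
        assert np.allclose(out.values, [0.0, 1.0, 2.0, 3.0])
        assert np.allclose(out.times, [0.0, 20.0, 40.0, 60.0])

    def test_identity_when_zero(self):
        tr = sine_trace(5.0)
        assert interpolate_upsample(tr, 0) is tr

    @settings(max_examples=30, deadline=None)
    @given(
        vals=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40),
        n_insert=st.integers(0, 4),
    )
    def test_bounded_and_preserving(self, vals, n_insert):
        tr = Trace(10.0 * np.arange(len(vals)), np.array(vals))
        out = interpolate_upsample(tr, n_insert)
        assert len(out) == (len(vals) - 1) * (n_insert + 1) + 1
        assert np.max(np.abs(out.values)) <= np.max(np.abs(tr.values)) + 1e-9
        assert np.allclose(out.values[:: n_insert + 1], tr.values)


class TestStftSpectrogram:
    def test_pure_sine_concentrates_at_true_period(self):
        tr = interpolate_upsample(background_subtract(sine_trace(5.0)), 2)
        spec = stft_spectrogram(tr)
        pm = spec.period_axis
        sel = (pm >= 2.0) & (pm <= 10.0)
        idx = np.flatnonzero(sel)
        for row in spec.magnitudes:
            k = idx[np.argmax(row[idx])]
            assert abs(pm[k] - 5.0) <= 0.15
        # energy concentration: > 80% of in-band spectral power within one
        # resolution bin (1/window-span) of the peak, at every window
        freqs = 1.0 / (pm * 60.0)
        df_res = 1.0 / spec.window_span_s
        for row in spec.magnitudes:
            p = row**2
            k = idx[np.argmax(p[idx])]
            band = np.abs(freqs - freqs[k]) <= df_res
            assert p[sel & band].sum() / p[sel].sum() > 0.8

    def test_zero_trace_all_zero(self):
        t = (20.0 / 3.0) * np.arange(400)
        spec = stft_spectrogram(Trace(t, np.zeros(400)))
        assert np.allclose(spec.magnitudes, 0.0)

    def test_short_trace_rejected(self):
        t = 20.0 * np.arange(100)
        with pytest.raises(InsufficientDataError):
            stft_spectrogram(Trace(t, np.sin(t)))

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            SpectrogramConfig(window_len=4)
        with pytest.raises(InvalidParameterError):
            SpectrogramConfig(hop=0)
        with pytest.raises(InvalidParameterError):
            SpectrogramConfig(n_freq_bins=10)


class TestMajorPeriod:
    @pytest.mark.parametrize("period, tol", [(4.1, 0.2), (5.0, 0.1), (3.0, 0.1)])
    def test_sine_periods(self, period, tol):
        assert major_period(sine_trace(period, duration_min=20.0)) == pytest.approx(
            period, abs=tol
        )

    def test_white_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(1)
        t = 20.0 * np.arange(270)
        tr = Trace(t, rng.normal(size=270))
        _, confident = major_period(tr, with_confidence=True)
        assert not confident

    def test_sine_flagged_confident(self):
        _, confident = major_period(sine_trace(5.0), with_confidence=True)
        assert confident

    def test_short_window_rejected(self):
        with pytest.raises(InsufficientDataError):
            major_period(sine_trace(5.0), t_window=(0.0, 100.0))

    def test_matches_brute_force_periodogram(self):
        # independent oracle: dense direct periodogram argmax
        rng = np.random.default_rng(42)
        for _ in range(100):
            period = rng.uniform(2.2, 12.0)
            amp = rng.uniform(0.5, 3.0)
            noise = rng.uniform(0.0, 0.3)
            tr = sine_trace(period, duration_min=90.0, amp=amp,
                            phase=rng.uniform(0, 1))
            tr = Trace(tr.times, tr.values + rng.normal(0, noise, len(tr)))
            got = major_period(tr)
            vals = tr.values - np.polynomial.polynomial.polyval(
                tr.times, np.polynomial.polynomial.polyfit(tr.times, tr.values, 1)
            )
            periods_grid = np.arange(2.0, 15.0, 0.02)
            power = [
                np.abs(np.sum(vals * np.exp(-2j * np.pi * tr.times / (p * 60.0)))) ** 2
                for p in periods_grid
            ]
            brute = periods_grid[int(np.argmax(power))]
            assert got == pytest.approx(brute, abs=0.15)


class TestClassifyEntrainment:
    @pytest.mark.parametrize(
        "stim, resp, mode",
        [(10.0, 5.0, "1:2"), (2.0, 4.0, "2:1"), (5.0, 5.0, "1:1"),
         (10.0, 3.3, "1:3"), (4.0, 5.0, "unentrained")],
    )
    def test_examples(self, stim, resp, mode):
        assert classify_entrainment(stim, resp) == mode

    @pytest.mark.parametrize("p,q", [(1, 1), (1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2)])
    @pytest.mark.parametrize("t_resp", [2.0, 4.7, 10.0])
    def test_exact_ratio_recovered(self, p, q, t_resp):
        stim = (q / p) * t_resp  # p pulses span q response cycles
        assert classify_entrainment(stim, t_resp) == f"{p}:{q}"

    def test_tolerance_validation(self):
        with pytest.raises(InvalidParameterError):
            classify_entrainment(5.0, 5.0, tol=0.5)


class TestSynchronizationIndex:
    def test_identical_in_phase_sines_score_one(self):
        tr = sine_trace(5.0)
        group = TraceGroup((tr, Trace(tr.times, tr.values.copy()),
                            Trace(tr.times, tr.values.copy())))
        assert synchronization_index(group) > 0.98

    def test_antiphase_pair_scores_zero(self):
        a = sine_trace(5.0, phase=0.0)
        b = sine_trace(5.0, phase=0.5)
        assert synchronization_index(TraceGroup((a, b))) < 0.05

    def test_uniform_phases_score_low(self):
        n = 50
        traces = tuple(sine_trace(5.0, phase=k / n) for k in range(n))
        assert synchronization_index(TraceGroup(traces)) <= 0.2

    def test_needs_two_traces(self):
        with pytest.raises(InvalidParameterError):
            synchronization_index(TraceGroup((sine_trace(5.0),)))


class TestAnalyzeGroup:
    def test_free_running_group_is_unsynchronized(self):
        from isletsync.synth import SynthSpec, synth_group

        spec = SynthSpec(n_islets=4, periods=(3.0, 4.2, 5.0, 6.3),
                         phases=(0.1, 0.4, 0.6, 0.9), duration=90.0, seed=1)
        report = analyze_group(synth_group(spec))
        assert report.sync_before is not None and report.sync_before < 0.6

    def test_resettable_group_synchronizes_during_pulses(self):
        from isletsync.pulses import PulseTrain
        from isletsync.synth import resettable_oscillator_group

        train = PulseTrain(1200.0 + 300.0 * np.arange(10), 10.0, 0.35)
        group = resettable_oscillator_group(
            4, (4.0, 5.0, 5.5, 6.0), train, reset_strength=0.9, seed=2,
            duration=110.0,
        )
        report = analyze_group(group, train)
        assert report.sync_during is not None and report.sync_before is not None
        assert report.sync_during > report.sync_before

    def test_single_islet_group_has_periods_but_no_index(self):
        tr = sine_trace(5.0)
        report = analyze_group(TraceGroup((tr,)))
        assert report.periods_before[0] == pytest.approx(5.0, abs=0.1)
        assert report.sync_before is None
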