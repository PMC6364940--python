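import numpy as np
import pytest
from scipy.integrate import solve_ivp

from isletsync.errors import InvalidParameterError, NumericError
from isletsync.model import (
    DEFAULT_INITIAL_STATE,
    ModelParams,
    ModelState,
    derivatives,
    ip3_rate,
    make_heterogeneous_population,
    natural_period,
    simulate,
)
from isletsync.pulses import PulseTrain, empty_train


class TestIp3Rate:
    def test_steady_state_at_drive_amplitude(self, default_params):
        assert ip3_rate(0.35, True, default_params) == pytest.approx(0.0)

    def test_zero_fixed_point_without_drive(self, default_params):
        assert ip3_rate(0.0, False, default_params) == pytest.approx(0.0)

    def test_ten_second_pulse_reaches_one_minus_e_inverse(self, default_params):
        # closed form: ip3(t) = A (1 - exp(-t/tau)) from ip3(0) = 0
        expected = 0.35 * (1.0 - np.exp(-1.0))
        sol = solve_ivp(
            lambda t, y: [ip3_rate(y[0], True, default_params)],
            (0.0, 10.0), [0.0], rtol=1e-10, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(expected, abs=1e-8)
        assert expected == pytest.approx(0.2213, abs=5e-4)

    def test_negative_ip3_rejected(self, default_params):
        with pytest.raises(InvalidParameterError):
            ip3_rate(-0.1, True, default_params)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(tau_ip3=0.0)


class TestDerivatives:
    def test_zero_ip3_reduces_to_unstimulated_model(self, default_params):
        state = DEFAULT_INITIAL_STATE
        no_train = derivatives(state, 0.0, None, default_params)
        with_train = derivatives(
            state, 0.0, PulseTrain(np.array([500.0]), 10.0, 0.35), default_params
        )
        assert no_train == with_train

    def test_ip3_opens_er_release_path(self, default_params):
        # with ca_er > ca_c, raising ip3 from 0 to 0.35 must increase
        # d(ca_c)/dt and decrease d(ca_er)/dt
        base = DEFAULT_INITIAL_STATE
        for ca_c, ca_er in [(0.05, 150.0), (0.3, 100.0), (0.02, 250.0)]:
            lo = ModelState(**{**base.__dict__, "ca_c": ca_c, "ca_er": ca_er, "ip3": 0.0})
            hi = ModelState(**{**base.__dict__, "ca_c": ca_c, "ca_er": ca_er, "ip3": 0.35})
            dlo = derivatives(lo, 0.0, None, default_params)
            dhi = derivatives(hi, 0.0, None, default_params)
            assert dhi.ca_c > dlo.ca_c
            assert dhi.ca_er < dlo.ca_er

    def test_ip3_decays_between_pulses(self, default_params):
        state = ModelState(**{**DEFAULT_INITIAL_STATE.__dict__, "ip3": 0.2})
        d = derivatives(state, 0.0, None, default_params)
        assert d.ip3 == pytest.approx(-0.2 / default_params.tau_ip3)

    def test_nonfinite_state_names_field(self, default_params):
        bad = ModelState(**{**DEFAULT_INITIAL_STATE.__dict__, "atp": float("nan")})
        with pytest.raises(NumericError, match="atp"):
            derivatives(bad, 0.0, None, default_params)


class TestSimulate:
    def test_ip3_matches_closed_form_under_pulses(self, default_params):
        train = PulseTrain(np.array([100.0, 300.0]), 10.0, 0.35)
        traj = simulate(default_params, train, t_end=500.0, dt_out=1.0)
        tau, amp = default_params.tau_ip3, 0.35

        def closed_form(t):
            # piecewise-constant drive: exponential toward amp while on,
            # toward 0 while off
            ip3 = 0.0
            edges = [0.0, 100.0, 110.0, 300.0, 310.0, t]
            for a, b in zip(edges[:-1], edges[1:]):
                if b <= a:
                    continue
                b = min(b, t)
                target = amp if (100.0 <= a < 110.0 or 300.0 <= a < 310.0) else 0.0
                ip3 = target + (ip3 - target) * np.exp(-(b - a) / tau)
                if b == t:
                    break
            return ip3

        for i in range(0, len(traj.times), 7):
            t = traj.times[i]
            assert traj["ip3"][i] == pytest.approx(closed_form(t), abs=1e-6)

    def test_ip3_stays_within_drive_bounds(self, default_params):
        train = PulseTrain(np.array([60.0, 180.0, 420.0]), 10.0, 0.35)
        traj = simulate(default_params, train, t_end=600.0, dt_out=0.5)
        assert np.all(traj["ip3"] >= -1e-12)
        assert np.all(traj["ip3"] <= 0.35 + 1e-12)

    def test_er_calcium_drops_during_pulse(self, default_params):
        onset = 1500.0
        train = PulseTrain(np.array([onset]), 10.0, 0.35)
        traj = simulate(default_params, train, t_end=onset + 60.0, dt_out=0.5)
        i0 = np.argmin(np.abs(traj.times - onset))
        i1 = np.argmin(np.abs(traj.times - (onset + 10.0)))
        assert traj["ca_er"][i0] > traj["ca_c"][i0]
        assert traj["ca_er"][i1] < traj["ca_er"][i0]

    def test_zero_amplitude_train_is_null_perturbation(self, default_params):
        train = PulseTrain(np.array([600.0, 900.0]), 10.0, 0.0)
        a = simulate(default_params, train, t_end=1800.0, dt_out=2.0)
        b = simulate(default_params, None, t_end=1800.0, dt_out=2.0)
        assert np.allclose(a["ca_c"], b["ca_c"], atol=1e-6)

    def test_invalid_time_arguments(self, default_params):
        with pytest.raises(InvalidParameterError):
            simulate(default_params, None, t_end=-1.0)
        with pytest.raises(InvalidParameterError):
            simulate(default_params, None, t_end=10.0, dt_out=0.0)


class TestOscillation:
    def test_natural_period_near_five_minutes(self, default_params):
        period = natural_period(default_params, t_end=7200.0, dt_out=1.0)
        assert 4.0 * 60.0 <= period <= 6.0 * 60.0

    def test_period_stable_over_two_hours(self, ca_trace_2h):
        from isletsync.prc import detect_nadirs

        nadirs = np.asarray(detect_nadirs(ca_trace_2h))
        periods = np.diff(nadirs)
        assert periods.size >= 10
        first, last = periods[:3].mean(), periods[-3:].mean()
        assert abs(last - first) / first < 0.02

    def test_fbp_locks_to_calcium_period(self, unperturbed_2h):
        # the glycolytic oscillation shares the Ca2+ period
        tr = unperturbed_2h
        mask = tr.times >= 1200.0
        t = tr.times[mask]
        dt = t[1] - t[0]

        def fft_period(x):
            x = x - x.mean()
            mags = np.abs(np.fft.rfft(x, n=4 * len(x)))
            freqs = np.fft.rfftfreq(4 * len(x), dt)
            mags[freqs < 1.0 / 1200.0] = 0.0
            return 1.0 / freqs[np.argmax(mags)]

        p_ca = fft_period(tr["ca_c"][mask])
        p_fbp = fft_period(tr["fbp"][mask])
        assert p_fbp == pytest.approx(p_ca, rel=0.02)


class TestHeterogeneousPopulation:
    def test_zero_islets(self):
        assert make_heterogeneous_population(0, seed=1) == []

    def test_same_seed_identical(self):
        a = make_heterogeneous_population(3, seed=5, validate=False)
        b = make_heterogeneous_population(3, seed=5, validate=False)
        assert a == b

    def test_default_ranges_give_distinct_periods_in_range(self):
        pops = make_heterogeneous_population(3, seed=2, validate=False)
        periods = [natural_period(p, t_end=3600.0, dt_out=2.0) for p in pops]
        assert all(3.0 * 60.0 <= p <= 7.0 * 60.0 for p in periods)
        assert np.std(periods) > 1.0
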