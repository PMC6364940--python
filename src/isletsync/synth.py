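"""Synthetic Ca2+ trace generators.

These emulate the statistical structure of islet fluorescence recordings —
per-islet oscillations with heterogeneous periods (most near 5 min),
phases and amplitudes, a slowly drifting baseline, additive Gaussian
noise, 20-s sampling — so that every analysis stage is testable without
experimental data.  Also provides the piecewise-sine validation waveform
used to exercise the spectrogram workflow, and a cheap resettable
phase-oscillator surrogate for testing synchronization metrics without
ODE runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import Trace, TraceGroup
from .errors import InvalidParameterError
from .pulses import PulseTrain


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic experiment group.

    Periods are minutes; ``drift_slope`` is signal units per minute;
    ``sampling_interval`` is seconds; ``phases`` are cycle fractions.
    Scalars broadcast across islets.
    """

    n_islets: int = 4
    periods: tuple = (5.0, 4.0, 6.0, 5.5)
    amplitudes: tuple | float = 1.0
    phases: tuple | float = (0.0, 0.3, 0.55, 0.8)
    baseline: float = 0.2
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    sampling_interval: float = 20.0
    duration: float = 90.0
    waveform: str = "sine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_islets < 1:
            raise InvalidParameterError(f"n_islets must be >= 1, got {self.n_islets}")
        periods = _broadcast(self.periods, self.n_islets, "periods")
        amps = _broadcast(self.amplitudes, self.n_islets, "amplitudes")
        phases = _broadcast(self.phases, self.n_islets, "phases")
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "phases", phases)
        if any(not 1.0 <= p <= 20.0 for p in periods):
            raise InvalidParameterError(f"periods must lie in [1, 20] min, got {periods}")
        if self.duration < 2.0 * max(periods):
            raise InvalidParameterError(
                f"duration {self.duration} min is under 2x the longest period"
            )
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.sampling_interval <= 0:
            raise InvalidParameterError("sampling_interval must be > 0")
        if self.waveform not in ("sine", "relaxation"):
            raise InvalidParameterError(
                f"waveform must be 'sine' or 'relaxation', got {self.waveform!r}"
            )


def _broadcast(x, n: int, name: str) -> tuple:
    if np.isscalar(x):
        return (float(x),) * n
    vals = tuple(float(v) for v in x)
    if len(vals) == n:
        return vals
    if len(vals) > n:
        return vals[:n]
    raise InvalidParameterError(f"{name} has {len(vals)} entries for {n} islets")


def _waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Unit-amplitude periodic waveform of a cycle-fraction phase.

    ``sine`` is a plain sinusoid; ``relaxation`` is a burst-like square
    wave (plateau for the first half of the cycle, trough for the second,
    5%-of-cycle raised-cosine edges) mimicking active/silent phases.
    """
    ph = np.mod(phase, 1.0)
    if kind == "sine":
        return np.sin(2.0 * np.pi * ph)
    ramp = 0.05
    out = np.empty_like(ph)
    for lo, hi, start, stop in ((0.0, 0.5, 1.0, -1.0), (0.5, 1.0, -1.0, 1.0)):
        seg = (ph >= lo) & (ph < hi)
        local = (ph[seg] - lo) / (hi - lo)
        val = np.full(local.shape, start)
        edge = local > 1.0 - ramp / (hi - lo)
        u = (local[edge] - (1.0 - ramp / (hi - lo))) / (ramp / (hi - lo))
        val[edge] = start + (stop - start) * 0.5 * (1.0 - np.cos(np.pi * u))
        out[seg] = val
    return out


def _time_grid(duration_min: float, dt_s: float) -> np.ndarray:
    n = int(np.floor(duration_min * 60.0 / dt_s)) + 1
    return dt_s * np.arange(n)


def synth_group(spec: SynthSpec) -> TraceGroup:
    """Generate a reproducible synthetic trace group from a spec."""
    rng = np.random.default_rng(spec.seed)
    t = _time_grid(spec.duration, spec.sampling_interval)
    traces = []
    for i in range(spec.n_islets):
        period_s = spec.periods[i] * 60.0
        phase = t / period_s + spec.phases[i]
        v = (
            spec.baseline
            + spec.drift_slope * t / 60.0
            + spec.amplitudes[i] * _waveform(phase, spec.waveform)
        )
        if spec.noise_sd > 0:
            v = v + rng.normal(0.0, spec.noise_sd, size=t.size)
        traces.append(Trace(t, v))
    return TraceGroup(tuple(traces))


def s2_fixture(background: float = 100.0) -> Trace:
    """The piecewise-sine spectrogram validation waveform.

    A 90-min record sampled every 20 s: period 5 min at amplitude 30 for
    the first 30 min, period 3 min at amplitude 50 for the next 30, and
    period 4 min at amplitude 20 for the final 30, riding on a constant
    background offset.
    """
    t = _time_grid(90.0, 20.0)
    v = np.full(t.shape, float(background))
    for t0, t1, period_min, amp in ((0.0, 30.0, 5.0, 30.0), (30.0, 60.0, 3.0, 50.0), (60.0, 90.001, 4.0, 20.0)):
        seg = (t >= t0 * 60.0) & (t < t1 * 60.0)
        v[seg] += amp * np.sin(2.0 * np.pi * (t[seg] - t0 * 60.0) / (period_min * 60.0))
    return Trace(t, v)


def resettable_oscillator_group(
    n: int,
    periods,
    pulse_train: PulseTrain | None,
    reset_strength: float,
    seed: int = 0,
    duration: float = 90.0,
    sampling_interval: float = 20.0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
) -> TraceGroup:
    """Phase oscillators whose phases jump toward a common target at each
    pulse: a cheap surrogate for pulse-resettable islets.

    Each oscillator advances at its own natural rate; at every pulse onset
    its phase moves a fraction ``reset_strength`` of the way (along the
    shortest arc) toward phase 0, the start of an active phase.  Emitted
    as burst-like relaxation waveforms.
    """
    if not 0.0 <= reset_strength <= 1.0:
        raise InvalidParameterError(f"reset_strength must lie in [0, 1], got {reset_strength}")
    periods = _broadcast(periods, n, "periods")
    rng = np.random.default_rng(seed)
    t = _time_grid(duration, sampling_interval)
    onsets = np.asarray(pulse_train.onsets) if pulse_train is not None else np.empty(0)
    init = rng.uniform(0.0, 1.0, size=n)
    traces = []
    for i in range(n):
        rate = 1.0 / (periods[i] * 60.0)
        phase = np.empty(t.size)
        ph = init[i]
        prev = t[0]
        for k, tk in enumerate(t):
            ph += rate * (tk - prev)
            for on in onsets[(onsets > prev) & (onsets <= tk)]:
                frac = np.mod(ph, 1.0)
                # shortest signed arc from current phase to the target 0
                arc = -frac if frac <= 0.5 else 1.0 - frac
                ph += reset_strength * arc
            phase[k] = ph
            prev = tk
        v = baseline + amplitude * _waveform(phase, "relaxation")
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=t.size)
        traces.append(Trace(t, v))
    return TraceGroup(tuple(traces))
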