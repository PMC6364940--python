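"""Phase response curves from nadir timing of perturbed vs unperturbed runs.

A single square IP3 pulse is applied at a grid of phases of the Ca2+
oscillation; the phase shift it produces is read from the timing of the
first Ca2+ nadir after the pulse relative to the matching nadir of the
unperturbed trajectory.  Phase 0 is the beginning of a burst active phase
(the upward crossing of the cycle midline) and phase 1 the end of the
following silent phase; a negative phase difference is an advance, a
positive one a delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import Trace
from .errors import (
    FlatTraceError,
    InsufficientDataError,
    InvalidParameterError,
    NadirMatchingError,
    RegimeError,
)
from .model import ModelParams, Trajectory, simulate
from .pulses import PulseTrain

#: Minimum relative peak-to-trough amplitude for a trace to count as
#: oscillating (fraction of the absolute signal level).
_FLAT_REL = 1e-3


@dataclass(frozen=True)
class PRCPoint:
    """One PRC sample: stimulus phase in [0, 1) and the resulting phase
    difference (negative = advance, positive = delay)."""

    phase: float
    delta_phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase < 1.0:
            raise InvalidParameterError(f"phase must lie in [0, 1), got {self.phase}")
        if abs(self.delta_phi) >= 1.0:
            raise InvalidParameterError(f"|delta_phi| must be < 1, got {self.delta_phi}")


@dataclass(frozen=True)
class PRCurve:
    """Ordered PRC samples plus the oscillator's natural period (s)."""

    points: tuple
    natural_period: float

    def __post_init__(self) -> None:
        if self.natural_period <= 0:
            raise InvalidParameterError("natural_period must be > 0")
        phases = [pt.phase for pt in self.points]
        if any(b <= a for a, b in zip(phases, phases[1:])):
            raise InvalidParameterError("PRC phases must be strictly increasing")
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def phases(self) -> np.ndarray:
        return np.array([pt.phase for pt in self.points])

    @property
    def delta_phis(self) -> np.ndarray:
        return np.array([pt.delta_phi for pt in self.points])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"phase": self.phases, "delta_phi": self.delta_phis})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.8g")


def _oscillation_bands(values: np.ndarray) -> tuple[float, float, float]:
    """Midline and hysteresis band of an oscillating signal.

    Quantiles rather than extremes, so an isolated transient (e.g. a
    stimulus-evoked Ca2+ spike) cannot drag the midline above the
    regular bursts."""
    lo, hi = (float(q) for q in np.quantile(values, (0.05, 0.95)))
    amp = hi - lo
    scale = max(abs(lo), abs(hi), 1e-30)
    if amp < _FLAT_REL * scale or amp == 0.0:
        raise FlatTraceError(
            f"peak-to-trough amplitude {amp:.3g} is below threshold; no oscillation"
        )
    mid = 0.5 * (lo + hi)
    return mid, mid - 0.2 * amp, mid + 0.2 * amp


def _crossings(times: np.ndarray, values: np.ndarray, low: float, high: float):
    """Hysteresis transition indices: upward (low band -> high band) and
    downward, as (kind, index-of-entry-into-high/low) pairs in time order."""
    state = 0  # -1 low, +1 high, 0 unknown
    ups: list[int] = []
    downs: list[int] = []
    for i, v in enumerate(values):
        if v > high:
            if state == -1:
                ups.append(i)
            state = 1
        elif v < low:
            if state == 1:
                downs.append(i)
            state = -1
    return np.array(ups, dtype=int), np.array(downs, dtype=int)


def detect_nadirs(trace: Trace) -> list[float]:
    """Times (s) of the Ca2+ nadir of every complete cycle in a trace.

    Cycles are delimited by hysteresis crossings of the cycle midline so
    that noise does not split cycles; within each inter-burst span the
    sampled minimum is refined by parabolic interpolation.  Raises
    :class:`FlatTraceError` when no oscillation is present.
    """
    t, v = trace.times, trace.values
    mid, low, high = _oscillation_bands(v)
    ups, _ = _crossings(t, v, low, high)
    if ups.size < 2:
        raise FlatTraceError("no repeated active-phase onsets found; no oscillation")
    amp = float(np.max(v) - np.min(v))
    nadirs = []
    for a, b in zip(ups[:-1], ups[1:]):
        seg = v[a:b]
        vmin = float(np.min(seg))
        # the nadir marks the end of the silent phase: on traces with a
        # flat inter-burst trough every trough sample ties for the
        # minimum, so take the last sample within a small band of it
        near = np.flatnonzero(seg <= vmin + 0.01 * amp)
        i = a + int(near[-1])
        nadirs.append(_refine_minimum(t, v, i))
    return nadirs


def _refine_minimum(t: np.ndarray, v: np.ndarray, i: int) -> float:
    """Parabolic refinement of a sampled minimum (degenerate fits fall
    back to the sample time)."""
    if i <= 0 or i >= t.size - 1:
        return float(t[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return float(t[i])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(t[i] + shift * (t[i + 1] - t[i]))


def active_phase_onsets(trace: Trace) -> np.ndarray:
    """Times of active-phase onsets (upward midline crossings, linearly
    interpolated); phase 0 of the oscillation."""
    t, v = trace.times, trace.values
    mid, low, high = _oscillation_bands(v)
    ups, _ = _crossings(t, v, low, high)
    out = []
    for i in ups:
        # walk back to the last sample below the midline, then interpolate
        j = i
        while j > 0 and v[j] > mid:
            j -= 1
        if v[j] > mid:  # crossed before the record started
            continue
        frac = (mid - v[j]) / (v[j + 1] - v[j])
        out.append(float(t[j] + frac * (t[j + 1] - t[j])))
    return np.asarray(out)


def phase_of_time(t: float, cycle_start: float, natural_period: float) -> float:
    """Oscillation phase of time ``t``: ``((t - cycle_start)/T) mod 1``."""
    if natural_period <= 0:
        raise InvalidParameterError(f"natural_period must be > 0, got {natural_period}")
    return float(((t - cycle_start) / natural_period) % 1.0)


def phase_shift(
    unperturbed: Trajectory,
    perturbed: Trajectory,
    pulse_time: float,
    natural_period: float | None = None,
    settle_s: float = 40.0,
) -> float:
    """Phase difference caused by a pulse, from matched post-pulse nadirs.

    The first Ca2+ nadir of the perturbed trajectory after the pulse has
    settled is paired with the nearest unperturbed nadir; the timing
    difference, normalized by the natural period and wrapped into
    (-0.5, 0.5], is the phase shift (negative = advance).  ``settle_s``
    skips the stimulus-evoked Ca2+ transient itself (pulse duration plus
    a few IP3 time constants), which is not an oscillation nadir; the
    nadir of the *reset* oscillation is the quantity of interest.
    Raises :class:`NadirMatchingError` when every unperturbed nadir is
    farther than 0.75 period from the perturbed one.
    """
    un = detect_nadirs(Trace(unperturbed.times, unperturbed["ca_c"]))
    per = detect_nadirs(Trace(perturbed.times, perturbed["ca_c"]))
    un = np.asarray(un)
    per = np.asarray(per)
    if natural_period is None:
        if un.size < 2:
            raise InsufficientDataError("unperturbed run has fewer than 2 nadirs")
        natural_period = float(np.mean(np.diff(un)))
    cand = per[per > pulse_time + settle_s]
    if cand.size == 0:
        raise InsufficientDataError("no perturbed nadir after the pulse")
    t_p = float(cand[0])
    dists = np.abs(un - t_p)
    j = int(np.argmin(dists))
    # ties toward the earlier unperturbed nadir
    if j > 0 and np.isclose(dists[j - 1], dists[j]):
        j -= 1
    if dists[j] > 0.75 * natural_period:
        raise NadirMatchingError(
            f"perturbed nadir at {t_p:.1f} s is {dists[j]:.1f} s from the nearest "
            f"unperturbed nadir (> 0.75 period)"
        )
    dphi = (t_p - float(un[j])) / natural_period
    # wrap into (-0.5, 0.5]
    dphi = dphi - np.floor(dphi + 0.5)
    return float(dphi)


def compute_prc(
    params: ModelParams | None = None,
    n_phases: int = 50,
    pulse_duration: float = 10.0,
    pulse_amplitude: float | None = None,
    transient: float | None = None,
    dt_out: float = 0.5,
) -> PRCurve:
    """Phase response curve of the model to a single IP3 pulse.

    One simulation per grid phase: after a discarded transient, a pulse of
    ``pulse_duration`` seconds is applied at each of ``n_phases`` evenly
    spaced phases of the cycle (phase measured from an active-phase
    onset), and the shift of the following Ca2+ nadir relative to the
    unperturbed run is recorded.
    """
    if n_phases < 4:
        raise InvalidParameterError(f"n_phases must be >= 4, got {n_phases}")
    p = params if params is not None else ModelParams()
    if pulse_amplitude is not None:
        p = p.with_(ip3_amp=pulse_amplitude)
    cut = p.transient_s if transient is None else transient

    probe = simulate(p, None, t_end=cut + 3600.0, dt_out=dt_out)
    mask = probe.times >= cut
    ca = Trace(probe.times[mask], probe["ca_c"][mask])
    try:
        onsets = active_phase_onsets(ca)
        nadirs = np.asarray(detect_nadirs(ca))
    except FlatTraceError as exc:
        raise RegimeError(f"model not oscillatory at these parameters: {exc}") from exc
    if onsets.size < 2 or nadirs.size < 2:
        raise RegimeError("too few cycles after the transient; not oscillatory")
    period = float(np.mean(np.diff(nadirs)))
    t_ref = float(onsets[0])

    t_end = t_ref + 4.0 * period
    base = simulate(p, None, t_end=t_end, dt_out=dt_out)

    points = []
    for k in range(n_phases):
        phase = k / n_phases
        t_pulse = t_ref + phase * period
        train = PulseTrain(np.array([t_pulse]), pulse_duration, p.ip3_amp)
        pert = simulate(p, train, t_end=t_end, dt_out=dt_out)
        dphi = phase_shift(base, pert, t_pulse, natural_period=period)
        points.append(PRCPoint(phase, dphi))
    return PRCurve(tuple(points), period)
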