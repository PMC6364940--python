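"""Ca2+ trace analysis: background subtraction, interpolation, STFT
spectrograms, dominant-period detection, entrainment classification and a
phase-based synchronization index.

The spectrogram pipeline mirrors the workflow used for islet fluorescence
recordings: the group-average trace is background subtracted with a linear
fit, smoothed by inserting linearly interpolated points, and analyzed with
a short-time Fourier transform on a 256-point Hanning window producing
1000 positive-frequency bins, the window advancing 5 samples at a time.
The frequency axis is reported as an oscillation period in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import get_window

from .errors import (
    FlatTraceError,
    InsufficientDataError,
    InvalidParameterError,
)

#: Relative tolerance for the uniform-sampling check.
_UNIFORM_RTOL = 1e-6

#: Reportable oscillation-period range (min) for dominant-period detection.
DEFAULT_PERIOD_RANGE_MIN = (2.0, 15.0)

#: Periods above this (min) are masked from dominant-band reporting: slow
#: bands beyond the window length are analysis artifacts of the STFT.
DEFAULT_BAND_MASK_MIN = 10.0


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled time series: ``times`` in seconds, ``values``
    in signal units (uM or arbitrary fluorescence)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise InvalidParameterError("times and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise InvalidParameterError(f"a trace needs at least 2 samples, got {t.size}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _UNIFORM_RTOL * max(abs(dt[0]), 1e-30):
            raise InvalidParameterError("trace sampling is not uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t0 <= t <= t1."""
        mask = (self.times >= t0) & (self.times <= t1)
        if int(mask.sum()) < 2:
            raise InsufficientDataError(
                f"window [{t0}, {t1}] s contains {int(mask.sum())} samples"
            )
        return Trace(self.times[mask], self.values[mask])


@dataclass(frozen=True)
class TraceGroup:
    """Several islet traces on a shared time grid."""

    traces: tuple
    labels: tuple = ()

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        if len(traces) == 0:
            raise InvalidParameterError("a trace group needs at least one trace")
        t0 = traces[0].times
        for k, tr in enumerate(traces[1:], start=2):
            if tr.times.size != t0.size or np.max(np.abs(tr.times - t0)) > _UNIFORM_RTOL * max(
                abs(t0[-1]), 1.0
            ):
                raise InvalidParameterError(f"trace {k} is not on the shared time grid")
        labels = tuple(self.labels) if self.labels else tuple(
            f"islet_{i + 1}" for i in range(len(traces))
        )
        if len(labels) != len(traces):
            raise InvalidParameterError("labels and traces differ in length")
        object.__setattr__(self, "traces", traces)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def times(self) -> np.ndarray:
        return self.traces[0].times

    def mean_trace(self) -> Trace:
        return Trace(self.times, np.mean([tr.values for tr in self.traces], axis=0))


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT settings: 256-sample Hanning window, hop of 5 samples, 1000
    positive-frequency bins obtained by zero-padding each window."""

    window_len: int = 256
    hop: int = 5
    n_freq_bins: int = 1000
    window_shape: str = "hann"

    def __post_init__(self) -> None:
        if self.window_len < 8:
            raise InvalidParameterError(f"window_len must be >= 8, got {self.window_len}")
        if self.hop < 1:
            raise InvalidParameterError(f"hop must be >= 1, got {self.hop}")
        if self.n_freq_bins < self.window_len // 2:
            raise InvalidParameterError(
                f"n_freq_bins must be >= window_len/2, got {self.n_freq_bins}"
            )


@dataclass(frozen=True)
class Spectrogram:
    """Time-by-period magnitude matrix.

    ``period_axis`` is in minutes, ordered to match the columns of
    ``magnitudes``; ``window_center_times`` is in seconds.
    """

    window_center_times: np.ndarray
    period_axis: np.ndarray
    magnitudes: np.ndarray
    window_span_s: float = 0.0

    def __post_init__(self) -> None:
        if self.magnitudes.shape != (self.window_center_times.size, self.period_axis.size):
            raise InvalidParameterError("magnitude matrix does not match its axes")
        if np.any(self.magnitudes < 0):
            raise InvalidParameterError("magnitudes must be non-negative")

    def dominant_band(
        self,
        t_range: tuple[float, float] | None = None,
        period_range_min: tuple[float, float] = (2.0, DEFAULT_BAND_MASK_MIN),
    ) -> float:
        """Dominant period (min) of the window-averaged magnitude within a
        time range, restricted to the reportable period band."""
        mags = self.magnitudes
        if t_range is not None:
            centers = self.window_center_times
            sel = (centers >= t_range[0]) & (centers <= t_range[1])
            if not np.any(sel):
                raise InsufficientDataError(f"no STFT windows centred in {t_range}")
            # prefer windows whose full span lies inside the range: they
            # are uncontaminated by neighbouring segments of the record
            half = 0.5 * self.window_span_s
            inner = sel & (centers - half >= t_range[0]) & (centers + half <= t_range[1])
            mags = mags[inner if np.any(inner) else sel]
        pmask = (self.period_axis >= period_range_min[0]) & (
            self.period_axis <= period_range_min[1]
        )
        if not np.any(pmask):
            raise InvalidParameterError("period mask excludes every bin")
        # a band is where the per-window peaks line up, so take the median
        # of per-window peak periods; this is robust to windows that
        # straddle a frequency transition
        sel = np.flatnonzero(pmask)
        peaks = self.period_axis[sel[np.argmax(mags[:, sel], axis=1)]]
        return float(np.median(peaks))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            self.magnitudes,
            index=pd.Index(self.window_center_times, name="time_s"),
            columns=[f"{p:.6g}" for p in self.period_axis],
        )
        return df


@dataclass(frozen=True)
class EntrainmentResult:
    """Per-islet entrainment summary: dominant periods before and during
    pulsing and the p:q locking mode (p pulses per q Ca2+ peaks)."""

    stimulus_period: float
    response_period_before: float | None
    response_period_during: float | None
    mode: str


def background_subtract(trace: Trace) -> Trace:
    """Remove the least-squares line from a trace (linear-fit background)."""
    if len(trace) < 3:
        raise InsufficientDataError("background subtraction needs at least 3 samples")
    coef = np.polynomial.polynomial.polyfit(trace.times, trace.values, 1)
    line = np.polynomial.polynomial.polyval(trace.times, coef)
    return Trace(trace.times, trace.values - line)


def interpolate_upsample(trace: Trace, n_insert: int = 2) -> Trace:
    """Insert ``n_insert`` linearly interpolated points between every pair
    of samples; the original samples are preserved exactly."""
    if n_insert < 0:
        raise InvalidParameterError(f"n_insert must be >= 0, got {n_insert}")
    if n_insert == 0:
        return trace
    L = len(trace)
    step = n_insert + 1
    new_len = (L - 1) * step + 1
    idx = np.arange(new_len) / step  # fractional sample index
    new_t = trace.times[0] + idx * trace.dt
    new_v = np.interp(idx, np.arange(L), trace.values)
    # pin original samples to their exact values (no round-off drift)
    new_v[::step] = trace.values
    new_t[::step] = trace.times
    return Trace(new_t, new_v)


def stft_spectrogram(trace: Trace, config: SpectrogramConfig | None = None) -> Spectrogram:
    """Short-time Fourier spectrogram of a trace on a period (min) axis.

    Each length-``window_len`` segment is tapered, zero-padded to
    ``2 * n_freq_bins`` samples and transformed; the magnitudes of the
    ``n_freq_bins`` positive-frequency bins form one spectrogram row.
    Successive windows are ``hop`` samples apart; trailing samples that do
    not fill a window are dropped.
    """
    cfg = config if config is not None else SpectrogramConfig()
    L = len(trace)
    if L < cfg.window_len:
        raise InsufficientDataError(
            f"trace of {L} samples is shorter than the {cfg.window_len}-sample window"
        )
    shape = "hann" if cfg.window_shape.lower() in ("hann", "hanning") else cfg.window_shape
    win = get_window(shape, cfg.window_len, fftbins=True)
    nfft = 2 * cfg.n_freq_bins
    starts = np.arange(0, L - cfg.window_len + 1, cfg.hop)
    segs = np.stack([trace.values[s : s + cfg.window_len] for s in starts])
    mags = np.abs(np.fft.rfft(segs * win, n=nfft, axis=1))[:, 1 : cfg.n_freq_bins + 1]
    freqs_hz = np.arange(1, cfg.n_freq_bins + 1) / (nfft * trace.dt)
    period_min = 1.0 / freqs_hz / 60.0
    centers = trace.times[starts] + 0.5 * (cfg.window_len - 1) * trace.dt
    return Spectrogram(centers, period_min, mags, (cfg.window_len - 1) * trace.dt)


def _next_pow2(n: int) -> int:
    return 1 << max(int(n) - 1, 1).bit_length()


def major_period(
    trace: Trace,
    t_window: tuple[float, float] | None = None,
    period_range_min: tuple[float, float] = DEFAULT_PERIOD_RANGE_MIN,
    resolution_min: float = 0.1,
    prominence_threshold: float = 6.0,
    with_confidence: bool = False,
):
    """Dominant oscillation period (min) of a trace segment by FFT.

    The segment is linearly detrended and zero-padded so the period axis
    is resolved to ``resolution_min`` or better across the reportable
    range; the period of the maximal-magnitude bin inside that range is
    returned, rounded to 0.1 min.  With ``with_confidence`` the result is
    a ``(period, confident)`` pair, where ``confident`` is False when the
    spectral peak does not stand out from the background (no dominant
    rhythm, e.g. white noise).
    """
    seg = trace if t_window is None else trace.window(*t_window)
    span_s = seg.times[-1] - seg.times[0]
    lo, hi = period_range_min
    if span_s < 2.0 * lo * 60.0:
        raise InsufficientDataError(
            f"segment of {span_s:.0f} s holds fewer than 2 cycles of a {lo}-min period"
        )
    hi = min(hi, span_s / 2.0 / 60.0)  # need >= 2 cycles of the reported period
    vals = background_subtract(seg).values

    # zero-pad so that d(period) <= resolution at the slow end of the range
    df_needed = resolution_min * 60.0 / (hi * 60.0) ** 2
    nfft = _next_pow2(max(len(seg), math.ceil(1.0 / (df_needed * seg.dt))))
    mags = np.abs(np.fft.rfft(vals, n=nfft))
    freqs = np.fft.rfftfreq(nfft, seg.dt)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-300) / 60.0, np.inf)
    mask = (periods >= lo) & (periods <= hi)
    if not np.any(mask):
        raise InsufficientDataError("no FFT bins inside the reportable period range")
    sel = np.flatnonzero(mask)
    peak = sel[np.argmax(mags[sel])]
    period = round(float(periods[peak]), 1)
    if not with_confidence:
        return period
    background = float(np.mean(mags[sel])) or 1e-300
    confident = bool(mags[peak] / background >= prominence_threshold)
    return period, confident


def classify_entrainment(
    stimulus_period: float, response_period: float, tol: float = 0.15
) -> str:
    """p:q locking mode of a response to a periodic stimulus.

    Returns the smallest coprime ``p:q`` (p, q <= 3, p stimulus pulses per
    q response oscillations) with ``|p*Ts - q*Tr| <= tol*q*Tr``, or
    ``"unentrained"`` if no such ratio exists.
    """
    if stimulus_period <= 0 or response_period <= 0:
        raise InvalidParameterError("periods must be positive")
    if not 0.0 < tol <= 0.3:
        raise InvalidParameterError(f"tol must lie in (0, 0.3], got {tol}")
    candidates = sorted(
        ((p, q) for p in (1, 2, 3) for q in (1, 2, 3) if math.gcd(p, q) == 1),
        key=lambda pq: (pq[0] + pq[1], pq[0]),
    )
    for p, q in candidates:
        if abs(p * stimulus_period - q * response_period) <= tol * q * response_period:
            return f"{p}:{q}"
    return "unentrained"


def synchronization_index(
    group: TraceGroup,
    t_window: tuple[float, float] | None = None,
    n_eval: int = 512,
) -> float:
    """Kuramoto-style order parameter of a group of oscillating traces.

    Each trace gets an instantaneous phase that grows linearly from 0 to 1
    between successive Ca2+ nadirs; the index is the time average of the
    modulus of the mean unit phase vector.  1 means the traces run in
    phase; independent or antiphase traces score near 0.
    """
    from .prc import detect_nadirs

    if len(group) < 2:
        raise InvalidParameterError("synchronization index needs at least 2 traces")
    traces = group.traces
    if t_window is not None:
        traces = tuple(tr.window(*t_window) for tr in traces)
    phase_start, phase_end = -np.inf, np.inf
    interps = []
    for tr in traces:
        nadirs = np.asarray(detect_nadirs(tr))
        if nadirs.size < 2:
            raise FlatTraceError("a trace has fewer than 2 nadirs in the window")
        interps.append((nadirs, np.arange(nadirs.size, dtype=float)))
        phase_start = max(phase_start, nadirs[0])
        phase_end = min(phase_end, nadirs[-1])
    if phase_end <= phase_start:
        raise InsufficientDataError("traces share no common span of whole cycles")
    t_eval = np.linspace(phase_start, phase_end, n_eval)
    z = np.zeros(n_eval, dtype=complex)
    for nadirs, cyc in interps:
        phi = np.interp(t_eval, nadirs, cyc)
        z += np.exp(2j * np.pi * phi)
    r = np.abs(z) / len(interps)
    return float(np.mean(r))


@dataclass(frozen=True)
class GroupReport:
    """Output of :func:`analyze_group`."""

    spectrogram: Spectrogram
    periods_before: tuple
    periods_during: tuple
    entrainment: tuple
    sync_before: float | None
    sync_during: float | None
    sync_after: float | None
    labels: tuple

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "periods_before_min": list(self.periods_before),
            "periods_during_min": list(self.periods_during),
            "entrainment": [
                None
                if e is None
                else {
                    "stimulus_period_min": e.stimulus_period,
                    "response_period_before_min": e.response_period_before,
                    "response_period_during_min": e.response_period_during,
                    "mode": e.mode,
                }
                for e in self.entrainment
            ],
            "sync_index": {
                "before": self.sync_before,
                "during": self.sync_during,
                "after": self.sync_after,
            },
        }


def analyze_group(
    group: TraceGroup,
    pulse_train=None,
    config: SpectrogramConfig | None = None,
    n_insert: int = 2,
    entrainment_tol: float = 0.15,
) -> GroupReport:
    """Full analysis pipeline for one experiment group.

    The mean trace is background subtracted, upsampled by linear
    interpolation and passed through the STFT spectrogram.  Per islet, the
    dominant period is measured before and during pulsing (windows
    delimited by the first and last pulse onsets) and classified against
    the stimulus period; the synchronization index is computed before,
    during and after the pulse train.  Without a pulse train only the
    spectrogram, whole-trace periods and the overall index are reported.
    """
    cfg = config if config is not None else SpectrogramConfig()
    mean = interpolate_upsample(background_subtract(group.mean_trace()), n_insert)
    spec = stft_spectrogram(mean, cfg)

    t0, t1 = group.times[0], group.times[-1]
    sync = _sync_or_none(group, None)
    if pulse_train is None or pulse_train.empty():
        periods = tuple(_period_or_none(tr, None) for tr in group.traces)
        return GroupReport(spec, periods, (None,) * len(group), (None,) * len(group),
                           sync, None, None, group.labels)

    first, last = float(pulse_train.onsets[0]), float(pulse_train.onsets[-1])
    gaps = np.diff(pulse_train.onsets)
    stim_period_min = float(np.mean(gaps)) / 60.0 if gaps.size else np.nan

    before = (t0, first)
    during = (first, last + pulse_train.duration_d)
    after = (last + pulse_train.duration_d, t1)

    periods_before = tuple(_period_or_none(tr, before) for tr in group.traces)
    periods_during = tuple(_period_or_none(tr, during) for tr in group.traces)
    ent = tuple(
        None
        if pd is None or not np.isfinite(stim_period_min)
        else EntrainmentResult(
            stim_period_min, pb, pd, classify_entrainment(stim_period_min, pd, entrainment_tol)
        )
        for pb, pd in zip(periods_before, periods_during)
    )
    return GroupReport(
        spec,
        periods_before,
        periods_during,
        ent,
        _sync_or_none(group, before),
        _sync_or_none(group, during),
        _sync_or_none(group, after),
        group.labels,
    )


def _period_or_none(trace: Trace, t_window) -> float | None:
    try:
        return major_period(trace, t_window)
    except (InsufficientDataError, FlatTraceError):
        return None


def _sync_or_none(group: TraceGroup, t_window) -> float | None:
    try:
        return synchronization_index(group, t_window)
    except (InvalidParameterError, InsufficientDataError, FlatTraceError):
        return None
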