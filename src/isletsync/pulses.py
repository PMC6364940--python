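"""Square-wave stimulus pulse trains.

A pulse train is characterized by three numbers: the rest time R between
pulses (min), the agonist concentration C of each pulse (uM), and the pulse
duration D (s).  R is interpreted as the onset-to-onset period: a train of
20 pulses at R = 2 min spans 38 min of pulsing, which is what an
onset-to-onset reading implies (19 intervals x 2 min).  A ``gap`` reading
(off-time between pulses) is available through ``r_semantics``.

Internally everything is in seconds; minutes appear only at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, InvalidProfileError

#: IP3 production-drive amplitude (uM) a saturating agonist pulse maps to.
DEFAULT_DRIVE_UM = 0.35

#: Default pulse duration (s).
DEFAULT_DURATION_S = 10.0

#: Default pre-pulse observation window (s): pulsing starts at 20 min.
DEFAULT_T_START_S = 1200.0


@dataclass(frozen=True)
class PulseProfile:
    """R/C/D characterization of a square-wave pulse train.

    Parameters
    ----------
    rest_time_r : float
        Rest time R between pulses, in minutes.
    concentration_c : float
        Agonist concentration C of each pulse, in uM.  Not used by the
        model directly (any saturating pulse maps to the same
        intracellular drive); retained for provenance.
    duration_d : float
        Pulse duration D, in seconds.
    """

    rest_time_r: float
    concentration_c: float = 10.0
    duration_d: float = DEFAULT_DURATION_S

    def __post_init__(self) -> None:
        if self.rest_time_r <= 0:
            raise InvalidProfileError(f"rest_time_r must be > 0, got {self.rest_time_r}")
        if self.duration_d <= 0:
            raise InvalidProfileError(f"duration_d must be > 0, got {self.duration_d}")
        if self.concentration_c < 0:
            raise InvalidProfileError(
                f"concentration_c must be >= 0, got {self.concentration_c}"
            )
        if self.duration_d >= self.rest_time_r * 60.0:
            raise InvalidProfileError(
                f"duration_d = {self.duration_d} s does not fit within "
                f"rest_time_r = {self.rest_time_r} min"
            )

    @property
    def period_s(self) -> float:
        """Onset-to-onset period in seconds."""
        return self.rest_time_r * 60.0


@dataclass(frozen=True)
class PulseTrain:
    """Realized square-wave train: sorted onset times plus a common D.

    ``drive_amplitude`` is the intracellular IP3 production drive (uM)
    switched on while a pulse is active.
    """

    onsets: np.ndarray
    duration_d: float = DEFAULT_DURATION_S
    drive_amplitude: float = DEFAULT_DRIVE_UM

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if self.duration_d <= 0:
            raise InvalidParameterError(f"duration_d must be > 0, got {self.duration_d}")
        if self.drive_amplitude < 0:
            raise InvalidParameterError(
                f"drive_amplitude must be >= 0, got {self.drive_amplitude}"
            )
        if onsets.ndim != 1:
            raise InvalidParameterError("onsets must be a 1-D array of times (s)")
        if onsets.size > 1:
            gaps = np.diff(onsets)
            if np.any(gaps <= 0):
                raise InvalidParameterError("onsets must be strictly increasing")
            if np.any(gaps < self.duration_d):
                raise InvalidParameterError(
                    "successive onsets closer than the pulse duration (overlap)"
                )

    def __len__(self) -> int:
        return int(self.onsets.size)

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.duration_d

    def drive_on(self, t: float) -> bool:
        """Whether the drive is on at time ``t`` (on-interval [onset, onset+D))."""
        i = np.searchsorted(self.onsets, t, side="right") - 1
        if i < 0:
            return False
        return bool(t < self.onsets[i] + self.duration_d)

    def switch_times(self, t0: float, t1: float) -> np.ndarray:
        """All pulse on/off boundaries strictly inside (t0, t1), sorted."""
        edges = np.concatenate([self.onsets, self.offsets])
        edges = edges[(edges > t0) & (edges < t1)]
        return np.unique(edges)

    def empty(self) -> bool:
        return self.onsets.size == 0


def empty_train(duration_d: float = DEFAULT_DURATION_S,
                drive_amplitude: float = DEFAULT_DRIVE_UM) -> PulseTrain:
    """A train with no pulses (unperturbed simulations)."""
    return PulseTrain(np.empty(0), duration_d, drive_amplitude)


def periodic_train(
    profile: PulseProfile,
    n_pulses: int,
    t_start: float = DEFAULT_T_START_S,
    drive_amplitude: float = DEFAULT_DRIVE_UM,
    r_semantics: str = "onset",
) -> PulseTrain:
    """Periodic train of ``n_pulses`` pulses from an R/C/D profile.

    With ``r_semantics='onset'`` (default) R is the onset-to-onset period,
    so onsets fall at ``t_start + k*R`` and the pulsing spans
    ``(n_pulses-1)*R``; with ``'gap'`` R is the off-time between pulses and
    the onset-to-onset period is ``R + D``.
    """
    if n_pulses < 1:
        raise InvalidParameterError(f"n_pulses must be >= 1, got {n_pulses}")
    if r_semantics not in ("onset", "gap"):
        raise InvalidParameterError(f"r_semantics must be 'onset' or 'gap', got {r_semantics!r}")
    period = profile.period_s if r_semantics == "onset" else profile.period_s + profile.duration_d
    if profile.duration_d >= period:
        raise InvalidProfileError("pulse duration exceeds the onset-to-onset period")
    onsets = t_start + period * np.arange(n_pulses, dtype=float)
    return PulseTrain(onsets, profile.duration_d, drive_amplitude)


def random_train(
    n_pulses: int,
    gap_min: int,
    gap_max: int,
    seed: int,
    t_start: float = DEFAULT_T_START_S,
    duration_d: float = DEFAULT_DURATION_S,
    drive_amplitude: float = DEFAULT_DRIVE_UM,
) -> PulseTrain:
    """Randomly spaced train: successive onset gaps are integer minutes
    drawn uniformly from ``[gap_min, gap_max]``.

    This reproduces the randomized stimulus protocol in which rest values
    between successive pulses are randomly selected integers from a stated
    range (e.g. 2-18 min).
    """
    if n_pulses < 1:
        raise InvalidParameterError(f"n_pulses must be >= 1, got {n_pulses}")
    if not (0 < gap_min <= gap_max):
        raise InvalidParameterError(
            f"need 0 < gap_min <= gap_max, got [{gap_min}, {gap_max}]"
        )
    if int(gap_min) != gap_min or int(gap_max) != gap_max:
        raise InvalidParameterError("gap_min and gap_max must be integer minutes")
    if gap_min * 60.0 <= duration_d:
        raise InvalidParameterError(
            f"smallest gap {gap_min} min does not clear the pulse duration {duration_d} s"
        )
    rng = np.random.default_rng(seed)
    gaps_min = rng.integers(int(gap_min), int(gap_max) + 1, size=n_pulses - 1)
    onsets = t_start + 60.0 * np.concatenate([[0.0], np.cumsum(gaps_min)])
    return PulseTrain(onsets, duration_d, drive_amplitude)
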