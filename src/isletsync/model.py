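"""Dual-oscillator model of islet Ca2+ oscillations with IP3 pulse dynamics.

The model couples the two conditional oscillators of the beta-cell
integrated-oscillator framework:

* an **electrical oscillator** — membrane potential ``v`` with voltage-gated
  Ca2+ (CaV) and delayed-rectifier K+ currents, a Ca2+-activated K+ current,
  and an ATP-inhibited K(ATP) current; cytosolic Ca2+ ``ca_c`` fed by CaV
  influx and cleared by plasma-membrane pumps;
* a **glycolytic oscillator** — fructose 6-phosphate ``f6p`` and fructose
  1,6-bisphosphate ``fbp`` linked by an allosteric phosphofructokinase
  (activated by AMP and by its product FBP, inhibited by ATP), fed by a
  constant glucokinase flux (clamped 11 mM glucose).

Coupling is bidirectional: ATP produced downstream of pyruvate
dehydrogenase (PDH) inhibits K(ATP) channels, while cytosolic Ca2+
stimulates PDH and thereby glycolytic throughput, and Ca2+ handling
consumes ATP.  An endoplasmic-reticulum compartment ``ca_er`` exchanges
Ca2+ with the cytosol through SERCA pumps, a passive leak, and an
IP3-gated release channel.  Muscarinic stimulation enters as a square
pulse of IP3 production:

    d[IP3]/dt = (IP3_amp(t) - [IP3]) / tau_ip3

with the drive amplitude IP3_amp = 0.35 uM while a pulse is on and 0
otherwise, tau_ip3 = 10 s.

Units: mV, pS, fA, fF, uM, s.  The model is run in a non-spiking plateau
regime: the depolarized phase is a stable quasi-steady plateau rather
than a train of fast spikes, so trajectories carry exactly the slow
envelope that 20-s-sampled fluorescence traces resolve.  Default
parameters give sustained relaxation oscillations of ``ca_c`` with a
period near 5 min.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict, fields as dc_fields

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    InvalidParameterError,
    IntegrationError,
    NumericError,
    RegimeError,
)
from .pulses import PulseTrain, empty_train

STATE_FIELDS = ("v", "n", "ca_c", "ca_er", "f6p", "fbp", "atp", "ip3")


@dataclass(frozen=True)
class ModelState:
    """The 8 dynamical variables of the extended model.

    v: membrane potential (mV); n: delayed-rectifier activation (0-1);
    ca_c / ca_er: free cytosolic / ER Ca2+ (uM); f6p, fbp: glycolytic
    intermediates (uM); atp: cytosolic ATP (uM); ip3: IP3 (uM).
    """

    v: float
    n: float
    ca_c: float
    ca_er: float
    f6p: float
    fbp: float
    atp: float
    ip3: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(x) for x in np.asarray(y, dtype=float)))

    def validate(self) -> None:
        for name in STATE_FIELDS:
            x = getattr(self, name)
            if not np.isfinite(x):
                raise NumericError(f"state field {name!r} is non-finite: {x}")
        if not 0.0 <= self.n <= 1.0:
            raise InvalidParameterError(f"n must lie in [0, 1], got {self.n}")
        for name in ("ca_c", "ca_er", "f6p", "fbp", "atp", "ip3"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.  Defaults give a ~5 min cytosolic Ca2+ period.

    The two conductances ``g_cav`` and ``g_katp`` are the heterogeneity
    knobs: islet-to-islet differences in them shift the natural period.
    """

    # -- electrical oscillator -------------------------------------------
    cm: float = 530.0          # membrane capacitance (fF)
    g_cav: float = 1000       # CaV conductance (pS)
    v_ca: float = 25.0          # Ca2+ reversal potential (mV)
    g_k: float = 2700         # delayed-rectifier conductance (pS)
    v_k: float = -75.0          # K+ reversal potential (mV)
    g_kca: float = 312.599        # Ca2+-activated K+ conductance (pS)
    kd_kca: float = 0.506943         # KCa half-activation [Ca2+] (uM)
    g_katp: float = 5396.36      # maximal K(ATP) conductance (pS)
    vm_m: float = -20.0         # CaV activation midpoint (mV)
    s_m: float = 8.0            # CaV activation slope (mV)
    vm_n: float = -16.0         # delayed-rectifier midpoint (mV)
    s_n: float = 5.0            # delayed-rectifier slope (mV)
    tau_n: float = 0.002        # delayed-rectifier time constant (s)

    # -- cytosolic / ER Ca2+ handling ------------------------------------
    f_ca: float = 0.03          # free fraction of cytosolic Ca2+
    alpha_ca: float = 4.5e-3    # current-to-flux conversion (uM / (fA s))
    k_pmca: float = 60        # plasma-membrane pump rate (1/s)
    k_serca: float = 1        # SERCA pump rate (1/s)
    p_leak: float = 0.001        # ER leak permeability (1/s)
    v_ip3r: float = 0.05        # maximal IP3R permeability (1/s)
    k_ip3: float = 0.146417         # IP3R half-activation [IP3] (uM)
    eps_er: float = 0.005       # f_er * (V_cyt / V_er): ER free fraction x volume ratio

    # -- glycolysis / PDH / nucleotides ----------------------------------
    j_gk: float = 0.448         # glucokinase flux at 11 mM glucose (uM/s)
    v_pfk: float = 12.8          # maximal PFK rate (uM/s)
    k1_amp: float = 5.0e4        # PFK: AMP association (uM)
    k2_fbp: float = 50.0         # PFK: FBP association (uM)
    k3_f6p: float = 100.0     # PFK: F6P^2 association (uM^2)
    k4_atp: float = 1.0e6      # PFK: ATP^2 association (uM^2)
    f13: float = 0.02           # PFK coupling AMP-F6P
    f23: float = 0.2            # PFK coupling FBP-F6P
    f41: float = 20.0           # PFK coupling AMP-ATP
    f42: float = 20.0           # PFK coupling FBP-ATP
    f43: float = 20.0           # PFK coupling F6P-ATP
    lambda_pfk: float = 0.06    # relative rate of non-activated PFK states
    kappa_gpi: float = 1.0      # F6P fraction of the G6P/F6P pool
    v_pdh: float = 1.12412         # maximal PDH flux (uM/s per sqrt(uM) FBP)
    k_pdh: float = 0.152284         # PDH Ca2+ half-activation (uM)
    alpha_pdh: float = 0.17759     # Ca2+-independent PDH activity fraction
    zeta_atp: float = 179.483     # ATP produced per FBP-derived PDH flux unit
    k_hyd: float = 0.0495767      # basal ATP consumption (1/s)
    k_hyd_act: float = 0.0741344   # extra ATP consumption during electrical activity (1/s)
    v_hyd: float = -55.0        # half-activation potential of activity-dependent ATP use (mV)
    s_hyd: float = 4.0          # slope of activity-dependent ATP use (mV)
    a_tot: float = 3000.0       # conserved adenine-nucleotide pool (uM)

    # -- IP3 pulse dynamics ----------------------------------------------
    ip3_amp: float = 0.35       # IP3 production-drive amplitude (uM)
    tau_ip3: float = 10.0       # IP3 time constant (s)

    # -- numerics ---------------------------------------------------------
    rtol: float = 1e-8          # solver relative tolerance
    transient_s: float = 1200.0 # default transient to discard (s)

    def __post_init__(self) -> None:
        for name in ("cm", "tau_n", "tau_ip3", "a_tot", "f_ca", "eps_er"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("g_cav", "g_k", "g_kca", "g_katp", "ip3_amp", "j_gk",
                     "v_pfk", "v_pdh", "k_serca", "p_leak", "v_ip3r"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)}")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dc_fields(cls)}
        bad = set(d) - known
        if bad:
            raise InvalidParameterError(f"unknown parameter(s): {sorted(bad)}")
        return cls(**d)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled solution: ``times`` (s) and a (len, 8) state array."""

    times: np.ndarray
    states: np.ndarray
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if y.shape != (t.size, len(STATE_FIELDS)):
            raise InvalidParameterError(
                f"states shape {y.shape} does not match times of length {t.size}"
            )
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# kinetic pieces
# --------------------------------------------------------------------------

def ip3_rate(ip3: float, drive_on: bool, params: ModelParams) -> float:
    """IP3 balance: ``(A - ip3)/tau_ip3`` with A = ip3_amp while the drive
    is on and 0 otherwise."""
    if ip3 < 0:
        raise InvalidParameterError(f"ip3 must be >= 0, got {ip3}")
    if params.tau_ip3 <= 0:
        raise InvalidParameterError(f"tau_ip3 must be > 0, got {params.tau_ip3}")
    amp = params.ip3_amp if drive_on else 0.0
    return (amp - ip3) / params.tau_ip3


def katp_open_fraction(atp: float, adp: float) -> float:
    """K(ATP) open probability as a function of ATP and ADP (uM).

    Nucleotide regulation follows the standard beta-cell formulation:
    MgADP (0.165 of ADP) activates with dissociation constant 17 uM,
    free ADP3- (0.135 of ADP) and ATP4- (0.05 of ATP) inhibit with
    constants 26 uM and 1 uM.
    """
    mgadp = 0.165 * adp / 17.0
    adp3 = 0.135 * adp / 26.0
    atp4 = 0.05 * atp / 1.0
    num = 0.08 * (1.0 + 2.0 * mgadp) + 0.89 * mgadp * mgadp
    den = (1.0 + mgadp) ** 2 * (1.0 + adp3 + atp4)
    return num / den


def pfk_rate(f6p: float, fbp: float, atp: float, amp: float, p: ModelParams) -> float:
    """Allosteric phosphofructokinase rate (uM/s).

    Weighted four-site binding scheme: the enzyme binds AMP (activator),
    FBP (product activator), F6P (substrate, as F6P^2) and ATP (inhibitor,
    as ATP^2); the fully activated F6P-bound state turns over at v_pfk and
    every other F6P-bound state at lambda_pfk * v_pfk.
    """
    wa = amp / p.k1_amp
    wf = fbp / p.k2_fbp
    ws = f6p * f6p / p.k3_f6p
    wt = atp * atp / p.k4_atp

    total = 0.0
    bound = 0.0        # sum of F6P-bound weights
    top = 0.0          # the AMP- and FBP-activated, ATP-free, F6P-bound state
    for i in (0, 1):
        for j in (0, 1):
            for k in (0, 1):
                for l in (0, 1):
                    w = (wa ** i) * (wf ** j) * (ws ** k) * (wt ** l)
                    if i and k:
                        w /= p.f13
                    if j and k:
                        w /= p.f23
                    if i and l:
                        w *= 1.0 / p.f41
                    if j and l:
                        w *= 1.0 / p.f42
                    if k and l:
                        w *= 1.0 / p.f43
                    total += w
                    if k:
                        bound += w
                        if i and j and not l:
                            top += w
    return p.v_pfk * (top + p.lambda_pfk * (bound - top)) / total


def pdh_rate(fbp: float, ca_c: float, p: ModelParams) -> float:
    """Ca2+-activated PDH flux (uM/s): sqrt-saturating in FBP with a basal
    plus Ca2+-stimulated activity."""
    s_ca = p.alpha_pdh + (1.0 - p.alpha_pdh) * ca_c / (ca_c + p.k_pdh)
    return p.v_pdh * np.sqrt(max(fbp, 0.0)) * s_ca


def _rhs(t: float, y: np.ndarray, p: ModelParams, drive_amp: float) -> np.ndarray:
    v, n, ca_c, ca_er, f6p, fbp, atp, ip3 = y

    # electrical currents (fA)
    m_inf = 1.0 / (1.0 + np.exp((p.vm_m - v) / p.s_m))
    n_inf = 1.0 / (1.0 + np.exp((p.vm_n - v) / p.s_n))
    i_ca = p.g_cav * m_inf * (v - p.v_ca)
    i_k = p.g_k * n * (v - p.v_k)
    w_kca = ca_c * ca_c / (ca_c * ca_c + p.kd_kca * p.kd_kca)
    i_kca = p.g_kca * w_kca * (v - p.v_k)
    adp = max(p.a_tot - atp, 0.0)
    i_katp = p.g_katp * katp_open_fraction(atp, adp) * (v - p.v_k)

    dv = -(i_ca + i_k + i_kca + i_katp) / p.cm
    dn = (n_inf - n) / p.tau_n

    # Ca2+ fluxes (uM/s, cytosolic volume)
    j_mem = -(p.alpha_ca * i_ca + p.k_pmca * ca_c)
    m_ip3 = ip3 * ip3 / (ip3 * ip3 + p.k_ip3 * p.k_ip3)
    j_er_out = (p.p_leak + p.v_ip3r * m_ip3) * (ca_er - ca_c)
    j_er = j_er_out - p.k_serca * ca_c
    dca_c = p.f_ca * (j_mem + j_er)
    dca_er = -p.eps_er * j_er

    # metabolism
    amp = adp * adp / atp if atp > 0 else 0.0  # adenylate-kinase equilibrium
    j_pfk = pfk_rate(f6p, fbp, atp, amp, p)
    j_pdh = pdh_rate(fbp, ca_c, p)
    df6p = p.kappa_gpi * (p.j_gk - j_pfk)
    dfbp = j_pfk - 0.5 * j_pdh
    # activity-dependent ATP consumption (ion pumping during the
    # depolarized phase); gated by voltage so the silent phase is cheap
    hyd_act = p.k_hyd_act / (1.0 + np.exp((p.v_hyd - v) / p.s_hyd))
    datp = p.zeta_atp * j_pdh - (p.k_hyd + hyd_act) * atp

    dip3 = (drive_amp - ip3) / p.tau_ip3

    return np.array([dv, dn, dca_c, dca_er, df6p, dfbp, datp, dip3])


def derivatives(
    state: ModelState,
    t: float,
    pulse_train: PulseTrain | None,
    params: ModelParams,
) -> ModelState:
    """Time derivatives of every state variable at time ``t``.

    The pulse train decides whether the IP3 drive is on at ``t``; pass
    ``None`` (or an empty train) for the unperturbed model.
    """
    state.validate()
    drive_on = pulse_train.drive_on(t) if pulse_train is not None else False
    amp = pulse_train.drive_amplitude if drive_on else 0.0
    dy = _rhs(t, state.to_array(), params, amp)
    if not np.all(np.isfinite(dy)):
        bad = STATE_FIELDS[int(np.argmin(np.isfinite(dy)))]
        raise NumericError(f"non-finite derivative for field {bad!r} at t = {t}")
    return ModelState.from_array(dy)


# A point on the default-parameter limit cycle (transient discarded),
# used as the default initial condition.  Taken near a cytosolic Ca2+
# nadir so that phase 0 (active-phase onset) follows shortly after t = 0.
DEFAULT_INITIAL_STATE = ModelState(
    v=-65.1859, n=5.34246e-05, ca_c=0.0257959, ca_er=148.509,
    f6p=11.0222, fbp=4.82703, atp=2304.23, ip3=0.0,
)


def simulate(
    params: ModelParams | None = None,
    pulse_train: PulseTrain | None = None,
    t_end: float = 7200.0,
    dt_out: float = 1.0,
    initial: ModelState | str = "default",
    t_start: float = 0.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model and return a trajectory sampled every ``dt_out``.

    Pulse on/off switching is resolved exactly: the integration is split
    at every pulse boundary, so no solver step straddles an onset or
    offset.  Default tolerances resolve Ca2+ nadir times to well under a
    second.
    """
    p = params if params is not None else ModelParams()
    train = pulse_train if pulse_train is not None else empty_train()
    if t_end <= t_start:
        raise InvalidParameterError(f"t_end must exceed t_start, got {t_end} <= {t_start}")
    if dt_out <= 0:
        raise InvalidParameterError(f"dt_out must be > 0, got {dt_out}")

    if isinstance(initial, str):
        if initial != "default":
            raise InvalidParameterError(f"unknown initial-state spec {initial!r}")
        y0 = DEFAULT_INITIAL_STATE.to_array()
    else:
        initial.validate()
        y0 = initial.to_array()

    t_grid = t_start + dt_out * np.arange(int(np.floor((t_end - t_start) / dt_out)) + 1)
    edges = np.concatenate([[t_start], train.switch_times(t_start, t_end), [t_end]])

    # per-variable absolute tolerances on the natural scale of each field,
    # rescaled if the user loosens/tightens rtol
    atol = np.array([1e-6, 1e-9, 1e-9, 1e-5, 1e-5, 1e-7, 1e-4, 1e-9]) * (p.rtol / 1e-8)

    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        drive_amp = train.drive_amplitude if train.drive_on(0.5 * (a + b)) else 0.0
        mask = (t_grid >= a) & (t_grid < b) if b < t_end else (t_grid >= a) & (t_grid <= b)
        t_eval = t_grid[mask]
        # append the segment endpoint so the state can be carried across
        # the pulse boundary exactly
        t_req = t_eval if t_eval.size and t_eval[-1] == b else np.append(t_eval, b)
        sol = solve_ivp(
            _rhs, (a, b), y, method=method, t_eval=t_req,
            rtol=p.rtol, atol=atol, args=(p, drive_amp), dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed near t = {sol.t[-1] if sol.t.size else a} s: {sol.message}"
            )
        y = sol.y[:, -1]
        keep = t_eval.size
        out_t.append(sol.t[:keep])
        out_y.append(sol.y[:, :keep].T)

    times = np.concatenate(out_t)
    states = np.vstack(out_y)
    return Trajectory(times, states, p)


def natural_period(
    params: ModelParams | None = None,
    t_end: float = 7200.0,
    transient: float | None = None,
    dt_out: float = 1.0,
) -> float:
    """Natural cytosolic Ca2+ period (s) from nadir spacing of an
    unperturbed run; raises ``RegimeError`` if no oscillation is found."""
    from .prc import detect_nadirs
    from .analysis import Trace
    from .errors import FlatTraceError

    p = params if params is not None else ModelParams()
    tr = simulate(p, None, t_end=t_end, dt_out=dt_out)
    cut = p.transient_s if transient is None else transient
    mask = tr.times >= cut
    try:
        nadirs = detect_nadirs(Trace(tr.times[mask], tr["ca_c"][mask]))
    except FlatTraceError as exc:
        raise RegimeError(f"model is not oscillatory at these parameters: {exc}") from exc
    if len(nadirs) < 3:
        raise RegimeError("fewer than 3 Ca2+ nadirs in the test run; not oscillatory")
    return float(np.mean(np.diff(nadirs)))


def on_cycle_state(
    params: ModelParams | None = None,
    phase: float = 0.0,
    dt_out: float = 1.0,
) -> ModelState:
    """State on the unperturbed limit cycle at a given oscillation phase.

    Phase 0 is a cytosolic Ca2+ nadir; the state is read from an
    unperturbed run after the standard transient.  Used to start
    population members at controlled, distinct phases."""
    from .analysis import Trace
    from .prc import detect_nadirs

    p = params if params is not None else ModelParams()
    if not 0.0 <= phase < 1.0:
        raise InvalidParameterError(f"phase must lie in [0, 1), got {phase}")
    traj = simulate(p, None, t_end=p.transient_s + 2400.0, dt_out=dt_out)
    mask = traj.times >= p.transient_s
    nad = detect_nadirs(Trace(traj.times[mask], traj["ca_c"][mask]))
    if len(nad) < 2:
        raise RegimeError("fewer than 2 nadirs after the transient; not oscillatory")
    t_target = nad[-2] + phase * (nad[-1] - nad[-2])
    i = int(np.argmin(np.abs(traj.times - t_target)))
    return ModelState.from_array(traj.states[i])


def make_heterogeneous_population(
    n: int,
    seed: int,
    g_cav_range: tuple[float, float] = (880.0, 1020.0),
    g_katp_range: tuple[float, float] = (5500.0, 5935.0),
    base: ModelParams | None = None,
    validate: bool = True,
) -> list[ModelParams]:
    """Draw ``n`` parameter sets with heterogeneous CaV and K(ATP)
    conductances, each verified (when ``validate``) to oscillate within a
    60-min test run."""
    if n < 0:
        raise InvalidParameterError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    base_p = base if base is not None else ModelParams()
    out: list[ModelParams] = []
    for _ in range(n):
        g_cav = rng.uniform(*g_cav_range)
        g_katp = rng.uniform(*g_katp_range)
        p = base_p.with_(g_cav=float(g_cav), g_katp=float(g_katp))
        if validate:
            try:
                natural_period(p, t_end=3600.0, dt_out=2.0)
            except RegimeError as exc:
                raise RegimeError(
                    f"sampled parameter set (g_cav={g_cav:.1f}, g_katp={g_katp:.1f}) "
                    f"does not oscillate: {exc}"
                ) from exc
        out.append(p)
    return out
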