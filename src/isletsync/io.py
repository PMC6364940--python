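"""File I/O and end-to-end experiment driver.

Conventions: time is seconds everywhere inside the package; minutes appear
only in reports.  Trace files are plain CSV with a ``time_s`` column and
one column per islet; parameter files are YAML (one document per model
islet); pulse trains are CSV with ``onset_s, duration_s, amplitude``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import SpectrogramConfig, Trace, TraceGroup, analyze_group
from .errors import FormatError, InvalidParameterError
from .model import ModelParams, simulate
from .pulses import PulseTrain, PulseProfile, empty_train, periodic_train, random_train
from .synth import SynthSpec, synth_group

_UNIFORM_RTOL = 1e-6


def read_trace_csv(path) -> TraceGroup:
    """Read a trace-group CSV (``time_s`` plus one column per islet).

    Validates monotone, uniform sampling and reports the first offending
    row on failure.  Times are assumed to be seconds.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one trace column")
    tcol = df.columns[0]
    if tcol not in ("time_s", "time", "t"):
        raise FormatError(f"{path}: first column must be the time column, got {tcol!r}")
    t = df[tcol].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise FormatError(
            f"{path}: non-monotone or duplicated timestamp at row {bad[0] + 3}"
        )
    if np.max(np.abs(dt - dt[0])) > _UNIFORM_RTOL * abs(dt[0]):
        k = int(np.argmax(np.abs(dt - dt[0])))
        raise FormatError(f"{path}: non-uniform sampling at row {k + 3}")
    traces = tuple(Trace(t, df[c].to_numpy(dtype=float)) for c in df.columns[1:])
    return TraceGroup(traces, tuple(str(c) for c in df.columns[1:]))


def write_trace_csv(path, group: TraceGroup) -> None:
    df = pd.DataFrame({"time_s": group.times})
    for label, tr in zip(group.labels, group.traces):
        df[label] = tr.values
    df.to_csv(path, index=False, float_format="%.17g")


def write_params_yaml(path, params_list) -> None:
    """One YAML document per model islet."""
    docs = [p.to_dict() for p in params_list]
    with open(path, "w") as fh:
        yaml.safe_dump_all(docs, fh, sort_keys=False)


def read_params_yaml(path) -> list[ModelParams]:
    with open(path) as fh:
        docs = list(yaml.safe_load_all(fh))
    return [ModelParams.from_dict(d) for d in docs if d]


def write_pulses_csv(path, train: PulseTrain) -> None:
    df = pd.DataFrame(
        {
            "onset_s": train.onsets,
            "duration_s": np.full(len(train), train.duration_d),
            "amplitude": np.full(len(train), train.drive_amplitude),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_pulses_csv(path) -> PulseTrain:
    df = pd.read_csv(path)
    for col in ("onset_s", "duration_s", "amplitude"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        return empty_train()
    return PulseTrain(
        df["onset_s"].to_numpy(dtype=float),
        float(df["duration_s"].iloc[0]),
        float(df["amplitude"].iloc[0]),
    )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_train(proto: dict, seed: int) -> PulseTrain:
    if not proto:
        return empty_train()
    kind = proto.get("kind", "periodic")
    t_start = float(proto.get("t_start_s", 1200.0))
    duration = float(proto.get("duration_s", 10.0))
    amplitude = float(proto.get("amplitude_um", 0.35))
    if kind == "none":
        return empty_train()
    if kind == "periodic":
        profile = PulseProfile(
            rest_time_r=float(proto.get("rest_min", 5.0)),
            concentration_c=float(proto.get("concentration_um", 10.0)),
            duration_d=duration,
        )
        return periodic_train(profile, int(proto.get("n_pulses", 12)), t_start, amplitude)
    if kind == "random":
        return random_train(
            int(proto.get("n_pulses", 8)),
            int(proto.get("gap_min", 2)),
            int(proto.get("gap_max", 18)),
            int(proto.get("seed", seed)),
            t_start,
            duration,
            amplitude,
        )
    raise InvalidParameterError(f"unknown protocol kind {kind!r}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for :func:`run_experiment`.

    ``mode`` is ``"simulate"`` (heterogeneous model islets driven by a
    pulse protocol) or ``"synth"`` (synthetic trace group).  Blocks are
    plain dictionaries so configs round-trip through YAML unchanged.
    """

    mode: str = "simulate"
    model: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0
    duration_min: float = 90.0
    n_islets: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise InvalidParameterError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "model": self.model,
            "protocol": self.protocol,
            "analysis": self.analysis,
            "synth": self.synth,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "duration_min": self.duration_min,
            "n_islets": self.n_islets,
        }


def run_experiment(config: RunConfig) -> dict:
    """Run a full simulate-or-synth -> analyze pipeline and write artifacts.

    Writes the trace-group CSV, pulse CSV, spectrogram CSV and a report
    JSON (with a provenance block: config hash, seed, package version)
    into ``config.out_dir``; returns the report dictionary.
    """
    from . import __version__
    from .model import make_heterogeneous_population

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    chash = _config_hash(cfg_dict)
    t_end = config.duration_min * 60.0
    sample_dt = float(config.analysis.get("sampling_interval_s", 20.0)) if config.analysis else 20.0

    train = _build_train(config.protocol, config.seed)

    if config.mode == "simulate":
        from .model import on_cycle_state

        base = ModelParams.from_dict(config.model) if config.model else ModelParams()
        pops = make_heterogeneous_population(
            config.n_islets, config.seed, base=base, validate=False
        )
        traces = []
        for k, p in enumerate(pops):
            # free-running islets start at staggered oscillation phases
            init = on_cycle_state(p, (0.15 + k / max(len(pops), 1)) % 1.0)
            traj = simulate(p, train, t_end=t_end, dt_out=sample_dt, initial=init)
            traces.append(Trace(traj.times, traj["ca_c"]))
        group = TraceGroup(tuple(traces))
        write_params_yaml(out / f"params_{chash}.yaml", pops)
    elif config.mode == "synth":
        spec_kwargs = dict(config.synth)
        spec_kwargs.setdefault("seed", config.seed)
        spec_kwargs.setdefault("duration", config.duration_min)
        spec = SynthSpec(**spec_kwargs)
        group = synth_group(spec)
    else:
        raise InvalidParameterError(f"unknown mode {config.mode!r}")

    write_trace_csv(out / f"traces_{chash}.csv", group)
    write_pulses_csv(out / f"pulses_{chash}.csv", train)

    cfg_analysis = config.analysis or {}
    spec_cfg = SpectrogramConfig(
        window_len=int(cfg_analysis.get("window", 256)),
        hop=int(cfg_analysis.get("hop", 5)),
        n_freq_bins=int(cfg_analysis.get("bins", 1000)),
    )
    n_insert = int(cfg_analysis.get("n_insert", 2))
    try:
        report = analyze_group(group, train if not train.empty() else None,
                               spec_cfg, n_insert=n_insert)
    except Exception as exc:  # stage failure: propagate with stage name
        raise type(exc)(f"analysis stage failed: {exc}") from exc

    report.spectrogram.to_dataframe().to_csv(out / f"spectrogram_{chash}.csv",
                                             float_format="%.8g")
    payload = {
        "provenance": {
            "config_hash": chash,
            "seed": config.seed,
            "version": __version__,
            "config": cfg_dict,
        },
        "report": report.to_dict(),
    }
    with open(out / f"report_{chash}.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return payload
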