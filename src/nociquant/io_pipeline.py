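"""Core containers, file readers/writers, run configuration and the stage runner.

All times are seconds, double precision, with t = 0 at recording start.
Re-referencing to an event (e.g. a light onset) is always explicit in the
operation that needs it.  All window conventions are half-open ``[lo, hi)``
so that shared boundaries are never counted twice.

File formats are plain CSV (comma separator, dot decimal, UTF-8, mandatory
header):

* spikes:   ``unit_id,time_s`` — one row per spike;
* protocol: ``kind,onset_s,duration_s,param`` with ``kind`` one of
  ``shock`` (param empty), ``light`` (param ``FREQ:PULSE_MS``) or ``drug``
  (param is the drug label).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("nociquant")

__all__ = [
    "SpikeTrain",
    "LightEpoch",
    "DrugEpoch",
    "StimulusProtocol",
    "RunConfig",
    "read_spikes",
    "write_spikes",
    "read_protocol",
    "write_protocol",
    "load_config",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit, in seconds from recording start."""

    unit_id: str
    times_s: np.ndarray
    t_start_s: float = 0.0
    t_stop_s: float = np.inf

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", times)
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"unit {self.unit_id!r}: spike times must be strictly increasing")
            if times[0] < self.t_start_s or times[-1] > self.t_stop_s:
                raise ValueError(
                    f"unit {self.unit_id!r}: spikes outside [{self.t_start_s}, {self.t_stop_s}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class LightEpoch:
    onset_s: float
    duration_s: float
    freq_hz: float
    pulse_ms: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("light epoch duration must be non-negative")


@dataclass(frozen=True)
class DrugEpoch:
    label: str
    onset_s: float


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical shock train plus light and drug epochs on a shared clock."""

    shock_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    light_epochs: tuple[LightEpoch, ...] = ()
    drug_epochs: tuple[DrugEpoch, ...] = ()

    def __post_init__(self) -> None:
        shocks = np.asarray(self.shock_times_s, dtype=float)
        if shocks.size and np.any(np.diff(shocks) < 0):
            raise ValueError("shock times must be sorted")
        object.__setattr__(self, "shock_times_s", shocks)
        object.__setattr__(self, "light_epochs", tuple(self.light_epochs))
        object.__setattr__(self, "drug_epochs", tuple(self.drug_epochs))


# ---------------------------------------------------------------------------
# Spike tables
# ---------------------------------------------------------------------------

def read_spikes(path: str | Path) -> list[SpikeTrain]:
    """Read a ``unit_id,time_s`` CSV into one :class:`SpikeTrain` per unit.

    Times are sorted per unit; exact duplicate timestamps within a unit are
    collapsed with a logged warning.  A malformed row raises a ``ValueError``
    naming its line number (1-based, counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"unit_id": str})
    required = {"unit_id", "time_s"}
    if set(df.columns) < required:
        raise ValueError(f"{path}: header must contain {sorted(required)}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = times.isna() | df["unit_id"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}: malformed row at line {line}")
    trains: list[SpikeTrain] = []
    for unit_id, grp in df.assign(time_s=times).groupby("unit_id", sort=True):
        t = np.sort(grp["time_s"].to_numpy(dtype=float))
        uniq = np.unique(t)
        if uniq.size < t.size:
            logger.warning(
                "unit %s: collapsed %d duplicate spike timestamps", unit_id, t.size - uniq.size
            )
        trains.append(SpikeTrain(unit_id=str(unit_id), times_s=uniq))
    return trains


def write_spikes(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    rows = [
        {"unit_id": tr.unit_id, "time_s": t} for tr in trains for t in tr.times_s
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stimulus protocol tables
# ---------------------------------------------------------------------------

_PROTOCOL_KINDS = {"shock", "light", "drug"}


def read_protocol(path: str | Path) -> StimulusProtocol:
    """Read an event table ``kind,onset_s,duration_s,param``.

    Unknown kinds and negative durations are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"kind": str, "param": str}, keep_default_na=False)
    if set(df.columns) < {"kind", "onset_s", "duration_s", "param"}:
        raise ValueError(f"{path}: header must be kind,onset_s,duration_s,param")
    shocks: list[float] = []
    lights: list[LightEpoch] = []
    drugs: list[DrugEpoch] = []
    for i, row in df.iterrows():
        kind = row["kind"]
        if kind not in _PROTOCOL_KINDS:
            raise ValueError(f"{path}: unknown event kind {kind!r} at line {i + 2}")
        onset = float(row["onset_s"])
        duration = float(row["duration_s"]) if str(row["duration_s"]) != "" else 0.0
        if duration < 0:
            raise ValueError(f"{path}: negative duration at line {i + 2}")
        if kind == "shock":
            shocks.append(onset)
        elif kind == "light":
            freq, pulse = (float(v) for v in str(row["param"]).split(":"))
            lights.append(LightEpoch(onset, duration, freq, pulse))
        else:
            drugs.append(DrugEpoch(str(row["param"]), onset))
    return StimulusProtocol(
        shock_times_s=np.sort(np.asarray(shocks, dtype=float)),
        light_epochs=tuple(lights),
        drug_epochs=tuple(drugs),
    )


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    rows = []
    for t in protocol.shock_times_s:
        rows.append({"kind": "shock", "onset_s": t, "duration_s": 0.0, "param": ""})
    for ep in protocol.light_epochs:
        rows.append(
            {
                "kind": "light",
                "onset_s": ep.onset_s,
                "duration_s": ep.duration_s,
                "param": f"{ep.freq_hz:g}:{ep.pulse_ms:g}",
            }
        )
    for ep in protocol.drug_epochs:
        rows.append({"kind": "drug", "onset_s": ep.onset_s, "duration_s": 0.0, "param": ep.label})
    pd.DataFrame(rows, columns=["kind", "onset_s", "duration_s", "param"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration and the stage runner
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters for a pipeline run.

    Defaults equal the analysis constants the method prescribes: 1-ms raster
    bins over a 0–800 ms latency range, a 21-trial moving average, the
    140–180 s and 570–600 s reduction windows, a 10 s / sd 5 s rate kernel,
    −100–0 s baseline and 0–300 s response windows, and 300-s photometry
    comparison windows.
    """

    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "windup")
    out_dir: str = "nociquant_out"
    spikes_path: str | None = None
    protocol_path: str | None = None
    trace_path: str | None = None
    # wind-up stage
    bin_ms: float = 1.0
    max_latency_ms: float = 800.0
    movmean_trials: int = 21
    reduction_windows_s: tuple[tuple[float, float], ...] = ((140.0, 180.0), (570.0, 600.0))
    # unit stage
    rate_bin_s: float = 1.0
    rate_kernel_width_s: float = 10.0
    rate_kernel_sd_s: float = 5.0
    baseline_window_s: tuple[float, float] = (-100.0, 0.0)
    response_window_s: tuple[float, float] = (0.0, 300.0)
    criterion_sd: float = 3.0
    min_duration_s: float = 5.0
    # photometry stage
    stim_onset_s: float = 300.0
    stim_duration_s: float = 30.0
    pre_window_s: tuple[float, float] = (-300.0, 0.0)
    post_window_s: tuple[float, float] = (0.0, 300.0)
    detrend_mode: str = "ratio"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("stages",):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("reduction_windows_s",):
            if key in data:
                data[key] = tuple(tuple(w) for w in data[key])
        for key in ("baseline_window_s", "response_window_s", "pre_window_s", "post_window_s"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — a YAML subset) run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default, allow_nan=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order.

    Each stage writes structured-text results under ``config.out_dir`` and the
    bundle of per-stage summaries is returned.  Inputs are validated before
    any computation; results are a pure function of (inputs, config, seed).
    """
    from . import fiber_windup, grab_sensor, synthgen, unit_response

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # validate stage inputs up front
    valid_stages = {"simulate", "windup", "units", "grab"}
    for stage in config.stages:
        if stage not in valid_stages:
            raise ValueError(f"unknown stage {stage!r}")
    have_spikes = config.spikes_path is not None or "simulate" in config.stages
    if ("windup" in config.stages or "units" in config.stages) and not have_spikes:
        raise ValueError("windup/units stages need spikes_path or a preceding simulate stage")
    if "grab" in config.stages and config.trace_path is None and "simulate" not in config.stages:
        raise ValueError("grab stage needs trace_path or a preceding simulate stage")

    bundle: dict = {"config": dataclasses.asdict(config)}
    spikes: list[SpikeTrain] | None = None
    protocol: StimulusProtocol | None = None
    trace = None

    if config.spikes_path:
        spikes = read_spikes(config.spikes_path)
    if config.protocol_path:
        protocol = read_protocol(config.protocol_path)
    if config.trace_path:
        trace = grab_sensor.read_trace(
            config.trace_path, stim_onset_s=config.stim_onset_s, stim_duration_s=config.stim_duration_s
        )

    for stage in config.stages:
        logger.info("stage %s", stage)
        if stage == "simulate":
            cfg = synthgen.WDRSimConfig(seed=config.seed)
            train, proto, truth = synthgen.simulate_wdr_recording(cfg)
            spikes, protocol = [train], proto
            write_spikes(spikes, out / "simulated_spikes.csv")
            write_protocol(proto, out / "simulated_protocol.csv")
            truth.per_trial.to_csv(out / "simulated_ground_truth.csv", index=False)
            gcfg = synthgen.GrabSimConfig(seed=config.seed)
            trace, gtruth = synthgen.simulate_grab_trace(gcfg)
            grab_sensor.write_trace(trace, out / "simulated_trace.csv")
            bundle["simulate"] = {
                "n_spikes": spikes[0].n_spikes,
                "n_shocks": int(proto.shock_times_s.size),
                "grab_truth": gtruth.params,
            }
            _write_json(bundle["simulate"], out / "simulate_summary.json")
        elif stage == "windup":
            if not protocol or protocol.shock_times_s.size == 0:
                raise ValueError("windup stage needs a protocol with shocks")
            t0 = protocol.light_epochs[0].onset_s if protocol.light_epochs else 0.0
            results = {}
            for tr in spikes:
                res = fiber_windup.windup_analysis(
                    tr,
                    protocol.shock_times_s,
                    t0_s=t0,
                    bin_ms=config.bin_ms,
                    max_latency_ms=config.max_latency_ms,
                    movmean_trials=config.movmean_trials,
                    reduction_windows_s=config.reduction_windows_s,
                )
                results[tr.unit_id] = res.as_dict()
                res.normalized.to_frame().to_csv(out / f"windup_{tr.unit_id}_trace.csv", index=False)
            bundle["windup"] = results
            _write_json(results, out / "windup_summary.json")
        elif stage == "units":
            t0 = protocol.light_epochs[0].onset_s if protocol and protocol.light_epochs else 0.0
            table, quantiles = unit_response.population_analysis(
                spikes,
                light_onset_s=t0,
                bin_s=config.rate_bin_s,
                kernel_width_s=config.rate_kernel_width_s,
                kernel_sd=config.rate_kernel_sd_s,
                baseline=config.baseline_window_s,
                response=config.response_window_s,
                criterion_sd=config.criterion_sd,
                min_duration_s=config.min_duration_s,
            )
            table.to_csv(out / "unit_responses.csv", index=False)
            bundle["units"] = quantiles
            _write_json(quantiles, out / "unit_quantiles.json")
        elif stage == "grab":
            fit = grab_sensor.fit_bleach(trace)
            verdict = grab_sensor.qc_recording(fit, trace)
            summary = {"fit": fit.as_dict(), "qc": verdict}
            if verdict == "keep":
                corrected = grab_sensor.detrend(trace, fit, mode=config.detrend_mode)
                metrics = grab_sensor.delta_metrics(
                    corrected, pre=config.pre_window_s, post=config.post_window_s
                )
                grab_sensor.write_trace(corrected, out / "corrected_trace.csv")
                summary["delta_max"] = metrics.delta_max
                summary["delta_auc"] = metrics.delta_auc
            bundle["grab"] = summary
            _write_json(summary, out / "grab_summary.json")

    _write_json(
        {"seed": config.seed, "stages": list(config.stages)}, out / "run_log.json"
    )
    return bundle
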