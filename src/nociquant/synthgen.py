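"""Synthetic recordings with known ground truth for every analysis stage.

Each generator emulates the statistical structure the corresponding analysis
assumes, at the effect sizes of the experimental protocol it mimics:

* :func:`simulate_wdr_recording` — a wide-dynamic-range unit under 1 Hz
  hind-paw shocks: per-trial Poisson spike counts per fiber-class latency
  window (uniform latency within the window), a linear wind-up ramp of the
  C and post-discharge intensities to a plateau, and a slow multiplicative
  suppression of those nociceptive windows after a light onset;
* :func:`simulate_unit_population` — a population of piecewise-homogeneous
  Poisson units: a minority excited from ~1 Hz to ~18 Hz after a per-unit
  onset latency, a couple of high-rate units inhibited, the rest stationary;
* :func:`simulate_grab_trace` — a sensor fluorescence trace with
  mono-exponential photobleaching, a stimulation-locked
  difference-of-exponentials transient, an optional square stimulation
  artifact and additive Gaussian noise;
* :func:`simulate_patch_cell` — epoch-labelled Poisson spiking plus
  first-spike-latency values with configurable jitter.

Reproducibility: every simulated object draws from its own
``numpy.random.default_rng([seed, object_index])`` stream, so outputs are
bit-identical under a fixed seed and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fiber_windup import FiberWindows
from .grab_sensor import FluoTrace
from .io_pipeline import LightEpoch, SpikeTrain, StimulusProtocol
from .patch_metrics import EpochedSpikes, FSLMeasurement

__all__ = [
    "WDRSimConfig",
    "UnitPopSimConfig",
    "GrabSimConfig",
    "WDRGroundTruth",
    "GrabGroundTruth",
    "PatchFixture",
    "simulate_wdr_recording",
    "simulate_unit_population",
    "simulate_grab_trace",
    "simulate_patch_cell",
]

_DEFAULT_CLASS_RATES = {"abeta": 2.0, "adelta": 2.0, "c": 8.0, "post_discharge": 4.0}


def _default_windows() -> dict[str, tuple[float, float]]:
    return {name: win for name, win in FiberWindows().items()}


# ---------------------------------------------------------------------------
# Wide-dynamic-range wind-up recording
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WDRSimConfig:
    """Shock-locked WDR simulation.

    Defaults follow the wind-up protocol this generator emulates: 1 Hz
    shocks, wind-up plateau reached after 30 trials, light onset at trial 40,
    a 0.61 multiplicative suppression of the C/post-discharge intensity with
    ~40 s rise so the activity minimum falls in the 140–180 s window, and a
    slow (1500 s) decay so partial suppression persists around 570–600 s.
    The 350 trials split into two stimulation series: 290 shocks, then a
    300-s pause (no trials) during which wind-up dissipates, then 60 more
    shocks over which the wind-up ramp restarts — the suppression envelope
    runs on the absolute clock and persists through the pause.
    """

    seed: int = 0
    n_trials: int = 350
    shock_period_s: float = 1.0
    class_rates: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_RATES))
    class_latency_windows: dict = field(default_factory=_default_windows)
    windup_ramp_trials: int = 30
    windup_start_fraction: float = 0.2
    light_onset_trial: int = 40
    light_duration_s: float = 20.0
    suppression_fraction: float = 0.61
    suppression_rise_s: float = 40.0
    suppression_decay_s: float = 1500.0
    gap_after_trial: int | None = 290  # first series length; None = continuous
    gap_duration_s: float = 300.0
    ramp_restarts_after_gap: bool = True

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.class_rates.values()):
            raise ValueError("class rates must be non-negative")
        wins = sorted(self.class_latency_windows.values())
        for lo, hi in wins:
            if not lo < hi:
                raise ValueError("latency windows need lo < hi")
        for (_, hi), (lo, _) in zip(wins, wins[1:]):
            if lo < hi:
                raise ValueError("latency windows must be pairwise disjoint")
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise ValueError("suppression_fraction must be in [0, 1]")
        if not 0.0 <= self.windup_start_fraction <= 1.0:
            raise ValueError("windup_start_fraction must be in [0, 1]")
        if self.n_trials < self.windup_ramp_trials:
            raise ValueError("n_trials must be >= windup_ramp_trials")


@dataclass(frozen=True)
class WDRGroundTruth:
    """Per-trial expected spike intensities and the envelope parameters."""

    per_trial: pd.DataFrame  # trial, time_s, ramp, suppression, lambda_<class>...
    params: dict

    def expected_c_window_count(self, window_ms: tuple[float, float] = (90.0, 800.0)) -> np.ndarray:
        """Expected per-trial count over fiber-class windows inside ``window_ms``."""
        lo, hi = window_ms
        total = np.zeros(len(self.per_trial))
        for name, (wlo, whi) in self.params["class_latency_windows"].items():
            overlap = max(0.0, min(hi, whi) - max(lo, wlo)) / (whi - wlo)
            total += overlap * self.per_trial[f"lambda_{name}"].to_numpy()
        return total


def _suppression_envelope(delta_s: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak rise-and-decay envelope, zero before the light onset."""
    env = np.where(
        delta_s >= 0,
        (1.0 - np.exp(-np.maximum(delta_s, 0.0) / rise_s)) * np.exp(-np.maximum(delta_s, 0.0) / decay_s),
        0.0,
    )
    t_peak = rise_s * np.log1p(decay_s / rise_s)
    peak = (1.0 - np.exp(-t_peak / rise_s)) * np.exp(-t_peak / decay_s)
    return env / peak


def simulate_wdr_recording(
    cfg: WDRSimConfig,
) -> tuple[SpikeTrain, StimulusProtocol, WDRGroundTruth]:
    """Draw one shock-locked WDR recording.

    Per trial and fiber class the spike count is Poisson with mean
    ``rate x ramp x (1 − suppression)`` (ramp and suppression applying to the
    C and post-discharge windows only) and latencies uniform within the
    class window.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    trials = np.arange(cfg.n_trials)
    shock_times = trials * cfg.shock_period_s
    ramp_index = trials.astype(float)
    if cfg.gap_after_trial is not None and cfg.gap_after_trial < cfg.n_trials:
        in_second_series = trials >= cfg.gap_after_trial
        shock_times = shock_times + np.where(in_second_series, cfg.gap_duration_s, 0.0)
        if cfg.ramp_restarts_after_gap:
            ramp_index = np.where(in_second_series, trials - cfg.gap_after_trial, trials).astype(float)
    light_onset = cfg.light_onset_trial * cfg.shock_period_s

    ramp_span = max(cfg.windup_ramp_trials, 1)
    ramp = cfg.windup_start_fraction + (1.0 - cfg.windup_start_fraction) * np.minimum(
        ramp_index, ramp_span
    ) / ramp_span
    envelope = _suppression_envelope(
        shock_times - light_onset, cfg.suppression_rise_s, cfg.suppression_decay_s
    )
    suppression = cfg.suppression_fraction * envelope
    nociceptive = {"c", "post_discharge"}

    truth_cols: dict = {"trial": trials, "time_s": shock_times, "ramp": ramp, "suppression": suppression}
    all_times: list[np.ndarray] = []
    for name, rate in cfg.class_rates.items():
        lo, hi = cfg.class_latency_windows[name]
        lam = np.full(cfg.n_trials, float(rate))
        if name in nociceptive:
            lam = lam * ramp * (1.0 - suppression)
        truth_cols[f"lambda_{name}"] = lam
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total:
            latencies = rng.uniform(lo, hi, size=total) / 1000.0
            all_times.append(np.repeat(shock_times, counts) + latencies)
    times = np.sort(np.concatenate(all_times)) if all_times else np.empty(0)
    times = np.unique(times)

    train = SpikeTrain(unit_id="wdr0", times_s=times, t_start_s=0.0, t_stop_s=shock_times[-1] + 1.0)
    protocol = StimulusProtocol(
        shock_times_s=shock_times,
        light_epochs=(LightEpoch(light_onset, cfg.light_duration_s, 30.0, 10.0),),
    )
    truth = WDRGroundTruth(
        per_trial=pd.DataFrame(truth_cols),
        params={
            "class_latency_windows": dict(cfg.class_latency_windows),
            "class_rates": dict(cfg.class_rates),
            "suppression_fraction": cfg.suppression_fraction,
            "light_onset_s": light_onset,
        },
    )
    return train, protocol, truth


# ---------------------------------------------------------------------------
# Optogenetically driven unit population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitPopSimConfig:
    """Population of units around a 20-s light epoch.

    Defaults mirror the recorded effect sizes this generator emulates: about
    a quarter of units excited from ~1.05 Hz to ~17.65 Hz, rare high-rate
    units inhibited (25.83 → 6.95 Hz), the rest stationary at a mid-range
    spontaneous rate.  Onset latencies are lognormal with median 4 s (upper
    quartile some tens of seconds); offsets are lognormal with median 250 s.
    """

    seed: int = 0
    n_units: int = 82
    class_mix: tuple[float, float, float] = (21 / 82, 2 / 82, 59 / 82)  # excited, inhibited, none
    baseline_rate_hz: dict = field(
        default_factory=lambda: {"excited": 1.05, "inhibited": 25.83, "none": 5.0}
    )
    peak_rate_hz: float = 17.65
    inhibited_low_rate_hz: float = 6.95
    onset_latency_dist: tuple[str, float, float] = ("lognormal", 4.0, 1.2)  # median_s, sigma
    offset_latency_dist: tuple[str, float, float] = ("lognormal", 250.0, 0.35)
    light_onset_s: float = 100.0
    light_duration_s: float = 20.0
    record_pre_s: float = 100.0
    record_post_s: float = 320.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if any(r < 0 for r in self.baseline_rate_hz.values()) or self.peak_rate_hz < 0:
            raise ValueError("rates must be >= 0")


def _draw_latency(rng: np.random.Generator, dist: tuple[str, float, float]) -> float:
    kind, median_s, sigma = dist
    if kind != "lognormal":
        raise ValueError(f"unsupported latency distribution {kind!r}")
    return float(rng.lognormal(mean=np.log(median_s), sigma=sigma))


def _piecewise_poisson(
    rng: np.random.Generator, segments: list[tuple[float, float, float]]
) -> np.ndarray:
    times = []
    for t0, t1, rate in segments:
        if t1 <= t0 or rate <= 0:
            continue
        n = rng.poisson(rate * (t1 - t0))
        if n:
            times.append(rng.uniform(t0, t1, size=n))
    if not times:
        return np.empty(0)
    return np.unique(np.concatenate(times))


def simulate_unit_population(cfg: UnitPopSimConfig) -> tuple[list[SpikeTrain], list[str]]:
    """Draw the unit population; returns (spike trains, ground-truth labels).

    Class counts are the largest-remainder rounding of ``class_mix``;
    excited units step from baseline to the peak rate between their onset and
    offset latencies after the light onset, inhibited units mirror the step
    downward, and "none" units stay stationary.
    """
    raw = np.array(cfg.class_mix) * cfg.n_units
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: cfg.n_units - counts.sum()]:
        counts[i] += 1
    labels = (
        ["excited"] * counts[0] + ["inhibited"] * counts[1] + ["none"] * counts[2]
    )
    t_stop = cfg.light_onset_s + cfg.record_post_s
    t_start = cfg.light_onset_s - cfg.record_pre_s
    trains = []
    for u, label in enumerate(labels):
        rng = np.random.default_rng([cfg.seed, u])
        base = cfg.baseline_rate_hz[label]
        if label == "none":
            segments = [(t_start, t_stop, base)]
        else:
            onset = cfg.light_onset_s + _draw_latency(rng, cfg.onset_latency_dist)
            offset = cfg.light_onset_s + _draw_latency(rng, cfg.offset_latency_dist)
            offset = max(offset, onset + 5.0)
            during = cfg.peak_rate_hz if label == "excited" else cfg.inhibited_low_rate_hz
            segments = [
                (t_start, min(onset, t_stop), base),
                (min(onset, t_stop), min(offset, t_stop), during),
                (min(offset, t_stop), t_stop, base),
            ]
        times = _piecewise_poisson(rng, segments)
        trains.append(
            SpikeTrain(unit_id=f"unit{u:03d}", times_s=times, t_start_s=t_start, t_stop_s=t_stop)
        )
    return trains, labels


# ---------------------------------------------------------------------------
# Sensor fluorescence trace
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrabSimConfig:
    """Sensor photometry simulation.

    Defaults emulate the imaging protocol this generator mimics: 2 Hz
    sampling, a 5-min baseline before a 30-s stimulation, mono-exponential
    bleaching, and a stimulation-locked transient normalized so
    ``transient_amp`` is its peak height above the bleach baseline.
    """

    seed: int = 0
    duration_s: float = 630.0
    sample_hz: float = 2.0
    f0: float = 10.0
    bleach_tau_s: float = 600.0
    bleach_offset: float = 2.0
    transient_amp: float = 8.0
    transient_rise_s: float = 5.0
    transient_decay_s: float = 60.0
    stim_onset_s: float = 300.0
    stim_duration_s: float = 30.0
    noise_sd: float = 0.3
    artifact_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_hz <= 0:
            raise ValueError("sample_hz must be positive")
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GrabGroundTruth:
    params: dict
    bleach: np.ndarray  # bleach baseline on the sample grid
    ideal_f: np.ndarray  # noiseless trace (bleach + transient + artifact)

    def corrected(self, mode: str = "ratio") -> np.ndarray:
        """Noiseless bleach-corrected trace, the analytic downstream target."""
        if mode == "ratio":
            return (self.ideal_f - self.bleach) / self.bleach
        return self.ideal_f - self.bleach


def _unit_peak_kernel(delta_s: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    d = np.maximum(delta_s, 0.0)
    k = np.where(delta_s >= 0, np.exp(-d / decay_s) - np.exp(-d / rise_s), 0.0)
    if decay_s == rise_s:
        raise ValueError("transient rise and decay must differ")
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def simulate_grab_trace(cfg: GrabSimConfig) -> tuple[FluoTrace, GrabGroundTruth]:
    """F(t) = f0 e^{−t/tau} + offset + transient + artifact + Gaussian noise."""
    rng = np.random.default_rng([cfg.seed, 0])
    t = np.arange(0.0, cfg.duration_s, 1.0 / cfg.sample_hz)
    bleach = cfg.f0 * np.exp(-t / cfg.bleach_tau_s) + cfg.bleach_offset
    transient = cfg.transient_amp * _unit_peak_kernel(
        t - cfg.stim_onset_s, cfg.transient_rise_s, cfg.transient_decay_s
    )
    artifact = np.where(
        (t >= cfg.stim_onset_s) & (t < cfg.stim_onset_s + cfg.stim_duration_s),
        cfg.artifact_amp,
        0.0,
    )
    ideal = bleach + transient + artifact
    noise = rng.normal(0.0, cfg.noise_sd, size=t.size) if cfg.noise_sd > 0 else 0.0
    trace = FluoTrace(
        times_s=t,
        f=ideal + noise,
        stim_onset_s=cfg.stim_onset_s,
        stim_duration_s=cfg.stim_duration_s,
    )
    truth = GrabGroundTruth(
        params={
            "f0": cfg.f0,
            "bleach_tau_s": cfg.bleach_tau_s,
            "bleach_offset": cfg.bleach_offset,
            "transient_amp": cfg.transient_amp,
            "transient_rise_s": cfg.transient_rise_s,
            "transient_decay_s": cfg.transient_decay_s,
            "stim_onset_s": cfg.stim_onset_s,
            "noise_sd": cfg.noise_sd,
            "artifact_amp": cfg.artifact_amp,
        },
        bleach=bleach,
        ideal_f=ideal,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Patch-clamp fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchFixture:
    spikes: EpochedSpikes
    fsl_baseline: FSLMeasurement
    fsl_agonist: FSLMeasurement
    truth: dict


def simulate_patch_cell(
    baseline_hz: float = 0.573,
    tgot_hz: float = 1.045,
    wash_hz: float = 0.514,
    fsl_base_ms: float = 129.31,
    fsl_tgot_ms: float = 41.42,
    seed: int = 0,
    epoch_duration_s: float = 300.0,
    fsl_jitter_ms: float = 0.0,
) -> PatchFixture:
    """Epoch-labelled Poisson spiking plus jittered first-spike latencies.

    Default rates and latencies are the effect sizes this fixture emulates
    (quiet baseline roughly doubling under the agonist, FSL shortening from
    ~130 ms to ~40 ms at a 50-pA step).
    """
    for rate in (baseline_hz, tgot_hz, wash_hz):
        if rate < 0:
            raise ValueError("rates must be >= 0")
    rng = np.random.default_rng([seed, 0])
    epochs = (
        ("baseline", 0.0, epoch_duration_s),
        ("agonist", epoch_duration_s, 2 * epoch_duration_s),
        ("wash", 2 * epoch_duration_s, 3 * epoch_duration_s),
    )
    times = _piecewise_poisson(
        rng, [(s, e, r) for (_, s, e), r in zip(epochs, (baseline_hz, tgot_hz, wash_hz))]
    )
    spikes = EpochedSpikes(epochs=epochs, times_s=times)
    jitter = rng.normal(0.0, fsl_jitter_ms, size=2) if fsl_jitter_ms > 0 else np.zeros(2)
    fsl_base = max(fsl_base_ms + jitter[0], 0.0)
    fsl_tgot = max(fsl_tgot_ms + jitter[1], 0.0)
    step_onset = 0.0
    fixture = PatchFixture(
        spikes=spikes,
        fsl_baseline=FSLMeasurement(
            step_onset_s=step_onset, first_spike_s=step_onset + fsl_base / 1000.0, fsl_ms=fsl_base
        ),
        fsl_agonist=FSLMeasurement(
            step_onset_s=step_onset, first_spike_s=step_onset + fsl_tgot / 1000.0, fsl_ms=fsl_tgot
        ),
        truth={
            "rates_hz": {"baseline": baseline_hz, "agonist": tgot_hz, "wash": wash_hz},
            "fsl_ms": {"baseline": fsl_base_ms, "agonist": fsl_tgot_ms},
        },
    )
    return fixture
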