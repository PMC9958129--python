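"""Single-unit light-response normalization, responder classification and latencies.

Midbrain units recorded around a 20-s blue-light epoch are summarized as a
Gaussian-smoothed firing-rate trace (10-s kernel, sd 5 s).  The mean rate over
the −100–0 s baseline (BSmean) defines 0 % activity; the largest absolute
21-s moving mean of (FR − BSmean) within the 0–300 s response window defines
±100 % (positive when the extremum exceeds BSmean, negative otherwise).
Units are classed excited / inhibited / none by a baseline-SD threshold with
a minimum duration — the threshold rule is this package's declared criterion,
exposed in configuration, chosen to reproduce the qualitative excited /
inhibited / unresponsive split of such recordings.  Onset, peak and offset
latencies are reported per unit and as population quartiles (linear
interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_pipeline import SpikeTrain

__all__ = [
    "RateTrace",
    "UnitNormalization",
    "UnitResponse",
    "smooth_rate",
    "normalize_unit",
    "classify_response",
    "response_latencies",
    "population_quantiles",
    "population_analysis",
]


@dataclass(frozen=True)
class RateTrace:
    """Smoothed instantaneous firing rate on a uniform time grid.

    ``raw_rate_hz`` keeps the unsmoothed binned rate: the baseline SD that
    gates responder classification is measured on it, not on the smoothed
    trace."""

    times_s: np.ndarray  # bin centers
    rate_hz: np.ndarray
    bin_s: float
    kernel_width_s: float
    kernel_sd: float
    raw_rate_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "rate_hz", np.asarray(self.rate_hz, dtype=float))
        if self.raw_rate_hz is None:
            object.__setattr__(self, "raw_rate_hz", self.rate_hz)
        else:
            object.__setattr__(self, "raw_rate_hz", np.asarray(self.raw_rate_hz, dtype=float))


def _truncated_gaussian(width_samples: float, sd_samples: float) -> np.ndarray:
    half = max(int(width_samples // 2), 0)
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd_samples) ** 2)
    return k / k.sum()


def smooth_rate(
    spikes: SpikeTrain,
    bin_s: float = 1.0,
    kernel_width_s: float = 10.0,
    kernel_sd: float = 5.0,
    t_start_s: float | None = None,
    t_stop_s: float | None = None,
) -> RateTrace:
    """Binned spike counts divided by the bin width, convolved with a unit-sum
    Gaussian (sd ``kernel_sd`` seconds, truncated at ``kernel_width_s`` total
    width).  Edges are renormalized over the kernel's valid support, so the
    trace integrates to the spike count for interior spikes."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    t0 = spikes.t_start_s if t_start_s is None else t_start_s
    t1 = spikes.t_stop_s if t_stop_s is None else t_stop_s
    if not np.isfinite(t1):
        t1 = float(spikes.times_s[-1]) + bin_s if spikes.n_spikes else t0 + bin_s
    n_bins = max(int(np.ceil((t1 - t0) / bin_s)), 1)
    edges = t0 + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(spikes.times_s, bins=edges)
    rate = counts / bin_s
    kernel = _truncated_gaussian(kernel_width_s / bin_s, kernel_sd / bin_s)
    num = np.convolve(rate, kernel, mode="same")
    den = np.convolve(np.ones_like(rate), kernel, mode="same")
    return RateTrace(
        times_s=(edges[:-1] + edges[1:]) / 2.0,
        rate_hz=num / den,
        bin_s=bin_s,
        kernel_width_s=kernel_width_s,
        kernel_sd=kernel_sd,
        raw_rate_hz=rate,
    )


@dataclass(frozen=True)
class UnitNormalization:
    """BSmean-referenced percent-activity series for one unit."""

    times_s: np.ndarray  # relative to light onset
    percent: np.ndarray  # 100 * (FR - BSmean) / |max-abs moving-mean deviation|
    moving_percent: np.ndarray  # 21-s moving mean of percent
    bs_mean_hz: float
    max_abs_dev_hz: float
    baseline_sd_hz: float  # SD of the unsmoothed binned rate over the baseline
    sign: int  # +1 excited-side extremum, -1 inhibited-side
    bin_s: float
    baseline: tuple[float, float]
    response: tuple[float, float]
    movmean_s: float

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.times_s >= lo) & (self.times_s < hi)


def normalize_unit(
    rate: RateTrace,
    light_onset_s: float,
    baseline: tuple[float, float] = (-100.0, 0.0),
    response: tuple[float, float] = (0.0, 300.0),
    movmean_s: float = 21.0,
) -> UnitNormalization:
    """BSmean (baseline mean rate) maps to 0 %; the highest absolute 21-s
    moving mean of (FR − BSmean) inside the response window maps to ±100 %,
    positive when that extremum exceeds BSmean.

    Both windows are relative to ``light_onset_s`` and must be covered by the
    trace.  A perfectly flat trace has no deviation to scale by and raises
    ``ValueError``.
    """
    t = rate.times_s - light_onset_s
    base_mask = (t >= baseline[0]) & (t < baseline[1])
    resp_mask = (t >= response[0]) & (t < response[1])
    if not base_mask.any() or not resp_mask.any():
        raise ValueError("baseline/response window not covered by the trace")
    bs_mean = float(rate.rate_hz[base_mask].mean())
    dev = rate.rate_hz - bs_mean
    window_bins = max(int(round(movmean_s / rate.bin_s)), 1)
    mov_dev = (
        pd.Series(dev).rolling(window=window_bins, center=True, min_periods=1).mean().to_numpy()
    )
    resp_vals = mov_dev[resp_mask]
    i_ext = int(np.argmax(np.abs(resp_vals)))
    max_abs = float(abs(resp_vals[i_ext]))
    if max_abs == 0.0:
        raise ValueError("degenerate normalization: flat trace")
    sign = 1 if resp_vals[i_ext] > 0 else -1
    percent = 100.0 * dev / max_abs
    moving_percent = 100.0 * mov_dev / max_abs
    baseline_sd = float(np.std(rate.raw_rate_hz[base_mask], ddof=1))
    return UnitNormalization(
        times_s=t,
        percent=percent,
        moving_percent=moving_percent,
        bs_mean_hz=bs_mean,
        max_abs_dev_hz=max_abs,
        baseline_sd_hz=baseline_sd,
        sign=sign,
        bin_s=rate.bin_s,
        baseline=baseline,
        response=response,
        movmean_s=movmean_s,
    )


@dataclass(frozen=True)
class UnitResponse:
    unit_id: str
    klass: str  # "excited" | "inhibited" | "none"
    onset_s: float = np.nan
    peak_s: float = np.nan
    offset_s: float = np.nan

    def __post_init__(self) -> None:
        if self.klass != "none" and not (
            np.isnan(self.onset_s) or self.onset_s <= self.peak_s <= self.offset_s
        ):
            raise ValueError("onset <= peak <= offset violated")


def _qualifying_runs(mask: np.ndarray, min_bins: int) -> list[tuple[int, int]]:
    """[start, end) index runs of True at least min_bins long."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_bins:
                runs.append((start, i))
            start = None
    if start is not None and mask.size - start >= min_bins:
        runs.append((start, mask.size))
    return runs


def _criterion_threshold(norm: UnitNormalization, criterion_sd: float) -> float:
    return criterion_sd * norm.baseline_sd_hz


def classify_response(
    norm: UnitNormalization,
    criterion_sd: float = 3.0,
    min_duration_s: float = 5.0,
) -> str:
    """"excited" when the moving-mean deviation exceeds +criterion_sd x
    baseline SD for at least ``min_duration_s`` inside the response window,
    "inhibited" for the mirrored rule, else "none".  When both rules fire the
    sign of the absolute extremum decides."""
    thr = _criterion_threshold(norm, criterion_sd)
    resp_mask = norm.window_mask(norm.response)
    mov_dev = norm.moving_percent[resp_mask] * norm.max_abs_dev_hz / 100.0
    min_bins = max(int(round(min_duration_s / norm.bin_s)), 1)
    excited = bool(_qualifying_runs(mov_dev > thr, min_bins))
    inhibited = bool(_qualifying_runs(mov_dev < -thr, min_bins))
    if excited and inhibited:
        return "excited" if norm.sign > 0 else "inhibited"
    if excited:
        return "excited"
    if inhibited:
        return "inhibited"
    return "none"


def response_latencies(
    norm: UnitNormalization,
    klass: str,
    criterion_sd: float = 3.0,
    min_duration_s: float = 5.0,
) -> tuple[float, float, float]:
    """(onset, peak, offset) seconds after light onset for a responding unit.

    Onset is the first time the classification criterion is met; peak the
    time of the moving-mean extremum; offset the first return below criterion
    after the peak, censored at the end of the response window.
    """
    if klass == "none":
        raise ValueError("latencies undefined for class 'none'")
    thr = _criterion_threshold(norm, criterion_sd)
    resp_mask = norm.window_mask(norm.response)
    t = norm.times_s[resp_mask]
    mov_dev = norm.moving_percent[resp_mask] * norm.max_abs_dev_hz / 100.0
    signed = mov_dev if klass == "excited" else -mov_dev
    min_bins = max(int(round(min_duration_s / norm.bin_s)), 1)
    runs = _qualifying_runs(signed > thr, min_bins)
    censor = norm.response[1]
    if not runs:
        # criterion never met for min duration: fall back to any crossing
        runs = _qualifying_runs(signed > thr, 1)
    if not runs:
        return float("nan"), float(t[int(np.argmax(signed))]), censor
    onset = float(max(t[runs[0][0]], 0.0))
    i_peak = int(np.argmax(signed))
    peak = float(t[i_peak])
    below = np.flatnonzero(signed[i_peak:] <= thr)
    offset = float(t[i_peak + below[0]]) if below.size else float(censor)
    peak = min(max(peak, onset), offset)
    return onset, peak, offset


def population_quantiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan"), float("nan"), float("nan")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return float(q1), float(q2), float(q3)


def population_analysis(
    units,
    light_onset_s: float,
    bin_s: float = 1.0,
    kernel_width_s: float = 10.0,
    kernel_sd: float = 5.0,
    baseline: tuple[float, float] = (-100.0, 0.0),
    response: tuple[float, float] = (0.0, 300.0),
    criterion_sd: float = 3.0,
    min_duration_s: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Classify every unit and summarize responder latencies.

    Returns a per-unit table and a dict with class counts and (Q1, median,
    Q3) latency quantiles over responding units.
    """
    rows = []
    for tr in units:
        rate = smooth_rate(tr, bin_s=bin_s, kernel_width_s=kernel_width_s, kernel_sd=kernel_sd)
        try:
            norm = normalize_unit(
                rate, light_onset_s, baseline=baseline, response=response
            )
        except ValueError:
            rows.append({"unit_id": tr.unit_id, "class": "none"})
            continue
        klass = classify_response(norm, criterion_sd=criterion_sd, min_duration_s=min_duration_s)
        row = {"unit_id": tr.unit_id, "class": klass, "bs_mean_hz": norm.bs_mean_hz}
        if klass != "none":
            onset, peak, offset = response_latencies(
                norm, klass, criterion_sd=criterion_sd, min_duration_s=min_duration_s
            )
            row.update(onset_s=onset, peak_s=peak, offset_s=offset)
        rows.append(row)
    table = pd.DataFrame(rows)
    summary: dict = {
        "n_units": len(rows),
        "counts": table["class"].value_counts().to_dict() if len(rows) else {},
    }
    responders = table[table["class"] != "none"] if len(rows) else table
    for key in ("onset_s", "peak_s", "offset_s"):
        if key in responders:
            summary[key.replace("_s", "_quantiles_s")] = population_quantiles(responders[key])
    return table, summary
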