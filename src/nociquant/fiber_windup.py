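"""Fiber-class latency gating, shock-locked rasters, and wind-up quantification.

A wide-dynamic-range (WDR) dorsal-horn neuron driven by 1 Hz electrical
shocks of its receptive field fires stimulus-locked spikes whose latency
identifies the afferent fiber class that carried them: A-beta at 0–20 ms,
A-delta at 20–90 ms, C at 90–300 ms and C-fiber post-discharge at
300–800 ms after each shock.  Repetitive C-strength stimulation produces
wind-up: the per-shock C-window spike count ramps to a plateau of maximal
discharge.  This module builds the trial x latency raster, smooths it for
display, counts C-window spikes per trial, normalizes the count trace so the
maximal 21-trial moving-average window reads 100 % activity, and extracts the
percent-reduction and latency statistics used to quantify a suppression of
the nociceptive discharge (e.g. after an optogenetic manipulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_pipeline import SpikeTrain

__all__ = [
    "FiberWindows",
    "Raster",
    "NormalizedActivity",
    "WUResult",
    "classify_spike_latency",
    "classify_spike_latencies",
    "build_raster",
    "smooth_raster",
    "count_c_window",
    "normalize_windup",
    "percent_reduction",
    "wu_latency_metrics",
    "windup_analysis",
]


@dataclass(frozen=True)
class FiberWindows:
    """Half-open latency windows (ms after shock) per afferent fiber class."""

    abeta: tuple[float, float] = (0.0, 20.0)
    adelta: tuple[float, float] = (20.0, 90.0)
    c: tuple[float, float] = (90.0, 300.0)
    post_discharge: tuple[float, float] = (300.0, 800.0)
    c_count_window: tuple[float, float] = (90.0, 800.0)

    def __post_init__(self) -> None:
        windows = [self.abeta, self.adelta, self.c, self.post_discharge]
        for lo, hi in windows + [self.c_count_window]:
            if not lo < hi:
                raise ValueError("each window needs lo < hi")
        ordered = sorted(windows)
        for (_, hi), (lo, _) in zip(ordered, ordered[1:]):
            if lo < hi:
                raise ValueError("fiber windows must be disjoint")

    def items(self):
        return (
            ("abeta", self.abeta),
            ("adelta", self.adelta),
            ("c", self.c),
            ("post_discharge", self.post_discharge),
        )


def classify_spike_latency(latency_ms: float, windows: FiberWindows | None = None) -> str:
    """Fiber class whose half-open window contains ``latency_ms``, else ``"none"``."""
    if not math.isfinite(latency_ms):
        raise ValueError("latency must be finite")
    windows = windows or FiberWindows()
    for name, (lo, hi) in windows.items():
        if lo <= latency_ms < hi:
            return name
    return "none"


def classify_spike_latencies(latencies_ms, windows: FiberWindows | None = None) -> np.ndarray:
    """Vectorized :func:`classify_spike_latency`."""
    windows = windows or FiberWindows()
    lat = np.asarray(latencies_ms, dtype=float)
    out = np.full(lat.shape, "none", dtype=object)
    for name, (lo, hi) in windows.items():
        out[(lat >= lo) & (lat < hi)] = name
    return out.astype(str)


@dataclass(frozen=True)
class Raster:
    """Trial x latency-bin spike-count matrix aligned to shock onsets."""

    counts: np.ndarray  # (n_trials, n_bins)
    bin_ms: float
    trial_times_s: np.ndarray
    max_latency_ms: float
    n_unassigned: int = 0  # spikes later than max_latency_ms but before the next shock

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (trials x bins)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "trial_times_s", np.asarray(self.trial_times_s, dtype=float))

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_edges_ms(self) -> np.ndarray:
        return np.arange(self.counts.shape[1] + 1) * self.bin_ms


def build_raster(
    spikes: SpikeTrain,
    shocks_s,
    bin_ms: float = 1.0,
    max_latency_ms: float = 800.0,
) -> Raster:
    """Bin each spike by latency to the latest shock at or before it.

    ``counts[i, j]`` holds spikes with latency to shock ``i`` in bin ``j``;
    each spike is assigned to at most one shock.  Spikes with latency beyond
    ``max_latency_ms`` (but before the next shock) are tallied in
    ``n_unassigned`` rather than silently dropped.
    """
    shocks = np.asarray(shocks_s, dtype=float)
    if shocks.size == 0:
        raise ValueError("shock list is empty")
    if np.any(np.diff(shocks) < 0):
        raise ValueError("shocks must be sorted")
    n_bins_f = max_latency_ms / bin_ms
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9:
        raise ValueError("bin_ms must divide max_latency_ms")
    if shocks.size > 1 and np.min(np.diff(shocks)) * 1000.0 < max_latency_ms:
        import logging

        logging.getLogger("nociquant").warning(
            "shock spacing below max_latency_ms; late spikes may be re-assigned to the next shock"
        )
    counts = np.zeros((shocks.size, n_bins))
    t = spikes.times_s
    trial = np.searchsorted(shocks, t, side="right") - 1
    valid = trial >= 0
    latency_ms = (t[valid] - shocks[trial[valid]]) * 1000.0
    in_range = latency_ms < max_latency_ms
    rows = trial[valid][in_range]
    cols = np.floor(latency_ms[in_range] / bin_ms).astype(int)
    np.add.at(counts, (rows, cols), 1.0)
    n_unassigned = int(np.sum(~valid) + np.sum(~in_range))
    return Raster(
        counts=counts,
        bin_ms=bin_ms,
        trial_times_s=shocks,
        max_latency_ms=max_latency_ms,
        n_unassigned=n_unassigned,
    )


def _truncated_gaussian(window_samples: float, sd: float) -> np.ndarray:
    """Unit-sum Gaussian kernel truncated to ``window_samples`` total width."""
    half = max(int(window_samples // 2), 0)
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def smooth_raster(
    raster: Raster,
    h_window_ms: float = 100.0,
    v_window_ms: float = 20.0,
    sd: float = 20.0,
) -> Raster:
    """Separable 2-D Gaussian smoothing of the raster, for averaged displays.

    The kernel is a unit-sum Gaussian of ``sd`` samples per axis, truncated to
    the stated widths: ``h_window_ms`` samples (at the raster's ms binning)
    along the within-trial latency axis and ``v_window_ms`` samples along the
    accumulating-trial axis.  Edges are handled by renormalizing the kernel
    over its valid support, so a constant matrix is reproduced exactly and an
    interior impulse conserves mass.
    """
    if h_window_ms <= 0 or v_window_ms <= 0 or sd <= 0:
        raise ValueError("kernel widths and sd must be positive")
    k_lat = _truncated_gaussian(h_window_ms / raster.bin_ms, sd)
    k_trial = _truncated_gaussian(v_window_ms, sd)
    num = ndimage.convolve1d(raster.counts, k_lat, axis=1, mode="constant", cval=0.0)
    num = ndimage.convolve1d(num, k_trial, axis=0, mode="constant", cval=0.0)
    den = ndimage.convolve1d(np.ones_like(raster.counts), k_lat, axis=1, mode="constant", cval=0.0)
    den = ndimage.convolve1d(den, k_trial, axis=0, mode="constant", cval=0.0)
    return Raster(
        counts=num / den,
        bin_ms=raster.bin_ms,
        trial_times_s=raster.trial_times_s,
        max_latency_ms=raster.max_latency_ms,
        n_unassigned=raster.n_unassigned,
    )


def count_c_window(raster: Raster, window_ms: tuple[float, float] = (90.0, 800.0)) -> np.ndarray:
    """Per-trial spike counts over latency bins starting within ``window_ms``."""
    lo, hi = window_ms
    if lo < 0 or hi > raster.max_latency_ms:
        raise ValueError("window outside raster support")
    starts = np.arange(raster.counts.shape[1]) * raster.bin_ms
    mask = (starts >= lo) & (starts < hi)
    return raster.counts[:, mask].sum(axis=1)


@dataclass(frozen=True)
class NormalizedActivity:
    """Percent-activity trace: 21-trial moving mean scaled so its max is 100."""

    percent: np.ndarray  # one value per trial, moving-mean trace in % of max
    trial_times_s: np.ndarray
    max_window: tuple[int, int]  # [start, end) trial indices of the maximal window
    scale: float  # the maximal moving-mean count, mapped to 100 %
    raw_counts: np.ndarray
    window_trials: int = 21

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_time_s": self.trial_times_s,
                "count": self.raw_counts,
                "percent": self.percent,
            }
        )


def normalize_windup(
    counts,
    trial_times_s=None,
    window_trials: int = 21,
) -> NormalizedActivity:
    """Centered moving average of per-trial counts, scaled to a 100 % maximum.

    The window holding the maximal moving-mean activity defines 100 %
    activity; ties are broken by the earliest window.  Edge windows are
    truncated (mean over the available trials).  All-zero counts cannot be
    normalized and raise ``ValueError``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < window_trials:
        raise ValueError(f"need at least {window_trials} trials")
    if not np.any(counts):
        raise ValueError("degenerate normalization: all-zero counts")
    if trial_times_s is None:
        trial_times_s = np.arange(counts.size, dtype=float)
    trial_times_s = np.asarray(trial_times_s, dtype=float)
    movmean = (
        pd.Series(counts).rolling(window=window_trials, center=True, min_periods=1).mean().to_numpy()
    )
    i_max = int(np.argmax(movmean))  # argmax returns the earliest tie
    scale = float(movmean[i_max])
    half = window_trials // 2
    max_window = (max(i_max - half, 0), min(i_max + half + 1, counts.size))
    return NormalizedActivity(
        percent=100.0 * movmean / scale,
        trial_times_s=trial_times_s,
        max_window=max_window,
        scale=scale,
        raw_counts=counts,
        window_trials=window_trials,
    )


def percent_reduction(
    norm: NormalizedActivity,
    window_s: tuple[float, float],
    t0_s: float,
) -> float:
    """100 minus the minimum percent activity among trials whose shock time
    falls in ``[t0 + lo, t0 + hi)``.  Trials inside recording gaps are simply
    absent; an empty intersection raises ``ValueError``."""
    lo, hi = window_s
    t = norm.trial_times_s
    mask = (t >= t0_s + lo) & (t < t0_s + hi)
    if not mask.any():
        raise ValueError("no trials fall inside the requested window")
    return 100.0 - float(np.min(norm.percent[mask]))


@dataclass(frozen=True)
class WUResult:
    """Wind-up summary: percent reductions per window and latency metrics."""

    reductions: dict = field(default_factory=dict)  # "lo-hi" (s after t0) -> %
    latency_to_max_s: float = np.nan
    latency_to_min_s: float = np.nan
    latency_to_half_s: float = np.nan

    def as_dict(self) -> dict:
        return {
            "reductions": dict(self.reductions),
            "latency_to_max_s": self.latency_to_max_s,
            "latency_to_min_s": self.latency_to_min_s,
            "latency_to_half_s": self.latency_to_half_s,
        }


def wu_latency_metrics(norm: NormalizedActivity, t0_s: float) -> tuple[float, float, float]:
    """Latencies (s after ``t0_s``) to the moving-mean maximum, the post-plateau
    minimum, and the first crossing of the midpoint between them.

    Ties break to the earliest time.  A monotone trace (maximum on the last
    trial) has no post-plateau minimum; missing values are returned as NaN.
    The minimum search stays within the contiguous stimulation series holding
    the maximum (a pause longer than five median shock intervals starts a new
    series, across which wind-up is re-induced and post-plateau kinetics are
    not comparable).
    """
    p = norm.percent
    t = norm.trial_times_s
    i_max = int(np.argmax(p))
    latency_to_max = float(t[i_max] - t0_s)
    # end of the contiguous series containing the maximum
    i_end = p.size - 1
    if t.size > 1:
        gaps = np.flatnonzero(np.diff(t) > 5.0 * np.median(np.diff(t)))
        later = gaps[gaps >= i_max]
        if later.size:
            i_end = int(later[0])
    if i_max == i_end:
        return latency_to_max, float("nan"), float("nan")
    p = p[: i_end + 1]
    post = p[i_max:]
    i_min = i_max + int(np.argmin(post))
    latency_to_min = float(t[i_min] - t0_s)
    half = (p[i_max] + p[i_min]) / 2.0
    crossing = np.flatnonzero(post <= half)
    latency_to_half = float(t[i_max + crossing[0]] - t0_s) if crossing.size else float("nan")
    return latency_to_max, latency_to_min, latency_to_half


def windup_analysis(
    spikes: SpikeTrain,
    shocks_s,
    t0_s: float,
    bin_ms: float = 1.0,
    max_latency_ms: float = 800.0,
    movmean_trials: int = 21,
    reduction_windows_s: tuple[tuple[float, float], ...] = ((140.0, 180.0), (570.0, 600.0)),
    c_window_ms: tuple[float, float] = (90.0, 800.0),
):
    """Full wind-up quantification for one unit.

    Returns an object with the raster, per-trial C-window counts, the
    normalized trace and a :class:`WUResult`; ``t0_s`` is the light onset the
    reduction windows are referenced to.
    """
    raster = build_raster(spikes, shocks_s, bin_ms=bin_ms, max_latency_ms=max_latency_ms)
    counts = count_c_window(raster, c_window_ms)
    norm = normalize_windup(counts, raster.trial_times_s, window_trials=movmean_trials)
    reductions = {}
    for lo, hi in reduction_windows_s:
        try:
            reductions[f"{lo:g}-{hi:g}"] = percent_reduction(norm, (lo, hi), t0_s)
        except ValueError:
            reductions[f"{lo:g}-{hi:g}"] = float("nan")
    lat_max, lat_min, lat_half = wu_latency_metrics(norm, t0_s)
    result = WUResult(
        reductions=reductions,
        latency_to_max_s=lat_max,
        latency_to_min_s=lat_min,
        latency_to_half_s=lat_half,
    )
    return WindupBundle(raster=raster, c_counts=counts, normalized=norm, result=result)


@dataclass(frozen=True)
class WindupBundle:
    """Everything :func:`windup_analysis` computes for one unit."""

    raster: Raster
    c_counts: np.ndarray
    normalized: NormalizedActivity
    result: WUResult

    def as_dict(self) -> dict:
        return self.result.as_dict()
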