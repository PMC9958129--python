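"""Patch-clamp excitability metrics: epoch AP frequency and first-spike latency.

Whole-cell recordings around a bath agonist application are epoch-labelled
(baseline / agonist / wash); activity per epoch is the plain spike count
divided by the epoch duration.  Intrinsic excitability is probed with a
supra-threshold 50-pA current step: the first-spike latency (FSL) is the
delay from step onset to the first action potential, and a cell is classed
as "decreased" when the agonist shortens its FSL by more than 10 ms (strict
inequality), "increased" for the mirrored change, and "unchanged" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EpochedSpikes",
    "FSLMeasurement",
    "ap_frequency",
    "first_spike_latency",
    "fsl_change_class",
]


@dataclass(frozen=True)
class EpochedSpikes:
    """Spike times with non-overlapping, ordered labelled epochs."""

    epochs: tuple[tuple[str, float, float], ...]  # (label, start_s, end_s)
    times_s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_s", np.asarray(self.times_s, dtype=float))
        object.__setattr__(self, "epochs", tuple(tuple(e) for e in self.epochs))
        prev_end = -np.inf
        for label, start, end in self.epochs:
            if start < prev_end:
                raise ValueError(f"epoch {label!r} overlaps or is out of order")
            if end < start:
                raise ValueError(f"epoch {label!r} has negative duration")
            prev_end = end

    def epoch(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.epochs:
            if lab == label:
                return start, end
        raise KeyError(f"no epoch labelled {label!r}")


def ap_frequency(spikes: EpochedSpikes, label: str) -> float:
    """Spike count in the half-open epoch divided by the epoch duration (Hz)."""
    start, end = spikes.epoch(label)
    if end - start <= 0:
        raise ValueError(f"epoch {label!r} has zero duration")
    n = int(np.sum((spikes.times_s >= start) & (spikes.times_s < end)))
    return n / (end - start)


@dataclass(frozen=True)
class FSLMeasurement:
    step_onset_s: float
    step_pA: float = 50.0
    first_spike_s: float | None = None
    fsl_ms: float | None = None

    def __post_init__(self) -> None:
        if self.fsl_ms is not None and self.fsl_ms < 0:
            raise ValueError("fsl_ms must be >= 0")


def first_spike_latency(
    times_s,
    step_onset_s: float,
    step_end_s: float,
    step_pA: float = 50.0,
) -> FSLMeasurement:
    """Latency (ms) from current-step onset to the first spike at or after it.

    If the cell never fires before the step end the measurement is missing
    (``fsl_ms is None``): such cells are excluded downstream rather than
    classed.
    """
    t = np.asarray(times_s, dtype=float)
    during = t[(t >= step_onset_s) & (t < step_end_s)]
    if during.size == 0:
        return FSLMeasurement(step_onset_s=step_onset_s, step_pA=step_pA)
    first = float(during[0])
    return FSLMeasurement(
        step_onset_s=step_onset_s,
        step_pA=step_pA,
        first_spike_s=first,
        fsl_ms=1000.0 * (first - step_onset_s),
    )


def fsl_change_class(
    fsl_baseline_ms: float,
    fsl_agonist_ms: float,
    threshold_ms: float = 10.0,
) -> str:
    """"decreased" iff baseline − agonist > threshold (strict); "increased"
    for the mirrored change (reported as its own class rather than folded
    into "unchanged"); otherwise "unchanged"."""
    if fsl_baseline_ms is None or fsl_agonist_ms is None:
        raise ValueError("both FSL values must be present")
    change = fsl_baseline_ms - fsl_agonist_ms
    if change > threshold_ms:
        return "decreased"
    if change < -threshold_ms:
        return "increased"
    return "unchanged"
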