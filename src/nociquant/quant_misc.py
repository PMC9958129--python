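"""Small quantifications: colocalization percentages, per-slice fiber-vs-cell
correlation, and the conditioned-place-preference change score."""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CountTable",
    "SliceCounts",
    "CPPOccupancy",
    "coloc_percentage",
    "fiber_cell_correlation",
    "cpp_delta_score",
]


@dataclass(frozen=True)
class CountTable:
    """Rows of (label, numerator, denominator) cell counts."""

    rows: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for label, num, den in self.rows:
            if not 0 <= num <= den:
                raise ValueError(f"{label}: need 0 <= numerator <= denominator")


def _round_half_up(value: float, ndigits: int = 1) -> float:
    return float(
        decimal.Decimal(repr(value)).quantize(
            decimal.Decimal("1." + "0" * ndigits), rounding=decimal.ROUND_HALF_UP
        )
    )


def coloc_percentage(table: CountTable) -> pd.DataFrame:
    """100 * numerator / denominator per row, with a one-decimal display value
    (half-up) alongside full precision."""
    rows = []
    for label, num, den in table.rows:
        if den == 0:
            raise ValueError(f"{label}: zero denominator")
        pct = 100.0 * num / den
        rows.append(
            {
                "label": label,
                "numerator": num,
                "denominator": den,
                "percent": pct,
                "percent_display": _round_half_up(pct, 1),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SliceCounts:
    """Per-slice fiber and cell counts (bregma level kept for bookkeeping)."""

    bregma_mm: np.ndarray
    n_fibers: np.ndarray
    n_cells: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bregma_mm", "n_fibers", "n_cells"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.n_fibers < 0) or np.any(self.n_cells < 0):
            raise ValueError("counts must be >= 0")


def fiber_cell_correlation(slices: SliceCounts) -> dict:
    """Pearson correlation of per-slice cell counts on fiber counts.

    Returns r, r^2, the least-squares slope of cells on fibers, and the
    two-sided p-value from the exact t transform of r.
    """
    x, y = slices.n_fibers, slices.n_cells
    if x.size < 3:
        raise ValueError("need >= 3 slices")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in fibers or cells")
    fit = sps.linregress(x, y)
    return {
        "pearson_r": float(fit.rvalue),
        "r_squared": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "p_two_sided": float(fit.pvalue),
        "n_slices": int(x.size),
    }


@dataclass(frozen=True)
class CPPOccupancy:
    """Chamber occupancy times (s): paired/unpaired at habituation and post-test."""

    paired_hab: float
    unpaired_hab: float
    paired_post: float
    unpaired_post: float

    def __post_init__(self) -> None:
        for name in ("paired_hab", "unpaired_hab", "paired_post", "unpaired_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def cpp_delta_score(occ: CPPOccupancy) -> float:
    """(paired_post − unpaired_post) − (paired_hab − unpaired_hab), seconds.

    Referencing the post-conditioning preference to the habituation
    preference controls for time spent in the neutral chamber and for any
    innate side bias.
    """
    return (occ.paired_post - occ.unpaired_post) - (occ.paired_hab - occ.unpaired_hab)
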