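"""Barcode-gap detection and best-compromise threshold estimation.

Given pools of intraspecific and congeneric-interspecific distances, the
best-compromise threshold t* minimises the summed cumulative error

    total_error(t) = Pr(intra > t) + Pr(inter <= t)

i.e. the proportion of conspecific pairs that a threshold t would fail to
match plus the proportion of heterospecific congeneric pairs it would
wrongly match.  A distance exactly equal to t counts as a match.  The
objective is a step function changing only at observed distances; when its
minimum is attained on an interval the midpoint is reported.  A "true
barcode gap" exists when the largest intraspecific distance falls below
the smallest congeneric-interspecific one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .distances import DistancePartition


@dataclass
class ThresholdCurve:
    """False-negative / false-positive rates over a grid of candidate thresholds."""

    grid: np.ndarray
    fn_rate: np.ndarray   # Pr(intraspecific d > t)
    fp_rate: np.ndarray   # Pr(congeneric-interspecific d <= t)
    intraspecific: np.ndarray
    congeneric_interspecific: np.ndarray
    w_fn: float = 1.0
    w_fp: float = 1.0

    @property
    def total_error(self) -> np.ndarray:
        return self.w_fn * self.fn_rate + self.w_fp * self.fp_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.grid,
                "fn_rate": self.fn_rate,
                "fp_rate": self.fp_rate,
                "total_error": self.total_error,
            }
        )


def _rates(intra: np.ndarray, inter: np.ndarray, grid: np.ndarray):
    fn = np.array([(intra > t).mean() for t in grid])
    fp = np.array([(inter <= t).mean() for t in grid])
    return fn, fp


def threshold_curve(
    part: DistancePartition,
    grid_rule: Literal["observed", "uniform"] = "observed",
    step: float = 0.001,
    w_fn: float = 1.0,
    w_fp: float = 1.0,
) -> ThresholdCurve:
    """Build the cumulative-error curve for a distance partition.

    ``observed`` grids on the sorted union of observed distances plus the
    midpoints between consecutive distinct values (the objective can only
    change at observed values, so this grid is exhaustive); ``uniform``
    uses a fixed-step grid from 0 to the largest observed distance.
    """
    intra = np.asarray(part.intraspecific, dtype=float)
    inter = np.asarray(part.congeneric_interspecific, dtype=float)
    if intra.size == 0 or inter.size == 0:
        raise ValueError(f"group {part.label!r}: both distance pools must be nonempty")
    observed = np.unique(np.concatenate([intra, inter]))
    if grid_rule == "observed":
        mids = (observed[:-1] + observed[1:]) / 2.0
        grid = np.unique(np.concatenate([observed, mids]))
    elif grid_rule == "uniform":
        grid = np.arange(0.0, observed[-1] + step, step)
    else:
        raise ValueError(f"unknown grid rule: {grid_rule!r}")
    fn, fp = _rates(intra, inter, grid)
    return ThresholdCurve(grid, fn, fp, intra, inter, w_fn, w_fp)


@dataclass
class ThresholdEstimate:
    threshold: float           # t*, midpoint of the minimising interval
    interval: tuple[float, float]
    total_error: float
    fn_rate: float
    fp_rate: float


def best_compromise_threshold(curve: ThresholdCurve) -> ThresholdEstimate:
    """Minimise total_error over the curve; interval midpoint on ties.

    The step objective is constant between consecutive observed distances,
    so the minimising region is an interval [a, b): a is the smallest
    observed distance attaining the minimum and b the next observed value
    after the last contiguous minimiser (b = a when the minimum is attained
    only at the largest observed value).  t* = (a + b) / 2.
    """
    observed = np.unique(
        np.concatenate([curve.intraspecific, curve.congeneric_interspecific])
    )
    fn, fp = _rates(curve.intraspecific, curve.congeneric_interspecific, observed)
    err = curve.w_fn * fn + curve.w_fp * fp
    best = err.min()
    minimisers = np.flatnonzero(np.isclose(err, best, rtol=0.0, atol=1e-12))
    # first contiguous run of minimising observed values
    run_end = minimisers[0]
    for k in minimisers[1:]:
        if k == run_end + 1:
            run_end = k
        else:
            break
    a = float(observed[minimisers[0]])
    b = float(observed[run_end + 1]) if run_end + 1 < observed.size else float(observed[run_end])
    t_star = (a + b) / 2.0
    fn_s = float((curve.intraspecific > t_star).mean())
    fp_s = float((curve.congeneric_interspecific <= t_star).mean())
    return ThresholdEstimate(
        threshold=t_star,
        interval=(a, b),
        total_error=curve.w_fn * fn_s + curve.w_fp * fp_s,
        fn_rate=fn_s,
        fp_rate=fp_s,
    )


@dataclass
class GapReport:
    label: str
    max_intra: float
    min_inter: float
    has_true_gap: bool
    gap_interval: tuple[float, float] | None


def detect_gap(part: DistancePartition) -> GapReport:
    """Report the barcode-gap extremes of a partition.

    The gap is "true" iff the intraspecific maximum lies strictly below the
    congeneric-interspecific minimum; extremes are reported either way.
    """
    intra = np.asarray(part.intraspecific, dtype=float)
    inter = np.asarray(part.congeneric_interspecific, dtype=float)
    if intra.size == 0 or inter.size == 0:
        raise ValueError(f"group {part.label!r}: both distance pools must be nonempty")
    max_intra = float(intra.max())
    min_inter = float(inter.min())
    has_gap = max_intra < min_inter
    return GapReport(
        label=part.label,
        max_intra=max_intra,
        min_inter=min_inter,
        has_true_gap=has_gap,
        gap_interval=(max_intra, min_inter) if has_gap else None,
    )


def gap_reports_frame(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "group": r.label,
                "max_intra": r.max_intra,
                "min_inter": r.min_inter,
                "has_true_gap": r.has_true_gap,
                "gap_low": r.gap_interval[0] if r.gap_interval else np.nan,
                "gap_high": r.gap_interval[1] if r.gap_interval else np.nan,
            }
        )
    return pd.DataFrame(rows)
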