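"""Dextran-ladder glucose-unit calibration.

A procainamide-labeled dextran ladder run under the same gradient as the
sample defines the glucose-unit (GU) retention scale: rung *n* elutes at
the retention of an n-glucose oligomer. Retention in minutes follows
rt = a + b * ln(GU) to good approximation over the usable rung range, so a
least-squares fit of that law converts minutes to GU and back, making
retention transferable across gradients and instruments. Ladders run
before and after the sample are averaged rung-wise to absorb drift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


class ExtrapolationWarning(UserWarning):
    """Retention time lies outside the fitted ladder range (plus guard)."""


@dataclass(frozen=True)
class LadderTable:
    """A dextran ladder: (GU rung, retention time in minutes) pairs."""

    run_label: str
    rungs: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.rungs) < 3:
            raise ValueError(
                f"insufficient rungs: need >= 3, got {len(self.rungs)}"
            )
        gu = [g for g, _ in self.rungs]
        rt = [t for _, t in self.rungs]
        if any(g <= 0 for g in gu):
            raise ValueError("gu_index values must be positive integers")
        if any(t <= 0 for t in rt):
            raise ValueError("rt_min values must be positive")
        if any(b <= a for a, b in zip(gu, gu[1:])):
            raise ValueError("gu_index values must be strictly increasing")
        if any(b <= a for a, b in zip(rt, rt[1:])):
            raise ValueError(
                "ladder not monotone: rt_min must strictly increase with gu_index"
            )

    @property
    def gu_indices(self) -> tuple[int, ...]:
        return tuple(g for g, _ in self.rungs)

    @property
    def rt_minutes(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.rungs)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted logarithmic minutes<->GU map: rt = a + b * ln(GU).

    ``intercept_a`` is in minutes; ``slope_b`` in minutes per ln(GU) and is
    positive because larger oligomers retain longer on HILIC. ``fit_rmse``
    is the root-mean-square residual of the fit, in minutes.
    """

    intercept_a: float
    slope_b: float
    fit_rmse: float
    n_rungs: int
    source_runs: tuple[str, ...]
    rt_range: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError("slope_b must be positive (retention increases with GU)")
        if self.n_rungs < 3:
            raise ValueError("a calibration needs >= 3 rungs")

    def summary(self) -> str:
        lo, hi = self.rt_range
        return (
            "GU calibration: rt[min] = "
            f"{self.intercept_a:.4f} + {self.slope_b:.4f} * ln(GU)\n"
            f"  rungs: {self.n_rungs}   rmse: {self.fit_rmse:.4f} min   "
            f"fitted rt range: {lo:.2f}-{hi:.2f} min\n"
            f"  source runs: {', '.join(self.source_runs)}"
        )


def average_bracketing(before: LadderTable, after: LadderTable) -> LadderTable:
    """Rung-wise mean of the bracketing ladder runs.

    Both ladders must cover exactly the same GU rungs; a mismatch reports
    the offending rungs rather than silently intersecting.
    """
    gu_before = set(before.gu_indices)
    gu_after = set(after.gu_indices)
    if gu_before != gu_after:
        diff = sorted(gu_before ^ gu_after)
        raise ValueError(f"ladders cover different rungs; mismatched gu_index: {diff}")
    after_rt = dict(after.rungs)
    rungs = tuple((g, (t + after_rt[g]) / 2.0) for g, t in before.rungs)
    return LadderTable(run_label=f"mean({before.run_label},{after.run_label})", rungs=rungs)


def fit_calibration(ladder: LadderTable) -> CalibrationCurve:
    """Ordinary least-squares fit of rt = a + b * ln(GU) to a ladder."""
    gu = np.array(ladder.gu_indices, dtype=float)
    rt = np.array(ladder.rt_minutes, dtype=float)
    if np.allclose(rt, rt[0]):
        raise ValueError("degenerate ladder: all retention times equal")
    x = np.log(gu)
    slope, intercept = np.polyfit(x, rt, 1)
    resid = rt - (intercept + slope * x)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CalibrationCurve(
        intercept_a=float(intercept),
        slope_b=float(slope),
        fit_rmse=rmse,
        n_rungs=len(ladder.rungs),
        source_runs=(ladder.run_label,),
        rt_range=(float(rt.min()), float(rt.max())),
    )


def min_to_gu(
    rt: float,
    curve: CalibrationCurve,
    guard_fraction: float = 0.2,
    strict: bool = False,
) -> float:
    """Convert a retention time in minutes to glucose units.

    Inverts the fitted law: GU = exp((rt - a) / b). Retention outside the
    fitted rung range widened by ``guard_fraction`` triggers an
    ``ExtrapolationWarning`` (or ``ValueError`` when ``strict``).
    """
    lo, hi = curve.rt_range
    if math.isfinite(hi):
        span = hi - lo
        glo, ghi = lo - guard_fraction * span, hi + guard_fraction * span
        if not (glo <= rt <= ghi):
            msg = (
                f"rt {rt:.2f} min outside calibrated range "
                f"[{glo:.2f}, {ghi:.2f}]; GU value is an extrapolation"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, ExtrapolationWarning, stacklevel=2)
    return math.exp((rt - curve.intercept_a) / curve.slope_b)


def gu_to_min(gu: float, curve: CalibrationCurve) -> float:
    """Convert glucose units to retention in minutes: rt = a + b * ln(GU)."""
    if gu <= 0:
        raise ValueError("GU must be positive")
    return curve.intercept_a + curve.slope_b * math.log(gu)


def maltopentaose_drift(observed_rt_min: float, curve: CalibrationCurve) -> float:
    """GU residual of the maltopentaose internal standard (true GU = 5).

    Reports observed GU minus 5 as a single-point drift check; the value
    never alters the fitted curve.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        return min_to_gu(observed_rt_min, curve) - 5.0
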