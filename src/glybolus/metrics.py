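"""Glycemic outcome metrics and the paired statistical comparison.

Covers the standard CGM consensus metrics — percentage time in range
[70, 180] mg/dL (TIR), time below 70 (TBR), time above 180 (TAR), mean
glucose, coefficient of variation — the Kovatchev low/high blood glucose
risk indices, control-variability grid analysis (CVGA) on per-day glucose
extrema, and a two-sided paired t-test for method comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .patient import CGMTrace, MINUTES_PER_DAY

__all__ = ["GlycemicReport", "range_metrics", "bg_risk_indices", "cvga_zone",
           "cvga_points", "glycemic_report", "paired_comparison",
           "CVGA_ZONES"]

#: CVGA zone labels ordered from best to worst control.
CVGA_ZONES = ("A", "Lower B", "Upper B", "B", "Lower C", "Upper C",
              "Lower D", "Upper D", "E")

#: Severity rank used for ordering checks (ties between symmetric zones).
CVGA_RANK = {"A": 0, "Lower B": 1, "Upper B": 1, "B": 2,
             "Lower C": 3, "Upper C": 3, "Lower D": 4, "Upper D": 4, "E": 5}

# 3x3 grid: rows = max-BG band (<=180, <=300, >300),
#           cols = min-BG band (>=90, [70,90), <70), both after clamping.
_ZONE_GRID = (
    ("A", "Lower B", "Lower C"),
    ("Upper B", "B", "Lower D"),
    ("Upper C", "Upper D", "E"),
)


def range_metrics(trace: CGMTrace | np.ndarray
                  ) -> tuple[float, float, float, float, float]:
    """TIR, TBR, TAR (percent of samples), mean (mg/dL) and CV (percent).

    The target band is the closed interval [70, 180]; CV is the whole-period
    sample StD (ddof=1) over the mean, times 100.
    """
    g = trace.values if isinstance(trace, CGMTrace) else np.asarray(trace,
                                                                    dtype=float)
    if g.size == 0:
        raise ValueError("empty glucose trace")
    tir = 100.0 * np.mean((g >= 70.0) & (g <= 180.0))
    tbr = 100.0 * np.mean(g < 70.0)
    tar = 100.0 * np.mean(g > 180.0)
    mean = float(np.mean(g))
    cv = 100.0 * float(np.std(g, ddof=1)) / mean if g.size > 1 else 0.0
    return float(tir), float(tbr), float(tar), mean, cv


def _risk(g: np.ndarray) -> np.ndarray:
    """Kovatchev symmetrized risk: f(G) = 1.509((ln G)^1.084 - 5.381)."""
    return 1.509 * (np.log(g) ** 1.084 - 5.381)


def bg_risk_indices(trace: CGMTrace | np.ndarray) -> tuple[float, float]:
    """Low and high blood glucose indices.

    Each sample contributes ``10 f(G)^2`` to the low (f < 0) or high (f > 0)
    side; the indices are the means of those one-sided contributions over
    all samples. Both are >= 0 and a trace at the symmetrization zero
    (about 112.5 mg/dL) scores (0, 0).
    """
    g = trace.values if isinstance(trace, CGMTrace) else np.asarray(trace,
                                                                    dtype=float)
    if g.size == 0:
        raise ValueError("empty glucose trace")
    if np.any(g <= 0):
        raise ValueError("glucose must be strictly positive")
    f = _risk(g)
    risk = 10.0 * f ** 2
    lbgi = float(np.mean(np.where(f < 0, risk, 0.0)))
    hbgi = float(np.mean(np.where(f > 0, risk, 0.0)))
    return lbgi, hbgi


def cvga_zone(day_min: float, day_max: float) -> str:
    """CVGA zone of one day's glucose extrema.

    The grid follows the standard convention: the minimum axis spans 110
    down to 50 mg/dL with boundaries at 90 and 70, the maximum axis spans
    110 up to 400 with boundaries at 180 and 300; values beyond the axes are
    clamped. The best corner (min >= 90, max <= 180) is zone A, the worst
    (min < 70, max > 300) is zone E.
    """
    if day_min > day_max:
        raise ValueError("day_min must be <= day_max")
    mn = min(max(day_min, 50.0), 110.0)
    mx = min(max(day_max, 110.0), 400.0)
    col = 0 if mn >= 90.0 else (1 if mn >= 70.0 else 2)
    row = 0 if mx <= 180.0 else (1 if mx <= 300.0 else 2)
    return _ZONE_GRID[row][col]


def cvga_points(trace: CGMTrace,
                day_length: float = MINUTES_PER_DAY) -> list[dict]:
    """Per-day (min, max, zone) points, days cut at midnight boundaries.

    Trailing partial days shorter than half a day are ignored.
    """
    points = []
    n_days = int(np.floor((trace.times[-1] - trace.times[0]) / day_length
                          + 0.5))
    for d in range(max(n_days, 1)):
        lo, hi = d * day_length, (d + 1) * day_length
        mask = (trace.times >= lo) & (trace.times < hi)
        if not np.any(mask):
            continue
        g = trace.values[mask]
        mn, mx = float(np.min(g)), float(np.max(g))
        points.append(dict(day=d, day_min_bg=mn, day_max_bg=mx,
                           zone=cvga_zone(mn, mx)))
    return points


@dataclass
class GlycemicReport:
    """Per-subject glycemic outcome summary."""

    tir: float
    tbr: float
    tar: float
    mean_bg: float
    cv: float
    lbgi: float
    hbgi: float
    cvga_zone_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.tir + self.tbr + self.tar - 100.0) > 1e-9:
            raise ValueError("TIR + TBR + TAR must partition to 100%")
        if self.lbgi < 0 or self.hbgi < 0:
            raise ValueError("risk indices must be nonnegative")

    @property
    def percent_ab(self) -> float:
        """Percent of days falling in CVGA zones A or B (any B subzone)."""
        total = sum(self.cvga_zone_counts.values())
        if total == 0:
            return float("nan")
        ab = sum(v for k, v in self.cvga_zone_counts.items()
                 if k in ("A", "Lower B", "Upper B", "B"))
        return 100.0 * ab / total

    def to_dict(self) -> dict:
        return asdict(self)


def glycemic_report(trace: CGMTrace) -> GlycemicReport:
    """Full outcome report for one CGM trace (pure: same trace, same report)."""
    tir, tbr, tar, mean, cv = range_metrics(trace)
    lbgi, hbgi = bg_risk_indices(trace)
    counts = {z: 0 for z in CVGA_ZONES}
    for p in cvga_points(trace):
        counts[p["zone"]] += 1
    return GlycemicReport(tir=tir, tbr=tbr, tar=tar, mean_bg=mean, cv=cv,
                          lbgi=lbgi, hbgi=hbgi, cvga_zone_counts=counts)


def paired_comparison(metric_a, metric_b) -> float:
    """Two-sided paired t-test p-value between matched per-subject metrics.

    Degenerate case: when every paired difference is identical the t
    statistic is undefined; we return 1.0 if the common difference is zero
    (no evidence of any difference) and 0.0 otherwise (a constant nonzero
    shift), flagging rather than propagating a NaN.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        return 1.0 if np.all(d == 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)
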