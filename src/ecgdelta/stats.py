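"""Paired G/NG boxplot statistics, deltas, directions and correlations.

For each segment series a boxplot-style summary is computed (mode, mean,
median, quartiles, interquartile range); the glucose-minus-control deltas of
those statistics classify each statistic's direction of change as increase
(I), decrease (D) or equality (E).  Inter-segment dependence within the
glucose session is measured with the Pearson product-moment coefficient and
classified as positive (P), negative (N) or zero (Z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .delineate import SegmentSeries

__all__ = [
    "BoxplotSummary",
    "DeltaSummary",
    "CorrelationResult",
    "DELTA_PARAMETERS",
    "MODE_RESOLUTION",
    "direction_of",
    "round_half_up",
    "summarize",
    "delta",
    "correlate",
    "correlation_percentage",
]

#: The six statistics whose deltas are scored downstream.
DELTA_PARAMETERS = ("md", "mn", "mdn", "Q3", "Q1", "Q")

#: Rounding grid used to make the mode well defined on continuous data:
#: intervals to 1 ms, heart rate to 1 bpm, wave heights to 0.01 mV.
MODE_RESOLUTION = {
    "RR-I": 1.0, "QRS": 1.0, "PRQ": 1.0, "QT": 1.0, "QTC": 1.0, "ST": 1.0,
    "HR": 1.0, "R-H": 0.01, "P-H": 0.01,
}

#: Exact-equality band for direction / correlation classification; reachable
#: in practice only by constructed ties (e.g. identical paired sessions).
EQUALITY_TOL = 1e-9


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero upward (the convention used in reports)."""
    scale = 10 ** decimals
    return math.floor(x * scale + 0.5) / scale


def direction_of(value: float, tol: float = EQUALITY_TOL) -> str:
    """Classify a signed delta as 'I', 'D' or 'E'."""
    if value > tol:
        return "I"
    if value < -tol:
        return "D"
    return "E"


@dataclass(frozen=True)
class BoxplotSummary:
    """Distributional summary of one segment series, in native units."""

    segment_id: str
    md: float       # mode (on the rounding grid)
    mn: float       # arithmetic mean
    mdn: float      # median (Q2)
    Q1: float
    Q3: float
    n: int

    @property
    def IQ(self) -> float:
        return self.Q3 - self.Q1

    def __post_init__(self) -> None:
        if not (self.Q1 <= self.mdn <= self.Q3):
            raise ValueError("quartiles out of order")


@dataclass(frozen=True)
class DeltaSummary:
    """Glucose-minus-control deltas of the summary statistics.

    ``d_IQ_g`` / ``d_IQ_ng`` are the two sessions' interquartile ranges and
    ``d_Q = d_IQ_g - d_IQ_ng`` their difference; ``directions`` maps each of
    the six scored parameters to its I/D/E label.
    """

    segment_id: str
    d_md: float
    d_mn: float
    d_mdn: float
    d_Q3: float
    d_Q1: float
    d_IQ_g: float
    d_IQ_ng: float
    d_Q: float
    directions: dict[str, str]

    def delta_of(self, parameter: str) -> float:
        return {"md": self.d_md, "mn": self.d_mn, "mdn": self.d_mdn,
                "Q3": self.d_Q3, "Q1": self.d_Q1, "Q": self.d_Q}[parameter]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson coefficient between two aligned segment series and its class."""

    segment_a: str
    segment_b: str
    coefficient: float      # NaN when either series has zero variance
    classification: str     # 'P', 'N' or 'Z'
    n: int


def _mode(values: np.ndarray, resolution: float) -> float:
    """Most frequent value after rounding to ``resolution``; ties -> smallest."""
    grid = np.round(np.asarray(values, dtype=float) / resolution).astype(np.int64)
    uniq, counts = np.unique(grid, return_counts=True)
    best = uniq[counts == counts.max()].min()
    return float(best * resolution)


def summarize(series: SegmentSeries | np.ndarray, segment_id: str | None = None,
              mode_resolution: float | None = None) -> BoxplotSummary:
    """Boxplot summary of one series.

    Quartiles use linear interpolation between order statistics (Q1 at rank
    1 + (n-1)/4).  The mode is taken on values rounded to the segment's
    resolution, ties broken toward the smallest value.  Requires >= 4 values.
    """
    if isinstance(series, SegmentSeries):
        values = series.values
        segment_id = segment_id or series.segment_id
    else:
        values = np.asarray(series, dtype=float)
        segment_id = segment_id or "RR-I"
    if len(values) < 4:
        raise ValueError(f"summarize needs >= 4 values, got {len(values)}")
    res = mode_resolution if mode_resolution is not None else MODE_RESOLUTION[segment_id]
    q1, mdn, q3 = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return BoxplotSummary(segment_id=segment_id, md=_mode(values, res),
                          mn=float(np.mean(values)), mdn=float(mdn),
                          Q1=float(q1), Q3=float(q3), n=len(values))


def delta(g: BoxplotSummary, ng: BoxplotSummary,
          tol: float = EQUALITY_TOL) -> DeltaSummary:
    """Glucose-minus-control deltas with per-parameter direction labels."""
    if g.segment_id != ng.segment_id:
        raise ValueError(f"segment mismatch: {g.segment_id!r} vs {ng.segment_id!r}")
    d_iq_g = g.IQ
    d_iq_ng = ng.IQ
    deltas = {
        "md": g.md - ng.md,
        "mn": g.mn - ng.mn,
        "mdn": g.mdn - ng.mdn,
        "Q3": g.Q3 - ng.Q3,
        "Q1": g.Q1 - ng.Q1,
        "Q": d_iq_g - d_iq_ng,
    }
    return DeltaSummary(
        segment_id=g.segment_id,
        d_md=deltas["md"], d_mn=deltas["mn"], d_mdn=deltas["mdn"],
        d_Q3=deltas["Q3"], d_Q1=deltas["Q1"],
        d_IQ_g=d_iq_g, d_IQ_ng=d_iq_ng, d_Q=deltas["Q"],
        directions={p: direction_of(deltas[p], tol) for p in DELTA_PARAMETERS},
    )


def _align(a: SegmentSeries, b: SegmentSeries) -> tuple[np.ndarray, np.ndarray]:
    """Pair two series on the intersection of their retained beat indices."""
    common, ia, ib = np.intersect1d(a.beat_index, b.beat_index,
                                    return_indices=True)
    return a.values[ia], b.values[ib]


def correlate(a: SegmentSeries, b: SegmentSeries,
              tol: float = EQUALITY_TOL) -> CorrelationResult:
    """Pearson correlation between two segment series of one session.

    Series are beat-aligned first; a zero-variance input yields class 'Z'
    with an undefined (NaN) coefficient.
    """
    va, vb = _align(a, b)
    n = len(va)
    if n < 3:
        raise ValueError(f"correlation needs >= 3 aligned beats, got {n}")
    sa, sb = float(np.sum(va)), float(np.sum(vb))
    saa, sbb = float(np.sum(va * va)), float(np.sum(vb * vb))
    sab = float(np.sum(va * vb))
    denom_a = n * saa - sa * sa
    denom_b = n * sbb - sb * sb
    if denom_a <= 0 or denom_b <= 0:
        return CorrelationResult(a.segment_id, b.segment_id, math.nan, "Z", n)
    r = (n * sab - sa * sb) / math.sqrt(denom_a * denom_b)
    r = min(1.0, max(-1.0, r))
    cls = "P" if r > tol else ("N" if r < -tol else "Z")
    return CorrelationResult(a.segment_id, b.segment_id, r, cls, n)


def correlation_percentage(results: list[CorrelationResult]) -> tuple[float, float]:
    """Cohort percentages of positively / negatively correlated participants.

    Returns integer-rounded (percent P, percent N).
    """
    if not results:
        raise ValueError("need at least one participant's correlation result")
    n = len(results)
    n_p = sum(1 for r in results if r.classification == "P")
    n_n = sum(1 for r in results if r.classification == "N")
    return (round_half_up(100.0 * n_p / n), round_half_up(100.0 * n_n / n))
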