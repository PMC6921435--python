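"""Cohort-level scoring of per-participant direction patterns.

Each participant contributes, per segment, a direction label (I/D/E) for six
boxplot-delta parameters and one spectral-peak comparison.  Cohort
percentages per direction feed a three-band status:

    h (high)      100 >= d_z% >= 80   strong common pattern
    m (moderate)   80 >  d_z% >= 60   above-average pattern
    l (low)        otherwise          weak pattern

A segment is declared changed by the statistical analysis when at least 4 of
its 6 parameter statuses are m or h (maximum score 6), and by the spectral
analysis when its dominant change-direction percentage reaches 60%.  Per-
pattern sensitivities S_h/S_m/S_l are the shares of each status label among
a pattern's statuses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .simulate import SEGMENTS
from .stats import DELTA_PARAMETERS, round_half_up

__all__ = [
    "DirectionTally",
    "ChangeDecision",
    "tally_directions",
    "classify_status",
    "statistical_change_decision",
    "spectral_change_decision",
    "sensitivity",
    "ScoreTables",
    "build_report",
]

STATUS_ORDER = {"l": 0, "m": 1, "h": 2}
PATTERN_NAME = {"I": "Increase", "D": "Decrease", "E": "Equality"}


@dataclass(frozen=True)
class DirectionTally:
    """Counts and percentages of I/D/E directions for one segment/parameter."""

    segment: str
    parameter: str
    n_increase: int
    n_decrease: int
    n_equal: int

    @property
    def n(self) -> int:
        return self.n_increase + self.n_decrease + self.n_equal

    def count(self, direction: str) -> int:
        return {"I": self.n_increase, "D": self.n_decrease,
                "E": self.n_equal}[direction]

    def percentage(self, direction: str) -> float:
        """Unrounded share of one direction among all observed changes."""
        return 100.0 * self.count(direction) / self.n

    def rounded_percentage(self, direction: str) -> int:
        return int(round_half_up(self.percentage(direction)))

    def dominant_change(self) -> str:
        """The leading change direction; a tie is reported as 'D'.

        Equality does not compete: it signals no change.
        """
        return "D" if self.n_decrease >= self.n_increase else "I"


def tally_directions(directions: Iterable[str], segment: str = "",
                     parameter: str = "") -> DirectionTally:
    """Count per-participant I/D/E labels for one segment/parameter."""
    counts = Counter(directions)
    unknown = set(counts) - {"I", "D", "E"}
    if unknown:
        raise ValueError(f"unknown direction labels: {sorted(unknown)}")
    if not counts:
        raise ValueError("need at least one participant direction")
    return DirectionTally(segment=segment, parameter=parameter,
                          n_increase=counts.get("I", 0),
                          n_decrease=counts.get("D", 0),
                          n_equal=counts.get("E", 0))


def classify_status(percent: float) -> str:
    """Band a direction percentage into 'h', 'm' or 'l'."""
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"percentage out of range: {percent}")
    if percent >= 80.0:
        return "h"
    if percent >= 60.0:
        return "m"
    return "l"


@dataclass(frozen=True)
class ChangeDecision:
    """Whether one segment is declared affected by one analysis."""

    segment: str
    analysis: str           # "statistical" or "spectral"
    n_moderate: int
    n_high: int
    decision: str           # "Yes" / "No"

    @property
    def total(self) -> int:
        return self.n_moderate + self.n_high


def statistical_change_decision(statuses: Sequence[str],
                                segment: str = "") -> ChangeDecision:
    """Occurrence-score decision from the six per-parameter statuses.

    ``statuses`` holds, for each of the six delta parameters, the status of
    that parameter's dominant change direction.  Yes when at least 4 of the
    6 are moderate or high.
    """
    if len(statuses) != len(DELTA_PARAMETERS):
        raise ValueError(
            f"expected {len(DELTA_PARAMETERS)} parameter statuses, got {len(statuses)}")
    bad = set(statuses) - set(STATUS_ORDER)
    if bad:
        raise ValueError(f"unknown status labels: {sorted(bad)}")
    n_m = sum(1 for s in statuses if s == "m")
    n_h = sum(1 for s in statuses if s == "h")
    return ChangeDecision(segment=segment, analysis="statistical",
                          n_moderate=n_m, n_high=n_h,
                          decision="Yes" if n_m + n_h >= 4 else "No")


def spectral_change_decision(tally: DirectionTally) -> ChangeDecision:
    """Spectral decision: Yes when a change direction reaches 60% of the cohort."""
    pct = max(tally.percentage("I"), tally.percentage("D"))
    status = classify_status(pct)
    return ChangeDecision(segment=tally.segment, analysis="spectral",
                          n_moderate=1 if status == "m" else 0,
                          n_high=1 if status == "h" else 0,
                          decision="Yes" if pct >= 60.0 else "No")


def sensitivity(statuses: Sequence[str]) -> dict[str, float]:
    """Shares of each status label, as percentages rounded to one decimal."""
    if not statuses:
        raise ValueError("need at least one status")
    bad = set(statuses) - set(STATUS_ORDER)
    if bad:
        raise ValueError(f"unknown status labels: {sorted(bad)}")
    n = len(statuses)
    counts = Counter(statuses)
    return {f"S_{label}": round_half_up(100.0 * counts.get(label, 0) / n, 1)
            for label in ("l", "m", "h")}


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

@dataclass
class ScoreTables:
    """Machine-readable cohort summary tables.

    ``pattern_matrix``            participant x (segment, parameter) directions
    ``direction_percentages``     per segment/parameter/pattern tallies+status
    ``statistical_occurrence``    per segment m/h counts and Yes/No decision
    ``spectral_summary``          per segment spectral percentages and decision
    ``statistical_sensitivity``   per segment/pattern S_l/S_m/S_h
    ``spectral_sensitivity``      pooled S_l/S_m/S_h over segments' dominant
                                  spectral patterns
    ``correlation_percentages``   optional cohort P%/N% per segment pair
    """

    pattern_matrix: pd.DataFrame
    direction_percentages: pd.DataFrame
    statistical_occurrence: pd.DataFrame
    spectral_summary: pd.DataFrame
    statistical_sensitivity: pd.DataFrame
    spectral_sensitivity: pd.DataFrame
    correlation_percentages: pd.DataFrame | None = None
    n_participants: int = 0
    notes: dict = field(default_factory=dict)

    def decisions(self, analysis: str) -> dict[str, str]:
        table = (self.statistical_occurrence if analysis == "statistical"
                 else self.spectral_summary)
        return dict(zip(table["segment"], table["decision"]))

    def to_json_dict(self) -> dict:
        out = {
            "n_participants": self.n_participants,
            "statistical_decisions": self.decisions("statistical"),
            "spectral_decisions": self.decisions("spectral"),
            "tables": {
                name: getattr(self, name).to_dict(orient="records")
                for name in ("direction_percentages", "statistical_occurrence",
                             "spectral_summary", "statistical_sensitivity",
                             "spectral_sensitivity")
            },
        }
        if self.correlation_percentages is not None:
            out["tables"]["correlation_percentages"] = (
                self.correlation_percentages.to_dict(orient="records"))
        return out


def _segment_order(segments: Iterable[str]) -> list[str]:
    present = set(segments)
    ordered = [s for s in SEGMENTS if s in present]
    return ordered + sorted(present - set(ordered))


def build_report(direction_matrix: pd.DataFrame,
                 correlation_percentages: pd.DataFrame | None = None) -> ScoreTables:
    """Aggregate the per-participant direction matrix into the cohort tables.

    ``direction_matrix`` needs columns ``participant``, ``segment``,
    ``parameter`` and ``direction``, with parameter one of the six delta
    parameters or ``"spectral-peak"``.
    """
    required = {"participant", "segment", "parameter", "direction"}
    missing = required - set(direction_matrix.columns)
    if missing:
        raise ValueError(f"direction matrix lacks columns {sorted(missing)}")

    n_participants = direction_matrix["participant"].nunique()
    segments = _segment_order(direction_matrix["segment"].unique())

    pct_rows = []
    occ_rows = []
    spec_rows = []
    stat_sens_rows = []
    spectral_dominant_statuses = []

    grouped = direction_matrix.groupby(["segment", "parameter"])["direction"]

    for segment in segments:
        param_status: dict[str, str] = {}
        pattern_statuses: dict[str, list[str]] = {"I": [], "D": []}
        for parameter in DELTA_PARAMETERS:
            try:
                labels = grouped.get_group((segment, parameter))
            except KeyError:
                continue
            tally = tally_directions(labels, segment, parameter)
            for pattern in ("I", "D", "E"):
                pct = tally.percentage(pattern)
                pct_rows.append({
                    "segment": segment, "parameter": parameter,
                    "analysis": "statistical",
                    "pattern": PATTERN_NAME[pattern],
                    "count": tally.count(pattern),
                    "percentage": tally.rounded_percentage(pattern),
                    "status": classify_status(pct),
                })
            dom = tally.dominant_change()
            param_status[parameter] = classify_status(tally.percentage(dom))
            for pattern in ("I", "D"):
                pattern_statuses[pattern].append(
                    classify_status(tally.percentage(pattern)))

        if len(param_status) == len(DELTA_PARAMETERS):
            decision = statistical_change_decision(
                [param_status[p] for p in DELTA_PARAMETERS], segment)
            occ_rows.append({
                "segment": segment, "m": decision.n_moderate,
                "h": decision.n_high, "total": decision.total,
                "decision": decision.decision,
            })
            for pattern in ("D", "I"):
                row = {"segment": segment, "pattern": PATTERN_NAME[pattern]}
                row.update(sensitivity(pattern_statuses[pattern]))
                stat_sens_rows.append(row)

        try:
            labels = grouped.get_group((segment, "spectral-peak"))
        except KeyError:
            labels = None
        if labels is not None:
            tally = tally_directions(labels, segment, "spectral-peak")
            decision = spectral_change_decision(tally)
            dom = tally.dominant_change()
            other = "I" if dom == "D" else "D"
            spec_rows.append({
                "segment": segment,
                "pattern": PATTERN_NAME[dom],
                "percentage": tally.rounded_percentage(dom),
                "status": classify_status(tally.percentage(dom)),
                "other_pattern": PATTERN_NAME[other],
                "other_percentage": tally.rounded_percentage(other),
                "decision": decision.decision,
            })
            spectral_dominant_statuses.append(
                classify_status(tally.percentage(dom)))
            for pattern in ("I", "D", "E"):
                pct_rows.append({
                    "segment": segment, "parameter": "spectral-peak",
                    "analysis": "spectral",
                    "pattern": PATTERN_NAME[pattern],
                    "count": tally.count(pattern),
                    "percentage": tally.rounded_percentage(pattern),
                    "status": classify_status(tally.percentage(pattern)),
                })

    spectral_sens = pd.DataFrame(
        [dict(segments="ALL", pattern="Dominant",
              **sensitivity(spectral_dominant_statuses))]
        if spectral_dominant_statuses else [])

    return ScoreTables(
        pattern_matrix=direction_matrix.copy(),
        direction_percentages=pd.DataFrame(pct_rows),
        statistical_occurrence=pd.DataFrame(occ_rows),
        spectral_summary=pd.DataFrame(spec_rows),
        statistical_sensitivity=pd.DataFrame(stat_sens_rows),
        spectral_sensitivity=spectral_sens,
        correlation_percentages=correlation_percentages,
        n_participants=int(n_participants),
    )
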