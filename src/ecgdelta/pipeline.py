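"""End-to-end orchestration: delineate -> extract -> compare -> score.

The in-memory entry points (`analyze_pair`, `analyze_cohort`) take per-session
segment series and return the cohort score tables; the disk-facing runners
(`run_simulate`, `run_analyze`) wrap them with CSV I/O, a reproducibility
manifest and the three input modes (raw ECG traces, precomputed segment
series, or direct simulation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .delineate import (ECGRecord, SegmentSeries, clean_series, delineate,
                        detect_r_peaks, extract_segments)
from .simulate import (SEGMENTS, GlucoseEffectProfile, GroundTruth,
                       SessionConfig, generate_cohort)
from .spectral import WelchConfig, spectral_direction, welch_psd
from .stats import (DELTA_PARAMETERS, CorrelationResult, DeltaSummary,
                    correlate, correlation_percentage, delta, summarize)
from .scoring import ScoreTables, build_report

__all__ = [
    "RunConfig", "CohortResult",
    "truth_to_series", "delineate_record", "analyze_pair", "analyze_cohort",
    "run_simulate", "run_analyze",
]

logger = logging.getLogger(__name__)

#: Segment pairs examined by the correlation analysis: rows x columns of the
#: cross matrix (RR-I is the HRV series).
CORRELATION_ROWS = ("ST", "QTC", "QT")
CORRELATION_COLS = ("PRQ", "QRS", "P-H", "R-H", "RR-I", "HR")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"                  # "raw-ecg" | "segment-series" | "simulate"
    output_dir: str | Path = "ecgdelta_out"
    master_seed: int = 0
    n_participants: int = 16
    session: SessionConfig = field(default_factory=SessionConfig)
    effect: GlucoseEffectProfile = field(default_factory=GlucoseEffectProfile)
    welch: WelchConfig = field(default_factory=WelchConfig)
    #: participant id -> {"G": path, "NG": path} (raw-ecg mode)
    participants: dict[str, dict[str, str]] = field(default_factory=dict)
    #: long-format series CSV (segment-series mode)
    series_path: str | Path | None = None
    render_traces: bool = True

    def validate(self) -> None:
        if self.mode not in ("raw-ecg", "segment-series", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "raw-ecg":
            for pid, sessions in self.participants.items():
                for label in ("G", "NG"):
                    if label not in sessions:
                        raise ValueError(
                            f"participant {pid} is missing the {label} session")
            for pid, sessions in self.participants.items():
                for label in ("G", "NG"):
                    if not Path(sessions[label]).exists():
                        raise FileNotFoundError(
                            f"participant {pid} {label} file not found: "
                            f"{sessions[label]}")
        if self.mode == "segment-series" and self.series_path is None:
            raise ValueError("segment-series mode needs series_path")


@dataclass
class CohortResult:
    """Score tables plus the intermediate per-participant artifacts."""

    tables: ScoreTables
    deltas: pd.DataFrame            # participant,segment,parameter,delta,direction
    correlations: pd.DataFrame      # participant,segment_a,segment_b,coefficient,class
    psds: pd.DataFrame | None = None
    beat_counts: dict = field(default_factory=dict)


def truth_to_series(truth: GroundTruth, session: str = "",
                    participant: str = "") -> dict[str, SegmentSeries]:
    """Turn generator ground truth into the nine segment series."""
    beat_index = np.arange(truth.n_beats)
    out = {}
    for seg in SEGMENTS:
        v = truth.segments[seg]
        mask = np.isfinite(v)
        out[seg] = SegmentSeries(segment_id=seg, values=v[mask],
                                 beat_index=beat_index[mask],
                                 timestamp_s=truth.timestamp_s[mask],
                                 session=session, participant=participant)
    return out


def delineate_record(record: ECGRecord, session: str = "",
                     participant: str = "") -> tuple[dict[str, SegmentSeries], dict]:
    """Raw trace -> cleaned segment series, with beat-accounting stats."""
    r_peaks = detect_r_peaks(record)
    fiducials = delineate(record, r_peaks)
    series = extract_segments(fiducials, record, session=session,
                              participant=participant)
    cleaned = {seg: clean_series(s) for seg, s in series.items()}
    stats = {
        "r_peaks": int(len(r_peaks)),
        "beats_delineated": int(fiducials.n_beats),
        "beats_dropped": int(fiducials.n_dropped),
        "drop_reasons": dict(fiducials.drop_reasons),
        "cleaned_removed": {seg: s.n_removed for seg, s in cleaned.items()},
    }
    return cleaned, stats


def analyze_pair(
    g: dict[str, SegmentSeries],
    ng: dict[str, SegmentSeries],
    welch: WelchConfig | None = None,
    participant: str = "",
) -> tuple[dict[str, DeltaSummary], dict[str, str], list[CorrelationResult]]:
    """Compare one participant's G and NG sessions.

    Returns per-segment delta summaries, per-segment spectral-peak directions,
    and the G-session inter-segment correlation results.
    """
    welch = welch or WelchConfig()
    deltas: dict[str, DeltaSummary] = {}
    spectral: dict[str, str] = {}
    for seg in SEGMENTS:
        if seg not in g or seg not in ng:
            continue
        deltas[seg] = delta(summarize(g[seg]), summarize(ng[seg]))
        if len(g[seg]) >= welch.frame_length and len(ng[seg]) >= welch.frame_length:
            spectral[seg] = spectral_direction(
                welch_psd(g[seg], welch), welch_psd(ng[seg], welch), welch)
        else:
            logger.warning("participant %s segment %s too short for Welch "
                           "frame length %d; spectral direction skipped",
                           participant, seg, welch.frame_length)
    correlations = [
        correlate(g[a], g[b])
        for a in CORRELATION_ROWS for b in CORRELATION_COLS
        if a in g and b in g
    ]
    return deltas, spectral, correlations


def analyze_cohort(
    pairs: list[tuple[str, dict[str, SegmentSeries], dict[str, SegmentSeries]]],
    welch: WelchConfig | None = None,
) -> CohortResult:
    """Score a cohort of (participant, G series, NG series) triples."""
    if not pairs:
        raise ValueError("cohort is empty")
    direction_rows = []
    delta_rows = []
    corr_rows = []
    for participant, g, ng in pairs:
        deltas, spectral, correlations = analyze_pair(g, ng, welch, participant)
        for seg, summary in deltas.items():
            for parameter in DELTA_PARAMETERS:
                direction_rows.append({
                    "participant": participant, "segment": seg,
                    "parameter": parameter,
                    "direction": summary.directions[parameter]})
                delta_rows.append({
                    "participant": participant, "segment": seg,
                    "parameter": parameter,
                    "delta": summary.delta_of(parameter),
                    "direction": summary.directions[parameter]})
        for seg, label in spectral.items():
            direction_rows.append({
                "participant": participant, "segment": seg,
                "parameter": "spectral-peak", "direction": label})
        for res in correlations:
            corr_rows.append({
                "participant": participant, "segment_a": res.segment_a,
                "segment_b": res.segment_b, "coefficient": res.coefficient,
                "class": res.classification})

    corr_df = pd.DataFrame(corr_rows)
    corr_pct = None
    if len(corr_df):
        pct_rows = []
        for (a, b), grp in corr_df.groupby(["segment_a", "segment_b"], sort=False):
            results = [CorrelationResult(a, b, c, k, 0)
                       for c, k in zip(grp["coefficient"], grp["class"])]
            p_pct, n_pct = correlation_percentage(results)
            pct_rows.append({"segment_a": a, "segment_b": b,
                             "percent_P": p_pct, "percent_N": n_pct})
        corr_pct = pd.DataFrame(pct_rows)

    tables = build_report(pd.DataFrame(direction_rows),
                          correlation_percentages=corr_pct)
    return CohortResult(tables=tables, deltas=pd.DataFrame(delta_rows),
                        correlations=corr_df)


# ---------------------------------------------------------------------------
# disk-facing runners
# ---------------------------------------------------------------------------

def _manifest(config: RunConfig, extra: dict | None = None) -> dict:
    from . import __version__
    doc = {
        "ecgdelta_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "master_seed": config.master_seed,
        "mode": config.mode,
        "session": dataclasses.asdict(config.session),
        "effect": dataclasses.asdict(config.effect),
        "welch": dataclasses.asdict(config.welch),
    }
    if extra:
        doc.update(extra)
    return doc


def run_simulate(config: RunConfig) -> Path:
    """Generate a synthetic cohort on disk.

    Writes, per participant and session, an ECG trace CSV (when traces are
    rendered) and a ground-truth CSV, plus a manifest.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.n_participants, config.session,
                             config.effect, master_seed=config.master_seed,
                             render_trace=config.render_traces)
    for pair in cohort:
        for sess in pair:
            stem = f"participant{sess.participant:02d}_{sess.session}"
            if sess.samples_mV is not None:
                eio.write_ecg_csv(out / f"ecg_{stem}.csv", sess)
            eio.write_ground_truth_csv(out / f"truth_{stem}.csv", sess.truth)
    (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=2))
    return out


def _load_pairs(config: RunConfig) -> tuple[list, dict]:
    """Resolve the configured input mode into in-memory cohort pairs."""
    beat_stats: dict = {}
    pairs = []
    if config.mode == "simulate":
        cohort = generate_cohort(config.n_participants, config.session,
                                 config.effect, master_seed=config.master_seed,
                                 render_trace=False)
        for g_sess, ng_sess in cohort:
            pid = str(g_sess.participant)
            pairs.append((pid,
                          truth_to_series(g_sess.truth, "G", pid),
                          truth_to_series(ng_sess.truth, "NG", pid)))
    elif config.mode == "segment-series":
        by_key = eio.read_segment_series_csv(config.series_path)
        participants = sorted({pid for pid, _ in by_key})
        for pid in participants:
            if (pid, "G") not in by_key or (pid, "NG") not in by_key:
                raise ValueError(f"participant {pid} is missing a session "
                                 "in the series file")
            pairs.append((pid, by_key[(pid, "G")], by_key[(pid, "NG")]))
    else:  # raw-ecg
        for pid, sessions in sorted(config.participants.items()):
            series = {}
            for label in ("G", "NG"):
                record = eio.read_ecg_csv(sessions[label])
                series[label], stats = delineate_record(record, label, pid)
                beat_stats[f"{pid}/{label}"] = stats
            pairs.append((pid, series["G"], series["NG"]))
    return pairs, beat_stats


def run_analyze(config: RunConfig, write_psds: bool = False) -> CohortResult:
    """Run the full comparison pipeline and write every intermediate.

    Deterministic given inputs and seed; the manifest records versions,
    configuration and beat-accounting so a run can be reproduced exactly.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, beat_stats = _load_pairs(config)
    result = analyze_cohort(pairs, config.welch)
    result.beat_counts = beat_stats

    eio.write_segment_series_csv(
        out / "segment_series.csv",
        [series for _, g, ng in pairs for series in (g, ng)])
    result.deltas.to_csv(out / "deltas.csv", index=False)
    result.correlations.to_csv(out / "correlations.csv", index=False)
    tables = result.tables
    tables.pattern_matrix.to_csv(out / "pattern_matrix.csv", index=False)
    tables.direction_percentages.to_csv(out / "direction_percentages.csv", index=False)
    tables.statistical_occurrence.to_csv(out / "statistical_occurrence.csv", index=False)
    tables.spectral_summary.to_csv(out / "spectral_summary.csv", index=False)
    tables.statistical_sensitivity.to_csv(out / "statistical_sensitivity.csv", index=False)
    tables.spectral_sensitivity.to_csv(out / "spectral_sensitivity.csv", index=False)
    if tables.correlation_percentages is not None:
        tables.correlation_percentages.to_csv(out / "correlation_percentages.csv",
                                              index=False)
    (out / "report.json").write_text(json.dumps(tables.to_json_dict(), indent=2))

    if write_psds:
        psd_rows = []
        for pid, g, ng in pairs:
            for series in list(g.values()) + list(ng.values()):
                if len(series) < config.welch.frame_length:
                    continue
                psd = welch_psd(series, config.welch)
                psd_rows.append(pd.DataFrame({
                    "participant": pid, "session": series.session,
                    "segment": series.segment_id,
                    "frequency": psd.frequency_hz, "power": psd.power}))
        if psd_rows:
            pd.concat(psd_rows, ignore_index=True).to_csv(
                out / "psd.csv", index=False)

    (out / "manifest.json").write_text(
        json.dumps(_manifest(config, {"beat_counts": beat_stats}), indent=2))
    return result
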