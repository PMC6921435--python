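"""CSV and configuration I/O for the pipeline.

All tabular artifacts are plain CSV:

* ECG traces:          ``time_s,ecg_mV`` (one row per sample)
* ground truth:        one row per beat, fiducial indices + segment values
* segment series:      ``participant,session,beat_index,time_s,segment,value``
* delta tables:        ``participant,segment,parameter,delta,direction``
* PSDs:                ``participant,session,segment,frequency,power``

Configuration files are flat YAML key/value mappings mirroring the dataclass
fields of the generator, delineator and Welch estimator.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .delineate import ECGRecord, SegmentSeries
from .simulate import (SEGMENTS, GlucoseEffectProfile, GroundTruth,
                       SessionConfig, SyntheticSession)
from .spectral import WelchConfig

__all__ = [
    "read_ecg_csv", "write_ecg_csv",
    "write_ground_truth_csv", "read_ground_truth_csv",
    "write_segment_series_csv", "read_segment_series_csv",
    "load_config", "dump_config",
]

FIDUCIAL_COLUMNS = ("P_onset", "P_peak", "Q", "R", "S", "T_onset", "T_peak", "T_end")


def read_ecg_csv(path: str | Path, sampling_rate_hz: float | None = None) -> ECGRecord:
    """Read a ``time_s,ecg_mV`` trace.

    Tolerates a header row and an optional leading index column.  The
    sampling rate is inferred from the time column unless given.
    """
    df = pd.read_csv(path)
    cols = [c for c in df.columns if not c.lower().startswith("unnamed")]
    if len(cols) < 2:
        raise ValueError(f"{path}: expected time and voltage columns, got {cols}")
    time = df[cols[-2]].to_numpy(dtype=float)
    volts = df[cols[-1]].to_numpy(dtype=float)
    if sampling_rate_hz is None:
        dt = np.diff(time)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError(f"{path}: cannot infer sampling rate from time column")
        sampling_rate_hz = 1.0 / float(np.median(dt))
    return ECGRecord(samples_mV=volts, sampling_rate_hz=float(sampling_rate_hz),
                     start_time_s=float(time[0]))


def write_ecg_csv(path: str | Path, session: SyntheticSession | ECGRecord,
                  start_time_s: float | None = None) -> None:
    if isinstance(session, SyntheticSession):
        if session.samples_mV is None:
            raise ValueError("session has no rendered trace to write")
        samples, fs, t0 = session.samples_mV, session.sampling_rate_hz, 0.0
    else:
        samples, fs, t0 = session.samples_mV, session.sampling_rate_hz, session.start_time_s
    if start_time_s is not None:
        t0 = start_time_s
    t = t0 + np.arange(len(samples)) / fs
    pd.DataFrame({"time_s": t, "ecg_mV": samples}).to_csv(
        path, index=False, float_format="%.6f")


def write_ground_truth_csv(path: str | Path, truth: GroundTruth) -> None:
    data: dict[str, np.ndarray] = {"timestamp_s": truth.timestamp_s}
    for name in FIDUCIAL_COLUMNS:
        data[f"idx_{name}"] = truth.fiducials[name]
    for seg in SEGMENTS:
        data[seg] = truth.segments[seg]
    pd.DataFrame(data).to_csv(path, index=False)


def read_ground_truth_csv(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    return GroundTruth(
        timestamp_s=df["timestamp_s"].to_numpy(dtype=float),
        fiducials={name: df[f"idx_{name}"].to_numpy(dtype=np.int64)
                   for name in FIDUCIAL_COLUMNS},
        segments={seg: df[seg].to_numpy(dtype=float) for seg in SEGMENTS},
    )


def write_segment_series_csv(path: str | Path,
                             series: dict[str, SegmentSeries] |
                             list[dict[str, SegmentSeries]]) -> None:
    """Write one or many sessions' segment series in long format."""
    sessions = series if isinstance(series, list) else [series]
    frames = []
    for sess in sessions:
        for seg_id, s in sess.items():
            frames.append(pd.DataFrame({
                "participant": s.participant, "session": s.session,
                "beat_index": s.beat_index, "time_s": s.timestamp_s,
                "segment": seg_id, "value": s.values,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_segment_series_csv(path: str | Path) -> dict[tuple[str, str],
                                                      dict[str, SegmentSeries]]:
    """Read a long-format series CSV -> {(participant, session): {segment: series}}."""
    df = pd.read_csv(path, dtype={"participant": str, "session": str})
    out: dict[tuple[str, str], dict[str, SegmentSeries]] = {}
    for (participant, session, segment), grp in df.groupby(
            ["participant", "session", "segment"], sort=False):
        out.setdefault((participant, session), {})[segment] = SegmentSeries(
            segment_id=segment,
            values=grp["value"].to_numpy(dtype=float),
            beat_index=grp["beat_index"].to_numpy(dtype=np.int64),
            timestamp_s=grp["time_s"].to_numpy(dtype=float),
            session=session, participant=str(participant),
        )
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SECTIONS = {
    "session": SessionConfig,
    "effect": GlucoseEffectProfile,
    "welch": WelchConfig,
}


def load_config(path: str | Path) -> dict:
    """Load a flat YAML config into dataclass sections.

    Keys may be namespaced (``session.duration_s``) or grouped under section
    mappings; unknown keys raise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    grouped: dict[str, dict] = {name: {} for name in _SECTIONS}
    extras: dict = {}
    for key, value in raw.items():
        if isinstance(value, dict) and key in _SECTIONS:
            grouped[key].update(value)
        elif "." in str(key) and str(key).split(".", 1)[0] in _SECTIONS:
            section, fieldname = str(key).split(".", 1)
            grouped[section][fieldname] = value
        else:
            extras[key] = value
    out: dict = dict(extras)
    for name, cls in _SECTIONS.items():
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(grouped[name]) - known
        if unknown:
            raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
        out[name] = cls(**{k: _coerce(v) for k, v in grouped[name].items()})
    return out


def _coerce(value):
    if isinstance(value, str) and value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def dump_config(path: str | Path, session: SessionConfig,
                effect: GlucoseEffectProfile, welch: WelchConfig,
                extras: dict | None = None) -> None:
    doc = {
        "session": dataclasses.asdict(session),
        "effect": dataclasses.asdict(effect),
        "welch": dataclasses.asdict(welch),
    }
    if extras:
        doc.update(extras)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
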