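"""Beat detection, fiducial delineation and per-beat segment extraction.

R peaks are found with a Pan–Tompkins-style chain (band-pass, differentiate,
square, moving-window integrate, adaptive threshold with refractory period).
The remaining landmarks are located with fixed search windows around each R
peak, and wave onsets/ends by walking outward from a peak until the signal
returns to within 5% of the local baseline.

Nine per-beat series are derived per the standard single-lead definitions:
RR-I (the HRV series), HR, R-H, P-H, QRS, PRQ, QT, QTC (Bazett) and ST
(S wave to T onset).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import SEGMENTS

__all__ = [
    "ECGRecord",
    "FiducialSet",
    "SegmentSeries",
    "DelineationConfig",
    "SEGMENTS",
    "INTERVAL_SEGMENTS",
    "HEIGHT_SEGMENTS",
    "detect_r_peaks",
    "delineate",
    "extract_segments",
    "clean_series",
]

logger = logging.getLogger(__name__)

INTERVAL_SEGMENTS = ("RR-I", "QRS", "PRQ", "QT", "QTC", "ST")
HEIGHT_SEGMENTS = ("R-H", "P-H")


@dataclass(frozen=True)
class ECGRecord:
    """A gap-free single-channel voltage trace in millivolts."""

    samples_mV: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples_mV, dtype=float)
        object.__setattr__(self, "samples_mV", samples)
        if samples.ndim != 1 or len(samples) < 2:
            raise ValueError("record needs at least 2 samples in one channel")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValueError("record contains missing/non-finite samples; split gaps upstream")

    @property
    def duration_s(self) -> float:
        return len(self.samples_mV) / self.sampling_rate_hz


@dataclass(frozen=True)
class DelineationConfig:
    """Search-window constants (ms) for landmark location around each R peak."""

    qs_window_ms: float = 80.0        # Q/S: nearest local extremum within this span
    p_window_ms: tuple[float, float] = (250.0, 80.0)     # P peak in (R-250, R-80)
    t_window_start_ms: float = 120.0
    t_window_end_ms: float = 450.0
    t_window_rr_frac: float = 0.7
    baseline_return_frac: float = 0.05
    onset_max_walk_ms: float = 200.0
    min_p_amplitude_mV: float = 0.02  # below this, the P wave is declared absent


@dataclass
class FiducialSet:
    """Per-beat landmark sample indices.

    Q, R and S are always present for a retained beat; P and T landmarks may
    be NaN when their search failed (those beats are excluded only from the
    series that depend on them).  ``n_dropped`` counts beats discarded
    entirely (boundary beats and Q/R/S failures).
    """

    R: np.ndarray
    Q: np.ndarray
    S: np.ndarray
    P_onset: np.ndarray
    P_peak: np.ndarray
    T_onset: np.ndarray
    T_peak: np.ndarray
    T_end: np.ndarray
    timestamp_s: np.ndarray
    sampling_rate_hz: float
    n_dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return len(self.R)


@dataclass
class SegmentSeries:
    """Per-beat values of one segment for one session of one participant."""

    segment_id: str
    values: np.ndarray
    beat_index: np.ndarray
    timestamp_s: np.ndarray
    session: str = ""
    participant: str = ""
    n_removed: int = 0

    def __post_init__(self) -> None:
        if self.segment_id not in SEGMENTS:
            raise ValueError(f"unknown segment id {self.segment_id!r}")
        if not (len(self.values) == len(self.beat_index) == len(self.timestamp_s)):
            raise ValueError("values, beat_index and timestamp_s must align")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(record: ECGRecord) -> np.ndarray:
    """Locate R peaks; returns sample indices into the original signal.

    Pipeline: 5–15 Hz band-pass, differentiate, square, 150 ms moving-window
    integration, adaptive threshold with a 200 ms refractory period, then
    refinement to the local maximum of the raw signal.  A constant record
    yields an empty result; a record shorter than the integration window is
    an error.
    """
    x = record.samples_mV
    fs = record.sampling_rate_hz
    win = max(1, int(round(0.150 * fs)))
    if len(x) <= max(win, 18):          # 18 = filtfilt padding for a 2nd-order sosfiltfilt
        raise ValueError(
            f"record of {len(x)} samples is shorter than the "
            f"{win}-sample integration window")
    if np.ptp(x) == 0.0:
        return np.array([], dtype=np.int64)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    squared = np.gradient(filtered) ** 2
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    candidates, _ = sps.find_peaks(integrated, distance=max(1, refractory))
    if len(candidates) == 0:
        return np.array([], dtype=np.int64)

    # adaptive signal/noise levels, classic running-estimate form
    spk = float(np.max(integrated[: min(len(integrated), int(2 * fs))])) * 0.5
    npk = float(np.mean(integrated[: min(len(integrated), int(2 * fs))])) * 0.5
    accepted = []
    for c in candidates:
        level = integrated[c]
        threshold = npk + 0.25 * (spk - npk)
        if level > threshold:
            accepted.append(c)
            spk = 0.125 * level + 0.875 * spk
        else:
            npk = 0.125 * level + 0.875 * npk

    # refine each detection to the raw-signal maximum nearby
    half = int(round(0.075 * fs))
    peaks = []
    for c in accepted:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.array(sorted(set(peaks)), dtype=np.int64)

    # enforce refractory in the refined domain, keeping the taller peak
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < refractory:
            if x[p] > x[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.array(keep, dtype=np.int64)


# ---------------------------------------------------------------------------
# fiducial delineation
# ---------------------------------------------------------------------------

def _nearest_local_min(seg: np.ndarray, from_right: bool) -> int | None:
    """Index of the local minimum nearest the R-side end of ``seg``."""
    if len(seg) < 3:
        return None
    interior = np.nonzero((seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:]))[0] + 1
    if len(interior) == 0:
        return None
    return int(interior[-1]) if from_right else int(interior[0])


def _walk_to_baseline(x: np.ndarray, peak: int, baseline: float,
                      frac: float, max_walk: int, step: int) -> int | None:
    """Walk from ``peak`` in ``step`` direction until within ``frac`` of baseline."""
    height = x[peak] - baseline
    if height == 0.0:
        return peak
    thresh = abs(height) * frac
    i = peak
    for _ in range(max_walk):
        i += step
        if i < 0 or i >= len(x):
            return None
        if abs(x[i] - baseline) <= thresh:
            return i
    return None


def delineate(record: ECGRecord, r_peaks: np.ndarray,
              config: DelineationConfig | None = None) -> FiducialSet:
    """Locate P/Q/S/T landmarks around each detected R peak.

    Boundary beats whose search windows leave the record, and beats where the
    Q, S or T search fails, are dropped (counted in ``drop_reasons``).  A
    missing P wave leaves NaN P landmarks but retains the beat.
    """
    cfg = config or DelineationConfig()
    x = record.samples_mV
    fs = record.sampling_rate_hz
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if len(r_peaks) < 2:
        raise ValueError("delineation needs at least 2 R peaks")

    ms = lambda v: int(round(v / 1000.0 * fs))
    qs_w = ms(cfg.qs_window_ms)
    p_lo, p_hi = ms(cfg.p_window_ms[0]), ms(cfg.p_window_ms[1])
    max_walk = ms(cfg.onset_max_walk_ms)

    rows: list[dict[str, float]] = []
    reasons = {"boundary": 0, "qs_search": 0, "t_search": 0, "ordering": 0}

    for k, r in enumerate(r_peaks[:-1]):
        rr = int(r_peaks[k + 1] - r)
        t_hi = min(ms(cfg.t_window_end_ms), int(cfg.t_window_rr_frac * rr))
        t_lo = ms(cfg.t_window_start_ms)
        if r - p_lo - max_walk < 0 or r + t_hi + max_walk >= len(x):
            reasons["boundary"] += 1
            continue

        q_rel = _nearest_local_min(x[r - qs_w: r + 1], from_right=True)
        s_rel = _nearest_local_min(x[r: r + qs_w + 1], from_right=False)
        if q_rel is None or s_rel is None:
            reasons["qs_search"] += 1
            continue
        q, s = r - qs_w + q_rel, r + s_rel

        # local baseline: the PR segment (between P end and Q onset) is the
        # classical isoelectric reference; the beat-window median is biased
        # upward by T/P wave mass
        pr_lo, pr_hi = r - ms(90.0), r - ms(50.0)
        baseline = float(np.median(x[pr_lo:pr_hi]))

        if t_hi <= t_lo:
            reasons["t_search"] += 1
            continue
        t_peak = r + t_lo + int(np.argmax(x[r + t_lo: r + t_hi + 1]))
        t_on = _walk_to_baseline(x, t_peak, baseline, cfg.baseline_return_frac,
                                 max_walk, step=-1)
        t_end = _walk_to_baseline(x, t_peak, baseline, cfg.baseline_return_frac,
                                  max_walk, step=+1)
        if t_on is None or t_end is None or t_on <= s:
            reasons["t_search"] += 1
            continue

        p_win = x[r - p_lo: r - p_hi + 1]
        p_peak_rel = int(np.argmax(p_win))
        p_peak: float = float(r - p_lo + p_peak_rel)
        p_on: float
        if p_win[p_peak_rel] - baseline < cfg.min_p_amplitude_mV:
            p_peak = math.nan
            p_on = math.nan
        else:
            got = _walk_to_baseline(x, int(p_peak), baseline,
                                    cfg.baseline_return_frac, max_walk, step=-1)
            p_on = math.nan if got is None else float(got)

        if not (q < r < s < t_on <= t_peak <= t_end):
            reasons["ordering"] += 1
            continue
        if not math.isnan(p_on) and not (p_on <= p_peak < q):
            p_peak = p_on = math.nan

        rows.append(dict(R=float(r), Q=float(q), S=float(s), P_onset=p_on,
                         P_peak=p_peak, T_onset=float(t_on),
                         T_peak=float(t_peak), T_end=float(t_end)))

    # the final R peak has no successor: always excluded
    reasons["boundary"] += 1
    n_dropped = len(r_peaks) - len(rows)
    if rows:
        cols = {k: np.array([row[k] for row in rows]) for k in rows[0]}
    else:
        cols = {k: np.array([]) for k in
                ("R", "Q", "S", "P_onset", "P_peak", "T_onset", "T_peak", "T_end")}
    ts = record.start_time_s + cols["R"] / fs
    if n_dropped:
        logger.info("delineation dropped %d of %d beats (%s)",
                    n_dropped, len(r_peaks), reasons)
    return FiducialSet(R=cols["R"].astype(np.int64), Q=cols["Q"].astype(np.int64),
                       S=cols["S"].astype(np.int64), P_onset=cols["P_onset"],
                       P_peak=cols["P_peak"], T_onset=cols["T_onset"],
                       T_peak=cols["T_peak"], T_end=cols["T_end"],
                       timestamp_s=ts, sampling_rate_hz=fs,
                       n_dropped=n_dropped, drop_reasons=reasons)


# ---------------------------------------------------------------------------
# segment extraction
# ---------------------------------------------------------------------------

def extract_segments(fiducials: FiducialSet, record: ECGRecord,
                     session: str = "", participant: str = "") -> dict[str, SegmentSeries]:
    """Compute the nine per-beat segment series from delineated landmarks.

    RR-dependent series use successive retained R peaks, so a dropped beat in
    between produces an inflated RR that ``clean_series`` removes.  P-wave
    series silently omit beats whose P landmarks are NaN.
    """
    if fiducials.n_beats < 2:
        raise ValueError("need at least 2 delineated beats (RR undefined otherwise)")
    fs = fiducials.sampling_rate_hz
    x = record.samples_mV
    to_ms = 1000.0 / fs

    r = fiducials.R.astype(float)
    rr = np.concatenate([np.diff(r), [np.nan]]) * to_ms
    with np.errstate(invalid="ignore", divide="ignore"):
        values = {
            "RR-I": rr,
            "HR": 60000.0 / rr,
            "R-H": x[fiducials.R],
            "P-H": np.where(np.isnan(fiducials.P_peak), np.nan,
                            x[np.nan_to_num(fiducials.P_peak).astype(np.int64)]),
            "QRS": (fiducials.S - fiducials.Q) * to_ms,
            "PRQ": (fiducials.R - fiducials.P_onset) * to_ms,
            "QT": (fiducials.T_end - fiducials.Q) * to_ms,
            "ST": (fiducials.T_onset - fiducials.S) * to_ms,
        }
        values["QTC"] = values["QT"] / np.sqrt(rr / 1000.0)

    out = {}
    beat_index = np.arange(fiducials.n_beats)
    for seg in SEGMENTS:
        v = np.asarray(values[seg], dtype=float)
        mask = ~np.isnan(v)
        out[seg] = SegmentSeries(segment_id=seg, values=v[mask],
                                 beat_index=beat_index[mask],
                                 timestamp_s=fiducials.timestamp_s[mask],
                                 session=session, participant=participant)
    return out


_PHYS_RANGE = {
    "HR": (20.0, 250.0),
    "RR-I": (60000.0 / 250.0, 60000.0 / 20.0),
}


def clean_series(series: SegmentSeries, mad_threshold: float = 5.0,
                 warn_fraction: float = 0.20) -> SegmentSeries:
    """Remove physiologically impossible values and gross outliers.

    Interval values must be positive; HR and RR-I must fall inside the
    (20, 250) bpm band.  Remaining values beyond ``mad_threshold`` scaled
    median absolute deviations (1.4826·MAD, the Gaussian-consistent scale)
    of the session median are discarded.  A degenerate spread (MAD = 0)
    skips the outlier rule.  Removing more than ``warn_fraction`` of the
    beats logs a warning for the run report.
    """
    v = series.values
    mask = np.isfinite(v)
    if series.segment_id in INTERVAL_SEGMENTS:
        mask &= v > 0
    lo_hi = _PHYS_RANGE.get(series.segment_id)
    if lo_hi is not None:
        mask &= (v > lo_hi[0]) & (v < lo_hi[1])

    kept = v[mask]
    if len(kept):
        med = float(np.median(kept))
        mad = float(np.median(np.abs(kept - med)))
        if mad > 0:
            scaled = 1.4826 * mad
            inlier = np.abs(v - med) <= mad_threshold * scaled
            mask &= inlier

    n_removed = int(len(v) - mask.sum())
    if len(v) and n_removed / len(v) > warn_fraction:
        logger.warning("clean_series removed %d/%d beats (> %.0f%%) from %s %s/%s",
                       n_removed, len(v), warn_fraction * 100,
                       series.segment_id, series.participant, series.session)
    return SegmentSeries(segment_id=series.segment_id, values=v[mask],
                         beat_index=series.beat_index[mask],
                         timestamp_s=series.timestamp_s[mask],
                         session=series.session, participant=series.participant,
                         n_removed=series.n_removed + n_removed)
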