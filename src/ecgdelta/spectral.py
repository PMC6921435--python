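"""Welch power-spectral-density estimation of beat-indexed segment series.

The estimator partitions a series into overlapping rectangular-windowed
frames, computes each frame's periodogram |DFT|^2 / M, and averages the
periodograms — trading frequency resolution for reduced estimator variance.
Each participant's G and NG spectra for a segment are then compared through
their peak power H(S): peak higher under glucose means direction I, lower
means D, equal within tolerance means E.

Segment series carry large constant offsets (an RR series sits near 800 ms),
so the series mean is subtracted by default and the zero-frequency bin is
excluded from the peak, making H reflect oscillatory content rather than DC
leakage; both behaviours are configuration switches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .delineate import SegmentSeries
from .stats import EQUALITY_TOL, direction_of

__all__ = ["WelchConfig", "PSDEstimate", "welch_psd", "peak_power",
           "spectral_direction"]


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator parameters.

    ``sampling_frequency_hz`` is the nominal rate assigned to the beat-domain
    series; it scales the frequency axis only and leaves the power ordering
    that the peak comparison uses untouched.  The frame step is
    ``frame_length - overlap_points``; trailing samples that do not fill a
    frame are discarded.
    """

    sampling_frequency_hz: float = 0.8
    frame_length: int = 256
    overlap_points: int = 10
    subtract_mean: bool = True
    include_dc_in_peak: bool = False

    def __post_init__(self) -> None:
        if self.frame_length < 8:
            raise ValueError("frame_length must be >= 8")
        if not (0 <= self.overlap_points < self.frame_length):
            raise ValueError("overlap_points must satisfy 0 <= overlap < frame_length")
        if self.sampling_frequency_hz <= 0:
            raise ValueError("sampling_frequency_hz must be positive")

    @property
    def step(self) -> int:
        return self.frame_length - self.overlap_points


@dataclass
class PSDEstimate:
    """One-sided averaged periodogram on the grid k * fs / M, k = 0 .. M/2."""

    frequency_hz: np.ndarray
    power: np.ndarray
    frames_used: int
    segment_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        if len(self.frequency_hz) != len(self.power):
            raise ValueError("frequency and power grids must align")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def welch_psd(series: SegmentSeries | np.ndarray,
              config: WelchConfig | None = None) -> PSDEstimate:
    """Welch PSD of one segment series.

    With a single frame (series length == frame length) the result equals
    the plain periodogram of that frame.  One-sided scaling doubles every
    bin except DC and Nyquist so total power is preserved.
    """
    cfg = config or WelchConfig()
    if isinstance(series, SegmentSeries):
        x = np.asarray(series.values, dtype=float)
        segment_id, session = series.segment_id, series.session
    else:
        x = np.asarray(series, dtype=float)
        segment_id = session = ""
    m = cfg.frame_length
    n = len(x)
    if n < m:
        raise ValueError(
            f"series of {n} samples is shorter than frame_length={m}; "
            "lower frame_length")
    if cfg.subtract_mean:
        x = x - np.mean(x)

    step = cfg.step
    k_frames = (n - m) // step + 1
    idx = np.arange(m)[None, :] + step * np.arange(k_frames)[:, None]
    frames = x[idx]                                   # (K, M), rectangular window
    spectra = np.fft.rfft(frames, n=m, axis=1)
    periodograms = (np.abs(spectra) ** 2) / m         # two-sided scale, per Welch
    psd = periodograms.mean(axis=0)

    # fold to one-sided: double all bins except DC (and Nyquist when M even)
    one_sided = psd.copy()
    last = len(one_sided) - 1 if m % 2 == 0 else len(one_sided)
    one_sided[1:last] *= 2.0

    freqs = np.fft.rfftfreq(m, d=1.0 / cfg.sampling_frequency_hz)
    return PSDEstimate(frequency_hz=freqs, power=one_sided,
                       frames_used=int(k_frames),
                       segment_id=segment_id, session=session)


def peak_power(psd: PSDEstimate, include_dc: bool | None = None,
               config: WelchConfig | None = None) -> float:
    """Peak value H(S) of the spectrum, excluding the DC bin by default."""
    if include_dc is None:
        include_dc = config.include_dc_in_peak if config is not None else False
    start = 0 if include_dc else 1
    if len(psd.power) <= start:
        raise ValueError("PSD has no bins beyond DC")
    return float(np.max(psd.power[start:]))


def spectral_direction(g: PSDEstimate, ng: PSDEstimate,
                       config: WelchConfig | None = None,
                       rtol: float = EQUALITY_TOL) -> str:
    """Compare peak powers of the G and NG spectra: 'I', 'D' or 'E'."""
    if len(g.power) != len(ng.power):
        raise ValueError("G and NG spectra must come from the same configuration")
    h_g = peak_power(g, config=config)
    h_ng = peak_power(ng, config=config)
    scale = max(abs(h_g), abs(h_ng), 1.0)
    return direction_of((h_g - h_ng) / scale, rtol)
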