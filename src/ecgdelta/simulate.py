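"""Synthetic paired-session ECG generator with analytic ground truth.

Emulates a two-day oral-glucose protocol: each participant is recorded for a
120-min control (NG) session and a 120-min glucose (G) session.  Thirty
minutes into the G session a glucose effect ramps in and multiplies selected
beat-geometry parameters (RR shortens, QT/ST/PRQ-type spans shrink, heart
rate rises).  Each cardiac cycle is rendered as a sum of five Gaussian bumps
(P, Q, R, S, T), which keeps every fiducial point and every derived segment
value analytically known.

The two sessions of a pair share one set of random substreams (common random
numbers): with all effect gains at 1 the G and NG outputs are bitwise
identical, so any downstream difference is attributable to the injected
effect alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveShape",
    "BeatMorphology",
    "SessionConfig",
    "GlucoseEffectProfile",
    "GroundTruth",
    "SyntheticSession",
    "ONSET_K",
    "generate_beat",
    "generate_session_pair",
    "generate_cohort",
]

#: Onset/offset constant: a Gaussian bump falls to 5% of its peak at
#: center +- ONSET_K * width, which is also where the delineator's
#: 5%-return-to-baseline search stops.
ONSET_K = math.sqrt(2.0 * math.log(20.0))

WAVES = ("P", "Q", "R", "S", "T")

#: Segment identifiers, in the conventional reporting order.
#: "RR-I" is the RR-interval series, i.e. the heart-rate-variability series.
SEGMENTS = ("RR-I", "HR", "R-H", "P-H", "QRS", "PRQ", "QT", "QTC", "ST")


@dataclass(frozen=True)
class WaveShape:
    """One Gaussian wave: signed amplitude, width and center offset from R."""

    amplitude_mV: float
    width_ms: float
    offset_ms: float


@dataclass(frozen=True)
class BeatMorphology:
    """Per-wave shape parameters for one cardiac cycle.

    Offsets are wave centers relative to the R peak (ms); P and Q sit before
    R (negative offsets), S and T after.  R must be the dominant deflection.
    """

    P: WaveShape
    Q: WaveShape
    R: WaveShape
    S: WaveShape
    T: WaveShape

    def __post_init__(self) -> None:
        for name in WAVES:
            w: WaveShape = getattr(self, name)
            if w.width_ms <= 0:
                raise ValueError(f"{name} width must be positive, got {w.width_ms}")
        amplitudes = [getattr(self, n).amplitude_mV for n in WAVES]
        if any(amplitudes):          # the all-zero (flat) morphology is allowed
            if self.R.amplitude_mV <= 0:
                raise ValueError("R amplitude must be positive")
            for name in ("P", "Q", "S", "T"):
                if abs(getattr(self, name).amplitude_mV) >= self.R.amplitude_mV:
                    raise ValueError(
                        f"R must be the largest deflection (violated by {name})")
        offsets = [getattr(self, n).offset_ms for n in WAVES]
        if not (offsets[0] < offsets[1] < 0.0 == offsets[2] < offsets[3] < offsets[4]):
            raise ValueError(f"wave offsets must satisfy P < Q < 0 = R < S < T, got {offsets}")

    @classmethod
    def default(cls) -> "BeatMorphology":
        """A plausible resting adult single-lead morphology."""
        return cls(
            P=WaveShape(0.15, 22.0, -170.0),
            Q=WaveShape(-0.10, 9.0, -34.0),
            R=WaveShape(1.20, 8.5, 0.0),
            S=WaveShape(-0.20, 9.0, 34.0),
            T=WaveShape(0.32, 42.0, 280.0),
        )

    # -- derived geometry (all ms, relative to R) -------------------------

    @property
    def p_onset_ms(self) -> float:
        return self.P.offset_ms - ONSET_K * self.P.width_ms

    @property
    def t_onset_ms(self) -> float:
        return self.T.offset_ms - ONSET_K * self.T.width_ms

    @property
    def t_end_ms(self) -> float:
        return self.T.offset_ms + ONSET_K * self.T.width_ms

    @property
    def span_ms(self) -> float:
        """Total extent of the waveform, P onset to T end."""
        return self.t_end_ms - self.p_onset_ms


@dataclass(frozen=True)
class SessionConfig:
    """Recording-session parameters.

    Defaults follow the emulated protocol: 120-min sessions, 500 Hz sampling,
    resting heart rate in the mid-60s with realistic beat-to-beat RR jitter
    and a respiratory RR modulation.
    """

    duration_s: float = 7200.0
    sampling_rate_hz: float = 500.0
    baseline_hr_bpm: float = 66.0
    hrv_sd_ms: float = 25.0
    noise_sd_mV: float = 0.02
    random_seed: int = 0
    resp_amplitude_ms: float = 15.0
    resp_freq_hz: float = 0.25
    span_jitter_frac: float = 0.01
    participant_variation: float = 0.06
    start_offset_s: float = 0.35

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz < 100:
            raise ValueError("sampling_rate_hz must be >= 100")
        if not (40.0 <= self.baseline_hr_bpm <= 180.0):
            raise ValueError("baseline_hr_bpm must lie in [40, 180]")
        if self.hrv_sd_ms < 0:
            raise ValueError("hrv_sd_ms must be non-negative")
        if self.noise_sd_mV < 0:
            raise ValueError("noise_sd_mV must be non-negative")


@dataclass(frozen=True)
class GlucoseEffectProfile:
    """Multiplicative glucose effect, ramped in linearly after onset.

    Every gain is a positive multiplier on the corresponding generator
    primitive once the ramp completes; 1 means no injected effect.  The RR
    interval is scaled by ``rr_gain / hr_gain`` so that either knob moves
    heart rate in its named direction.  ``qt_gain`` scales the T-wave
    duration; the QT span (= QRS + ST + T-wave duration) therefore responds
    jointly to ``qrs_gain``, ``st_gain`` and ``qt_gain``.

    Defaults model a mild post-ingestion response: HR up ~10%, RR down,
    ventricular spans shortened by 5%.
    """

    onset_s: float = 1800.0
    ramp_s: float = 600.0
    hr_gain: float = 1.1
    rr_gain: float = 0.9
    qt_gain: float = 0.95
    st_gain: float = 0.95
    prq_gain: float = 0.95
    qrs_gain: float = 1.0
    ph_gain: float = 1.0
    rh_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if self.ramp_s < 0:
            raise ValueError("ramp_s must be non-negative")
        for name in ("hr_gain", "rr_gain", "qt_gain", "st_gain",
                     "prq_gain", "qrs_gain", "ph_gain", "rh_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def null(cls) -> "GlucoseEffectProfile":
        """No injected effect (all gains 1)."""
        return cls(hr_gain=1.0, rr_gain=1.0, qt_gain=1.0, st_gain=1.0,
                   prq_gain=1.0, qrs_gain=1.0, ph_gain=1.0, rh_gain=1.0)

    def ramp_fraction(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """Fraction of the full effect active at session time ``t_s``."""
        if self.ramp_s == 0:
            return np.where(np.asarray(t_s) >= self.onset_s, 1.0, 0.0)
        return np.clip((np.asarray(t_s, dtype=float) - self.onset_s) / self.ramp_s, 0.0, 1.0)


@dataclass
class GroundTruth:
    """Per-beat true fiducials and segment values for one session.

    Fiducial arrays are sample indices (rounded to the session's sampling
    grid); segment values are computed from the continuous geometry, so they
    are exact, not quantized.  RR-dependent values (RR-I, HR, QTC) are NaN
    for the final beat, which has no successor.
    """

    timestamp_s: np.ndarray
    fiducials: dict[str, np.ndarray]        # P_onset, P_peak, Q, R, S, T_onset, T_peak, T_end
    segments: dict[str, np.ndarray]         # keyed by SEGMENTS

    @property
    def n_beats(self) -> int:
        return len(self.timestamp_s)

    def __post_init__(self) -> None:
        order = ("P_onset", "P_peak", "Q", "R", "S", "T_onset", "T_peak", "T_end")
        stacked = np.stack([self.fiducials[k] for k in order])
        if stacked.shape[1] != self.n_beats:
            raise ValueError("fiducial arrays must have one entry per beat")
        if self.n_beats:
            if np.any(np.diff(stacked, axis=0) < 0):
                raise ValueError("fiducials out of order within a beat")
            if np.any(np.diff(self.fiducials["R"]) <= 0):
                raise ValueError("R indices must be strictly increasing across beats")


@dataclass
class SyntheticSession:
    """One generated session: optional rendered trace plus its ground truth."""

    participant: int
    session: str                      # "G" or "NG"
    sampling_rate_hz: float
    truth: GroundTruth
    samples_mV: np.ndarray | None = None


# ---------------------------------------------------------------------------
# single-beat rendering
# ---------------------------------------------------------------------------

def _add_gaussian(out: np.ndarray, fs: float, center_s: float,
                  amplitude: float, width_ms: float) -> None:
    """Add one Gaussian bump to ``out`` in place (support limited to +-5 widths)."""
    if amplitude == 0.0:
        return
    width_s = width_ms / 1000.0
    lo = max(0, int(math.floor((center_s - 5 * width_s) * fs)))
    hi = min(len(out), int(math.ceil((center_s + 5 * width_s) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    out[lo:hi] += amplitude * np.exp(-0.5 * ((t - center_s) / width_s) ** 2)


def generate_beat(morphology: BeatMorphology, rr_ms: float,
                  sampling_rate_hz: float) -> tuple[np.ndarray, dict[str, int]]:
    """Render one cardiac cycle and return (samples, fiducial indices).

    The cycle spans ``rr_ms``; the R peak is placed so the P onset falls at
    the start of the cycle.  Raises ``ValueError`` when ``rr_ms`` is shorter
    than the waveform span.
    """
    span = morphology.span_ms
    if rr_ms <= span:
        raise ValueError(
            f"rr_ms={rr_ms:.1f} ms cannot contain the waveform: "
            f"P onset to T end spans {span:.1f} ms"
        )
    fs = float(sampling_rate_hz)
    n = int(round(rr_ms / 1000.0 * fs))
    out = np.zeros(n)
    # P onset at t ~ 0, with the R peak aligned to the sampling grid
    r_time_s = math.ceil(-morphology.p_onset_ms / 1000.0 * fs) / fs
    for name in WAVES:
        w: WaveShape = getattr(morphology, name)
        _add_gaussian(out, fs, r_time_s + w.offset_ms / 1000.0, w.amplitude_mV, w.width_ms)

    def idx(offset_ms: float) -> int:
        return int(round((r_time_s + offset_ms / 1000.0) * fs))

    fiducials = {
        "P_onset": idx(morphology.p_onset_ms),
        "P_peak": idx(morphology.P.offset_ms),
        "Q": idx(morphology.Q.offset_ms),
        "R": idx(0.0),
        "S": idx(morphology.S.offset_ms),
        "T_onset": idx(morphology.t_onset_ms),
        "T_peak": idx(morphology.T.offset_ms),
        "T_end": idx(morphology.t_end_ms),
    }
    return out, fiducials


# ---------------------------------------------------------------------------
# session-pair generation
# ---------------------------------------------------------------------------

def _participant_morphology(base: BeatMorphology, rng: np.random.Generator,
                            variation: float) -> tuple[BeatMorphology, float]:
    """Draw per-participant morphology and heart-rate factors."""
    def factor(sd: float) -> float:
        return float(np.clip(rng.normal(1.0, sd), 1.0 - 2.5 * sd, 1.0 + 2.5 * sd))

    width_f = factor(variation * 0.5)
    offset_f = factor(variation * 0.5)
    waves = {}
    for name in WAVES:
        w: WaveShape = getattr(base, name)
        amp_f = factor(variation) if name != "R" else factor(variation * 0.5)
        waves[name] = WaveShape(w.amplitude_mV * amp_f, w.width_ms * width_f,
                                w.offset_ms * offset_f)
    hr_factor = factor(variation)
    return BeatMorphology(**waves), hr_factor


def _session_truth(
    morph: BeatMorphology,
    config: SessionConfig,
    rr_base_ms: float,
    rr_jitter: np.ndarray,
    span_jitter: np.ndarray,
    effect: GlucoseEffectProfile | None,
) -> tuple[GroundTruth, list[dict[str, float]]]:
    """Build per-beat geometry and ground truth for one session.

    ``effect=None`` means the control session.  The effect ramp is indexed by
    the unscaled (control-clock) beat time, which keeps the pre-onset window
    of the G session bitwise identical to the control.
    """
    fs = config.sampling_rate_hz
    n_max = len(rr_jitter)
    k = np.arange(n_max)
    resp = config.resp_amplitude_ms * np.sin(
        2 * math.pi * config.resp_freq_hz * k * rr_base_ms / 1000.0)
    rr_ng = rr_base_ms + rr_jitter + resp            # control RR series, ms
    t_nominal_s = config.start_offset_s + np.concatenate(([0.0], np.cumsum(rr_ng)[:-1] / 1000.0))

    if effect is None:
        ramp = np.zeros(n_max)
        rr_mult = 1.0
        gains = dict(qt=1.0, st=1.0, prq=1.0, qrs=1.0, ph=1.0, rh=1.0)
    else:
        ramp = np.asarray(effect.ramp_fraction(t_nominal_s))
        rr_mult = effect.rr_gain / effect.hr_gain
        gains = dict(qt=effect.qt_gain, st=effect.st_gain, prq=effect.prq_gain,
                     qrs=effect.qrs_gain, ph=effect.ph_gain, rh=effect.rh_gain)

    def g(name: str) -> np.ndarray:
        return 1.0 + (gains[name] - 1.0) * ramp

    rr = rr_ng * (1.0 + (rr_mult - 1.0) * ramp)

    # span jitter columns: prq, qrs, st, t-width, r-amp, p-amp
    jit = 1.0 + span_jitter
    prq = -morph.p_onset_ms * jit[:, 0] * g("prq")
    p_width = morph.P.width_ms * jit[:, 0] * g("prq")
    q_off = morph.Q.offset_ms * jit[:, 1] * g("qrs")
    s_off = morph.S.offset_ms * jit[:, 1] * g("qrs")
    st_span = (morph.t_onset_ms - morph.S.offset_ms) * jit[:, 2] * g("st")
    t_width = morph.T.width_ms * jit[:, 3] * g("qt")
    r_amp = morph.R.amplitude_mV * jit[:, 4] * g("rh")
    p_amp = morph.P.amplitude_mV * jit[:, 5] * g("ph")

    t_on = s_off + st_span
    t_center = t_on + ONSET_K * t_width
    t_end = t_center + ONSET_K * t_width
    qrs_span = s_off - q_off
    qt_span = t_end - q_off

    # each beat must fit inside its RR interval: clip extreme jitter draws at
    # the waveform span plus a margin (a refractory floor; applied with the
    # same rule in both sessions, so common-random-number pairing is kept)
    margin_ms = 20.0
    rr = np.maximum(rr, t_end + prq + margin_ms)

    t_r = config.start_offset_s + np.concatenate(([0.0], np.cumsum(rr)[:-1] / 1000.0))
    # the beat count is fixed on the control clock for both sessions of a
    # pair: the effect session contributes the same cardiac cycles (matched
    # by index), merely compressed in time — the paired-design counterpart
    # of the shared random substreams
    n_beats = int(np.searchsorted(
        t_nominal_s + t_end / 1000.0 + margin_ms / 1000.0, config.duration_s))
    if n_beats < 2:
        raise ValueError("session too short to contain two beats")

    sl = slice(0, n_beats)
    t_r = t_r[sl]
    rr_b = rr[sl]

    def to_idx(offset_ms: np.ndarray | float) -> np.ndarray:
        return np.round((t_r + np.asarray(offset_ms)[sl] / 1000.0) * fs).astype(np.int64)

    fiducials = {
        "P_onset": to_idx(-prq),
        "P_peak": to_idx(-prq + ONSET_K * p_width),
        "Q": to_idx(q_off),
        "R": np.round(t_r * fs).astype(np.int64),
        "S": to_idx(s_off),
        "T_onset": to_idx(t_on),
        "T_peak": to_idx(t_center),
        "T_end": to_idx(t_end),
    }

    rr_next = np.concatenate([t_r[1:] * 1000.0 - t_r[:-1] * 1000.0, [np.nan]])
    with np.errstate(invalid="ignore"):
        segments = {
            "RR-I": rr_next,
            "HR": 60000.0 / rr_next,
            "R-H": r_amp[sl],
            "P-H": p_amp[sl],
            "QRS": qrs_span[sl],
            "PRQ": prq[sl],
            "QT": qt_span[sl],
            "QTC": qt_span[sl] / np.sqrt(rr_next / 1000.0),
            "ST": st_span[sl],
        }

    truth = GroundTruth(timestamp_s=t_r, fiducials=fiducials, segments=segments)
    geometry = dict(t_r=t_r, prq=prq[sl], p_width=p_width[sl], p_amp=p_amp[sl],
                    q_off=q_off[sl], s_off=s_off[sl], t_on=t_on[sl],
                    t_width=t_width[sl], r_amp=r_amp[sl])
    return truth, geometry


def _render_trace(morph: BeatMorphology, config: SessionConfig,
                  geometry: dict[str, np.ndarray], noise: np.ndarray) -> np.ndarray:
    fs = config.sampling_rate_hz
    n_samples = int(round(config.duration_s * fs))
    out = np.zeros(n_samples)
    q_amp, s_amp, t_amp = morph.Q.amplitude_mV, morph.S.amplitude_mV, morph.T.amplitude_mV
    q_w, s_w = morph.Q.width_ms, morph.S.width_ms
    g = geometry
    for i in range(len(g["t_r"])):
        t_r = g["t_r"][i]
        _add_gaussian(out, fs,
                      t_r - g["prq"][i] / 1000.0 + ONSET_K * g["p_width"][i] / 1000.0,
                      g["p_amp"][i], g["p_width"][i])
        _add_gaussian(out, fs, t_r + g["q_off"][i] / 1000.0, q_amp, q_w)
        _add_gaussian(out, fs, t_r, g["r_amp"][i], morph.R.width_ms)
        _add_gaussian(out, fs, t_r + g["s_off"][i] / 1000.0, s_amp, s_w)
        _add_gaussian(out, fs,
                      t_r + g["t_on"][i] / 1000.0 + ONSET_K * g["t_width"][i] / 1000.0,
                      t_amp, g["t_width"][i])
    if config.noise_sd_mV > 0:
        out += noise
    return out


def generate_session_pair(
    config: SessionConfig,
    effect: GlucoseEffectProfile,
    participant_seed: int,
    morphology: BeatMorphology | None = None,
    render_trace: bool = True,
    participant: int = 0,
) -> tuple[SyntheticSession, SyntheticSession]:
    """Generate the (G, NG) session pair for one participant.

    Both sessions share the participant's morphology and all random
    substreams; the G session additionally applies the effect profile.  Fully
    reproducible from ``(participant_seed, config.random_seed)``.  With
    ``render_trace=False`` only ground truth is produced (fast path for
    cohort-scale statistics).
    """
    base = morphology if morphology is not None else BeatMorphology.default()
    ss = np.random.SeedSequence([int(participant_seed) % (2 ** 31),
                                 int(config.random_seed) % (2 ** 31)])
    morph_ss, physio_ss, noise_ss = ss.spawn(3)
    morph, hr_factor = _participant_morphology(
        base, np.random.default_rng(morph_ss), config.participant_variation)

    rr_base = 60000.0 / (config.baseline_hr_bpm * hr_factor)
    rr_floor = rr_base * min(1.0, effect.rr_gain / effect.hr_gain)
    n_max = int(config.duration_s * 1000.0 / (rr_floor * 0.8)) + 32

    physio = np.random.default_rng(physio_ss)
    rr_jitter = physio.normal(0.0, config.hrv_sd_ms, n_max)
    span_jitter = physio.normal(0.0, config.span_jitter_frac, (n_max, 6))

    truth_ng, geom_ng = _session_truth(morph, config, rr_base, rr_jitter,
                                       span_jitter, None)
    truth_g, geom_g = _session_truth(morph, config, rr_base, rr_jitter,
                                     span_jitter, effect)

    samples_g = samples_ng = None
    if render_trace:
        n_samples = int(round(config.duration_s * config.sampling_rate_hz))
        noise = (np.random.default_rng(noise_ss).normal(0.0, config.noise_sd_mV, n_samples)
                 if config.noise_sd_mV > 0 else np.zeros(n_samples))
        samples_g = _render_trace(morph, config, geom_g, noise)
        samples_ng = _render_trace(morph, config, geom_ng, noise)

    fs = config.sampling_rate_hz
    return (
        SyntheticSession(participant, "G", fs, truth_g, samples_g),
        SyntheticSession(participant, "NG", fs, truth_ng, samples_ng),
    )


def generate_cohort(
    n_participants: int,
    config: SessionConfig,
    effect: GlucoseEffectProfile,
    master_seed: int = 0,
    render_trace: bool = False,
) -> list[tuple[SyntheticSession, SyntheticSession]]:
    """Generate one (G, NG) pair per participant, deterministic in ``master_seed``.

    Participant seeds are spawned from the master seed, so cohorts of
    different sizes share their leading participants.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    seeds = participant_seeds(n_participants, master_seed)
    return [
        generate_session_pair(config, effect, seed, render_trace=render_trace,
                              participant=i + 1)
        for i, seed in enumerate(seeds)
    ]


def participant_seeds(n: int, master_seed: int) -> list[int]:
    """Deterministic per-participant seeds derived from a master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(int(master_seed) % (2 ** 31)))
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]
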