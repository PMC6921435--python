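# Methods

`ecgdelta` implements a paired-session analysis of nine per-beat ECG segment
series, asking which of them respond when a participant ingests 75 g of
glucose (an oral glucose tolerance test) compared with a matched control
session.  The pipeline has four stages — delineation, paired boxplot-delta
statistics, Welch spectral comparison, and cohort scoring — plus a synthetic
paired-session generator that provides ground truth for every stage.

## The nine segments

For each retained beat the package derives, from the P/Q/R/S/T landmarks:

| id    | meaning                                   | units |
|-------|-------------------------------------------|-------|
| RR-I  | RR interval (the HRV series)              | ms    |
| HR    | heart rate, 60000 / RR-I                  | bpm   |
| R-H   | signal height at the R peak               | mV    |
| P-H   | signal height at the P peak               | mV    |
| QRS   | Q-to-S span                               | ms    |
| PRQ   | P-wave onset to R peak                    | ms    |
| QT    | Q to T end                                | ms    |
| QTC   | QT corrected for rate (Bazett, QT/√RR_s)  | ms    |
| ST    | S wave to T onset                         | ms    |

Bazett is used for QTC because it is the default clinical correction; the
heights are raw signal values at the peak (baseline subtraction is an
option, off by default).  ST here is an interval (S to T onset), not the
clinical ST-elevation amplitude.

## Synthetic paired sessions

Each cardiac cycle is a sum of five Gaussian bumps with per-wave amplitude,
width and center offset from R.  Wave onsets/ends are defined at the 5%
amplitude crossing, `center ± k·width` with `k = √(2 ln 20) ≈ 2.448` — the
same 5%-return-to-baseline rule the delineator applies, so delineation
accuracy can be judged against analytic truth.

Per session, the RR series is a participant baseline plus i.i.d. Gaussian
beat-to-beat jitter (`hrv_sd_ms`, default 25 ms) plus a respiratory
sinusoidal modulation (15 ms at 0.25 Hz, phased on the beat index so the
modulation is a clean oscillation in the beat domain the spectra operate
on).  Wave-geometry spans get 1% multiplicative per-beat jitter.  Additive
white Gaussian measurement noise (default 0.02 mV) is applied to the
rendered trace; baseline wander is not modelled.

Defaults mirror the emulated protocol: 120-min sessions (7200 s), 500 Hz
sampling (typical for laboratory ECG hardware), resting heart rate 66 bpm
(≈ 7900 cycles per session, the scale of the recordings being emulated,
with ±6% per-participant variation), glucose effect onset 30 min into the
G session with a 10-min linear ramp to a sustained plateau.  The blood
glucose excursion itself peaks and declines in reality, but the analysis
scores only the *direction* of change, so a sustained effect is sufficient.

The effect is multiplicative on generator primitives: RR is scaled by
`rr_gain / hr_gain` (the two knobs describe the same physiological effect
from either side), the PRQ / QRS / ST spans and the T-wave duration by
their gains, and the P / R amplitudes by theirs.  QT = QRS + ST + T-span,
so it responds jointly to the `qrs`, `st` and `qt` gains — the spans are
the independent primitives, and scaling overlapping intervals separately
would be inconsistent.  Default gains model a mild response: HR +10 %,
RR/QT/ST/PRQ shortened by 5–10 %, amplitudes unchanged.  The magnitudes
are free parameters; no published calibration exists for them.  Extreme
RR jitter draws are clipped at the waveform span plus 20 ms, a refractory
floor applied identically in both sessions.

### The paired design (common random numbers)

The two sessions of a pair share the participant morphology *and all random
substreams*: beat-to-beat jitter, span jitter and trace noise are identical
arrays, the beat count is fixed on the control clock (both sessions contain
the same cardiac cycles, matched by index; the glucose session is merely
compressed in time), and the effect is a deterministic multiplier ramp on
top.  Consequences:

* with all gains at 1, the G and NG outputs are **bitwise identical** — any
  downstream difference is attributable to the injected effect alone, and a
  null cohort produces exact ties (direction E) everywhere;
* segments whose generator primitives are untouched by the effect tie
  exactly even when other segments change.

This is the matched-pairs ideal: the generator does **not** emulate
day-to-day physiological variability between a participant's two sessions.
Real paired recordings carry that extra between-session noise, which is why
published cohort percentages sit near 81% where this synthetic pipeline
under a sustained effect produces 100%.  Passing tests therefore show the
pipeline recovers directions correctly when a direction exists; they do not
quantify its power against realistic session-to-session variability.

A second consequence of scoring whole sessions: QTC responds *indirectly*
to an RR effect.  With RR shortened 10–18% and QT ~4–5%, Bazett's √RR
denominator shrinks faster than QT, so QTC rises consistently.  End-to-end
tests therefore constrain only the truly untouched segments (QRS, R-H, P-H)
to show no change.

## Delineation

R peaks: band-pass 5–15 Hz (2nd-order Butterworth, zero-phase),
differentiate, square, 150-ms moving-window integration, adaptive
signal/noise threshold with a 200-ms refractory period, then refinement to
the raw-signal maximum within ±75 ms.  Landmarks per beat: Q and S are the
local minima nearest R within 80 ms; the P peak is the maximum in
(R−250 ms, R−80 ms), the T peak the maximum in (R+120 ms,
R+min(450 ms, 0.7·RR)); onsets/ends walk outward from a peak until the
signal returns within 5% of the local baseline (median of the PR segment,
R−90 to R−50 ms — the classical isoelectric reference; a whole-beat median
is biased upward by T/P wave mass).  All window constants are
configuration.  Boundary beats and beats with failed Q/S/T searches are
dropped and counted; a P wave below 0.02 mV is declared absent, removing
that beat from the P-dependent series (P-H, PRQ) only.

Cleaning removes impossible values (HR outside 20–250 bpm, non-positive
intervals) and values beyond 5 scaled MADs (1.4826·MAD, the
Gaussian-consistent scale, ≈ 7.4 σ) of the session median; MAD = 0 skips
the outlier rule; removing > 20% of beats triggers a logged warning.  The
σ-consistent scale keeps the rule from clipping the tails of clean
multi-thousand-beat sessions.

On noise-free synthetic sessions every fiducial is recovered within ±5 ms
(measured: within ±1 sample at 500 Hz) and every interval series within
2 sample periods of ground truth.

## Paired statistics

Per segment and session: mode, mean, median, quartiles (linear
interpolation between order statistics, Q1 at rank 1+(n−1)/4) and the
interquartile range; minima/maxima are deliberately not used.  The mode is
computed on a rounding grid (1 ms for intervals, 1 bpm for HR, 0.01 mV for
heights) because a mode on continuous data is otherwise ill-defined.  The
six scored deltas are glucose-minus-control mode, mean, median, Q3, Q1 and
the interquartile difference ΔQ = IQ_G − IQ_NG.  Directions: I if the
delta exceeds +1e−9 in native units, D below −1e−9, E otherwise — the band
is reachable only by exact ties, which the paired generator produces by
construction under the null.

Inter-segment dependence within the glucose session is the Pearson
product-moment coefficient over beats retained in both series (aligned by
beat index), classified P/N/Z with the same tolerance; the cohort
percentage of P (or N) participants is reported per pair over the cross
matrix {ST, QTC, QT} × {PRQ, QRS, P-H, R-H, RR-I, HR}.

## Spectral comparison

Welch's method with rectangular windows: frames of M = 256 at step
M − overlap (overlap 10), per-frame periodogram |DFT|²/M, averaged, folded
one-sided.  The nominal beat-domain sampling frequency (default 0.8) only
scales the frequency axis; peak ordering is unaffected.  The series mean is
subtracted first and the DC bin is excluded from the peak H(S) — segment
series carry large constant offsets (RR ≈ 800 ms) whose DC leakage would
otherwise dominate every peak, and the mean level is already compared by
the statistics stage.  Both behaviours are switches (`subtract_mean`,
`include_dc_in_peak`).  Trailing samples that do not fill a frame are
discarded.  Directions compare H(S_G) against H(S_NG) with a 1e−9 relative
band.

Note that under a sustained RR effect the mean-subtracted G series contains
a large onset step, so its low-frequency peak *rises* even as the RR level
falls: spectral directions reflect oscillatory/transient content, not the
level shift, and need not match the statistical directions.

## Cohort scoring

Per segment × parameter, the cohort direction percentages (counting E in
the denominator) feed the status bands h (≥ 80%), m (60–80%), l (rest),
boundaries inclusive as stated.  Percentages are reported rounded half-up
to integers; classification uses unrounded values.  The statistical change
decision counts m/h statuses across the six parameters (each parameter's
dominant change direction; I and D cannot both reach 60%, so the maximum
score is 6) and declares a segment affected at ≥ 4.  The spectral decision
declares a segment affected when its dominant change direction reaches 60%
of the cohort.  Sensitivities S_h/S_m/S_l are the shares of each status
label within a pattern's statuses, rounded half-up to one decimal.  A tie
between increase and decrease reports decrease first, matching the
convention of the published tables this layer reproduces.

## Problem sizes

Tests and the acceptance script use: full-scale cohorts (16 participants,
120-min sessions, ≈ 7900 beats/session) for end-to-end direction recovery,
generated through the segment-series fast path (no trace rendering); a
noise-free 10-min 500 Hz rendered session for delineation accuracy; and
15–30-min sessions with proportionally earlier onsets for pipeline
plumbing tests.  These sizes were chosen so the full suite and the
acceptance script each run in well under a minute of compute per stage
while exercising the same code paths as a full run.

## Known limitations

* No arrhythmia, ectopy, baseline wander or electrode-artifact modelling;
  the delineator assumes sinus rhythm with one R per cycle.
* Between-session physiological variability is not simulated (see the
  paired-design section); synthetic cohort percentages are therefore
  saturated relative to real cohorts.
* The mode depends on the rounding grid; published analyses rarely state
  theirs.
* Bazett's correction over-corrects at shortened RR; QTC conclusions depend
  on the correction formula, which is configurable only by replacing the
  extraction step.
* Spectral peak comparison is sensitive to nonstationarity (the onset
  step); it answers "did the dominant oscillation change", not "did the
  level change".
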