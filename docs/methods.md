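# Methods

## The extraction model

The target quantity is the end-expiratory transpulmonary pressure
P_Lee = P_aw − P_es at a prescribed (set) PEEP.  The extraction assumes:

- the monitor exports a uniformly sampled multichannel recording (time,
  flow, volume, P_aw, P_es, P_L, …) whose P_L column equals
  P_aw − P_es (when P_L was not exported it is derived from those two
  channels, and the path taken is logged);
- at end-expiration the airway pressure sits near the **set** PEEP and
  flow is approximately zero.  Set PEEP, not measured/intrinsic PEEP,
  parameterises the window because P_Lee is reported per protocol PEEP
  step, which is how the quantity is used in research practice;
- disturbances (oesophageal contractions, surgical manipulation, cursor
  artifacts) are sparse relative to the recording, so a robust fence +
  median suppresses them without modelling them.

The pipeline is: trim to the experiment window → keep samples with
|P_aw − set PEEP| ≤ paw_margin **and** |flow| ≤ flow_margin → remove P_L
values strictly outside Tukey's fences [Q1 − k·IQR, Q3 + k·IQR] → median.
Each stage only discards samples, so the audit counts
(n_total ≥ n_after_trim ≥ n_endexp ≥ n_retained) are monotone by
construction and reported with every result.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| paw_margin | 1 | cmH₂O | absorbs measurement variation around the set PEEP; PEEP steps 5 cmH₂O apart stay disjoint |
| flow_margin | 10 | L/min | "flow approximately zero" with room for sensor noise; excludes active in/expiration |
| tukey_k | 1.5 | — | the conventional fence multiplier; robust for multiple outliers |
| plateau_offset | 2 | cmH₂O | inspiratory-hold filter P_aw > set PEEP + offset for P_Lplat |
| min_samples | 10 | count | below this a low-sample warning is logged (result still returned) |
| quartile_method | linear | — | see numerical choices |

Filter bounds are inclusive (a sample at exactly 16 cmH₂O passes the
PEEP-15 window; a flow of exactly ±10 L/min passes); the fences are
exclusive (only values strictly outside are removed).  The original
wording ("between", "around zero") does not settle inclusivity; ties sit
exactly on the boundary with probability ~0 on real signals, so the
choice is made once and documented rather than exposed.

Tukey removal runs in a single pass: the fences are computed once on the
input and never recomputed on the survivors.  Iterating to convergence
would remove progressively more of a heavy-tailed but clean distribution.

## Numerical choices

- **Quartiles.**  Linear interpolation between order statistics (the
  default of most numerical environments).  A `quartile_method="hinges"`
  switch offers Tukey's hinges; on recordings of thousands of samples the
  difference is far below the 0.1 cmH₂O reporting precision.
- **Median.**  Even-count medians are the mean of the two middle values.
- **Reporting precision.**  The output table rounds to one decimal;
  downstream arithmetic (driving pressure, method comparison) uses full
  precision.  DrivingPressureResult computes Δ P_L = P_Lplat − P_Lee as
  an exact difference of the stored full-precision medians.
- **Experiment end.**  The CRF carries only `datastart`; an optional
  `dataend` defaults to the end of the recording.
- **Corrupt time stamps.**  A cell that loses its decimal separator in
  export still parses as a number but jumps off the sampling grid.  The
  parser flags any sample whose step from the last accepted sample is not
  positive or exceeds 10 grid intervals: an error by default (a corrupt
  stamp may indicate an acquisition fault worth investigating), dropped
  with a warning under `coerce=True`.  Silent correction is deliberately
  not offered.
- **Dialect detection.**  `decimal_separator="auto"` inspects the first
  rows: any comma-bearing numeric token (and none mixing comma and dot)
  selects the comma dialect.  Blank cells parse to NaN — the parser never
  invents values.

## Catheter check

Δ values are peak-to-trough amplitudes of P_es and P_aw within a
user-chosen occlusion window (≥ 0.5 s); position is acceptable when
ΔP_es/ΔP_aw ∈ [0.8, 1.2], bounds inclusive.  Whether the original
workflow read Δ off the monitor cursor or computed amplitudes is not
determinable, so a `method="regression"` alternative (slope of P_es on
P_aw) is provided for sensitivity analysis; on noise-free scaled signals
both give the same ratio.  Airway swings below 1 cmH₂O mean no usable
occlusion and raise instead of returning a meaningless ratio.
Automatic detection of the occlusion window is out of scope.

## Cardiac filter

Cardiac motion oscillates P_es but not pleural pressure, so the
oscillation is removable artifact.  The filter zeroes the FFT bins within
`notch_halfwidth_hz` (default 0.15 Hz) of each of the first
`n_harmonics` (default 3) multiples of the heart rate and transforms
back.  A comb of narrow notches is used rather than a low-pass because
respiratory harmonics and the cardiac fundamental can interleave; the
half-width absorbs ordinary heart-rate variability.

The transform runs on the **unpadded** signal, making the filter an exact
orthogonal projection: idempotent, linear, and mean-preserving to machine
precision.  Mirror-padding before the transform was considered to
suppress edge leakage, but pad-filter-crop is not a projection — the
boundary mismatch on refiltering leaves residue orders of magnitude above
the 1e-6 cmH₂O tolerance this package holds the filter to — so leakage
control is left to the notch width instead.  Note the projection removes
*whatever* occupies the notch band, including respiratory harmonics that
genuinely fall there.

Heart-rate estimation (when no rate was recorded): subtract a moving mean
over one respiratory period (estimated from the dominant sub-cardiac
spectral peak), drop one window length at each end where the moving mean
is unreliable, Hann-window, and take the largest spectral peak in the
physiologic band (0.67–3 Hz ≈ 40–180 bpm).  The peak must stand ≥ 3× the
median in-band power **and** imply an oscillation ≥ 0.1 cmH₂O — an
absolute floor, since a relative test alone latches onto numerical
residue when no cardiac component exists.  Peaks sitting on a multiple of
the respiratory fundamental are not candidates: a heart rate coinciding
with a respiratory harmonic is spectrally unidentifiable and must be
supplied by the caller (estimation then fails loudly rather than
guessing).

## Method-comparison statistics

Pearson r with a Fisher z-transform CI (tanh(atanh r ± z₍α₎/√(n−3));
degenerate |r| = 1 collapses the interval to a point).  Bland–Altman bias
is the mean of (method A − method B) differences — A the manual
reference, B the scripted extraction, so a positive bias means manual
reads higher — with the SD of differences on the n−1 denominator and
limits of agreement at the conventional exact ±1.96 SD (not a
t-quantile).  The Fisher interval's small-sample coverage is verified by
simulation (93–97% at ρ = 0.9, n = 15) in the test suite.

## The simulator

`ventsim` emulates what the extraction needs from a real recording:

- single-compartment mechanics, P_aw = PEEP + (E_L + E_cw)·V + R·V̇.
  Volume control delivers constant inspiratory flow with passive
  exponential expiration (τ = R/(E_L + E_cw)); pressure control applies a
  square driving pressure.  Because expiration is passive, P_aw sits at
  PEEP throughout expiration and flow decays toward zero — exactly the
  window the filters select.  Residual volumes below 1 mL are clamped to
  zero, so each breath ends with true zero-flow samples, volume is
  conserved breath-to-breath, and at relaxed end-expiration
  P_L ≡ set PEEP − P_es baseline, the generator's ground truth;
- an optional end-inspiratory hold (`pause_fraction`) produces genuine
  plateau samples for driving-pressure work;
- P_es carries the chest-wall component E_cw·V, a cardiac sinusoid with
  seeded random phase, optional artifacts (raised-cosine oesophageal
  contraction; rectangular surgical step), and white Gaussian noise;
  P_aw and flow carry independent noise of the same SD.  P_L is computed
  as P_aw − P_es after everything, preserving the export identity.

Defaults describe an anaesthetized, paralysed, normal-weight adult:
tidal volume 500 mL, 12 breaths/min, I:E 1:2, E_L 12 and E_cw 8 cmH₂O/L,
R 10 cmH₂O/(L/s), P_es baseline 5 cmH₂O, cardiac oscillation 2 cmH₂O at
72 bpm, noise 0.3 cmH₂O, 7 min per PEEP level at 256 Hz.  Exported
projects vary oesophageal baseline (2–8 cmH₂O), airway resistance
(8–10 cmH₂O/(L/s)) and heart rate (60–90 bpm) across participants from
seeded child generators; a fixed seed reproduces the file tree
bit-for-bit.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: spontaneous breathing effort, heart-rate
variability (the cardiac component is a fixed-frequency sinusoid; with
the default 72 bpm it phase-locks to the 12/min breath, the worst case
for the median and the case where the cardiac filter helps most),
non-sinusoidal cardiac waveforms, oesophageal balloon calibration errors,
Trendelenburg/abdominal-pressure mechanics, leaks, and drift.  Real P_Lee
accuracy also depends on catheter position and balloon filling, which are
physical, not computational, matters.

A known systematic of the method itself, visible on noise-free
simulations: the ±10 L/min flow window admits late-expiratory samples
where the chest wall is not fully relaxed, biasing the median low by up
to ~E_cw·τ·(10/60) ≈ 0.05 cmH₂O at the default mechanics — half the
reporting resolution, and inherent to the window definition rather than
to this implementation.

## Problem sizes

End-to-end checks run at the study's own geometry: 5 participants × PEEP
15/10/5 × 7 min at 256 Hz (≈ 1.6 M samples per run).  Unit tests use
30–60 s segments, which already contain enough breaths for every
property; the brute-force oracle comparison uses 100 random recordings of
up to 1000 samples, where an exhaustive per-sample reimplementation is
practical.

## Known limitations

- PEEP levels are user inputs; the package does not detect PEEP steps
  from the P_aw trace, and a wrong level yields a no-end-expiration
  error, not a silent wrong answer.
- No breath segmentation: the median pools all end-expiratory samples in
  the window rather than summarising per breath.
- The cardiac filter needs the heart rate (recorded or estimable); with
  the rate on a respiratory harmonic, estimation refuses and the rate
  must be given.
- The file parser targets the signals export; the separate parameters
  export and CO₂-derived computations are out of scope.
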