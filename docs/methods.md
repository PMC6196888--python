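# Methods

## Problem

Pulse transit time (PTT) — the delay between the ECG R-wave and a
distal pulse landmark on the PPG within the same cardiac cycle — is the
workhorse of cuff-less blood-pressure estimation.  Calibrated models of
the form `BP = K1/PTT + K2` track the fast, mechanically driven
high-frequency (HF, 0.2–0.35 Hz) component of beat-to-beat BP well, but
fail on the autonomically mediated low-frequency (LF, 0.1–0.15 Hz)
component.  This package implements, end to end, the analysis that
attributes that failure to arterial-baroreflex (ABR) regulation: when
the reflex is sensitive, slow LF pressure ramps drive large heart-rate
ramps (high HRV), and HRV perturbs PTT independently of pressure, so
PTT stops encoding LF-BP.  The pipeline quantifies the effect as the
within-subject correlation between band-wise estimation error and
dynamic baroreflex sensitivity (BRS), compared between LF and HF bands
across a cohort.

Because the original recordings are not publicly deposited, the cohort
is synthetic: a beat-domain cardiovascular simulator with full ground
truth stands in for the 42-subject study, and the pipeline's claims are
validated as properties (oracle equivalence, parameter recovery, and
qualitative replication of the LF-vs-HF contrast) rather than as
numeric reproductions of the published correlation coefficients.

## Simulator

Beat-domain first.  At each beat time `t`:

- SBP(t) = baseline + A_LF·sin(2π f_LF t + φ_LF) + A_HF·sin(2π f_HF t + φ_HF) + ε,
  with ε white Gaussian device noise (the Finapres reading), and the
  noise-free part being the true arterial pressure.  DBP is SBP minus a
  pulse-pressure process: the same oscillators scaled by
  `dbp_amp_scale` (default 0.6) about a lower baseline, so SBP > DBP by
  construction.  Phases are drawn uniformly per subject.
- Heart rate follows the logistic ABR curve
  `HR(P) = HR_l + (HR_h − HR_l)/(1 + exp(−ε_ABR (P − P_n)))` evaluated
  on the true oscillatory pressure; RRi = 60000/HR advances the beat
  clock.  The curve is implemented exactly as written, with a *signed*
  slope parameter: the classical reflex (HR falls as BP rises, so RRi
  and SBP ramp in the same direction — the premise of the sequence
  method) corresponds to negative ε_ABR, which is the orientation the
  cohort generator applies to the drawn sensitivity magnitude.
- PTT = K1/(P_eff − K2) + g·ΔHR_slow + jitter, where P_eff is the true
  systolic pressure plus a pressure-equivalent vasomotor disturbance
  (same SD as the device noise), ΔHR_slow is the beat-to-beat increment
  of the *slow-arm* reflex response HR(baseline + LF term), and
  g = `hrv_ptt_gain` ≤ 0 is the HRV→PTT coupling.  Optional Gaussian
  timing jitter (`ptt_noise_sd`, ms) is off by default at beat level:
  timing noise enters physically when PTT is re-measured from rendered
  waveforms.

Two design points deserve emphasis, both fixed before any cohort-level
testing and both physiological rather than free dials:

1. **Which pressure drives HR.**  RRi must be beat-to-beat coherent
   with both LF and HF pressure oscillations, because the windowed
   sequence method estimates BRS from *within-window* covariation of
   dRRi and dSBP; if HR tracked only the slow component, dRRi would be
   nearly constant inside every 16-beat window and the estimator would
   return noise around zero.  The HF coherence is the respiratory
   (vagal/RSA) arm of heart-rate control.
2. **Which heart-rate changes perturb PTT.**  Only the slow (LF,
   sympathetically timed) HR ramps feed the PTT perturbation.  This is
   the mechanism under study — fast vagal RSA does not re-tone the
   arterial wall — and it is what makes the injected estimation failure
   specific to the LF band, growing with the ABR sensitivity.

### Session structure

The default subject is one continuous recording.  The cohort generator
emulates the study protocol: two recordings per subject
(`n_segments=2`, default 10 min each, separated by an unrecorded
exercise gap), with the post-exercise segment shifted by
`post_shift` mmHg (10–25) in SBP (DBP follows with the same 0.6
scaling), `post_hr_shift` bpm (10–20) of central-command tachycardia,
and partial baroreflex resetting: the set point `P_n` follows half the
pressure shift (`baroreflex_reset = 0.5`).  Resetting is the
established description of exercise baroreflex behaviour; its fraction
controls how much the post-exercise operating point slides down the
logistic slope, and 0.5 leaves a clear pre/post BRS contrast while
keeping post-exercise heart rate in a realistic range.  This
within-subject BRS contrast is what the error-vs-BRS correlations feed
on; single-segment cohorts have almost no within-subject BRS variation
and correspondingly null correlations.

### Cohort ranges (study conditions)

Per-subject uniform draws: sensitivity magnitude 0.05–0.5 /mmHg,
HR range 50–65 to 90–110 bpm, resting SBP 110–130 mmHg with `P_n`
within ±5 mmHg of it, pulse pressure 35–50 mmHg, A_LF 2–5 mmHg,
A_HF 1.5–4 mmHg, f_LF 0.10–0.15 Hz, f_HF 0.20–0.35 Hz,
K1 20000–40000 mmHg·ms, K2 0–30 mmHg, g −1.5 to −0.5 ms/bpm, device
noise 0.5–1.5 mmHg.  These give PTT ≈ 130–500 ms and LF-band BP
oscillations of a few mmHg — the scales seen in resting human
recordings.

### Waveform rendering

ECG is a Gaussian R-template (SD 8 ms) at each beat time; PPG is a
raised-cosine upstroke (80 ms) whose midpoint — the maximal first
derivative — lags the R-wave by exactly the beat's PTT, followed by an
exponential decay; the BP channel attains SBP/DBP as its per-cycle
max/min.  Landmark sample indices are stored, so the fiducial
extractors can be scored against exact truth.  The renderer does not
model P/T waves, dicrotic notches, respiration-induced amplitude
modulation, or motion artifacts; waveform-level tests therefore
validate timing logic, not robustness to real-world morphology.

## Extraction

ECG: 0.5–35 Hz, PPG: 0.05–10 Hz, both 4th-order Butterworth applied
forward-backward (zero phase, so fiducial timing is unshifted).
R-peaks: derivative-energy detector (smoothed squared derivative,
adaptive threshold at 0.3× the median candidate height, 250 ms
refractory, apex refinement within ±50 ms).  PPG landmarks per RR
window [R_i, R_{i+1}): pulse foot (minimum), maximal first derivative
(Savitzky–Golay smoothed), and peak — giving PTT3 ≤ PTT2 ≤ PTT1; PTT2
is the default variant.  SBP/DBP are the BP channel's max/min in the
window.  Quality gates drop beats with PTT outside 50–600 ms or RRi
outside 300–2000 ms, logged with reasons; the final beat (no complete
window) is always dropped.

## Calibration

`BP = K1·x + K2` with x = 1/PTT (default) or ln PTT, solved per subject
and per target (SBP, DBP) by the closed-form normal equations over the
full recording.  "Adaptive" retraining is interpreted as this single
per-subject fit; a sliding recalibration was considered and rejected as
under-specified.

## Band decomposition

Beat series are unevenly sampled, so each series is cubic-spline
interpolated onto a 4 Hz grid, mean-removed, and decomposed by
variational mode decomposition (VMD): K = 5 modes, bandwidth penalty
α = 2000, uniform center-frequency initialization, tolerance 1e-7,
≤ 500 iterations, mirror extension of half the signal length on each
side.  The ADMM solver alternates spectral-domain Wiener updates of
each mode with power-weighted center-frequency updates.  The dual
ascent step τ is 0 by default — the noise-robust setting, which leaves
unmodelled content (including boundary transients) in the residual —
and τ = 1 enforces near-exact reconstruction for clean synthetic
signals; tests of reconstruction fidelity use the latter, the pipeline
the former.  LF/HF components are the sums of modes whose center
frequencies fall in [0.10, 0.15] / [0.20, 0.35] Hz; modes between the
bands belong to neither; an empty band yields zeros with a warning.
Band series are spline-mapped back to beat times so errors are
per-beat.

## BRS

First-order forward differences of RRi (ms) and SBP (mmHg); a 16-point
window sliding by one beat; within each window, pairs with
dRRi < 0 ∧ dSBP < 0 and pairs with dRRi > 0 ∧ dSBP > 0 are regressed
(OLS slope of dRRi on dSBP) separately and the two slopes averaged.
Zero differences join neither set.  A quadrant with fewer than two
pairs (or zero dSBP variance) is skipped; if both are degenerate the
window is invalid (NaN, flagged).  The BRS value is indexed to the
window's first beat.

## Cohort statistics

Six error series per subject (estimate − reference; overall, LF, HF ×
SBP, DBP).  Each valid BRS window is paired with the error at its
start-beat index; segments are processed separately (they are disjoint
recordings) and pooled per subject before correlating.  Pearson r per
(error × BRS) group; cohort criteria are the mean μ, the population SD
(divisor N), and the minimum absolute value (MAV) over subjects; LF vs
HF groups are compared with a pooled two-sample t-test, SBP and DBP
separately, with no multiple-testing correction.

Signed vs absolute error: the correlation is computed on signed error
by default, matching the error definitions as written.  The headline
LF-vs-HF replication, however, uses |error| (`abs_error=True`): the
mechanism couples BRS to the *amplitude* of the LF error, while the
signed LF error is a zero-mean oscillation whose phase carries no BRS
information — its correlation with a slowly varying BRS is structurally
≈ 0 regardless of coupling strength.  Uniformly positive, tight
per-subject LF correlations are only possible under a magnitude-type
association, which is what the absolute convention measures.

## What the synthetic tests do and do not show

Passing cohorts demonstrate that the pipeline (i) recovers every
component quantity it is supposed to recover (fiducials to < 2 ms,
calibration parameters to machine precision on clean data, band
components against both ground truth and an independent band-pass
oracle, BRS against a brute-force oracle), and (ii) reproduces the
qualitative headline — LF error correlates with BRS, HF error does not
— if and only if the HRV→PTT coupling is present (uncoupled null
cohorts show no contrast).  They do not certify performance on real
recordings: the simulator has stationary sinusoidal variability, white
noise, no respiration or motion artifacts, no pre-ejection-period
component in PTT, and idealized waveform morphology.

## Numerical choices and degenerate inputs

- Resampling at 4 Hz resolves the HF band (Nyquist 2 Hz) with margin;
  grids below 0.7 Hz are rejected.
- VMD requires K ≥ 2 and ≥ 16 samples; non-convergence returns a
  flagged result with a warning rather than raising.
- Calibration raises on constant PTT (rank-deficient design) and
  nonpositive PTT.
- pearson_r requires ≥ 3 pairs and nonzero variances; the t-test
  special-cases zero pooled variance (t = 0, p = 1 for equal means).
- Subjects failing any stage (too few beats, all-invalid BRS windows)
  are excluded with a logged reason; the cohort analysis requires ≥ 2
  survivors.
- Analysis problem sizes: the numbered scripts default to the full
  protocol (two 10-min segments per subject); the test suite and the
  acceptance script run the same cohorts at two 5-min segments, which
  preserves every mechanism at roughly half the beat count.

## Known limitations

- The logistic ABR curve is static; real baroreflex gain is dynamic
  and frequency-dependent.  The split into an HF-coherent RRi arm and
  an LF-only PTT-perturbing arm is the minimal structure that exposes
  the mechanism, not a validated transfer-function model.
- Exercise effects are reduced to three numbers (pressure shift, HR
  shift, reset fraction); recovery transients are not modelled.
- The BRS estimator's absolute scale is attenuated relative to the
  analytic curve slope (regression dilution from HF and noise in
  dSBP); comparisons across subjects and segments remain valid because
  the attenuation is common-mode.
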