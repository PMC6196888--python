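# pttbp

Why does cuff-less blood-pressure estimation from pulse transit time
(PTT) fail in the low-frequency band?  This package implements the full
analysis pipeline behind that question — PTT/RRi/SBP/DBP extraction
from ECG+PPG+BP waveforms, `BP = K1/PTT + K2` calibration, variational
mode decomposition (VMD) into LF (0.1–0.15 Hz) and HF (0.2–0.35 Hz)
blood-pressure variability bands, dynamic baroreflex sensitivity (BRS)
by the sliding-window sequence method, and cohort-level correlation
statistics — together with a synthetic cardiovascular cohort simulator
that provides ground truth for every stage.

It is written for physiological-signal researchers who want to study
the interaction between arterial-baroreflex (ABR) regulation and
PTT-based BP estimates, or to reuse any stage (fiducial extraction,
VMD, sequence-method BRS) on their own beat series.

## The model

Heart rate responds to arterial pressure through a logistic ABR curve

    HR(P) = HR_l + (HR_h − HR_l) / (1 + exp(−ε (P − P_n)))

whose slope parameter ε is the subject's baroreflex sensitivity
(classical orientation: HR falls as BP rises).  Transit time follows
the inverse calibration model perturbed by heart-rate variability,

    PTT = K1 / (SBP − K2) + g · ΔHR_slow,      g ≤ 0,

where ΔHR_slow is the beat-to-beat increment of the reflex response to
the slow (LF) pressure component.  Because the perturbation scales with
the reflex slope, subjects and episodes with sensitive baroreflexes
accumulate LF-band estimation error, while the HF band — where PTT
genuinely tracks pressure — stays clean.  The pipeline quantifies this
as per-subject Pearson correlations r between band-wise estimation
error and dynamic BRS, summarized per group by the mean μ, population
SD, and minimum absolute value (MAV), with LF-vs-HF two-sample
t-tests.

BRS itself is estimated by the time-domain sequence method: over
16-beat sliding windows, the OLS slope of dRRi on dSBP among
same-direction pairs (both differences negative, or both positive),
averaged over the two quadrants (ms/mmHg).

## Worked example

Simulate the 42-subject study cohort (two 10-minute recordings per
subject, pre/post exercise) and run the staged analysis:

    python analysis/01_simulate_cohort.py --seed 0
    python analysis/02_waveform_roundtrip.py --seed 0
    python analysis/03_calibrate_estimate.py
    python analysis/04_band_decomposition.py
    python analysis/05_brs_dynamics.py
    python analysis/06_cohort_correlations.py

The final step prints (seed 0):

    Overall correlation (per-subject r of error vs BRS):
    group    mu    sd   mav
    e_SBP 0.098 0.141 0.003
    e_DBP 0.075 0.098 0.001

    Band correlation:
    class   group    mu    sd   mav
       LF e_LFSBP 0.232 0.250 0.001
       LF e_LFDBP 0.210 0.219 0.001
       HF e_HFSBP 0.021 0.108 0.002
       HF e_HFDBP 0.009 0.093 0.002

    LF vs HF t-tests:
      LF_vs_HF_SBP: t = 4.96, p = 3.78e-06
      LF_vs_HF_DBP: t = 5.43, p = 5.69e-07

Reading: the LF estimation error correlates with BRS (μ ≈ 0.23 for
both SBP and DBP) while the HF error does not (μ ≈ 0.02), and the
difference is highly significant — the qualitative signature of
baroreflex-mediated LF failure.  Upstream stages report their own
checks: PTT re-measured from rendered 1 kHz waveforms lands within
0.6 ms (median) of ground truth, calibration recovers K1 with ≈ 2%
median error despite the HRV perturbation (median fit R² = 0.96), and
the VMD reference-band components correlate at r ≈ 0.99 with the true
LF forcing.

Magnitude convention: these correlations pair |error| with BRS; the
generator couples BRS to the amplitude of the LF error, and the signed
per-beat error is a zero-mean oscillation carrying no BRS information
(`--signed-error` computes the signed version).

A `pttbp` command-line tool wraps the same stages
(`pttbp simulate|extract|calibrate|decompose|brs|analyze|run-all`) for
use on externally produced CSV beat series or waveform records.

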