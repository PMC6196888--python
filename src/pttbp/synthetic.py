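"""Synthetic cardiovascular cohort generator.

Beat-to-beat SBP/DBP carry distinct low-frequency (LF, 0.1-0.15 Hz,
autonomically mediated) and high-frequency (HF, 0.2-0.35 Hz,
respiration-coupled) oscillations.  Heart rate is driven from pressure
through a logistic arterial-baroreflex (ABR) curve

    HR(P) = HR_l + (HR_h - HR_l) / (1 + exp(-eps * (P - P_n)))

whose slope parameter ``eps`` is the subject's ABR sensitivity.  The
classical reflex orientation (HR falls as BP rises, so RRi and SBP move
in the same direction) corresponds to ``eps < 0`` in this
parameterization; the cohort generator applies that orientation by
default while drawing the sensitivity magnitude per subject.

Heart rate is evaluated on the true (noise-free) oscillatory pressure,
so beat-to-beat RRi is coherent with both the LF and HF pressure
oscillations — the beat-scale coherence the sequence-method BRS
estimator measures.  Pulse transit time follows the inverse calibration
model ``PTT = K1 / (SBP - K2)`` plus an HRV-coupled perturbation
``hrv_ptt_gain * dHR_slow`` driven by the *slow-arm* HR increment (the
reflex response to the baseline + LF pressure alone): the sympathetic
LF ramps of heart rate disturb transit time, while the vagal
respiratory-frequency HR fluctuation does not.  The gain is <= 0 (high
HRV depresses PTT variability tracking).  This is the mechanism that
corrupts the LF band of any downstream PTT-based BP estimate while
leaving the HF band intact, and it grows with the ABR sensitivity.

Simulation is beat-domain first; waveform synthesis exists to exercise
the fiducial extractors and stores exact landmark positions as ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

from pttbp.waveforms import BeatSeries, WaveformRecord

__all__ = [
    "ABRParams",
    "SubjectSpec",
    "SubjectTruth",
    "WaveformTruth",
    "DEFAULT_COHORT_RANGES",
    "abr_heart_rate",
    "abr_slope",
    "analytic_brs",
    "simulate_subject",
    "simulate_cohort",
    "synthesize_waveforms",
]


@dataclass(frozen=True)
class ABRParams:
    """Logistic baroreflex curve parameters.

    ``sensitivity`` is signed: its magnitude is the slope-steepness
    (1/mmHg) and its sign sets the reflex orientation (negative =
    classical: HR falls as pressure rises).
    """

    hr_low: float  # beats/min, lower HR asymptote
    hr_high: float  # beats/min, upper HR asymptote
    p_mid: float  # mmHg, pressure at the HR-range midpoint
    sensitivity: float  # 1/mmHg, signed logistic slope parameter

    def __post_init__(self) -> None:
        if not (self.hr_high > self.hr_low > 0):
            raise ValueError("require hr_high > hr_low > 0")
        if not (30.0 <= self.p_mid <= 250.0):
            raise ValueError(f"p_mid {self.p_mid} outside physiologic 30-250 mmHg")
        if not np.isfinite(self.sensitivity):
            raise ValueError("sensitivity must be finite")


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to simulate one subject, with ground truth."""

    abr: ABRParams
    sbp_baseline: float  # mmHg
    dbp_baseline: float  # mmHg
    lf_amp: float  # mmHg
    hf_amp: float  # mmHg
    lf_freq: float  # Hz, in [0.1, 0.15]
    hf_freq: float  # Hz, in [0.2, 0.35]
    k1_true: float  # mmHg*ms, inverse-model gain
    k2_true: float  # mmHg, inverse-model offset
    hrv_ptt_gain: float  # ms per (beats/min), <= 0
    noise_sd: float  # mmHg, additive white beat noise
    duration: float = 600.0  # s, per recording segment
    seed: int = 0
    ptt_noise_sd: float = 0.0  # ms timing jitter on top of the BP-equivalent noise
    n_segments: int = 1  # recordings (e.g. 2 = pre/post exercise)
    segment_gap: float = 300.0  # s of unrecorded time between segments
    post_shift: float = 20.0  # mmHg SBP baseline rise of later segments
    post_hr_shift: float = 15.0  # bpm chronotropic rise after exercise
    baroreflex_reset: float = 0.5  # fraction of the pressure shift the
    # reflex set point follows post-exercise (0 = none, 1 = complete)
    dbp_amp_scale: float = 0.6  # DBP LF/HF amplitude relative to SBP's

    def __post_init__(self) -> None:
        if not (self.lf_freq < self.hf_freq):
            raise ValueError("lf_freq must be below hf_freq")
        if self.lf_amp < 0 or self.hf_amp < 0:
            raise ValueError("oscillation amplitudes must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.hrv_ptt_gain > 0:
            raise ValueError("hrv_ptt_gain must be <= 0 (HRV up -> PTTV down)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sbp_baseline <= self.dbp_baseline:
            raise ValueError("sbp_baseline must exceed dbp_baseline")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")



@dataclass
class SubjectTruth:
    """Simulated beat series plus exact ground truth for every stage."""

    beat_series: BeatSeries
    true_lf_sbp: np.ndarray  # mmHg, the LF sinusoid term per beat
    true_hf_sbp: np.ndarray
    true_lf_dbp: np.ndarray
    true_hf_dbp: np.ndarray
    true_brs_like: float  # ms/mmHg sensitivity proxy at the resting point
    spec: SubjectSpec

    def __post_init__(self) -> None:
        n = len(self.beat_series)
        for name in ("true_lf_sbp", "true_hf_sbp", "true_lf_dbp", "true_hf_dbp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"{name} length differs from beat series")


@dataclass
class WaveformTruth:
    """Exact sample indices of the synthesized landmarks."""

    r_sample: np.ndarray
    ppg_foot: np.ndarray
    ppg_max_deriv: np.ndarray
    ppg_peak: np.ndarray


def abr_heart_rate(pressure, abr: ABRParams):
    """Logistic ABR heart-rate response HR(P).

    Strictly increasing in P for positive sensitivity, decreasing for
    negative; bounded in (hr_low, hr_high).  Scalar or array pressure.
    """
    p = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure must be finite")
    hr = abr.hr_low + (abr.hr_high - abr.hr_low) * expit(
        abr.sensitivity * (p - abr.p_mid)
    )
    return float(hr) if np.isscalar(pressure) else hr


def abr_slope(pressure: float, abr: ABRParams) -> float:
    """Analytic dHR/dP of the logistic curve at ``pressure`` (bpm/mmHg)."""
    e = np.exp(-abr.sensitivity * (pressure - abr.p_mid))
    return float(
        abr.sensitivity * (abr.hr_high - abr.hr_low) * e / (1.0 + e) ** 2
    )


def analytic_brs(pressure: float, abr: ABRParams) -> float:
    """Sequence-method BRS implied by the curve at an operating point:
    dRRi/dSBP = -60000 / HR^2 * dHR/dP, in ms/mmHg."""
    hr = abr_heart_rate(float(pressure), abr)
    return -60000.0 / hr**2 * abr_slope(pressure, abr)


def simulate_subject(spec: SubjectSpec) -> SubjectTruth:
    """Beat-by-beat simulation of one subject.

    Each beat samples the pressure oscillators at the current beat time,
    maps the oscillatory pressure through the ABR curve to HR (hence
    RRi), and advances time by RRi.  PTT follows the inverse model of the
    *noisy* SBP plus the HRV perturbation (slow-arm HR increment) and
    measurement noise.  Raises if any beat would make
    ``SBP <= k2_true`` (PTT undefined) or ``SBP <= DBP``.
    """
    rng = np.random.default_rng(spec.seed)
    phi_lf = rng.uniform(0.0, 2.0 * np.pi)
    phi_hf = rng.uniform(0.0, 2.0 * np.pi)

    beat_time, rri, ptt, sbp, dbp, seg_lab = [], [], [], [], [], []
    lf_s, hf_s, lf_d, hf_d = [], [], [], []

    t = 0.0
    for seg in range(spec.n_segments):
        shift = spec.post_shift if seg > 0 else 0.0
        # exercise resets the reflex set point part-way toward the
        # prevailing (elevated) pressure
        abr_seg = (
            spec.abr
            if shift == 0.0
            else replace(spec.abr, p_mid=spec.abr.p_mid + spec.baroreflex_reset * shift)
        )
        sbp_base = spec.sbp_baseline + shift
        # DBP follows SBP with the same scaling everywhere (oscillation
        # and exercise shift), keeping the DBP-PTT relation homogeneous
        dbp_base = spec.dbp_baseline + spec.dbp_amp_scale * shift
        seg_end = t + spec.duration
        hr_prev = None
        while t < seg_end:
            lf = spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t + phi_lf)
            hf = spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * t + phi_hf)
            slow = sbp_base + lf  # the sympathetic (LF) reflex input
            sbp_true = slow + hf  # actual arterial systolic pressure
            # recorded pressures carry device noise; the arterial wall and
            # the reflex see the true pressure
            sbp_i = sbp_true + rng.normal(0.0, spec.noise_sd)
            dbp_i = (
                dbp_base
                + spec.dbp_amp_scale * (lf + hf)
                + rng.normal(0.0, spec.noise_sd)
            )
            if sbp_i <= dbp_i:
                raise ValueError(
                    "simulated SBP fell below DBP; narrow the amplitudes/noise"
                )
            # post-exercise tachycardia: a central-command chronotropic
            # offset on top of the reflex response
            hr_i = abr_heart_rate(sbp_true, abr_seg) + (
                spec.post_hr_shift if seg > 0 else 0.0
            )
            hr_slow_i = abr_heart_rate(slow, abr_seg)
            d_hr = 0.0 if hr_prev is None else hr_slow_i - hr_prev
            hr_prev = hr_slow_i
            # vasomotor PTT variability acts as a pressure-equivalent
            # disturbance inside the transit-time path
            p_eff = sbp_true + rng.normal(0.0, spec.noise_sd)
            if p_eff <= spec.k2_true:
                raise ValueError(
                    f"SBP {p_eff:.1f} <= k2_true {spec.k2_true}: PTT undefined"
                )
            ptt_i = (
                spec.k1_true / (p_eff - spec.k2_true)
                + spec.hrv_ptt_gain * d_hr
                + rng.normal(0.0, spec.ptt_noise_sd)
            )
            rri_i = 60000.0 / hr_i

            beat_time.append(t)
            rri.append(rri_i)
            ptt.append(ptt_i)
            sbp.append(sbp_i)
            dbp.append(dbp_i)
            seg_lab.append(seg)
            lf_s.append(lf)
            hf_s.append(hf)
            lf_d.append(spec.dbp_amp_scale * lf)
            hf_d.append(spec.dbp_amp_scale * hf)
            t += rri_i / 1000.0
        t = seg_end + spec.segment_gap

    series = BeatSeries(
        beat_time=np.asarray(beat_time),
        rri=np.asarray(rri),
        ptt=np.asarray(ptt),
        sbp=np.asarray(sbp),
        dbp=np.asarray(dbp),
        ptt_variant="PTT2",
        segment=np.asarray(seg_lab, dtype=int),
    )
    return SubjectTruth(
        beat_series=series,
        true_lf_sbp=np.asarray(lf_s),
        true_hf_sbp=np.asarray(hf_s),
        true_lf_dbp=np.asarray(lf_d),
        true_hf_dbp=np.asarray(hf_d),
        true_brs_like=analytic_brs(spec.sbp_baseline, spec.abr),
        spec=spec,
    )


#: study-condition parameter ranges for the synthetic cohort.
#: Uniform draws per subject; ``sensitivity`` is the magnitude of the
#: logistic slope, applied with ``reflex_sign``.
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "sensitivity": (0.05, 0.5),  # 1/mmHg
    "hr_low": (50.0, 65.0),  # bpm
    "hr_high": (90.0, 110.0),  # bpm
    "sbp_baseline": (110.0, 130.0),  # mmHg
    "pulse_pressure": (35.0, 50.0),  # mmHg (SBP - DBP baseline)
    "p_mid_offset": (-5.0, 5.0),  # mmHg around the resting SBP
    "lf_amp": (2.0, 5.0),  # mmHg
    "hf_amp": (1.5, 4.0),  # mmHg
    "lf_freq": (0.10, 0.15),  # Hz
    "hf_freq": (0.20, 0.35),  # Hz
    "k1_true": (20000.0, 40000.0),  # mmHg*ms
    "k2_true": (0.0, 30.0),  # mmHg
    "hrv_ptt_gain": (-1.5, -0.5),  # ms/bpm
    "noise_sd": (0.5, 1.5),  # mmHg
    # beat-level PTT variability is pressure-equivalent (scales with
    # noise_sd inside the transit-time path); extra timing jitter enters
    # physically during waveform-level fiducial extraction
    "ptt_noise_sd": (0.0, 0.0),
    "post_shift": (10.0, 25.0),  # mmHg
    "post_hr_shift": (10.0, 20.0),  # bpm
}


def simulate_cohort(
    n_subjects: int,
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    duration: float = 600.0,
    n_segments: int = 2,
    reflex_sign: float = -1.0,
) -> list[SubjectTruth]:
    """Draw ``n_subjects`` independent SubjectSpecs from uniform ranges
    and simulate each.

    Defaults emulate the study protocol: two recordings per subject with
    a post-exercise baseline rise, and ABR sensitivity varied widely so
    realized BRS spans a broad range.  ``reflex_sign=-1`` applies the
    classical baroreflex orientation (HR falls as BP rises).
    """
    if n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects")
    rng_ranges = dict(DEFAULT_COHORT_RANGES)
    if ranges:
        rng_ranges.update(ranges)
    for key, (lo, hi) in rng_ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)

    def draw(key: str) -> float:
        lo, hi = rng_ranges[key]
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    cohort = []
    for _ in range(n_subjects):
        sbp0 = draw("sbp_baseline")
        abr = ABRParams(
            hr_low=draw("hr_low"),
            hr_high=draw("hr_high"),
            p_mid=sbp0 + draw("p_mid_offset"),
            sensitivity=reflex_sign * draw("sensitivity"),
        )
        spec = SubjectSpec(
            abr=abr,
            sbp_baseline=sbp0,
            dbp_baseline=sbp0 - draw("pulse_pressure"),
            lf_amp=draw("lf_amp"),
            hf_amp=draw("hf_amp"),
            lf_freq=draw("lf_freq"),
            hf_freq=draw("hf_freq"),
            k1_true=draw("k1_true"),
            k2_true=draw("k2_true"),
            hrv_ptt_gain=draw("hrv_ptt_gain"),
            noise_sd=draw("noise_sd"),
            ptt_noise_sd=draw("ptt_noise_sd"),
            duration=duration,
            n_segments=n_segments,
            post_shift=draw("post_shift"),
            post_hr_shift=draw("post_hr_shift"),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(simulate_subject(spec))
    return cohort


def synthesize_waveforms(
    truth: SubjectTruth,
    fs: float = 1000.0,
    rise_time: float = 0.08,
) -> tuple[WaveformRecord, WaveformTruth]:
    """Render a SubjectTruth into sampled ECG/PPG/BP channels.

    - ECG: a narrow Gaussian R-wave template (sd 8 ms) at each beat time.
    - PPG: a raised-cosine upstroke of duration ``rise_time`` followed by
      an exponential decay; the upstroke midpoint — the maximal first
      derivative — lags the beat's R-wave by exactly that beat's PTT, so
      the pulse foot precedes it by ``rise_time/2`` and the peak follows
      by the same margin.
    - BP: a per-cycle pressure pulse whose minimum/maximum equal
      DBP_i/SBP_i inside the beat's RR window.

    Returns the record together with the exact landmark sample indices.
    Rejects fs < 250 Hz and parameter combinations where templates would
    collide (PTT too short for the upstroke, or upstroke longer than the
    beat).
    """
    if fs < 250.0:
        raise ValueError(f"fs {fs} Hz too low for fiducial-grade synthesis")
    bs = truth.beat_series
    n = len(bs)
    if n == 0:
        raise ValueError("zero-beat truth cannot be rendered")
    ptt_s = bs.ptt / 1000.0
    rri_s = bs.rri / 1000.0
    if np.any(ptt_s - rise_time / 2 <= 0):
        raise ValueError("PTT too short for the PPG upstroke template")
    if np.any(rise_time >= rri_s):
        raise ValueError("PPG upstroke longer than a beat: templates collide")

    t_end = bs.beat_time[-1] + rri_s[-1] + 0.5
    n_samples = int(np.ceil(t_end * fs)) + 1
    tgrid = np.arange(n_samples) / fs
    ecg = np.zeros(n_samples)
    ppg = np.zeros(n_samples)
    bp = np.zeros(n_samples)

    r_sample = np.round(bs.beat_time * fs).astype(int)
    r_times = r_sample / fs  # quantized R instants used for all templates

    # ECG: Gaussian R-waves, sd 8 ms
    sd = 0.008
    half = int(round(4 * sd * fs))
    kernel_t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-0.5 * (kernel_t / sd) ** 2)
    for rs in r_sample:
        lo, hi = max(rs - half, 0), min(rs + half + 1, n_samples)
        klo = lo - (rs - half)
        ecg[lo:hi] += kernel[klo:klo + (hi - lo)]

    # PPG: onset (foot) at R + PTT - rise/2; raised-cosine upstroke to 1,
    # exponential decay afterwards until the next onset.
    onset = r_times + ptt_s - rise_time / 2
    onset_idx = np.round(onset * fs).astype(int)
    peak_idx = np.round((onset + rise_time) * fs).astype(int)
    maxd_idx = np.round((onset + rise_time / 2) * fs).astype(int)
    for i in range(n):
        a = onset_idx[i]
        b = onset_idx[i + 1] if i + 1 < n else n_samples - 1
        p = min(peak_idx[i], n_samples - 1)
        tt = tgrid[a:p + 1] - onset[i]
        ppg[a:p + 1] = 0.5 * (1 - np.cos(np.pi * np.clip(tt / rise_time, 0, 1)))
        if b > p:
            tau = max((b - p) / fs / 4.0, 1.0 / fs)
            ppg[p + 1:b + 1] = np.exp(-(tgrid[p + 1:b + 1] - tgrid[p]) / tau)

    # BP: within [R_i, R_{i+1}): DBP at the window start, sin^2 systolic
    # rise to SBP over 30% of the cycle, exponential diastolic decay.
    for i in range(n):
        a = r_sample[i]
        b = r_sample[i + 1] if i + 1 < n else min(
            int(round((r_times[i] + rri_s[i]) * fs)), n_samples - 1
        )
        if b <= a:
            continue
        m = a + max(int(round(0.3 * (b - a))), 1)
        m = min(m, b)
        shape = np.zeros(b - a)
        upst = np.arange(m - a) / max(m - a, 1)
        shape[: m - a] = np.sin(0.5 * np.pi * upst) ** 2
        if m - a > 0:
            shape[m - a - 1] = 1.0  # peak sample attains SBP exactly
        ndec = b - m
        if ndec > 0:
            tau = max(ndec / 3.0, 1.0)
            shape[m - a:] = np.exp(-np.arange(1, ndec + 1) / tau)
        bp[a:b] = bs.dbp[i] + (bs.sbp[i] - bs.dbp[i]) * shape
    bp[r_sample[-1]:] = np.maximum(bp[r_sample[-1]:], bs.dbp[-1])
    bp[: r_sample[0]] = bs.dbp[0]

    record = WaveformRecord(fs=fs, ecg=ecg, ppg=ppg, bp=bp)
    wf_truth = WaveformTruth(
        r_sample=r_sample,
        ppg_foot=onset_idx,
        ppg_max_deriv=maxd_idx,
        ppg_peak=peak_idx,
    )
    return record, wf_truth
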