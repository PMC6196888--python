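"""Waveform conditioning and per-beat fiducial extraction.

Raw ECG/PPG/BP records are band-limited with zero-phase Butterworth
filters, R-waves are located with a derivative-energy detector, and the
three classical PPG fiducials are measured inside each cardiac cycle:

- PTT1: R-wave to PPG systolic peak,
- PTT2: R-wave to the point of maximal first derivative of the PPG
  upstroke (the default; most robust to pulse-shape distortion),
- PTT3: R-wave to the PPG minimum (pulse foot).

Per-beat SBP/DBP are the max/min of the continuous pressure channel
within the cycle's RR window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "WaveformRecord",
    "BeatSeries",
    "PPGFiducials",
    "filter_ecg",
    "filter_ppg",
    "detect_r_peaks",
    "ppg_fiducials",
    "extract_beat_series",
]

#: beat-quality gates, ms; beats outside are dropped and logged
PTT_LIMITS_MS = (50.0, 600.0)
RRI_LIMITS_MS = (300.0, 2000.0)

#: minimum number of surviving beats for a usable series
MIN_VALID_BEATS = 20


@dataclass
class WaveformRecord:
    """Synchronously sampled ECG, PPG and continuous BP channels."""

    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    bp: np.ndarray
    start: float = 0.0

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.bp = np.asarray(self.bp, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not (len(self.ecg) == len(self.ppg) == len(self.bp)):
            raise ValueError("ECG, PPG and BP channels must share one length")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def time(self) -> np.ndarray:
        return self.start + np.arange(self.n_samples) / self.fs

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BeatSeries:
    """Per-beat aligned series: R-wave times, RRi, PTT, SBP, DBP.

    ``rri[i]`` is the interval (ms) initiated at beat ``i``.  ``segment``
    labels recording segments (e.g. pre/post exercise); beat bookkeeping
    invariants are enforced within segments, since consecutive recordings
    are separated by an unrecorded gap.
    """

    beat_time: np.ndarray
    rri: np.ndarray
    ptt: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    ptt_variant: str = "PTT2"
    segment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.rri = np.asarray(self.rri, dtype=float)
        self.ptt = np.asarray(self.ptt, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        n = len(self.beat_time)
        for name in ("rri", "ptt", "sbp", "dbp"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from beat_time")
        if self.segment is None:
            self.segment = np.zeros(n, dtype=int)
        else:
            self.segment = np.asarray(self.segment, dtype=int)
            if len(self.segment) != n:
                raise ValueError("segment length differs from beat_time")
        if n and np.any(np.diff(self.beat_time) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if n and np.any(self.sbp <= self.dbp):
            raise ValueError("SBP must exceed DBP at every beat")
        if self.ptt_variant not in ("PTT1", "PTT2", "PTT3"):
            raise ValueError(f"unknown PTT variant {self.ptt_variant!r}")

    def __len__(self) -> int:
        return len(self.beat_time)

    def segment_labels(self) -> np.ndarray:
        return np.unique(self.segment)

    def segment_view(self, label: int) -> "BeatSeries":
        """Sub-series of one recording segment (a view by copy)."""
        m = self.segment == label
        return BeatSeries(
            beat_time=self.beat_time[m],
            rri=self.rri[m],
            ptt=self.ptt[m],
            sbp=self.sbp[m],
            dbp=self.dbp[m],
            ptt_variant=self.ptt_variant,
            segment=self.segment[m],
        )


@dataclass
class PPGFiducials:
    """Sample indices of the three PPG landmarks for each complete beat."""

    peak: np.ndarray
    max_first_derivative: np.ndarray
    minimum: np.ndarray
    valid: np.ndarray


def _butter_sos(corner_hz: float | tuple[float, float], fs: float, btype: str, order: int = 4):
    return sps.butter(order, corner_hz, btype=btype, fs=fs, output="sos")


def _bandlimit(x: np.ndarray, fs: float, hp: float, lp: float, order: int = 4) -> np.ndarray:
    """Zero-phase high-pass + low-pass Butterworth cascade.

    Forward-backward application keeps fiducial timing unshifted; the two
    corners are applied as separate passes, mirroring the acquisition
    hardware's independent high-pass and low-pass stages.
    """
    if fs <= 2.0 * lp:
        raise ValueError(f"sampling rate {fs} Hz below 2x low-pass corner {lp} Hz")
    y = sps.sosfiltfilt(_butter_sos(hp, fs, "highpass", order), x)
    y = sps.sosfiltfilt(_butter_sos(lp, fs, "lowpass", order), y)
    return y


def filter_ecg(record: WaveformRecord) -> WaveformRecord:
    """Band-limit the ECG channel to 0.5-35 Hz (zero phase, order 4)."""
    ecg = _bandlimit(record.ecg, record.fs, 0.5, 35.0)
    return replace(record, ecg=ecg)


def filter_ppg(record: WaveformRecord) -> WaveformRecord:
    """Band-limit the PPG channel to 0.05-10 Hz (zero phase, order 4)."""
    ppg = _bandlimit(record.ppg, record.fs, 0.05, 10.0)
    return replace(record, ppg=ppg)


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """Locate R-wave instants with a derivative-energy detector.

    The squared first derivative is smoothed with a 80 ms moving window,
    peaks are picked above an adaptive threshold (a fraction of the median
    candidate height), and each detection is refined to the ECG maximum
    within +/-50 ms.  A refractory period suppresses double counting.

    Returns beat times in seconds.  A flat or featureless signal yields an
    empty array with a warning rather than an error.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < int(fs):
        raise ValueError("ECG shorter than one second")
    d = np.gradient(ecg)
    energy = d * d
    win = max(int(round(0.08 * fs)), 1)
    kernel = np.ones(win) / win
    smooth = np.convolve(energy, kernel, mode="same")
    if smooth.max() <= 0 or np.ptp(ecg) < 1e-12:
        warnings.warn("flat ECG: no R-peaks detected", stacklevel=2)
        return np.array([])
    dist = max(int(round(refractory_s * fs)), 1)
    # first pass: liberal height, then adapt to the median candidate
    cand, props = sps.find_peaks(smooth, height=0.1 * smooth.max(), distance=dist)
    if len(cand) == 0:
        warnings.warn("no R-peak candidates above threshold", stacklevel=2)
        return np.array([])
    thr = 0.3 * np.median(props["peak_heights"])
    peaks, _ = sps.find_peaks(smooth, height=thr, distance=dist)
    # refine to local ECG maximum (R apex) within +/-50 ms
    half = int(round(0.05 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(ecg))
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # re-enforce refractory after refinement
    keep = [refined[0]]
    for p in refined[1:]:
        if p - keep[-1] >= dist:
            keep.append(p)
    return np.asarray(keep, dtype=float) / fs


def ppg_fiducials(
    ppg: np.ndarray,
    fs: float,
    beat_times: np.ndarray,
    min_amplitude_frac: float = 0.05,
) -> PPGFiducials:
    """Per-beat PPG landmarks: systolic peak, maximal first derivative
    of the upstroke, and pulse-foot minimum.

    The search for beat ``i`` is confined to the RR window
    ``[R_i, R_{i+1})``; the final (incomplete) beat is skipped.  The first
    derivative is a smoothed first difference (Savitzky-Golay).  Beats
    whose pulse excursion is below ``min_amplitude_frac`` of the global
    excursion, or whose landmark ordering minimum <= max-derivative <=
    peak fails, are flagged invalid.
    """
    ppg = np.asarray(ppg, dtype=float)
    beat_times = np.asarray(beat_times, dtype=float)
    if len(beat_times) < 2:
        raise ValueError("need at least two beats to form one RR window")
    sg_win = max(int(round(0.03 * fs)) | 1, 5)  # odd, ~30 ms
    deriv = sps.savgol_filter(ppg, sg_win, polyorder=3, deriv=1)
    n_beats = len(beat_times) - 1
    peak = np.zeros(n_beats, dtype=int)
    maxd = np.zeros(n_beats, dtype=int)
    mini = np.zeros(n_beats, dtype=int)
    valid = np.ones(n_beats, dtype=bool)
    global_ptp = np.ptp(ppg)
    for i in range(n_beats):
        a = int(round(beat_times[i] * fs))
        b = int(round(beat_times[i + 1] * fs))
        a, b = max(a, 0), min(b, len(ppg))
        if b - a < 4:
            valid[i] = False
            continue
        seg = ppg[a:b]
        if np.ptp(seg) < min_amplitude_frac * global_ptp or global_ptp < 1e-12:
            valid[i] = False  # flat / no upstroke
            continue
        p = a + int(np.argmax(seg))
        # upstroke landmarks precede the peak within the window
        if p <= a:
            valid[i] = False
            continue
        up = deriv[a:p + 1]
        d = a + int(np.argmax(up))
        m = a + int(np.argmin(ppg[a:d + 1])) if d > a else a
        peak[i], maxd[i], mini[i] = p, d, m
        if not (m <= d <= p):
            valid[i] = False
    return PPGFiducials(peak=peak, max_first_derivative=maxd, minimum=mini, valid=valid)


_VARIANT_ATTR = {
    "PTT1": "peak",
    "PTT2": "max_first_derivative",
    "PTT3": "minimum",
}


def extract_beat_series(
    record: WaveformRecord,
    ptt_variant: str = "PTT2",
    prefiltered: bool = False,
    drop_log: list | None = None,
) -> BeatSeries:
    """Full fiducial pipeline: filter, detect R-waves, measure PTT/RRi
    and per-cycle SBP/DBP, and gate beat quality.

    ``PTT = (PPG fiducial time - R time) * 1000`` ms with the requested
    variant (default PTT2, the maximal-first-derivative point).  SBP/DBP
    are the max/min of the pressure channel within ``[R_i, R_{i+1})``.
    Beats violating quality gates are dropped and appended to
    ``drop_log`` as ``(beat_index, reason)``.
    """
    if ptt_variant not in _VARIANT_ATTR:
        raise ValueError(f"unknown PTT variant {ptt_variant!r}")
    if drop_log is None:
        drop_log = []
    rec = record if prefiltered else filter_ppg(filter_ecg(record))
    r_times = detect_r_peaks(rec.ecg - np.median(rec.ecg), rec.fs)
    if len(r_times) < 3:
        raise ValueError("fewer than three R-peaks detected")
    fid = ppg_fiducials(rec.ppg, rec.fs, r_times)
    fid_idx = getattr(fid, _VARIANT_ATTR[ptt_variant])

    n_beats = len(r_times) - 1  # last beat has no RR window
    rri = np.diff(r_times) * 1000.0
    beat_time, ptt, sbp, dbp, seg = [], [], [], [], []
    for i in range(n_beats):
        if not fid.valid[i]:
            drop_log.append((i, "ppg_fiducial_invalid"))
            continue
        ptt_i = (fid_idx[i] / rec.fs - r_times[i]) * 1000.0
        if not (PTT_LIMITS_MS[0] <= ptt_i <= PTT_LIMITS_MS[1]):
            drop_log.append((i, f"ptt_out_of_range:{ptt_i:.1f}ms"))
            continue
        if not (RRI_LIMITS_MS[0] <= rri[i] <= RRI_LIMITS_MS[1]):
            drop_log.append((i, f"rri_out_of_range:{rri[i]:.1f}ms"))
            continue
        a = int(round(r_times[i] * rec.fs))
        b = int(round(r_times[i + 1] * rec.fs))
        window = rec.bp[max(a, 0):min(b, rec.n_samples)]
        if len(window) == 0:
            drop_log.append((i, "empty_bp_window"))
            continue
        s, d = float(window.max()), float(window.min())
        if s <= d:
            drop_log.append((i, "sbp_not_above_dbp"))
            continue
        beat_time.append(r_times[i])
        ptt.append(ptt_i)
        sbp.append(s)
        dbp.append(d)
    if len(beat_time) < MIN_VALID_BEATS:
        raise ValueError(
            f"only {len(beat_time)} valid beats (< {MIN_VALID_BEATS}); "
            "record unusable for variability analysis"
        )
    beat_time = np.asarray(beat_time)
    kept = np.searchsorted(r_times, beat_time)
    return BeatSeries(
        beat_time=beat_time,
        rri=rri[kept],
        ptt=np.asarray(ptt),
        sbp=np.asarray(sbp),
        dbp=np.asarray(dbp),
        ptt_variant=ptt_variant,
    )
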