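"""Cohort correlation analysis between PTT-based BP estimation error
and baroreflex sensitivity.

Per subject, six error series are formed (overall, LF and HF, for SBP
and DBP; estimate minus reference), each is paired with the dynamic BRS
series, and a Pearson correlation r_n is computed per (error x BRS)
group.  Cohort criteria per group are the mean mu, the population
standard deviation SD (divisor N), and the minimum absolute value MAV
of the per-subject correlations; LF vs HF groups are compared with a
two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

from pttbp.banddecomp import BandComponents, decompose_lf_hf
from pttbp.brs import BRSSeries, dynamic_brs
from pttbp.calibration import fit_ptt_bp, predict_bp
from pttbp.waveforms import BeatSeries

__all__ = [
    "GROUPS",
    "PressureEstimate",
    "ErrorSeries",
    "CohortStats",
    "band_errors",
    "pearson_r",
    "align_error_brs",
    "cohort_criteria",
    "lf_hf_ttest",
    "run_full_analysis",
]

#: the six error-vs-BRS correlation groups, in report order
GROUPS = ("e_SBP", "e_DBP", "e_LFSBP", "e_LFDBP", "e_HFSBP", "e_HFDBP")


@dataclass
class PressureEstimate:
    """One pressure series together with its LF/HF band content."""

    overall: np.ndarray  # mmHg per beat
    bands: BandComponents


@dataclass
class ErrorSeries:
    """Per-beat estimation errors, estimate minus reference (mmHg)."""

    e_SBP: np.ndarray
    e_DBP: np.ndarray
    e_LFSBP: np.ndarray
    e_LFDBP: np.ndarray
    e_HFSBP: np.ndarray
    e_HFDBP: np.ndarray
    subject_id: int | str | None = None

    def __post_init__(self) -> None:
        n = len(self.e_SBP)
        for g in GROUPS:
            arr = np.asarray(getattr(self, g), dtype=float)
            setattr(self, g, arr)
            if len(arr) != n:
                raise ValueError(f"{g} length differs from e_SBP")

    def __len__(self) -> int:
        return len(self.e_SBP)


@dataclass
class CohortStats:
    """Per-subject correlations and cohort criteria per group."""

    per_subject_r: dict  # group -> list of r_n over subjects
    criteria: dict  # group -> {"mu", "sd", "mav"}
    ttests: dict  # comparison -> {"t", "p"}
    n_subjects: int
    excluded: list = field(default_factory=list)
    abs_error: bool = False


def band_errors(
    est_sbp: PressureEstimate,
    ref_sbp: PressureEstimate,
    est_dbp: PressureEstimate,
    ref_dbp: PressureEstimate,
    subject_id=None,
) -> ErrorSeries:
    """Elementwise estimate-minus-reference errors, overall and per band."""
    n = len(est_sbp.overall)
    for pe in (ref_sbp, est_dbp, ref_dbp):
        if len(pe.overall) != n:
            raise ValueError("aligned per-beat series required")
    return ErrorSeries(
        e_SBP=np.asarray(est_sbp.overall) - np.asarray(ref_sbp.overall),
        e_DBP=np.asarray(est_dbp.overall) - np.asarray(ref_dbp.overall),
        e_LFSBP=est_sbp.bands.lf - ref_sbp.bands.lf,
        e_LFDBP=est_dbp.bands.lf - ref_dbp.bands.lf,
        e_HFSBP=est_sbp.bands.hf - ref_sbp.bands.hf,
        e_HFDBP=est_dbp.bands.hf - ref_dbp.bands.hf,
        subject_id=subject_id,
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation via the one-pass sums

        r = (S_xy - S_x S_y / M) / sqrt((S_xx - S_x^2/M)(S_yy - S_y^2/M)).

    Requires M >= 3 and nonzero variance in both inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal lengths")
    m = len(x)
    if m < 3:
        raise ValueError("need at least 3 pairs")
    sx, sy = x.sum(), y.sum()
    sxx = np.sum(x * x) - sx * sx / m
    syy = np.sum(y * y) - sy * sy / m
    if sxx <= 0 or syy <= 0:
        raise ValueError("undefined correlation: zero variance")
    r = (np.sum(x * y) - sx * sy / m) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def align_error_brs(
    errors: ErrorSeries,
    brs: BRSSeries,
) -> tuple[dict, np.ndarray]:
    """Pair each valid BRS window with the error at its start-beat index.

    Returns ``(aligned_errors, brs_values)`` where ``aligned_errors``
    maps each group name to the error values at the valid windows.
    Raises if fewer than 3 valid pairs survive (subject unusable).
    """
    idx = brs.window_start[brs.valid]
    idx = idx[idx < len(errors)]
    if len(idx) < 3:
        raise ValueError("fewer than 3 valid BRS windows: subject excluded")
    brs_vals = brs.brs[brs.valid][: len(idx)]
    aligned = {g: getattr(errors, g)[idx] for g in GROUPS}
    return aligned, brs_vals


def cohort_criteria(r_list) -> tuple[float, float, float]:
    """Mean, population SD (divisor N) and minimum absolute value of the
    per-subject correlation coefficients."""
    r = np.asarray(r_list, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 subjects")
    mu = float(r.mean())
    sd = float(np.sqrt(np.mean((r - mu) ** 2)))
    mav = float(np.min(np.abs(r)))
    return mu, sd, mav


def lf_hf_ttest(r_lf, r_hf) -> tuple[float, float]:
    """Two-sample (pooled-variance) t-test between per-subject
    correlation groups; returns (statistic, two-sided p).

    Degenerate (zero pooled variance) inputs yield t = 0, p = 1 for
    equal means or an infinite statistic with p = 0, with a warning.
    """
    a = np.asarray(r_lf, dtype=float)
    b = np.asarray(r_hf, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn("degenerate variance in t-test inputs", stacklevel=2)
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sst.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _subject_correlations(
    bs: BeatSeries,
    form: str,
    brs_window: int,
    target_fs: float,
    n_modes: int,
    alpha: float,
    abs_error: bool,
    subject_id,
) -> dict:
    """Calibrate -> predict -> decompose -> errors -> BRS -> six r values.

    Calibration is one OLS fit per target over the full recording; band
    decomposition and BRS run per recording segment (segments are
    separated by unrecorded gaps) and the aligned pairs are pooled
    before correlating.
    """
    sbp_model = fit_ptt_bp(bs.ptt, bs.sbp, form=form, target="SBP")
    dbp_model = fit_ptt_bp(bs.ptt, bs.dbp, form=form, target="DBP")
    pooled_err = {g: [] for g in GROUPS}
    pooled_brs = []
    for label in bs.segment_labels():
        seg = bs.segment_view(int(label))
        if len(seg) < brs_window + 2:
            continue
        est_sbp = predict_bp(sbp_model, seg.ptt)
        est_dbp = predict_bp(dbp_model, seg.ptt)

        def bands(values):
            return decompose_lf_hf(
                seg.beat_time, values, target_fs=target_fs,
                n_modes=n_modes, alpha=alpha,
            )

        errors = band_errors(
            est_sbp=PressureEstimate(est_sbp, bands(est_sbp)),
            ref_sbp=PressureEstimate(seg.sbp, bands(seg.sbp)),
            est_dbp=PressureEstimate(est_dbp, bands(est_dbp)),
            ref_dbp=PressureEstimate(seg.dbp, bands(seg.dbp)),
            subject_id=subject_id,
        )
        brs = dynamic_brs(seg.rri, seg.sbp, window=brs_window)
        aligned, brs_vals = align_error_brs(errors, brs)
        for g in GROUPS:
            pooled_err[g].append(aligned[g])
        pooled_brs.append(brs_vals)
    if not pooled_brs:
        raise ValueError("no segment long enough for BRS windows")
    brs_all = np.concatenate(pooled_brs)
    out = {}
    for g in GROUPS:
        e = np.concatenate(pooled_err[g])
        out[g] = pearson_r(np.abs(e) if abs_error else e, brs_all)
    return out


def run_full_analysis(
    cohort,
    form: str = "inverse",
    brs_window: int = 16,
    target_fs: float = 4.0,
    n_modes: int = 5,
    alpha: float = 2000.0,
    abs_error: bool = False,
) -> CohortStats:
    """Stage-by-stage cohort analysis.

    ``cohort`` is a sequence of BeatSeries (or SubjectTruth objects, in
    which case their beat series are used).  Per-subject failures are
    logged and excluded; at least 2 subjects must survive.  The result
    carries per-subject correlations, per-group cohort criteria (mu, SD,
    MAV), the LF-vs-HF t-tests per pressure target, and the overall
    SBP-vs-DBP comparison.
    """
    per_subject = {g: [] for g in GROUPS}
    excluded = []
    for sid, subject in enumerate(cohort):
        bs = getattr(subject, "beat_series", subject)
        try:
            r = _subject_correlations(
                bs, form, brs_window, target_fs, n_modes, alpha, abs_error, sid
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            excluded.append((sid, str(exc)))
            continue
        for g in GROUPS:
            per_subject[g].append(r[g])
    n_ok = len(per_subject[GROUPS[0]])
    if n_ok < 2:
        raise ValueError(
            f"only {n_ok} subjects survived the pipeline; cannot form cohort stats"
        )
    criteria = {}
    for g in GROUPS:
        mu, sd, mav = cohort_criteria(per_subject[g])
        criteria[g] = {"mu": mu, "sd": sd, "mav": mav}
    ttests = {}
    for target, lf_g, hf_g in (
        ("SBP", "e_LFSBP", "e_HFSBP"),
        ("DBP", "e_LFDBP", "e_HFDBP"),
    ):
        t, p = lf_hf_ttest(per_subject[lf_g], per_subject[hf_g])
        ttests[f"LF_vs_HF_{target}"] = {"t": t, "p": p}
    t, p = lf_hf_ttest(per_subject["e_SBP"], per_subject["e_DBP"])
    ttests["overall_SBP_vs_DBP"] = {"t": t, "p": p}
    return CohortStats(
        per_subject_r=per_subject,
        criteria=criteria,
        ttests=ttests,
        n_subjects=n_ok,
        excluded=excluded,
        abs_error=abs_error,
    )
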