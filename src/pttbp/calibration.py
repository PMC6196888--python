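"""PTT -> BP calibration by ordinary least squares.

Two classical model forms are supported:

- inverse: BP = K1 / PTT + K2   (1/PTT is linear in BP; the default)
- log:     BP = K1 * ln(PTT) + K2

Fitting minimizes sum((K1 * x_i + K2 - BP_i)^2) with x = 1/PTT or
ln(PTT), solved in closed form via the normal equations.  SBP and DBP
are calibrated separately with the same PTT regressor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["CalibrationModel", "fit_ptt_bp", "predict_bp"]

_FORMS = ("inverse", "log")


@dataclass
class CalibrationModel:
    form: str  # "inverse" | "log"
    k1: float  # mmHg*ms (inverse) or mmHg per ln(ms) (log)
    k2: float  # mmHg
    target: str = "SBP"  # which pressure this model estimates
    r_squared: float = float("nan")
    residual_sd: float = float("nan")  # mmHg
    n: int = 0

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        if not (np.isfinite(self.k1) and np.isfinite(self.k2)):
            raise ValueError("calibration parameters must be finite")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        return cls(**json.loads(text))


def _regressor(ptt: np.ndarray, form: str) -> np.ndarray:
    ptt = np.asarray(ptt, dtype=float)
    if np.any(ptt <= 0):
        raise ValueError("PTT must be strictly positive")
    return 1.0 / ptt if form == "inverse" else np.log(ptt)


def fit_ptt_bp(
    ptt: np.ndarray,
    bp_ref: np.ndarray,
    form: str = "inverse",
    target: str = "SBP",
) -> CalibrationModel:
    """Closed-form OLS fit of the chosen calibration model.

    Raises on length mismatch, fewer than 3 beats, nonpositive PTT, or a
    rank-deficient design (zero variance in the regressor).
    """
    if form not in _FORMS:
        raise ValueError(f"unknown model form {form!r}")
    ptt = np.asarray(ptt, dtype=float)
    bp_ref = np.asarray(bp_ref, dtype=float)
    if len(ptt) != len(bp_ref):
        raise ValueError("ptt and bp_ref must have equal lengths")
    if len(ptt) < 3:
        raise ValueError("need at least 3 beats to calibrate")
    x = _regressor(ptt, form)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0 or not np.isfinite(sxx):
        raise np.linalg.LinAlgError("rank-deficient design: PTT has zero variance")
    k1 = float(np.sum((x - x.mean()) * (bp_ref - bp_ref.mean())) / sxx)
    k2 = float(bp_ref.mean() - k1 * x.mean())
    resid = bp_ref - (k1 * x + k2)
    sst = np.sum((bp_ref - bp_ref.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / sst) if sst > 0 else float("nan")
    return CalibrationModel(
        form=form,
        k1=k1,
        k2=k2,
        target=target,
        r_squared=r2,
        residual_sd=float(np.std(resid)),
        n=len(ptt),
    )


def predict_bp(model: CalibrationModel, ptt: np.ndarray) -> np.ndarray:
    """Apply a fitted model elementwise: K1/PTT + K2 or K1*ln(PTT) + K2."""
    x = _regressor(np.asarray(ptt, dtype=float), model.form)
    return model.k1 * x + model.k2
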