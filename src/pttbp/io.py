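"""CSV/JSON serialization of the analysis artifacts."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pttbp.synthetic import ABRParams, SubjectSpec, SubjectTruth
from pttbp.waveforms import BeatSeries, WaveformRecord

__all__ = [
    "write_beat_series",
    "read_beat_series",
    "write_truth",
    "write_waveform_record",
    "read_waveform_record",
    "write_subject_spec",
    "read_subject_spec",
]

BEAT_COLUMNS = ["beat_time_s", "rri_ms", "ptt_ms", "sbp_mmhg", "dbp_mmhg", "segment"]


def write_beat_series(bs: BeatSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "beat_time_s": bs.beat_time,
            "rri_ms": bs.rri,
            "ptt_ms": bs.ptt,
            "sbp_mmhg": bs.sbp,
            "dbp_mmhg": bs.dbp,
            "segment": bs.segment,
        }
    ).to_csv(path, index=False)


def read_beat_series(path: str | Path, ptt_variant: str = "PTT2") -> BeatSeries:
    df = pd.read_csv(path)
    seg = df["segment"].to_numpy() if "segment" in df else None
    return BeatSeries(
        beat_time=df["beat_time_s"].to_numpy(),
        rri=df["rri_ms"].to_numpy(),
        ptt=df["ptt_ms"].to_numpy(),
        sbp=df["sbp_mmhg"].to_numpy(),
        dbp=df["dbp_mmhg"].to_numpy(),
        ptt_variant=ptt_variant,
        segment=seg,
    )


def write_truth(truth: SubjectTruth, path: str | Path) -> None:
    """Companion ground-truth CSV: the exact LF/HF forcing per beat."""
    pd.DataFrame(
        {
            "beat_time_s": truth.beat_series.beat_time,
            "true_lf_sbp_mmhg": truth.true_lf_sbp,
            "true_hf_sbp_mmhg": truth.true_hf_sbp,
            "true_lf_dbp_mmhg": truth.true_lf_dbp,
            "true_hf_dbp_mmhg": truth.true_hf_dbp,
        }
    ).to_csv(path, index=False)


def write_waveform_record(rec: WaveformRecord, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": rec.time, "ecg": rec.ecg, "ppg": rec.ppg, "bp": rec.bp}
    ).to_csv(path, index=False, float_format="%.6g")


def read_waveform_record(path: str | Path) -> WaveformRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("waveform CSV needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return WaveformRecord(
        fs=fs,
        ecg=df["ecg"].to_numpy(),
        ppg=df["ppg"].to_numpy(),
        bp=df["bp"].to_numpy(),
        start=float(t[0]),
    )


def write_subject_spec(spec: SubjectSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(spec), indent=2))


def read_subject_spec(path: str | Path) -> SubjectSpec:
    d = json.loads(Path(path).read_text())
    d["abr"] = ABRParams(**d["abr"])
    return SubjectSpec(**d)
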