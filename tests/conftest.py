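import numpy as np
import pytest

from pttbp import ABRParams, SubjectSpec, simulate_subject


def make_spec(**overrides):
    """A mid-range subject: classical reflex, moderate LF/HF forcing."""
    abr = overrides.pop(
        "abr", ABRParams(hr_low=60.0, hr_high=100.0, p_mid=120.0, sensitivity=-0.2)
    )
    base = dict(
        abr=abr,
        sbp_baseline=120.0,
        dbp_baseline=75.0,
        lf_amp=3.0,
        hf_amp=2.0,
        lf_freq=0.12,
        hf_freq=0.28,
        k1_true=30000.0,
        k2_true=10.0,
        hrv_ptt_gain=-1.0,
        noise_sd=1.0,
        ptt_noise_sd=0.5,
        duration=120.0,
        seed=42,
    )
    base.update(overrides)
    return SubjectSpec(**base)


@pytest.fixture
def subject_spec():
    return make_spec()


@pytest.fixture
def subject_truth(subject_spec):
    return simulate_subject(subject_spec)


@pytest.fixture
def noiseless_truth():
    """No forcing noise, no HRV coupling: PTT obeys the inverse model
    exactly at every beat."""
    return simulate_subject(
        make_spec(hrv_ptt_gain=0.0, noise_sd=0.0, ptt_noise_sd=0.0)
    )
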