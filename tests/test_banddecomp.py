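"""Uneven-to-uniform resampling, VMD, and LF/HF band selection."""

import warnings

import numpy as np
import pytest
from scipy import signal as sps

from pttbp import (
    HF_BAND,
    LF_BAND,
    decompose_lf_hf,
    resample_uniform,
    select_band_modes,
    simulate_subject,
    vmd,
)
from conftest import make_spec

FS = 4.0


def two_tone(duration=300.0, fs=FS, f1=0.12, f2=0.28):
    t = np.arange(0, duration, 1 / fs)
    return t, np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t)


class TestResample:
    def test_uniform_grid_identity(self):
        t = np.arange(0, 30, 0.25)
        x = np.sin(t)
        tg, y = resample_uniform(t, x, target_fs=4.0)
        np.testing.assert_allclose(y, np.sin(tg), atol=1e-6)

    def test_beat_sampled_sinusoid_amplitude_error_below_2pct(self):
        # 0.12 Hz sinusoid sampled at the beats of a 70 bpm rhythm
        beats = np.arange(0, 300, 60.0 / 70.0)
        x = np.sin(2 * np.pi * 0.12 * beats)
        tg, y = resample_uniform(beats, x, target_fs=4.0)
        ref = np.sin(2 * np.pi * 0.12 * tg)
        core = slice(20, -20)  # spline edges excluded
        assert np.max(np.abs(y[core] - ref[core])) < 0.02

    def test_single_beat_rejected(self):
        with pytest.raises(ValueError):
            resample_uniform(np.array([1.0]), np.array([2.0]))

    def test_duplicate_beat_times_rejected(self):
        with pytest.raises(ValueError):
            resample_uniform(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_undersampling_grid_rejected(self):
        t = np.arange(0, 100, 1.0)
        with pytest.raises(ValueError):
            resample_uniform(t, np.zeros(len(t)), target_fs=0.5)


class TestVMD:
    def test_two_tone_centers_correlation_reconstruction(self):
        # clean signal: dual-ascent (exact-reconstruction) mode
        t, x = two_tone()
        ms = vmd(x, n_modes=2, fs=FS, tau=1.0)
        assert ms.converged
        assert ms.center_freqs[0] == pytest.approx(0.12, abs=0.01)
        assert ms.center_freqs[1] == pytest.approx(0.28, abs=0.01)
        for k, f in enumerate((0.12, 0.28)):
            src = np.sin(2 * np.pi * f * t)
            r = np.corrcoef(ms.modes[k], src)[0, 1]
            assert r > 0.95
        rel_err = np.linalg.norm(x - ms.reconstruction()) / np.linalg.norm(x)
        assert rel_err < 0.05

    def test_two_tone_default_mode_interior_reconstruction(self):
        # noise-robust default (tau=0): boundary transients stay in the
        # residual, the interior reconstructs cleanly
        t, x = two_tone()
        ms = vmd(x, n_modes=2, fs=FS)
        assert ms.center_freqs[0] == pytest.approx(0.12, abs=0.01)
        assert ms.center_freqs[1] == pytest.approx(0.28, abs=0.01)
        core = slice(len(x) // 10, -len(x) // 10)
        rel = np.linalg.norm((x - ms.reconstruction())[core]) / np.linalg.norm(
            x[core]
        )
        assert rel < 0.01

    def test_constant_signal_dc_mode_carries_mean(self):
        x = np.full(256, 3.0)
        ms = vmd(x, n_modes=2, fs=FS)
        assert ms.center_freqs[0] < 0.02
        assert np.mean(ms.modes[0]) == pytest.approx(3.0, rel=0.05)
        assert np.sum(ms.modes[1] ** 2) < 0.05 * np.sum(x**2)

    def test_mode_order_sorted_by_center_frequency(self):
        t, x = two_tone()
        ms = vmd(x, n_modes=4, fs=FS)
        assert np.all(np.diff(ms.center_freqs) >= 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            vmd(np.zeros(100), n_modes=1)
        with pytest.raises(ValueError):
            vmd(np.zeros(8), n_modes=2)
        with pytest.raises(ValueError):
            vmd(np.full(100, np.nan), n_modes=2)

    def test_nonconvergence_warns_not_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        with pytest.warns(UserWarning):
            ms = vmd(x, n_modes=3, fs=FS, max_iter=2, tol=0.0)
        assert not ms.converged


class TestBandSelection:
    def test_two_tone_band_assignment(self):
        t, x = two_tone()
        ms = vmd(x, n_modes=2, fs=FS)
        lf = select_band_modes(ms, "LF")
        src = np.sin(2 * np.pi * 0.12 * t)
        assert np.corrcoef(lf, src)[0, 1] > 0.95

    def test_empty_band_returns_zeros_with_warning(self):
        t, x = two_tone()
        ms = vmd(x, n_modes=2, fs=FS)
        with pytest.warns(UserWarning):
            out = select_band_modes(ms, (1.5, 1.9))
        np.testing.assert_array_equal(out, 0.0)

    def test_partition_identity(self):
        """LF + HF + unassigned modes reproduce the full reconstruction."""
        t, x = two_tone()
        ms = vmd(x, n_modes=3, fs=FS)
        lf = select_band_modes(ms, "LF")
        hf = select_band_modes(ms, "HF")
        in_band = (
            ((ms.center_freqs >= LF_BAND[0]) & (ms.center_freqs <= LF_BAND[1]))
            | ((ms.center_freqs >= HF_BAND[0]) & (ms.center_freqs <= HF_BAND[1]))
        )
        rest = ms.modes[~in_band].sum(axis=0) if (~in_band).any() else 0.0
        np.testing.assert_allclose(lf + hf + rest, ms.reconstruction(), atol=1e-9)

    def test_invalid_band_rejected(self):
        t, x = two_tone()
        ms = vmd(x, n_modes=2, fs=FS)
        with pytest.raises(ValueError):
            select_band_modes(ms, (0.3, 0.1))


class TestDecomposeLfHf:
    def test_recovers_known_lf_forcing(self):
        tr = simulate_subject(make_spec(duration=300.0, noise_sd=0.3))
        bs = tr.beat_series
        bands = decompose_lf_hf(bs.beat_time, bs.sbp)
        r = np.corrcoef(bands.lf, tr.true_lf_sbp)[0, 1]
        assert r > 0.9
        r_hf = np.corrcoef(bands.hf, tr.true_hf_sbp)[0, 1]
        assert r_hf > 0.9

    def test_zero_lf_forcing_leaves_little_lf_energy(self):
        tr = simulate_subject(make_spec(duration=300.0, lf_amp=0.0, noise_sd=0.1))
        bs = tr.beat_series
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # LF band may be empty
            bands = decompose_lf_hf(bs.beat_time, bs.sbp)
        assert np.sum(bands.lf**2) < 0.05 * np.sum(bands.hf**2)

    def test_approximate_linearity_on_two_tone(self):
        """Decomposing a difference of two-tone signals is close to the
        difference of their band decompositions."""
        t = np.arange(0, 300, 60.0 / 70.0)
        a = 2.0 * np.sin(2 * np.pi * 0.12 * t) + np.sin(2 * np.pi * 0.28 * t)
        b = 1.0 * np.sin(2 * np.pi * 0.12 * t) + 0.5 * np.sin(2 * np.pi * 0.28 * t)
        lf_diff = decompose_lf_hf(t, a - b).lf
        lf_a = decompose_lf_hf(t, a).lf
        lf_b = decompose_lf_hf(t, b).lf
        core = slice(20, -20)
        resid = lf_diff[core] - (lf_a - lf_b)[core]
        assert np.sqrt(np.mean(resid**2)) < 0.1 * np.std(a[core] - b[core])


class TestOracles:
    def test_vmd_band_agrees_with_butterworth_bandpass(self):
        """Independent oracle: zero-phase Butterworth band-pass into the
        same band correlates > 0.95 with the VMD band component."""
        t, x = two_tone()
        ms = vmd(x, n_modes=2, fs=FS)
        for band in (LF_BAND, HF_BAND):
            sos = sps.butter(4, band, btype="bandpass", fs=FS, output="sos")
            oracle = sps.sosfiltfilt(sos, x)
            got = select_band_modes(ms, band)
            core = slice(40, -40)
            r = np.corrcoef(got[core], oracle[core])[0, 1]
            assert r > 0.95

    def test_band_content_invariant_to_init(self):
        t, x = two_tone()
        lf_by_init = []
        for init in ("uniform", "zero", "random"):
            ms = vmd(x, n_modes=2, fs=FS, init=init)
            lf_by_init.append(select_band_modes(ms, "LF"))
        for other in lf_by_init[1:]:
            r = np.corrcoef(lf_by_init[0], other)[0, 1]
            assert r > 0.99
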