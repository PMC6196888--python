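"""Error series, correlation criteria, and the cohort analysis."""

import numpy as np
import pytest
from scipy import stats as sst

from pttbp import (
    align_error_brs,
    band_errors,
    cohort_criteria,
    dynamic_brs,
    lf_hf_ttest,
    pearson_r,
    run_full_analysis,
    simulate_cohort,
)
from pttbp.banddecomp import BandComponents
from pttbp.brs import BRSSeries
from pttbp.stats import ErrorSeries, PressureEstimate


def make_estimate(overall, lf=None, hf=None):
    n = len(overall)
    return PressureEstimate(
        overall=np.asarray(overall, float),
        bands=BandComponents(
            lf=np.zeros(n) if lf is None else np.asarray(lf, float),
            hf=np.zeros(n) if hf is None else np.asarray(hf, float),
        ),
    )


class TestBandErrors:
    def test_identical_inputs_give_zero_errors(self):
        x = make_estimate(np.linspace(110, 130, 50))
        err = band_errors(x, x, x, x)
        for g in ("e_SBP", "e_LFSBP", "e_HFDBP"):
            np.testing.assert_array_equal(getattr(err, g), 0.0)

    def test_constant_offset_appears_in_overall_error(self):
        ref = make_estimate(np.linspace(110, 130, 50))
        est = make_estimate(ref.overall + 3.0)
        err = band_errors(est, ref, ref, ref)
        np.testing.assert_allclose(err.e_SBP, 3.0)

    def test_band_errors_sum_to_overall_when_bands_partition(self):
        t = np.arange(0, 300, 0.25)
        lf_e, hf_e = np.sin(2 * np.pi * 0.12 * t), np.sin(2 * np.pi * 0.28 * t)
        lf_r, hf_r = 0.5 * lf_e, 0.25 * hf_e
        est = make_estimate(lf_e + hf_e, lf=lf_e, hf=hf_e)
        ref = make_estimate(lf_r + hf_r, lf=lf_r, hf=hf_r)
        err = band_errors(est, ref, ref, ref)
        np.testing.assert_allclose(err.e_LFSBP + err.e_HFSBP, err.e_SBP, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            band_errors(
                make_estimate(np.zeros(10)),
                make_estimate(np.zeros(11)),
                make_estimate(np.zeros(10)),
                make_estimate(np.zeros(10)),
            )


class TestPearsonR:
    def test_perfect_correlation(self):
        assert pearson_r([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_r([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]) == pytest.approx(-1.0)

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            want = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
            assert pearson_r(x, y) == pytest.approx(want, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=200), rng.normal(size=200)
        assert pearson_r(x, y) == pytest.approx(sst.pearsonr(x, y).statistic,
                                                abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


class TestAlignErrorBRS:
    def make_errors(self, n):
        z = np.arange(n, dtype=float)
        return ErrorSeries(*(z.copy() for _ in range(6)))

    def make_brs(self, starts, valid):
        starts = np.asarray(starts)
        valid = np.asarray(valid)
        brs = np.where(valid, 1.0, np.nan)
        return BRSSeries(window_start=starts, brs=brs,
                         n_q1=np.ones(len(starts), int),
                         n_q3=np.ones(len(starts), int), valid=valid)

    def test_full_valid_brs_pairs_every_window(self):
        errors = self.make_errors(50)
        brs = self.make_brs(np.arange(30), np.ones(30, bool))
        aligned, vals = align_error_brs(errors, brs)
        assert len(vals) == 30
        np.testing.assert_array_equal(aligned["e_SBP"], np.arange(30, dtype=float))

    def test_invalid_windows_reduce_pair_count_exactly(self):
        errors = self.make_errors(50)
        valid = np.ones(30, bool)
        valid[[3, 7, 20]] = False
        aligned, vals = align_error_brs(errors, self.make_brs(np.arange(30), valid))
        assert len(vals) == 27

    def test_all_invalid_excludes_subject(self):
        errors = self.make_errors(50)
        with pytest.raises(ValueError):
            align_error_brs(errors, self.make_brs(np.arange(30), np.zeros(30, bool)))


class TestCohortCriteria:
    def test_given_list_arithmetic(self):
        mu, sd, mav = cohort_criteria([0.5, -0.2, 0.8])
        assert mu == pytest.approx(0.3667, abs=1e-4)
        # population SD, divisor N
        assert sd == pytest.approx(np.sqrt(np.mean((np.array([0.5, -0.2, 0.8])
                                                    - mu) ** 2)), abs=1e-12)
        assert mav == pytest.approx(0.2)

    def test_identical_values_zero_sd(self):
        mu, sd, mav = cohort_criteria([0.4, 0.4, 0.4])
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert mav == pytest.approx(0.4)

    def test_mav_invariant_under_sign_flips(self):
        r = np.array([0.5, -0.2, 0.8, 0.1])
        _, _, mav1 = cohort_criteria(r)
        _, _, mav2 = cohort_criteria(r * np.array([1, -1, -1, 1]))
        assert mav1 == mav2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_criteria([])


class TestTTest:
    def test_identical_groups_t0_p1(self):
        with pytest.warns(UserWarning):
            t, p = lf_hf_ttest([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert t == 0.0 and p == 1.0

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        a = 1.0 + rng.normal(0, 1e-4, 4)
        b = 0.0 + rng.normal(0, 1e-4, 4)
        t, p = lf_hf_ttest(a, b)
        assert p < 1e-6

    def test_matches_manual_t_statistic(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0.6, 0.1, 12), rng.normal(0.3, 0.2, 12)
        t, p = lf_hf_ttest(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_manual, abs=1e-12)

    def test_short_groups_rejected(self):
        with pytest.raises(ValueError):
            lf_hf_ttest([0.1], [0.2, 0.3])


class TestRunFullAnalysis:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        return simulate_cohort(4, seed=13, duration=150.0, n_segments=2)

    def test_repeated_run_identical(self, small_cohort):
        a = run_full_analysis(small_cohort, abs_error=True)
        b = run_full_analysis(small_cohort, abs_error=True)
        assert a.per_subject_r == b.per_subject_r
        assert a.criteria == b.criteria

    def test_report_structure_complete(self, small_cohort):
        cs = run_full_analysis(small_cohort, abs_error=True)
        assert cs.n_subjects == 4
        for g in ("e_SBP", "e_DBP", "e_LFSBP", "e_LFDBP", "e_HFSBP", "e_HFDBP"):
            assert set(cs.criteria[g]) == {"mu", "sd", "mav"}
            assert all(abs(r) <= 1.0 for r in cs.per_subject_r[g])
        assert {"LF_vs_HF_SBP", "LF_vs_HF_DBP", "overall_SBP_vs_DBP"} <= set(
            cs.ttests
        )

    def test_too_small_cohort_rejected(self):
        cohort = simulate_cohort(2, seed=1, duration=10.0, n_segments=1)
        # 10 s gives too few beats for any BRS window in every subject
        with pytest.raises(ValueError):
            run_full_analysis(cohort)
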