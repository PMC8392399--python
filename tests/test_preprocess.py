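"""Each conditioning step against its analytic or plant-and-recover oracle."""

import numpy as np
import pandas as pd
import pytest

from ramanidh import (
    PreprocessConfig,
    SpectraSet,
    despike,
    generate_cohort,
    iqr_outlier_filter,
    minmax_normalize,
    msc_normalize,
    run_pipeline,
    s2n_filter,
    s2n_value,
    savgol_smooth,
    truncate,
    vra_baseline,
)
from ramanidh.preprocess import robust_noise_sigma

from conftest import flat_set, noiseless_config

AXIS = np.arange(350.0, 1801.0)


def _as_set(rows, axis=AXIS, labels=None):
    rows = np.atleast_2d(rows)
    n = rows.shape[0]
    meta = pd.DataFrame(
        {
            "point_id": [f"p{i}" for i in range(n)],
            "sample_id": [f"s{i}" for i in range(n)],
            "patient_id": [f"s{i}" for i in range(n)],
            "label": labels or ["unknown"] * n,
        }
    )
    return SpectraSet(axis, rows, meta)


class TestDespike:
    def test_noop_on_smooth_signal(self):
        y = 10 + np.sin(AXIS / 100.0)
        np.testing.assert_array_equal(despike(y), y)

    def test_single_spike_recovered(self):
        rng = np.random.default_rng(4)
        sigma = 0.5
        y = 10 + rng.normal(0, sigma, AXIS.size)
        clean = y.copy()
        y[700] += 50 * sigma
        out = despike(y)
        assert abs(out[700] - 10) < 3 * sigma
        # bins away from the spike untouched
        np.testing.assert_array_equal(out[:698], clean[:698])
        np.testing.assert_array_equal(out[703:], clean[703:])

    def test_two_spikes_recovered(self):
        rng = np.random.default_rng(5)
        sigma = 0.5
        clean = 10 + rng.normal(0, sigma, AXIS.size)
        y = clean.copy()
        y[300] += 80 * sigma
        y[900] -= 60 * sigma
        out = despike(y)
        assert np.max(np.abs(out - clean)) < 3 * sigma


class TestTruncate:
    def test_closed_interval_count(self, small_cohort):
        out = truncate(small_cohort, 400.0, 1750.0)
        assert out.axis.size == 1351  # 1750 - 400 + 1 on a unit grid
        assert out.axis[0] == 400.0 and out.axis[-1] == 1750.0

    def test_identity_when_already_inside(self, small_cohort):
        out = truncate(small_cohort, 0.0, 5000.0)
        np.testing.assert_array_equal(out.axis, small_cohort.axis)
        np.testing.assert_array_equal(out.intensities, small_cohort.intensities)

    def test_idempotent(self, small_cohort):
        once = truncate(small_cohort, 400.0, 1750.0)
        twice = truncate(once, 400.0, 1750.0)
        assert once == twice

    def test_empty_overlap_errors(self, small_cohort):
        with pytest.raises(ValueError):
            truncate(small_cohort, 2000.0, 2100.0)


class TestIqrOutlierFilter:
    def test_identical_spectra_none_rejected(self):
        kept, rejected = iqr_outlier_filter(flat_set(20), k=1.5)
        assert rejected == [] and len(kept) == 20

    def test_single_gross_outlier_caught(self):
        rows = np.ones((20, 100)) + np.random.default_rng(1).normal(0, 1e-3, (20, 100))
        rows[7] *= 100
        axis = np.linspace(400, 1750, 100)
        kept, rejected = iqr_outlier_filter(_as_set(rows, axis), k=1.5)
        assert rejected == ["p7"] and len(kept) == 19

    def test_infinite_k_rejects_nothing(self):
        rows = np.random.default_rng(2).uniform(0, 10, (30, 50))
        axis = np.linspace(400, 1750, 50)
        _, rejected = iqr_outlier_filter(_as_set(rows, axis), k=np.inf)
        assert rejected == []

    def test_too_few_spectra_error(self):
        with pytest.raises(ValueError):
            iqr_outlier_filter(flat_set(3), k=1.5)


class TestMsc:
    def test_affine_distortion_exactly_inverted(self):
        ref = 5 + np.sin(AXIS / 80.0) ** 2
        distorted = 2.0 + 3.0 * ref
        out = msc_normalize(_as_set(np.vstack([distorted, ref])), reference=ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-8)

    def test_reference_maps_to_itself(self):
        ref = 5 + np.cos(AXIS / 60.0)
        other = 1 + 2 * ref
        out = msc_normalize(_as_set(np.vstack([ref, other])), reference=ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-8)

    def test_post_msc_refit_slope_one_intercept_zero(self):
        cohort = generate_cohort(
            noiseless_config(seed=8, scatter_slope_sd=0.2, scatter_offset_sd=3.0,
                             n_patients_per_class=5, spectra_per_patient=4)
        )
        ref = cohort.intensities.mean(axis=0)
        out = msc_normalize(cohort, reference=ref)
        design = np.column_stack([np.ones_like(ref), ref])
        coef, *_ = np.linalg.lstsq(design, out.intensities.T, rcond=None)
        np.testing.assert_allclose(coef[0], 0.0, atol=1e-8)
        np.testing.assert_allclose(coef[1], 1.0, atol=1e-8)

    def test_idempotent_with_fixed_reference(self):
        rng = np.random.default_rng(3)
        ref = 5 + np.sin(AXIS / 90.0)
        rows = np.array([a + b * ref for a, b in rng.uniform(0.5, 2, (6, 2))])
        once = msc_normalize(_as_set(rows), reference=ref)
        twice = msc_normalize(once, reference=ref)
        np.testing.assert_allclose(once.intensities, twice.intensities, atol=1e-9)


class TestS2N:
    cfg = PreprocessConfig()

    def _peak_spectrum(self, noise_sd, seed=0, amplitude=50.0):
        rng = np.random.default_rng(seed)
        y = amplitude * 16.0 / ((AXIS - 1004.0) ** 2 + 16.0)
        y[AXIS >= 1690] = 0.0  # keep the noise-estimation window flat
        return y + rng.normal(0, noise_sd, AXIS.size) if noise_sd else y

    def test_noiseless_peak_gives_infinite_s2n(self):
        assert s2n_value(AXIS, self._peak_spectrum(0.0)) == np.inf
        kept, values = s2n_filter(_as_set(self._peak_spectrum(0.0)), self.cfg)
        assert len(kept) == 1

    def test_s2n_halves_when_noise_doubles(self):
        ratios = []
        for seed in range(200):
            s1 = s2n_value(AXIS, self._peak_spectrum(1.0, seed))
            s2 = s2n_value(AXIS, self._peak_spectrum(2.0, seed + 10_000))
            ratios.append(s1 / s2)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.2)

    def test_signal_free_spectrum_rejected(self):
        rng = np.random.default_rng(9)
        flat_noisy = 5 + rng.normal(0, 1.0, AXIS.size)
        kept, values = s2n_filter(_as_set(flat_noisy), self.cfg)
        assert len(kept) == 0
        assert abs(list(values.values())[0]) < 3.5

    def test_noise_sigma_estimates_true_sd(self):
        rng = np.random.default_rng(12)
        estimates = [
            robust_noise_sigma(AXIS, rng.normal(0, 2.0, AXIS.size), (1700, 1750))
            for _ in range(100)
        ]
        assert np.mean(estimates) == pytest.approx(2.0, rel=0.15)


class TestVraBaseline:
    def test_pure_polynomial_is_all_baseline(self):
        x = np.linspace(-1, 1, AXIS.size)
        y = 100 + 30 * x - 50 * x**2 + 10 * x**3 + 5 * x**4
        baseline, corrected, converged = vra_baseline(y, AXIS, order=5)
        assert converged
        np.testing.assert_allclose(baseline, y, rtol=1e-6)
        assert np.max(np.abs(corrected)) < 1e-4 * np.max(y)

    def test_planted_peak_recovered_within_5pct(self):
        x = np.linspace(-1, 1, AXIS.size)
        base = 200 + 40 * x - 60 * x**2 + 20 * x**3
        peak = 100 * 64.0 / ((AXIS - 1100.0) ** 2 + 64.0)
        baseline, corrected, _ = vra_baseline(base + peak, AXIS, order=5)
        assert np.max(corrected) == pytest.approx(100.0, rel=0.05)

    def test_zero_input(self):
        baseline, corrected, converged = vra_baseline(np.zeros(AXIS.size), AXIS, order=5)
        np.testing.assert_array_equal(baseline, 0.0)
        np.testing.assert_array_equal(corrected, 0.0)
        assert converged

    def test_peak_free_regions_centered_near_zero(self):
        rng = np.random.default_rng(6)
        x = np.linspace(-1, 1, AXIS.size)
        base = 300 - 100 * x + 50 * x**2
        noise = rng.normal(0, 1.0, AXIS.size)
        peak = 80 * 36.0 / ((AXIS - 900.0) ** 2 + 36.0)
        _, corrected, _ = vra_baseline(base + peak + noise, AXIS, order=5)
        quiet = (AXIS < 700) | (AXIS > 1200)
        dev = np.std(corrected[quiet])
        assert abs(np.mean(corrected[quiet])) < dev

    def test_nonconvergence_flag(self):
        rng = np.random.default_rng(10)
        y = 100 + rng.normal(0, 5, AXIS.size)
        _, _, converged = vra_baseline(y, AXIS, order=5, max_iter=1)
        assert not converged


class TestSavgol:
    def test_cubic_polynomial_invariant(self):
        y = 1 + 2 * AXIS + 3e-3 * AXIS**2 - 4e-7 * AXIS**3
        np.testing.assert_allclose(savgol_smooth(y), y, rtol=1e-9)

    def test_constant_unchanged(self):
        y = np.full(AXIS.size, 7.0)
        np.testing.assert_allclose(savgol_smooth(y), y, rtol=1e-12)

    def test_noise_power_reduced(self):
        cubic = 1e-6 * (AXIS - 1000.0) ** 3
        worse = 0
        for seed in range(50):
            noise = np.random.default_rng(seed).normal(0, 1.0, AXIS.size)
            smoothed = savgol_smooth(cubic + noise)
            worse += np.var(smoothed - cubic) >= np.var(noise)
        assert worse == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(50), order=3, window=8)


class TestMinMax:
    def test_global_scope_attains_0_and_1(self, small_cohort):
        out = minmax_normalize(small_cohort, "global")
        assert out.intensities.min() == 0.0
        assert out.intensities.max() == 1.0

    def test_affine_invariance(self, small_cohort):
        shifted = small_cohort.with_intensities(3.0 * small_cohort.intensities + 11.0)
        a = minmax_normalize(small_cohort, "global")
        b = minmax_normalize(shifted, "global")
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-12)

    def test_global_idempotent(self, small_cohort):
        once = minmax_normalize(small_cohort, "global")
        twice = minmax_normalize(once, "global")
        np.testing.assert_allclose(once.intensities, twice.intensities, atol=1e-15)

    def test_per_spectrum_scope(self):
        rows = np.vstack([np.linspace(0, 10, 100), np.linspace(5, 6, 100)])
        out = minmax_normalize(_as_set(rows, np.linspace(400, 1750, 100)), "per_spectrum")
        for row in out.intensities:
            assert row.min() == 0.0 and row.max() == 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(flat_set(5), "global")


class TestPipeline:
    def test_artifact_free_cohort_loses_nothing(self):
        cohort = generate_cohort(noiseless_config(seed=2))
        out, report = run_pipeline(cohort)
        assert report.n_input == report.n_after_outlier == report.n_after_s2n == len(cohort)
        assert len(out) == len(cohort)

    def test_planted_gross_outliers_all_caught(self, small_cohort):
        boosted = small_cohort.intensities.copy()
        planted = [3, 17, 41, 66, 90]  # ~5% of the cohort
        boosted[planted] *= 100
        cohort = small_cohort.with_intensities(boosted)
        _, report = run_pipeline(cohort)
        rejected_iqr = {
            r["point_id"] for r in report.rejections if r["reason"] == "iqr_outlier"
        }
        assert {str(cohort.point_ids[i]) for i in planted} <= rejected_iqr

    def test_report_counts_monotone(self, small_cohort):
        _, report = run_pipeline(small_cohort)
        assert report.n_input >= report.n_after_outlier >= report.n_after_s2n
        assert all(r["reason"] in ("iqr_outlier", "low_s2n") for r in report.rejections)

    def test_deterministic(self, small_cohort):
        a, _ = run_pipeline(small_cohort)
        b, _ = run_pipeline(small_cohort)
        assert a == b

    def test_unknown_step_rejected(self, small_cohort):
        cfg = PreprocessConfig(step_order=("despike", "fourier_magic"))
        with pytest.raises(ValueError, match="fourier_magic"):
            run_pipeline(small_cohort, cfg)

    def test_axis_only_changed_by_truncate(self, small_cohort):
        cfg = PreprocessConfig(
            step_order=("despike", "iqr_outlier_filter", "msc_normalize",
                        "s2n_filter", "vra_baseline", "savgol_smooth",
                        "minmax_normalize")
        )
        out, _ = run_pipeline(small_cohort, cfg)
        np.testing.assert_array_equal(out.axis, small_cohort.axis)

    def test_alternative_step_order_runs(self, small_cohort):
        """S2N gate before vs after background subtraction — both orders runnable."""
        cfg = PreprocessConfig(
            step_order=("despike", "truncate", "iqr_outlier_filter", "msc_normalize",
                        "vra_baseline", "s2n_filter", "savgol_smooth",
                        "minmax_normalize")
        )
        out, report = run_pipeline(small_cohort, cfg)
        assert report.n_input >= report.n_after_s2n
        assert len(out) == report.n_after_s2n
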