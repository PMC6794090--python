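"""Statistical and determinism properties of the synthetic generators."""

import numpy as np
import pytest

from flyclock.dam import default_schedule
from flyclock.simulate import (
    SyntheticCohortSpec,
    SyntheticFlyParams,
    SyntheticTimecourseParams,
    expected_rate,
    simulate_cohort,
    simulate_fly,
    simulate_nucleus_image,
    simulate_timecourse,
)


@pytest.fixture(scope="module")
def sched():
    return default_schedule(n_ld_days=0)


class TestFly:
    def test_flat_fly_total_counts_match_poisson_moments(self, sched):
        p = SyntheticFlyParams(baseline_rate=0.1, amplitude=0.0, arrhythmic=True, seed=4)
        s = simulate_fly(p, sched, 1)
        expected = 0.1 * 1440  # 144
        sd = np.sqrt(expected)
        assert abs(s.counts.sum() - expected) < 3 * sd

    def test_identical_seed_identical_series(self, sched):
        p = SyntheticFlyParams(seed=123)
        a = simulate_fly(p, sched, 3)
        b = simulate_fly(p, sched, 3)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_circular_mean_phase_matches_rate_model(self, sched):
        """Activity phase (circular mean) agrees with the lambda(t) model."""
        p = SyntheticFlyParams(amplitude=2.0, period_h=24.0, seed=9)
        s = simulate_fly(p, sched, 9)
        lam = expected_rate(p, sched, 9)
        phi = (np.arange(lam.size) / 60.0) % 24.0
        ang = 2 * np.pi * phi / 24

        def circ_mean(w):
            return (np.angle(np.sum(w * np.exp(1j * ang))) / (2 * np.pi) * 24) % 24

        implanted = circ_mean(lam)
        observed = circ_mean(s.counts)
        diff = min(abs(observed - implanted), 24 - abs(observed - implanted))
        assert diff < 1.0

    def test_negative_rate_parameters_rejected(self):
        with pytest.raises(ValueError):
            SyntheticFlyParams(baseline_rate=-1)
        with pytest.raises(ValueError):
            SyntheticFlyParams(amplitude=-0.5)

    def test_arrhythmic_flag_flattens_rate(self, sched):
        p = SyntheticFlyParams(
            amplitude=2.0, anticipation_ramp="both", ramp_gain=2.0, arrhythmic=True
        )
        lam = expected_rate(p, sched, 2)
        assert np.ptp(lam) == 0

    def test_damping_attenuates_rate_per_day(self, sched):
        p = SyntheticFlyParams(amplitude=0, arrhythmic=True, damping_per_day=0.5)
        lam = expected_rate(p, sched, 3)
        assert lam[0] == pytest.approx(2 * lam[1440])
        assert lam[1440] == pytest.approx(2 * lam[2880])


class TestCohort:
    def test_determinism(self, sched):
        spec = SyntheticCohortSpec(n_flies=3, master_seed=5, n_ld_days=0, n_dd_days=2)
        a = simulate_cohort(spec, sched)
        b = simulate_cohort(spec, sched)
        for x, y in zip(a["synthetic"], b["synthetic"]):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_fly_records_independent_of_cohort_size(self, sched):
        small = SyntheticCohortSpec(n_flies=2, master_seed=5, n_ld_days=0, n_dd_days=2)
        big = SyntheticCohortSpec(n_flies=4, master_seed=5, n_ld_days=0, n_dd_days=2)
        a = simulate_cohort(small, sched)["synthetic"]
        b = simulate_cohort(big, sched)["synthetic"]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_invalid_cohort_size(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n_flies=0)

    def test_period_jitter_centers_on_spec_period(self, sched):
        # jittered per-fly periods average back to the shared value
        spec = SyntheticCohortSpec(
            n_flies=200,
            params=SyntheticFlyParams(period_h=24.0),
            period_jitter_sd_h=0.3,
            master_seed=11,
            n_ld_days=0,
            n_dd_days=1,
        )
        periods = []
        for i in range(spec.n_flies):
            ss = np.random.SeedSequence([spec.master_seed, i])
            rng = np.random.default_rng(ss)
            periods.append(24.0 + rng.normal(0, 0.3))
        # the cohort draws the same per-fly jitter stream
        cohort = simulate_cohort(spec, sched)
        assert len(cohort["synthetic"]) == 200
        assert abs(np.mean(periods) - 24.0) < 3 * 0.3 / np.sqrt(200)


class TestTimecourse:
    def test_zero_amplitude_flat_expectation(self):
        p = SyntheticTimecourseParams(rel_amplitude=0.0, noise_cv=0.0)
        tc = simulate_timecourse(p)
        _, y = tc.flat()
        np.testing.assert_allclose(y, p.mesor)

    def test_zero_noise_exact_cosine(self):
        p = SyntheticTimecourseParams(noise_cv=0.0, rel_amplitude=0.5, acrophase_ct=13.0)
        tc = simulate_timecourse(p)
        for t, vals in zip(tc.timepoints, tc.values):
            expect = 1.0 * (1 + 0.5 * np.cos(2 * np.pi * (t - 13.0) / 24.0))
            np.testing.assert_allclose(vals, expect)

    def test_sample_cv_matches_noise_cv(self):
        p = SyntheticTimecourseParams(
            rel_amplitude=0.0, noise_cv=0.2, n_replicates=4000, seed=8
        )
        tc = simulate_timecourse(p)
        _, y = tc.flat()
        # lognormal with mean 1 and CV 0.2; SE of sample CV ~ cv/sqrt(2n)
        assert abs(y.std(ddof=1) / y.mean() - 0.2) < 0.01

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTimecourseParams(noise_cv=-0.1)


class TestNucleusImage:
    def test_noiseless_means_exact(self):
        intensities = np.linspace(50, 200, 16)
        img, labels = simulate_nucleus_image(16, intensities, 20.0, 0.0, seed=2)
        for k in range(1, 17):
            assert img[labels == k].mean() == pytest.approx(intensities[k - 1])
        assert img[labels == 0].mean() == pytest.approx(20.0)

    def test_noisy_means_within_standard_error(self):
        intensities = np.full(10, 100.0)
        img, labels = simulate_nucleus_image(10, intensities, 20.0, 5.0, seed=3)
        for k in range(1, 11):
            area = (labels == k).sum()
            assert abs(img[labels == k].mean() - 100.0) < 3 * 5.0 / np.sqrt(area)

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="place"):
            simulate_nucleus_image(
                500, np.full(500, 100.0), 10.0, 0.0, seed=1, shape=(64, 64), radius=6
            )
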