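import numpy as np
import pytest

from flyclock.dam import ActivitySeries, LightSchedule, default_schedule


@pytest.fixture(scope="session")
def schedule() -> LightSchedule:
    """12:12 LD schedule, 2 LD days then DD, lights-on 08:00."""
    return default_schedule(n_ld_days=2)


@pytest.fixture(scope="session")
def dd_schedule() -> LightSchedule:
    """Schedule with no recorded LD days (record starts at DD day 1, CT0)."""
    return default_schedule(n_ld_days=0)


@pytest.fixture
def make_series(dd_schedule):
    """Factory for a DD ActivitySeries from raw counts at a given bin width."""

    def _make(counts, bin_width=15, fly_id="fly", schedule=dd_schedule):
        return ActivitySeries.from_counts(
            fly_id=fly_id,
            t0=schedule.dd_start,
            bin_width=bin_width,
            counts=np.asarray(counts),
            schedule=schedule,
        )

    return _make


@pytest.fixture
def sine_series(make_series):
    """Noiseless sinusoid around a positive mean, 9 days at 15-min bins."""

    def _make(period_h=24.0, n_days=9, bin_width=15, amp=40.0, mean=100.0, phase=0.0):
        n = n_days * 1440 // bin_width
        t = np.arange(n) * bin_width / 60.0
        x = mean + amp * np.cos(2 * np.pi * (t - phase) / period_h)
        return make_series(np.round(x).astype(int), bin_width=bin_width)

    return _make
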