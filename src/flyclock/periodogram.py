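"""Periodograms for evenly-binned locomotor activity.

Two statistics are standard in circadian analysis and both are computed here:

* the classical normalized Lomb-Scargle periodogram ``P_N(omega)`` — for each
  candidate period, the least-squares sine+cosine fit's reduction in sum of
  squares divided by twice the sample variance, with Scargle's time-offset
  ``tau`` making the two quadrature terms independent;
* the Sokolove-Bushell chi-square periodogram ``Q_P`` — the series is folded
  at each candidate period and the variance of the column means is compared
  to the total variance, referred to a chi-square distribution with ``P - 1``
  degrees of freedom (``P`` = bins per candidate period).

Significance lines follow the conventional constructions: for Lomb-Scargle
the independent-frequency approximation over the ``M`` candidate periods,
``-ln(1 - (1 - alpha)^(1/M))``; for the chi-square periodogram the
``1 - alpha`` quantile of chi-square with ``P - 1`` df.  ``alpha`` defaults
to 0.001 throughout, the customary cutoff for rhythmicity screening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dam import ActivitySeries

DEFAULT_PERIOD_RANGE_H = (18.0, 30.0)
DEFAULT_ALPHA = 1e-3


@dataclass
class Periodogram:
    """Periodogram statistic and significance line over candidate periods."""

    method: str  # "lomb_scargle" | "chi_square"
    periods_h: np.ndarray
    stat: np.ndarray
    threshold: np.ndarray
    alpha: float
    peak_period_h: float
    peak_stat: float
    peak_threshold: float

    @property
    def peak_delta(self) -> float:
        """Peak statistic minus its significance line (rhythm-power style)."""
        return self.peak_stat - self.peak_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"period_h": self.periods_h, "stat": self.stat, "threshold": self.threshold}
        )

    def peak_summary(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "peak_period_h": float(self.peak_period_h),
            "peak_stat": float(self.peak_stat),
            "peak_threshold": float(self.peak_threshold),
            "peak_delta": float(self.peak_delta),
        }


def candidate_periods(
    bin_width_min: int, period_range_h: tuple[float, float] = DEFAULT_PERIOD_RANGE_H
) -> np.ndarray:
    """Candidate periods: integer multiples of the bin width inside the range."""
    lo, hi = period_range_h
    if not lo < hi:
        raise ValueError("period range must satisfy lo < hi")
    step = bin_width_min / 60.0
    k_lo = int(np.ceil(lo / step - 1e-9))
    k_hi = int(np.floor(hi / step + 1e-9))
    periods = np.arange(k_lo, k_hi + 1) * step
    if periods.size == 0:
        raise ValueError("empty candidate period grid")
    return periods


def _check_series(series: ActivitySeries) -> np.ndarray:
    x = np.asarray(series.counts, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("constant signal: periodogram undefined for zero variance")
    return x


def lomb_scargle(
    series: ActivitySeries,
    period_range_h: tuple[float, float] = DEFAULT_PERIOD_RANGE_H,
    alpha: float = DEFAULT_ALPHA,
    periods_h: np.ndarray | None = None,
) -> Periodogram:
    """Classical normalized Lomb-Scargle periodogram of a binned series.

    Normalization is by the sample variance (ddof=1) of the counts, so the
    power at a candidate period equals the least-squares sinusoid fit's
    reduction in sum of squares divided by ``2 * variance``.
    """
    x = _check_series(series)
    if periods_h is None:
        periods_h = candidate_periods(series.bin_width, period_range_h)
    periods_h = np.asarray(periods_h, dtype=float)
    if periods_h.size == 0:
        raise ValueError("empty candidate period grid")
    t = np.arange(x.size) * (series.bin_width / 60.0)  # hours
    xc = x - x.mean()
    var = x.var(ddof=1)
    omega = 2 * np.pi / periods_h[:, None]  # (M, 1)
    two_wt = 2 * omega * t[None, :]
    tau = np.arctan2(np.sin(two_wt).sum(axis=1), np.cos(two_wt).sum(axis=1)) / (
        2 * omega[:, 0]
    )
    arg = omega * (t[None, :] - tau[:, None])
    c, s = np.cos(arg), np.sin(arg)
    power = 0.5 / var * (
        (c @ xc) ** 2 / (c * c).sum(axis=1) + (s @ xc) ** 2 / (s * s).sum(axis=1)
    )
    m = periods_h.size
    z = -np.log(1 - (1 - alpha) ** (1.0 / m))
    threshold = np.full(m, z)
    i = int(np.argmax(power))
    return Periodogram(
        method="lomb_scargle",
        periods_h=periods_h,
        stat=power,
        threshold=threshold,
        alpha=alpha,
        peak_period_h=float(periods_h[i]),
        peak_stat=float(power[i]),
        peak_threshold=float(threshold[i]),
    )


def ls_power_oracle(series: ActivitySeries, period_h: float) -> float:
    """Least-squares reference for the Lomb-Scargle power at one period.

    Fits ``a*cos(omega t) + b*sin(omega t)`` to the mean-centered counts by
    ordinary least squares and returns the reduction in the sum of squares
    divided by ``2 * variance``.  Kept deliberately independent of
    :func:`lomb_scargle` as a cross-check.
    """
    x = np.asarray(series.counts, dtype=float)
    t = np.arange(x.size) * (series.bin_width / 60.0)
    xc = x - x.mean()
    omega = 2 * np.pi / period_h
    design = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    coef, *_ = np.linalg.lstsq(design, xc, rcond=None)
    resid = xc - design @ coef
    ss_reduction = xc @ xc - resid @ resid
    return float(ss_reduction / (2 * x.var(ddof=1)))


def chi_square_periodogram(
    series: ActivitySeries,
    period_range_h: tuple[float, float] = DEFAULT_PERIOD_RANGE_H,
    alpha: float = DEFAULT_ALPHA,
) -> Periodogram:
    """Sokolove-Bushell chi-square periodogram.

    For each candidate period of ``P`` bins the series is folded into ``P``
    columns over ``K = floor(N / P)`` complete cycles (a trailing partial
    cycle is discarded) and

    ``Q_P = K * sum_h (M_h - Mbar)^2 / sigma^2``

    with ``M_h`` the column means, ``Mbar`` the grand mean and ``sigma^2``
    the population variance of the retained bins.  The significance line is
    the ``1 - alpha`` chi-square quantile with ``P - 1`` df.
    """
    x = _check_series(series)
    periods_h = candidate_periods(series.bin_width, period_range_h)
    p_bins = np.round(periods_h * 60.0 / series.bin_width).astype(int)
    if x.size // p_bins.max() < 2:
        raise ValueError(
            "need at least 2 complete cycles at the longest candidate period"
        )
    q = np.empty(p_bins.size)
    thr = np.empty(p_bins.size)
    for j, p in enumerate(p_bins):
        k = x.size // p
        kept = x[: k * p].reshape(k, p)
        col_means = kept.mean(axis=0)
        grand = kept.mean()
        var = ((kept - grand) ** 2).mean()
        if var == 0:
            raise ValueError("constant signal in retained window")
        q[j] = k * ((col_means - grand) ** 2).sum() / var
        thr[j] = sps.chi2.ppf(1 - alpha, df=p - 1)
    i = int(np.argmax(q))
    return Periodogram(
        method="chi_square",
        periods_h=periods_h,
        stat=q,
        threshold=thr,
        alpha=alpha,
        peak_period_h=float(periods_h[i]),
        peak_stat=float(q[i]),
        peak_threshold=float(thr[i]),
    )
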