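"""Synthetic cohorts, expression time courses and nucleus images.

The generators emulate the statistical structure of a standard fly circadian
experiment so that every downstream analysis stage can be exercised without
recordings: per-minute Poisson beam-break counts with a bimodal (morning +
evening peak) daily activity profile, optional anticipation ramps rising over
the 3 h before each projected light transition, per-fly period/phase jitter
and amplitude damping; cosine expression time courses sampled at discrete
circadian times with multiplicative lognormal noise; and grayscale images of
disk-shaped nuclei over a uniform noisy background, with ground-truth masks.

All generators are pure functions of their seed: identical parameters and
seed reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .dam import ActivitySeries, CohortTable, LightSchedule, default_schedule
from .jtk import ExpressionTimeCourse

DEFAULT_TIMEPOINTS_CT = (1.0, 5.0, 9.0, 13.0, 17.0, 21.0, 25.0)


@dataclass(frozen=True)
class SyntheticFlyParams:
    """Generative parameters for one fly's activity record.

    The expected beam-break rate per minute is

    ``lambda(t) = baseline_rate * [1 + amplitude * template(phi(t)) + ramp(phi(t))]
    * (1 - damping_per_day) ** day``

    where ``phi(t)`` is the fly's internal circadian hour (entrained, 24 h, on
    LD days; advancing at ``24 / period_h`` per hour in DD) and ``template``
    is a pair of raised-cosine bumps at the morning and evening peaks.  Ramps
    rise linearly from 0 to ``ramp_gain`` over the 3 h before the projected
    lights-on (morning) and/or lights-off (evening) transition.
    """

    period_h: float = 24.0
    baseline_rate: float = 0.6  # expected counts per minute
    amplitude: float = 1.5
    morning_peak_ct: float = 0.0
    evening_peak_ct: float = 12.0
    morning_weight: float = 0.5  # evening-dominant profile, typical of DD
    peak_width_h: float = 4.0
    anticipation_ramp: str = "none"  # none | morning | evening | both
    ramp_gain: float = 1.0
    damping_per_day: float = 0.0
    phase_offset_h: float = 0.0
    arrhythmic: bool = False
    dispersion: float | None = None  # negative-binomial shape; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.amplitude < 0 or self.ramp_gain < 0:
            raise ValueError("amplitude and ramp_gain must be >= 0")
        if not 0 <= self.damping_per_day < 1:
            raise ValueError("damping_per_day must lie in [0, 1)")
        if self.anticipation_ramp not in ("none", "morning", "evening", "both"):
            raise ValueError(f"unknown anticipation_ramp {self.anticipation_ramp!r}")
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A cohort of flies sharing parameters up to per-fly jitter."""

    n_flies: int
    params: SyntheticFlyParams = field(default_factory=SyntheticFlyParams)
    period_jitter_sd_h: float = 0.0
    phase_jitter_sd_h: float = 0.0
    n_ld_days: int = 2
    n_dd_days: int = 9
    group: str = "synthetic"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")


@dataclass(frozen=True)
class SyntheticTimecourseParams:
    """Cosine expression time course with multiplicative lognormal noise."""

    mesor: float = 1.0
    rel_amplitude: float = 0.5
    period_h: float = 24.0
    acrophase_ct: float = 13.0
    noise_cv: float = 0.2
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS_CT
    n_replicates: int = 4
    gene: str = "gene"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mesor <= 0:
            raise ValueError("mesor must be positive")
        if not 0 <= self.rel_amplitude <= 1:
            raise ValueError("rel_amplitude must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _raised_cosine(phi: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Bump of height 1 at ``center``, support ``center +/- half_width`` (circular)."""
    d = (phi - center + 12.0) % 24.0 - 12.0
    out = np.zeros_like(phi)
    inside = np.abs(d) <= half_width
    out[inside] = 0.5 * (1 + np.cos(np.pi * d[inside] / half_width))
    return out


def expected_rate(
    params: SyntheticFlyParams, schedule: LightSchedule, n_days: int
) -> np.ndarray:
    """Per-minute expected rate lambda(t) over ``n_days`` from the record start."""
    n_min = n_days * 1440
    t0 = schedule.ld_start()
    minutes = np.arange(n_min)
    hours = minutes / 60.0
    dd_offset_h = (schedule.dd_start - t0).total_seconds() / 3600.0
    in_dd = hours >= dd_offset_h
    # internal phase: entrained 24 h clock in LD, free-running at period_h in DD
    phi = np.empty(n_min)
    start_phase = schedule.phase_of(t0)
    phi[~in_dd] = (start_phase + hours[~in_dd]) % 24.0
    phase_at_dd = (start_phase + dd_offset_h) % 24.0
    phi[in_dd] = (
        phase_at_dd + (hours[in_dd] - dd_offset_h) * 24.0 / params.period_h
    ) % 24.0
    phi = (phi + params.phase_offset_h) % 24.0

    amplitude = 0.0 if params.arrhythmic else params.amplitude
    gain = 0.0 if params.arrhythmic else params.ramp_gain
    template = params.morning_weight * _raised_cosine(
        phi, params.morning_peak_ct, params.peak_width_h
    ) + _raised_cosine(phi, params.evening_peak_ct, params.peak_width_h)
    ramp = np.zeros(n_min)
    if gain > 0 and params.anticipation_ramp in ("morning", "both"):
        m = (phi >= 21.0) & (phi < 24.0)
        ramp[m] += gain * (phi[m] - 21.0) / 3.0
    if gain > 0 and params.anticipation_ramp in ("evening", "both"):
        m = (phi >= 9.0) & (phi < 12.0)
        ramp[m] += gain * (phi[m] - 9.0) / 3.0
    day = minutes // 1440
    lam = (
        params.baseline_rate
        * (1 + amplitude * template + ramp)
        * (1 - params.damping_per_day) ** day
    )
    if np.any(lam < 0):
        raise ValueError("expected rate lambda(t) went negative")
    return lam


def simulate_fly(
    params: SyntheticFlyParams,
    schedule: LightSchedule,
    n_days: int,
    fly_id: str = "sim",
) -> ActivitySeries:
    """Draw one fly's per-minute counts from the specified rate model."""
    lam = expected_rate(params, schedule, n_days)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    if params.dispersion is None:
        counts = rng.poisson(lam)
    else:
        # gamma-Poisson mixture: mean lam, shape params.dispersion
        k = params.dispersion
        counts = rng.poisson(rng.gamma(shape=k, scale=lam / k))
    return ActivitySeries.from_counts(
        fly_id=fly_id,
        t0=schedule.ld_start(),
        bin_width=1,
        counts=counts,
        schedule=schedule,
        flagged=None,
    )


def simulate_cohort(
    spec: SyntheticCohortSpec, schedule: LightSchedule | None = None
) -> CohortTable:
    """Simulate ``n_flies`` records with per-fly jittered period and phase.

    Per-fly seeds are spawned from ``master_seed`` and the fly index, so the
    record of fly ``i`` does not depend on the cohort size.
    """
    if schedule is None:
        schedule = default_schedule(n_ld_days=spec.n_ld_days)
    n_days = spec.n_ld_days + spec.n_dd_days
    flies: list[ActivitySeries] = []
    for i in range(spec.n_flies):
        ss = np.random.SeedSequence([spec.master_seed, i])
        jit_rng = np.random.default_rng(ss)
        period = spec.params.period_h
        phase = spec.params.phase_offset_h
        if spec.period_jitter_sd_h > 0:
            period = max(1.0, period + jit_rng.normal(0, spec.period_jitter_sd_h))
        if spec.phase_jitter_sd_h > 0:
            phase = phase + jit_rng.normal(0, spec.phase_jitter_sd_h)
        fly_seed = int(ss.generate_state(1)[0] % (2**31))
        p = replace(
            spec.params, period_h=period, phase_offset_h=phase, seed=fly_seed
        )
        flies.append(
            simulate_fly(p, schedule, n_days, fly_id=f"{spec.group}#{i:03d}")
        )
    return CohortTable({spec.group: flies})


def simulate_timecourse(p: SyntheticTimecourseParams) -> ExpressionTimeCourse:
    """Cosine time course with mean-one multiplicative lognormal noise.

    ``y(t, rep) = mesor * (1 + rel_amplitude * cos(2 pi (t - acrophase) / period))
    * exp(N(-s^2/2, s))`` with ``s^2 = ln(1 + noise_cv^2)``, so the noise factor
    has mean 1 and coefficient of variation ``noise_cv``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    t = np.asarray(p.timepoints, dtype=float)
    mean = p.mesor * (
        1 + p.rel_amplitude * np.cos(2 * np.pi * (t - p.acrophase_ct) / p.period_h)
    )
    s2 = np.log1p(p.noise_cv**2)
    s = np.sqrt(s2)
    values = []
    for mu in mean:
        noise = np.exp(rng.normal(-s2 / 2, s, size=p.n_replicates)) if s > 0 else np.ones(p.n_replicates)
        values.append(mu * noise)
    return ExpressionTimeCourse(gene=p.gene, timepoints=t, values=values)


def simulate_nucleus_image(
    n_nuclei: int,
    intensities: np.ndarray | list[float],
    background_level: float,
    noise_sd: float,
    seed: int,
    shape: tuple[int, int] = (256, 256),
    radius: int = 6,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint disk-shaped nuclei over a uniform background plus Gaussian noise.

    Returns ``(image, labels)`` where ``labels`` is an integer mask with
    label ``k`` marking nucleus ``k`` (1-based).  Raises if the requested
    number of non-overlapping disks cannot be placed.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size != n_nuclei:
        raise ValueError("need one intensity per nucleus")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    img = np.full(shape, float(background_level))
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    centers: list[tuple[int, int]] = []
    for k in range(n_nuclei):
        for attempt in range(max_tries):
            cy = int(rng.integers(radius, shape[0] - radius))
            cx = int(rng.integers(radius, shape[1] - radius))
            if all((cy - y) ** 2 + (cx - x) ** 2 > (2 * radius + 2) ** 2 for y, x in centers):
                break
        else:
            raise ValueError(
                f"could not place {n_nuclei} disjoint nuclei of radius {radius} "
                f"in a {shape} image"
            )
        centers.append((cy, cx))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        img[disk] = intensities[k]
        labels[disk] = k + 1
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, size=shape)
    return img, labels
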