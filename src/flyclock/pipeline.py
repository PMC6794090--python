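"""End-to-end orchestration: monitor files or synthetic cohorts to tables.

A single :class:`RunConfig` drives the whole locomotor analysis: read (or
simulate) per-minute records, bin to 15 min, classify the DD window of every
fly, summarize each group, compute anticipation indices over the standard
spans, compare groups, and emit actogram matrices plus a provenance record
with every threshold and seed.  All outputs are deterministic functions of
the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import dam
from .anticipation import DEFAULT_SPANS, cohort_anticipation
from .dam import ActivitySeries, CohortTable, LightSchedule, default_schedule
from .rhythmicity import (
    RhythmConfig,
    calls_to_frame,
    classify_fly,
    summarize_cohort,
)
from .simulate import SyntheticCohortSpec, SyntheticFlyParams, simulate_cohort
from .stats import anova_tukey, comparison_to_frame, kruskal_dunn

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass
class GroupSpec:
    """One synthetic genotype group: name plus fly-parameter overrides."""

    name: str
    n_flies: int = 16
    params: dict[str, Any] = field(default_factory=dict)
    period_jitter_sd_h: float = 0.1
    phase_jitter_sd_h: float = 0.25


@dataclass
class RunConfig:
    """Everything a run needs; defaults follow the standard protocol.

    Input is either a list of ``(monitor file, channel -> group map)`` pairs
    or a list of synthetic group specs.  Analysis windows, the periodogram
    alpha (0.001), the rhythmicity delta threshold (150) and the 18-30 h
    period range are all explicit here and recorded in the provenance file.
    """

    groups: list[GroupSpec] = field(default_factory=list)
    dam_files: list[tuple[str, dict[int, str]]] = field(default_factory=list)
    n_ld_days: int = 2
    n_dd_days: int = 9
    lights_on_hour: float = 8.0
    rhythm: RhythmConfig = field(default_factory=RhythmConfig)
    dd_window: tuple[int, int] = (1, 9)  # (start_day, n_days) for classification
    anticipation_spans: tuple = DEFAULT_SPANS
    stats_method: str = "kruskal_dunn"  # per the behavioral figures
    actogram_days: int = 6
    actogram_bin_min: int = 30
    master_seed: int = 0
    out_dir: str | None = None

    def schedule(self) -> LightSchedule:
        return default_schedule(
            n_ld_days=self.n_ld_days, lights_on_hour=self.lights_on_hour
        )


def validate_config(config: RunConfig) -> RunConfig:
    """Fill defaults, check consistency, and return a normalized config."""
    if not 0 < config.rhythm.alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if config.n_ld_days < 0 or config.n_dd_days <= 0:
        raise ValueError("need n_ld_days >= 0 and n_dd_days > 0")
    start, n_days = config.dd_window
    if start < 1 or n_days < 1 or start + n_days - 1 > config.n_dd_days:
        raise ValueError(
            f"DD window days {start}..{start + n_days - 1} exceed the "
            f"{config.n_dd_days}-day DD record"
        )
    if not config.groups and not config.dam_files:
        raise ValueError("config names neither synthetic groups nor DAM files")
    if config.groups and config.dam_files:
        raise ValueError("choose synthetic groups or DAM files, not both")
    if config.stats_method not in ("kruskal_dunn", "anova_tukey"):
        raise ValueError(f"unknown stats_method {config.stats_method!r}")
    return config


def config_from_mapping(raw: Mapping[str, Any]) -> RunConfig:
    """Build a RunConfig from a plain mapping (parsed YAML/JSON)."""
    raw = dict(raw)
    groups = [GroupSpec(**g) for g in raw.pop("groups", [])]
    dam_files = [
        (str(path), {int(k): v for k, v in chmap.items()})
        for path, chmap in raw.pop("dam_files", [])
    ]
    rhythm = RhythmConfig(**raw.pop("rhythm", {}))
    cfg = RunConfig(groups=groups, dam_files=dam_files, rhythm=rhythm, **raw)
    return validate_config(cfg)


# ---------------------------------------------------------------------------
# actograms
# ---------------------------------------------------------------------------

@dataclass
class ActogramMatrix:
    """Double-plotted actogram: row d shows day d followed by day d+1."""

    days: list[int]
    bin_width: int
    values: np.ndarray  # (n_days, 2 * bins_per_day)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin{j:03d}" for j in range(self.values.shape[1])]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "day", self.days)
        return df


def actogram_matrix(
    series: ActivitySeries | Sequence[ActivitySeries],
    n_days: int,
    bin_width: int = 30,
) -> ActogramMatrix:
    """Double-plotted activity matrix for one fly or a group average.

    Needs ``n_days + 1`` days of data; for a group, flies are averaged per
    bin after binning each to ``bin_width``.
    """
    series_list = [series] if isinstance(series, ActivitySeries) else list(series)
    per_day = 1440 // bin_width
    mats = []
    for s in series_list:
        b = dam.bin_series(s, bin_width)
        need = (n_days + 1) * per_day
        if len(b) < need:
            raise ValueError(
                f"{s.fly_id}: {len(b) / per_day:.2f} days available, "
                f"{n_days + 1} needed for {n_days} double-plotted rows"
            )
        daymat = b.counts[: need].reshape(n_days + 1, per_day)
        mats.append(
            np.hstack([daymat[:-1], daymat[1:]]).astype(float)
        )
    values = np.mean(mats, axis=0)
    return ActogramMatrix(days=list(range(1, n_days + 1)), bin_width=bin_width, values=values)


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def _load_cohort(config: RunConfig) -> CohortTable:
    if config.groups:
        merged: dict[str, list[ActivitySeries]] = {}
        for gi, gspec in enumerate(config.groups):
            params = SyntheticFlyParams(**gspec.params)
            spec = SyntheticCohortSpec(
                n_flies=gspec.n_flies,
                params=params,
                period_jitter_sd_h=gspec.period_jitter_sd_h,
                phase_jitter_sd_h=gspec.phase_jitter_sd_h,
                n_ld_days=config.n_ld_days,
                n_dd_days=config.n_dd_days,
                group=gspec.name,
                master_seed=int(
                    np.random.SeedSequence([config.master_seed, gi]).generate_state(1)[0]
                    % (2**31)
                ),
            )
            merged[gspec.name] = simulate_cohort(spec, config.schedule())[gspec.name]
        return CohortTable(merged)
    schedule = config.schedule()
    merged = {}
    for path, chmap in config.dam_files:
        series = dam.read_dam_monitor(path, schedule, keep_empty=True)
        by_channel = {
            int(s.fly_id.rsplit("#ch", 1)[1]): s for s in series
        }
        for ch, group in chmap.items():
            if ch not in by_channel:
                raise ValueError(f"{path}: channel {ch} not present in monitor file")
            merged.setdefault(group, []).append(by_channel[ch])
    # drop channels that were never mapped; empty unmapped channels are fine
    return CohortTable(merged)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full locomotor analysis and return (and optionally write) tables.

    Returns a dict with per-fly rhythm calls, cohort summaries, anticipation
    indices, group statistics, actogram matrices and a provenance record.
    When ``config.out_dir`` is set, every table is also written as TSV and
    the provenance as JSON.
    """
    config = validate_config(config)
    cohort = _load_cohort(config)
    start_day, n_days = config.dd_window

    calls_frames = []
    summaries = []
    per_group_calls: dict[str, list] = {}
    for group, series_list in cohort.items():
        calls = []
        for s in series_list:
            s15 = dam.bin_series(s, 15)
            window = dam.slice_window(s15, "DD", start_day, n_days)
            calls.append(classify_fly(window, config.rhythm))
        per_group_calls[group] = calls
        f = calls_to_frame(calls)
        f.insert(0, "group", group)
        calls_frames.append(f)
        summaries.append(summarize_cohort(calls, config.rhythm, group=group))
    calls_df = pd.concat(calls_frames, ignore_index=True)
    summary_df = pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "n": [s.n for s in summaries],
            "percent_rhythmic": [s.percent_rhythmic for s in summaries],
            "percent_weakly_rhythmic": [s.percent_weakly_rhythmic for s in summaries],
            "percent_arrhythmic": [s.percent_arrhythmic for s in summaries],
            "period_mean_h": [s.period_mean_h for s in summaries],
            "period_sem_h": [s.period_sem_h for s in summaries],
        }
    )

    hourly = CohortTable(
        {
            g: [dam.bin_series(s, 60) for s in series_list]
            for g, series_list in cohort.items()
        }
    )
    antic_df = cohort_anticipation(hourly, config.anticipation_spans)

    stats_frames = []
    test = kruskal_dunn if config.stats_method == "kruskal_dunn" else anova_tukey
    if len(cohort.groups) >= 2:
        for span in antic_df["span"].unique():
            sub = antic_df[antic_df["span"] == span]
            for metric in ("mai", "eai"):
                groups = {
                    g: sub.loc[sub["group"] == g, metric].dropna().to_numpy()
                    for g in cohort.groups
                }
                groups = {g: v for g, v in groups.items() if v.size >= 2}
                if len(groups) < 2:
                    continue
                comp = test(groups)
                f = comparison_to_frame(comp)
                f.insert(0, "metric", metric)
                f.insert(0, "span", span)
                stats_frames.append(f)
        power_groups = {
            g: np.array([c.cs_power_raw for c in cs]) for g, cs in per_group_calls.items()
        }
        comp = test(power_groups)
        f = comparison_to_frame(comp)
        f.insert(0, "metric", "rhythm_power")
        f.insert(0, "span", f"DD{start_day}-{start_day + n_days - 1}")
        stats_frames.append(f)
    stats_df = (
        pd.concat(stats_frames, ignore_index=True) if stats_frames else pd.DataFrame()
    )

    actograms = {}
    for group, series_list in cohort.items():
        dd = [
            dam.slice_window(dam.bin_series(s, config.actogram_bin_min), "DD", 1, config.n_dd_days)
            for s in series_list
        ]
        actograms[group] = actogram_matrix(dd, config.actogram_days, config.actogram_bin_min)

    provenance = {
        "package": "flyclock",
        "master_seed": config.master_seed,
        "alpha": config.rhythm.alpha,
        "delta_threshold": config.rhythm.delta_threshold,
        "period_range_h": list(config.rhythm.period_range_h),
        "dd_window": list(config.dd_window),
        "n_ld_days": config.n_ld_days,
        "n_dd_days": config.n_dd_days,
        "stats_method": config.stats_method,
        "groups": [g.name for g in config.groups] or sorted(cohort.groups),
        "n_flies": cohort.n_flies,
    }

    results: dict[str, Any] = {
        "rhythm_calls": calls_df,
        "cohort_summary": summary_df,
        "anticipation": antic_df,
        "group_stats": stats_df,
        "actograms": actograms,
        "provenance": provenance,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("rhythm_calls", "cohort_summary", "anticipation", "group_stats"):
            results[name].to_csv(
                out / f"{name}.tsv", sep="\t", index=False, float_format=_FLOAT_FORMAT
            )
        for group, mat in actograms.items():
            mat.to_frame().to_csv(
                out / f"actogram_{group}.tsv",
                sep="\t",
                index=False,
                float_format=_FLOAT_FORMAT,
            )
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return results
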