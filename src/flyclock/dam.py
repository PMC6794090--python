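"""Reading, writing and windowing of Drosophila Activity Monitor (DAM) records.

TriKinetics DAM monitors count infrared beam breaks per fly per minute and
write tab-delimited ``Monitor*.txt`` files.  This module parses that layout,
annotates each bin with its circadian phase (Zeitgeber time under the light:dark
entrainment days, circadian time after release into constant darkness) and
provides the binning/windowing operations the downstream rhythm analyses
expect: summing into 15-min or hourly bins and slicing whole subjective days.

Conventions
-----------
* Bins are half-open ``[t, t + width)`` and timestamped by their start.
* ZT0 is lights-on; CT0 in DD is the projection of the prior lights-on time.
  Day boundaries sit at phase 0.
* Rows whose status code is not 1 are treated as monitor dropouts: their
  counts are zeroed and the bin flagged, preserving the regular sampling the
  periodograms assume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: number of count channels in a DAM monitor file
N_CHANNELS = 32
#: total tab-separated columns: index, date, time, status, 6 metadata, 32 counts
N_COLUMNS = 4 + 6 + N_CHANNELS

_DATE_FORMAT = "%d %b %y"
_TIME_FORMAT = "%H:%M:%S"


class DamFormatError(ValueError):
    """Raised when a monitor file does not follow the expected dialect."""


@dataclass(frozen=True)
class LightSchedule:
    """Light regime of an experiment: LD entrainment followed by DD free-run.

    Parameters
    ----------
    lights_on_hour, lights_off_hour:
        Clock hours in [0, 24) of the light transitions; for the standard
        12:12 regime these differ by 12 h.
    n_ld_days:
        Recorded days of LD before the release into constant darkness.
    dd_start:
        Timestamp of the first subjective day in DD, i.e. the projected
        lights-on instant of the first DD day.
    """

    lights_on_hour: float
    lights_off_hour: float
    n_ld_days: int
    dd_start: datetime

    def __post_init__(self) -> None:
        for name in ("lights_on_hour", "lights_off_hour"):
            v = getattr(self, name)
            if not 0 <= v < 24:
                raise ValueError(f"{name} must lie in [0, 24), got {v}")
        if self.lights_on_hour == self.lights_off_hour:
            raise ValueError("lights_on_hour and lights_off_hour must differ")
        if self.n_ld_days < 0:
            raise ValueError("n_ld_days must be >= 0")

    @property
    def photoperiod_h(self) -> float:
        """Light-phase duration, (lights_off - lights_on) mod 24."""
        return (self.lights_off_hour - self.lights_on_hour) % 24

    def phase_of(self, t: datetime) -> float:
        """Circadian hour of ``t``: ZT before ``dd_start``, projected CT after."""
        clock_h = t.hour + t.minute / 60 + t.second / 3600
        return (clock_h - self.lights_on_hour) % 24

    def regime_of(self, t: datetime) -> str:
        return "DD" if t >= self.dd_start else "LD"

    def ld_start(self) -> datetime:
        """Lights-on instant of the first recorded LD day."""
        return self.dd_start - timedelta(days=self.n_ld_days)


def default_schedule(
    n_ld_days: int = 2,
    lights_on_hour: float = 8.0,
    first_day: datetime | None = None,
) -> LightSchedule:
    """A 12:12 LD schedule anchored at an arbitrary reference date."""
    if first_day is None:
        first_day = datetime(2024, 1, 1)
    on = first_day.replace(
        hour=int(lights_on_hour), minute=int(round((lights_on_hour % 1) * 60))
    )
    return LightSchedule(
        lights_on_hour=lights_on_hour,
        lights_off_hour=(lights_on_hour + 12) % 24,
        n_ld_days=n_ld_days,
        dd_start=on + timedelta(days=n_ld_days),
    )


@dataclass
class ActivitySeries:
    """One fly's binned beam-break counts with circadian annotation.

    ``counts[i]`` is the number of beam breaks in the half-open bin starting
    ``t0 + i * bin_width`` minutes.  ``phase[i]`` is the circadian hour of the
    bin start (ZT on LD days, CT on DD days) and ``regime[i]`` is ``"LD"`` or
    ``"DD"``.  ``flagged[i]`` marks bins zeroed because of an invalid monitor
    status code.
    """

    fly_id: str
    t0: datetime
    bin_width: int  # minutes
    counts: np.ndarray
    phase: np.ndarray
    regime: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.phase = np.asarray(self.phase, dtype=float)
        self.regime = np.asarray(self.regime, dtype=object)
        if self.flagged is None:
            self.flagged = np.zeros(self.counts.shape, dtype=bool)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        n = len(self.counts)
        if not (len(self.phase) == len(self.regime) == len(self.flagged) == n):
            raise ValueError("counts, phase, regime and flagged must share length")
        if np.any(self.counts < 0):
            raise ValueError("beam-break counts must be non-negative")

    @classmethod
    def from_counts(
        cls,
        fly_id: str,
        t0: datetime,
        bin_width: int,
        counts: Sequence[int],
        schedule: LightSchedule,
        flagged: Sequence[bool] | None = None,
    ) -> "ActivitySeries":
        counts = np.asarray(counts, dtype=np.int64)
        times = [t0 + timedelta(minutes=bin_width * i) for i in range(len(counts))]
        phase = np.array([schedule.phase_of(t) for t in times])
        regime = np.array([schedule.regime_of(t) for t in times], dtype=object)
        return cls(fly_id, t0, bin_width, counts, phase, regime, flagged)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration_days(self) -> float:
        return len(self) * self.bin_width / 1440

    def bin_times(self) -> list[datetime]:
        return [self.t0 + timedelta(minutes=self.bin_width * i) for i in range(len(self))]

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: fly_id, t, bin_width, regime, phase, count."""
        return pd.DataFrame(
            {
                "fly_id": self.fly_id,
                "t": self.bin_times(),
                "bin_width": self.bin_width,
                "regime": self.regime,
                "phase": self.phase,
                "count": self.counts,
            }
        )

    def day_numbers(self) -> np.ndarray:
        """1-based day index within each regime; 0 marks a leading partial day.

        A new day starts whenever the phase wraps past 0 (or at a bin whose
        phase is exactly 0), counted separately within the LD and DD stretches.
        """
        n = len(self)
        day = np.zeros(n, dtype=int)
        for reg in ("LD", "DD"):
            idx = np.flatnonzero(self.regime == reg)
            if idx.size == 0:
                continue
            ph = self.phase[idx]
            # a boundary is a bin at phase 0, or a wrap past 0 between bins
            boundary = np.empty(idx.size, dtype=bool)
            boundary[0] = np.isclose(ph[0], 0.0)
            boundary[1:] = (ph[1:] < ph[:-1]) | np.isclose(ph[1:], 0.0)
            day[idx] = np.cumsum(boundary)
        return day


@dataclass
class CohortTable:
    """Mapping from genotype/group label to that group's activity series."""

    groups: dict[str, list[ActivitySeries]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for series_list in self.groups.values():
            for s in series_list:
                if s.fly_id in seen:
                    raise ValueError(f"duplicate fly_id in cohort: {s.fly_id!r}")
                seen.add(s.fly_id)

    def __getitem__(self, group: str) -> list[ActivitySeries]:
        return self.groups[group]

    def items(self):
        return self.groups.items()

    @property
    def n_flies(self) -> int:
        return sum(len(v) for v in self.groups.values())


# ---------------------------------------------------------------------------
# monitor file I/O
# ---------------------------------------------------------------------------

def read_dam_monitor(
    path: str | Path,
    schedule: LightSchedule,
    keep_empty: bool = False,
    fly_prefix: str | None = None,
) -> list[ActivitySeries]:
    """Parse a TriKinetics ``Monitor*.txt`` file into per-channel series.

    Each row must carry ``N_COLUMNS`` tab-separated fields: reading index,
    date (``dd mmm yy``), time (``HH:MM:SS``), a status code, six metadata
    columns and 32 channel counts.  Rows with a status code other than 1 are
    flagged and their counts zeroed.  Channels with no activity at all are
    dropped unless ``keep_empty`` is set.
    """
    path = Path(path)
    prefix = fly_prefix if fly_prefix is not None else path.stem
    times: list[datetime] = []
    status_ok: list[bool] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != N_COLUMNS:
                raise DamFormatError(
                    f"{path.name}: line {lineno} has {len(fields)} columns, "
                    f"expected {N_COLUMNS}"
                )
            try:
                t = datetime.strptime(
                    f"{fields[1]} {fields[2]}", f"{_DATE_FORMAT} {_TIME_FORMAT}"
                )
                status = int(fields[3])
                counts = [int(c) for c in fields[4 + 6 :]]
            except ValueError as exc:
                raise DamFormatError(
                    f"{path.name}: line {lineno}: {exc}"
                ) from exc
            if any(c < 0 for c in counts):
                raise DamFormatError(
                    f"{path.name}: line {lineno}: negative count"
                )
            times.append(t)
            status_ok.append(status == 1)
            rows.append(counts)
    if not rows:
        raise DamFormatError(f"{path.name}: no data rows")
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise DamFormatError(
                f"{path.name}: non-monotonic timestamps at row {i + 1}"
            )
    counts_mat = np.asarray(rows, dtype=np.int64)  # rows x 32
    flagged = ~np.asarray(status_ok, dtype=bool)
    if flagged.any():
        logger.warning(
            "%s: %d rows with invalid status flagged and zeroed",
            path.name,
            int(flagged.sum()),
        )
        counts_mat[flagged, :] = 0
    out: list[ActivitySeries] = []
    for ch in range(N_CHANNELS):
        col = counts_mat[:, ch]
        if not keep_empty and not col.any():
            continue
        out.append(
            ActivitySeries.from_counts(
                fly_id=f"{prefix}#ch{ch + 1:02d}",
                t0=times[0],
                bin_width=1,
                counts=col,
                schedule=schedule,
                flagged=flagged,
            )
        )
    return out


def write_dam_monitor(series: Sequence[ActivitySeries], path: str | Path) -> Path:
    """Write 1-min series as a DAM monitor file readable by :func:`read_dam_monitor`."""
    series = list(series)
    if not series:
        raise ValueError("no series to write")
    if len(series) > N_CHANNELS:
        raise ValueError(f"at most {N_CHANNELS} channels per monitor file, got {len(series)}")
    n = len(series[0])
    for s in series:
        if len(s) != n:
            raise ValueError("all series must have equal length")
        if s.bin_width != 1:
            raise ValueError("monitor files hold 1-min bins")
        if s.t0 != series[0].t0:
            raise ValueError("all series must share t0")
    path = Path(path)
    t0 = series[0].t0
    with open(path, "w") as fh:
        for i in range(n):
            t = t0 + timedelta(minutes=i)
            counts = [int(s.counts[i]) for s in series]
            counts += [0] * (N_CHANNELS - len(counts))
            fields = (
                [str(i + 1), t.strftime(_DATE_FORMAT), t.strftime(_TIME_FORMAT), "1"]
                + ["0"] * 6
                + [str(c) for c in counts]
            )
            fh.write("\t".join(fields) + "\n")
    return path


# ---------------------------------------------------------------------------
# binning & windowing
# ---------------------------------------------------------------------------

def bin_series(series: ActivitySeries, bin_width: int) -> ActivitySeries:
    """Sum counts into wider bins (e.g. 1 -> 15 min, 15 -> 60 min).

    ``bin_width`` must be a multiple of the series' current width and divide
    60 so that bins never straddle an hour boundary.  A trailing partial bin
    is dropped (and logged); complete bins conserve total counts exactly.
    """
    if bin_width == series.bin_width:
        return series
    if bin_width % series.bin_width != 0 or 60 % bin_width != 0:
        raise ValueError(
            f"bin_width {bin_width} must be a multiple of {series.bin_width} "
            "and divide 60"
        )
    factor = bin_width // series.bin_width
    n_out = len(series) // factor
    dropped = len(series) - n_out * factor
    if dropped:
        logger.info("%s: dropping trailing partial bin of %d input bins", series.fly_id, dropped)
    kept = series.counts[: n_out * factor].reshape(n_out, factor)
    flg = series.flagged[: n_out * factor].reshape(n_out, factor)
    return ActivitySeries(
        fly_id=series.fly_id,
        t0=series.t0,
        bin_width=bin_width,
        counts=kept.sum(axis=1),
        phase=series.phase[: n_out * factor : factor],
        regime=series.regime[: n_out * factor : factor],
        flagged=flg.any(axis=1),
    )


def slice_window(
    series: ActivitySeries, regime: str, start_day: int, n_days: int
) -> ActivitySeries:
    """Extract ``n_days`` whole subjective days from one regime.

    Days are 1-based and begin at phase 0 (ZT0 / CT0).  The result has exactly
    ``n_days * 1440 / bin_width`` bins.
    """
    if regime not in ("LD", "DD"):
        raise ValueError("regime must be 'LD' or 'DD'")
    if start_day < 1 or n_days < 1:
        raise ValueError("start_day and n_days are 1-based positive integers")
    per_day = 1440 // series.bin_width
    idx = np.flatnonzero(series.regime == regime)
    if idx.size == 0:
        raise ValueError(f"record has no {regime} data")
    ph = series.phase[idx]
    boundaries = idx[np.isclose(ph, 0.0)]
    avail = 0
    if boundaries.size:
        # complete days available from the first phase-0 boundary
        last = idx[-1]
        avail = (last - boundaries[0] + 1) // per_day
    if boundaries.size < start_day or boundaries[start_day - 1] + n_days * per_day - 1 > idx[-1]:
        raise ValueError(
            f"requested {regime} days {start_day}..{start_day + n_days - 1}, "
            f"but only {avail} complete {regime} day(s) are available"
        )
    i0 = boundaries[start_day - 1]
    i1 = i0 + n_days * per_day
    t0 = series.t0 + timedelta(minutes=int(i0) * series.bin_width)
    return ActivitySeries(
        fly_id=series.fly_id,
        t0=t0,
        bin_width=series.bin_width,
        counts=series.counts[i0:i1],
        phase=series.phase[i0:i1],
        regime=series.regime[i0:i1],
        flagged=series.flagged[i0:i1],
    )


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """Tidy long table for a whole cohort (one row per fly per bin)."""
    frames = []
    for group, series_list in cohort.items():
        for s in series_list:
            f = s.to_frame()
            f.insert(0, "group", group)
            frames.append(f)
    return pd.concat(frames, ignore_index=True)
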