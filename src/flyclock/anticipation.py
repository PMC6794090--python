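"""Morning and evening anticipation indices from hourly-binned activity.

Anticipation of a light transition shows up as rising activity in the hours
just before it.  The index divides the beam breaks in the 3 h immediately
preceding the (projected) transition by the beam breaks in the 6 h preceding
it, so a flat activity profile scores 0.5 and activity concentrated right
before the transition approaches 1:

* **MAI** (morning): hours 21-23 over hours 18-23 of circadian/Zeitgeber
  phase, the windows before lights-on at phase 0;
* **EAI** (evening): hours 9-11 over hours 6-11, before lights-off at
  phase 12.

For multi-day spans counts are summed across days before dividing (robust to
a day of low activity; a mean-of-daily-indices mode is available).  A span
with zero denominator activity leaves the index undefined — such flies are
flagged and excluded from group statistics with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dam import ActivitySeries, CohortTable

logger = logging.getLogger(__name__)

_WINDOWS = {
    # transition -> (numerator phases, denominator phases), whole hourly bins
    "lights_on": ((21, 22, 23), (18, 19, 20, 21, 22, 23)),
    "lights_off": ((9, 10, 11), (6, 7, 8, 9, 10, 11)),
}


@dataclass
class AnticipationResult:
    fly_id: str
    day_label: str
    mai: float | None
    eai: float | None


def _index_for(
    series: ActivitySeries,
    transition: str,
    regime: str,
    days: Sequence[int],
    per_day_mean: bool = False,
) -> float | None:
    if transition not in _WINDOWS:
        raise ValueError("transition must be 'lights_on' or 'lights_off'")
    if series.bin_width != 60:
        raise ValueError("anticipation indices require 60-min bins")
    num_ph, den_ph = _WINDOWS[transition]
    day_no = series.day_numbers()
    hour = np.floor(series.phase + 1e-9).astype(int)
    in_regime = series.regime == regime
    want_days = set(int(d) for d in days)
    present = set(day_no[in_regime].tolist()) - {0}
    missing = want_days - present
    if missing:
        raise ValueError(
            f"{regime} day(s) {sorted(missing)} not present in record "
            f"(available: {sorted(present)})"
        )
    sel = in_regime & np.isin(day_no, list(want_days))

    def one(day_mask: np.ndarray) -> tuple[int, int]:
        num = int(series.counts[day_mask & np.isin(hour, num_ph)].sum())
        den = int(series.counts[day_mask & np.isin(hour, den_ph)].sum())
        return num, den

    if per_day_mean:
        vals = []
        for d in sorted(want_days):
            num, den = one(sel & (day_no == d))
            if den > 0:
                vals.append(num / den)
        return float(np.mean(vals)) if vals else None
    num, den = one(sel)
    if den == 0:
        return None
    return num / den


def anticipation_index(
    series_hourly: ActivitySeries,
    transition: str,
    regime: str,
    days: Sequence[int],
    day_label: str | None = None,
    per_day_mean: bool = False,
) -> AnticipationResult:
    """Anticipation index for one fly over the named days of one regime.

    ``days`` are 1-based whole subjective days (day 1 starts at the first
    phase-0 boundary of the regime).  Returns both indices with the one for
    ``transition`` computed; use :func:`both_indices` for MAI and EAI at once.
    """
    val = _index_for(series_hourly, transition, regime, days, per_day_mean)
    label = day_label or f"{regime}{','.join(str(d) for d in days)}"
    if transition == "lights_on":
        return AnticipationResult(series_hourly.fly_id, label, mai=val, eai=None)
    return AnticipationResult(series_hourly.fly_id, label, mai=None, eai=val)


def both_indices(
    series_hourly: ActivitySeries,
    regime: str,
    days: Sequence[int],
    day_label: str,
    per_day_mean: bool = False,
) -> AnticipationResult:
    mai = _index_for(series_hourly, "lights_on", regime, days, per_day_mean)
    eai = _index_for(series_hourly, "lights_off", regime, days, per_day_mean)
    if mai is None or eai is None:
        logger.info(
            "%s %s: zero denominator window, index undefined", series_hourly.fly_id, day_label
        )
    return AnticipationResult(series_hourly.fly_id, day_label, mai=mai, eai=eai)


#: the standard analysis spans: (label, regime, 1-based days)
DEFAULT_SPANS: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    ("LD2", "LD", (2,)),
    ("DD2", "DD", (2,)),
    ("DD3-9", "DD", tuple(range(3, 10))),
)


def cohort_anticipation(
    cohort: CohortTable,
    spans: Iterable[tuple[str, str, Sequence[int]]] = DEFAULT_SPANS,
    per_day_mean: bool = False,
) -> pd.DataFrame:
    """MAI and EAI per fly per span, as a tidy table for group statistics.

    Input series must already be in 60-min bins.  Undefined indices appear as
    NaN and are logged; downstream tests drop them listwise.
    """
    rows = []
    for group, series_list in cohort.items():
        for s in series_list:
            for label, regime, days in spans:
                r = both_indices(s, regime, days, label, per_day_mean)
                rows.append(
                    {
                        "group": group,
                        "fly_id": s.fly_id,
                        "span": r.day_label,
                        "mai": np.nan if r.mai is None else r.mai,
                        "eai": np.nan if r.eai is None else r.eai,
                    }
                )
    return pd.DataFrame(rows)
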