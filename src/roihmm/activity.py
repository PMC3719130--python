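"""Detection-frequency activity patterns.

Per-recording presence calls are aggregated into the standard passive
acoustic monitoring activity metric: detection frequency, the number of
recordings with a positive detection divided by the total number of
recordings in the time period.  Grouping is by hour of day (diel
pattern), calendar year-month (long-term trend) or month of year
(seasonal pooling), always in the site's local time zone — a dusk
chorus at 18:00 is only meaningful in local time.  A recording belongs
to the group of its start timestamp.  Periods with no recordings are
omitted (missing), never reported as zero activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

__all__ = ["ActivitySeries", "detection_frequency", "expected_schedule",
           "completeness", "plot_activity"]

_GROUPINGS = ("hour", "month", "month_of_year")


@dataclass
class ActivitySeries:
    """Detection frequency per time group for one species.

    ``table`` columns: group, n_recordings, n_detected, frequency.
    Only groups with at least one recording appear.
    """

    species: str
    grouping: str
    table: pd.DataFrame
    n_detected_total: int

    def __post_init__(self) -> None:
        t = self.table
        if np.any(t["n_detected"] > t["n_recordings"]):
            raise ValueError("n_detected cannot exceed n_recordings")
        if np.any((t["frequency"] < 0) | (t["frequency"] > 1)):
            raise ValueError("detection frequency must lie in [0, 1]")


def detection_frequency(
    detections: pd.DataFrame,
    grouping: str = "hour",
    time_zone: str | ZoneInfo | None = None,
    species: str | None = None,
) -> ActivitySeries:
    """Aggregate presence calls into an activity series.

    ``detections`` columns: recording_id, timestamp (time-zone aware),
    present; optionally species (filtered if ``species`` given).
    Timestamps are converted to ``time_zone`` (site-local) before
    grouping; naive timestamps are rejected.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {_GROUPINGS}, got {grouping!r}")
    det = detections
    if species is not None and "species" in det:
        det = det[det["species"] == species]
    elif species is None and "species" in det and len(det):
        uniq = det["species"].unique()
        if len(uniq) > 1:
            raise ValueError("multiple species present; pass species=...")
        species = str(uniq[0]) if len(uniq) else ""

    ts = pd.to_datetime(det["timestamp"], format="ISO8601")
    if len(ts) and ts.dt.tz is None:
        raise ValueError(
            "naive timestamps: detections must carry a time zone "
            "(pass tz-aware timestamps)")
    if time_zone is not None and len(ts):
        ts = ts.dt.tz_convert(ZoneInfo(time_zone)
                              if isinstance(time_zone, str) else time_zone)

    if grouping == "hour":
        groups = ts.dt.hour
    elif grouping == "month":
        groups = ts.dt.strftime("%Y-%m")
    else:  # month_of_year
        groups = ts.dt.month

    present = det["present"].astype(bool).to_numpy()
    agg = pd.DataFrame({"group": groups.to_numpy(), "present": present})
    table = (agg.groupby("group", sort=True)["present"]
             .agg(n_recordings="size", n_detected="sum")
             .reset_index())
    table["n_detected"] = table["n_detected"].astype(int)
    table["frequency"] = table["n_detected"] / table["n_recordings"]
    return ActivitySeries(species=species or "", grouping=grouping,
                          table=table,
                          n_detected_total=int(present.sum()))


def expected_schedule(
    start: datetime,
    end: datetime,
    period: timedelta = timedelta(minutes=10),
    duration: timedelta = timedelta(minutes=1),
) -> list[datetime]:
    """Recording start times for a fixed schedule over [start, end).

    The canonical monitoring schedule — 1 min of audio every 10 min —
    yields 144 recordings per day.  ``duration`` is carried for
    completeness bookkeeping; timestamps are spaced by ``period``.
    """
    if period <= timedelta(0):
        raise ValueError(f"period must be positive, got {period}")
    if duration > period:
        raise ValueError("clip duration cannot exceed the schedule period")
    out = []
    t = start
    while t < end:
        out.append(t)
        t = t + period
    return out


def completeness(n_observed: int, expected: list[datetime]) -> float:
    """Fraction of the expected schedule actually collected."""
    if not expected:
        raise ValueError("expected schedule is empty")
    return n_observed / len(expected)


def plot_activity(series: ActivitySeries, path: str) -> None:
    """Bar plot of detection frequency per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    t = series.table
    ax.bar(range(len(t)), t["frequency"], color="#33567d")
    ax.set_xticks(range(len(t)))
    ax.set_xticklabels([str(g) for g in t["group"]], rotation=45, ha="right")
    ax.set_ylabel("detection frequency")
    ax.set_xlabel(series.grouping)
    ax.set_title(f"{series.species} ({series.n_detected_total})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
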