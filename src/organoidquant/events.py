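"""Mitosis/apoptosis event analytics from time-lapse annotations.

Event logs record the time and type of every division and death observed in
an organoid movie.  Chronological ranking of those events reconstructs the
relative cell-count (organoid size) trajectory; binning yields per-window
event rates; linear fits of trajectory segments give growth speeds, e.g.
over the first versus second half of a recovery recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventLog",
    "CountTrajectory",
    "reconstruct_trajectory",
    "event_rates",
    "fit_growth_speed",
]

EVENT_TYPES = ("mitosis", "apoptosis")
# at equal times apoptosis sorts before mitosis (fixed, arbitrary tie order)
_TIE_ORDER = {"apoptosis": 0, "mitosis": 1}


@dataclass
class EventLog:
    """Timed mitosis/apoptosis records, one row per event."""

    records: pd.DataFrame  # organoid_id, time_min, event_type

    def __post_init__(self) -> None:
        df = self.records
        missing = {"organoid_id", "time_min", "event_type"} - set(df.columns)
        if missing:
            raise ValueError(f"event log missing columns {sorted(missing)}")
        if (df["time_min"] < 0).any():
            raise ValueError("event times must be >= 0")
        bad = set(df["event_type"]) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def sorted(self) -> pd.DataFrame:
        """Canonical order: time, then apoptosis before mitosis, then input order."""
        df = self.records.reset_index(drop=True).copy()
        df["_tie"] = df["event_type"].map(_TIE_ORDER)
        df = df.sort_values(["time_min", "_tie"], kind="stable").drop(columns="_tie")
        return df.reset_index(drop=True)

    def n_events(self) -> tuple[int, int]:
        """(mitoses, apoptoses) totals."""
        counts = self.records["event_type"].value_counts()
        return int(counts.get("mitosis", 0)), int(counts.get("apoptosis", 0))


@dataclass
class CountTrajectory:
    """Step trajectory of relative cell count reconstructed from events.

    ``points`` holds (time_min, count) with the starting count first;
    consecutive counts differ by exactly +1 (mitosis) or -1 (apoptosis).
    """

    points: pd.DataFrame  # time_min, count
    n0: int

    @property
    def final_count(self) -> int:
        return int(self.points["count"].iloc[-1])

    def count_at(self, time_min: float) -> int:
        """Count in effect at a time (right-continuous step function)."""
        pts = self.points
        idx = np.searchsorted(pts["time_min"].to_numpy(), time_min, side="right") - 1
        return int(pts["count"].iloc[max(idx, 0)])

    def sampled(self, window: tuple[float, float]) -> pd.DataFrame:
        """Trajectory sampled at its change points within a window, plus the
        window endpoints — the point set used for growth-speed fits."""
        t0, t1 = window
        pts = self.points
        inside = pts[(pts["time_min"] > t0) & (pts["time_min"] < t1)]
        times = np.concatenate([[t0], inside["time_min"].to_numpy(), [t1]])
        counts = np.array([self.count_at(t) for t in times])
        return pd.DataFrame({"time_min": times, "count": counts})


def reconstruct_trajectory(log: EventLog, n0: int = 1) -> CountTrajectory:
    """Chronologically rank events into a relative cell-count trajectory.

    Each mitosis steps the count by +1 and each apoptosis by -1 from the
    starting count ``n0``.  A log whose running count would drop below zero
    is inconsistent and raises.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    df = log.sorted()
    steps = np.where(df["event_type"] == "mitosis", 1, -1)
    counts = n0 + np.cumsum(steps)
    if (counts < 0).any():
        t_bad = df["time_min"].iloc[int(np.argmax(counts < 0))]
        raise ValueError(f"inconsistent log: count drops below 0 at t={t_bad}")
    points = pd.DataFrame(
        {
            "time_min": np.concatenate([[0.0], df["time_min"].to_numpy(dtype=float)]),
            "count": np.concatenate([[n0], counts]),
        }
    )
    return CountTrajectory(points=points, n0=n0)


def event_rates(log: EventLog, window_min: float, n_organoids: int) -> pd.DataFrame:
    """Per-window mitosis and apoptosis counts per organoid.

    Events fall into half-open windows [k*w, (k+1)*w); a boundary event
    belongs to the later window.  Counts are divided by the number of
    organoids the log covers.
    """
    if window_min <= 0:
        raise ValueError("window_min must be > 0")
    if n_organoids <= 0:
        raise ValueError("n_organoids must be > 0")
    df = log.records
    if len(df) == 0:
        return pd.DataFrame(
            columns=["window", "t_start_min", "t_end_min",
                     "mitosis_per_organoid", "apoptosis_per_organoid"]
        )
    win = (df["time_min"] // window_min).astype(int)
    n_windows = int(win.max()) + 1
    rows = []
    for k in range(n_windows):
        sub = df[win == k]
        rows.append(
            dict(
                window=k,
                t_start_min=k * window_min,
                t_end_min=(k + 1) * window_min,
                mitosis_per_organoid=(sub["event_type"] == "mitosis").sum() / n_organoids,
                apoptosis_per_organoid=(sub["event_type"] == "apoptosis").sum() / n_organoids,
            )
        )
    return pd.DataFrame(rows)


def fit_growth_speed(
    traj: CountTrajectory, window: tuple[float, float]
) -> tuple[float, float]:
    """OLS growth speed (cells/hour) of a trajectory over a time window.

    The step trajectory is sampled at its change points inside the window
    plus the window endpoints; returns (slope, standard error) with time in
    hours.  Requires at least two sample points.
    """
    pts = traj.sampled(window)
    if len(pts) < 2:
        raise ValueError("need at least 2 trajectory points in the window")
    t_h = pts["time_min"].to_numpy() / 60.0
    y = pts["count"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return 0.0, 0.0
    res = stats.linregress(t_h, y)
    return float(res.slope), float(res.stderr)


def growth_speed_halves(traj: CountTrajectory, duration_min: float) -> pd.DataFrame:
    """Growth speeds over the first and second half of a recording."""
    half = duration_min / 2.0
    rows = []
    for name, win in (("first_half", (0.0, half)), ("second_half", (half, duration_min))):
        slope, se = fit_growth_speed(traj, win)
        rows.append(dict(window=name, t_start_min=win[0], t_end_min=win[1],
                         slope_cells_per_h=slope, stderr=se))
    return pd.DataFrame(rows)
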