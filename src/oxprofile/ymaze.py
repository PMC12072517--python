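"""Y-maze behavioural scoring.

Sessions are ordered arm-entry events with dwell times. Scored outcomes per
the two-trial (sample/retrieval) protocol: percent entries per arm, percent
time per arm (arm dwell only; center-zone time excluded), and the cohort-level
forced-alternation percentage (fraction of mice whose first retrieval entry is
the previously blocked novel arm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

ARMS = ("start", "sample", "novel")

__all__ = ["ARMS", "ArmEvent", "YMazeSession", "arm_summary", "forced_alternation", "cohort_table"]


class ArmEvent(NamedTuple):
    arm: str
    entry_time: float  # s
    exit_time: float  # s


@dataclass(frozen=True)
class YMazeSession:
    """One trial for one mouse: ordered, non-overlapping arm visits.

    Sample trials have the novel arm blocked, so only start/sample visits are
    legal there; retrieval trials may visit all three arms. Events record arm
    entries only — the initial placement into the start arm is not an event.
    """

    mouse_id: str
    group: str
    trial: str  # "sample" | "retrieval"
    events: tuple

    def __post_init__(self):
        if self.trial not in ("sample", "retrieval"):
            raise ValueError("trial must be 'sample' or 'retrieval'")
        allowed = ("start", "sample") if self.trial == "sample" else ARMS
        prev_exit = -np.inf
        for ev in self.events:
            if ev.arm not in allowed:
                raise ValueError(f"arm {ev.arm!r} not allowed in a {self.trial} trial")
            if ev.exit_time <= ev.entry_time:
                raise ValueError("event exit must follow entry")
            if ev.entry_time < prev_exit:
                raise ValueError("events must be time-ordered and non-overlapping")
            prev_exit = ev.exit_time


def arm_summary(session: YMazeSession) -> pd.DataFrame:
    """Percent entries and percent time per arm for a retrieval trial.

    Entry percent = entries into the arm / total arm entries x 100; time
    percent = dwell in the arm / total dwell across arms x 100 (time in the
    center zone, i.e. between events, does not enter the denominator).
    Percentages each sum to 100.
    """
    if not session.events:
        raise ValueError(f"session {session.mouse_id!r} has no arm entries")
    entries = {arm: 0 for arm in ARMS}
    dwell = {arm: 0.0 for arm in ARMS}
    for ev in session.events:
        entries[ev.arm] += 1
        dwell[ev.arm] += ev.exit_time - ev.entry_time
    total_entries = sum(entries.values())
    total_dwell = sum(dwell.values())
    return pd.DataFrame(
        {
            "arm": ARMS,
            "entries": [entries[a] for a in ARMS],
            "entry_percent": [100.0 * entries[a] / total_entries for a in ARMS],
            "dwell_s": [dwell[a] for a in ARMS],
            "time_percent": [100.0 * dwell[a] / total_dwell for a in ARMS],
        }
    ).set_index("arm")


def forced_alternation(sessions: Iterable[YMazeSession]) -> float:
    """Cohort forced-alternation percentage.

    100 x (number of mice whose first retrieval-trial entry is the novel arm)
    / (number of mice). The very first event decides, even when it is into the
    start or sample arm.
    """
    retrieval = [s for s in sessions if s.trial == "retrieval"]
    if not retrieval:
        raise ValueError("no retrieval sessions in cohort")
    for s in retrieval:
        if not s.events:
            raise ValueError(f"session {s.mouse_id!r} has no arm entries")
    novel_first = sum(1 for s in retrieval if s.events[0].arm == "novel")
    return 100.0 * novel_first / len(retrieval)


def cohort_table(sessions: Iterable[YMazeSession]) -> pd.DataFrame:
    """Group x arm means +/- SEM of per-mouse entry and time percentages.

    One row per (group, arm); columns: n mice, entry_percent_mean/sem,
    time_percent_mean/sem. Mean entry percentages sum to 100 within a group.
    """
    rows = []
    for s in sessions:
        if s.trial != "retrieval":
            continue
        summary = arm_summary(s)
        for arm in ARMS:
            rows.append(
                {
                    "group": s.group,
                    "mouse_id": s.mouse_id,
                    "arm": arm,
                    "entry_percent": summary.loc[arm, "entry_percent"],
                    "time_percent": summary.loc[arm, "time_percent"],
                }
            )
    if not rows:
        raise ValueError("no retrieval sessions in cohort")
    long = pd.DataFrame(rows)
    grouped = long.groupby(["group", "arm"], sort=False)
    out = grouped.agg(
        n=("mouse_id", "count"),
        entry_percent_mean=("entry_percent", "mean"),
        entry_percent_sem=("entry_percent", "sem"),
        time_percent_mean=("time_percent", "mean"),
        time_percent_sem=("time_percent", "sem"),
    )
    return out
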