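"""Behavioural-state analysis: huddle episodes, time budgets, sleep, cell means.

Locomotive states (per 1-s video annotation): ``inactive`` (no movement),
``active_still`` (head movement without trunk displacement), ``active``
(trunk displacement).  A huddle is trunk-to-trunk contact of >= 2 mice; only
contact runs persisting strictly more than 10 s count as huddle episodes.
Sleep is defined behaviourally as sustained immobility (inactive runs of at
least ``min_immobile_s`` seconds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AnnotationTable, LOCOMOTIVE_STATES
from .spectral import HlrSeries

__all__ = [
    "HuddleEpisode",
    "huddle_episodes",
    "huddle_size_per_second",
    "time_budget",
    "label_sleep",
    "condition_means",
    "segment_table",
    "MIN_HUDDLE_PERSISTENCE_S",
]

#: Contact runs must persist strictly longer than this to count as a huddle.
MIN_HUDDLE_PERSISTENCE_S = 10


@dataclass
class HuddleEpisode:
    """One huddle: a maximal contiguous run of the same contact group.

    ``members`` is the subject set in contact; ``start``/``end`` are
    inclusive seconds.  Size is constant within an episode because an
    interruption or membership change of any length splits the run before
    the >10 s persistence rule is applied.
    """

    episode_id: str
    start: int
    end: int
    members: frozenset[str]

    @property
    def duration_s(self) -> int:
        return self.end - self.start + 1

    @property
    def size(self) -> int:
        return len(self.members)


def huddle_episodes(
    table: AnnotationTable, min_persistence_s: int = MIN_HUDDLE_PERSISTENCE_S
) -> list[HuddleEpisode]:
    """Extract huddle episodes from per-second contact-group labels.

    Seconds sharing the same ``huddle_group_id`` and the same member set
    form a run; runs of duration <= ``min_persistence_s`` are discarded
    (strict "> 10 s" rule).  Two disjoint groups huddling simultaneously are
    distinct episodes.
    """
    if table.condition != "group":
        raise ValueError("huddle episodes are only defined for group-condition sessions")
    df = table.df[table.df["huddle_group_id"].notna()]
    episodes: list[HuddleEpisode] = []
    for gid, sub in df.groupby("huddle_group_id"):
        # member set per second of this label
        per_sec = sub.groupby("second")["subject_id"].agg(frozenset).sort_index()
        secs = per_sec.index.to_numpy(dtype=int)
        runs = _contiguous_runs(secs, per_sec.to_numpy(dtype=object))
        for k, (start, end, members) in enumerate(runs):
            if len(members) < 2:
                continue  # a lone non-contacting mouse is not a huddle
            if end - start + 1 <= min_persistence_s:
                continue
            episodes.append(
                HuddleEpisode(
                    episode_id=f"{gid}" if len(runs) == 1 else f"{gid}.{k}",
                    start=int(start),
                    end=int(end),
                    members=members,
                )
            )
    episodes.sort(key=lambda e: (e.start, e.episode_id))
    return episodes


def _contiguous_runs(secs, member_sets):
    """Split (sorted seconds, member-set) into maximal constant contiguous runs."""
    runs = []
    if len(secs) == 0:
        return runs
    start = secs[0]
    cur = member_sets[0]
    prev = secs[0]
    for s, m in zip(secs[1:], member_sets[1:]):
        if s != prev + 1 or m != cur:
            runs.append((start, prev, cur))
            start, cur = s, m
        prev = s
    runs.append((start, prev, cur))
    return runs


def huddle_size_per_second(
    table: AnnotationTable, episodes: list[HuddleEpisode] | None = None
) -> pd.DataFrame:
    """Per-second huddle size and per-subject huddled flags.

    Returns a frame with columns ``subject_id, second, huddled, huddle_size``
    where ``huddle_size`` is the size of the episode the subject belongs to
    (0 when not huddled).  A subject is huddled at a second iff it is a
    member of an episode spanning that second.
    """
    if episodes is None:
        episodes = huddle_episodes(table)
    n = table.n_seconds
    subjects = table.subjects
    size = {sid: np.zeros(n, dtype=int) for sid in subjects}
    for ep in episodes:
        for sid in ep.members:
            size[sid][ep.start : ep.end + 1] = ep.size
    rows = []
    for sid in subjects:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "second": np.arange(n),
                    "huddled": size[sid] > 0,
                    "huddle_size": size[sid],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def time_budget(table: AnnotationTable, by: str = "locomotive_state") -> pd.DataFrame:
    """Fraction of session seconds per category, per subject.

    ``by`` is ``"locomotive_state"`` or ``"huddle_size"`` (sizes {0,2,3,4},
    0 meaning non-huddled).  Fractions sum to 1 per subject.
    """
    if by == "locomotive_state":
        df = table.df
        counts = (
            df.groupby(["subject_id", "locomotive_state"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        counts = counts.reindex(columns=list(LOCOMOTIVE_STATES), fill_value=0)
    elif by == "huddle_size":
        sizes = huddle_size_per_second(table)
        counts = (
            sizes.groupby(["subject_id", "huddle_size"]).size().unstack(fill_value=0)
        )
    else:
        raise ValueError(f"unknown grouping {by!r}")
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return fractions


def label_sleep(table: AnnotationTable, min_immobile_s: int = 40) -> AnnotationTable:
    """Flag immobility-defined sleep: inactive runs of >= ``min_immobile_s`` s.

    Any interruption (even one active-still second) resets the run.  Returns
    a new table with a boolean ``sleep`` column; sleep seconds are by
    construction a subset of inactive seconds.
    """
    if min_immobile_s < 1:
        raise ValueError("min_immobile_s must be >= 1")
    df = table.df.sort_values(["subject_id", "second"]).reset_index(drop=True)
    sleep = np.zeros(len(df), dtype=bool)
    for _, idx in df.groupby("subject_id").groups.items():
        idx = np.asarray(idx)
        inactive = (df.loc[idx, "locomotive_state"] == "inactive").to_numpy()
        sleep[idx] = _long_runs(inactive, min_immobile_s)
    out = df.assign(sleep=sleep)
    return AnnotationTable(df=out, condition=table.condition)


def _long_runs(flags: np.ndarray, min_len: int) -> np.ndarray:
    """Mark elements belonging to True-runs of length >= min_len."""
    out = np.zeros_like(flags)
    n = len(flags)
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# HLR cell means
# ---------------------------------------------------------------------------

def segment_table(
    hlrs: list[HlrSeries],
    table: AnnotationTable,
    *,
    with_sleep: bool = False,
) -> pd.DataFrame:
    """Long-format per-(subject, second) table joining HLR with behaviour.

    Columns: subject_id, second, hlr, locomotive_state, condition,
    huddle_status (single | huddled | non_huddled) and optionally sleep.
    Seconds with invalid HLR are dropped (counts of dropped seconds are in
    the ``attrs`` of the result).  This is the table a two-way ANOVA on
    segments would consume.
    """
    if table.condition == "group":
        flags = {
            s.subject_id: table.huddled_flags(s.subject_id) for s in hlrs
        }
    frames = []
    dropped = 0
    for s in hlrs:
        ann = table.for_subject(s.subject_id)
        n = min(len(s), len(ann))
        valid = s.valid[:n]
        dropped += int(n - valid.sum())
        if table.condition == "group":
            f = flags[s.subject_id][:n]
            status = np.where(f, "huddled", "non_huddled")
        else:
            status = np.full(n, "single")
        frame = pd.DataFrame(
            {
                "subject_id": s.subject_id,
                "second": np.arange(n),
                "hlr": s.values[:n],
                "locomotive_state": ann["locomotive_state"].to_numpy()[:n],
                "condition": table.condition,
                "huddle_status": status,
            }
        )
        if with_sleep and "sleep" in ann.columns:
            frame["sleep"] = ann["sleep"].to_numpy()[:n]
        frames.append(frame[valid])
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_dropped_invalid"] = dropped
    return out


def condition_means(
    hlrs: list[HlrSeries],
    table: AnnotationTable,
    *,
    with_sleep: bool = False,
) -> pd.DataFrame:
    """HLR mean, SD and n per (locomotive_state x condition x huddle_status).

    Empty cells are reported with n=0 and NaN mean.  The companion
    :func:`segment_table` provides the per-segment long format.
    """
    seg = segment_table(hlrs, table, with_sleep=with_sleep)
    keys = ["locomotive_state", "condition", "huddle_status"]
    if with_sleep and "sleep" in seg.columns:
        keys.append("sleep")
    grouped = seg.groupby(keys, observed=True)["hlr"].agg(["mean", "std", "count"])
    grouped = grouped.rename(columns={"count": "n"}).reset_index()
    return grouped
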