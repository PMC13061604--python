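"""Dual-colour co-movement: colocalization runs, events, per-cell summaries.

An interaction ("co-movement event") is a maximal run of consecutive frames
in which a chaperone-channel track and a client-channel track are closer
than ``max_distance`` (strictly), lasting at least ``min_frames`` frames
(default 10 frames = 500 ms at 50-ms frames).  A single above-threshold
frame, or a tracking dropout in either channel, terminates a run.  When a
chaperone is within range of several clients in one frame only the nearest
partner is counted (one interaction per molecule per time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ColocConfig",
    "CoMovementEvent",
    "pair_distances",
    "extract_events",
    "summarize_cells",
    "event_distance_stats",
]


@dataclass(frozen=True)
class ColocConfig:
    max_distance: float = 0.5    # µm, strict upper bound
    min_frames: int = 10
    frame_interval: float = 0.05  # s
    nearest_partner_only: bool = True
    exclude_boundary_censored: bool = False

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def min_duration(self) -> float:
        return self.min_frames * self.frame_interval


@dataclass
class CoMovementEvent:
    chaperone_track: int
    client_track: int
    start_frame: int
    end_frame: int           # inclusive
    duration_s: float        # (end - start + 1) * frame_interval
    distances: np.ndarray = field(repr=False)
    boundary_censored: bool = False

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def _tracks_by_id(table: pd.DataFrame) -> dict[int, pd.DataFrame]:
    return {tid: g.set_index("frame") for tid, g in table.groupby("track_id")}


def pair_distances(tracks_a: pd.DataFrame, tracks_b: pd.DataFrame) -> pd.DataFrame:
    """Per-frame Euclidean distances for every (A-track, B-track) pair.

    Both tables need columns ``track_id``, ``frame``, ``x_um``, ``y_um`` and
    share the frame clock.  Frames where either track has no spot are absent
    from the output (they break colocalization runs downstream).
    """
    a_by = _tracks_by_id(tracks_a)
    b_by = _tracks_by_id(tracks_b)
    rows = []
    for ida, ga in a_by.items():
        for idb, gb in b_by.items():
            shared = ga.index.intersection(gb.index)
            if shared.empty:
                continue
            dx = ga.loc[shared, "x_um"].to_numpy() - gb.loc[shared, "x_um"].to_numpy()
            dy = ga.loc[shared, "y_um"].to_numpy() - gb.loc[shared, "y_um"].to_numpy()
            dist = np.hypot(dx, dy)
            for f, d in zip(shared, dist):
                rows.append((ida, idb, int(f), float(d)))
    return pd.DataFrame(rows, columns=["track_a", "track_b", "frame", "distance_um"])


def extract_events(
    distances: pd.DataFrame,
    config: ColocConfig | None = None,
    track_spans: dict[str, dict[int, tuple[int, int]]] | None = None,
) -> list[CoMovementEvent]:
    """Extract co-movement events from a pair-distance table.

    ``track_spans`` optionally maps ``{"a": {track_id: (first, last)}, "b": …}``
    so events touching the start/end of either track can be flagged
    boundary-censored (they are retained unless the config excludes them).
    """
    config = config or ColocConfig()
    if distances.empty:
        return []
    dist = distances.copy()
    below = dist[dist["distance_um"] < config.max_distance]
    if config.nearest_partner_only and not below.empty:
        # per chaperone per frame keep only the nearest client
        keep = below.groupby(["track_a", "frame"])["distance_um"].idxmin()
        below = below.loc[sorted(keep)]

    events: list[CoMovementEvent] = []
    for (ida, idb), g in below.groupby(["track_a", "track_b"]):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        dists = g["distance_um"].to_numpy()
        breaks = np.flatnonzero(np.diff(frames) != 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(frames) - 1]))
        for s, e in zip(starts, ends):
            if e - s + 1 < config.min_frames:
                continue
            start_f, end_f = int(frames[s]), int(frames[e])
            censored = False
            if track_spans is not None:
                fa = track_spans.get("a", {}).get(ida)
                fb = track_spans.get("b", {}).get(idb)
                for span in (fa, fb):
                    if span is not None and (start_f <= span[0] or end_f >= span[1]):
                        censored = True
            if censored and config.exclude_boundary_censored:
                continue
            events.append(
                CoMovementEvent(
                    chaperone_track=ida,
                    client_track=idb,
                    start_frame=start_f,
                    end_frame=end_f,
                    duration_s=(end_f - start_f + 1) * config.frame_interval,
                    distances=dists[s:e + 1].copy(),
                    boundary_censored=censored,
                )
            )
    events.sort(key=lambda ev: (ev.start_frame, ev.chaperone_track, ev.client_track))
    return events


def events_to_frame(events: list[CoMovementEvent], cell_id: str | int = 0) -> pd.DataFrame:
    rows = [
        (cell_id, ev.chaperone_track, ev.client_track, ev.start_frame, ev.end_frame,
         ev.duration_s, ev.boundary_censored)
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=["cell", "chaperone_track", "client_track", "start_frame",
                 "end_frame", "duration_s", "censored"],
    )


def summarize_cells(events_by_cell: dict, n_cells: int) -> tuple[pd.DataFrame, float]:
    """Per-cell event counts plus the condition-level normalized count.

    Normalized events = total events across cells / ``n_cells`` (cells with
    zero events still count in the denominator).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rows = []
    total = 0
    for cell, events in events_by_cell.items():
        durations = [ev.duration_s for ev in events]
        rows.append(
            (cell, len(events), float(np.mean(durations)) if durations else np.nan)
        )
        total += len(events)
    normalized = total / n_cells
    summary = pd.DataFrame(rows, columns=["cell", "n_events", "mean_duration_s"])
    summary["normalized_events"] = normalized
    return summary, normalized


def event_distance_stats(events: list[CoMovementEvent]) -> dict:
    """Distance statistics over event traces (pooled and per event)."""
    if not events:
        raise ValueError("need at least one event")
    pooled = np.concatenate([ev.distances for ev in events])
    per_event_mean = np.array([ev.distances.mean() for ev in events])
    per_event_min = np.array([ev.distances.min() for ev in events])
    return {
        "mean_distance_um": float(pooled.mean()),
        "per_event_mean_um": per_event_mean,
        "per_event_min_um": per_event_min,
    }
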