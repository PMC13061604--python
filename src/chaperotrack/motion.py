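"""Per-track diffusion analysis and on-off-on rebinding cycles.

MSD is the time-averaged mean squared displacement over all start points at
each lag; the diffusion coefficient comes from a linear fit of the first
few lags (slope/4 in 2-D, with the intercept absorbing localization noise)
and the anomalous exponent from the log-log slope over the same lags.
Tracks are classified stationary / sub-diffusive / diffusive by declared
thresholds (D < D_stat, else alpha < alpha_sub, else diffusive).

A rebinding cycle is a pair of consecutive co-movement events between the
same chaperone and the same client separated by an "off" interval during
which the chaperone remains tracked; the off-state excursion (peak distance
from the client) and motion class are reported.  Chaperones lost during the
off interval are counted separately as untrackable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comove import CoMovementEvent

__all__ = [
    "MotionThresholds",
    "MotionStats",
    "RebindCycle",
    "msd",
    "fit_diffusion",
    "classify_motion",
    "find_rebind_cycles",
    "off_state_summary",
]


@dataclass(frozen=True)
class MotionThresholds:
    d_stationary: float = 0.02     # µm²/s
    alpha_subdiffusive: float = 0.7
    n_fit_lags: int = 4


@dataclass
class MotionStats:
    track_id: int
    lags_s: np.ndarray
    msd_um2: np.ndarray
    d: float = np.nan              # µm²/s
    alpha_exp: float = np.nan
    motion_class: str = ""


@dataclass
class RebindCycle:
    chaperone_track: int
    client_track: int
    on1: CoMovementEvent
    on2: CoMovementEvent
    off_start: int                 # first off frame
    off_end: int                   # last off frame (inclusive)
    off_duration_s: float
    max_excursion_um: float
    off_class: str                 # stationary | sub-diffusive | lost


def msd(track: pd.DataFrame, max_lag: int, frame_interval: float = 0.05) -> np.ndarray:
    """Time-averaged MSD of one track for lags 1..max_lag (µm²).

    The track (columns ``frame``, ``x_um``, ``y_um``) must have consecutive
    frames and length >= max_lag + 1.
    """
    track = track.sort_values("frame")
    xy = track[["x_um", "y_um"]].to_numpy()
    n = len(xy)
    if n < max_lag + 1:
        raise ValueError(f"track too short ({n} frames) for max_lag={max_lag}")
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        disp = xy[lag:] - xy[:-lag]
        out[lag - 1] = float(np.mean((disp**2).sum(axis=1)))
    return out


def fit_diffusion(
    msd_curve: np.ndarray,
    frame_interval: float = 0.05,
    n_fit_lags: int = 4,
) -> tuple[float, float]:
    """(D, anomalous exponent) from an MSD curve.

    D = slope/4 of a linear fit of MSD vs lag time over the first
    ``n_fit_lags`` lags (intercept free, absorbing the localization-noise
    floor); alpha from the log-log slope over the same lags.  D is floored
    at 0.
    """
    msd_curve = np.asarray(msd_curve, float)
    k = min(n_fit_lags, len(msd_curve))
    if k < 2:
        raise ValueError("need at least 2 lags")
    lags = np.arange(1, k + 1) * frame_interval
    y = msd_curve[:k]
    slope, _ = np.polyfit(lags, y, 1)
    d = max(float(slope) / 4.0, 0.0)
    if np.all(y > 0):
        alpha, _ = np.polyfit(np.log(lags), np.log(y), 1)
        alpha = float(alpha)
    else:
        alpha = 0.0   # zero MSD anywhere => immobile
    return d, alpha


def classify_motion(d: float, alpha_exp: float,
                    thresholds: MotionThresholds | None = None) -> str:
    th = thresholds or MotionThresholds()
    if d < th.d_stationary:
        return "stationary"
    if alpha_exp < th.alpha_subdiffusive:
        return "sub-diffusive"
    return "diffusive"


def analyze_track(
    track_id: int,
    track: pd.DataFrame,
    max_lag: int = 10,
    frame_interval: float = 0.05,
    thresholds: MotionThresholds | None = None,
) -> MotionStats:
    th = thresholds or MotionThresholds()
    curve = msd(track, max_lag, frame_interval)
    d, alpha = fit_diffusion(curve, frame_interval, th.n_fit_lags)
    return MotionStats(
        track_id=track_id,
        lags_s=np.arange(1, max_lag + 1) * frame_interval,
        msd_um2=curve,
        d=d,
        alpha_exp=alpha,
        motion_class=classify_motion(d, alpha, th),
    )


def find_rebind_cycles(
    events: list[CoMovementEvent],
    tracks_a: pd.DataFrame,
    tracks_b: pd.DataFrame,
    frame_interval: float = 0.05,
    thresholds: MotionThresholds | None = None,
    reident_radius: float = 0.3,
) -> tuple[list[RebindCycle], int]:
    """Detect on-off-on cycles among a chaperone's events on the same client.

    Returns (cycles, n_untrackable): consecutive event pairs whose off
    interval is fully covered by the chaperone track give a cycle; pairs
    where the chaperone is lost during the off interval are counted in
    ``n_untrackable``.  The client is identified by track id; if the client
    spot is missing in some off frames its last seen position within
    ``reident_radius`` frames is used for the excursion.
    """
    th = thresholds or MotionThresholds()
    a_by = {tid: g.set_index("frame") for tid, g in tracks_a.groupby("track_id")}
    b_by = {tid: g.set_index("frame") for tid, g in tracks_b.groupby("track_id")}
    cycles: list[RebindCycle] = []
    untrackable = 0

    by_pair: dict[tuple[int, int], list[CoMovementEvent]] = {}
    for ev in events:
        by_pair.setdefault((ev.chaperone_track, ev.client_track), []).append(ev)

    for (ida, idb), evs in by_pair.items():
        evs = sorted(evs, key=lambda e: e.start_frame)
        ga = a_by.get(ida)
        gb = b_by.get(idb)
        for on1, on2 in zip(evs, evs[1:]):
            off_start, off_end = on1.end_frame + 1, on2.start_frame - 1
            if off_end < off_start:
                continue
            off_frames = np.arange(off_start, off_end + 1)
            if ga is None or not np.isin(off_frames, ga.index).all():
                untrackable += 1
                continue
            chap = ga.loc[off_frames, ["x_um", "y_um"]].to_numpy()
            # client position per off frame (last seen, within the off span)
            if gb is not None:
                cli_frames = gb.index.to_numpy()
                cli_xy = gb[["x_um", "y_um"]].to_numpy()
                pos = np.searchsorted(cli_frames, off_frames, side="right") - 1
                pos = np.clip(pos, 0, len(cli_frames) - 1)
                cli = cli_xy[pos]
                dist = np.linalg.norm(chap - cli, axis=1)
                max_exc = float(dist.max())
            else:
                max_exc = np.nan
            off_class = _off_class(chap, frame_interval, th)
            cycles.append(
                RebindCycle(
                    chaperone_track=ida,
                    client_track=idb,
                    on1=on1,
                    on2=on2,
                    off_start=int(off_start),
                    off_end=int(off_end),
                    off_duration_s=len(off_frames) * frame_interval,
                    max_excursion_um=max_exc,
                    off_class=off_class,
                )
            )
    cycles.sort(key=lambda c: (c.chaperone_track, c.client_track, c.off_start))
    return cycles, untrackable


def _off_class(xy: np.ndarray, frame_interval: float, th: MotionThresholds) -> str:
    if len(xy) < 3:
        return "stationary" if len(xy) < 2 or np.allclose(xy[0], xy[-1]) else "sub-diffusive"
    max_lag = min(th.n_fit_lags, len(xy) - 1)
    curve = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        disp = xy[lag:] - xy[:-lag]
        curve[lag - 1] = float(np.mean((disp**2).sum(axis=1)))
    if max_lag < 2:
        step = float(curve[0])
        return "stationary" if step / (4 * frame_interval) < th.d_stationary else "sub-diffusive"
    d, alpha = fit_diffusion(curve, frame_interval, max_lag)
    cls = classify_motion(d, alpha, th)
    return cls


def off_state_summary(
    cycles: list[RebindCycle],
    n_trackable_off: int,
    n_all_trajectories: int,
    bins: np.ndarray | None = None,
) -> dict:
    """Fractions and off-state statistics, with both denominators reported."""
    n_cycling = len({(c.chaperone_track, c.client_track) for c in cycles})
    exc = np.array([c.max_excursion_um for c in cycles if np.isfinite(c.max_excursion_um)])
    durs = np.array([c.off_duration_s for c in cycles])
    if bins is None:
        bins = np.arange(0.0, (durs.max() if len(durs) else 0.0) + 0.55, 0.5)
    hist, edges = np.histogram(durs, bins=bins) if len(durs) else (np.array([], int), bins)
    classes = pd.Series([c.off_class for c in cycles])
    class_fracs = (classes.value_counts(normalize=True).to_dict() if len(classes) else {})
    return {
        "n_cycles": len(cycles),
        "fraction_per_trackable_off": (n_cycling / n_trackable_off
                                       if n_trackable_off > 0 else 0.0),
        "fraction_per_all_trajectories": (n_cycling / n_all_trajectories
                                          if n_all_trajectories > 0 else 0.0),
        "mean_excursion_um": float(exc.mean()) if len(exc) else 0.0,
        "max_excursion_um": float(exc.max()) if len(exc) else 0.0,
        "off_duration_hist": (hist.tolist(), np.asarray(edges).tolist()),
        "off_class_fractions": class_fracs,
    }
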