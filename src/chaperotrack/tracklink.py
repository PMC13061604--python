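"""Spot detection (Laplacian-of-Gaussian) and LAP trajectory linking.

Linking follows the canonical frame-to-frame linear-assignment formulation:
candidate links cost the squared displacement, the non-linking alternative
costs ``linking_max_distance**2``, and the globally optimal one-to-one
assignment is solved per consecutive frame pair.  With ``max_frame_gap = 0``
(the default used throughout) no gap closing is performed, so every track is
a run of strictly consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from xml.etree import ElementTree

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = ["LinkConfig", "detect_spots_log", "link_tracks", "read_trackmate_xml"]


@dataclass(frozen=True)
class LinkConfig:
    linking_max_distance: float = 0.5   # µm
    gap_close_max_distance: float = 0.5  # µm; inert while max_frame_gap == 0
    max_frame_gap: int = 0

    def __post_init__(self) -> None:
        if self.linking_max_distance <= 0 or self.gap_close_max_distance <= 0:
            raise ValueError("distances must be > 0")
        if self.max_frame_gap < 0:
            raise ValueError("max_frame_gap must be >= 0")


def detect_spots_log(
    stack: np.ndarray,
    psf_sigma: float,
    quality_threshold: float,
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Detect bright spots in an image stack with a LoG filter.

    The response is the negated Gaussian-Laplacian at scale ``psf_sigma``
    (scale-normalized by sigma^2, so the threshold is comparable across
    scales); local maxima above ``quality_threshold`` are kept and refined
    to sub-pixel precision by a quadratic fit around the peak.  Positions
    are returned in µm via ``pixel_size``.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    stack = np.asarray(stack, float)
    if stack.size == 0:
        return pd.DataFrame(columns=["frame", "x_um", "y_um", "quality"])
    if stack.ndim == 2:
        stack = stack[None]

    rows = []
    for f, img in enumerate(stack):
        resp = -(psf_sigma**2) * ndimage.gaussian_laplace(img, psf_sigma)
        footprint = np.ones((3, 3), bool)
        local_max = (resp == ndimage.maximum_filter(resp, footprint=footprint))
        local_max &= resp > quality_threshold
        # keep maxima strictly above every neighbour to avoid plateaus
        ys, xs = np.nonzero(local_max)
        for y, x in zip(ys, xs):
            if y in (0, resp.shape[0] - 1) or x in (0, resp.shape[1] - 1):
                continue
            dx = _quadratic_offset(resp[y, x - 1], resp[y, x], resp[y, x + 1])
            dy = _quadratic_offset(resp[y - 1, x], resp[y, x], resp[y + 1, x])
            rows.append((f, (x + dx) * pixel_size, (y + dy) * pixel_size,
                         float(resp[y, x])))
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "quality"])


def _quadratic_offset(left: float, centre: float, right: float) -> float:
    denom = left - 2.0 * centre + right
    if denom == 0:
        return 0.0
    off = 0.5 * (left - right) / denom
    return float(np.clip(off, -0.5, 0.5))


def link_tracks(spots: pd.DataFrame, config: LinkConfig | None = None) -> pd.DataFrame:
    """Link a per-frame spot table into trajectories.

    Parameters
    ----------
    spots : DataFrame with columns ``frame``, ``x_um``, ``y_um``.
    config : LinkConfig

    Returns
    -------
    DataFrame with columns ``track_id``, ``frame``, ``x_um``, ``y_um``;
    tracks are maximal chains of optimal frame-to-frame links with inter-spot
    distance strictly below ``linking_max_distance``.  Output order is by
    (track first frame, x, y) then frame, with track ids renumbered 0..n-1.
    """
    config = config or LinkConfig()
    spots = spots.sort_values("frame", kind="stable").reset_index(drop=True)
    if spots.empty:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])

    frames = sorted(spots["frame"].unique())
    by_frame = {
        f: spots.loc[spots["frame"] == f, ["x_um", "y_um"]].to_numpy()
        for f in frames
    }
    # active track id carried by each spot of the previous frame
    track_of_prev: list[int] = []
    track_points: dict[int, list[tuple[int, float, float]]] = {}
    next_id = 0
    prev_frame = None

    for f in frames:
        pts = by_frame[f]
        n = len(pts)
        if prev_frame is None or f != prev_frame + 1 or not track_of_prev:
            assign = {}  # no predecessor frame: all spots open tracks
        else:
            prev_pts = by_frame[prev_frame]
            assign = _lap_assign(prev_pts, pts, config.linking_max_distance)

        track_of_cur = [-1] * n
        for i_prev, j_cur in assign.items():
            track_of_cur[j_cur] = track_of_prev[i_prev]
        for j in range(n):
            if track_of_cur[j] < 0:
                track_of_cur[j] = next_id
                track_points[next_id] = []
                next_id += 1
            track_points[track_of_cur[j]].append((f, pts[j, 0], pts[j, 1]))
        track_of_prev = track_of_cur
        prev_frame = f

    # deterministic renumbering by (first frame, x, y)
    order = sorted(
        track_points,
        key=lambda tid: (track_points[tid][0][0], track_points[tid][0][1],
                         track_points[tid][0][2]),
    )
    rows = []
    for new_id, tid in enumerate(order):
        for f, x, y in track_points[tid]:
            rows.append((new_id, f, x, y))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])


def _lap_assign(prev_pts: np.ndarray, cur_pts: np.ndarray, max_dist: float) -> dict[int, int]:
    """Optimal one-to-one link assignment between two frames.

    Augmented cost matrix: top-left = squared distances (feasible pairs only),
    top-right / bottom-left diagonals = the non-link alternative cost
    ``max_dist**2``, bottom-right = zeros.  Returns {prev index -> cur index}.
    """
    n, m = len(prev_pts), len(cur_pts)
    if n == 0 or m == 0:
        return {}
    d2 = ((prev_pts[:, None, :] - cur_pts[None, :, :]) ** 2).sum(axis=2)
    alt = max_dist**2
    big = 1e9
    cost = np.full((n + m, n + m), big)
    link = np.where(d2 < alt, d2, big)
    cost[:n, :m] = link
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), alt, big)
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), alt, big)
    cost[n:, m:] = 0.0  # completion block
    rows, cols = linear_sum_assignment(cost)
    out = {}
    for r, c in zip(rows, cols):
        if r < n and c < m and d2[r, c] < alt:
            out[int(r)] = int(c)
    return out


def read_trackmate_xml(path: str) -> pd.DataFrame:
    """Read a TrackMate XML export into a track table (subset of the schema).

    Only spot positions (POSITION_X/Y, FRAME) and track membership are used;
    positions are taken as already calibrated (µm).
    """
    tree = ElementTree.parse(path)
    root = tree.getroot()
    spots = {}
    for spot in root.iter("Spot"):
        sid = spot.get("ID")
        spots[sid] = (
            int(float(spot.get("FRAME"))),
            float(spot.get("POSITION_X")),
            float(spot.get("POSITION_Y")),
        )
    rows = []
    for tid, track in enumerate(root.iter("Track")):
        seen = set()
        for edge in track.iter("Edge"):
            seen.add(edge.get("SPOT_SOURCE_ID"))
            seen.add(edge.get("SPOT_TARGET_ID"))
        for sid in seen:
            if sid in spots:
                f, x, y = spots[sid]
                rows.append((tid, f, x, y))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)
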