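"""Gap-free single-molecule track building from localization tables.

Localizations in consecutive frames are linked when their lateral distance
is at most the linking radius (default 0.32 um).  Assignment within each
frame pair is globally greedy by ascending distance; no gaps are permitted,
so a missed frame always terminates a track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Track",
    "Centerline",
    "filter_axial",
    "link_localizations",
    "effective_residence_time",
    "distance_from_pole",
    "tracks_to_frame",
]

DEFAULT_RADIUS_UM = 0.32


@dataclass
class Track:
    """An ordered, gap-free run of localizations of one molecule."""

    track_id: int
    frames: np.ndarray  # strictly consecutive integers
    x: np.ndarray  # um
    y: np.ndarray  # um
    rows: np.ndarray  # row indices into the source table

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.n >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be strictly consecutive")

    @property
    def n(self) -> int:
        return int(self.frames.size)


@dataclass(frozen=True)
class Centerline:
    """Pole-to-pole cell centerline as an ordered polyline, um."""

    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("centerline needs >= 2 (x, y) points")
        if self.length <= 0:
            raise ValueError("centerline has zero arclength")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def filter_axial(
    locs: pd.DataFrame, z_min: float = -0.2, z_max: float = 0.2
) -> pd.DataFrame:
    """Keep rows with z_min <= z_um <= z_max (inclusive), order preserved."""
    if "z_um" not in locs.columns:
        raise ValueError("localization table has no 'z_um' column")
    mask = (locs["z_um"] >= z_min) & (locs["z_um"] <= z_max)
    return locs.loc[mask].copy()


def link_localizations(
    locs: pd.DataFrame, radius: float = DEFAULT_RADIUS_UM, max_gap: int = 0
) -> list[Track]:
    """Link localizations into gap-free tracks.

    A localization in frame f+1 extends a track ending in frame f iff its
    lateral distance to the track end is <= ``radius``.  Candidate links in
    each frame pair are assigned greedily in ascending distance, breaking
    ties by lower track id and then by lower row index.  Unlinked
    localizations start new tracks.  Every input row ends up in exactly one
    track.
    """
    if max_gap != 0:
        raise ValueError("no gaps within tracks are permitted (max_gap must be 0)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(locs.columns):
        raise ValueError(f"localization table must have columns {sorted(required)}")

    if locs.duplicated(subset=["frame", "x_um", "y_um"]).any():
        warnings.warn("duplicate (frame, x, y) localizations found; keeping all")

    frames = locs["frame"].to_numpy(dtype=np.int64)
    xs = locs["x_um"].to_numpy(dtype=float)
    ys = locs["y_um"].to_numpy(dtype=float)
    order = np.argsort(frames, kind="stable")

    # open tracks: lists of row positions (into locs order), keyed by track id
    track_rows: list[list[int]] = []
    open_by_frame: dict[int, list[int]] = {}  # frame -> track ids ending there

    unique_frames = np.unique(frames)
    pos_by_frame = {
        f: order[np.searchsorted(frames[order], f, "left") : np.searchsorted(frames[order], f, "right")]
        for f in unique_frames
    }

    for f in unique_frames:
        rows_here = pos_by_frame[f]
        prev_ids = open_by_frame.pop(f - 1, [])
        assigned_rows: set[int] = set()
        extended: dict[int, int] = {}  # track id -> row
        if prev_ids:
            ends = np.array(
                [[xs[track_rows[tid][-1]], ys[track_rows[tid][-1]]] for tid in prev_ids]
            )
            here = np.column_stack([xs[rows_here], ys[rows_here]])
            dist = cdist(ends, here)
            ti, li = np.nonzero(dist <= radius)
            cand = sorted(
                zip(dist[ti, li], ti, li), key=lambda c: (c[0], prev_ids[c[1]], c[2])
            )
            used_tracks: set[int] = set()
            for d, i, j in cand:
                tid = prev_ids[i]
                row = int(rows_here[j])
                if tid in used_tracks or row in assigned_rows:
                    continue
                used_tracks.add(tid)
                assigned_rows.add(row)
                extended[tid] = row
        ending_here: list[int] = []
        for tid, row in extended.items():
            track_rows[tid].append(row)
            ending_here.append(tid)
        for row in rows_here:
            row = int(row)
            if row not in assigned_rows:
                track_rows.append([row])
                ending_here.append(len(track_rows) - 1)
        open_by_frame[f] = ending_here

    index = locs.index.to_numpy()
    return [
        Track(
            track_id=tid,
            frames=frames[rows],
            x=xs[rows],
            y=ys[rows],
            rows=index[rows],
        )
        for tid, rows in enumerate(track_rows)
    ]


def effective_residence_time(track: Track, tau_tl: float) -> float:
    """Effective residence time (n - 1) * tau_tl, s."""
    if tau_tl <= 0:
        raise ValueError("tau_tl must be positive")
    return (track.n - 1) * tau_tl


def distance_from_pole(track: Track, centerline: Centerline) -> float:
    """Arclength from the nearer pole to the track's first localization.

    The first point is projected onto the centerline polyline; the arclength
    of the projection is folded to the nearer pole, so the result lies in
    [0, length / 2].
    """
    p = np.array([track.x[0], track.y[0]])
    pts = centerline.points
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    best_d2, best_arc = np.inf, 0.0
    for i in range(seg.shape[0]):
        if seg_len[i] == 0:
            continue
        t = np.dot(p - pts[i], seg[i]) / (seg_len[i] ** 2)
        t = min(max(t, 0.0), 1.0)
        proj = pts[i] + t * seg[i]
        d2 = float(np.sum((p - proj) ** 2))
        if d2 < best_d2:
            best_d2 = d2
            best_arc = cum[i] + t * seg_len[i]
    total = cum[-1]
    return float(min(best_arc, total - best_arc))


def tracks_to_frame(
    tracks: list[Track],
    tau_tl: float,
    centerline: Centerline | None = None,
    source: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format track table: track_id, frame, x_um, y_um, t_eff_s,
    distance_from_pole_um (NaN without a centerline), and event_id when the
    source table carries ground truth."""
    chunks = []
    for tr in tracks:
        dist = distance_from_pole(tr, centerline) if centerline is not None else np.nan
        chunk = pd.DataFrame(
            {
                "track_id": tr.track_id,
                "frame": tr.frames,
                "x_um": tr.x,
                "y_um": tr.y,
                "t_eff_s": effective_residence_time(tr, tau_tl),
                "distance_from_pole_um": dist,
            }
        )
        if source is not None and "event_id" in source.columns:
            chunk["event_id"] = source.loc[tr.rows, "event_id"].to_numpy()
        chunks.append(chunk)
    if not chunks:
        return pd.DataFrame(
            columns=["track_id", "frame", "x_um", "y_um", "t_eff_s", "distance_from_pole_um"]
        )
    return pd.concat(chunks, ignore_index=True)
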