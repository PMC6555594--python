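"""Node-resolved TIRF intensity time-series analysis.

Covers photobleaching correction of ROI traces, encounter detection as
maximal runs above an intensity threshold, cell-length-grouped summaries,
and minimal cluster lifetimes with censoring flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NodeSeries",
    "Encounter",
    "ClusterRecord",
    "LengthGroupSummary",
    "DEFAULT_LENGTH_BINS",
    "bleach_correct",
    "bleach_correct_group",
    "encounter_durations",
    "group_by_length",
    "cluster_lifetimes",
    "cluster_geometry",
]

DEFAULT_THRESHOLD_AU = 20.0
DEFAULT_LENGTH_BINS = ((6.0, 8.0), (9.0, 11.0), (12.0, 14.0))  # closed [lo, hi] um
_REL_TOL = 1e-6


@dataclass
class NodeSeries:
    """Intensity vs time inside one fixed cortical ROI."""

    node_id: int
    t: np.ndarray  # s, uniform interval
    intensity: np.ndarray  # a.u.
    cell_id: int = 0
    cell_length: float = float("nan")  # um
    is_control_roi: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.size != self.intensity.size:
            raise ValueError("t and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def frame_interval(self) -> float:
        dt = np.diff(self.t)
        if dt.size == 0:
            raise ValueError("series needs >= 2 samples")
        if np.any(np.abs(dt - dt[0]) > _REL_TOL * max(abs(dt[0]), 1e-12)):
            raise ValueError("non-uniform sampling interval")
        return float(dt[0])


@dataclass(frozen=True)
class Encounter:
    node_id: int
    start_t: float  # s
    duration: float  # s (run length * frame interval)
    peak_intensity: float  # a.u.
    censored: bool  # run touches the start or end of the window


@dataclass(frozen=True)
class ClusterRecord:
    cluster_id: int
    first_frame: int
    last_frame: int
    minimal_lifetime: float  # s, lower bound when censored
    left_censored: bool
    right_censored: bool
    area_um2: float = float("nan")
    mean_intensity: float = float("nan")


@dataclass(frozen=True)
class LengthGroupSummary:
    bin_label: str
    bin_lo: float
    bin_hi: float
    n_nodes: int
    mean_intensity: float
    sem_intensity: float
    encounter_durations: np.ndarray  # s
    continuous_fraction: float  # nodes occupied for the whole window


def bleach_correct(series: NodeSeries, method: str = "mono_exp") -> NodeSeries:
    """Correct a trace for photobleaching.

    ``mono_exp`` fits I(t) = I0 exp(-b t) (b clamped >= 0) and divides each
    sample by exp(-b t); ``none`` returns a copy.  A failed fit falls back
    to the identity correction with a warning.
    """
    if method == "none":
        return _copy_with(series, series.intensity.copy())
    if method != "mono_exp":
        raise ValueError(f"unknown bleach-correction method {method!r}")
    if series.t.size < 10:
        raise ValueError("need >= 10 samples for bleach correction")
    t, y = series.t, series.intensity
    try:
        ymean = float(np.mean(y))
        if ymean <= 0:
            raise RuntimeError("non-positive mean intensity")
        popt, _ = optimize.curve_fit(
            lambda tt, i0, b: i0 * np.exp(-b * tt),
            t,
            y,
            p0=(max(float(y[0]), 1e-6), 0.01),
            maxfev=10_000,
        )
        i0, b = popt
        if not np.isfinite(b):
            raise RuntimeError("non-finite bleach rate")
    except RuntimeError as exc:
        warnings.warn(f"bleach fit failed ({exc}); applying identity correction")
        return _copy_with(series, y.copy())
    b = max(float(b), 0.0)
    return _copy_with(series, y / np.exp(-b * t))


def bleach_correct_group(series_list: list[NodeSeries]) -> list[NodeSeries]:
    """Whole-field bleach correction.

    Fits the mono-exponential decay to the mean trace pooled across all
    series (robust for telegraph-like signals, where a single ROI's
    occupancy pattern masquerades as a trend) and divides every series by
    the common ``exp(-b t)``.
    """
    if not series_list:
        raise ValueError("no series to correct")
    t = series_list[0].t
    for s in series_list[1:]:
        if s.t.size != t.size or np.any(np.abs(s.t - t) > _REL_TOL):
            raise ValueError("all series must share the same time base")
    pooled = np.mean([s.intensity for s in series_list], axis=0)
    template = NodeSeries(node_id=-1, t=t, intensity=pooled)
    corrected_pool = bleach_correct(template)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(pooled != 0, corrected_pool.intensity / pooled, 1.0)
    return [_copy_with(s, s.intensity * factor) for s in series_list]


def _copy_with(series: NodeSeries, intensity: np.ndarray) -> NodeSeries:
    return NodeSeries(
        node_id=series.node_id,
        t=series.t.copy(),
        intensity=intensity,
        cell_id=series.cell_id,
        cell_length=series.cell_length,
        is_control_roi=series.is_control_roi,
    )


def encounter_durations(
    series: NodeSeries, threshold: float = DEFAULT_THRESHOLD_AU
) -> list[Encounter]:
    """Maximal runs of samples strictly above ``threshold``.

    Duration = run length * frame interval.  Runs touching either end of the
    observation window are flagged censored; a node above threshold for the
    whole window yields a single censored encounter spanning it.
    """
    dt = series.frame_interval
    above = series.intensity > threshold
    encounters: list[Encounter] = []
    i = 0
    n = above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        encounters.append(
            Encounter(
                node_id=series.node_id,
                start_t=float(series.t[i]),
                duration=(j - i) * dt,
                peak_intensity=float(series.intensity[i:j].max()),
                censored=(i == 0) or (j == n),
            )
        )
        i = j
    return encounters


def group_by_length(
    series_list: list[NodeSeries],
    threshold: float = DEFAULT_THRESHOLD_AU,
    bins: tuple[tuple[float, float], ...] = DEFAULT_LENGTH_BINS,
) -> tuple[list[LengthGroupSummary], dict]:
    """Summarise node series by cell-length bin.

    Bins are closed intervals; nodes whose cell length falls in a gap are
    excluded (their count is reported).  Returns the per-bin summaries and a
    stats dict with the Welch t-test of mean node intensity between the
    shortest and longest bins.
    """
    groups: dict[tuple[float, float], list[NodeSeries]] = {b: [] for b in bins}
    excluded = 0
    for s in series_list:
        placed = False
        for lo, hi in bins:
            if lo <= s.cell_length <= hi:
                groups[(lo, hi)].append(s)
                placed = True
                break
        if not placed:
            excluded += 1

    summaries = []
    for (lo, hi), members in groups.items():
        means = np.array([float(np.mean(s.intensity)) for s in members])
        durations: list[float] = []
        continuous = 0
        for s in members:
            encs = encounter_durations(s, threshold)
            durations.extend(e.duration for e in encs)
            window = s.t[-1] - s.t[0] + s.frame_interval
            if any(abs(e.duration - window) < _REL_TOL * window for e in encs):
                continuous += 1
        summaries.append(
            LengthGroupSummary(
                bin_label=f"{lo:g}-{hi:g}",
                bin_lo=lo,
                bin_hi=hi,
                n_nodes=len(members),
                mean_intensity=float(means.mean()) if means.size else math.nan,
                sem_intensity=(
                    float(means.std(ddof=1) / math.sqrt(means.size))
                    if means.size > 1
                    else math.nan
                ),
                encounter_durations=np.array(durations),
                continuous_fraction=continuous / len(members) if members else math.nan,
            )
        )

    stats_out: dict = {"n_excluded": excluded}
    short = [float(np.mean(s.intensity)) for s in groups[bins[0]]]
    long_ = [float(np.mean(s.intensity)) for s in groups[bins[-1]]]
    if len(short) > 1 and len(long_) > 1:
        t, p = stats.ttest_ind(short, long_, equal_var=False)
        stats_out["welch_t"] = float(t)
        stats_out["welch_p"] = float(p)
    return summaries, stats_out


def cluster_lifetimes(
    presence: pd.DataFrame, frame_interval: float, n_frames: int
) -> list[ClusterRecord]:
    """Minimal lifetimes from per-frame cluster presence calls.

    ``presence`` has columns (cluster_id, frame) listing frames in which a
    cluster is present.  Minimal lifetime = (last - first + 1) * interval of
    continuous presence; presence touching frame 0 (left) or the final frame
    (right) is censored.  Non-contiguous presence without split annotation
    is broken into separate records with a warning.
    """
    required = {"cluster_id", "frame"}
    if not required.issubset(presence.columns):
        raise ValueError(f"presence table must have columns {sorted(required)}")
    records: list[ClusterRecord] = []
    next_id = 0
    for cid, grp in presence.groupby("cluster_id"):
        frames = np.sort(grp["frame"].to_numpy(dtype=np.int64))
        runs = np.split(frames, np.nonzero(np.diff(frames) > 1)[0] + 1)
        if len(runs) > 1:
            warnings.warn(
                f"cluster {cid}: non-contiguous presence split into {len(runs)} records"
            )
        for run in runs:
            first, last = int(run[0]), int(run[-1])
            records.append(
                ClusterRecord(
                    cluster_id=next_id,
                    first_frame=first,
                    last_frame=last,
                    minimal_lifetime=(last - first + 1) * frame_interval,
                    left_censored=first == 0,
                    right_censored=last == n_frames - 1,
                )
            )
            next_id += 1
    return records


def cluster_geometry(
    pixel_count: int, pixel_size_um: float, mean_pixel_value: float, background: float = 0.0
) -> tuple[float, float]:
    """Cluster area (pixel count * pixel area) and background-subtracted
    mean intensity."""
    if pixel_count <= 0:
        raise ValueError("zero-pixel ROI rejected")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    return pixel_count * pixel_size_um**2, mean_pixel_value - background
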