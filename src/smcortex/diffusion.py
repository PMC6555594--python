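"""Per-track diffusion estimation from mean squared displacement curves.

For 2D Brownian motion MSD = 2 d D dt with d = 2, so D is the slope of the
MSD-versus-lag line divided by 4.  Each track's time-averaged MSD is fitted
over the first 25% of its lags by unweighted ordinary least squares; the
intercept is retained as a localization-error proxy (~ 4 sigma^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = [
    "MsdCurve",
    "DiffusionEstimate",
    "MOBILITY_THRESHOLDS",
    "compute_msd",
    "estimate_diffusion",
    "classify_mobility",
    "population_proportions",
    "spatial_mobility_profile",
    "max_travel_distance",
]

MIN_TRACK_LOCS = 6  # tracks need more than five consecutive localizations
MOBILITY_THRESHOLDS = (0.1, 0.01)  # fast >= 0.1; intermediate >= 0.01; slow below


class TrackTooShort(ValueError):
    """Track shorter than the minimum length for MSD analysis."""


@dataclass(frozen=True)
class MsdCurve:
    lags: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # um^2
    counts: np.ndarray  # pairs averaged per lag
    track_id: int
    n: int  # localizations in the source track


@dataclass(frozen=True)
class DiffusionEstimate:
    D: float  # um^2/s (negative slopes allowed and reported)
    intercept: float  # um^2
    fit_lags_used: int
    track_id: int
    n: int
    d: int = 2


def compute_msd(track: Track, tau_tl: float) -> MsdCurve:
    """Time-averaged MSD over all ordered pairs at each lag m * tau_tl."""
    if track.n < MIN_TRACK_LOCS:
        raise TrackTooShort(
            f"track {track.track_id} has {track.n} localizations; "
            f"need >= {MIN_TRACK_LOCS}"
        )
    n = track.n
    xy = np.column_stack([track.x, track.y])
    lags = np.arange(1, n)
    msd = np.empty(n - 1)
    counts = np.empty(n - 1, dtype=np.int64)
    for m in lags:
        disp = xy[m:] - xy[:-m]
        msd[m - 1] = float(np.mean(np.sum(disp**2, axis=1)))
        counts[m - 1] = n - m
    return MsdCurve(
        lags=lags * tau_tl, msd=msd, counts=counts, track_id=track.track_id, n=n
    )


def estimate_diffusion(
    curve: MsdCurve, d: int = 2, fit_fraction: float = 0.25
) -> DiffusionEstimate:
    """Estimate D from an unweighted linear fit of the first lags.

    Uses the first ``ceil(fit_fraction * n_lags)`` lags (minimum 2);
    D = slope / (2 d).
    """
    n_lags = curve.lags.size
    k = max(2, math.ceil(fit_fraction * n_lags))
    if n_lags < 2:
        raise ValueError("need at least 2 MSD lags to fit a slope")
    x = curve.lags[:k]
    y = curve.msd[:k]
    slope, intercept = np.polyfit(x, y, 1)
    return DiffusionEstimate(
        D=float(slope) / (2 * d),
        intercept=float(intercept),
        fit_lags_used=k,
        track_id=curve.track_id,
        n=curve.n,
        d=d,
    )


def classify_mobility(D: float, thresholds: tuple[float, float] = MOBILITY_THRESHOLDS) -> str:
    """Classify a diffusion coefficient as fast / intermediate / slow.

    Boundaries are inclusive on the lower side: D exactly at the fast
    threshold is fast, exactly at the intermediate threshold is
    intermediate; non-positive D is slow.
    """
    hi, lo = thresholds
    if not np.isfinite(D):
        raise ValueError(f"D must be finite, got {D!r}")
    if D >= hi:
        return "fast"
    if D >= lo:
        return "intermediate"
    return "slow"


def population_proportions(
    estimates: list[DiffusionEstimate],
    thresholds: tuple[float, float] = MOBILITY_THRESHOLDS,
) -> pd.DataFrame:
    """Fractions (and counts) of fast / intermediate / slow tracks."""
    if not estimates:
        raise ValueError("no diffusion estimates provided")
    labels = [classify_mobility(e.D, thresholds) for e in estimates]
    counts = {c: labels.count(c) for c in ("fast", "intermediate", "slow")}
    total = len(labels)
    return pd.DataFrame(
        {
            "class": list(counts),
            "count": list(counts.values()),
            "fraction": [v / total for v in counts.values()],
        }
    )


def spatial_mobility_profile(
    distances: np.ndarray,
    estimates: list[DiffusionEstimate],
    bin_width_um: float = 0.5,
    thresholds: tuple[float, float] = MOBILITY_THRESHOLDS,
) -> pd.DataFrame:
    """Per-distance-bin mobility composition along the cell axis.

    ``distances`` holds each track's distance from the pole (same order as
    ``estimates``).  Returns, per bin: class counts, max-normalized total
    count, the fast / (intermediate + slow) ratio (NaN where the denominator
    is zero) and per-class mean D.
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    distances = np.asarray(distances, dtype=float)
    if distances.size != len(estimates):
        raise ValueError("one distance per estimate required")
    df = pd.DataFrame(
        {
            "distance": distances,
            "D": [e.D for e in estimates],
            "class": [classify_mobility(e.D, thresholds) for e in estimates],
        }
    )
    edges = np.arange(0.0, df["distance"].max() + bin_width_um, bin_width_um)
    if edges.size < 2:
        edges = np.array([0.0, bin_width_um])
    df["bin"] = pd.cut(df["distance"], edges, right=False, include_lowest=True)

    rows = []
    for interval, grp in df.groupby("bin", observed=False):
        by_class = grp.groupby("class")["D"]
        cnt = {c: 0 for c in ("fast", "intermediate", "slow")}
        cnt.update(by_class.size().to_dict())
        denom = cnt["intermediate"] + cnt["slow"]
        rows.append(
            {
                "bin_left_um": interval.left,
                "bin_right_um": interval.right,
                "n_total": len(grp),
                "n_fast": cnt["fast"],
                "n_intermediate": cnt["intermediate"],
                "n_slow": cnt["slow"],
                "fast_over_rest": cnt["fast"] / denom if denom > 0 else np.nan,
                "mean_D_fast": by_class.mean().get("fast", np.nan),
                "mean_D_intermediate": by_class.mean().get("intermediate", np.nan),
                "mean_D_slow": by_class.mean().get("slow", np.nan),
            }
        )
    out = pd.DataFrame(rows)
    max_n = out["n_total"].max()
    out["n_total_normalized"] = out["n_total"] / max_n if max_n > 0 else np.nan
    return out


def max_travel_distance(D: float, t: float) -> float:
    """Maximum travel distance x = sqrt(2 D t), um."""
    if D < 0 or t < 0:
        raise ValueError("D and t must be non-negative")
    return math.sqrt(2.0 * D * t)
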