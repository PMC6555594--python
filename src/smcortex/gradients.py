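"""Cortical concentration-gradient shape and buffering statistics.

Profiles (intensity vs arclength from the cell pole) are aligned to their
maximum, optionally Gaussian-smoothed, and characterised by: window means at
the pole (first 0.83 um) and at mid-cell (last 1.5 um), an exponential
decay length from log-linear regression, an amplitude-sorted binned
amplitude/decay-length correlation (gradient buffering), and per-position
coefficients of variation across cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "ProfileSet",
    "DecayFit",
    "BufferingSummary",
    "CvProfile",
    "profiles_from_frame",
    "align_profiles",
    "smooth_profile",
    "midcell_intensity",
    "pole_intensity",
    "decay_length",
    "buffering_correlation",
    "cv_profile",
]

MIDCELL_WINDOW_UM = 1.5
POLE_WINDOW_UM = 0.83
DROP_HEAD_UM = 0.5
_EPS = 1e-12


@dataclass(frozen=True)
class ProfileSet:
    """Profiles on a common uniform grid: x (n_points,), intensity
    (n_cells, n_points)."""

    x: np.ndarray
    intensity: np.ndarray
    cell_ids: np.ndarray

    @property
    def step(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass(frozen=True)
class DecayFit:
    decay_length_um: float  # lambda = -1 / slope; inf when non-decaying
    amplitude: float  # intensity at the pole of the aligned profile
    fit_x_min: float
    fit_x_max: float
    slope: float
    slope_se: float
    r_squared: float
    non_decaying: bool


@dataclass(frozen=True)
class BufferingSummary:
    bins: pd.DataFrame  # per-bin amplitude, decay length, slope SE weight
    correlation: float  # Pearson r of log(lambda) vs log(A)
    ci_low: float
    ci_high: float
    n_bins: int


@dataclass(frozen=True)
class CvProfile:
    x: np.ndarray
    cv: np.ndarray  # NaN where the cross-cell mean is zero
    tip_cv: float
    middle_cv: float
    fold_decrease: float  # tip_cv / middle_cv


def profiles_from_frame(df: pd.DataFrame) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Split a long-format profile table into (cell_id, x, intensity) tuples."""
    required = {"cell_id", "x_um", "intensity_au"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile table must have columns {sorted(required)}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("x_um")
        out.append((cid, grp["x_um"].to_numpy(), grp["intensity_au"].to_numpy()))
    return out


def align_profiles(profiles: list[tuple[int, np.ndarray, np.ndarray]]) -> ProfileSet:
    """Align each profile so x = 0 sits at its maximum-intensity sample.

    Samples before the maximum are discarded; the common grid is obtained by
    truncating to the shortest aligned profile.  A profile whose maximum
    falls on its last sample has no tail and is flagged with a warning.
    """
    if not profiles:
        raise ValueError("no profiles to align")
    aligned = []
    for cid, x, inten in profiles:
        imax = int(np.argmax(inten))
        if imax == len(inten) - 1:
            warnings.warn(f"profile {cid}: maximum at last sample, no gradient tail")
        aligned.append((cid, inten[imax:]))
    n_common = min(len(v) for _, v in aligned)
    step = float(profiles[0][1][1] - profiles[0][1][0])
    x = np.arange(n_common) * step
    intensity = np.vstack([v[:n_common] for _, v in aligned])
    return ProfileSet(
        x=x, intensity=intensity, cell_ids=np.array([cid for cid, _ in aligned])
    )


def smooth_profile(intensity: np.ndarray, sigma_um: float, step: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundary; sigma 0 is the identity."""
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    if sigma_um == 0:
        return np.asarray(intensity, dtype=float).copy()
    return gaussian_filter1d(
        np.asarray(intensity, dtype=float), sigma_um / step, axis=-1, mode="reflect"
    )


def _window_mean(x: np.ndarray, intensity: np.ndarray, lo: float, hi: float) -> float:
    mask = (x >= lo - _EPS) & (x <= hi + _EPS)
    return float(np.mean(intensity[..., mask], axis=-1))


def midcell_intensity(
    x: np.ndarray, intensity: np.ndarray, window: float = MIDCELL_WINDOW_UM
) -> float:
    """Mean intensity over the final ``window`` um of the profile."""
    length = float(x[-1] - x[0])
    if window >= length:
        raise ValueError(f"window {window} um >= profile length {length} um")
    return _window_mean(x, intensity, x[-1] - window, x[-1])


def pole_intensity(
    x: np.ndarray, intensity: np.ndarray, window: float = POLE_WINDOW_UM
) -> float:
    """Mean intensity over the initial ``window`` um of the profile."""
    length = float(x[-1] - x[0])
    if window > length:
        raise ValueError(f"window {window} um > profile length {length} um")
    return _window_mean(x, intensity, x[0], x[0] + window)


def decay_length(
    x: np.ndarray, intensity: np.ndarray, drop_head: float = DROP_HEAD_UM
) -> DecayFit:
    """Exponential decay length from log-linear regression.

    The first ``drop_head`` um are discarded to avoid the plateau at the
    pole, then log(intensity) is regressed on x by ordinary least squares;
    lambda = -1 / slope.  All intensities in the fit range must be positive
    (background-correct first).  A non-negative slope yields an infinite
    decay length, flagged via ``non_decaying``.
    """
    x = np.asarray(x, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    mask = x >= drop_head - _EPS
    if mask.sum() < 3:
        raise ValueError("profile too short after dropping the head")
    xf, yf = x[mask], intensity[mask]
    if np.any(yf <= 0):
        raise ValueError(
            "non-positive intensities in the fit range; background-correct the "
            "profiles before fitting"
        )
    logy = np.log(yf)
    n = xf.size
    slope, inter = np.polyfit(xf, logy, 1)
    pred = slope * xf + inter
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    sxx = float(np.sum((xf - xf.mean()) ** 2))
    slope_se = math.sqrt(ss_res / max(n - 2, 1) / sxx) if sxx > 0 else math.inf
    non_decaying = slope >= 0
    lam = math.inf if non_decaying else -1.0 / slope
    return DecayFit(
        decay_length_um=lam,
        amplitude=float(intensity[0]),
        fit_x_min=float(xf[0]),
        fit_x_max=float(xf[-1]),
        slope=float(slope),
        slope_se=slope_se,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        non_decaying=non_decaying,
    )


def buffering_correlation(
    profiles: ProfileSet,
    bin_fraction: float = 0.05,
    drop_head: float = DROP_HEAD_UM,
    pole_window: float = POLE_WINDOW_UM,
    n_boot: int = 1000,
    seed: int = 0,
) -> BufferingSummary:
    """Amplitude-sorted binned decay-length vs amplitude correlation.

    Profiles are sorted by pole amplitude and grouped into consecutive bins
    each holding ``bin_fraction`` of the profiles; each bin's average profile
    is fitted for its decay length.  Reports the Pearson correlation of
    log(lambda) against log(amplitude) across bins, with a bootstrap CI.
    A negative correlation is the signature of gradient buffering.
    """
    n_cells = profiles.intensity.shape[0]
    if n_cells < 20:
        raise ValueError(f"need >= 20 profiles, got {n_cells}")
    per_bin = int(round(bin_fraction * n_cells))
    if per_bin < 3:
        raise ValueError(
            f"bins of {per_bin} profiles are too small; need >= 3 per bin"
        )
    amps = np.array(
        [pole_intensity(profiles.x, row, pole_window) for row in profiles.intensity]
    )
    if np.std(amps) <= 1e-12 * np.mean(np.abs(amps)):
        raise ValueError("zero amplitude variance across profiles")
    order = np.argsort(amps)
    n_bins = n_cells // per_bin

    rows = []
    for b in range(n_bins):
        idx = order[b * per_bin : (b + 1) * per_bin]
        avg = profiles.intensity[idx].mean(axis=0)
        fit = decay_length(profiles.x, avg, drop_head=drop_head)
        rows.append(
            {
                "bin": b,
                "amplitude": fit.amplitude,
                "decay_length_um": fit.decay_length_um,
                "slope_se": fit.slope_se,
                "non_decaying": fit.non_decaying,
            }
        )
    bins = pd.DataFrame(rows)
    usable = bins[np.isfinite(bins["decay_length_um"])]
    if len(usable) < 3:
        raise ValueError("too few decaying bins to correlate")
    la = np.log(usable["amplitude"].to_numpy())
    ll = np.log(usable["decay_length_um"].to_numpy())
    r = float(np.corrcoef(la, ll)[0, 1])

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, la.size, la.size)
        if np.std(la[idx]) == 0 or np.std(ll[idx]) == 0:
            continue
        boots.append(np.corrcoef(la[idx], ll[idx])[0, 1])
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return BufferingSummary(
        bins=bins, correlation=r, ci_low=float(lo), ci_high=float(hi), n_bins=len(usable)
    )


def cv_profile(
    profiles: ProfileSet,
    pole_window: float = POLE_WINDOW_UM,
    midcell_window: float = MIDCELL_WINDOW_UM,
) -> CvProfile:
    """Coefficient of variation across cells at each position.

    The fold decrease is the mean CV over the pole window divided by the
    mean CV over the mid-cell window; buffered gradients show a fold
    decrease > 1.
    """
    if profiles.intensity.shape[0] < 3:
        raise ValueError("need >= 3 profiles for a CV profile")
    mean = profiles.intensity.mean(axis=0)
    sd = profiles.intensity.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    x = profiles.x
    tip_mask = x <= x[0] + pole_window + _EPS
    mid_mask = x >= x[-1] - midcell_window - _EPS
    tip_cv = float(np.nanmean(cv[tip_mask]))
    middle_cv = float(np.nanmean(cv[mid_mask]))
    return CvProfile(
        x=x,
        cv=cv,
        tip_cv=tip_cv,
        middle_cv=middle_cv,
        fold_decrease=tip_cv / middle_cv if middle_cv > 0 else math.inf,
    )
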