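"""Ground-truthed synthetic data generation.

Produces localization tables, cortical gradient profiles and node intensity
time series with the statistical structure assumed by the downstream
analysis stages.  Every generator returns the ground truth alongside the
observable data so that estimators can be tested against exact oracles.

The binding-event model couples two independent hazards:

* dissociation, a continuous-time exponential hazard with rate ``k_off``;
* photobleaching, a hazard with rate ``k_bleach`` that is active only while
  the camera shutter is open (i.e. during the integration time ``tau_int``
  of each frame, not during the inter-frame delay).

Under this model the per-frame survival probability factorises as
``exp(-k_off * tau_tl) * exp(-k_bleach * tau_int)``, which is exactly the
structure exploited by the rate-separation fit in
:mod:`smcortex.kinetics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticPopulation",
    "ImagingScheme",
    "CellGeometryModel",
    "GroundTruthEvent",
    "GradientModel",
    "NodeOccupancyModel",
    "validate_populations",
    "simulate_binding_events",
    "observed_frame_counts",
    "simulate_localizations",
    "simulate_gradient_profiles",
    "simulate_node_series",
    "events_to_frame",
]

_FRACTION_TOL = 1e-9


def _check_rate(value: float, name: str) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


@dataclass(frozen=True)
class KineticPopulation:
    """One kinetic sub-population of membrane-binding molecules."""

    label: str
    k_off: float  # dissociation rate, 1/s
    diffusion_coeff: float  # um^2/s
    fraction: float  # mixture weight

    def __post_init__(self) -> None:
        _check_rate(self.k_off, "k_off")
        _check_rate(self.diffusion_coeff, "diffusion_coeff")
        if not np.isfinite(self.fraction) or not (0 <= self.fraction <= 1):
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction!r}")


def validate_populations(populations: Sequence[KineticPopulation]) -> None:
    """Raise unless the population fractions sum to 1 (within 1e-9)."""
    if not populations:
        raise ValueError("at least one population is required")
    total = sum(p.fraction for p in populations)
    if abs(total - 1.0) > _FRACTION_TOL:
        raise ValueError(f"population fractions must sum to 1, got {total!r}")


@dataclass(frozen=True)
class ImagingScheme:
    """Time-lapse imaging scheme.

    The time-lapse period ``tau_tl`` is the sum of the camera integration
    time and the inter-frame dark delay; it is derived, never stored, so the
    invariant cannot be violated.
    """

    tau_int: float  # camera integration time, s
    delay: float = 0.0  # inter-frame dark time, s
    k_bleach: float = 0.0  # photobleaching rate while exposed, 1/s
    loc_error_sd: float = 0.025  # lateral localization error SD, um
    detection_prob: float = 1.0  # per-frame detection probability

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau_int) or self.tau_int <= 0:
            raise ValueError(f"tau_int must be positive, got {self.tau_int!r}")
        if not np.isfinite(self.delay) or self.delay < 0:
            raise ValueError(f"delay must be non-negative, got {self.delay!r}")
        _check_rate(self.k_bleach, "k_bleach")
        _check_rate(self.loc_error_sd, "loc_error_sd")
        if not (0 <= self.detection_prob <= 1):
            raise ValueError(
                f"detection_prob must lie in [0, 1], got {self.detection_prob!r}"
            )

    @property
    def tau_tl(self) -> float:
        """Time-lapse period (integration + delay), s."""
        return self.tau_int + self.delay


@dataclass(frozen=True)
class CellGeometryModel:
    """Idealised straight cell along the x axis, poles at 0 and ``length``."""

    length: float = 10.0  # um
    pole_position: float = 0.0  # arclength origin, um
    binding_profile: str = "uniform"  # "uniform" | "exponential"
    binding_decay_um: float | None = None  # decay of exponential binding density

    def __post_init__(self) -> None:
        if not np.isfinite(self.length) or self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length!r}")
        if self.binding_profile not in ("uniform", "exponential"):
            raise ValueError(f"unknown binding_profile {self.binding_profile!r}")
        if self.binding_profile == "exponential":
            if self.binding_decay_um is None or self.binding_decay_um <= 0:
                raise ValueError("exponential binding_profile needs binding_decay_um > 0")


@dataclass(frozen=True)
class GroundTruthEvent:
    """Simulator bookkeeping for one membrane-binding event."""

    event_id: int
    birth_time: float  # s, wall clock
    true_lifetime: float  # s, dissociation-limited (inf when k_off == 0)
    bleach_time: float  # s after birth, wall clock (inf when never bleached)
    bleach_exposure: float  # s of accumulated illumination before bleaching
    population_label: str
    birth_position: tuple[float, float]  # (x, y) um


def simulate_binding_events(
    populations: Sequence[KineticPopulation],
    scheme: ImagingScheme,
    geometry: CellGeometryModel,
    n_events: int,
    seed: int,
    horizon_s: float = 60.0,
) -> list[GroundTruthEvent]:
    """Draw membrane-binding events with ground-truth lifetimes.

    Each event's population is drawn by mixture fraction, its dissociation
    lifetime is ``Exponential(k_off)`` and its bleach time is determined by a
    hazard active only during integration windows (per-frame bleach survival
    ``exp(-k_bleach * tau_int)``).  Identical seed implies identical output.
    """
    if n_events < 1:
        raise ValueError(f"n_events must be >= 1, got {n_events!r}")
    validate_populations(populations)
    rng = np.random.default_rng(seed)

    fractions = np.array([p.fraction for p in populations])
    pop_idx = rng.choice(len(populations), size=n_events, p=fractions / fractions.sum())

    k_off = np.array([p.k_off for p in populations])[pop_idx]
    with np.errstate(divide="ignore"):
        lifetimes = np.where(
            k_off > 0, rng.exponential(1.0, size=n_events) / np.where(k_off > 0, k_off, 1.0), np.inf
        )

    # exposure budget until bleaching, in seconds of accumulated illumination
    if scheme.k_bleach > 0:
        exposure = rng.exponential(1.0 / scheme.k_bleach, size=n_events)
    else:
        exposure = np.full(n_events, np.inf)
    # convert the exposure budget to wall-clock time after birth: illumination
    # accrues only during the tau_int window of each tau_tl cycle
    finite = np.isfinite(exposure)
    exp_f = np.where(finite, exposure, 0.0)
    n_full = np.floor(exp_f / scheme.tau_int)
    bleach_wall = np.where(
        finite, n_full * scheme.tau_tl + (exp_f - n_full * scheme.tau_int), np.inf
    )

    birth = rng.uniform(0.0, horizon_s, size=n_events)
    x = _sample_arclength(rng, geometry, n_events)
    y = np.zeros(n_events)

    labels = [populations[i].label for i in pop_idx]
    return [
        GroundTruthEvent(
            event_id=i,
            birth_time=float(birth[i]),
            true_lifetime=float(lifetimes[i]),
            bleach_time=float(bleach_wall[i]),
            bleach_exposure=float(exposure[i]),
            population_label=labels[i],
            birth_position=(float(x[i]), float(y[i])),
        )
        for i in range(n_events)
    ]


def _sample_arclength(
    rng: np.random.Generator, geometry: CellGeometryModel, n: int
) -> np.ndarray:
    if geometry.binding_profile == "uniform":
        return rng.uniform(0.0, geometry.length, size=n)
    # truncated exponential from the pole
    lam = geometry.binding_decay_um
    u = rng.uniform(0.0, 1.0, size=n)
    cap = 1.0 - math.exp(-geometry.length / lam)
    return -lam * np.log1p(-u * cap)


def observed_frame_counts(
    events: Sequence[GroundTruthEvent], scheme: ImagingScheme, max_frames: int = 100_000
) -> np.ndarray:
    """Number of frames in which each event is observed.

    A molecule appearing at frame 0 is observed in frame ``k`` iff it has
    neither dissociated by wall time ``k * tau_tl`` nor exhausted its bleach
    exposure budget by ``k * tau_int`` of accumulated illumination.  The
    resulting count is ``min(ceil(T_d / tau_tl), ceil(B / tau_int))``,
    clipped to ``max_frames``.
    """
    lifetimes = np.array([e.true_lifetime for e in events])
    exposure = np.array([e.bleach_exposure for e in events])
    with np.errstate(over="ignore"):
        n_d = np.where(np.isfinite(lifetimes), np.ceil(lifetimes / scheme.tau_tl), np.inf)
        n_b = np.where(np.isfinite(exposure), np.ceil(exposure / scheme.tau_int), np.inf)
    n = np.minimum(np.minimum(n_d, n_b), max_frames)
    return np.maximum(n, 1).astype(np.int64)


def simulate_localizations(
    events: Sequence[GroundTruthEvent],
    populations: Sequence[KineticPopulation],
    scheme: ImagingScheme,
    geometry: CellGeometryModel,
    seed: int,
    max_frames: int = 100_000,
    axial_sd: float = 0.0,
) -> pd.DataFrame:
    """Render events into a localization table.

    Positions evolve by 2D Brownian steps with per-axis variance
    ``2 * D * tau_tl`` per frame, observed with additive Gaussian
    localization error of SD ``scheme.loc_error_sd``.  Molecules that have
    dissociated or bleached emit no further rows.  The returned table keeps
    the ground-truth ``event_id`` column for oracle tests.

    Columns: frame, x_um, y_um, z_um, intensity, event_id.
    """
    if scheme.tau_tl <= 0:
        raise ValueError("scheme with tau_tl <= 0 rejected")
    validate_populations(populations)
    rng = np.random.default_rng(seed)
    d_by_label = {p.label: p.diffusion_coeff for p in populations}

    counts = observed_frame_counts(events, scheme, max_frames=max_frames)
    chunks: list[pd.DataFrame] = []
    for event, n_obs in zip(events, counts):
        diff = d_by_label[event.population_label]
        birth_frame = int(math.ceil(event.birth_time / scheme.tau_tl))
        step_sd = math.sqrt(2.0 * diff * scheme.tau_tl)
        steps = rng.normal(0.0, step_sd, size=(n_obs, 2)) if step_sd > 0 else np.zeros((n_obs, 2))
        steps[0] = 0.0
        pos = np.cumsum(steps, axis=0) + np.asarray(event.birth_position)
        err = (
            rng.normal(0.0, scheme.loc_error_sd, size=(n_obs, 2))
            if scheme.loc_error_sd > 0
            else np.zeros((n_obs, 2))
        )
        z = rng.normal(0.0, axial_sd, size=n_obs) if axial_sd > 0 else np.zeros(n_obs)
        keep = (
            rng.uniform(size=n_obs) < scheme.detection_prob
            if scheme.detection_prob < 1.0
            else np.ones(n_obs, dtype=bool)
        )
        if not keep.any():
            continue
        obs = pos + err
        chunks.append(
            pd.DataFrame(
                {
                    "frame": birth_frame + np.arange(n_obs)[keep],
                    "x_um": obs[keep, 0],
                    "y_um": obs[keep, 1],
                    "z_um": z[keep],
                    "intensity": np.full(int(keep.sum()), 1000.0),
                    "event_id": event.event_id,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["frame", "x_um", "y_um", "z_um", "intensity", "event_id"]
        )
    table = pd.concat(chunks, ignore_index=True)
    return table.sort_values(["frame", "event_id"], kind="stable").reset_index(drop=True)


def events_to_frame(events: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    """Sidecar ground-truth table keyed by event_id."""
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "birth_time_s": [e.birth_time for e in events],
            "true_lifetime_s": [e.true_lifetime for e in events],
            "bleach_time_s": [e.bleach_time for e in events],
            "population_label": [e.population_label for e in events],
            "birth_x_um": [e.birth_position[0] for e in events],
            "birth_y_um": [e.birth_position[1] for e in events],
        }
    )


@dataclass(frozen=True)
class GradientModel:
    """Exponentially decaying cortical gradient with optional buffering.

    Per-cell amplitudes are log-normal; when ``buffering_exponent`` (beta)
    is positive, brighter cells decay more steeply:
    ``lambda_i = decay_length_base * (A_i / amplitude_median) ** (-beta)``.
    """

    amplitude_median: float = 100.0  # a.u.
    amplitude_gsd: float = 1.0  # geometric SD (1 = no variability)
    decay_length_base: float = 1.5  # lambda_0, um
    buffering_exponent: float = 0.0  # beta >= 0
    background: float = 0.0  # a.u.
    noise_frac_sd: float = 0.0  # multiplicative fractional SD
    noise_add_sd: float = 0.0  # additive SD, a.u.

    def __post_init__(self) -> None:
        if self.decay_length_base <= 0:
            raise ValueError("decay_length_base must be positive")
        if self.buffering_exponent < 0:
            raise ValueError(
                f"buffering_exponent must be >= 0, got {self.buffering_exponent!r}"
            )
        if self.amplitude_gsd < 1:
            raise ValueError("amplitude_gsd must be >= 1")


def simulate_gradient_profiles(
    model: GradientModel,
    n_cells: int,
    profile_length: float,
    step: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate cortical intensity profiles plus their ground truth.

    Returns ``(profiles, truth)`` where profiles has columns
    (cell_id, x_um, intensity_au) and truth has (cell_id, amplitude,
    decay_length_um).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, profile_length + step / 2, step)

    sigma = math.log(model.amplitude_gsd)
    amps = model.amplitude_median * np.exp(rng.normal(0.0, sigma, size=n_cells))
    lams = model.decay_length_base * (amps / model.amplitude_median) ** (
        -model.buffering_exponent
    )

    rows = []
    for cid in range(n_cells):
        signal = amps[cid] * np.exp(-x / lams[cid]) + model.background
        if model.noise_frac_sd > 0:
            signal = signal * (1.0 + rng.normal(0.0, model.noise_frac_sd, size=x.size))
        if model.noise_add_sd > 0:
            signal = signal + rng.normal(0.0, model.noise_add_sd, size=x.size)
        rows.append(
            pd.DataFrame({"cell_id": cid, "x_um": x, "intensity_au": signal})
        )
    profiles = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {"cell_id": np.arange(n_cells), "amplitude": amps, "decay_length_um": lams}
    )
    return profiles, truth


@dataclass(frozen=True)
class NodeOccupancyModel:
    """Two-state telegraph occupancy of a cortical node ROI."""

    on_rate: float = 0.1  # 1/s, off -> on
    off_rate: float = 0.1  # 1/s, on -> off
    on_intensity: float = 50.0  # a.u.
    baseline: float = 5.0  # a.u.
    noise_sd: float = 2.0  # a.u.
    bleach_rate: float = 0.0  # 1/s
    cell_length_effect: Callable[[float], float] | None = None  # length -> on_rate multiplier

    def __post_init__(self) -> None:
        _check_rate(self.on_rate, "on_rate")
        _check_rate(self.off_rate, "off_rate")
        _check_rate(self.bleach_rate, "bleach_rate")
        if self.on_intensity <= self.baseline:
            raise ValueError("on_intensity must exceed baseline")


def _telegraph(
    rng: np.random.Generator, on_rate: float, off_rate: float, t_samples: np.ndarray
) -> np.ndarray:
    """Exact CTMC simulation sampled at t_samples; True = occupied."""
    horizon = t_samples[-1]
    if on_rate == 0 and off_rate == 0:
        return np.zeros(t_samples.size, dtype=bool)
    p_on = on_rate / (on_rate + off_rate)
    state = bool(rng.uniform() < p_on)
    switch_times = []
    states = [state]
    t = 0.0
    s = state
    while True:
        rate = off_rate if s else on_rate
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate)
        if t > horizon:
            break
        switch_times.append(t)
        s = not s
        states.append(s)
    idx = np.searchsorted(np.array(switch_times), t_samples, side="right")
    return np.array(states, dtype=bool)[idx]


def simulate_node_series(
    model: NodeOccupancyModel,
    n_nodes: int,
    duration: float,
    frame_interval: float,
    seed: int,
    cell_lengths: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate telegraph-occupancy node intensity time series.

    Returns ``(series, truth)``.  series columns: node_id, t_s,
    intensity_au, cell_length_um; truth columns: node_id, t_s, occupied.
    Sampling runs from 0 to ``duration`` inclusive, so a 60 s duration at
    1 s intervals yields 61 samples.
    """
    if not (duration >= frame_interval > 0):
        raise ValueError("require duration >= frame_interval > 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration / frame_interval)) + 1
    t = np.arange(n_samples) * frame_interval

    if cell_lengths is None:
        cell_lengths = rng.uniform(6.0, 14.0, size=n_nodes)
    cell_lengths = np.asarray(cell_lengths, dtype=float)
    if cell_lengths.size != n_nodes:
        raise ValueError("cell_lengths must have one entry per node")

    series_rows, truth_rows = [], []
    decay = np.exp(-model.bleach_rate * t)
    for nid in range(n_nodes):
        mult = (
            model.cell_length_effect(float(cell_lengths[nid]))
            if model.cell_length_effect is not None
            else 1.0
        )
        occ = _telegraph(rng, model.on_rate * mult, model.off_rate, t)
        clean = np.where(occ, model.on_intensity, model.baseline) * decay
        noisy = clean + (
            rng.normal(0.0, model.noise_sd, size=t.size) if model.noise_sd > 0 else 0.0
        )
        series_rows.append(
            pd.DataFrame(
                {
                    "node_id": nid,
                    "t_s": t,
                    "intensity_au": noisy,
                    "cell_length_um": cell_lengths[nid],
                }
            )
        )
        truth_rows.append(pd.DataFrame({"node_id": nid, "t_s": t, "occupied": occ}))
    return (
        pd.concat(series_rows, ignore_index=True),
        pd.concat(truth_rows, ignore_index=True),
    )
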