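"""Adhesion metrics computed from trajectories and event logs.

All percentage metrics are fractions of the full integrin population, on a
0-100 scale.  Window arguments are (t_start, t_end) in seconds; a sample at
time t belongs to the window when t_start < t <= t_end.  The default window
runs from the burn-in marker to the end of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Trajectory
from .mechanics import minimum_image
from .state import EventLog

__all__ = ["ligated_fraction", "event_rates", "total_ligated_time",
           "adhesion_angle", "angle_series", "density_profile",
           "rupture_tension_distribution", "MetricsSummary", "summarize"]


def _window(traj: Trajectory, window) -> np.ndarray:
    if window is None:
        window = (traj.params.t_burnin, traj.params.t_total)
    t0, t1 = window
    mask = (traj.times > t0) & (traj.times <= t1)
    if not mask.any():
        raise ValueError(f"empty analysis window {window}")
    return mask


def ligated_fraction(traj: Trajectory, window=None):
    """(times, per-sample ligated %, window mean %)."""
    m = _window(traj, window)
    pct = traj.ligated_pct
    return traj.times[m], pct[m], float(pct[m].mean())


def event_rates(events: EventLog, window, n_integrins: int):
    """(bind rate 1/s, unbinding % of integrins per second) over a window."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    span = t1 - t0
    nb = int(np.count_nonzero((events.bind_time > t0) & (events.bind_time <= t1)))
    nr = int(np.count_nonzero((events.rupture_time > t0) & (events.rupture_time <= t1)))
    return nb / span, 100.0 * nr / span / n_integrins


def total_ligated_time(traj: Trajectory) -> np.ndarray:
    """Per-integrin total time spent ligated over the run, seconds.

    Bonds still closed at the end of the run contribute their elapsed time.
    """
    return traj.total_ligated_time


def _unwrap_about_circular_mean(coords: np.ndarray, side: float) -> np.ndarray:
    """Unwrap periodic 1D coordinates to within +-side/2 of their circular mean."""
    theta = coords * (2 * np.pi / side)
    mean = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()) * side / (2 * np.pi)
    return mean + minimum_image(coords - mean, side)


def adhesion_angle(points: np.ndarray, side: float | None = None) -> float:
    """Acute angle (degrees, in [0, 90]) between the leading principal axis
    of a 2D point cloud and the fiber (x) axis.

    Points on the periodic domain are unwrapped about their per-axis circular
    mean before the covariance is formed, so an adhesion straddling the seam
    is treated as one cluster.  Returns NaN for degenerate inputs: fewer than
    two points, coincident points, or an isotropic covariance (the principal
    direction is then undefined).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return float("nan")
    if side is not None:
        pts = np.column_stack([_unwrap_about_circular_mean(pts[:, 0], side),
                               _unwrap_about_circular_mean(pts[:, 1], side)])
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    scale = max(evals[1], 0.0)
    if scale <= 0.0 or (evals[1] - evals[0]) <= 1e-12 * scale:
        return float("nan")
    v = evecs[:, 1]  # leading principal axis
    return float(np.degrees(np.arctan2(abs(v[1]), abs(v[0]))))


def angle_series(traj: Trajectory, window=None):
    """(times, per-sample adhesion angle deg, mean over defined samples).

    Samples with an undefined angle (fewer than two ligated integrins or
    degenerate scatter) are NaN and excluded from the mean.
    """
    m = _window(traj, window)
    side = traj.params.domain_side
    out = np.full(int(m.sum()), np.nan)
    for k, idx in enumerate(np.flatnonzero(m)):
        pts = traj.positions[idx][traj.bound_mask[idx]]
        out[k] = adhesion_angle(pts, side=side)
    mean = float(np.nanmean(out)) if np.isfinite(out).any() else float("nan")
    return traj.times[m], out, mean


def density_profile(traj: Trajectory, n_bins: int = 20, window=None) -> np.ndarray:
    """Mean % of all integrins that are ligated, per transverse (y) bin.

    Bins partition [-side/2, +side/2); the profile sums to the mean ligated
    percentage over the window.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    m = _window(traj, window)
    half = traj.params.domain_side / 2.0
    edges = np.linspace(-half, half, n_bins + 1)
    acc = np.zeros(n_bins)
    idxs = np.flatnonzero(m)
    for idx in idxs:
        y = traj.positions[idx][traj.bound_mask[idx], 1]
        h, _ = np.histogram(y, bins=edges)
        acc += h
    return 100.0 * acc / (len(idxs) * traj.params.n_integrins)


def rupture_tension_distribution(events: EventLog, window=None):
    """(tension samples pN, mean, std) of the tension recorded at rupture.

    Open bonds never contribute (the metric is tension *before failure*);
    an empty event set yields an empty distribution with NaN summaries.
    """
    t = events.rupture_time
    m = np.ones(t.size, dtype=bool) if window is None else \
        (t > window[0]) & (t <= window[1])
    samples = events.rupture_tension[m]
    if samples.size == 0:
        return samples, float("nan"), float("nan")
    return samples, float(samples.mean()), float(samples.std())


@dataclass
class MetricsSummary:
    """Scalar metrics of one run over one analysis window."""

    mean_ligated_pct: float
    bind_rate: float            # events/s, domain-wide
    unbind_pct_per_s: float     # % of integrins rupturing per second
    mean_total_ligated_time: float  # s, per integrin
    mean_rupture_tension: float     # pN
    std_rupture_tension: float      # pN
    mean_angle: float           # degrees
    window: tuple


def summarize(traj: Trajectory, window=None) -> MetricsSummary:
    if window is None:
        window = (traj.params.t_burnin, traj.params.t_total)
    _, _, pct = ligated_fraction(traj, window)
    bind_rate, unbind = event_rates(traj.events, window, traj.params.n_integrins)
    _, _, angle = angle_series(traj, window)
    _, t_mean, t_std = rupture_tension_distribution(traj.events, window)
    return MetricsSummary(
        mean_ligated_pct=pct,
        bind_rate=bind_rate,
        unbind_pct_per_s=unbind,
        mean_total_ligated_time=float(traj.total_ligated_time.mean()),
        mean_rupture_tension=t_mean,
        std_rupture_tension=t_std,
        mean_angle=angle,
        window=tuple(window),
    )
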