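"""Period, peak-time, phase and amplitude extraction; circular phase algebra.

Phase is the time of peak expression relative to lights-on (0 h), multiplied
by 2*pi and divided by the period, expressed in radians.  Peaks are located
by local-maximum bracketing with quadratic refinement; data phases default to
the peak of the replicate-mean profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from circaclock.dde import Trajectory
from circaclock.models import GENE_INDEX

__all__ = [
    "PhaseEstimate",
    "NoOscillationError",
    "UndefinedPhaseError",
    "find_peaks",
    "estimate_period",
    "estimate_phase_trajectory",
    "estimate_phase_profile",
    "phase_difference",
]

MIN_AMPLITUDE = 1e-6  # flat-profile guard for phase extraction


class NoOscillationError(RuntimeError):
    """Fewer than two peaks found — no period can be estimated."""


class UndefinedPhaseError(RuntimeError):
    """Profile amplitude below threshold — phase is undefined."""


@dataclass(frozen=True)
class PhaseEstimate:
    gene: str
    period: float          # hours
    peak_time: float       # hours after lights-on, modulo period
    phase: float           # radians in [0, 2*pi)
    amplitude: float       # peak - trough over one cycle

    def __post_init__(self):
        if not self.period > 0:
            raise ValueError("period must be positive")


def _grid_series(traj_or_grid, gene, dt=0.01):
    """Uniform (t, y) samples for one gene from a Trajectory or (t, Y) pair."""
    if isinstance(traj_or_grid, Trajectory):
        ts = np.arange(traj_or_grid.t0, traj_or_grid.t_end, dt)
        idx = GENE_INDEX[gene] if isinstance(gene, str) else int(gene)
        return ts, traj_or_grid.evaluate(ts)[:, idx]
    ts, Y = traj_or_grid
    idx = GENE_INDEX[gene] if isinstance(gene, str) else int(gene)
    y = Y[:, idx] if Y.ndim == 2 else Y
    return np.asarray(ts, dtype=float), np.asarray(y, dtype=float)


def _quadratic_refine(t, y, i):
    """Parabolic vertex through points i-1, i, i+1 (returns t*, y*)."""
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2.0 * y1 + y2)
    if denom == 0:
        return t1, y1
    # uniform-spacing vertex formula
    h = 0.5 * (t2 - t0)
    shift = 0.5 * (y0 - y2) / denom
    shift = np.clip(shift, -1.0, 1.0)
    tstar = t1 + shift * h
    ystar = y1 - 0.25 * (y0 - y2) * shift
    return tstar, ystar


def find_peaks(t, y, min_prominence_frac: float = 0.2):
    """Refined times/heights of prominent local maxima of a sampled series.

    Prominence threshold is a fraction of the global peak-to-trough range, so
    solver ripple and shoulder bumps are not counted as peaks.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    from scipy.signal import find_peaks as _sp_find_peaks

    rng = y.max() - y.min()
    if rng <= 0:
        return np.array([]), np.array([])
    idx, _ = _sp_find_peaks(y, prominence=min_prominence_frac * rng)
    times = np.empty(idx.size)
    heights = np.empty(idx.size)
    for k, i in enumerate(idx):
        times[k], heights[k] = _quadratic_refine(t, y, i)
    return times, heights


def estimate_period(traj_or_grid, gene, dt: float = 0.01,
                    min_prominence_frac: float = 0.2) -> float:
    """Mean successive peak-to-peak interval of one gene's trajectory."""
    t, y = _grid_series(traj_or_grid, gene, dt)
    times, _ = find_peaks(t, y, min_prominence_frac)
    if times.size < 2:
        raise NoOscillationError(
            f"found {times.size} peak(s) for {gene}; need >= 2 to estimate a period"
        )
    return float(np.diff(times).mean())


def estimate_phase_trajectory(traj_or_grid, gene, period: float | None = None,
                              dt: float = 0.01) -> PhaseEstimate:
    """Phase of a simulated gene: first refined peak after the window start.

    The trajectory's own time axis is interpreted as hours after lights-on
    (alignment of a free-running simulation to clock time is handled by the
    estimation layer's offset parameter).
    """
    t, y = _grid_series(traj_or_grid, gene, dt)
    if period is None:
        period = estimate_period((t, np.asarray(y)[:, None]), 0)
    times, heights = find_peaks(t, y)
    if times.size == 0:
        raise NoOscillationError(f"no peaks found for {gene}")
    # amplitude over the cycle that follows the first peak
    mask = (t >= times[0]) & (t <= times[0] + period)
    amplitude = float(y[mask].max() - y[mask].min())
    if amplitude < MIN_AMPLITUDE:
        raise UndefinedPhaseError(f"amplitude {amplitude:.2e} below threshold for {gene}")
    peak_time = float(times[0] % period)
    phase = 2.0 * np.pi * peak_time / period
    name = gene if isinstance(gene, str) else str(gene)
    return PhaseEstimate(gene=name, period=float(period), peak_time=peak_time,
                         phase=float(phase % (2.0 * np.pi)), amplitude=amplitude)


def estimate_phase_profile(times, values, gene: str, period: float,
                           amplitude_eps: float = MIN_AMPLITUDE) -> PhaseEstimate:
    """Phase of a measured profile (replicate mean) on one cycle.

    ``values`` may be 1-D (already averaged) or 2-D ``(n_times, n_reps)``;
    replicate means are used, with quadratic interpolation across the three
    time points around the maximum.
    """
    times = np.asarray(times, dtype=float)
    vals = np.asarray(values, dtype=float)
    prof = vals.mean(axis=1) if vals.ndim == 2 else vals
    if times.size != prof.size:
        raise ValueError("times and values have mismatched lengths")
    amplitude = float(prof.max() - prof.min())
    if amplitude < amplitude_eps:
        raise UndefinedPhaseError(f"amplitude {amplitude:.2e} below threshold for {gene}")
    i = int(np.argmax(prof))
    if 0 < i < times.size - 1:
        peak_time, _ = _quadratic_refine(times, prof, i)
    else:
        peak_time = float(times[i])
    peak_time = float(peak_time % period)
    phase = (2.0 * np.pi * peak_time / period) % (2.0 * np.pi)
    return PhaseEstimate(gene=gene, period=float(period), peak_time=peak_time,
                         phase=float(phase), amplitude=amplitude)


def phase_difference(phi_a: float, phi_b: float) -> float:
    """Circular difference ``phi_a - phi_b`` mapped to ``(-pi, pi]``.

    Positive sign means ``a`` leads ``b``; exact antiphase maps to ``+pi``
    (documented tie-break).
    """
    d = (float(phi_a) - float(phi_b)) % (2.0 * np.pi)
    if d > np.pi:
        d -= 2.0 * np.pi
    return float(d)
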