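"""Integrator for systems of delay differential equations with constant delays.

The method of steps is realized by capping the step size of an embedded
explicit Runge-Kutta pair at the smallest positive delay, so that every
delayed lookup falls on an already-committed dense-output segment (or on the
constant pre-initial history).  Dense output is piecewise polynomial and is
continuous across segment boundaries.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import RK45

__all__ = [
    "HistoryFunction",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the solver cannot advance (e.g. non-finite derivatives)."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


@dataclass(frozen=True)
class HistoryFunction:
    """Constant pre-initial history: ``y(t) = values`` for all ``t <= t0``."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("history must be a 1-D vector of state values")
        if not np.all(np.isfinite(vals)):
            raise ValueError("history values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def dim(self) -> int:
        return self.values.size

    def __call__(self, t) -> np.ndarray:
        return self.values


@dataclass
class Trajectory:
    """Dense-output solution of a (delay) differential equation system.

    Evaluable on ``[t0 - max(delays), t_end]``; for ``t <= t0`` the constant
    history is returned.  Evaluation inside ``(t0, t_end)`` interpolates the
    committed dense segments and never extrapolates.
    """

    t0: float
    t_end: float
    history: HistoryFunction
    delays_used: list[float] = field(default_factory=list)
    _seg_starts: list[float] = field(default_factory=list)
    _segments: list = field(default_factory=list)
    _t_start: float | None = None   # integration start (t0 may be relabeled, e.g. to a burn-in)

    @property
    def dim(self) -> int:
        return self.history.dim

    @property
    def t_start(self) -> float:
        """Original integration start (history applies for all earlier times)."""
        return self.t0 if self._t_start is None else self._t_start

    @property
    def t_min(self) -> float:
        """Earliest evaluable time (history reaches back by the largest delay)."""
        max_delay = max(self.delays_used, default=0.0)
        return self.t_start - max_delay

    def _append(self, segment) -> None:
        self._seg_starts.append(segment.t_old)
        self._segments.append(segment)
        self.t_end = segment.t

    def evaluate(self, t):
        """Evaluate the solution at scalar or array ``t``.

        Raises :class:`ValueError` for times outside the evaluable range.
        """
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        flat = np.atleast_1d(t_arr)
        eps = 1e-9 * max(1.0, abs(self.t_end))
        if flat.size and (flat.min() < self.t_min - eps or flat.max() > self.t_end + eps):
            raise ValueError(
                f"evaluation time outside [{self.t_min}, {self.t_end}]: "
                f"requested [{flat.min()}, {flat.max()}]"
            )
        out = np.empty((flat.size, self.dim))
        for i, ti in enumerate(flat):
            out[i] = self._eval_scalar(float(ti))
        if scalar:
            return out[0]
        return out.reshape(t_arr.shape + (self.dim,))

    # bisect over committed segment start times; cheap relative to rhs work
    def _eval_scalar(self, t: float) -> np.ndarray:
        if not self._segments or t <= self._seg_starts[0]:
            if not self._segments and t > self.t_start:
                raise ValueError("empty trajectory")
            return self.history(t)
        idx = bisect.bisect_right(self._seg_starts, t) - 1
        idx = min(max(idx, 0), len(self._segments) - 1)
        return self._segments[idx](min(t, self.t_end))

    __call__ = evaluate

    def to_frame(self, times: np.ndarray, names: Sequence[str] | None = None):
        """Tidy export (columns: time_h, variable, value)."""
        import pandas as pd

        times = np.asarray(times, dtype=float)
        vals = self.evaluate(times)
        names = list(names) if names is not None else [f"y{i}" for i in range(self.dim)]
        rows = []
        for j, name in enumerate(names):
            rows.append(pd.DataFrame({"time_h": times, "variable": name, "value": vals[:, j]}))
        return pd.concat(rows, ignore_index=True)


def _discontinuity_points(delays, t0, t_end, levels, cap=2000):
    """Times t0 + k1*d1 + k2*d2 + ... where derivative kinks propagate.

    Only the first few levels matter (each propagation raises the smoothness
    order); points are deduplicated and truncated to the span.
    """
    pos = sorted({d for d in delays if d > 0})
    if not pos or levels <= 0:
        return []
    current = {0.0}
    found: set[float] = set()
    for _ in range(levels):
        nxt = set()
        for base in current:
            for d in pos:
                s = base + d
                if s < t_end - t0:
                    nxt.add(round(s, 9))
        nxt -= found
        found |= nxt
        current = nxt
        if not current or len(found) > cap:
            break
    return sorted(t0 + s for s in found)


def integrate(
    rhs: Callable,
    delays: Sequence[float],
    history: HistoryFunction | Sequence[float],
    t_span: tuple[float, float],
    rel_tol: float = DEFAULT_RTOL,
    abs_tol: float = DEFAULT_ATOL,
    max_step: float | None = None,
    discontinuity_levels: int = 5,
) -> Trajectory:
    """Integrate ``y'(t) = rhs(t, y(t), [y(t - d) for d in delays])``.

    Parameters
    ----------
    rhs
        Callable ``(t, y, delayed) -> dy/dt`` where ``delayed`` is a list of
        state vectors, one per entry of ``delays`` (evaluations of the
        solution, or of the history for ``t - d <= t0``).
    delays
        Non-negative constant delays (hours).  A zero delay receives the
        current state.
    history
        Constant pre-initial state, applied for all ``t <= t0``.
    t_span
        ``(t0, t_end)`` with ``t_end > t0``.
    """
    delays = [float(d) for d in delays]
    if any(d < 0 for d in delays):
        raise ValueError(f"delays must be non-negative, got {delays}")
    t0, t_end = map(float, t_span)
    if not t_end > t0:
        raise ValueError(f"t_span must be increasing, got {t_span}")
    if not isinstance(history, HistoryFunction):
        history = HistoryFunction(np.asarray(history, dtype=float))

    traj = Trajectory(t0=t0, t_end=t0, history=history, delays_used=list(delays),
                      _t_start=t0)

    positive = [d for d in delays if d > 0]
    cap = min(positive) if positive else np.inf
    if max_step is not None:
        cap = min(cap, max_step)

    def wrapped(t, y):
        delayed = []
        for d in delays:
            if d == 0.0:
                delayed.append(y)
            else:
                delayed.append(traj._eval_scalar(t - d))
        dy = np.asarray(rhs(t, y, delayed), dtype=float)
        if not np.all(np.isfinite(dy)):
            raise IntegrationError(f"non-finite derivative at t={t:.6g}", t=t)
        return dy

    # steps restart at propagated derivative discontinuities so the error
    # estimator never integrates across a kink
    bounds = _discontinuity_points(delays, t0, t_end, discontinuity_levels)
    y = history.values
    t_from = t0
    for t_to in bounds + [t_end]:
        if t_to - t_from < 1e-12:
            continue
        solver = RK45(
            wrapped, t_from, y, t_to,
            max_step=cap, rtol=rel_tol, atol=abs_tol,
        )
        while solver.status == "running":
            msg = solver.step()
            if solver.status == "failed":
                raise IntegrationError(
                    f"integration failed at t={solver.t:.6g}: {msg}", t=solver.t
                )
            traj._append(solver.dense_output())
        y = solver.y
        t_from = t_to
    return traj
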