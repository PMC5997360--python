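"""Fast fixed-step integrator for the core-clock system (estimation hot path).

Parameter fitting needs thousands of simulations, so the five-gene system
gets a specialized fixed-step RK4 integrator compiled with numba.  Delayed
lookups use cubic Hermite interpolation on the committed solution grid
(state and derivative arrays), which keeps the interpolation error at the
same order as the step error.  Correctness is cross-checked against the
general adaptive engine in the test suite; this module is an internal
optimization, not part of the public modeling surface.

Parameter vector layout (34 entries)::

    0-4   tau_Bmal1, tau_RevErba, tau_Per2, tau_Cry1, tau_Dbp
    5-9   d_Bmal1, d_RevErba, d_Per2, d_Cry1, d_Dbp
    10-33 ar1 ar4 cr2 cr3 cr4 cr5 gr2 gr3 gr4 gr5
          b2 ba2 b3 ba3 b4 ba4 b5 ba5 f2 fa2 f3 fa3 f4 fa4
"""

from __future__ import annotations

import numpy as np
from numba import njit

from circaclock.models import CoreClockParameters

__all__ = ["pack_params", "unpack_params", "simulate_grid", "DEFAULT_DT"]

DEFAULT_DT = 0.01  # hours

_CONST_NAMES = (
    "ar1", "ar4", "cr2", "cr3", "cr4", "cr5", "gr2", "gr3", "gr4", "gr5",
    "b2", "ba2", "b3", "ba3", "b4", "ba4", "b5", "ba5",
    "f2", "fa2", "f3", "fa3", "f4", "fa4",
)


def pack_params(params: CoreClockParameters) -> np.ndarray:
    vec = np.empty(34)
    vec[0:5] = params.delays
    vec[5:10] = params.degradations
    for i, name in enumerate(_CONST_NAMES):
        vec[10 + i] = getattr(params, name)
    return vec


def unpack_params(vec: np.ndarray) -> CoreClockParameters:
    taus = ("tau_Bmal1", "tau_RevErba", "tau_Per2", "tau_Cry1", "tau_Dbp")
    ds = ("d_Bmal1", "d_RevErba", "d_Per2", "d_Cry1", "d_Dbp")
    kw = {n: float(vec[i]) for i, n in enumerate(taus)}
    kw.update({n: float(vec[5 + i]) for i, n in enumerate(ds)})
    kw.update({n: float(vec[10 + i]) for i, n in enumerate(_CONST_NAMES)})
    return CoreClockParameters(**kw)


@njit(cache=True, fastmath=False)
def _hermite_lookup(Y, F, dt, s, gene):
    """Cubic Hermite evaluation of gene column at time s<=committed (s>=0)."""
    if s <= 0.0:
        return Y[0, gene]
    x = s / dt
    i = int(x)
    u = x - i
    y0 = Y[i, gene]
    y1 = Y[i + 1, gene]
    f0 = F[i, gene]
    f1 = F[i + 1, gene]
    h00 = (1.0 + 2.0 * u) * (1.0 - u) * (1.0 - u)
    h10 = u * (1.0 - u) * (1.0 - u)
    h01 = u * u * (3.0 - 2.0 * u)
    h11 = u * u * (u - 1.0)
    return h00 * y0 + h10 * dt * f0 + h01 * y1 + h11 * dt * f1


@njit(cache=True, fastmath=False)
def _rhs(t, y, p, Y, F, dt, out):
    B = _hermite_lookup(Y, F, dt, t - p[0], 0)
    R = _hermite_lookup(Y, F, dt, t - p[1], 1)
    P = _hermite_lookup(Y, F, dt, t - p[2], 2)
    C = _hermite_lookup(Y, F, dt, t - p[3], 3)
    D = _hermite_lookup(Y, F, dt, t - p[4], 4)
    ar1, ar4 = p[10], p[11]
    cr2, cr3, cr4, cr5 = p[12], p[13], p[14], p[15]
    gr2, gr3, gr4, gr5 = p[16], p[17], p[18], p[19]
    b2, ba2, b3, ba3, b4, ba4, b5, ba5 = p[20], p[21], p[22], p[23], p[24], p[25], p[26], p[27]
    f2, fa2, f3, fa3, f4, fa4 = p[28], p[29], p[30], p[31], p[32], p[33]

    rB2 = B / ba2
    rB3 = B / ba3
    rB4 = B / ba4
    rB5 = B / ba5
    rD2 = D / fa2
    rD3 = D / fa3
    rD4 = D / fa4

    out[0] = (1.0 / (1.0 + R / ar1)) ** 2 - p[5] * y[0]
    out[1] = (
        ((1.0 + b2 * rB2) / (1.0 + rB2)) ** 3
        * (1.0 / (1.0 + P / cr2)) ** 3
        * (1.0 / (1.0 + C / gr2)) ** 3
        * ((1.0 + f2 * rD2) / (1.0 + rD2))
        - p[6] * y[1]
    )
    out[2] = (
        ((1.0 + b3 * rB3) / (1.0 + rB3)) ** 2
        * (1.0 / (1.0 + P / cr3)) ** 2
        * (1.0 / (1.0 + C / gr3)) ** 2
        * ((1.0 + f3 * rD3) / (1.0 + rD3))
        - p[7] * y[2]
    )
    out[3] = (
        ((1.0 + b4 * rB4) / (1.0 + rB4)) ** 2
        * (1.0 / (1.0 + P / cr4)) ** 2
        * (1.0 / (1.0 + C / gr4)) ** 2
        * (1.0 / (1.0 + R / ar4)) ** 2
        * ((1.0 + f4 * rD4) / (1.0 + rD4))
        - p[8] * y[3]
    )
    out[4] = (
        ((1.0 + b5 * rB5) / (1.0 + rB5)) ** 3
        * (1.0 / (1.0 + P / cr5)) ** 3
        * (1.0 / (1.0 + C / gr5)) ** 3
        - p[9] * y[4]
    )


@njit(cache=True, fastmath=False)
def _integrate(p, y0, n_steps, dt):
    Y = np.empty((n_steps + 1, 5))
    F = np.empty((n_steps + 1, 5))
    Y[0] = y0
    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    ytmp = np.empty(5)
    _rhs(0.0, Y[0], p, Y, F, dt, k1)
    F[0] = k1
    for n in range(n_steps):
        t = n * dt
        y = Y[n]
        # k1 already stored in F[n]
        for j in range(5):
            k1[j] = F[n, j]
            ytmp[j] = y[j] + 0.5 * dt * k1[j]
        _rhs(t + 0.5 * dt, ytmp, p, Y, F, dt, k2)
        for j in range(5):
            ytmp[j] = y[j] + 0.5 * dt * k2[j]
        _rhs(t + 0.5 * dt, ytmp, p, Y, F, dt, k3)
        for j in range(5):
            ytmp[j] = y[j] + dt * k3[j]
        _rhs(t + dt, ytmp, p, Y, F, dt, k4)
        for j in range(5):
            Y[n + 1, j] = y[j] + dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        _rhs(t + dt, Y[n + 1], p, Y, F, dt, k1)
        F[n + 1] = k1
    return Y, F


def simulate_grid(
    params: CoreClockParameters | np.ndarray,
    t_end: float,
    dt: float = DEFAULT_DT,
    y0: np.ndarray | None = None,
):
    """Integrate the core clock on a uniform grid from constant history.

    Returns ``(t, Y)`` with ``Y`` of shape ``(n, 5)``.  The step must stay
    well below the smallest delay so that delayed RK stages only reach
    committed grid nodes.
    """
    vec = params if isinstance(params, np.ndarray) else pack_params(params)
    min_tau = float(np.min(vec[0:5]))
    if dt >= min_tau:
        raise ValueError(f"dt={dt} must be smaller than the smallest delay {min_tau}")
    if y0 is None:
        y0 = np.ones(5)
    n_steps = int(round(t_end / dt))
    Y, _ = _integrate(vec, np.asarray(y0, dtype=float), n_steps, dt)
    if not np.all(np.isfinite(Y)):
        raise FloatingPointError("fast core-clock integration produced non-finite values")
    t = np.arange(n_steps + 1) * dt
    return t, Y
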