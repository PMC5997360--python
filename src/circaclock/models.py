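"""Core-clock gene network and clock-controlled gene (CCG) dynamics.

The core network couples five genes — Bmal1, Rev-Erba, Per2, Cry1, Dbp —
through delayed transcriptional activation/inhibition terms of the form

    activation: ((1 + b * X/K) / (1 + X/K)) ** p
    inhibition: (1 / (1 + X/K)) ** p

where ``X`` is the regulator's expression evaluated at ``t - tau_X`` and the
integer powers ``p`` are the element counts of each promoter (fixed, never
fitted).  A CCG is a scalar equation forced one-way by delayed evaluations of
a committed core trajectory, with powers ``n1`` (Ebox: BMAL1 activation and
PER2/CRY1 inhibition), ``n2`` (RRE) and ``n3`` (Dbox).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from circaclock.dde import HistoryFunction, IntegrationError, Trajectory, integrate

__all__ = [
    "GENES",
    "GENE_INDEX",
    "CoreClockParameters",
    "CCGParameters",
    "TissueModel",
    "load_tissue_parameters",
    "available_tissues",
    "core_clock_rhs",
    "simulate_core_clock",
    "ccg_rhs",
    "simulate_ccg",
    "cycle_mean",
    "DEFAULT_BURN_IN",
    "DEFAULT_WINDOW",
]

GENES = ("Bmal1", "RevErba", "Per2", "Cry1", "Dbp")
GENE_INDEX = {g: i for i, g in enumerate(GENES)}

DEFAULT_BURN_IN = 240.0  # hours; transients from unit history decay well before this
DEFAULT_WINDOW = 120.0  # hours of post-burn-in trajectory kept for analysis

_POSITIVE_FIELDS = None  # cache


@dataclass(frozen=True)
class CoreClockParameters:
    """All rate constants of the five-gene core-clock system.

    Delays ``tau_*`` are in hours, degradation rates ``d_*`` in 1/hour;
    dissociation constants and fold changes are in the (arbitrary) units of
    the normalized expression data.  The integer promoter-element exponents
    are structural and hard-coded in :func:`core_clock_rhs`.
    """

    tau_Bmal1: float
    tau_RevErba: float
    tau_Per2: float
    tau_Cry1: float
    tau_Dbp: float
    d_Bmal1: float
    d_RevErba: float
    d_Per2: float
    d_Cry1: float
    d_Dbp: float
    ar1: float
    ar4: float
    cr2: float
    cr3: float
    cr4: float
    cr5: float
    gr2: float
    gr3: float
    gr4: float
    gr5: float
    b2: float
    ba2: float
    b3: float
    ba3: float
    b4: float
    ba4: float
    b5: float
    ba5: float
    f2: float
    fa2: float
    f3: float
    fa3: float
    f4: float
    fa4: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v <= 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v}")

    @property
    def delays(self) -> tuple[float, float, float, float, float]:
        """Delays in gene order (Bmal1, RevErba, Per2, Cry1, Dbp)."""
        return (self.tau_Bmal1, self.tau_RevErba, self.tau_Per2, self.tau_Cry1, self.tau_Dbp)

    @property
    def degradations(self) -> tuple[float, float, float, float, float]:
        return (self.d_Bmal1, self.d_RevErba, self.d_Per2, self.d_Cry1, self.d_Dbp)

    def replace(self, **changes) -> "CoreClockParameters":
        d = self.to_dict()
        d.update(changes)
        return CoreClockParameters(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CCGParameters:
    """Parameters of a single clock-controlled gene.

    ``n1``, ``n2``, ``n3`` are the promoter element counts for Ebox, RRE and
    Dbox; a zero count makes the corresponding regulatory term identically 1.
    """

    b: float
    ba: float
    cr: float
    gr: float
    ar: float
    f: float
    fa: float
    d: float
    n1: int
    n2: int
    n3: int

    def __post_init__(self):
        for name in ("b", "ba", "cr", "gr", "ar", "f", "fa", "d"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"CCG parameter {name} must be finite and > 0, got {v}")
        for name in ("n1", "n2", "n3"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"element count {name} must be a non-negative integer, got {v!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **changes) -> "CCGParameters":
        d = self.to_dict()
        d.update(changes)
        return CCGParameters(**d)


@dataclass(frozen=True)
class TissueModel:
    """A labeled core-clock parameterization (five states, fixed gene order)."""

    tissue: str
    params: CoreClockParameters

    @property
    def gene_index(self) -> Mapping[str, int]:
        return GENE_INDEX


def available_tissues() -> list[str]:
    root = resources.files("circaclock").joinpath("data/params")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_tissue_parameters(tissue: str) -> TissueModel:
    """Load one of the bundled parameter columns (liver, muscle, adipose,
    lung, all_tissues) or a YAML file path with the same flat key layout."""
    import os

    if os.path.exists(tissue):
        with open(tissue) as fh:
            raw = yaml.safe_load(fh)
        label = raw.pop("tissue", os.path.splitext(os.path.basename(tissue))[0])
    else:
        ref = resources.files("circaclock").joinpath(f"data/params/{tissue}.yaml")
        if not ref.is_file():
            raise FileNotFoundError(
                f"unknown tissue {tissue!r}; bundled: {available_tissues()}"
            )
        raw = yaml.safe_load(ref.read_text())
        label = raw.pop("tissue", tissue)
    return TissueModel(tissue=label, params=CoreClockParameters(**raw))


def _act(x, b, k, p):
    """Activation term ((1 + b x/k)/(1 + x/k))**p."""
    r = x / k
    return ((1.0 + b * r) / (1.0 + r)) ** p


def _inh(x, k, p):
    """Inhibition term (1/(1 + x/k))**p."""
    return (1.0 + x / k) ** (-p)


def core_clock_rhs(params: CoreClockParameters):
    """Build the five-gene rhs for :func:`circaclock.dde.integrate`.

    The returned callable has signature ``(t, state, delayed)`` where
    ``delayed[k]`` is the full state vector at ``t - delays[k]`` with delays
    ordered as :attr:`CoreClockParameters.delays`.
    """
    p = params

    def rhs(t, y, delayed):
        B = delayed[0][0]   # Bmal1(t - tau_Bmal1)
        R = delayed[1][1]   # RevErba(t - tau_RevErba)
        P = delayed[2][2]   # Per2(t - tau_Per2)
        C = delayed[3][3]   # Cry1(t - tau_Cry1)
        D = delayed[4][4]   # Dbp(t - tau_Dbp)
        dBmal1 = _inh(R, p.ar1, 2) - p.d_Bmal1 * y[0]
        dRev = (
            _act(B, p.b2, p.ba2, 3) * _inh(P, p.cr2, 3) * _inh(C, p.gr2, 3)
            * _act(D, p.f2, p.fa2, 1)
            - p.d_RevErba * y[1]
        )
        dPer2 = (
            _act(B, p.b3, p.ba3, 2) * _inh(P, p.cr3, 2) * _inh(C, p.gr3, 2)
            * _act(D, p.f3, p.fa3, 1)
            - p.d_Per2 * y[2]
        )
        dCry1 = (
            _act(B, p.b4, p.ba4, 2) * _inh(P, p.cr4, 2) * _inh(C, p.gr4, 2)
            * _inh(R, p.ar4, 2) * _act(D, p.f4, p.fa4, 1)
            - p.d_Cry1 * y[3]
        )
        dDbp = (
            _act(B, p.b5, p.ba5, 3) * _inh(P, p.cr5, 3) * _inh(C, p.gr5, 3)
            - p.d_Dbp * y[4]
        )
        return np.array([dBmal1, dRev, dPer2, dCry1, dDbp])

    return rhs


DEFAULT_HISTORY = np.ones(5)


def simulate_core_clock(
    model: TissueModel,
    duration: float = DEFAULT_BURN_IN + DEFAULT_WINDOW,
    burn_in: float = DEFAULT_BURN_IN,
    history: HistoryFunction | np.ndarray | None = None,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-9,
) -> Trajectory:
    """Simulate the core clock and return the post-burn-in trajectory.

    The full span ``[0, duration]`` is integrated; the returned
    :class:`Trajectory` is restricted (by convention of its ``t0``) to
    ``[burn_in, duration]`` but still holds the earlier segments needed for
    delayed lookups.
    """
    if not duration > burn_in >= 0:
        raise ValueError("need duration > burn_in >= 0")
    if history is None:
        history = HistoryFunction(DEFAULT_HISTORY.copy())
    elif not isinstance(history, HistoryFunction):
        history = HistoryFunction(np.asarray(history, dtype=float))
    rhs = core_clock_rhs(model.params)
    try:
        traj = integrate(
            rhs, list(model.params.delays), history, (0.0, duration),
            rel_tol=rel_tol, abs_tol=abs_tol,
        )
    except IntegrationError as exc:
        raise IntegrationError(
            f"core-clock integration failed for tissue {model.tissue!r}: {exc}", exc.t
        ) from exc
    traj.t0 = burn_in  # pre-burn-in segments are retained for delayed lookups
    return traj


def ccg_production(ccg: CCGParameters, core_params: CoreClockParameters,
                   core: Trajectory, t):
    """Production rate of a CCG at time(s) ``t`` (delayed core forcing only)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    B = core.evaluate(t_arr - core_params.tau_Bmal1)[:, 0]
    R = core.evaluate(t_arr - core_params.tau_RevErba)[:, 1]
    P = core.evaluate(t_arr - core_params.tau_Per2)[:, 2]
    C = core.evaluate(t_arr - core_params.tau_Cry1)[:, 3]
    D = core.evaluate(t_arr - core_params.tau_Dbp)[:, 4]
    prod = (
        _act(B, ccg.b, ccg.ba, ccg.n1)
        * _inh(P, ccg.cr, ccg.n1)
        * _inh(C, ccg.gr, ccg.n1)
        * _inh(R, ccg.ar, ccg.n2)
        * _act(D, ccg.f, ccg.fa, ccg.n3)
    )
    prod = np.broadcast_to(np.asarray(prod, dtype=float), t_arr.shape)
    return prod[0] if np.ndim(t) == 0 else prod.copy()


def ccg_rhs(ccg: CCGParameters, core: Trajectory,
            core_params: CoreClockParameters):
    """One-way-coupled scalar rhs for a clock-controlled gene.

    ``core`` must span the integration range shifted back by every delay of
    ``core_params``; a too-short core raises a range error naming the
    required extension.
    """

    max_tau = max(core_params.delays)

    def rhs(t, y, delayed):
        if t - max_tau < core.t_min:
            raise ValueError(
                f"core trajectory too short: need evaluation at t={t - max_tau:.3f} "
                f"but core starts at {core.t_min:.3f}; extend core by "
                f"{core.t_min - (t - max_tau):.3f} h"
            )
        prod = ccg_production(ccg, core_params, core, float(t))
        return np.array([prod - ccg.d * y[0]])

    return rhs


def simulate_ccg(
    ccg: CCGParameters,
    core: Trajectory,
    core_params: CoreClockParameters,
    duration: float,
    burn_in: float = 0.0,
    y0: float = 1.0,
    t_start: float | None = None,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-9,
) -> Trajectory:
    """Integrate a CCG forced by a committed core trajectory.

    ``t_start`` defaults to the core's analysis window start (``core.t0``),
    clipped so that all delayed lookups stay inside the evaluable core range.
    """
    if not duration > burn_in >= 0:
        raise ValueError("need duration > burn_in >= 0")
    max_tau = max(core_params.delays)
    if t_start is None:
        t_start = max(core.t0, core.t_min + max_tau)
    t_end = t_start + duration
    if t_end > core.t_end:
        raise ValueError(
            f"core trajectory ends at {core.t_end:.3f} but CCG integration "
            f"needs {t_end:.3f}; extend core by {t_end - core.t_end:.3f} h"
        )
    rhs = ccg_rhs(ccg, core, core_params)
    traj = integrate(rhs, [], HistoryFunction(np.array([float(y0)])),
                     (t_start, t_end), rel_tol=rel_tol, abs_tol=abs_tol,
                     max_step=1.0)
    traj.t0 = t_start + burn_in
    return traj


def cycle_mean(traj: Trajectory, period: float, t_start: float | None = None,
               dt: float = 0.05) -> np.ndarray:
    """Per-variable mean over one cycle, used to scale profiles around 1.

    Scaling for comparison with normalized data happens outside the dynamics.
    """
    if t_start is None:
        t_start = traj.t0
    ts = np.arange(t_start, t_start + period, dt)
    return traj.evaluate(ts).mean(axis=0)
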