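"""Local sensitivity of core-clock gene phases to delays and degradations.

Each parameter is perturbed by a fraction of its nominal value (default
+10%, one at a time), the system is re-simulated, and the phase change of
every gene — unwrapped circularly to (-pi, pi] — is divided by the parameter
change:

    s_ij = delta(phi_i) / delta(p_j)

The normalized form |(delta phi_i / phi_i) / (delta p_j / p_j)| is reported
alongside; phases are taken at each simulation's own period (phase in
radians is period-scaled by definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circaclock.models import (
    GENES,
    CoreClockParameters,
    TissueModel,
    simulate_core_clock,
)
from circaclock.phases import (
    NoOscillationError,
    estimate_period,
    estimate_phase_trajectory,
    phase_difference,
)

__all__ = ["SensitivityMatrix", "phase_sensitivities", "SENSITIVITY_PARAMETERS"]

SENSITIVITY_PARAMETERS = (
    "tau_Bmal1", "tau_RevErba", "tau_Per2", "tau_Cry1", "tau_Dbp",
    "d_Bmal1", "d_RevErba", "d_Per2", "d_Cry1", "d_Dbp",
)


@dataclass
class SensitivityMatrix:
    """Raw and normalized phase-sensitivity coefficients (genes x params)."""

    genes: tuple[str, ...]
    parameters: tuple[str, ...]
    raw: np.ndarray           # d(phase)/d(param), radians per parameter unit
    normalized: np.ndarray    # |(dphi/phi)/(dp/p)|, dimensionless
    perturbation: float
    flags: np.ndarray = field(default=None)  # True where entry non-computable

    def __post_init__(self):
        if self.flags is None:
            self.flags = np.zeros(self.raw.shape, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.genes):
            for j, p in enumerate(self.parameters):
                rows.append({"output_gene": g, "parameter": p,
                             "raw": self.raw[i, j],
                             "normalized": self.normalized[i, j],
                             "flag": "non-computable" if self.flags[i, j] else ""})
        return pd.DataFrame(rows)

    def rank_parameters(self, subset: tuple[str, ...] | None = None) -> list[str]:
        """Parameters ordered by mean |normalized| across genes (descending)."""
        params = subset or self.parameters
        idx = [self.parameters.index(p) for p in params]
        with np.errstate(invalid="ignore"):
            score = np.nanmean(np.abs(self.normalized[:, idx]), axis=0)
        order = np.argsort(-score, kind="stable")
        return [params[i] for i in order]


def _phases(params: CoreClockParameters, burn_in: float, window: float,
            rel_tol: float, abs_tol: float) -> tuple[np.ndarray, np.ndarray]:
    traj = simulate_core_clock(
        TissueModel("sensitivity", params),
        duration=burn_in + window, burn_in=burn_in,
        rel_tol=rel_tol, abs_tol=abs_tol,
    )
    phases = np.empty(len(GENES))
    periods = np.empty(len(GENES))
    for i, g in enumerate(GENES):
        period = estimate_period(traj, g)
        est = estimate_phase_trajectory(traj, g, period=period)
        phases[i] = est.phase
        periods[i] = period
    return phases, periods


def phase_sensitivities(
    params: CoreClockParameters,
    rel_perturbation: float = 0.10,
    parameters: tuple[str, ...] = SENSITIVITY_PARAMETERS,
    central: bool = False,
    burn_in: float = 240.0,
    window: float = 96.0,
    extra_params: dict | None = None,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-9,
) -> SensitivityMatrix:
    """Finite-difference phase sensitivities for all five genes.

    ``extra_params`` may supply named values that enter no equation (their
    columns come out exactly zero — a self-test hook).  A perturbed system
    that loses oscillation flags its column entries as non-computable rather
    than zeroing them.  ``central=True`` uses a two-sided difference.
    """
    extra_params = extra_params or {}
    all_names = tuple(parameters) + tuple(extra_params)
    base_phi, _ = _phases(params, burn_in, window, rel_tol, abs_tol)

    raw = np.full((len(GENES), len(all_names)), np.nan)
    norm = np.full_like(raw, np.nan)
    flags = np.zeros(raw.shape, dtype=bool)

    def perturbed(name: str, factor: float) -> CoreClockParameters:
        if name in extra_params:
            return params  # enters no equation
        return params.replace(**{name: getattr(params, name) * factor})

    for j, name in enumerate(all_names):
        p0 = extra_params.get(name, getattr(params, name, None))
        dp = p0 * rel_perturbation
        try:
            hi_phi, _ = _phases(perturbed(name, 1.0 + rel_perturbation),
                                burn_in, window, rel_tol, abs_tol)
            if central:
                lo_phi, _ = _phases(perturbed(name, 1.0 - rel_perturbation),
                                    burn_in, window, rel_tol, abs_tol)
            else:
                lo_phi = base_phi
        except NoOscillationError:
            flags[:, j] = True
            continue
        denom = 2.0 * dp if central else dp
        for i in range(len(GENES)):
            dphi = phase_difference(hi_phi[i], lo_phi[i])
            raw[i, j] = dphi / denom if denom != 0 else 0.0
            phi = base_phi[i]
            norm[i, j] = abs(raw[i, j] * p0 / phi) if phi != 0 else np.nan
    return SensitivityMatrix(genes=GENES, parameters=all_names, raw=raw,
                             normalized=norm, perturbation=rel_perturbation,
                             flags=flags)
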