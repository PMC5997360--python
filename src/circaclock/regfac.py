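"""Regulation-factor time series, coefficients of variation and inter-tissue
ΔCV% statistics for clock-controlled genes.

Each regulation factor is one multiplicative term of the CCG production rate,
evaluated with the same delayed arguments and exponents:

    BMAL1:   ((1 + b*B/ba)/(1 + B/ba))**n1        in [1, b**n1)
    PER2:    (1/(1 + P/cr))**n1                   in (0, 1]
    CRY1:    (1/(1 + C/gr))**n1                   in (0, 1]
    REVERBA: (1/(1 + R/ar))**n2                   in (0, 1]
    DBP:     ((1 + f*D/fa)/(1 + D/fa))**n3        in [1, f**n3)

CV = population standard deviation / mean over one cycle on a uniform grid
(default 0.05 h).  ΔCV% between two tissues is (max-min)/max*100, with the
0/0 case defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circaclock.dde import Trajectory
from circaclock.models import CCGParameters, CoreClockParameters, _act, _inh
from circaclock.phases import phase_difference

__all__ = [
    "FACTORS",
    "RegulationFactorSeries",
    "DeltaCVRecord",
    "compute_regulation_factors",
    "delta_cv_percent",
    "phase_vs_regfac_table",
]

FACTORS = ("BMAL1", "PER2", "CRY1", "REVERBA", "DBP")
DEFAULT_GRID_DT = 0.05  # hours


@dataclass
class RegulationFactorSeries:
    """Five factor time series over one cycle plus their CVs."""

    tissue: str
    gene: str
    times: np.ndarray
    series: dict = field(default_factory=dict)   # factor name -> array
    cv: dict = field(default_factory=dict)       # factor name -> float

    def normalized(self, factor: str) -> np.ndarray:
        """Series divided by its own cycle mean (plotting/export only)."""
        s = self.series[factor]
        return s / s.mean()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fac in FACTORS:
            rows.append(pd.DataFrame({
                "tissue": self.tissue, "gene": self.gene, "factor": fac,
                "time_h": self.times, "value": self.series[fac],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class DeltaCVRecord:
    gene: str
    tissue_a: str
    tissue_b: str
    delta_cv: dict            # factor name -> percent in [0, 100]
    phase_difference: float   # radians, a relative to b
    phase_defined: bool = True


def compute_regulation_factors(
    core: Trajectory,
    ccg: CCGParameters,
    core_params: CoreClockParameters,
    period: float,
    tissue: str = "",
    gene: str = "",
    t_start: float | None = None,
    dt: float = DEFAULT_GRID_DT,
) -> RegulationFactorSeries:
    """Evaluate the five regulation factors of one CCG over one cycle.

    ``core`` must span ``[t_start - max delay, t_start + period]``.
    """
    if t_start is None:
        t_start = core.t_min + max(core_params.delays)
    ts = np.arange(t_start, t_start + period, dt)
    if ts[-1] > core.t_end or ts[0] - max(core_params.delays) < core.t_min:
        raise ValueError("core trajectory does not span one period plus max delay")
    vals = {
        "B": core.evaluate(ts - core_params.tau_Bmal1)[:, 0],
        "R": core.evaluate(ts - core_params.tau_RevErba)[:, 1],
        "P": core.evaluate(ts - core_params.tau_Per2)[:, 2],
        "C": core.evaluate(ts - core_params.tau_Cry1)[:, 3],
        "D": core.evaluate(ts - core_params.tau_Dbp)[:, 4],
    }
    series = {
        "BMAL1": _act(vals["B"], ccg.b, ccg.ba, ccg.n1),
        "PER2": _inh(vals["P"], ccg.cr, ccg.n1),
        "CRY1": _inh(vals["C"], ccg.gr, ccg.n1),
        "REVERBA": _inh(vals["R"], ccg.ar, ccg.n2),
        "DBP": _act(vals["D"], ccg.f, ccg.fa, ccg.n3),
    }
    counts = {"BMAL1": ccg.n1, "PER2": ccg.n1, "CRY1": ccg.n1,
              "REVERBA": ccg.n2, "DBP": ccg.n3}
    out = RegulationFactorSeries(tissue=tissue, gene=gene, times=ts)
    for fac in FACTORS:
        s = np.broadcast_to(np.asarray(series[fac], dtype=float), ts.shape).copy()
        if counts[fac] == 0:
            s = np.ones_like(ts)  # zero count: term identically 1
            cv = 0.0
        else:
            cv = float(s.std() / s.mean())
        out.series[fac] = s
        out.cv[fac] = cv
    return out


def delta_cv_percent(cv_i: float, cv_j: float) -> float:
    """(max - min)/max * 100 of two coefficients of variation.

    Both zero returns 0 by convention (0/0 guarded).
    """
    if cv_i < 0 or cv_j < 0:
        raise ValueError(f"CVs must be non-negative, got ({cv_i}, {cv_j})")
    hi, lo = max(cv_i, cv_j), min(cv_i, cv_j)
    if hi == 0.0:
        return 0.0
    return float((hi - lo) / hi * 100.0)


def phase_vs_regfac_table(results: list[dict]) -> list[DeltaCVRecord]:
    """Build the per-gene, per-tissue-pair ΔCV%-vs-phase-lag table.

    Each entry of ``results`` describes one gene in one tissue pair::

        {"gene": str,
         "tissue_a": str, "tissue_b": str,
         "regfac_a": RegulationFactorSeries, "regfac_b": RegulationFactorSeries,
         "phase_a": float | None, "phase_b": float | None}

    An undefined phase (``None``) flags the record instead of dropping it.
    """
    records = []
    for item in results:
        ra, rb = item["regfac_a"], item["regfac_b"]
        delta = {fac: delta_cv_percent(ra.cv[fac], rb.cv[fac]) for fac in FACTORS}
        pa, pb = item.get("phase_a"), item.get("phase_b")
        if pa is None or pb is None:
            records.append(DeltaCVRecord(
                gene=item["gene"], tissue_a=item["tissue_a"], tissue_b=item["tissue_b"],
                delta_cv=delta, phase_difference=float("nan"), phase_defined=False))
        else:
            records.append(DeltaCVRecord(
                gene=item["gene"], tissue_a=item["tissue_a"], tissue_b=item["tissue_b"],
                delta_cv=delta, phase_difference=phase_difference(pa, pb)))
    return records


def delta_cv_frame(records: list[DeltaCVRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"gene": r.gene, "tissue_a": r.tissue_a, "tissue_b": r.tissue_b,
               "phase_difference_rad": r.phase_difference,
               "phase_defined": r.phase_defined}
        for fac in FACTORS:
            row[f"delta_cv_{fac}_pct"] = r.delta_cv[fac]
        rows.append(row)
    return pd.DataFrame(rows)


def phase_regfac_correlations(records: list[DeltaCVRecord]) -> dict:
    """Spearman rank correlation of |phase difference| vs each factor's ΔCV%.

    Reported without thresholding; NaN when fewer than 3 defined records.
    """
    from scipy.stats import spearmanr

    defined = [r for r in records if r.phase_defined]
    out = {}
    for fac in FACTORS:
        if len(defined) < 3:
            out[fac] = (float("nan"), float("nan"))
            continue
        x = [abs(r.phase_difference) for r in defined]
        y = [r.delta_cv[fac] for r in defined]
        if np.std(y) == 0 or np.std(x) == 0:
            out[fac] = (float("nan"), float("nan"))
            continue
        rho, p = spearmanr(x, y)
        out[fac] = (float(rho), float(p))
    return out
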