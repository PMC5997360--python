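"""Synthetic inputs with the statistical structure of the study design.

Two generators, each returning a ground-truth manifest sufficient to
regenerate its output bit-exactly:

- time courses on the 18-point lights-on sampling grid (0.25 ... 23.75 h),
  triplicate, values normalized around 1, multiplicative lognormal noise;
- promoter FASTA sequences with consensus motifs planted at recorded
  non-overlapping positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from circaclock.models import (
    GENES,
    GENE_INDEX,
    CCGParameters,
    CoreClockParameters,
    TissueModel,
)
from circaclock.profiles import CycleProfile, cycle_profile
from circaclock.phases import NoOscillationError

__all__ = [
    "TIME_GRID",
    "TimeCourseDataset",
    "TruthManifest",
    "generate_timecourse",
    "generate_ccg_timecourse",
    "generate_promoters",
]

# Sampling design: 18 time points per 24 h cycle, 12:12 light:dark,
# light = [0, 12) h, dark = [12, 24) h after lights-on.
TIME_GRID = np.array([
    0.25, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 11.0, 11.75,
    12.25, 13.0, 14.0, 16.0, 18.0, 20.0, 22.0, 23.0, 23.75,
])

DEFAULT_REPLICATES = 3


@dataclass
class TimeCourseDataset:
    """Replicate expression measurements of one gene in one tissue."""

    tissue: str
    gene: str
    times: np.ndarray            # hours after lights-on, strictly increasing
    values: np.ndarray           # (n_times, n_replicates), > 0, near 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.size:
            raise ValueError("values must have one row per time point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing within a cycle")
        if np.any(self.values <= 0):
            raise ValueError("expression values must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def light_dark(self) -> np.ndarray:
        """'light' for t in [0,12), 'dark' for t in [12,24)."""
        return np.where(np.mod(self.times, 24.0) < 12.0, "light", "dark")

    def replicate_mean(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_replicates):
            rows.append(pd.DataFrame({
                "tissue": self.tissue, "gene": self.gene,
                "time_h": self.times, "replicate": r + 1,
                "value": self.values[:, r],
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class TruthManifest:
    """Everything needed to regenerate a synthetic dataset bit-exactly."""

    seed: int
    noise_model: str
    noise_cv: float
    n_replicates: int
    params: dict = field(default_factory=dict)       # tissue -> parameter dict
    ccg_params: dict = field(default_factory=dict)   # tissue -> CCG parameter dict
    time_grid: list = field(default_factory=lambda: TIME_GRID.tolist())
    offsets: dict = field(default_factory=dict)      # tissue -> clock offset (h)
    period: dict = field(default_factory=dict)       # tissue -> simulated period
    warnings: list = field(default_factory=list)
    plantings: dict = field(default_factory=dict)    # gene -> list of plantings

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and CV exactly ``cv``."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=shape))


def _simulate_profile(params: CoreClockParameters, burn_in: float,
                      window: float, dt: float) -> CycleProfile:
    from circaclock.fastsim import simulate_grid

    t, Y = simulate_grid(params, burn_in + window, dt=dt)
    post = t >= burn_in
    return cycle_profile(t[post], Y[post])


def generate_timecourse(
    true_params: dict[str, CoreClockParameters] | CoreClockParameters | TissueModel,
    genes=GENES,
    noise_cv: float = 0.10,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    noise_model: str = "lognormal",
    burn_in: float = 240.0,
    window: float = 72.0,
    dt: float = 0.01,
    offsets: dict[str, float] | None = None,
) -> tuple[list[TimeCourseDataset], TruthManifest]:
    """Simulate tissue truths, normalize to cycle mean 1, sample the study
    grid and apply seeded replicate noise.

    ``true_params`` maps tissue label to its parameters (a single parameter
    set is treated as one tissue named "tissue1").  Non-oscillatory truths
    produce a manifest warning; their values fall back to the constant 1
    profile so data are still emitted.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if isinstance(true_params, TissueModel):
        true_params = {true_params.tissue: true_params.params}
    elif isinstance(true_params, CoreClockParameters):
        true_params = {"tissue1": true_params}
    offsets = offsets or {}
    rng = np.random.default_rng(seed)
    manifest = TruthManifest(seed=seed, noise_model=noise_model, noise_cv=noise_cv,
                             n_replicates=n_replicates)
    datasets: list[TimeCourseDataset] = []
    for tissue, params in true_params.items():
        manifest.params[tissue] = params.to_dict()
        off = float(offsets.get(tissue, 0.0))
        manifest.offsets[tissue] = off
        try:
            prof = _simulate_profile(params, burn_in, window, dt)
            manifest.period[tissue] = float(prof.period)
        except (NoOscillationError, FloatingPointError) as exc:
            manifest.warnings.append(f"{tissue}: non-oscillatory truth ({exc})")
            prof = None
        for gene in genes:
            if prof is None:
                clean = np.ones(TIME_GRID.size)
            else:
                clean = prof.sample(GENE_INDEX[gene], TIME_GRID, offset=off)
            if noise_model == "lognormal":
                noise = _lognormal_factors(rng, noise_cv, (TIME_GRID.size, n_replicates))
                vals = clean[:, None] * noise
            elif noise_model == "additive":
                vals = clean[:, None] + rng.normal(
                    0.0, noise_cv, size=(TIME_GRID.size, n_replicates))
                vals = np.maximum(vals, 1e-6)  # noise model must preserve positivity
            else:
                raise ValueError(f"unknown noise model {noise_model!r}")
            datasets.append(TimeCourseDataset(tissue=tissue, gene=gene,
                                              times=TIME_GRID.copy(), values=vals))
    return datasets, manifest


def generate_ccg_timecourse(
    core_params: CoreClockParameters,
    ccg_params: dict[str, dict[str, CCGParameters]],
    noise_cv: float = 0.10,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    burn_in: float = 240.0,
    window: float = 72.0,
    dt: float = 0.01,
) -> tuple[list[TimeCourseDataset], TruthManifest]:
    """Synthetic CCG data: one shared core-clock truth drives per-tissue CCGs.

    ``ccg_params`` maps tissue -> gene -> :class:`CCGParameters`; tissues
    share the core truth (consensus assumption) while CCG parameters differ,
    which is the inter-tissue variability scenario used for recovery testing.
    """
    from circaclock.estimation import CCGForcing, periodic_ccg_profile

    rng = np.random.default_rng(seed)
    manifest = TruthManifest(seed=seed, noise_model="lognormal", noise_cv=noise_cv,
                             n_replicates=n_replicates)
    manifest.params["__core__"] = core_params.to_dict()
    forcing = CCGForcing.from_params(core_params, burn_in=burn_in, window=window, dt=dt)
    manifest.period["__core__"] = float(forcing.period)
    datasets: list[TimeCourseDataset] = []
    for tissue, genes in ccg_params.items():
        manifest.ccg_params[tissue] = {g: p.to_dict() for g, p in genes.items()}
        for gene, cp in genes.items():
            prof = periodic_ccg_profile(forcing, cp)
            clean = np.interp(np.mod(TIME_GRID, forcing.period),
                              forcing.grid, prof / prof.mean())
            noise = _lognormal_factors(rng, noise_cv, (TIME_GRID.size, n_replicates))
            datasets.append(TimeCourseDataset(
                tissue=tissue, gene=gene, times=TIME_GRID.copy(),
                values=clean[:, None] * noise))
    return datasets, manifest


# ---------------------------------------------------------------------------
# promoter sequences

_BASES = np.array(list("ACGT"))


def generate_promoters(
    plan: list[tuple[str, int, int, int]],
    motifs: dict[str, str] | None = None,
    length: int = 15000,
    gc: float = 0.42,
    seed: int = 0,
) -> tuple[dict[str, str], TruthManifest]:
    """Random promoter sequences with planted consensus motifs.

    ``plan`` lists ``(gene, k_ebox, k_rre, k_dbox)``; ``motifs`` maps the
    class names ``ebox``/``rre``/``dbox`` to consensus strings (defaults to
    the bundled stand-in matrices' consensi).  Background is i.i.d. at the
    requested GC content; plantings are non-overlapping, on a random strand,
    and recorded in the manifest.
    """
    from circaclock.pwm import load_bundled_pwm, reverse_complement

    if motifs is None:
        motifs = {name: load_bundled_pwm(name).consensus for name in ("ebox", "rre", "dbox")}
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    manifest = TruthManifest(seed=seed, noise_model="promoter", noise_cv=0.0,
                             n_replicates=0)
    sequences: dict[str, str] = {}
    for gene, k_ebox, k_rre, k_dbox in plan:
        wanted = [("ebox", k_ebox), ("rre", k_rre), ("dbox", k_dbox)]
        if any(k < 0 for _, k in wanted):
            raise ValueError("plan counts must be >= 0")
        total_len = sum(len(motifs[m]) * k for m, k in wanted)
        if total_len > length // 2:
            raise ValueError(
                f"plan for {gene!r} needs {total_len} motif bases; "
                f"infeasible for length {length}")
        seq = rng.choice(_BASES, size=length, p=p)
        placed: list[tuple[int, int]] = []
        plantings = []
        for motif_name, k in wanted:
            consensus = motifs[motif_name]
            L = len(consensus)
            for _ in range(k):
                for _attempt in range(10000):
                    pos = int(rng.integers(0, length - L + 1))
                    if all(pos + L <= s or pos >= e for s, e in placed):
                        break
                else:  # pragma: no cover - essentially unreachable under the feasibility check
                    raise ValueError(f"could not place motifs for {gene!r}")
                strand = "+" if rng.random() < 0.5 else "-"
                planted = consensus if strand == "+" else reverse_complement(consensus)
                seq[pos:pos + L] = list(planted)
                placed.append((pos, pos + L))
                plantings.append({"motif": motif_name, "start": pos,
                                  "end": pos + L, "strand": strand})
        sequences[gene] = "".join(seq)
        manifest.plantings[gene] = plantings
    return sequences, manifest


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    """Deterministic FASTA output (byte-identical for identical inputs)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
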