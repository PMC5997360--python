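"""Readers/writers for the pipeline's file formats, run configuration and
logging.

Tabular interchange is tidy CSV; sequences are FASTA; motifs are JASPAR-style
text PFMs; hits export as BED-like rows.  Every command writes the effective
run configuration next to its outputs so any artifact can be traced to the
exact defaults that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from circaclock.synth import TimeCourseDataset

logger = logging.getLogger("circaclock")

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_timecourse",
    "write_timecourse",
    "read_fasta",
    "write_phase_report",
    "setup_logging",
]

TIMECOURSE_COLUMNS = ("tissue", "gene", "time_h", "replicate", "value")


class SchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    """Effective configuration of a run; echoed verbatim to the log."""

    seed: int = 0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    burn_in: float = 240.0
    window: float = 120.0
    fit_burn_in: float = 120.0
    fit_window: float = 60.0
    fast_dt: float = 0.01
    pwm_threshold: float = 0.85
    pwm_pseudocount: float = 0.8
    noise_cv: float = 0.10
    noise_model: str = "lognormal"
    n_replicates: int = 3
    n_starts: int = 5
    sigma_mode: str = "standard"
    offset_bounds: tuple = (-24.0, 24.0)
    delay_bounds: tuple = (0.05, 8.0)
    degradation_bounds: tuple = (0.1, 1.5)
    regfac_grid_dt: float = 0.05
    extra: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def write(self, directory) -> Path:
        path = Path(directory) / "run_config.yaml"
        path.write_text(self.to_yaml())
        logger.info("effective config:\n%s", self.to_yaml())
        return path


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def write_timecourse(datasets: list[TimeCourseDataset], path) -> None:
    frames = [ds.to_frame() for ds in datasets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_timecourse(path) -> list[TimeCourseDataset]:
    """Read a tidy time-course CSV into validated datasets.

    Rows are canonically sorted (tissue, gene, time, replicate), so files
    with shuffled row order load to identical datasets.  An empty file is an
    error, not an empty list.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty time-course file: {path}") from None
    for col in TIMECOURSE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if df.empty:
        raise SchemaError(f"no data rows in {path}")
    for col in ("time_h", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise SchemaError(f"non-numeric {col!r} at line(s) {rows} in {path}")
        df[col] = pd.to_numeric(df[col])
    df = df.sort_values(["tissue", "gene", "time_h", "replicate"],
                        kind="stable").reset_index(drop=True)
    datasets = []
    for (tissue, gene), grp in df.groupby(["tissue", "gene"], sort=True):
        try:
            piv = grp.pivot(index="time_h", columns="replicate", values="value")
        except ValueError as exc:
            raise SchemaError(
                f"duplicate (time, replicate) rows for {tissue}/{gene} "
                f"in {path}: {exc}") from None
        if piv.isna().any().any():
            raise SchemaError(
                f"unbalanced replicates for {tissue}/{gene} in {path}")
        datasets.append(TimeCourseDataset(
            tissue=str(tissue), gene=str(gene),
            times=piv.index.to_numpy(dtype=float),
            values=piv.to_numpy(dtype=float)))
    return datasets


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader (uppercased sequences, insertion order kept)."""
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise SchemaError(f"sequence data before header in {path}")
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks).upper()
    if not sequences:
        raise SchemaError(f"no FASTA records in {path}")
    return sequences


def write_phase_report(estimates, path) -> None:
    """Phase report CSV: gene, tissue, period_h, peak_time_h, phase_rad,
    amplitude."""
    rows = [{
        "gene": e.gene, "tissue": tissue, "period_h": e.period,
        "peak_time_h": e.peak_time, "phase_rad": e.phase,
        "amplitude": e.amplitude,
    } for tissue, e in estimates]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_bed_hits(all_hits: list, path) -> None:
    """BED-like hits: seq_id, start, end, motif_id, score*1000, strand."""
    with open(path, "w") as fh:
        for hits in all_hits:
            for row in hits.to_bed_rows():
                fh.write("\t".join(str(x) for x in row) + "\n")


def write_counts_tsv(counts_by_gene: dict, path) -> None:
    """Counts TSV (gene, n1, n2, n3) mirroring the element-count tables."""
    with open(path, "w") as fh:
        fh.write("gene\tn1\tn2\tn3\n")
        for gene, (n1, n2, n3) in counts_by_gene.items():
            fh.write(f"{gene}\t{n1}\t{n2}\t{n3}\n")
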