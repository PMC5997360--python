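"""PWM promoter scanning: Ebox/RRE/Dbox element counts at a relative-score
threshold.

Scoring scheme (conventional, documented): count matrices get a pseudocount
of 0.8 distributed by a uniform background (0.25 per base), columns are
normalized to frequencies, and log-odds are taken against the background.
The relative score of a window is (S - S_min)/(S_max - S_min) where S_min /
S_max are the lowest / highest achievable log-odds sums.  Both strands are
scanned; windows containing N are skipped; overlapping hits all count.

Coordinates are 0-based half-open internally; BED-like exports report
start/end in that convention with 1-based positions available via the
report helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "PositionWeightMatrix",
    "PromoterRegion",
    "MotifHit",
    "MotifHits",
    "PFMParseError",
    "read_pfm",
    "parse_pfm_text",
    "load_bundled_pwm",
    "relative_score",
    "scan",
    "count_elements",
    "reverse_complement",
]

BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(BASES)}
_CODE["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_BACKGROUND = np.full(4, 0.25)
DEFAULT_THRESHOLD = 0.85
MAX_REGION_LENGTH = 15000


class PFMParseError(ValueError):
    def __init__(self, message, line_number=None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """Motif count matrix with derived log-odds scoring matrix."""

    matrix_id: str
    name: str
    counts: np.ndarray                      # (4, L), rows A,C,G,T
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())
    log_odds: np.ndarray = field(init=False)      # bits
    score_min: float = field(init=False)
    score_max: float = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape[0] != 4 or counts.shape[1] < 4:
            raise ValueError(f"counts must be 4 x L with L >= 4, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts
        # column sums may differ across positions (raw counts); normalize per column
        col_tot = counts.sum(axis=0) + self.pseudocount
        freqs = (counts + self.pseudocount * self.background[:, None]) / col_tot
        freqs = np.maximum(freqs, np.finfo(float).eps)
        self.log_odds = np.log2(freqs / self.background[:, None])
        self.score_min = float(self.log_odds.min(axis=0).sum())
        self.score_max = float(self.log_odds.max(axis=0).sum())
        if not self.score_max > self.score_min:
            raise ValueError("degenerate matrix: max score equals min score")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    @property
    def anticonsensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmin(axis=0))

    def reverse_complement_matrix(self) -> np.ndarray:
        """Log-odds matrix scoring the reverse complement of a window."""
        return self.log_odds[::-1, ::-1]


def _parse_count_row(line: str, lineno: int) -> tuple[str | None, list[float]]:
    raw = line.strip()
    letter = None
    if raw and raw[0].upper() in BASES and (len(raw) == 1 or not raw[1].isdigit()):
        letter = raw[0].upper()
        raw = raw[1:]
    raw = raw.replace("[", " ").replace("]", " ")
    try:
        values = [float(tok) for tok in raw.split()]
    except ValueError as exc:
        raise PFMParseError(f"non-numeric count: {exc}", lineno) from None
    return letter, values


def read_pfm(path) -> PositionWeightMatrix:
    """Parse one JASPAR-style text PFM record from a file.

    Accepts the common dialects: a ``>ID name`` header followed by four rows,
    either bare numbers or ``A [ 1 2 3 ]`` style, in A,C,G,T order.
    """
    with open(path) as fh:
        return parse_pfm_text(fh.read())


def parse_pfm_text(text: str) -> PositionWeightMatrix:
    lines = text.splitlines()
    matrix_id, name = "", ""
    rows: list[list[float]] = []
    letters: list[str | None] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            if rows:
                raise PFMParseError("multiple records found; expected one", lineno)
            parts = line[1:].split(None, 1)
            matrix_id = parts[0] if parts else ""
            name = parts[1].strip() if len(parts) > 1 else ""
            continue
        letter, values = _parse_count_row(line, lineno)
        if len(rows) == 4:
            raise PFMParseError("more than 4 matrix rows", lineno)
        if rows and len(values) != len(rows[0]):
            raise PFMParseError(
                f"row length {len(values)} differs from first row {len(rows[0])}",
                lineno)
        rows.append(values)
        letters.append(letter)
    if len(rows) != 4:
        raise PFMParseError(f"expected 4 rows (A,C,G,T), found {len(rows)}")
    if any(letters):
        order = "".join(l or "?" for l in letters)
        if order != "ACGT":
            raise PFMParseError(f"rows must be in A,C,G,T order, found {order}")
    return PositionWeightMatrix(matrix_id=matrix_id, name=name,
                                counts=np.array(rows))


def load_bundled_pwm(motif_class: str) -> PositionWeightMatrix:
    """Load one of the bundled stand-in matrices: ``ebox``, ``rre``, ``dbox``.

    These are clearly-labeled example matrices for the three motif classes,
    not the database originals; real analyses should pass their own PFMs.
    """
    ref = resources.files("circaclock").joinpath(f"data/motifs/{motif_class}.pfm")
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled motif {motif_class!r}")
    return parse_pfm_text(ref.read_text())


@dataclass
class PromoterRegion:
    """Promoter window sequence (convention: -10 kb .. +5 kb around the TSS)."""

    gene_id: str
    sequence: str
    strand: str = "+"

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) > MAX_REGION_LENGTH:
            raise ValueError(
                f"region length {len(self.sequence)} exceeds {MAX_REGION_LENGTH}")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"invalid characters in sequence: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    offset: int          # 0-based start of the window
    strand: str          # '+' or '-'
    score: float         # relative score in [0, 1]


@dataclass
class MotifHits:
    gene_id: str
    motif_id: str
    hits: list[MotifHit] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD

    @property
    def count(self) -> int:
        return len(self.hits)

    def to_bed_rows(self) -> list[tuple]:
        """BED-like rows: (seq_id, start, end, motif_id, score*1000, strand)."""
        return [(self.gene_id, h.offset, h.offset + self._length, self.motif_id,
                 int(round(h.score * 1000)), h.strand) for h in self.hits]

    _length: int = 0


def relative_score(pwm: PositionWeightMatrix, subsequence: str,
                   strand: str = "+") -> float:
    """Relative log-odds score of one window, in [0, 1].

    The minus strand scores the reverse complement of the subsequence.
    """
    if len(subsequence) != pwm.length:
        raise ValueError(
            f"subsequence length {len(subsequence)} != motif length {pwm.length}")
    seq = subsequence.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if "N" in seq:
        raise ValueError("subsequence contains N; windows with N are skipped")
    s = sum(pwm.log_odds[_CODE[c], i] for i, c in enumerate(seq))
    return float((s - pwm.score_min) / (pwm.score_max - pwm.score_min))


def scan(region: PromoterRegion, pwm: PositionWeightMatrix,
         threshold: float = DEFAULT_THRESHOLD) -> MotifHits:
    """All offsets on both strands with relative score >= threshold.

    Overlapping hits are all counted; windows containing N are skipped.  A
    region shorter than the motif yields an empty hit list.
    """
    L = pwm.length
    out = MotifHits(gene_id=region.gene_id, motif_id=pwm.matrix_id,
                    threshold=threshold)
    out._length = L
    n = len(region) - L + 1
    if n <= 0:
        import warnings

        warnings.warn(f"region {region.gene_id!r} shorter than motif "
                      f"{pwm.matrix_id!r}; no scan possible", stacklevel=2)
        return out
    codes = np.array([_CODE[c] for c in region.sequence], dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~np.any(windows == 4, axis=1)
    cols = np.arange(L)
    span = pwm.score_max - pwm.score_min
    lom = pwm.log_odds
    lom_rc = pwm.reverse_complement_matrix()
    safe = np.where(windows == 4, 0, windows)
    fwd = (lom[safe, cols].sum(axis=1) - pwm.score_min) / span
    rev = (lom_rc[safe, cols].sum(axis=1) - pwm.score_min) / span
    for off in np.nonzero(valid & (fwd >= threshold))[0]:
        out.hits.append(MotifHit(int(off), "+", float(fwd[off])))
    for off in np.nonzero(valid & (rev >= threshold))[0]:
        out.hits.append(MotifHit(int(off), "-", float(rev[off])))
    out.hits.sort(key=lambda h: (h.offset, h.strand))
    return out


def count_elements(region: PromoterRegion,
                   pwm_ebox: PositionWeightMatrix,
                   pwm_rre: PositionWeightMatrix,
                   pwm_dbox: PositionWeightMatrix,
                   threshold: float = DEFAULT_THRESHOLD):
    """(n1, n2, n3) element counts with full hit provenance.

    Returns ``(counts, hits)`` where counts is the (Ebox, RRE, Dbox) triple
    used as the CCG exponents.
    """
    hits = {
        "ebox": scan(region, pwm_ebox, threshold),
        "rre": scan(region, pwm_rre, threshold),
        "dbox": scan(region, pwm_dbox, threshold),
    }
    counts = (hits["ebox"].count, hits["rre"].count, hits["dbox"].count)
    return counts, hits
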