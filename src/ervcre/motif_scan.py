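"""PWM scanning for AP-1 (FOS::JUN) binding sites in LTR sequences.

A JASPAR-style count matrix is pseudocount-normalised to per-position
probabilities; a sliding window of the motif length (7 for AP-1) scores
every subsequence as the sum of log probabilities, ln(p + epsilon); the
raw score is min-max normalised to [0, 1] over the matrix's attainable
range.  A window passes at either a raw-score threshold (default 8) or
a normalised threshold (default 0.5), depending on the configured mode.

Two points are deliberate, documented choices: the log transform uses
ln(p + epsilon) with a small epsilon (1e-6) rather than ln(p + 1) —
ln(p + 1) makes every score positive and incompatible with thresholding
a sum of log-probabilities — and the normalisation maps the per-column
argmax consensus to exactly 1 and the anti-consensus to exactly 0.
Scanning is forward-strand by default (an LTR consensus has a defined
orientation); reverse-complement scanning is optional.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .formats_io import SequenceRecord

__all__ = [
    "PWMCounts",
    "PWMProbabilities",
    "MotifHit",
    "ScanConfig",
    "normalize_pwm",
    "score_window",
    "normalize_score",
    "scan_sequence",
    "read_jaspar_counts",
]

_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWMCounts:
    counts: np.ndarray  # (4, L), rows A,C,G,T, non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if (self.counts < 0).any():
            raise ValueError("negative counts in PWM")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class PWMProbabilities:
    probs: np.ndarray  # (4, L), columns sum to 1, all entries > 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("PWM probabilities must all be > 0")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    start: int  # 0-based window start
    kmer: str
    raw_score: float
    normalized_score: float
    passes: bool
    strand: str = "+"


@dataclass
class ScanConfig:
    window: int = 7
    pseudocount: float = 1.0
    epsilon: float = 1e-6
    raw_threshold: float = 8.0
    normalized_threshold: float = 0.5
    mode: str = "normalized"  # raw | normalized
    drop_n_windows: bool = False
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.mode not in {"raw", "normalized"}:
            raise ValueError(f"unknown scan mode {self.mode!r}")


def normalize_pwm(counts: PWMCounts, pseudocount: float = 1.0) -> PWMProbabilities:
    """Per-column probabilities: (count + pseudocount) / (column sum + 4*pseudocount)."""
    adjusted = counts.counts + pseudocount
    col_sums = adjusted.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValueError(
            "zero column total with zero pseudocount: probabilities undefined"
        )
    return PWMProbabilities(adjusted / col_sums)


def _log_matrix(pwm: PWMProbabilities, epsilon: float) -> np.ndarray:
    return np.log(pwm.probs + epsilon)


def score_window(pwm: PWMProbabilities, kmer: str, epsilon: float = 1e-6) -> float:
    """Raw score: sum over positions of ln(prob[base][i] + epsilon).

    An N contributes ln(0.25 + epsilon) — the uniform-composition score.
    """
    if len(kmer) != pwm.length:
        raise ValueError(
            f"k-mer length {len(kmer)} != PWM length {pwm.length}"
        )
    logm = _log_matrix(pwm, epsilon)
    n_score = math.log(0.25 + epsilon)
    total = 0.0
    for i, base in enumerate(kmer):
        row = _ROW.get(base)
        total += n_score if row is None else logm[row, i]
    return total


def score_bounds(pwm: PWMProbabilities, epsilon: float = 1e-6) -> tuple[float, float]:
    """(raw_min, raw_max): per-column min/max log-probability sums."""
    logm = _log_matrix(pwm, epsilon)
    return float(logm.min(axis=0).sum()), float(logm.max(axis=0).sum())


def normalize_score(raw: float, pwm: PWMProbabilities, epsilon: float = 1e-6) -> float:
    """Min-max normalisation over the PWM's attainable raw-score range.

    A uniform PWM (raw_max == raw_min) yields 1.0 with a warning.
    """
    lo, hi = score_bounds(pwm, epsilon)
    if hi == lo:
        warnings.warn("uniform PWM: normalized score defined as 1.0")
        return 1.0
    return (raw - lo) / (hi - lo)


def _scan_one_strand(
    seq: str, pwm: PWMProbabilities, config: ScanConfig, strand: str
) -> list[MotifHit]:
    logm = _log_matrix(pwm, config.epsilon)
    lo, hi = score_bounds(pwm, config.epsilon)
    span = hi - lo
    n_score = math.log(0.25 + config.epsilon)
    L = pwm.length
    hits = []
    for start in range(len(seq) - L + 1):
        kmer = seq[start : start + L]
        if config.drop_n_windows and "N" in kmer:
            continue
        raw = 0.0
        for i, base in enumerate(kmer):
            row = _ROW.get(base)
            raw += n_score if row is None else logm[row, i]
        norm = 1.0 if span == 0 else (raw - lo) / span
        passes = (
            raw >= config.raw_threshold
            if config.mode == "raw"
            else norm >= config.normalized_threshold
        )
        hits.append(MotifHit(start, kmer, raw, norm, passes, strand))
    return hits


def scan_sequence(
    record: SequenceRecord, pwm: PWMProbabilities, config: ScanConfig
) -> list[MotifHit]:
    """All stride-1 windows of the sequence scored against the PWM.

    Every window is reported with its raw and normalised score and a
    pass flag (mode-dependent threshold); a sequence shorter than the
    window yields an empty list.  With ``both_strands`` the
    reverse-complement is scanned too, hit starts reported in forward
    coordinates.
    """
    if pwm.length != config.window:
        raise ValueError(
            f"PWM length {pwm.length} != configured window {config.window}"
        )
    seq = record.sequence
    if len(seq) < pwm.length:
        return []
    hits = _scan_one_strand(seq, pwm, config, "+")
    if config.both_strands:
        rc = seq.translate(_COMPLEMENT)[::-1]
        for h in _scan_one_strand(rc, pwm, config, "-"):
            fwd_start = len(seq) - pwm.length - h.start
            hits.append(
                MotifHit(fwd_start, h.kmer, h.raw_score, h.normalized_score,
                         h.passes, "-")
            )
    return hits


def read_jaspar_counts(path) -> PWMCounts:
    """Read a JASPAR plain-text count matrix.

    Accepts both the bracketed format (``A  [ 3 5 ... ]``) and bare
    4-row numeric matrices, with an optional ``>`` header line.
    """
    rows: dict[str, list[float]] = {}
    order = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            parts = line.replace("[", " ").replace("]", " ").split()
            if parts[0].upper() in _ROW:
                base = parts[0].upper()
                values = [float(v) for v in parts[1:]]
            else:
                base = "ACGT"[len(rows)]
                values = [float(v) for v in parts]
            rows[base] = values
            order.append(base)
    if set(rows) != set("ACGT"):
        raise ValueError(f"{path}: expected rows A,C,G,T, got {order}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal row lengths {lengths}")
    return PWMCounts(np.array([rows[b] for b in "ACGT"]))
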