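"""Readers and writers for the on-disk formats the pipeline consumes.

All genomic coordinates are 0-based, half-open (BED convention).  Formats
handled: FASTA (60-column wrapped on write), BED6, ENCODE narrowPeak
(10 columns), bedGraph, and TSV expression matrices with a sample-metadata
sidecar.  Every reader is gzip-transparent (a ``.gz`` suffix triggers
decompression).

Soft-masked (lowercase) FASTA bases are uppercased on read, but the
fraction of masked bases is recorded per record so downstream consumers
do not silently lose the masking signal — repeat sequences are routinely
soft-masked.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RepeatAnnotation",
    "Peak",
    "CoverageTrack",
    "SequenceRecord",
    "ExpressionMatrix",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_expression",
    "write_expression",
]

VALID_STRANDS = {"+", "-", "."}
SEQ_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand and name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class RepeatAnnotation:
    """A RepeatMasker-style repeat locus with family/superfamily labels."""

    interval: GenomicInterval
    family: str  # e.g. "MLT1G1"
    superfamily: str = "other"  # ERV1 / ERV2 / ERV3 / other

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")

    @property
    def id(self) -> str:
        return self.interval.name


@dataclass(frozen=True)
class Peak:
    """A called ChIP peak (narrowPeak row); peak calling happens upstream."""

    interval: GenomicInterval
    signal: float = 0.0
    q_value: float | None = None  # -log10 scale
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.signal) or self.signal < 0:
            raise ValueError(f"peak signal must be finite and >= 0, got {self.signal}")

    @property
    def id(self) -> str:
        return self.interval.name


@dataclass
class SequenceRecord:
    """A DNA sequence over {A,C,G,T,N}, uppercased, with masked fraction."""

    id: str
    sequence: str
    masked_fraction: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.sequence) - SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        """GC fraction over non-N bases; 0.0 for an all-N sequence."""
        acgt = sum(self.sequence.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (self.sequence.count("G") + self.sequence.count("C")) / acgt


class CoverageTrack:
    """A flat (non-overlapping) step function per chromosome.

    Steps are ``(start, end, value)`` triples in 0-based half-open
    coordinates, kept sorted.  Positions not covered by any step have
    value 0.
    """

    def __init__(self, steps: dict[str, list[tuple[int, int, float]]] | None = None):
        self.steps: dict[str, list[tuple[int, int, float]]] = {}
        if steps:
            for chrom, ch_steps in steps.items():
                self.add_chrom(chrom, ch_steps)

    def add_chrom(self, chrom: str, ch_steps: Iterable[tuple[int, int, float]]) -> None:
        ordered = sorted(ch_steps)
        prev_end = -1
        for start, end, value in ordered:
            if start < 0 or start >= end:
                raise ValueError(f"invalid step {chrom}:{start}-{end}")
            if not math.isfinite(value):
                raise ValueError(f"non-finite value at {chrom}:{start}-{end}")
            if start < prev_end:
                raise ValueError(
                    f"overlapping steps at {chrom}:{start} (previous ends {prev_end})"
                )
            prev_end = end
        self.steps[chrom] = ordered

    def integral(self, chrom: str, a: float, b: float) -> float:
        """Integral of the step function over [a, b); uncovered span counts 0."""
        if b <= a:
            return 0.0
        total = 0.0
        for start, end, value in self.steps.get(chrom, []):
            if end <= a:
                continue
            if start >= b:
                break
            total += (min(end, b) - max(start, a)) * value
        return total

    def mean(self, chrom: str, a: float, b: float) -> float:
        if b <= a:
            return 0.0
        return self.integral(chrom, a, b) / (b - a)


@dataclass
class ExpressionMatrix:
    """Features (genes + ERV loci) x samples, typically log2(TPM+1) scale.

    ``values`` is indexed by feature id; ``metadata`` is indexed by sample
    id with at least ``condition`` (control/PE) and ``batch`` columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    log_scale: bool = True  # True: values are log2(TPM+1)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r} in expression matrix")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(
                f"samples missing from metadata: {sorted(missing)}"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def condition_samples(self, condition: str) -> list[str]:
        meta = self.metadata.loc[list(self.values.columns)]
        return list(meta.index[meta["condition"] == condition])


# ---------------------------------------------------------------------------
# gzip-transparent file helpers
# ---------------------------------------------------------------------------


def _open_text(path, mode: str = "rt") -> io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[SequenceRecord]:
    """Strict FASTA reader.

    Sequences are uppercased; the fraction of soft-masked (lowercase)
    bases is recorded per record.  Malformed headers and empty sequences
    raise :class:`FormatError` naming the offending line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(
                f"{path}: record {header!r} (line {header_line}) has empty sequence"
            )
        masked = sum(1 for c in seq if c.islower()) / len(seq)
        records.append(SequenceRecord(header, seq.upper(), masked_fraction=masked))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                rec_id = line[1:].split()[0] if line[1:].strip() else ""
                if not rec_id:
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                flush()
                header, header_line, chunks = rec_id, lineno, []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                chunks.append(line)
        flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED-family
# ---------------------------------------------------------------------------

BedKind = Literal["bed6", "narrowPeak", "repeat_table"]


def _parse_interval(fields: list[str], lineno: int, path) -> tuple[str, int, int]:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer coordinate at line {lineno}") from exc
    if start < 0 or start >= end:
        raise FormatError(
            f"{path}: invalid interval {fields[0]}:{start}-{end} at line {lineno}"
        )
    return fields[0], start, end


def read_bed(path, kind: BedKind = "bed6"):
    """Read BED6, narrowPeak or a repeat table into typed records.

    narrowPeak: column 7 -> signal, 9 -> q_value (-log10), 10 -> summit
    offset (sentinel -1 -> absent).  repeat_table requires columns
    chrom, start, end, strand, family, superfamily (with header).
    """
    if kind == "repeat_table":
        return _read_repeat_table(path)
    out = []
    min_cols = 10 if kind == "narrowPeak" else 3
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}: expected >= {min_cols} columns at line {lineno}, "
                    f"got {len(fields)}"
                )
            chrom, start, end = _parse_interval(fields, lineno, path)
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise FormatError(
                    f"{path}: unknown strand symbol {strand!r} at line {lineno}"
                )
            iv = GenomicInterval(chrom, start, end, strand, name)
            if kind == "narrowPeak":
                signal = float(fields[6])
                q = float(fields[8])
                summit = int(fields[9])
                out.append(
                    Peak(
                        iv,
                        signal=signal,
                        q_value=None if q < 0 else q,
                        summit_offset=None if summit < 0 else summit,
                    )
                )
            else:
                out.append(iv)
    return out


def _read_repeat_table(path) -> list[RepeatAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "family": str})
    required = {"chrom", "start", "end", "strand", "family", "superfamily"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: repeat table missing columns {sorted(missing)}")
    repeats = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = getattr(row, "name", "") or f"repeat_{i - 2}"
        try:
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand, str(name))
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        repeats.append(RepeatAnnotation(iv, str(row.family), str(row.superfamily)))
    return repeats


def write_bed(items, path, kind: BedKind = "bed6") -> None:
    with _open_text(path, "wt") as fh:
        if kind == "repeat_table":
            fh.write("chrom\tstart\tend\tstrand\tfamily\tsuperfamily\tname\n")
            for rep in items:
                iv = rep.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                    f"{rep.family}\t{rep.superfamily}\t{iv.name}\n"
                )
            return
        for item in items:
            if kind == "narrowPeak":
                iv = item.interval
                q = -1.0 if item.q_value is None else item.q_value
                summit = -1 if item.summit_offset is None else item.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                    f"{iv.strand}\t{item.signal:.17g}\t-1\t{q:.17g}\t{summit}\n"
                )
            else:
                iv = item
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path) -> CoverageTrack:
    """Read a 4-column bedGraph into a flat coverage track.

    Lines may arrive unsorted; overlapping steps are rejected because the
    track must describe a single-valued function.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: expected 4 columns at line {lineno}")
            chrom, start, end = _parse_interval(fields, lineno, path)
            try:
                value = float(fields[3])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric value at line {lineno}"
                ) from exc
            by_chrom.setdefault(chrom, []).append((start, end, value))
    track = CoverageTrack()
    for chrom, steps in by_chrom.items():
        try:
            track.add_chrom(chrom, steps)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in sorted(track.steps):
            for start, end, value in track.steps[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression(path, metadata_path) -> ExpressionMatrix:
    """Read a feature x sample TSV plus a sample metadata TSV.

    The metadata file must have columns ``sample``, ``condition``
    (control/PE) and ``batch``; every matrix column must appear in it.
    """
    df = pd.read_csv(_open_text(path), sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    meta = pd.read_csv(_open_text(metadata_path), sep="\t")
    required = {"sample", "condition", "batch"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{metadata_path}: missing columns {sorted(missing)}")
    meta = meta.set_index("sample")
    try:
        return ExpressionMatrix(df.astype(float), meta)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path, metadata_path) -> None:
    with _open_text(path, "wt") as fh:
        expr.values.to_csv(fh, sep="\t", index_label="feature")
    with _open_text(metadata_path, "wt") as fh:
        expr.metadata.to_csv(fh, sep="\t", index_label="sample")
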