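"""Peak/repeat interval arithmetic and coverage signal matrices.

Implements reciprocal-overlap intersection (bedtools ``intersectBed``
style with a minimum reciprocal fraction, inclusive ``>=`` comparisons),
any-overlap blacklist exclusion (common ENCODE practice), and
deepTools-style scale-regions signal matrices over repeat coordinates.
Strand is ignored for overlap tests but honoured (column reversal) in
signal matrices.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import CoverageTrack, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "SignalMatrix",
    "reciprocal_overlap",
    "intersect_annotations",
    "subtract_blacklist",
    "signal_matrix",
]


@dataclass(frozen=True)
class OverlapResult:
    query_id: str
    subject_id: str
    overlap_bp: int
    frac_query: float
    frac_subject: float


@dataclass
class SignalMatrix:
    """Rows = region ids; columns = upstream flank bins + scaled body bins
    + downstream flank bins; values = length-weighted mean coverage."""

    row_ids: list[str]
    values: np.ndarray  # (n_regions, n_columns)
    n_body_bins: int
    n_flank_bins: int

    @property
    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> OverlapResult:
    """Overlap in bp and the fraction of each interval covered by the other."""
    bp = a.overlap_bp(b)
    return OverlapResult(
        query_id=a.name,
        subject_id=b.name,
        overlap_bp=bp,
        frac_query=bp / len(a),
        frac_subject=bp / len(b),
    )


def _interval_of(item) -> GenomicInterval:
    return item if isinstance(item, GenomicInterval) else item.interval


def intersect_annotations(peaks, repeats, min_frac: float = 0.5):
    """Peak/repeat pairs with reciprocal overlap >= ``min_frac`` on both sides.

    Sorted-sweep implementation; output ordered by repeat then peak
    coordinate.  ``min_frac = 0`` reduces to plain any-overlap
    intersection (a zero-length overlap never qualifies).
    """
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(_interval_of(p).chrom, []).append(p)
    prefix_max_end: dict[str, list[int]] = {}
    for chrom, ch_peaks in by_chrom.items():
        ch_peaks.sort(key=lambda p: (_interval_of(p).start, _interval_of(p).end))
        acc, running = [], 0
        for p in ch_peaks:
            running = max(running, _interval_of(p).end)
            acc.append(running)
        prefix_max_end[chrom] = acc

    out = []
    for rep in sorted(
        repeats, key=lambda r: (_interval_of(r).chrom, _interval_of(r).start, _interval_of(r).end)
    ):
        riv = _interval_of(rep)
        ch_peaks = by_chrom.get(riv.chrom, [])
        max_end = prefix_max_end.get(riv.chrom, [])
        # first peak that could overlap: walk left while any earlier peak
        # still reaches past the repeat start (prefix max of ends)
        starts = [_interval_of(p).start for p in ch_peaks]
        j = bisect.bisect_left(starts, riv.start)
        while j > 0 and max_end[j - 1] > riv.start:
            j -= 1
        for p in ch_peaks[j:]:
            piv = _interval_of(p)
            if piv.start >= riv.end:
                break
            bp = riv.overlap_bp(piv)
            if bp > 0 and bp / len(piv) >= min_frac and bp / len(riv) >= min_frac:
                out.append((p, rep))
    return out


def subtract_blacklist(peaks, blacklist):
    """Drop every peak overlapping a blacklist interval by >= 1 bp."""
    bl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blacklist:
        bl_by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in bl_by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)

    kept = []
    removed = 0
    for p in peaks:
        piv = _interval_of(p)
        hit = any(
            piv.overlap_bp(iv) > 0 for iv in bl_by_chrom.get(piv.chrom, [])
        )
        if hit:
            removed += 1
        else:
            kept.append(p)
    logger.info("blacklist removed %d of %d peaks", removed, len(peaks))
    return kept


def signal_matrix(
    track: CoverageTrack,
    intervals,
    n_bins: int = 10,
    flank_bp: int = 0,
    flank_bin_bp: int = 50,
) -> SignalMatrix:
    """Scale-regions signal matrix: each region body resampled to
    ``n_bins`` equal sub-windows, flanks binned at ``flank_bin_bp`` per
    bin.  Bin value = length-weighted mean of step values overlapping
    the bin; uncovered positions count as 0.  Minus-strand regions are
    column-reversed.

    Regions shorter than ``n_bins`` are retained with a warning; their
    bins fall on fractional boundaries.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n_flank_bins = 0 if flank_bp <= 0 else max(1, round(flank_bp / flank_bin_bp))
    rows = []
    ids = []
    for item in intervals:
        iv = _interval_of(item)
        if len(iv) < n_bins:
            logger.warning(
                "region %s shorter (%d bp) than n_bins=%d; fractional bins used",
                iv.name or f"{iv.chrom}:{iv.start}", len(iv), n_bins,
            )
        cols = []
        # upstream flank (reference orientation: left of start)
        if n_flank_bins:
            # positions before the chromosome start simply carry no coverage
            edges = np.linspace(iv.start - flank_bp, iv.start, n_flank_bins + 1)
            for a, b in zip(edges[:-1], edges[1:]):
                cols.append(track.mean(iv.chrom, a, b))
        body_edges = np.linspace(iv.start, iv.end, n_bins + 1)
        for a, b in zip(body_edges[:-1], body_edges[1:]):
            cols.append(track.mean(iv.chrom, a, b))
        if n_flank_bins:
            edges = np.linspace(iv.end, iv.end + flank_bp, n_flank_bins + 1)
            for a, b in zip(edges[:-1], edges[1:]):
                cols.append(track.mean(iv.chrom, a, b))
        row = np.array(cols)
        if iv.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
    values = np.vstack(rows) if rows else np.zeros((0, n_bins + 2 * n_flank_bins))
    return SignalMatrix(ids, values, n_bins, n_flank_bins)
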