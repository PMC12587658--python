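"""ERV-to-gene cis-regulatory pairing.

Finds ERVs overlapping the 15-kb strand-aware window upstream of gene
TSSs, correlates ERV and gene expression (Spearman, BH-adjusted), calls
strong enhancer/gene pairs, and clusters the pairwise correlation
structure with k-means.

"Upstream" is interpreted relative to gene strand: for a + gene the
window is [tss - w, tss); for a - gene it is [tss, tss + w).  A repeat
qualifies as a candidate if it overlaps the window by >= 1 bp and its
enhancer call is "strong".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .enhancer_cnn import CLASS_STRONG, EnhancerCall
from .formats_io import ExpressionMatrix, GenomicInterval

__all__ = [
    "GeneModel",
    "ERVGenePair",
    "upstream_window",
    "find_candidate_pairs",
    "spearman",
    "pair_correlations",
    "call_strong_pairs",
    "cluster_correlation_matrix",
    "genes_from_bed",
]

# smallest positive float: reported instead of an exact-zero p-value when
# rho = +/-1 makes the t approximation degenerate
_P_MIN = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int  # 0-based position
    strand: str  # + or - (required; "." not allowed for genes)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")


@dataclass
class ERVGenePair:
    erv_id: str
    gene_id: str
    distance_bp: int  # TSS to nearest repeat edge (0 if repeat spans TSS)
    rho: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    is_strong_pair: bool = False


def genes_from_bed(intervals) -> list[GeneModel]:
    """Interpret BED6 single-bp TSS records as gene models."""
    return [
        GeneModel(iv.name, iv.chrom, iv.start, iv.strand) for iv in intervals
    ]


def upstream_window(gene: GeneModel, w: int = 15_000) -> GenomicInterval | None:
    """The w-bp window upstream of the TSS, strand-aware; ``None`` when the
    window is empty (TSS at position 0 on the + strand)."""
    if w <= 0:
        raise ValueError("window size must be > 0")
    if gene.strand == "+":
        start = max(0, gene.tss - w)
        if start == gene.tss:
            return None
        return GenomicInterval(gene.chrom, start, gene.tss, "+", gene.gene_id)
    return GenomicInterval(gene.chrom, gene.tss, gene.tss + w, "-", gene.gene_id)


def find_candidate_pairs(
    repeats,
    genes: list[GeneModel],
    calls: list[EnhancerCall],
    w: int = 15_000,
) -> list[tuple[str, str, int]]:
    """(erv_id, gene_id, distance_bp) for every strong-called repeat that
    overlaps a gene's upstream window by >= 1 bp.

    A repeat may pair with several genes and vice versa; distance is from
    the TSS to the nearest repeat edge (0 when the repeat spans the TSS).
    """
    strong_ids = {
        c.sequence_id for c in calls if c.enhancer_class == CLASS_STRONG
    }
    out: list[tuple[str, str, int]] = []
    for gene in genes:
        win = upstream_window(gene, w)
        if win is None:
            continue
        for rep in repeats:
            iv = rep.interval
            if iv.name not in strong_ids or iv.overlap_bp(win) == 0:
                continue
            if iv.start <= gene.tss < iv.end:
                dist = 0
            elif iv.end <= gene.tss:
                dist = gene.tss - iv.end
            else:
                dist = iv.start - gene.tss
            out.append((iv.name, gene.gene_id, dist))
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with average ranks for ties and a two-sided p-value
    from the t approximation.

    Returns ``(nan, nan)`` for zero-variance input (rho undefined);
    |rho| = 1 reports an underflow-safe minimal p instead of zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("need n >= 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0 - 1e-12:  # perfect monotone up to float rounding
        return float(np.sign(rho)), _P_MIN
    return float(rho), float(max(p, _P_MIN))


def pair_correlations(
    candidates: list[tuple[str, str, int]], expr: ExpressionMatrix
) -> list[ERVGenePair]:
    """Correlate each candidate (erv, gene) across all samples; q-values by
    Benjamini-Hochberg over the candidate list."""
    from .pe_dysregulation import bh_adjust  # deferred: avoids import cycle

    features = set(expr.features)
    for erv_id, gene_id, _ in candidates:
        for fid in (erv_id, gene_id):
            if fid not in features:
                raise KeyError(f"feature {fid!r} missing from expression matrix")
    pairs = []
    for erv_id, gene_id, dist in candidates:
        rho, p = spearman(
            expr.values.loc[erv_id].to_numpy(),
            expr.values.loc[gene_id].to_numpy(),
        )
        pairs.append(ERVGenePair(erv_id, gene_id, dist, rho=rho, p_value=p))
    valid = [i for i, pr in enumerate(pairs) if np.isfinite(pr.p_value)]
    if valid:
        q = bh_adjust([pairs[i].p_value for i in valid])
        for i, qi in zip(valid, q):
            pairs[i].q_value = float(qi)
    return pairs


def call_strong_pairs(
    pairs: list[ERVGenePair], rho_min: float = 0.5, q_max: float = 0.05
) -> list[ERVGenePair]:
    """Flag pairs with rho >= rho_min and BH q <= q_max as strong."""
    return [
        replace(
            p,
            is_strong_pair=bool(
                np.isfinite(p.rho) and p.rho >= rho_min and p.q_value <= q_max
            ),
        )
        for p in pairs
    ]


def cluster_correlation_matrix(
    feature_ids: list[str],
    expr: ExpressionMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, float]:
    """k-means (Euclidean) over the rows of the pairwise Spearman
    correlation matrix of the given features.

    Returns ``(labels, within-cluster sum of squares)``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(feature_ids):
        raise ValueError(f"k={k} exceeds number of features {len(feature_ids)}")
    sub = expr.values.loc[feature_ids]
    corr = sub.T.corr(method="spearman").to_numpy()
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(corr)
    return labels, float(km.inertia_)
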