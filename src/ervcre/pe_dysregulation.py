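"""Preeclampsia dysregulation statistics.

The intersection stage of the analysis: DEG filtering (adjusted
p < 0.05 and |log2FC| > 1, strict inequalities), Benjamini-Hochberg
adjustment, a location/scale per-batch adjustment (a deliberate,
documented stand-in for empirical-Bayes batch correction, with a PCA
diagnostic of residual batch variance), per-gene relative abundance on
the linear scale, overexpression-in-PE hypergeometric enrichment with
exact log-binomial arithmetic, and shared-DEG log2FC correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .erv_gene_pairing import spearman
from .formats_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentInput",
    "filter_degs",
    "bh_adjust",
    "batch_center",
    "relative_abundance",
    "flag_high",
    "hypergeom_enrichment",
    "common_deg_correlation",
    "wilcoxon_de",
    "load_de_table",
]

DE_COLUMNS = ["gene", "log2fc", "pvalue", "padj"]


@dataclass(frozen=True)
class EnrichmentInput:
    """2x2 occupancy for the enrichment test: N samples in total, K flagged
    high overall, n in the PE group, k flagged high within PE."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid margins N={self.N}, K={self.K}, n={self.n}")
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(
                f"k={self.k} outside [0, min(K={self.K}, n={self.n})]"
            )


def load_de_table(path) -> pd.DataFrame:
    """Read a DE TSV with columns gene, log2fc, pvalue, padj."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing DE columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return df


def filter_degs(
    table: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    absolute: bool = True,
) -> pd.DataFrame:
    """Rows with padj < alpha and log2FC beyond lfc_min (strict inequalities).

    ``absolute`` applies the fold-change cut to |log2FC| (dysregulation in
    either direction); otherwise only upregulation passes.
    """
    lfc = table["log2fc"].abs() if absolute else table["log2fc"]
    kept = table[(table["padj"] < alpha) & (lfc > lfc_min)]
    logger.info("DEG filter kept %d of %d genes", len(kept), len(table))
    return kept.reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def batch_center(
    expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Per-batch location/scale adjustment of every gene.

    Within each batch a gene is standardised to mean 0 / unit variance,
    then restored to its pooled mean and pooled standard deviation.
    Genes with zero variance inside a batch skip the scale step (shift
    only) and are counted in the diagnostics.  Returns the adjusted
    matrix and a diagnostic dict with the variance in the top principal
    component explained by batch label before and after adjustment.
    """
    meta = expr.metadata.loc[expr.samples]
    batches = meta["batch"].unique()
    for b in batches:
        if (meta["batch"] == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    values = expr.values.to_numpy(dtype=float)
    pooled_mean = values.mean(axis=1, keepdims=True)
    # pooled sd in the statistical sense: the within-batch pooled standard
    # deviation, so the restored scale excludes between-batch variance
    var_acc = np.zeros(values.shape[0])
    n_acc = 0
    for b in batches:
        cols = np.asarray(meta["batch"] == b)
        sub = values[:, cols]
        var_acc += sub.var(axis=1, ddof=0) * cols.sum()
        n_acc += cols.sum()
    pooled_sd = np.sqrt(var_acc / n_acc)[:, None]

    adjusted = values.copy()
    n_zero_var = 0
    for b in batches:
        cols = np.asarray(meta["batch"] == b)
        sub = values[:, cols]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        zero = (sd == 0)[:, 0]
        n_zero_var += int(zero.sum())
        scale = np.where(sd == 0, 1.0, pooled_sd / np.where(sd == 0, 1.0, sd))
        scale = np.where(pooled_sd == 0, 1.0, scale)
        adjusted[:, cols] = (sub - mu) * scale + pooled_mean
    if n_zero_var:
        logger.warning("%d gene/batch cells had zero variance; scale skipped", n_zero_var)

    def _batch_pc_r2(mat: np.ndarray) -> float:
        pc1 = PCA(n_components=1).fit_transform(mat.T)[:, 0]
        group_means = np.array(
            [pc1[np.asarray(meta["batch"] == b)].mean() for b in batches]
        )
        counts = np.array([(meta["batch"] == b).sum() for b in batches])
        ss_between = float((counts * (group_means - pc1.mean()) ** 2).sum())
        ss_total = float(((pc1 - pc1.mean()) ** 2).sum())
        return 0.0 if ss_total == 0 else ss_between / ss_total

    diagnostics = {
        "batch_pc1_r2_before": _batch_pc_r2(values),
        "batch_pc1_r2_after": _batch_pc_r2(adjusted),
        "n_zero_variance_gene_batches": float(n_zero_var),
    }
    out = ExpressionMatrix(
        pd.DataFrame(adjusted, index=expr.values.index, columns=expr.values.columns),
        expr.metadata,
        log_scale=expr.log_scale,
    )
    return out, diagnostics


def relative_abundance(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene ratio of each sample's expression to the gene's mean.

    Computed on the linear scale (2**x for log2 input) because a ratio
    of log values is not a fold measure.  Per-gene mean of the ratios is
    exactly 1.
    """
    values = expr.values.to_numpy(dtype=float)
    linear = np.power(2.0, values) if expr.log_scale else values
    means = linear.mean(axis=1, keepdims=True)
    if (means <= 0).any():
        bad = expr.values.index[(means <= 0)[:, 0]].tolist()
        raise ValueError(f"zero/negative mean expression for genes {bad}")
    return pd.DataFrame(
        linear / means, index=expr.values.index, columns=expr.values.columns
    )


def flag_high(
    ra: pd.DataFrame, gene_id: str, threshold: float = 1.0
) -> set[str]:
    """Samples whose relative abundance of ``gene_id`` strictly exceeds
    ``threshold`` (i.e. lies above the gene's cross-sample mean)."""
    if gene_id not in ra.index:
        raise KeyError(f"gene {gene_id!r} not in relative-abundance matrix")
    row = ra.loc[gene_id]
    return set(row.index[row > threshold])


def hypergeom_enrichment(inp: EnrichmentInput) -> float:
    """One-sided upper-tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Summed term-by-term in log space (log-binomial coefficients via
    gammaln), so there is no factorial overflow even at N = 10,000.
    """
    def log_c(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    N, K, n, k = inp.N, inp.K, inp.n, inp.k
    if k <= max(0, K + n - N):
        return 1.0  # tail covers the whole support
    terms = []
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        terms.append(log_c(K, j) + log_c(N - K, n - j) - log_c(N, n))
    if not terms:
        return 0.0
    m = max(terms)
    return float(min(1.0, np.exp(m) * np.sum(np.exp(np.array(terms) - m))))


def common_deg_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[int, float, float]:
    """Filter both DE tables, intersect the gene sets, and correlate the
    shared genes' log2FC (Spearman).

    Returns ``(n_common, rho, p)``; with fewer than 4 shared genes rho/p
    are reported as NaN while n_common is still counted.
    """
    fa = filter_degs(a, alpha, lfc_min, absolute=True).set_index("gene")
    fb = filter_degs(b, alpha, lfc_min, absolute=True).set_index("gene")
    common = sorted(set(fa.index) & set(fb.index))
    if len(common) < 4:
        return len(common), float("nan"), float("nan")
    rho, p = spearman(
        fa.loc[common, "log2fc"].to_numpy(), fb.loc[common, "log2fc"].to_numpy()
    )
    return len(common), rho, p


def wilcoxon_de(expr: ExpressionMatrix, group_col: str = "condition",
                case: str = "PE", control: str = "control") -> pd.DataFrame:
    """Convenience two-group rank-sum DE with BH adjustment for synthetic
    data; the canonical input to the intersection stage is a pre-computed
    DE table from an external pipeline."""
    meta = expr.metadata.loc[expr.samples]
    case_cols = meta.index[meta[group_col] == case]
    ctrl_cols = meta.index[meta[group_col] == control]
    if len(case_cols) < 3 or len(ctrl_cols) < 3:
        raise ValueError("need >= 3 samples per group for rank-sum DE")
    rows = []
    for gene in expr.features:
        x = expr.values.loc[gene, case_cols].to_numpy(dtype=float)
        y = expr.values.loc[gene, ctrl_cols].to_numpy(dtype=float)
        lfc = float(x.mean() - y.mean())  # log-scale difference of means
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append((gene, lfc, max(p, np.finfo(float).tiny)))
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue"])
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    return df
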