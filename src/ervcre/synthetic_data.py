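"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study system —
a genome scattered with ERV/LTR repeats, a subset of which behave as
trophoblast enhancers (planted AP-1-like motif copies plus a GC-content
shift), H3K4me1-style ChIP peaks over those enhancer repeats, a
gene/ERV expression matrix with planted Spearman-correlated upstream
pairs, and a two-condition (control/preeclampsia) two-batch cohort with
a planted overexpressed gene — with full ground truth recorded so that
every downstream stage's recovery can be scored.

All generators are pure functions of ``(config, seed)``: identical
inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (
    CoverageTrack,
    ExpressionMatrix,
    GenomicInterval,
    Peak,
    RepeatAnnotation,
    SequenceRecord,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GenomeSim",
    "make_genome",
    "make_training_set",
    "make_chip",
    "make_expression",
    "make_de_tables",
    "consensus_counts",
    "spearman_to_pearson",
]

BASES = np.array(list("ACGT"))

# Human-like background composition: 41% GC keeps GC content a usable but
# not dominating feature next to the planted motif.
BACKGROUND_GC = 0.41


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's default conditions.

    Cohort sizes default to 24 preeclampsia / 22 control samples; the
    planted overexpression affects 60% of PE and ~25% (5/22) of control
    samples with a +1.5 log2 shift.
    """

    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_length: int = 600_000
    n_repeats: int = 60
    fraction_enhancer_repeats: float = 0.4
    motif: str = "TGACTCA"
    repeat_length_range: tuple[int, int] = (450, 700)
    n_genes: int = 30
    upstream_window: int = 15_000
    # training set
    n_pos: int = 200
    n_neg: int = 200
    seq_length: int = 600
    background_gc: float = BACKGROUND_GC
    gc_shift: float = 0.10
    # expression
    n_pe: int = 24
    n_control: int = 22
    planted_pair_rho: float = 0.9
    n_planted_pairs: int = 20
    batch_shift: float = 2.0
    expr_mean: float = 4.0
    expr_sd: float = 1.0
    overexpressed_gene: str = "EPS8L1"
    oe_shift: float = 1.5
    oe_noise_sd: float = 0.25
    pe_high_fraction: float = 0.60
    control_high_fraction: float = 0.25
    # DE tables
    n_de_genes: int = 400
    n_common_degs: int = 25
    de_log2fc_rho: float = 0.9
    # ChIP
    decoy_peak_fraction: float = 0.05
    peak_signal: float = 10.0
    background_signal: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_length", "n_repeats", "n_genes", "n_pos",
                     "n_neg", "seq_length", "n_pe", "n_control",
                     "n_planted_pairs", "n_de_genes", "n_common_degs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("fraction_enhancer_repeats", "background_gc", "gc_shift",
                     "pe_high_fraction", "control_high_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.planted_pair_rho <= 1:
            raise ValueError("planted_pair_rho must be in (0, 1]")
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over {A,C,G,T}")
        if self.seq_length < len(self.motif):
            raise ValueError("seq_length shorter than motif")
        if min(self.n_pe, self.n_control) < 3:
            raise ValueError("need >= 3 samples per condition")

    @property
    def n_enhancer_repeats(self) -> int:
        return round(self.n_repeats * self.fraction_enhancer_repeats)


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage."""

    enhancer_repeat_ids: set[str] = field(default_factory=set)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    pe_high_samples: set[str] = field(default_factory=set)
    control_high_samples: set[str] = field(default_factory=set)
    common_deg_ids: set[str] = field(default_factory=set)
    gene_ids: list[str] = field(default_factory=list)
    erv_ids: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "enhancer_repeat_ids": sorted(self.enhancer_repeat_ids),
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "pe_high_samples": sorted(self.pe_high_samples),
            "control_high_samples": sorted(self.control_high_samples),
            "common_deg_ids": sorted(self.common_deg_ids),
            "gene_ids": self.gene_ids,
            "erv_ids": self.erv_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            enhancer_repeat_ids=set(d["enhancer_repeat_ids"]),
            planted_pairs=[tuple(p) for p in d["planted_pairs"]],
            pe_high_samples=set(d["pe_high_samples"]),
            control_high_samples=set(d["control_high_samples"]),
            common_deg_ids=set(d["common_deg_ids"]),
            gene_ids=list(d["gene_ids"]),
            erv_ids=list(d["erv_ids"]),
        )


@dataclass
class GenomeSim:
    """In-memory product of :func:`make_genome`."""

    chromosomes: list[SequenceRecord]
    repeats: list[RepeatAnnotation]
    genes: list  # list[erv_gene_pairing.GeneModel]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# low-level sequence helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return BASES[rng.choice(4, size=length, p=p)]


def _plant_motifs(
    rng: np.random.Generator, seq: np.ndarray, motif: str, n_copies: int
) -> None:
    """Embed non-overlapping motif copies at random offsets, in place."""
    L, m = len(seq), len(motif)
    placed: list[int] = []
    attempts = 0
    while len(placed) < n_copies:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not place motif copies without overlap")
        pos = int(rng.integers(0, L - m + 1))
        if all(abs(pos - q) >= m for q in placed):
            seq[pos : pos + m] = list(motif)
            placed.append(pos)


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: the Pearson rho whose bivariate normal
    has Spearman correlation ``rho_s`` (rho_p = 2 sin(pi rho_s / 6))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def consensus_counts(motif: str, strength: int = 12, off: int = 1) -> np.ndarray:
    """A synthetic PWM count matrix (4 x L, rows A,C,G,T) concentrated on
    a consensus string — a stand-in for a JASPAR AP-1 count matrix built
    from the canonical TGACTCA consensus."""
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.full((4, len(motif)), off, dtype=float)
    for j, b in enumerate(motif):
        counts[idx[b], j] = strength
    return counts


# ---------------------------------------------------------------------------
# genome + repeats + genes
# ---------------------------------------------------------------------------


def make_genome(config: SimulationConfig) -> GenomeSim:
    """Simulate chromosomes with non-overlapping repeats and gene TSSs.

    A ``fraction_enhancer_repeats`` subset of repeats carries >= 2 embedded
    motif copies and a GC content elevated by ``gc_shift`` over the
    background; for each planted ERV-gene pair, one enhancer repeat is
    placed wholly within the 15-kb strand-aware upstream window of its
    gene's TSS.
    """
    from .erv_gene_pairing import GeneModel, upstream_window

    rng = np.random.default_rng(config.seed)
    n_enh = config.n_enhancer_repeats
    if config.n_planted_pairs > min(n_enh, config.n_genes):
        raise ValueError(
            "n_planted_pairs exceeds available enhancer repeats or genes"
        )

    w = config.upstream_window
    genes_per_chrom = math.ceil(config.n_genes / config.n_chrom)
    slot_w = config.chrom_length // genes_per_chrom
    max_rep_len = config.repeat_length_range[1]
    if slot_w < 2 * (w + 2000) + 4 * max_rep_len:
        raise ValueError(
            "genome too small to place requested repeats/genes without overlap"
        )

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    genes: list[GeneModel] = []
    # free zones (per chrom) well clear of every upstream window, for
    # placing repeats that must not create unplanned candidate pairs
    free_zones: list[tuple[str, int, int]] = []
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chrom]
        slot_idx = gi // config.n_chrom
        slot_start = slot_idx * slot_w
        tss = slot_start + int(rng.integers(w + 1000, slot_w - w - 1000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"GENE{gi:03d}", chrom, tss, strand))
        lo, hi = slot_start + 200, slot_start + slot_w - 200
        if tss - (w + 1000) - lo > 3 * max_rep_len:
            free_zones.append((chrom, lo, tss - (w + 1000)))
        if hi - (tss + w + 1000) > 3 * max_rep_len:
            free_zones.append((chrom, tss + w + 1000, hi))

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def try_place(chrom: str, start: int, end: int) -> bool:
        for s, e in placed[chrom]:
            if start < e and s < end:
                return False
        placed[chrom].append((start, end))
        return True

    repeats: list[RepeatAnnotation] = []
    truth = GroundTruth()
    enh_families = ["MLT1G1", "MLT1B", "MLT2B4", "LTR10A"]
    other_families = ["MER41B", "L1PA4", "AluY", "MIRb"]

    def rep_len() -> int:
        lo, hi = config.repeat_length_range
        return int(rng.integers(lo, hi + 1))

    # planted enhancer repeats: wholly inside the gene's upstream window
    pair_genes = list(rng.choice(len(genes), size=config.n_planted_pairs, replace=False))
    rep_idx = 0
    for gi in pair_genes:
        gene = genes[gi]
        win = upstream_window(gene, w)
        length = rep_len()
        for _ in range(200):
            start = int(rng.integers(win.start + 50, win.end - length - 50))
            if try_place(gene.chrom, start, start + length):
                break
        else:
            raise RuntimeError("could not place planted repeat in window")
        rid = f"ERV{rep_idx:04d}"
        rep_idx += 1
        fam = enh_families[rep_idx % len(enh_families)]
        iv = GenomicInterval(gene.chrom, start, start + length, ".", rid)
        repeats.append(RepeatAnnotation(iv, fam, "ERV3"))
        truth.enhancer_repeat_ids.add(rid)
        truth.planted_pairs.append((rid, gene.gene_id))

    # remaining repeats go into free zones far from every window
    def place_in_free_zone(length: int) -> GenomicInterval | None:
        for _ in range(500):
            zi = int(rng.integers(0, len(free_zones)))
            chrom, lo, hi = free_zones[zi]
            if hi - lo <= length:
                continue
            start = int(rng.integers(lo, hi - length))
            if try_place(chrom, start, start + length):
                return GenomicInterval(chrom, start, start + length, ".", "")
        return None

    n_extra_enh = n_enh - config.n_planted_pairs
    for i in range(config.n_repeats - config.n_planted_pairs):
        length = rep_len()
        iv = place_in_free_zone(length)
        if iv is None:
            raise RuntimeError(
                "genome too small to place requested repeats without overlap"
            )
        rid = f"ERV{rep_idx:04d}"
        rep_idx += 1
        iv = dataclasses.replace(iv, name=rid)
        is_enh = i < n_extra_enh
        fam = (enh_families if is_enh else other_families)[rep_idx % 4]
        sup = "ERV3" if is_enh else "other"
        repeats.append(RepeatAnnotation(iv, fam, sup))
        if is_enh:
            truth.enhancer_repeat_ids.add(rid)

    # chromosome sequences: background, enhancer repeats rewritten with
    # elevated GC and >= 2 planted motif copies
    enh_ids = truth.enhancer_repeat_ids
    chromosomes = []
    for chrom in chrom_names:
        seq = _random_seq(rng, config.chrom_length, config.background_gc)
        for rep in repeats:
            if rep.interval.chrom != chrom or rep.id not in enh_ids:
                continue
            s, e = rep.interval.start, rep.interval.end
            sub = _random_seq(rng, e - s, config.background_gc + config.gc_shift)
            _plant_motifs(rng, sub, config.motif, int(rng.integers(2, 4)))
            seq[s:e] = sub
        chromosomes.append(SequenceRecord(chrom, "".join(seq)))

    truth.gene_ids = [g.gene_id for g in genes]
    truth.erv_ids = [r.id for r in repeats]
    repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return GenomeSim(chromosomes, repeats, genes, truth)


# ---------------------------------------------------------------------------
# labelled training sequences
# ---------------------------------------------------------------------------


def make_training_set(config: SimulationConfig) -> tuple[list[SequenceRecord], np.ndarray]:
    """Labelled enhancer (1) / non-enhancer (0) sequences.

    Positives carry >= 2 motif copies at random offsets on a GC-elevated
    background; negatives are i.i.d. background in which chance motif
    occurrences are not suppressed.  Returns records and a parallel 0/1
    label array.
    """
    rng = np.random.default_rng(config.seed + 1)
    records: list[SequenceRecord] = []
    labels = []
    for i in range(config.n_pos):
        seq = _random_seq(rng, config.seq_length, config.background_gc + config.gc_shift)
        _plant_motifs(rng, seq, config.motif, int(rng.integers(2, 5)))
        records.append(SequenceRecord(f"pos_{i:04d}", "".join(seq)))
        labels.append(1)
    for i in range(config.n_neg):
        seq = _random_seq(rng, config.seq_length, config.background_gc)
        records.append(SequenceRecord(f"neg_{i:04d}", "".join(seq)))
        labels.append(0)
    return records, np.array(labels, dtype=int)


# ---------------------------------------------------------------------------
# ChIP peaks + coverage
# ---------------------------------------------------------------------------


def make_chip(
    config: SimulationConfig, genome: GenomeSim
) -> tuple[list[Peak], CoverageTrack]:
    """H3K4me1-like peaks over enhancer repeats plus a flat coverage track.

    Every enhancer repeat is covered by a peak with >= 50% reciprocal
    overlap (the peak is the repeat interval shifted by at most 1/8 of
    its length); ~5% additional decoy peaks fall off-repeat.  Coverage
    has plateau ``peak_signal`` over peaks and ``background_signal``
    elsewhere.
    """
    rng = np.random.default_rng(config.seed + 2)
    peaks: list[Peak] = []
    occupied: dict[str, list[tuple[int, int]]] = {c.id: [] for c in genome.chromosomes}
    for rep in genome.repeats:
        occupied.setdefault(rep.interval.chrom, []).append(
            (rep.interval.start, rep.interval.end)
        )

    pi = 0
    for rep in genome.repeats:
        if rep.id not in genome.truth.enhancer_repeat_ids:
            continue
        iv = rep.interval
        shift = int(rng.integers(-(len(iv) // 8), len(iv) // 8 + 1))
        start = max(0, iv.start + shift)
        end = min(config.chrom_length, iv.end + shift)
        peaks.append(
            Peak(
                GenomicInterval(iv.chrom, start, end, ".", f"peak_{pi:04d}"),
                signal=config.peak_signal,
                q_value=50.0,
            )
        )
        pi += 1

    n_decoy = max(1, round(config.decoy_peak_fraction * len(peaks)))
    chrom_names = [c.id for c in genome.chromosomes]
    for _ in range(n_decoy):
        for _attempt in range(500):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            length = int(rng.integers(*config.repeat_length_range))
            start = int(rng.integers(0, config.chrom_length - length))
            end = start + length
            clash = any(
                start < e and s < end for s, e in occupied.get(chrom, [])
            ) or any(
                p.interval.chrom == chrom
                and start < p.interval.end
                and p.interval.start < end
                for p in peaks
            )
            if not clash:
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, start, end, ".", f"peak_{pi:04d}"),
                        signal=config.peak_signal,
                        q_value=20.0,
                    )
                )
                pi += 1
                break

    # flat coverage: background everywhere, plateau over peaks
    steps: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in chrom_names:
        ch_peaks = sorted(
            (p.interval.start, p.interval.end)
            for p in peaks
            if p.interval.chrom == chrom
        )
        ch_steps = []
        cursor = 0
        for s, e in ch_peaks:
            if s > cursor:
                ch_steps.append((cursor, s, config.background_signal))
            ch_steps.append((s, e, config.peak_signal))
            cursor = e
        if cursor < config.chrom_length:
            ch_steps.append((cursor, config.chrom_length, config.background_signal))
        steps[chrom] = ch_steps
    return peaks, CoverageTrack(steps)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


def make_expression(
    config: SimulationConfig, truth: GroundTruth
) -> ExpressionMatrix:
    """Gene + ERV-locus expression on the log2(TPM+1) scale.

    Background entries are i.i.d. Normal(expr_mean, expr_sd).  Planted
    (erv, gene) pairs are drawn from a bivariate Gaussian whose Pearson
    correlation is chosen so the Spearman correlation targets
    ``planted_pair_rho`` (rho_p = 2 sin(pi rho_s / 6)).  Batch 2 samples
    receive an additive ``batch_shift``; the overexpressed gene is
    shifted by ``oe_shift`` in the planted high samples (60% of PE,
    5/22 of controls by default) on a tighter within-gene noise so the
    bimodal pattern is recoverable.  Updates ``truth.pe_high_samples``
    and ``truth.control_high_samples`` in place.
    """
    rng = np.random.default_rng(config.seed + 3)
    pe_samples = [f"PE_{i + 1:02d}" for i in range(config.n_pe)]
    ct_samples = [f"CT_{i + 1:02d}" for i in range(config.n_control)]
    samples = pe_samples + ct_samples
    n = len(samples)

    gene_ids = list(truth.gene_ids) if truth.gene_ids else [
        f"GENE{i:03d}" for i in range(config.n_genes)
    ]
    if config.overexpressed_gene not in gene_ids:
        gene_ids.append(config.overexpressed_gene)
    erv_ids = list(truth.erv_ids) if truth.erv_ids else [
        f"ERV{i:04d}" for i in range(config.n_repeats)
    ]
    features = gene_ids + erv_ids
    values = pd.DataFrame(
        rng.normal(config.expr_mean, config.expr_sd, size=(len(features), n)),
        index=features,
        columns=samples,
    )

    # planted correlated (erv, gene) pairs via the Gaussian copula
    rho_p = spearman_to_pearson(config.planted_pair_rho)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]]) * config.expr_sd**2
    for erv_id, gene_id in truth.planted_pairs:
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        values.loc[erv_id] = config.expr_mean + z[:, 0]
        values.loc[gene_id] = config.expr_mean + z[:, 1]

    # planted overexpression with tight within-gene noise
    k_pe = round(config.pe_high_fraction * config.n_pe)
    k_ct = int(config.control_high_fraction * config.n_control)  # 5.5 -> 5
    pe_high = sorted(rng.choice(pe_samples, size=k_pe, replace=False))
    ct_high = sorted(rng.choice(ct_samples, size=k_ct, replace=False))
    oe = config.overexpressed_gene
    values.loc[oe] = config.expr_mean + rng.normal(0, config.oe_noise_sd, size=n)
    values.loc[oe, pe_high + ct_high] += config.oe_shift
    truth.pe_high_samples = set(pe_high)
    truth.control_high_samples = set(ct_high)

    # two batches, balanced within each condition; additive shift on batch 2
    batch = {}
    for group in (pe_samples, ct_samples):
        for i, s in enumerate(group):
            batch[s] = 1 if i % 2 == 0 else 2
    batch2 = [s for s in samples if batch[s] == 2]
    values.loc[:, batch2] += config.batch_shift

    metadata = pd.DataFrame(
        {
            "condition": ["PE"] * config.n_pe + ["control"] * config.n_control,
            "batch": [batch[s] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(values, metadata)


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------


def make_de_tables(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Two DE tables with a planted common-DEG overlap.

    A configured set of genes passes the DEG filter (padj < 0.05 and
    |log2FC| > 1) in both tables with positively correlated log2FC; the
    remaining genes fail the filter in at least one table.  Returns
    ``(table_a, table_b, common_deg_ids)``.
    """
    rng = np.random.default_rng(config.seed + 4)
    n = config.n_de_genes
    k = config.n_common_degs
    if k + 30 > n:
        raise ValueError("n_de_genes too small for requested common DEGs")
    genes = [f"DEG{i:04d}" for i in range(n)]
    common = set(genes[:k])

    rho = config.de_log2fc_rho
    cov = np.array([[1.0, rho], [rho, 1.0]]) * 0.4**2

    rows_a, rows_b = [], []
    for i, g in enumerate(genes):
        if g in common:
            # correlated magnitudes safely past the fold-change cut, with a
            # random shared sign (dysregulation goes both ways)
            z = rng.multivariate_normal([2.2, 2.2], cov)
            z = np.clip(z, 1.2, None)
            sign = -1.0 if rng.random() < 0.5 else 1.0
            lfc_a, lfc_b = sign * z[0], sign * z[1]
            pa = float(rng.uniform(1e-8, 0.02))
            pb = float(rng.uniform(1e-8, 0.02))
            rows_a.append((g, lfc_a, pa / 2, pa))
            rows_b.append((g, lfc_b, pb / 2, pb))
            continue
        # 15 genes pass only in A, 15 only in B, the rest fail both
        passes_a = k <= i < k + 15
        passes_b = k + 15 <= i < k + 30
        for passes, rows in ((passes_a, rows_a), (passes_b, rows_b)):
            if passes:
                lfc = float(rng.uniform(1.2, 3.0)) * (1 if rng.random() < 0.5 else -1)
                p = float(rng.uniform(1e-6, 0.03))
            elif rng.random() < 0.5:
                lfc = float(rng.uniform(-0.9, 0.9))  # fails fold-change cut
                p = float(rng.uniform(1e-4, 1.0))
            else:
                lfc = float(rng.uniform(1.1, 2.5)) * (1 if rng.random() < 0.5 else -1)
                p = float(rng.uniform(0.06, 1.0))  # fails padj cut
            rows.append((g, lfc, p / 2, p))

    cols = ["gene", "log2fc", "pvalue", "padj"]
    return (
        pd.DataFrame(rows_a, columns=cols),
        pd.DataFrame(rows_b, columns=cols),
        common,
    )
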