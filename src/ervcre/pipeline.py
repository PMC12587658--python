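"""End-to-end orchestration of the analysis stages.

The full workflow on synthetic data: simulate -> train/score the
enhancer CNN -> ChIP/repeat intersection -> ERV-gene pairing ->
differential expression -> AP-1 motif scan -> PE dysregulation report.
Every stage writes plain standard-format outputs so any stage can be
re-run standalone on user data, and a run manifest records the funnel
counts, resolved parameters, seeds and versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import enhancer_cnn as cnn
from . import erv_gene_pairing as pairing
from . import motif_scan
from . import pe_dysregulation as pe
from . import signal_overlap
from . import synthetic_data as synth
from .formats_io import (
    GenomicInterval,
    SequenceRecord,
    write_bed,
    write_bedgraph,
    write_expression,
    write_fasta,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline"]


@dataclass
class OverlapConfig:
    min_frac: float = 0.5
    n_bins: int = 10
    flank_bp: int = 1000
    flank_bin_bp: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.min_frac <= 1:
            raise ValueError("overlap.min_frac must be in [0, 1]")
        if self.n_bins < 1:
            raise ValueError("overlap.n_bins must be >= 1")


@dataclass
class PairingConfig:
    window: int = 15_000
    rho_min: float = 0.5
    q_max: float = 0.05
    kmeans_k: int = 7  # config-exposed; stylistic default

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("pairing.window must be > 0")


@dataclass
class DysregulationConfig:
    alpha: float = 0.05
    lfc_min: float = 1.0
    flag_threshold: float = 1.0
    batch_adjust: bool = True


@dataclass
class StageToggles:
    simulate: bool = True
    train: bool = True
    score: bool = True
    intersect: bool = True
    pair: bool = True
    de: bool = True
    scan: bool = True
    dysregulate: bool = True


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "ervcre_run"
    simulation: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    classifier: cnn.ClassifierConfig = field(default_factory=cnn.ClassifierConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    scan: motif_scan.ScanConfig = field(default_factory=motif_scan.ScanConfig)
    dysregulation: DysregulationConfig = field(default_factory=DysregulationConfig)
    stages: StageToggles = field(default_factory=StageToggles)

    def resolved(self) -> "PipelineConfig":
        """Propagate the global seed into every stochastic stage."""
        sim = dataclasses.replace(self.simulation, seed=self.seed)
        clf = dataclasses.replace(self.classifier, seed=self.seed)
        return dataclasses.replace(self, simulation=sim, classifier=clf)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier"]["conv_blocks"] = [
            list(b) for b in d["classifier"]["conv_blocks"]
        ]
        d["simulation"]["repeat_length_range"] = list(
            d["simulation"]["repeat_length_range"]
        )
        return d


_SECTIONS = {
    "simulation": synth.SimulationConfig,
    "classifier": cnn.ClassifierConfig,
    "overlap": OverlapConfig,
    "pairing": PairingConfig,
    "scan": motif_scan.ScanConfig,
    "dysregulation": DysregulationConfig,
    "stages": StageToggles,
}


def validate_config(path) -> PipelineConfig:
    """Load, schema-check and default-fill a YAML pipeline config.

    Unknown keys are rejected with a path-to-key diagnostic; an empty
    file yields all defaults.  Every resolved parameter is echoed to the
    log so there are no silent defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in ("seed", "outdir"):
            kwargs[key] = value
            continue
        if key not in _SECTIONS:
            raise ValueError(f"{path}: unknown section {key!r}")
        cls = _SECTIONS[key]
        if not isinstance(value, dict):
            raise ValueError(f"{path}: section {key!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(value) - valid
        if unknown:
            raise ValueError(
                f"{path}: unknown key(s) {sorted(unknown)} in section {key!r}"
            )
        coerced = dict(value)
        if key == "classifier" and "conv_blocks" in coerced:
            coerced["conv_blocks"] = [tuple(b) for b in coerced["conv_blocks"]]
        if key == "simulation" and "repeat_length_range" in coerced:
            coerced["repeat_length_range"] = tuple(coerced["repeat_length_range"])
        try:
            kwargs[key] = cls(**coerced)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: section {key!r}: {exc}") from exc
    config = PipelineConfig(**kwargs)
    for line in yaml.safe_dump(config.to_dict(), sort_keys=True).splitlines():
        logger.info("config: %s", line)
    return config


@dataclass
class RunManifest:
    seed: int
    counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute enabled stages in dependency order; outputs land in
    ``config.outdir`` and the manifest records the funnel counts."""
    config = config.resolved()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    manifest = RunManifest(
        seed=config.seed,
        parameters=config.to_dict(),
        versions={"ervcre": __version__, "numpy": np.__version__},
    )

    def check_dep(stage: str, dep: str) -> None:
        if not getattr(stages, dep):
            raise StageError(
                stage, f"requires stage {dep!r}, which is disabled"
            )

    timer: dict[str, float] = {}

    def tic(stage: str) -> None:
        timer[stage] = time.perf_counter()
        logger.info("stage %s: start", stage)

    def toc(stage: str) -> None:
        manifest.stage_seconds[stage] = round(time.perf_counter() - timer[stage], 3)

    genome = peaks = track = expr = None
    records = labels = None
    calls: list[cnn.EnhancerCall] = []

    # -- simulate ----------------------------------------------------------
    if stages.simulate:
        tic("simulate")
        genome = synth.make_genome(config.simulation)
        records, labels = synth.make_training_set(config.simulation)
        peaks, track = synth.make_chip(config.simulation, genome)
        expr = synth.make_expression(config.simulation, genome.truth)
        de_a, de_b, common_ids = synth.make_de_tables(config.simulation)
        genome.truth.common_deg_ids = common_ids

        write_fasta(genome.chromosomes, outdir / "genome.fa")
        write_bed(genome.repeats, outdir / "repeats.tsv", kind="repeat_table")
        tss_rows = [
            GenomicInterval(g.chrom, g.tss, g.tss + 1, g.strand, g.gene_id)
            for g in genome.genes
        ]
        write_bed(tss_rows, outdir / "tss.bed", kind="bed6")
        write_bed(peaks, outdir / "peaks.narrowPeak", kind="narrowPeak")
        write_bedgraph(track, outdir / "coverage.bedgraph")
        write_fasta(
            [r for r, l in zip(records, labels) if l == 1], outdir / "train_pos.fa"
        )
        write_fasta(
            [r for r, l in zip(records, labels) if l == 0], outdir / "train_neg.fa"
        )
        write_expression(expr, outdir / "expr.tsv", outdir / "meta.tsv")
        de_a.to_csv(outdir / "de_oe.tsv", sep="\t", index=False)
        de_b.to_csv(outdir / "de_pe.tsv", sep="\t", index=False)
        genome.truth.to_json(outdir / "ground_truth.json")
        manifest.counts["n_repeats"] = len(genome.repeats)
        manifest.counts["n_enhancer_repeats_truth"] = len(
            genome.truth.enhancer_repeat_ids
        )
        toc("simulate")

    # -- train -------------------------------------------------------------
    model = None
    if stages.train:
        check_dep("train", "simulate")
        tic("train")
        L = config.classifier.input_length
        examples = []
        for rec, lab in zip(records, labels):
            ex = cnn.one_hot_encode(rec, L)
            ex.label = int(lab)
            examples.append(ex)
        train_set, test_set = cnn.split_train_test(
            examples, config.classifier.test_fraction, config.seed
        )
        model, loss_log = cnn.train(train_set, config.classifier)
        preds = cnn.predict_proba(model, test_set)
        acc = float(
            np.mean(
                [
                    (p >= 0.5) == bool(ex.label)
                    for (_, p), ex in zip(preds, test_set)
                ]
            )
        )
        cnn.save_model(model, outdir / "model.npz")
        manifest.counts["train_final_loss"] = loss_log[-1]
        manifest.counts["heldout_accuracy"] = acc
        toc("train")

    # -- score -------------------------------------------------------------
    if stages.score:
        check_dep("score", "train")
        tic("score")
        chrom_seq = {c.id: c.sequence for c in genome.chromosomes}
        repeat_records = [
            SequenceRecord(
                r.id, chrom_seq[r.interval.chrom][r.interval.start : r.interval.end]
            )
            for r in genome.repeats
        ]
        encoded = [
            cnn.one_hot_encode(rec, config.classifier.input_length)
            for rec in repeat_records
        ]
        probs = cnn.predict_proba(model, encoded)
        calls = [
            cnn.EnhancerCall(sid, p, cnn.classify(p, config.classifier))
            for sid, p in probs
        ]
        with open(outdir / "calls.tsv", "w") as fh:
            fh.write("id\tprobability\tclass\n")
            for c in calls:
                fh.write(f"{c.sequence_id}\t{c.probability:.6f}\t{c.enhancer_class}\n")
        for klass in ("strong", "weak", "non"):
            manifest.counts[f"n_{klass}"] = sum(
                1 for c in calls if c.enhancer_class == klass
            )
        toc("score")

    # -- intersect ---------------------------------------------------------
    if stages.intersect:
        check_dep("intersect", "simulate")
        tic("intersect")
        kept = signal_overlap.subtract_blacklist(peaks, [])
        hits = signal_overlap.intersect_annotations(
            kept, genome.repeats, min_frac=config.overlap.min_frac
        )
        mat = signal_overlap.signal_matrix(
            track,
            genome.repeats,
            n_bins=config.overlap.n_bins,
            flank_bp=config.overlap.flank_bp,
            flank_bin_bp=config.overlap.flank_bin_bp,
        )
        np.savetxt(
            outdir / "signal_matrix.tsv",
            mat.values,
            delimiter="\t",
            header="\t".join(str(i) for i in range(mat.values.shape[1])),
        )
        manifest.counts["n_peak_repeat_pairs"] = len(hits)
        manifest.counts["n_chip_supported_repeats"] = len(
            {rep.id for _, rep in hits}
        )
        toc("intersect")

    # -- pair --------------------------------------------------------------
    strong_pairs: list[pairing.ERVGenePair] = []
    adjusted = None
    if stages.pair:
        check_dep("pair", "score")
        tic("pair")
        candidates = pairing.find_candidate_pairs(
            genome.repeats, genome.genes, calls, w=config.pairing.window
        )
        adjusted, diag = pe.batch_center(expr)
        manifest.diagnostics["batch"] = diag
        corr_pairs = pairing.pair_correlations(candidates, adjusted)
        scored = pairing.call_strong_pairs(
            corr_pairs, rho_min=config.pairing.rho_min, q_max=config.pairing.q_max
        )
        strong_pairs = [p for p in scored if p.is_strong_pair]
        with open(outdir / "pairs.tsv", "w") as fh:
            fh.write("erv_id\tgene_id\tdistance_bp\trho\tp\tq\tstrong\n")
            for p in scored:
                fh.write(
                    f"{p.erv_id}\t{p.gene_id}\t{p.distance_bp}\t{p.rho:.4f}\t"
                    f"{p.p_value:.3e}\t{p.q_value:.3e}\t{int(p.is_strong_pair)}\n"
                )
        manifest.counts["n_candidate_pairs"] = len(candidates)
        manifest.counts["n_strong_pairs"] = len(strong_pairs)
        toc("pair")

    # -- differential expression ------------------------------------------
    degs = None
    if stages.de:
        check_dep("de", "simulate")
        tic("de")
        source = adjusted if adjusted is not None else expr
        de_table = pe.wilcoxon_de(source)
        de_table.to_csv(outdir / "de_cohort.tsv", sep="\t", index=False)
        degs = set(
            pe.filter_degs(
                de_table,
                alpha=config.dysregulation.alpha,
                lfc_min=config.dysregulation.lfc_min,
            )["gene"]
        )
        pairs_after_de = [p for p in strong_pairs if p.gene_id in degs]
        de_a, de_b, _ = synth.make_de_tables(config.simulation)
        n_common, rho_c, p_c = pe.common_deg_correlation(
            de_a,
            de_b,
            alpha=config.dysregulation.alpha,
            lfc_min=config.dysregulation.lfc_min,
        )
        manifest.counts["n_degs_cohort"] = len(degs)
        manifest.counts["n_pairs_after_de"] = len(pairs_after_de)
        manifest.counts["n_common_degs"] = n_common
        manifest.counts["common_deg_log2fc_rho"] = rho_c
        toc("de")

    # -- motif scan --------------------------------------------------------
    if stages.scan:
        check_dep("scan", "simulate")
        tic("scan")
        pwm = motif_scan.normalize_pwm(
            motif_scan.PWMCounts(
                synth.consensus_counts(config.simulation.motif)
            ),
            config.scan.pseudocount,
        )
        scan_cfg = dataclasses.replace(
            config.scan, window=pwm.length
        )
        chrom_seq = {c.id: c.sequence for c in genome.chromosomes}
        n_hits = 0
        with open(outdir / "motif_hits.tsv", "w") as fh:
            fh.write("seq_id\tstart\tkmer\traw\tnormalized\tpasses\n")
            for rep in genome.repeats:
                rec = SequenceRecord(
                    rep.id,
                    chrom_seq[rep.interval.chrom][
                        rep.interval.start : rep.interval.end
                    ],
                )
                for h in motif_scan.scan_sequence(rec, pwm, scan_cfg):
                    if h.passes:
                        n_hits += 1
                        fh.write(
                            f"{rep.id}\t{h.start}\t{h.kmer}\t{h.raw_score:.4f}\t"
                            f"{h.normalized_score:.4f}\t1\n"
                        )
        manifest.counts["n_motif_hits"] = n_hits
        toc("scan")

    # -- dysregulation -----------------------------------------------------
    if stages.dysregulate:
        check_dep("dysregulate", "de")
        tic("dysregulate")
        source = expr
        if config.dysregulation.batch_adjust:
            if adjusted is None:
                adjusted, diag = pe.batch_center(expr)
                manifest.diagnostics["batch"] = diag
            source = adjusted
        ra = pe.relative_abundance(source)
        oe = config.simulation.overexpressed_gene
        flagged = pe.flag_high(ra, oe, config.dysregulation.flag_threshold)
        pe_samples = set(source.condition_samples("PE"))
        inp = pe.EnrichmentInput(
            N=len(source.samples),
            K=len(flagged),
            n=len(pe_samples),
            k=len(flagged & pe_samples),
        )
        p_enrich = pe.hypergeom_enrichment(inp)
        report = {
            "gene": oe,
            "N": inp.N,
            "K": inp.K,
            "n": inp.n,
            "k": inp.k,
            "hypergeometric_p": p_enrich,
            "flag_threshold": config.dysregulation.flag_threshold,
            "batch_adjusted": config.dysregulation.batch_adjust,
        }
        with open(outdir / "dysregulation.json", "w") as fh:
            json.dump(report, fh, indent=1)
        manifest.counts["enrichment_p"] = p_enrich
        manifest.counts.update(
            {"enrichment_N": inp.N, "enrichment_K": inp.K,
             "enrichment_n": inp.n, "enrichment_k": inp.k}
        )
        toc("dysregulate")

    manifest.outputs = {
        p.name: str(p) for p in sorted(outdir.iterdir()) if p.is_file()
    }
    manifest.to_json(outdir / "manifest.json")
    return manifest
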