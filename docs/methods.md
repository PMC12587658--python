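# Methods

This note documents the models and procedures implemented in `ervcre`,
the defaults chosen where the underlying analysis left a choice open,
and what the synthetic benchmark does and does not demonstrate.

## Coordinates and formats

All intervals are 0-based half-open (BED convention); 1-based inputs
must be converted at the boundary. Strand `.` is accepted for peaks and
repeats but genes require `+`/`−` because the upstream window is
strand-aware. Soft-masked (lowercase) FASTA is uppercased on read with
the masked fraction recorded per record, since repeat sequences are
routinely soft-masked and that signal should not vanish silently.
'N' bases are permitted; each consumer states its own handling (below).

## Enhancer classifier

A 1D CNN over one-hot DNA (rows A,C,G,T; N encodes as an all-zero
column) with a GC-content scalar concatenated before the dense layer.

Defaults: input length 600 bp (longer sequences centre-cropped, shorter
symmetrically zero-padded; GC is computed on the *uncropped* sequence so
cropping cannot change it); two conv blocks (32 filters × width 12,
max-pool 4; 64 × 8, pool 4); global max pooling; 32-unit dense with
dropout 0.25; sigmoid output; Adam at 1e-3, batch 32, 15 epochs. The
capacity is deliberately minimal — enough to act as a motif detector
while training on a single CPU in seconds. All randomness (weight
init, shuffling, dropout) flows from one seed, so a training run is
exactly reproducible; the model serialises to a single self-describing
artifact (config + weights).

Probability cut-points for the strong/weak/non classes are not fixed by
the underlying analysis; the defaults 0.8/0.5 are config-exposed and
inclusive at each class's lower edge. Scoring is single-strand: the
probability is computed for the sequence as given, with no
reverse-complement averaging.

A practical note on the GC feature: a convolutional network with
max-pooled motif detectors can infer base composition from the one-hot
input alone (filters matching GC-rich k-mers activate more often in
GC-rich sequence), so removing the GC scalar does *not* reduce a
composition-only task to chance. The tests therefore verify the
feature's wiring directly — a composition-only task is learnable and
the output responds to the gc input — rather than expecting chance-level
ablation.

## ChIP intersection and signal matrices

Reciprocal overlap follows bedtools semantics with inclusive
comparisons: a (peak, repeat) pair is kept iff the overlap covers at
least `min_frac` (default 0.5) of *both* intervals; reciprocity makes
the query/subject roles symmetric. The implementation is a sorted sweep
with a prefix-maximum of interval ends, verified against an O(n·m)
brute force. Blacklist exclusion uses any-overlap (≥ 1 bp), the common
practice for ENCODE blacklists; no overlap fraction applies there.

Signal matrices follow deepTools scale-regions logic: each region body
is resampled to `n_bins` equal sub-windows and flanks are binned at a
fixed bp-per-bin; each bin value is the length-weighted mean of the
step-function coverage (uncovered positions count 0, including
positions beyond the chromosome start), so binning exactly conserves
the integrated signal. Minus-strand rows are column-reversed. Regions
shorter than `n_bins` are retained with fractional bin boundaries and a
warning.

## ERV–gene pairing

The upstream window is [tss − w, tss) on `+` genes and [tss, tss + w)
on `−` genes, w = 15,000 bp by default, clamped at the chromosome
start. A strong-called repeat becomes a candidate when it overlaps the
window by ≥ 1 bp (full containment is not required); a repeat may pair
with several genes and vice versa.

Spearman ρ uses average ranks for ties with the two-sided t
approximation; |ρ| = 1 reports the smallest positive float rather than
p = 0, and zero-variance input yields NaN (flagged, excluded from BH).
Candidates are adjusted with Benjamini–Hochberg; strong pairs require
ρ ≥ 0.5 and q ≤ 0.05 (both config-exposed — the thresholds are
conventional, transparent, and validated against planted truth rather
than derived from the source analysis, which does not state them).
Correlation should be computed on batch-adjusted expression: an
additive batch effect common to all features otherwise induces
spurious positive correlation between every feature pair.

k-means clustering of the pairwise Spearman correlation matrix uses
Euclidean distance on matrix rows (scikit-learn, seeded, 10 restarts);
k defaults to 7 and is a stylistic choice, config-exposed.

## Motif scanning

The PWM arrives as JASPAR-style counts; probabilities are
(count + pseudocount) / (colsum + 4·pseudocount) with pseudocount 1.
The raw window score is Σᵢ ln(p[baseᵢ, i] + ε) with ε = 1e-6. Two
log-transform variants circulate for this procedure — ln(p + 1) and
ln(p + ε); ln(p + 1) makes every score positive and destroys the
interpretability of thresholding a sum of log-probabilities, so
ln(p + ε) is implemented and ε is config-exposed. Normalised scores
are min–max over the PWM's attainable range (per-column max/min sums),
mapping the consensus to exactly 1 and the anti-consensus to 0; the
method is exhaustively checkable at motif length 7 (4⁷ = 16,384
k-mers). Both a raw-score threshold (default 8) and a normalised
threshold (default 0.5) are supported behind an explicit `mode`; the
two defaults are mutually inconsistent (raw log-probability sums are
negative), which is why the mode must be chosen explicitly. An N in a
window scores as uniform composition, ln(0.25 + ε); `drop_n_windows`
gives the stricter behaviour. Scanning is forward-strand by default
(an LTR consensus has a defined orientation); `both_strands` adds
reverse-complement scanning with strand reported.

## PE dysregulation

DEG filtering keeps rows with adjusted p < 0.05 **and** |log2FC| > 1,
strict inequalities (a row at exactly padj = 0.05 or |log2FC| = 1
fails); `absolute=False` restricts to upregulation. The adjustment
behind "adjusted p" is taken to be Benjamini–Hochberg.

Batch adjustment is a deliberate location/scale stand-in, not a
re-implementation of empirical-Bayes batch correction (ComBat), which
is an established external method: within each batch every gene is
standardised and then restored to its pooled mean and *pooled
(within-batch) standard deviation* — pooled in the statistical sense,
so the restored scale excludes the between-batch variance being
removed. A PCA diagnostic reports the variance in PC1 explained by
batch label before and after, so residual batch structure is visible.
Genes with zero variance inside a batch skip the scale step (shift
only) and are counted.

Relative abundance is each sample's expression divided by the gene's
cross-sample mean, computed on the linear scale (2^x for log2 input)
because a ratio of log values is not a fold measure; by construction
the per-gene mean ratio is 1. "Relatively high" means ratio strictly
> 1 (above the gene's mean; a median reference is available by flag).
The enrichment p-value is the exact one-sided upper tail
P(X ≥ k) of the hypergeometric distribution, evaluated term-by-term in
log space with gammaln binomial coefficients (no overflow to at least
N = 10,000) and exchange-symmetric in (K, n).

At the study's cohort sizes — 46 samples, 24 PE — with the
overexpressed gene high in round(0.60·24) = 14 PE samples and 5 of 22
controls, the p-value is 0.0150; with 6 of 22 controls it is 0.0333.
Only the former rounding of the half-integer 5.5 is consistent with an
enrichment bound of 0.03, so the generator plants 5 control highs
(22.7%, i.e. "~25%").

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (config, seed); identical inputs
give byte-identical outputs. Defaults define the benchmark conditions:

- **Genome**: 2 chromosomes × 600 kb, background GC 0.41 (human-like);
  60 non-overlapping repeats of 450–700 bp, 40% of them "enhancer"
  repeats carrying 2–4 embedded copies of TGACTCA and GC elevated by
  +0.10; 30 genes with random strand; 20 planted (ERV, gene) pairs with
  the repeat wholly inside the gene's 15-kb upstream window. The
  planted enhancer signal is motif presence plus a GC shift because
  those are exactly the two feature families the classifier consumes.
- **Training set**: 200 positives (≥ 2 motif copies, GC-shifted) and
  200 negatives (i.i.d. background; chance motif occurrences are not
  suppressed), 600 bp each.
- **ChIP**: every enhancer repeat covered by a peak of the same length
  shifted by at most 1/8 of it (reciprocal overlap ≥ 75%); ~5% decoy
  peaks off-repeat; coverage 10 over peaks, 1 elsewhere.
- **Expression**: features = genes ∪ ERV loci on the log2(TPM+1)
  scale, background i.i.d. Normal(4, 1); planted pairs drawn from a
  bivariate Gaussian with Pearson ρ = 2·sin(π·ρ_s/6) targeting Spearman
  ρ_s = 0.9; 24 PE / 22 control samples in two batches balanced within
  condition, batch 2 shifted by +2; the overexpressed gene (EPS8L1)
  drawn at Normal(4, 0.25²) with +1.5 in 14 PE and 5 control samples.
  The tight within-gene sd makes the planted high/low dichotomy
  unambiguous (6σ), which is what a clearly bimodal overexpression
  pattern across a cohort looks like and what the recovery guarantees
  of the benchmark presuppose; background features keep sd 1.
- **DE tables**: 400 genes each; 25 planted common DEGs passing the
  filter in both tables with log2FC drawn at target correlation 0.9
  and a shared random sign; 15 genes pass in only one table each;
  everything else fails padj or the fold-change cut.

What the benchmark does **not** emulate: read-level noise, alignment
and peak-calling artifacts, realistic ChIP signal shapes, linked
repeats (each locus is independent), multi-mapping ambiguity of ERV
expression quantification (the matrix is locus-resolved by fiat),
non-Gaussian expression marginals, and confounded batch/condition
designs. Passing tests therefore demonstrate correctness of the
implemented statistics and recoverability of planted signals under
clean conditions — not performance on real cohort data.

## Problem sizes

The default benchmark was sized so a full pipeline run (simulation,
CNN training, all downstream stages) completes in well under a minute
on one CPU: 400 training sequences, 60 repeats, 46 samples, 100
replicate cohorts for the enrichment success rate. All sizes are
config fields and scale up trivially.

## Known limitations

- The CNN is a minimal motif detector; it is not intended to transfer
  to real enhancer compendia without retraining, and no saliency or
  interpretability tooling is provided.
- The batch stand-in removes location/scale effects only; non-linear
  platform effects need a real ComBat/SVA run upstream.
- The DE convenience routine (two-group rank-sum + BH) exists for
  synthetic data; real analyses should supply DE tables from a
  dedicated pipeline.
- bigWig and BAM are out of scope; bedGraph and narrowPeak stand in.
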